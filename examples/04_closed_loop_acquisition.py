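"""Uncertainty-driven closed-loop acquisition versus a static mask.

Starts from a sparser Poisson-disc mask and lets the adaptive policy spend
the remaining sampling budget where topology uncertainty points, then
compares Betti deviation against plain CS on a static mask with the same
final acceleration.
"""

import numpy as np

from vascsense import (NoiseModel, PhantomSpec, PolicyConfig, ReconConfig,
                       TopologyConfig, betti_deviation, cs_reconstruct,
                       generate_vascular_phantom, poisson_disc_mask,
                       run_closed_loop, simulate_kspace)
from vascsense.experiments import ExperimentConfig
from vascsense.topology import diagrams_from_image

cfg = ExperimentConfig(seed=0)
img, truth = generate_vascular_phantom(cfg.phantom)
ks = simulate_kspace(img, cfg.noise, seed=1)
total = int(np.prod(cfg.phantom.grid_shape))

static = poisson_disc_mask(cfg.phantom.grid_shape, cfg.accel_target,
                           cfg.min_radius, cfg.center_fraction, seed=3)
x_cs = cs_reconstruct(ks.restrict(static), cfg.recon)
_, g_cs = diagrams_from_image(x_cs, cfg.topo)

a0 = cfg.accel_target + cfg.budget * cfg.policy.batch_size / total
init = poisson_disc_mask(cfg.phantom.grid_shape, a0, cfg.min_radius,
                         cfg.center_fraction, seed=3)
final_mask, recon, log = run_closed_loop(
    ks, init, cfg.budget, cfg.full_recon_cfg(), cfg.policy, cfg.topo,
    ref_graph=truth, tol_rel=None)
_, g_ad = diagrams_from_image(recon, cfg.topo)

print("closed-loop iteration log:")
print(log.to_string(index=False))
print(f"\nstatic CS      @ accel {static.acceleration:.3f}: "
      f"Betti deviation {betti_deviation(g_cs, truth):.3f}")
print(f"adaptive loop  @ accel {final_mask.acceleration:.3f}: "
      f"Betti deviation {betti_deviation(g_ad, truth):.3f}")
# The adaptive run reallocates the same sampling budget toward k-space
# regions that stabilize fragile vessels, typically recovering connectivity
# that the static mask misses.
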