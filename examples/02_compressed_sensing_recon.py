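"""Undersampled acquisition and compressed-sensing reconstruction.

Builds a variable-density Poisson-disc mask at 70% acceleration, reconstructs
with wavelet-sparsity FISTA, and compares against the full reconstructor
(Hankel structured low-rank prior + vessel-enhancing regularization + exact
data consistency).
"""

from dataclasses import replace

from vascsense import (NoiseModel, PhantomSpec, ReconConfig, cs_reconstruct,
                       generate_vascular_phantom, nmse, poisson_disc_mask,
                       psnr, reconstruct_full, simulate_kspace, ssim)
from vascsense.recon import HankelConfig, TopoRegConfig

img, truth = generate_vascular_phantom(
    PhantomSpec(grid_shape=(96, 96), n_main_branches=5,
                n_collateral_loops=2, seed=0))
ks = simulate_kspace(img, NoiseModel(0.06), seed=1)
mask = poisson_disc_mask((96, 96), target_acceleration=0.70, min_radius=1.2,
                         center_fraction=0.08, seed=2)
print(f"mask: {mask.mask.sum()} of {mask.mask.size} samples "
      f"(acceleration {mask.acceleration:.3f})")
y = ks.restrict(mask)

cfg = ReconConfig(lambda_reg=1e-2, max_iterations=80)
x_cs = cs_reconstruct(y, cfg)
x_hankel = reconstruct_full(y, replace(cfg, hankel=HankelConfig(enabled=True)))
x_topo = reconstruct_full(y, replace(cfg, hankel=HankelConfig(enabled=True),
                                     topo=TopoRegConfig(enabled=True)))

for name, x in [("zero-filled", y.zero_filled_image()),
                ("CS (wavelet l1)", x_cs),
                ("CS + Hankel + DC", x_hankel),
                ("CS + Hankel + vessel reg", x_topo)]:
    print(f"{name:>25s}: PSNR {psnr(img, x):6.2f} dB  "
          f"SSIM {ssim(img, x):.3f}  NMSE {nmse(img, x):.4f}")
# The Hankel prior and the final data-consistency projection match or
# slightly improve plain CS; the vessel-enhancing regularization trades a
# little pixelwise fidelity for vessel continuity (see the topology example).
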