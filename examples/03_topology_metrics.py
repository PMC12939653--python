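"""Vascular graph extraction and persistent-homology topology metrics.

Extracts the vessel graph from a reconstruction, computes Betti deviation and
branch completeness against the known ground truth, superlevel-set
persistence diagrams, the topology-aware uncertainty U over a stochastic
reconstruction ensemble, and the composite macro uncertainty.
"""

from vascsense import (NoiseModel, PhantomSpec, ReconConfig, TopologyConfig,
                       betti_deviation, branch_completeness,
                       generate_vascular_phantom, macro_uncertainty,
                       persistence_stability, poisson_disc_mask,
                       simulate_kspace, stochastic_realizations,
                       superlevel_persistence, topology_uncertainty,
                       vesselness, extract_graph, prune_graph)

img, truth = generate_vascular_phantom(
    PhantomSpec(grid_shape=(96, 96), n_main_branches=5,
                n_collateral_loops=2, seed=3))
ks = simulate_kspace(img, NoiseModel(0.06), seed=4)
mask = poisson_disc_mask((96, 96), 0.70, 1.2, 0.08, seed=5)
y = ks.restrict(mask)
cfg = ReconConfig(lambda_reg=1e-2, max_iterations=80)
tc = TopologyConfig()

from vascsense import reconstruct_full
recon = reconstruct_full(y, cfg)
g = prune_graph(extract_graph(vesselness(recon, tc.scales_mm),
                              tc.vesselness_threshold),
                tc.prune_min_length_mm)
print(f"truth:  beta0={truth.betti0()} beta1={truth.betti1()}")
print(f"recon:  beta0={g.betti0()} beta1={g.betti1()}")
dbeta = betti_deviation(g, truth)
bc = branch_completeness(g, truth, tol_mm=1.0)
print(f"Betti deviation: {dbeta:.3f}  branch completeness: {bc:.2f}")

d0, d1 = superlevel_persistence(g)
print(f"persistence: {len(d0.births)} dim-0 classes "
      f"({len(d0.essential_births)} essential), "
      f"{len(d1.births)} dim-1 (loop) classes")

ens = stochastic_realizations(y, cfg, K=4, perturb_scale=1.0, seed=6)
U = topology_uncertainty(ens, recon, tc)
stab = persistence_stability(ens, recon, cfg=tc)
u_macro = macro_uncertainty(U, bc, dbeta)
print(f"topology uncertainty U = {U:.4f} (mean Wasserstein distance of "
      f"K=4 realization diagrams to the reference)")
print(f"persistence stability = {stab:.3f} (1 = perfectly reproducible)")
print(f"macro uncertainty U_macro = {u_macro:.4f} "
      f"(0.6*U + 0.25*(1-BC) + 0.15*dBeta)")
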