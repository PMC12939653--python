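"""Generate a seeded vascular phantom and simulate its k-space acquisition.

Builds a 192x192 phantom (0.5 mm voxels) with two collateral loops, reports
the exact ground-truth graph, and shows the effect of measurement noise and a
rigid-motion perturbation on the zero-filled reconstruction.
"""

import numpy as np

from vascsense import (NoiseModel, PhantomSpec, apply_motion_perturbation,
                       generate_vascular_phantom, psnr, simulate_kspace)

spec = PhantomSpec(grid_shape=(192, 192), n_main_branches=6,
                   n_collateral_loops=2, seed=42)
img, truth = generate_vascular_phantom(spec)
print(f"phantom: {img.shape} voxels, intensity range "
      f"[{img.values.min():.2f}, {img.values.max():.2f}]")
print(f"ground truth: {truth.n_nodes} nodes, {truth.n_edges} edges, "
      f"beta0={truth.betti0()} (components), beta1={truth.betti1()} (loops)")
print(f"total vessel length: {truth.total_length_mm():.1f} mm")

ks_clean = simulate_kspace(img, NoiseModel(0.0))
ks_noisy = simulate_kspace(img, NoiseModel(kspace_noise_sigma=0.06), seed=1)
ks_moved = apply_motion_perturbation(ks_noisy, shift_mm=1.5,
                                     affected_fraction=0.25, seed=2)

for name, ks in [("clean", ks_clean), ("noisy", ks_noisy),
                 ("noisy+motion", ks_moved)]:
    zf = np.abs(ks.zero_filled_image())
    print(f"zero-filled PSNR ({name:>12s}): {psnr(img, zf):6.2f} dB")
# The drop from clean (infinite) to noisy to motion-corrupted quantifies how
# much each perturbation alone degrades a naive reconstruction.
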