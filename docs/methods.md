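# Methods

`vascsense` is a fully synthetic, desk-scale implementation of a closed-loop,
topology-aware accelerated MRI pipeline for neurovascular imaging, together
with a cross-scale simulator that propagates reconstruction uncertainty from
vascular topology to perfusion and tissue-viability proxies. This note
documents the models, the numerical choices, and what the synthetic studies
do and do not show.

## Synthetic phantoms (what the generator emulates)

The generator emulates a 2-D slice of a time-of-flight–like angiogram:
bright tubular vessels on a uniform unit background, with an exactly known
vessel graph. A stochastic binary tree is grown from one or two root points
by momentum random walks; chords between tree nodes close a prescribed
number of collateral loops, so the ground-truth Betti numbers are exact by
construction (β₀ from connectivity, β₁ = number of chords). Growth is
self-avoiding (a walk truncates when it would come within ~3 mm of another
vessel) so the rasterized image has exactly the intended topology — without
this, incidental crossings would create loops absent from the ground truth.

Defaults: 192×192 grid at 0.5 mm isotropic voxels (the multi-seed studies
use 96×96 for tractability on a single CPU; the phantom model is identical),
5–6 terminal branches, 2 collateral loops, diameters 0.8–2.4 mm tapering
child ≤ parent, vessel-to-background contrast 6. The cross-section intensity
profile is Gaussian with FWHM equal to the local diameter; the rasterization
floors the Gaussian σ at 0.85 voxel so that sub-voxel vessels remain
resolvable on the discrete grid (the annotated diameter is unaffected).

What the phantoms do **not** emulate: MR physics (relaxation, inflow
enhancement, coil sensitivities), 3-D+t dynamics, tissue texture, partial
volume at air/bone interfaces, or realistic motion beyond a rigid in-plane
translation of a contiguous phase-encode block. Consequently, passing tests
demonstrate correctness and internal consistency of the algorithms under
controlled conditions — not clinical performance.

## Acquisition

k-space uses the centered-DC convention with unitary FFTs. Masks:

* **Poisson-disc** — seeded, density-weighted dart throwing with a minimum
  pairwise distance (default 1.2–1.4 voxels) and a fully sampled center band
  (default 8% per axis); the variable-density weight decays with normalized
  radius (exponent 2). Sampling stops exactly at the target budget, so the
  achieved acceleration matches the target up to quantization.
* **Partial Fourier** — a contiguous block of `ceil(pf · n)` phase-encode
  lines from one edge plus the symmetric center band.

The **adaptive policy** implements one-step greedy lookahead on the
topology-aware uncertainty `U`: candidate batches of unsampled locations are
proposed (by default drawn from the *spectrum* profile — weighted by the
magnitude spectrum of an image-space instability map, i.e. the voxelwise
variance of ensemble vessel segmentations, Gaussian-dilated; other profiles:
annulus-coverage repair, low-frequency bias, uniform). Candidate
measurements are synthesized by the plug-in approximation (the current
reconstruction stands in for the unknown image), reconstructed with a
cheap surrogate (15 iterations), and scored by `U` over a small stochastic
ensemble (K = 2); ties break by candidate index. Exact expectation over the
unknown image is intractable; plug-in one-step lookahead is the standard
substitute. The closed loop can stop early when `U` saturates (relative
decrease below 1%); the matched-budget studies disable early stopping so all
methods end at the same acceleration.

A caveat found during design and worth stating: `U` measures *stability*,
not correctness. A candidate that leaves a vessel stably invisible can score
a lower `U` than one that recovers it marginally. The spectrum-profile
candidate distribution (rather than the selection step alone) therefore
carries most of the topology benefit; the selection step is exercised and
verified on a constructed two-candidate instance where the informative
candidate is also the stable one.

## Reconstruction

The core estimator minimizes `½‖W(F_M x − y)‖² + λ‖Ψx‖₁` by FISTA with
objective-based restarts (monotone within restarts; step size must satisfy
`step ≤ 1/max(W²)`, enforced). Ψ is an orthogonal multi-level wavelet
(`db4`, ≤3 levels, periodization), so the proximal step is exact soft
thresholding; `identity` (for 1-D sparse-spike work) and an approximate
total-variation prox are available. Default λ = 1e-2 at 80 iterations for
the 96×96 studies (chosen for image quality on the phantom class before the
comparative studies were frozen).

Structured priors are applied at fixed iteration cadences as projection
steps; a projection is not a descent step of the ℓ₁ objective, so the
monotonicity baseline restarts from the projected point while FISTA momentum
is carried through (a full momentum reset at every projection slows
convergence without changing the prior's effect):

* **Hankel structured low-rank** — 1-D windows (default 24) along rows and
  columns, SVD truncation to rank 16, anti-diagonal de-lifting, blended at
  α = 0.5 every 25 iterations. On smooth phantom profiles this acts as a
  mild structured denoiser; the k-space domain variant (annihilating-filter
  view) is available but aggressive at these window sizes.
* **Topology-aware regularization (classical)** — vessel-enhancing oriented
  diffusion: Hessian-based orientation and tubularity at σ = 1.2 voxels,
  anisotropic smoothing (σ∥ = 2, σ⊥ = 0.6 voxels, 8 orientation bins)
  blended in proportion to tubularity. No learned components.
* **Partial-Fourier completion** — homodyne: low-resolution phase from an
  apodized, DC-symmetric center sub-band; pre-weighted conjugate synthesis
  (exact for real images); a few POCS rounds re-impose measured samples.
  Used once, as initialization, when the mask is a partial-Fourier mask.
* **Exact data consistency** — the final step replaces predicted k-space
  with the measured samples, bit-exact on the mask up to FFT round-trip.

**Stochastic realization ensembles** for uncertainty: K reconstructions with
i.i.d. complex Gaussian noise injection (std = perturb_scale × noise σ) and
λ jittered ±20% log-uniformly, all seeded. Sensor-informed weighting enters
as per-readout weights `W ∈ [0.7, 1.0]` in the data term.

## Topology metrics

Pipeline: multi-scale Frangi-type vesselness (radii 0.4–1.35 mm, response
normalized to [0, 1]) → threshold (default 0.12) → skeletonize → graph.
The pixel graph uses orthogonal-preferred adjacency (a diagonal link is kept
only when no closer common neighbor exists), which removes the spurious
triangles of plain 8-connectivity so the skeleton's cycle rank equals the
number of holes. Junction pixels cluster into single nodes; edges carry
polyline, arclength, diameter (2× mean distance-transform along the
centerline), and confidence (mean vesselness). Two hygiene steps are part of
extraction (not pruning): segmentation blobs far below vessel size are
dropped before skeletonization, and junction-scale cycle artifacts (parallel
chains or self-loops shorter than max(1.5 × caliber, 2.5 mm)) are
consolidated. Pruning then removes terminal spurs and short acyclic
components below 2.5 mm (the 2–3 mm physical scale), never touching cycle
edges, and merges pass-through nodes (idempotent).

**Persistence** is computed on the extracted 1-complex under the
superlevel-set filtration of edge confidence: edges enter at their
confidence as the threshold decreases, nodes with their first incident edge.
Dim-0 pairs follow the elder rule (ties broken by creating-edge index);
zero-persistence pairs are dropped; each surviving component is an essential
class born at its maximum confidence. Independent cycles are essential dim-1
classes born at the minimum confidence along the cycle. A brute-force
threshold-sweep oracle validates both diagrams on all small graphs in the
test suite.

**Wasserstein distance** (order q = 2 default, L∞ ground metric): optimal
partial matching with diagonal matches at cost (birth−death)/2, solved as a
linear assignment on the standard augmented cost matrix; essential classes
are matched separately by sorted birth, unmatched ones contributing their
birth (distance to 0). Verified against exhaustive matching and checked for
the metric axioms.

Derived metrics: topology uncertainty `U` = mean summed (dim-0 + dim-1)
distance of ensemble diagrams to the reference diagram; Betti deviation
`Δβ = (|Δβ₀| + |Δβ₁|) / max(1, β₀ʳᵉᶠ + β₁ʳᵉᶠ)`; branch completeness = the
fraction of reference edges with ≥80% of their resampled points within
1 mm of the pooled reconstructed centerline, claimed greedily against a
reconstructed-arclength budget (strict per-edge one-to-one pairing
undercounts perfect recoveries when pruning merges pass-through nodes);
persistence stability = `1 − clamp(U / total persistence of the reference)`;
macro uncertainty `U_macro = 0.6·U + 0.25·(1−BC) + 0.15·Δβ` (fixed weights).

## Cross-scale simulator

All fixed parameters live in one place (`crossscale.TABLE_DEFAULTS`) and are
never re-tuned in tests: ε = 1e-6, macro weights (0.6, 0.25, 0.15),
D = 0.80 mm²/s, clearance λ = 0.012 /s, Δt = 0.10 s, horizon T = 60 s,
α = 1.10, β = 0.85, γ = 0.06, θ = 0.20, logistic slope 8.0.

* **Macro** — conductance g = d⁴/(ℓ + ε) (Poiseuille scaling, unit
  constant; flows in arbitrary units since only ratios matter downstream);
  node pressures from the conductance-weighted graph Laplacian with inlets
  at pressure 1 and outlets at 0 (inlets = degree-1 nodes nearest the
  declared border, default left; if loops have absorbed every terminal, the
  lowest-degree nodes stand in); flows g·Δp conserve mass at internal nodes
  to machine precision.
* **Meso** — edge flows are splatted as tangential velocity contributions
  onto the tissue grid and Gaussian-smoothed. Transport follows
  ∂c/∂t + ∇·(uc) = D∇²c − λc + S with donor-cell upwind advection, 5-point
  diffusion, zero-flux boundaries, explicit Euler. The transport grid is
  1.0 mm (coarser than the 0.5 mm voxels) because the fixed explicit step
  is stable only for h ≥ √(2·dim·D·Δt) ≈ 0.57 mm in 2-D; perfusion is a
  tissue-scale quantity, so this is physically natural. Advective CFL is
  guarded by capping |u| at h/(2Δt) (the flow units are arbitrary). The
  bolus S is a Gaussian source at the inlet for 5 s. Endpoints: voxelwise
  peak (CBV proxy), first-occurrence time-to-peak, trapezoidal AUC (CBF
  proxy).
* **Micro** — dE/dt = αΦ − βΓ − γE by forward Euler (dt < 2/γ enforced),
  with supply Φ = AUC normalized by its positive median and demand
  Γ = min(2, 1 + deficit) where deficit is the relative shortfall of Φ
  against its reference; survival P = logistic(8·(E − 0.20)).
* **Uncertainty propagation** — the full cascade runs per reconstruction
  realization; U_meso is the unbiased (n−1) voxelwise variance of each
  perfusion endpoint, spatially averaged; U_micro is the voxelwise variance
  of P, summarized by its mean over the at-risk region. The at-risk region
  is defined voxelwise — lesioned AUC < fraction × healthy AUC at the same
  voxel, within the perfused domain — because a voxelwise reference makes
  the mask empty when nothing changed and monotone in the fraction; a
  global-median reference satisfies neither.

## Sensor layer

Streams: ECG at 1000 Hz (Gaussian R-wave train + baseline drift), PPG and
respiration at 100 Hz, gradient/RF telemetry at 1 kHz, table encoder at
10 Hz, temperature at 1 Hz; calibration-residual noise at 0.3–0.6% of
nominal for telemetry. Instability epochs inject amplified noise plus
low-frequency excursions. Preprocessing is zero-phase per channel: ECG
high-pass 0.5 Hz + mains notch (50 Hz default, configurable), PPG low-pass
8 Hz, respiration low-pass 2 Hz, telemetry z-scored (RF smoothed first).
Channels are linearly interpolated onto the readout clock; the instability
score is the per-channel robust z-score (median/MAD) of short-window
variance, clipped after division by a saturation constant (5), combined by
maximum. The confidence map is affine, `w = 1 − 0.3·score`, the simplest map
with the stated endpoints w(0) = 1 and w(1) = 0.7; weights are per readout
(all samples of a phase-encode line share a weight, matching how motion
corruption enters k-space).

## Study conditions and what the comparisons mean

The multi-seed studies (the benchmark, the acceptance script, and the
corresponding tests) use: 96×96 phantoms (0.5 mm voxels, 5 branches, 2
collateral loops, contrast 6), k-space noise σ = 0.06, target acceleration
70%, matched sampling budgets in every comparison. Plain CS reconstructs a
static variable-density Poisson-disc mask; the full pipeline starts from a
sparser mask and spends the difference (6 batches of 128 locations) through
the closed loop, with Hankel and vessel-enhancing priors and final data
consistency. In the policy-sanity comparison both arms use a heterogeneous
four-profile candidate set so that random selection is a meaningful control
for uncertainty-driven selection.

At these conditions plain CS fragments thin vessels and loses collateral
loops (its Betti errors are dominated by extra components and missing
cycles), which is precisely the failure mode the adaptive, topology-aware
pipeline targets. The claim verified is *relative*: an approximately twofold
reduction in mean Betti deviation at matched acceleration — not any absolute
clinical number.

## Known limitations

* Topology metrics on 20-seed phantom cohorts carry substantial
  seed-to-seed variance (Betti deviations are small-integer counts divided
  by three); cohort-level comparisons such as the CS-versus-full ratio
  should be read with that sampling noise in mind.

* The uncertainty signal rewards stability, not correctness (see above);
  on very poor starting masks the one-step lookahead can prefer stably
  wrong actions.
* Vesselness thresholding remains the most brittle stage; the extracted
  graph on a *clean* phantom deviates from the exact ground truth on a
  minority of seeds (spurious short loops or faint gaps), which sets the
  floor of the Betti-deviation comparisons. Threshold sensitivity can be
  quantified with `threshold_sensitivity`.
* The Hankel prior is mild for this image class (flat background, smooth
  tube profiles); it is kept both for completeness and because it becomes
  material for spectrally structured data.
* 3-D support is limited to thin slabs through the same code paths and is
  not exercised by the default studies.
* Flows, velocities, and concentrations are in arbitrary consistent units;
  only ratios and derived proxies are meaningful.
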