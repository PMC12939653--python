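# vascsense

Topology-aware adaptive compressed-sensing MRI, on fully synthetic
neurovascular phantoms.

## The problem

In accelerated neurovascular MRI, small reconstruction errors concentrated
along thin vessels can disconnect distal branches or fabricate spurious
loops. Pixelwise quality metrics barely notice, but the *vascular graph* —
connectivity, bifurcations, collateral loops — is exactly what downstream
perfusion estimates and stroke-triage decisions depend on. `vascsense`
implements and evaluates a closed-loop answer at desk scale: measure
uncertainty in *topology space*, and let that uncertainty decide which
k-space samples to acquire next.

The package is aimed at researchers in computational MRI and topological
data analysis who want a reproducible, self-contained sandbox: every input
is generated internally (seeded phantoms with exact ground-truth graphs,
simulated k-space, simulated physiological sensors), so every number it
prints can be traced to a seed.

## The model

With `x` the unknown image, `F_M` the masked (centered, unitary) Fourier
operator and `y = F_M x + η` the measurements, the baseline estimator is
classical compressed sensing,

    x̂ = argmin_x  ½‖F_M x − y‖₂² + λ‖Ψx‖₁,

solved by FISTA with an orthogonal wavelet Ψ. The full reconstructor adds a
patch-wise Hankel structured low-rank projection, a classical
vessel-enhancing (topology-aware) regularization, optional partial-Fourier
completion, per-sample sensor confidence weights `W(s) ∈ [0.7, 1.0]` in the
data term, and an exact data-consistency projection.

From a reconstruction x̂ the vessel graph G is extracted (vesselness →
segmentation → skeleton → graph) and the **topology-aware uncertainty**

    U(x̂) = E_k [ d_Wass( PD(x̂⁽ᵏ⁾), PD(x̂) ) ]

is the mean Wasserstein distance between the persistence diagrams of K
stochastic reconstruction realizations and the reference diagram
(superlevel-set filtration of vessel confidence on the skeleton graph; β₀ =
components, β₁ = collateral loops). The closed loop acquires the batch of
k-space locations with the largest predicted reduction of U, one-step
greedy, with plug-in synthesized candidate measurements and fast surrogate
reconstructions.

A macro–meso–micro simulator propagates topology errors to physiology:
Poiseuille-type conductances g = d⁴/(ℓ+ε) and Kirchhoff flow on the graph,
an advection–diffusion–reaction bolus (∂c/∂t + ∇·(uc) = D∇²c − λc + S) for
perfusion proxies (peak, time-to-peak, AUC), and an energy-balance survival
proxy dE/dt = αΦ − βΓ − γE, P = σ(slope·(E − θ)), with variances across
realizations reported at each scale.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/02_compressed_sensing_recon.py
mask: 2765 of 9216 samples (acceleration 0.700)
              zero-filled: PSNR  19.02 dB  SSIM 0.456  NMSE 0.1080
          CS (wavelet l1): PSNR  22.07 dB  SSIM 0.634  NMSE 0.0536
         CS + Hankel + DC: PSNR  22.09 dB  SSIM 0.632  NMSE 0.0533
 CS + Hankel + vessel reg: PSNR  21.19 dB  SSIM 0.593  NMSE 0.0655
```

At 70% acceleration the structured prior plus data consistency matches or
slightly improves plain CS; the vessel-enhancing regularization deliberately
trades ~1 dB of pixel fidelity for vessel continuity. The topology example
shows what that buys:

```bash
$ python examples/03_topology_metrics.py
truth:  beta0=1 beta1=2
recon:  beta0=1 beta1=2
Betti deviation: 0.000  branch completeness: 0.91
persistence: 1 dim-0 classes (1 essential), 2 dim-1 (loop) classes
topology uncertainty U = 0.0683 (mean Wasserstein distance of K=4 realization diagrams to the reference)
persistence stability = 0.954 (1 = perfectly reproducible)
macro uncertainty U_macro = 0.0637 (0.6*U + 0.25*(1-BC) + 0.15*dBeta)
```

Both collateral loops of the ground truth are recovered (β₁ = 2, Betti
deviation 0) and 91% of reference branches are matched within 1 mm; U and
U_macro summarize how reproducible that topology is across the stochastic
ensemble. Other examples cover the phantom generator, the closed acquisition
loop, the cross-scale simulator, and sensor-informed weighting.

A thin CLI wraps the same drivers:

```bash
vascsense run --seed 1 --out results/       # cs / cs+priors / full, one seed
vascsense benchmark --n-seeds 5 --out results/
vascsense generate --seed 1 --out fixtures/  # phantom + k-space + sensors
```

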