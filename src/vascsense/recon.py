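"""Physics-grounded reconstruction from undersampled k-space.

The core estimator solves

    min_x  1/2 || W (F_M x - y) ||_2^2  +  lambda || Psi x ||_1

by accelerated proximal gradient (FISTA with objective-based restarts), where
``F_M`` is the masked unitary centered Fourier transform, ``Psi`` an
orthogonal sparsifying transform (multi-level wavelet by default; the
proximal step is then exact soft thresholding of transform coefficients) and
``W`` an optional per-sample confidence weighting.  The full reconstructor
interleaves these iterations with a patch-wise Hankel structured low-rank
projection of image rows/columns, optionally initializes from a
partial-Fourier (homodyne) completion, and ends with an exact
data-consistency projection.

Uncertainty enters through stochastic realization ensembles: repeated
reconstructions under controlled measurement-noise injection and randomized
regularization (log-uniform +-20% jitter of lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt

from .core import (ImageVolume, KSpaceMeasurement, SamplingMask,
                   center_band_slices, fft_centered, ifft_centered)

__all__ = [
    "ReconConfig",
    "StochasticEnsemble",
    "cs_reconstruct",
    "weighted_reconstruct",
    "reconstruct_full",
    "data_consistency_project",
    "hankel_lowrank_project",
    "partial_fourier_complete",
    "stochastic_realizations",
]


@dataclass(frozen=True)
class HankelConfig:
    enabled: bool = False
    window: int = 24
    rank: int = 16
    every: int = 25        # apply every n-th FISTA iteration
    domain: str = "image"  # "image" (smooth-profile view) | "kspace"
    alpha: float = 0.5     # blend weight of the projected signal


@dataclass(frozen=True)
class PartialFourierConfig:
    enabled: bool = False
    phase_band_fraction: float = 0.08


@dataclass(frozen=True)
class TopoRegConfig:
    """Classical topology-aware regularization: vessel-enhancing diffusion.

    Oriented anisotropic smoothing along locally detected vessel directions,
    blended in proportionally to tubularity; bridges sub-voxel gaps in thin
    vessels that plain sparsity regularization tends to break, without a
    learned component.
    """

    enabled: bool = False
    alpha: float = 0.5        # blend weight on tubular voxels
    sigma_along: float = 2.0  # smoothing extent along the vessel (voxels)
    sigma_across: float = 0.6
    detect_sigma: float = 1.2  # Hessian scale for orientation (voxels)
    every: int = 25


@dataclass(frozen=True)
class ReconConfig:
    lambda_reg: float = 1e-3
    transform: str = "wavelet"  # "wavelet" | "identity" | "tv"
    wavelet: str = "db4"
    levels: int = 3
    max_iterations: int = 100
    step_size: float = 1.0
    tol: float = 1e-7
    hankel: HankelConfig = field(default_factory=HankelConfig)
    pf: PartialFourierConfig = field(default_factory=PartialFourierConfig)
    topo: TopoRegConfig = field(default_factory=TopoRegConfig)

    def __post_init__(self):
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.hankel.rank < 1:
            raise ValueError("hankel rank must be >= 1")


@dataclass
class StochasticEnsemble:
    """K reconstructions under perturbed data / jittered regularization."""

    members: list  # of ImageVolume
    perturb_scale: float
    seed: int

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("ensemble needs K >= 1 members")
        shapes = {m.shape for m in self.members}
        if len(shapes) > 1:
            raise ValueError("ensemble members must share a grid")

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


# ---------------------------------------------------------------------------
# sparsifying transforms
# ---------------------------------------------------------------------------

class _Transform:
    """Orthogonal analysis/synthesis pair with exact soft-threshold prox."""

    def __init__(self, cfg: ReconConfig, shape):
        self.kind = cfg.transform
        self.wavelet = cfg.wavelet
        self.levels = cfg.levels
        self.shape = shape
        if self.kind == "wavelet":
            max_lvl = pywt.dwtn_max_level(shape, cfg.wavelet)
            self.levels = max(1, min(cfg.levels, max_lvl))

    def prox(self, x: np.ndarray, thresh: float) -> np.ndarray:
        if thresh <= 0:
            return x
        if self.kind == "identity":
            return _soft(x, thresh)
        if self.kind == "wavelet":
            coeffs = pywt.wavedecn(x, self.wavelet, mode="periodization",
                                   level=self.levels)
            arr, slices = pywt.coeffs_to_array(coeffs)
            arr = _soft(arr, thresh)
            coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedecn")
            return pywt.waverecn(coeffs, self.wavelet, mode="periodization")
        if self.kind == "tv":
            from skimage.restoration import denoise_tv_chambolle
            re = denoise_tv_chambolle(np.real(x), weight=thresh)
            if np.iscomplexobj(x):
                im = denoise_tv_chambolle(np.imag(x), weight=thresh)
                return re + 1j * im
            return re.astype(x.dtype)
        raise ValueError(f"unknown transform {self.kind!r}")

    def l1(self, x: np.ndarray) -> float:
        if self.kind == "identity":
            return float(np.abs(x).sum())
        if self.kind == "wavelet":
            coeffs = pywt.wavedecn(x, self.wavelet, mode="periodization",
                                   level=self.levels)
            arr, _ = pywt.coeffs_to_array(coeffs)
            return float(np.abs(arr).sum())
        # TV penalty value (isotropic, finite differences)
        g = np.gradient(np.real(x))
        tv = np.sqrt(sum(gi**2 for gi in g)).sum()
        if np.iscomplexobj(x):
            gi_ = np.gradient(np.imag(x))
            tv += np.sqrt(sum(gi**2 for gi in gi_)).sum()
        return float(tv)


def _soft(z: np.ndarray, t: float) -> np.ndarray:
    mag = np.abs(z)
    scale = np.maximum(0.0, 1.0 - t / np.maximum(mag, 1e-300))
    return z * scale


# ---------------------------------------------------------------------------
# FISTA core
# ---------------------------------------------------------------------------

def _fista(y: KSpaceMeasurement, cfg: ReconConfig, weights=None, x0=None,
           prior_cb=None):
    m = y.mask.mask
    yv = y.values
    if weights is None:
        w2 = m.astype(float)
        lmax = 1.0
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != m.shape:
            raise ValueError("weights must be a full-grid array on the mask")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        w2 = (weights**2) * m
        lmax = float(max(w2.max(), 1e-12))
    if cfg.step_size > 1.0 / lmax + 1e-12:
        raise ValueError(
            f"step_size {cfg.step_size} violates the convergence bound; "
            f"use step_size <= {1.0 / lmax:.6g}"
        )
    step = cfg.step_size
    tr = _Transform(cfg, m.shape)

    def grad(x):
        return ifft_centered(w2 * (fft_centered(x) - yv))

    def objective(x):
        r = fft_centered(x) - yv
        return 0.5 * float(np.sum(w2 * np.abs(r) ** 2)) \
            + cfg.lambda_reg * tr.l1(x)

    x = ifft_centered(w2 * yv) if x0 is None else np.asarray(
        x0, dtype=np.complex128).copy()
    z = x.copy()
    t_mom = 1.0
    f_prev = objective(x)
    history = [f_prev]
    for it in range(1, cfg.max_iterations + 1):
        x_new = tr.prox(z - step * grad(z), cfg.lambda_reg * step)
        f_new = objective(x_new)
        if f_new > f_prev:  # objective-based restart keeps monotone descent
            z = x.copy()
            t_mom = 1.0
            x_new = tr.prox(z - step * grad(z), cfg.lambda_reg * step)
            f_new = objective(x_new)
            if f_new > f_prev:  # still no descent: keep the previous iterate
                history.append(f_prev)
                break
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = x_new + ((t_mom - 1.0) / t_new) * (x_new - x)
        x, t_mom = x_new, t_new
        history.append(f_new)
        converged = abs(f_prev - f_new) <= cfg.tol * max(abs(f_prev), 1e-30)
        f_prev = f_new
        if prior_cb is not None:
            # structured-prior projection at a segment boundary: it is not a
            # descent step of the l1 objective, so the monotonicity baseline
            # restarts from the projected point while momentum is carried
            # (skipped when the projection is a no-op on this iterate)
            x_proj = prior_cb(x, it)
            delta = np.linalg.norm(x_proj - x) / max(np.linalg.norm(x), 1e-30)
            if delta > 1e-9:
                z = z + (x_proj - x)  # carry momentum through the projection
                x = x_proj
                f_prev = objective(x)
                history.append(f_prev)
                converged = False
        if converged:
            break
    return x, np.asarray(history)


def cs_reconstruct(y: KSpaceMeasurement, cfg: ReconConfig) -> ImageVolume:
    """Compressed-sensing reconstruction (sparsity-regularized least squares)."""
    if not y.mask.mask.any():
        raise ValueError("mask is empty")
    x, _ = _fista(y, cfg)
    return ImageVolume(x, y.voxel_size_mm)


def weighted_reconstruct(y: KSpaceMeasurement, weights: np.ndarray,
                         cfg: ReconConfig) -> ImageVolume:
    """CS reconstruction with per-sample confidence weighting of the data term."""
    x, _ = _fista(y, cfg, weights=weights)
    return ImageVolume(x, y.voxel_size_mm)


def data_consistency_project(x: ImageVolume | np.ndarray,
                             y: KSpaceMeasurement) -> ImageVolume:
    """Replace the k-space of ``x`` with ``y`` on sampled locations (idempotent)."""
    xv = np.asarray(getattr(x, "values", x), dtype=np.complex128)
    if xv.shape != y.shape:
        raise ValueError("shape mismatch")
    k = fft_centered(xv)
    k = np.where(y.mask.mask, y.values, k)
    out = ifft_centered(k)
    vx = getattr(x, "voxel_size_mm", y.voxel_size_mm)
    return ImageVolume(out, vx)


# ---------------------------------------------------------------------------
# Hankel structured low-rank prior
# ---------------------------------------------------------------------------

def hankel_lowrank_project(block: np.ndarray, window: int, rank: int) -> np.ndarray:
    """SVD-truncate the Hankel lifting of a 1-D block, de-lift by averaging.

    The block is lifted to the ``window x (n - window + 1)`` Hankel matrix
    ``H[i, j] = block[i + j]``, truncated to the given rank, and mapped back
    by averaging anti-diagonals.
    """
    b = np.asarray(block)
    n = b.shape[-1]
    if window >= n:
        raise ValueError("window must be smaller than the block length")
    if rank > min(window, n - window + 1):
        raise ValueError("rank exceeds the Hankel matrix dimensions")
    idx = np.arange(window)[:, None] + np.arange(n - window + 1)[None, :]
    H = b[idx]
    U, s, Vh = np.linalg.svd(H, full_matrices=False)
    s[rank:] = 0.0
    Hr = (U * s) @ Vh
    out = np.zeros(n, dtype=Hr.dtype)
    counts = np.zeros(n)
    np.add.at(out, idx.ravel(), Hr.ravel())
    np.add.at(counts, idx.ravel(), 1.0)
    return out / counts


def _hankel_image_project(x: np.ndarray, window: int, rank: int) -> np.ndarray:
    """Apply the 1-D Hankel projection along every row and column, averaged."""
    def along(arr):
        out = np.empty_like(arr)
        for i in range(arr.shape[0]):
            out[i] = hankel_lowrank_project(arr[i], window, rank)
        return out

    if x.ndim == 3:  # slice-wise for thin slabs
        return np.stack([_hankel_image_project(x[..., k], window, rank)
                         for k in range(x.shape[2])], axis=-1)
    rows = along(x)
    cols = along(x.T).T
    return 0.5 * (rows + cols)


# ---------------------------------------------------------------------------
# topology-aware regularization (vessel-enhancing oriented diffusion)
# ---------------------------------------------------------------------------

def _oriented_kernels(sigma_along, sigma_across, n_orient=8):
    half = int(np.ceil(3 * sigma_along))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    kernels = []
    for i in range(n_orient):
        th = np.pi * i / n_orient
        u = yy * np.cos(th) + xx * np.sin(th)     # along
        w = -yy * np.sin(th) + xx * np.cos(th)    # across
        k = np.exp(-(u**2) / (2 * sigma_along**2)
                   - (w**2) / (2 * sigma_across**2))
        kernels.append(k / k.sum())
    return kernels


def vessel_enhancing_step(x: np.ndarray, cfg: TopoRegConfig) -> np.ndarray:
    """One blend of orientation-matched anisotropic smoothing.

    The local vessel orientation and tubularity are estimated from the
    Hessian of the magnitude at ``detect_sigma``; each voxel is replaced by
    ``(1 - a*m) x + a*m * smooth_along_orientation(x)`` where ``m`` is the
    normalized tubularity.  2-D only (applied slice-wise for thin slabs).
    """
    from scipy.ndimage import convolve
    from skimage.feature import hessian_matrix, hessian_matrix_eigvals

    if x.ndim == 3:
        return np.stack([vessel_enhancing_step(x[..., k], cfg)
                         for k in range(x.shape[2])], axis=-1)
    mag = np.abs(x)
    H = hessian_matrix(mag, sigma=cfg.detect_sigma, order="rc",
                       use_gaussian_derivatives=False)
    l1, l2 = hessian_matrix_eigvals(H)  # l1 >= l2
    # bright tubes: strongly negative l2, small l1
    tub = np.maximum(0.0, -l2) * np.exp(
        -np.abs(l1) / (np.abs(l2) + 1e-12))
    top = tub.max()
    m = tub / top if top > 0 else tub
    # orientation of the vessel = eigenvector of the smaller-|lambda|
    # eigenvalue; derive angle from the Hessian components
    Hrr, Hrc, Hcc = H
    theta = 0.5 * np.arctan2(2 * Hrc, Hrr - Hcc)  # principal direction
    # vessel axis is orthogonal to the principal curvature direction
    theta = theta + np.pi / 2
    kernels = _oriented_kernels(cfg.sigma_along, cfg.sigma_across)
    n_orient = len(kernels)
    bins = np.round(((theta % np.pi) / np.pi) * n_orient).astype(int) % n_orient
    smoothed = np.zeros_like(x)
    for i, k in enumerate(kernels):
        sel = bins == i
        if not sel.any():
            continue
        if np.iscomplexobj(x):
            conv = convolve(x.real, k, mode="nearest") \
                + 1j * convolve(x.imag, k, mode="nearest")
        else:
            conv = convolve(x, k, mode="nearest")
        smoothed[sel] = conv[sel]
    w = cfg.alpha * m
    return (1.0 - w) * x + w * smoothed


# ---------------------------------------------------------------------------
# partial Fourier completion (homodyne)
# ---------------------------------------------------------------------------

def partial_fourier_complete(ks: KSpaceMeasurement,
                             phase_band_fraction: float = 0.08,
                             pocs_iterations: int = 8) -> KSpaceMeasurement:
    """Fill the conjugate half of a partial-Fourier acquisition.

    A low-resolution phase map is estimated from the fully sampled center
    band; homodyne weighting synthesizes a phase-consistent real-valued image
    whose k-space fills the unsampled conjugate locations.  A few POCS
    refinement rounds alternate the phase constraint with exact data
    consistency.  Sampled locations are returned untouched.
    """
    m = ks.mask.mask
    band = center_band_slices(m.shape, phase_band_fraction)
    if not m[band].all():
        raise ValueError("mask lacks a fully sampled center band")
    if m.all():
        return KSpaceMeasurement(ks.values.copy(), ks.mask, ks.noise_sigma,
                                 ks.voxel_size_mm)
    # phase from an apodized, DC-symmetric center sub-band (symmetry keeps
    # the low-resolution image of a real object real)
    apod = np.ones(m.shape)
    for ax, n in enumerate(m.shape):
        sl = band[ax]
        half = min(n // 2 - sl.start, sl.stop - 1 - n // 2)
        w1 = np.zeros(n)
        lo, hi = n // 2 - half, n // 2 + half
        w1[lo:hi + 1] = np.hanning(hi - lo + 1) if hi > lo else 1.0
        shape1 = [1] * len(m.shape)
        shape1[ax] = n
        apod = apod * w1.reshape(shape1)
    x_lo = ifft_centered(ks.values * apod)
    phase = np.exp(1j * np.angle(x_lo))

    # homodyne pre-weighting: 2 where the conjugate sample is missing
    conj_m = _point_reflect(m)
    w = np.where(m & ~conj_m, 2.0, 1.0) * m
    x_h = np.real(ifft_centered(w * ks.values) * np.conj(phase))
    x = x_h * phase
    for _ in range(pocs_iterations):
        k = fft_centered(x)
        k = np.where(m, ks.values, k)
        x = ifft_centered(k)
        x = np.real(x * np.conj(phase)) * phase
    k = fft_centered(x)
    filled = np.where(m, ks.values, k)
    full = SamplingMask(np.ones(m.shape, dtype=bool), center_fraction=0.0)
    return KSpaceMeasurement(filled, full, ks.noise_sigma, ks.voxel_size_mm)


def _point_reflect(a: np.ndarray) -> np.ndarray:
    """Sample at -k for a centered grid (DC at shape//2)."""
    out = a
    for ax, n in enumerate(a.shape):
        idx = (2 * (n // 2) - np.arange(n)) % n  # centered grid: index of -k
        out = np.take(out, idx, axis=ax)
    return out


# ---------------------------------------------------------------------------
# full reconstructor and stochastic ensembles
# ---------------------------------------------------------------------------

def reconstruct_full(y: KSpaceMeasurement, cfg: ReconConfig,
                     weights: np.ndarray | None = None) -> ImageVolume:
    """CS + structured priors + optional PF init + final DC projection.

    Priors (each optional, applied at its own iteration cadence inside the
    proximal scheme): patch-wise Hankel structured low-rank projection and
    the classical topology-aware vessel-enhancing regularization.
    """
    x0 = None
    if cfg.pf.enabled:
        try:
            completed = partial_fourier_complete(y, cfg.pf.phase_band_fraction)
            x0 = completed.zero_filled_image()
        except ValueError:
            x0 = None  # mask has no usable center band: skip PF init
    prior_cb = None
    if cfg.hankel.enabled or cfg.topo.enabled:
        hc, tc = cfg.hankel, cfg.topo

        def prior_cb(x, it):
            if hc.enabled and it % max(1, hc.every) == 0:
                if hc.domain == "kspace":
                    k = fft_centered(x)
                    kp = _hankel_image_project(k, hc.window, hc.rank)
                    x = ifft_centered((1 - hc.alpha) * k + hc.alpha * kp)
                else:
                    xp = _hankel_image_project(x, hc.window, hc.rank)
                    x = (1 - hc.alpha) * x + hc.alpha * xp
            if tc.enabled and it % max(1, tc.every) == 0:
                x = vessel_enhancing_step(x, tc)
            return x
    x, _ = _fista(y, cfg, weights=weights, x0=x0, prior_cb=prior_cb)
    out = data_consistency_project(ImageVolume(x, y.voxel_size_mm), y)
    return out


def stochastic_realizations(y: KSpaceMeasurement, cfg: ReconConfig, K: int,
                            perturb_scale: float, seed: int = 0,
                            jitter_lambda: bool = True,
                            reconstructor=reconstruct_full) -> StochasticEnsemble:
    """K reconstructions under noise injection and randomized regularization.

    Each member adds i.i.d. complex Gaussian noise of std
    ``perturb_scale * noise_sigma`` to the measured samples and (optionally)
    jitters lambda log-uniformly by +-20%.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = perturb_scale * (y.noise_sigma if y.noise_sigma > 0 else
                             _sigma_estimate(y))
    members = []
    for _ in range(K):
        yv = y.values.copy()
        if sigma > 0:
            noise = sigma / np.sqrt(2) * (
                rng.standard_normal(yv.shape)
                + 1j * rng.standard_normal(yv.shape))
            yv = yv + noise * y.mask.mask
        lam = cfg.lambda_reg
        if jitter_lambda:
            lam = lam * np.exp(rng.uniform(np.log(0.8), np.log(1.2)))
        cfg_k = replace(cfg, lambda_reg=lam)
        yk = KSpaceMeasurement(yv, y.mask, y.noise_sigma, y.voxel_size_mm)
        members.append(reconstructor(yk, cfg_k))
    return StochasticEnsemble(members, perturb_scale, seed)


def _sigma_estimate(y: KSpaceMeasurement) -> float:
    """Fallback noise scale: robust std of the outermost sampled annulus."""
    m = y.mask.mask
    if not m.any():
        return 0.0
    coords = np.indices(m.shape)
    center = [(n // 2) for n in m.shape]
    r = np.sqrt(sum((c - c0) ** 2 for c, c0 in zip(coords, center)))
    ring = (r > 0.8 * r[m].max()) & m
    if not ring.any():
        return 0.0
    vals = y.values[ring]
    return float(np.median(np.abs(vals - np.median(vals))) * 1.4826)
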