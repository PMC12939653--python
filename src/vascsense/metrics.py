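"""Image-fidelity metrics (PSNR, SSIM, NMSE) and report assembly.

Complex inputs are compared on magnitude.  ``data_range`` defaults to the
reference's max - min so every metric is fully reproducible from the inputs.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

__all__ = ["psnr", "ssim", "nmse", "FidelityReport"]


def _as_mag(x) -> np.ndarray:
    x = np.asarray(getattr(x, "values", x))
    if np.iscomplexobj(x):
        x = np.abs(x)
    return x.astype(float)


def _check_shapes(ref, test):
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")


def psnr(ref, test, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images agree."""
    ref, test = _as_mag(ref), _as_mag(test)
    _check_shapes(ref, test)
    if data_range is None:
        data_range = float(ref.max() - ref.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def nmse(ref, test) -> float:
    """Normalized mean squared error ||test - ref||^2 / ||ref||^2."""
    ref, test = _as_mag(ref), _as_mag(test)
    _check_shapes(ref, test)
    denom = float(np.sum(ref**2))
    if denom == 0:
        raise ValueError("reference is identically zero")
    return float(np.sum((test - ref) ** 2) / denom)


def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    ax = np.arange(window) - (window - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(ref, test, data_range: float | None = None, window: int = 7,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local structural similarity with a Gaussian window.

    Local weighted means/variances/covariance are computed on every fully
    valid window position and combined with the standard stabilizers
    ``C1=(k1*L)^2``, ``C2=(k2*L)^2``.  Symmetric in its arguments.
    """
    ref, test = _as_mag(ref), _as_mag(test)
    _check_shapes(ref, test)
    if ref.ndim != 2:
        raise ValueError("ssim expects 2-D images")
    if data_range is None:
        data_range = float(max(ref.max() - ref.min(), test.max() - test.min()))
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    w = _gaussian_kernel(window, sigma)

    def filt(x):
        return fftconvolve(x, w, mode="valid")

    mu_x, mu_y = filt(ref), filt(test)
    xx, yy, xy = filt(ref * ref), filt(test * test), filt(ref * test)
    var_x = xx - mu_x**2
    var_y = yy - mu_y**2
    cov = xy - mu_x * mu_y
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


class FidelityReport:
    """Rows of (method, seed, acceleration, psnr_db, ssim, nmse, ...)."""

    def __init__(self):
        self.rows: list[dict] = []

    def add(self, method: str, ref, test, seed: int = 0,
            acceleration: float = float("nan"), **extra):
        row = {
            "method": method,
            "seed": seed,
            "acceleration": acceleration,
            "psnr_db": psnr(ref, test),
            "ssim": ssim(ref, test),
            "nmse": nmse(ref, test),
        }
        row.update(extra)
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = json.dumps(self.rows, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload
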