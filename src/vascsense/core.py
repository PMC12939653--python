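"""Shared containers: images, k-space measurements, sampling masks.

Conventions used throughout the package:

* images live on a regular grid with isotropic physical voxel spacing
  (``voxel_size_mm``), axis order ``(row, col[, slice])``, 0-based indices;
* k-space uses the centered-DC convention: the DC coefficient sits at
  ``shape // 2`` and transforms are unitary (``norm="ortho"``), so a full-mask
  round trip is an isometry;
* axis 0 is the phase-encode direction (the one acquired line by line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "SamplingMask",
    "KSpaceMeasurement",
    "fft_centered",
    "ifft_centered",
]


def fft_centered(x: np.ndarray) -> np.ndarray:
    """Unitary centered discrete Fourier transform (image -> k-space)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x), norm="ortho"))


def ifft_centered(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft_centered` (k-space -> image)."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k), norm="ortho"))


@dataclass
class ImageVolume:
    """Complex- or real-valued image on a regular grid.

    Parameters
    ----------
    values : ndarray
        Voxel values, 2-D or 3-D.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    origin_mm : tuple of float
        Physical position of voxel ``(0, 0[, 0])``.
    """

    values: np.ndarray
    voxel_size_mm: float = 0.5
    origin_mm: tuple = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.origin_mm is None:
            self.origin_mm = (0.0,) * self.values.ndim

    @property
    def shape(self):
        return self.values.shape

    @property
    def ndim(self):
        return self.values.ndim

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def copy_with(self, values: np.ndarray) -> "ImageVolume":
        return ImageVolume(values, self.voxel_size_mm, self.origin_mm)


def center_band_slices(shape, center_fraction: float):
    """Slices of the fully sampled low-frequency block (central hyper-cube)."""
    slices = []
    for n in shape:
        w = int(np.ceil(center_fraction * n))
        lo = n // 2 - w // 2
        slices.append(slice(lo, lo + w))
    return tuple(slices)


@dataclass
class SamplingMask:
    """Binary k-space sampling indicator with a fully sampled center band.

    ``acceleration`` is the fraction of k-space locations *not* sampled,
    stored at construction and re-validated against the mask on demand.
    """

    mask: np.ndarray
    center_fraction: float = 0.08
    acceleration: float = field(default=None)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        computed = 1.0 - self.mask.sum() / self.mask.size
        if self.acceleration is None:
            self.acceleration = float(computed)
        self.validate()

    def validate(self):
        computed = 1.0 - self.mask.sum() / self.mask.size
        if abs(computed - self.acceleration) > 1e-9:
            raise ValueError(
                f"stored acceleration {self.acceleration} does not match mask "
                f"({computed})"
            )
        band = center_band_slices(self.mask.shape, self.center_fraction)
        if not self.mask[band].all():
            raise ValueError("center band is not fully sampled")
        return True

    @property
    def shape(self):
        return self.mask.shape

    def center_band(self):
        return center_band_slices(self.mask.shape, self.center_fraction)

    def with_added(self, locations: np.ndarray) -> "SamplingMask":
        """New mask with extra (row, col, ...) locations sampled."""
        new = self.mask.copy()
        new[tuple(np.asarray(locations).T)] = True
        return SamplingMask(new, self.center_fraction)


@dataclass
class KSpaceMeasurement:
    """Fourier samples on a mask (full-grid array, zero off the support)."""

    values: np.ndarray
    mask: SamplingMask
    noise_sigma: float = 0.0
    voxel_size_mm: float = 0.5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        # enforce support: values defined exactly on the mask
        self.values = np.where(self.mask.mask, self.values, 0.0)

    @property
    def shape(self):
        return self.values.shape

    def restrict(self, mask: SamplingMask) -> "KSpaceMeasurement":
        """Measurement revealed on a (sub)mask of this one."""
        return KSpaceMeasurement(
            np.where(mask.mask, self.values, 0.0), mask,
            self.noise_sigma, self.voxel_size_mm,
        )

    def zero_filled_image(self) -> np.ndarray:
        return ifft_centered(self.values)
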