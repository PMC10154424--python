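"""Acquisition-resolution simulation: slice thickness, slice spacing, resampling.

Clinical 2D acquisitions trade through-plane resolution for speed: a random
slice-normal direction is chosen, a slice spacing r_spac ~ U(r_HR, b_res) and
a slice thickness r_thick ~ U(r_HR, r_spac) are drawn (slices rarely overlap,
so thickness is bounded by spacing). Thickness is modelled by blurring along
the slice axis with a Gaussian approximating the slice excitation profile,
whose standard deviation attenuates the HR signal power by a factor of 10 at
the low-resolution cut-off frequency:

    sigma_thick = 2 * alpha * ln(10) / (2*pi) * r_thick / r_HR

with alpha a small random jitter mitigating the Gaussian-profile assumption.
Spacing is modelled by trilinear downsampling along the axis to r_spac and
resampling back to the HR grid, so the partial-volume corrupted image lives
on the same grid as its crisp HR target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume

__all__ = [
    "ResolutionParams",
    "sample_resolution_params",
    "thickness_sigma",
    "simulate_acquisition",
]


@dataclass
class ResolutionParams:
    """One simulated acquisition: slice axis, spacing/thickness (mm), jitter."""

    axis: int
    r_spac: float
    r_thick: float
    alpha: float
    r_hr: float

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if not (self.r_hr <= self.r_thick <= self.r_spac + 1e-12):
            raise ValueError("need r_hr <= r_thick <= r_spac")


def sample_resolution_params(config, rng: np.random.Generator) -> ResolutionParams:
    """axis ~ U{0,1,2}; r_spac ~ U(r_hr, b_res); r_thick ~ U(r_hr, r_spac); alpha ~ U."""
    if config.b_res < config.r_hr:
        raise ValueError("b_res must be >= r_hr")
    if config.a_alpha > config.b_alpha:
        raise ValueError("inverted alpha bounds")
    axis = int(rng.integers(0, 3))
    r_spac = float(rng.uniform(config.r_hr, config.b_res))
    r_thick = float(rng.uniform(config.r_hr, r_spac))
    alpha = float(rng.uniform(config.a_alpha, config.b_alpha))
    return ResolutionParams(axis, r_spac, r_thick, alpha, config.r_hr)


def thickness_sigma(p: ResolutionParams) -> float:
    """Blur std (HR voxels along the slice axis) dividing signal power by 10."""
    return 2.0 * p.alpha * np.log(10.0) / (2.0 * np.pi) * p.r_thick / p.r_hr


def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Truncated (3 sigma) Gaussian kernel, normalised to unit sum."""
    radius = int(np.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def blur_axis(data: np.ndarray, sigma: float, axis: int) -> np.ndarray:
    """1D Gaussian blur along one axis with edge replication."""
    if sigma <= 0:
        return data.copy()
    return ndimage.convolve1d(data, _gaussian_kernel(sigma), axis=axis, mode="nearest")


def _resample_axis(data: np.ndarray, axis: int, coords_1d: np.ndarray) -> np.ndarray:
    """Linear interpolation of ``data`` at fractional positions along one axis."""
    data = np.moveaxis(data, axis, 0)
    n = data.shape[0]
    pos = np.clip(coords_1d, 0.0, n - 1.0)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = (pos - lo).reshape((-1,) + (1,) * (data.ndim - 1))
    out = data[lo] * (1.0 - w) + data[hi] * w
    return np.moveaxis(out, 0, axis)


def simulate_acquisition(i_hr: IntensityVolume, p: ResolutionParams) -> IntensityVolume:
    """Blur along the slice axis, downsample to r_spac, resample back to HR.

    The coordinate convention keeps the centre of the first voxel fixed: LR
    voxel i sits at HR position i * (r_spac / r_hr). Output grid equals input.
    """
    factor = p.r_spac / p.r_hr
    blurred = blur_axis(i_hr.data, thickness_sigma(p), p.axis)
    n_hr = i_hr.shape[p.axis]
    if factor > 1.0 + 1e-12:
        n_lr = max(1, int(np.ceil(n_hr / factor)))
        lr = _resample_axis(blurred, p.axis, np.arange(n_lr) * factor)
        out = _resample_axis(lr, p.axis, np.arange(n_hr) / factor)
    else:
        out = blurred
    return IntensityVolume(out, i_hr.spacing.copy(), i_hr.affine.copy())
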