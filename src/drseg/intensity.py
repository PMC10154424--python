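"""Label-conditioned intensity synthesis: GMM sampling, bias field, gamma.

Given a (deformed) label map L, a first synthetic scan G is produced by a
Gaussian mixture conditioned on L: each label k receives a mean mu_k and a
standard deviation sigma_k drawn fresh from wide uniform priors at every
draw, and voxel intensities are sampled independently as
N(mu_L(x), sigma_L(x)^2). The per-label sigma jointly stands in for tissue
heterogeneity and scanner noise. A multiplicative bias field exp(B) — B being
a trilinearly upsampled 4^3 Gaussian grid — corrupts G, and the result is
min-max rescaled to [0, 1] and passed through a random gamma transform
(voxel-wise exponentiation with exponent exp(gamma), gamma ~ N(0, sigma_g^2))
to skew the histogram while keeping the unit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial import _upsample_trilinear
from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "GMMParams",
    "sample_gmm_params",
    "sample_gmm_image",
    "sample_bias_field",
    "apply_bias",
    "rescale_and_gamma",
]

COARSE_BIAS_SHAPE = (4, 4, 4)


@dataclass
class GMMParams:
    """Per-label Gaussian intensity parameters (means and standard deviations)."""

    means: dict
    stds: dict

    def __post_init__(self):
        self.means = {int(k): float(v) for k, v in self.means.items()}
        self.stds = {int(k): float(v) for k, v in self.stds.items()}
        if set(self.means) != set(self.stds):
            raise ValueError("means and stds must cover the same labels")
        if any(s < 0 for s in self.stds.values()):
            raise ValueError("standard deviations must be non-negative")


def sample_gmm_params(labels, config, rng: np.random.Generator) -> GMMParams:
    """Draw mu_k ~ U(a_mu, b_mu) and sigma_k ~ U(a_sigma, b_sigma) per label."""
    if config.a_mu > config.b_mu or config.a_sigma > config.b_sigma:
        raise ValueError("inverted GMM prior bounds")
    labels = [int(l) for l in labels]
    means = {l: float(rng.uniform(config.a_mu, config.b_mu)) for l in labels}
    stds = {l: float(rng.uniform(config.a_sigma, config.b_sigma)) for l in labels}
    return GMMParams(means, stds)


def sample_gmm_image(
    vol: LabelVolume, params: GMMParams, rng: np.random.Generator
) -> IntensityVolume:
    """Sample G(x) ~ N(mu_L(x), sigma_L(x)^2) independently at every voxel."""
    present = set(int(l) for l in vol.label_set)
    missing = present - set(params.means)
    if missing:
        raise ValueError(f"labels without GMM parameters: {sorted(missing)}")
    max_label = int(vol.data.max())
    mu_lut = np.zeros(max_label + 1)
    sd_lut = np.zeros(max_label + 1)
    for lab in present:
        mu_lut[lab] = params.means[lab]
        sd_lut[lab] = params.stds[lab]
    mean_map = mu_lut[vol.data]
    std_map = sd_lut[vol.data]
    data = rng.normal(mean_map, std_map) if np.any(std_map > 0) else mean_map.copy()
    return IntensityVolume(data, vol.spacing.copy(), vol.affine.copy())


def sample_bias_field(image_shape, config, rng: np.random.Generator) -> IntensityVolume:
    """Sample the smooth log-bias field (before exponentiation).

    sigma_B ~ U(0, b_B); a 4^3 grid ~ N(0, sigma_B^2) is trilinearly upsampled
    (centre-aligned) to the image grid. Zero-mean in the log domain, so
    brightening and darkening by the same factor are equally likely.
    """
    if config.b_bias < 0:
        raise ValueError("b_bias must be non-negative")
    sigma = float(rng.uniform(0.0, config.b_bias))
    coarse = (
        rng.normal(0.0, sigma, COARSE_BIAS_SHAPE)
        if sigma > 0
        else np.zeros(COARSE_BIAS_SHAPE)
    )
    dense = _upsample_trilinear(coarse, image_shape)
    return IntensityVolume(dense, np.ones(3), np.eye(4))


def apply_bias(g: IntensityVolume, log_bias: IntensityVolume) -> IntensityVolume:
    """Multiply by the strictly positive field exp(log_bias), voxel-wise."""
    if g.shape != log_bias.shape:
        raise ValueError("bias field shape does not match the image")
    return IntensityVolume(g.data * np.exp(log_bias.data), g.spacing.copy(), g.affine.copy())


def rescale_and_gamma(
    gb: IntensityVolume,
    sigma_gamma: float,
    rng: np.random.Generator,
    gamma: float | None = None,
    minmax_source: IntensityVolume | None = None,
) -> tuple[IntensityVolume, float]:
    """Min-max rescale to [0, 1] then exponentiate by exp(gamma).

    gamma ~ N(0, sigma_gamma^2) unless forced. The rescaling anchors (min and
    max) are taken from ``minmax_source`` when given, otherwise from the input
    itself; values are clipped to [0, 1] before exponentiation so the output
    range is preserved for any gamma. Returns the image and the gamma used.
    """
    src = minmax_source.data if minmax_source is not None else gb.data
    lo, hi = float(src.min()), float(src.max())
    if hi <= lo:
        raise ValueError("cannot rescale a constant image")
    if gamma is None:
        gamma = float(rng.normal(0.0, sigma_gamma)) if sigma_gamma > 0 else 0.0
    scaled = np.clip((gb.data - lo) / (hi - lo), 0.0, 1.0)
    out = scaled ** np.exp(gamma)
    return IntensityVolume(out, gb.spacing.copy(), gb.affine.copy()), float(gamma)
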