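"""Configuration of the generative model: every prior bound in one place.

The whole point of the approach is that these priors are *wide*: instead of
matching a target modality, contrast (GMM means/stds), resolution, bias and
deformation parameters are drawn fresh from broad uniform distributions at
every training example, so the network never sees the same domain twice.
Narrowing any bound specialises the generator; collapsing a pair (a == b)
freezes that parameter, and collapsing all of them makes the pipeline a
deterministic function of the input label map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field


@dataclass
class GenerationConfig:
    """Uniform prior bounds and label bookkeeping for the generative model.

    Units: rotations degrees, translations voxels (at r_hr), spacings mm.
    Reference GMM priors are mu in [0, 255] and sigma in [0, 35]; resolution
    and jitter defaults cover clinical slice spacings up to b_res mm.
    """

    r_hr: float = 1.0
    # affine priors
    a_rot: float = -15.0
    b_rot: float = 15.0
    a_sc: float = 0.85
    b_sc: float = 1.15
    a_sh: float = -0.012
    b_sh: float = 0.012
    a_tr: float = -10.0
    b_tr: float = 10.0
    # nonlinear deformation
    b_nonlin: float = 3.0
    svf_steps: int = 7
    # GMM priors
    a_mu: float = 0.0
    b_mu: float = 255.0
    a_sigma: float = 0.0
    b_sigma: float = 35.0
    # bias and gamma
    b_bias: float = 0.4
    sigma_gamma: float = 0.4
    gamma_minmax_from: str = "biased"  # or "pre_bias": anchors from the unbiased image
    # resolution priors
    b_res: float = 9.0
    a_alpha: float = 0.95
    b_alpha: float = 1.05
    # corpus-level augmentation
    crop_shape: tuple | None = None
    flip_p: float = 0.5
    lr_axis: int = 0
    drop_p: float = 0.5
    lesion_p: float = 0.5
    lesion_label: int = 0
    # label bookkeeping
    generation_labels: tuple = ()
    segmentation_labels: tuple = ()
    extracerebral_labels: tuple = ()
    host_labels: tuple = ()
    lateral_pairs: tuple = ()  # ((left, right), ...)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for a, b, name in [
            (self.a_rot, self.b_rot, "rotation"),
            (self.a_sc, self.b_sc, "scaling"),
            (self.a_sh, self.b_sh, "shearing"),
            (self.a_tr, self.b_tr, "translation"),
            (self.a_mu, self.b_mu, "gmm mean"),
            (self.a_sigma, self.b_sigma, "gmm std"),
            (self.a_alpha, self.b_alpha, "alpha"),
        ]:
            if a > b:
                raise ValueError(f"inverted bounds for {name}: [{a}, {b}]")
        if self.r_hr <= 0:
            raise ValueError("r_hr must be positive")
        if self.b_nonlin < 0 or self.b_bias < 0 or self.sigma_gamma < 0:
            raise ValueError("b_nonlin, b_bias and sigma_gamma must be non-negative")
        if self.b_res < self.r_hr:
            raise ValueError("b_res must be >= r_hr")
        for p, name in [
            (self.flip_p, "flip_p"),
            (self.drop_p, "drop_p"),
            (self.lesion_p, "lesion_p"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gamma_minmax_from not in ("biased", "pre_bias"):
            raise ValueError("gamma_minmax_from must be 'biased' or 'pre_bias'")
        if self.generation_labels and not set(self.segmentation_labels) <= set(
            self.generation_labels
        ):
            raise ValueError("segmentation labels must be a subset of generation labels")

    # serialisation -----------------------------------------------------------

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("crop_shape", "generation_labels", "segmentation_labels",
                    "extracerebral_labels", "host_labels", "lateral_pairs"):
            if d[key] is not None:
                d[key] = list(d[key]) if key != "lateral_pairs" else [list(p) for p in d[key]]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GenerationConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("generation_labels", "segmentation_labels", "extracerebral_labels",
                    "host_labels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("crop_shape") is not None:
            d["crop_shape"] = tuple(d["crop_shape"])
        if d.get("lateral_pairs"):
            d["lateral_pairs"] = tuple(tuple(p) for p in d["lateral_pairs"])
        return cls(**d)

    def degenerate(self) -> "GenerationConfig":
        """Copy with every prior collapsed to its identity value.

        Rotations/shears/translations 0, scales 1, no nonlinear warp, GMM
        noise off (means still drawn), no bias, no gamma, native resolution,
        no flipping/dropping/pasting. The pipeline then reduces to the
        min-max-rescaled per-label mean map.
        """
        d = asdict(self)
        d.update(
            a_rot=0.0, b_rot=0.0, a_sc=1.0, b_sc=1.0, a_sh=0.0, b_sh=0.0,
            a_tr=0.0, b_tr=0.0, b_nonlin=0.0, a_sigma=0.0, b_sigma=0.0,
            b_bias=0.0, sigma_gamma=0.0, b_res=d["r_hr"], a_alpha=0.0,
            b_alpha=0.0, flip_p=0.0, drop_p=0.0, lesion_p=0.0,
        )
        return GenerationConfig(**d)
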