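"""End-to-end generative pipeline emitting on-the-fly training pairs {I, T}.

Each call draws every parameter of the generative model afresh: a source
label map is selected uniformly from the corpus, augmented at the label level
(flip / crop / extra-cerebral drop / lesion paste), spatially deformed
(random affine composed with an integrated stationary velocity field),
rendered to intensities by the label-conditioned GMM, corrupted by bias
field, rescaled + gamma-transformed, and degraded to a random acquisition
resolution before resampling back to the HR grid. The segmentation target T
is derived from the *same* deformed label map that produced the intensities —
image and target are perfectly aligned by construction — with all labels
outside the segmentation set reset to background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import intensity, resolution, spatial, volumes
from .config import GenerationConfig
from .volumes import IntensityVolume, LabelVolume, LateralPairs

__all__ = ["TrainingSample", "build_target", "sample_training_pair", "generate_batch"]


@dataclass
class TrainingSample:
    """A synthetic image in [0, 1] and its aligned segmentation target."""

    image: IntensityVolume
    target: LabelVolume
    provenance: dict

    def __post_init__(self):
        if self.image.shape != self.target.shape:
            raise ValueError("image and target must share one grid")


def build_target(vol: LabelVolume, config: GenerationConfig) -> LabelVolume:
    """Reset every label outside the segmentation set to background."""
    keep = set(int(l) for l in config.segmentation_labels)
    mapping = {int(l): (int(l) if int(l) in keep else 0) for l in vol.label_set}
    return volumes.remap_labels(vol, mapping, default=0)


def sample_training_pair(
    corpus, config: GenerationConfig, rng: np.random.Generator,
    lesion_masks=None,
) -> TrainingSample:
    """Draw one fully randomised training pair from the generative model."""
    if not corpus:
        raise ValueError("corpus is empty")
    config.validate()
    prov: dict = {}

    idx = int(rng.integers(0, len(corpus)))
    prov["corpus_index"] = idx
    lab = corpus[idx]

    pairs = LateralPairs(list(config.lateral_pairs))
    lab = volumes.random_flip(lab, pairs, rng, p=config.flip_p,
                              axis=config.lr_axis, info=prov)
    if config.crop_shape is not None:
        lab = volumes.random_crop(lab, config.crop_shape, rng, info=prov)
    if config.extracerebral_labels:
        lab = volumes.drop_extracerebral(lab, config.extracerebral_labels, rng,
                                         p=config.drop_p, info=prov)
    if config.lesion_p > 0 and lesion_masks:
        lab = volumes.paste_lesions(lab, lesion_masks, config.lesion_label,
                                    config.host_labels, rng, p=config.lesion_p,
                                    info=prov)

    aff_params = spatial.sample_affine(config, rng)
    prov.update(
        rot_x=aff_params.rotations[0], rot_y=aff_params.rotations[1],
        rot_z=aff_params.rotations[2],
        scale_x=aff_params.scalings[0], scale_y=aff_params.scalings[1],
        scale_z=aff_params.scalings[2],
        shear_x=aff_params.shearings[0], shear_y=aff_params.shearings[1],
        shear_z=aff_params.shearings[2],
        trans_x=aff_params.translations[0], trans_y=aff_params.translations[1],
        trans_z=aff_params.translations[2],
    )
    center = (np.asarray(lab.shape, dtype=float) - 1.0) / 2.0
    aff = spatial.affine_matrix(aff_params, center)
    svf = spatial.sample_svf(config, lab.shape, rng)
    prov["sigma_svf"] = svf.sigma_svf
    nonlin = spatial.integrate_svf(svf, config.svf_steps) if svf.sigma_svf > 0 else None
    warped = spatial.apply_transform_labels(lab, aff, nonlin)

    gmm = intensity.sample_gmm_params(warped.label_set, config, rng)
    for k in sorted(gmm.means):
        prov[f"mu_{k}"] = gmm.means[k]
        prov[f"sigma_{k}"] = gmm.stds[k]
    g = intensity.sample_gmm_image(warped, gmm, rng)

    log_b = intensity.sample_bias_field(g.shape, config, rng)
    prov["sigma_bias"] = float(np.std(log_b.data)) if config.b_bias > 0 else 0.0
    gb = intensity.apply_bias(g, log_b)

    minmax_src = g if config.gamma_minmax_from == "pre_bias" else None
    img, gamma = intensity.rescale_and_gamma(gb, config.sigma_gamma, rng,
                                             minmax_source=minmax_src)
    prov["gamma"] = gamma

    res = resolution.sample_resolution_params(config, rng)
    prov.update(res_axis=res.axis, r_spac=res.r_spac, r_thick=res.r_thick,
                alpha=res.alpha)
    img = resolution.simulate_acquisition(img, res)
    img.data = np.clip(img.data, 0.0, 1.0)

    target = build_target(warped, config)
    return TrainingSample(image=img, target=target, provenance=prov)


def generate_batch(
    corpus, config: GenerationConfig, n: int, rng: np.random.Generator,
    out_dir, lesion_masks=None,
) -> pd.DataFrame:
    """Write n image/target NIfTI pairs plus a provenance manifest CSV."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        sample = sample_training_pair(corpus, config, rng, lesion_masks=lesion_masks)
        img_path = out_dir / f"image_{i:04d}.nii.gz"
        tgt_path = out_dir / f"target_{i:04d}.nii.gz"
        volumes.write_volume(sample.image, img_path)
        volumes.write_volume(sample.target, tgt_path)
        row = {"sample": i, "image": img_path.name, "target": tgt_path.name}
        row.update(sample.provenance)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
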