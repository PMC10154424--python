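"""Synthetic label-map corpora standing in for an anatomical training set.

The generative model only needs label maps, so a fully self-contained corpus
of "phantom" anatomies is enough to exercise and validate every stage:
nested smooth blobby shapes with a background (0), an extra-cerebral shell
(1), a tissue interior (2), and interior sub-structures (3, 4, ...) of which
the first two form a lateralised left/right pair, mirror-symmetric about the
mid-plane of axis 0 before per-phantom perturbation. No anatomical realism
is attempted — the premise of domain randomisation is that none is needed —
but the corpus reproduces the *structural* features the pipeline relies on:
a shared labelling convention, lateral pairs for flip augmentation, an
extra-cerebral shell to drop, and host tissue for lesion pasting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import GenerationConfig
from .volumes import LabelVolume, LateralPairs

__all__ = [
    "make_phantom_labels",
    "make_phantom_corpus",
    "make_lesion_blobs",
    "phantom_generation_config",
]

SHELL_LABEL = 1
TISSUE_LABEL = 2
FIRST_STRUCTURE_LABEL = 3


def _normalised_coords(shape):
    axes = [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) / ((n - 1) / 2.0) for n in shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def _smooth_noise(shape, rng, sigma):
    f = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma)
    scale = np.max(np.abs(f))
    return f / scale if scale > 0 else f


def _blob(coords, center, radii, noise=None, amp=0.0):
    d = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
    thresh = 1.0 if noise is None else (1.0 + amp * noise) ** 2
    return d < thresh


def make_phantom_labels(
    shape, n_structures: int = 3, rng: np.random.Generator | None = None
) -> LabelVolume:
    """One phantom label map; deterministic for a given generator state.

    Labels: 0 background, 1 extra-cerebral shell, 2 tissue, then
    ``n_structures`` interior structures starting at 3. When two or more
    structures are requested, labels 3 and 4 are a left/right pair mirrored
    about the mid-plane of axis 0 (identical voxel counts by construction),
    after which a small smooth random warp individualises the phantom.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError("phantom shape must be at least 16 per axis")
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    if n_structures > 6:
        raise ValueError("phantoms support at most 6 interior structures")
    rng = np.random.default_rng() if rng is None else rng
    coords = _normalised_coords(shape)
    smooth_sigma = max(2.0, min(shape) / 8.0)

    tissue_noise = _smooth_noise(shape, rng, smooth_sigma)
    tissue_r = 0.72 * float(rng.uniform(0.95, 1.05))
    tissue = _blob(coords, (0, 0, 0), (tissue_r,) * 3, tissue_noise, amp=0.12)
    shell = ndimage.binary_dilation(tissue, iterations=2) & ~tissue

    labels = np.zeros(shape, dtype=np.int32)
    labels[shell] = SHELL_LABEL
    labels[tissue] = TISSUE_LABEL

    structure_masks = []
    if n_structures >= 2:
        # mirrored pair: build the left blob, reflect it for the right one
        pair_noise = _smooth_noise(shape, rng, smooth_sigma)
        cy, cz = rng.uniform(-0.08, 0.08, 2)
        r = 0.22 * float(rng.uniform(0.9, 1.1))
        left = _blob(coords, (-0.42, cy, cz), (r, r, r), pair_noise, amp=0.2)
        right = np.flip(left, axis=0)
        structure_masks += [left, right]
    extra = n_structures - len(structure_masks)
    centers = [(0.0, 0.38, 0.0), (0.0, -0.38, 0.0), (0.0, 0.0, 0.38),
               (0.0, 0.0, -0.38), (0.3, 0.0, 0.3), (-0.3, 0.0, -0.3)]
    for i in range(extra):
        c = np.asarray(centers[i % len(centers)]) + rng.uniform(-0.05, 0.05, 3)
        r = 0.18 * float(rng.uniform(0.9, 1.1))
        noise = _smooth_noise(shape, rng, smooth_sigma)
        structure_masks.append(_blob(coords, c, (r, r, r), noise, amp=0.2))

    for i, mask in enumerate(structure_masks):
        labels[mask & tissue] = FIRST_STRUCTURE_LABEL + i

    # per-phantom smooth warp: distinguishes corpus members without breaking
    # the labelling convention
    disp = np.stack(
        [_smooth_noise(shape, rng, smooth_sigma) for _ in range(3)], axis=0
    ) * (0.04 * min(shape))
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    )
    labels = ndimage.map_coordinates(labels, grid + disp, order=0, mode="constant",
                                     cval=0)

    # guarantee every declared label keeps at least one voxel
    for i, mask in enumerate(structure_masks):
        lab = FIRST_STRUCTURE_LABEL + i
        if not np.any(labels == lab):
            idx = np.unravel_index(int(np.argmax(mask & tissue)), shape)
            labels[idx] = lab
    for lab, mask in ((SHELL_LABEL, shell), (TISSUE_LABEL, tissue)):
        if not np.any(labels == lab):
            idx = np.unravel_index(int(np.argmax(mask)), shape)
            labels[idx] = lab
    return LabelVolume(labels)


def make_phantom_corpus(
    n_maps: int, shape=(32, 32, 32), n_structures: int = 3,
    rng: np.random.Generator | None = None,
):
    """Corpus of morphologically distinct phantoms sharing one convention.

    Returns ``(volumes, lateral_pairs, role_table)`` where the role table maps
    every label to its role: background / extracerebral / tissue (the
    lesion host) / structure / lesion.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    corpus = [make_phantom_labels(shape, n_structures, rng) for _ in range(n_maps)]
    pairs = LateralPairs(
        [(FIRST_STRUCTURE_LABEL, FIRST_STRUCTURE_LABEL + 1)] if n_structures >= 2 else []
    )
    lesion_label = FIRST_STRUCTURE_LABEL + n_structures
    rows = [
        {"label": 0, "role": "background"},
        {"label": SHELL_LABEL, "role": "extracerebral"},
        {"label": TISSUE_LABEL, "role": "tissue"},
    ]
    for i in range(n_structures):
        rows.append({"label": FIRST_STRUCTURE_LABEL + i, "role": "structure"})
    rows.append({"label": lesion_label, "role": "lesion"})
    return corpus, pairs, pd.DataFrame(rows)


def make_lesion_blobs(
    n: int, rng: np.random.Generator | None = None, max_radius: int = 3
) -> list:
    """Small binary blob masks to paste into host tissue."""
    rng = np.random.default_rng() if rng is None else rng
    blobs = []
    for _ in range(n):
        r = int(rng.integers(1, max_radius + 1))
        size = 2 * r + 1
        coords = _normalised_coords((size, size, size))
        radii = rng.uniform(0.6, 1.0, 3)
        mask = _blob(coords, (0, 0, 0), radii)
        mask[r, r, r] = True
        blobs.append(LabelVolume(mask.astype(np.int32)))
    return blobs


def phantom_generation_config(
    n_structures: int = 3, desk: bool = True, **overrides
) -> GenerationConfig:
    """GenerationConfig wired to the phantom labelling convention.

    ``desk=True`` scales the spatial and resolution priors to small (~32^3)
    volumes: translations within 3 voxels, velocity-field bound 1.5 voxels,
    slice spacings up to 5 mm at r_hr = 1 mm. Contrast, bias and gamma priors
    keep their full-width reference values — randomised contrast is the point.
    """
    lesion_label = FIRST_STRUCTURE_LABEL + n_structures
    labels = tuple(range(lesion_label + 1))
    seg = (TISSUE_LABEL,) + tuple(
        FIRST_STRUCTURE_LABEL + i for i in range(n_structures)
    )
    pairs = ((FIRST_STRUCTURE_LABEL, FIRST_STRUCTURE_LABEL + 1),) if n_structures >= 2 else ()
    params = dict(
        generation_labels=labels,
        segmentation_labels=seg,
        extracerebral_labels=(SHELL_LABEL,),
        host_labels=(TISSUE_LABEL,),
        lesion_label=lesion_label,
        lateral_pairs=pairs,
    )
    if desk:
        params.update(a_tr=-3.0, b_tr=3.0, a_sc=0.9, b_sc=1.1, a_sh=-0.01,
                      b_sh=0.01, b_nonlin=1.5, b_res=5.0)
    params.update(overrides)
    return GenerationConfig(**params)
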