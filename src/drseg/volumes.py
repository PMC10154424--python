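"""Label and intensity volume containers, NIfTI I/O, and label-level augmentations.

The generative model is conditioned on 3D integer label maps; at inference time
the network consumes 3D intensity volumes. Both are carried around as light
dataclasses wrapping a numpy array plus voxel spacing (mm) and a 4x4
voxel-to-world affine. Corpus-level augmentations (left/right flipping with
lateral label swapping, cropping, extra-cerebral label dropping, lesion
pasting) operate purely on label maps, before any intensity is synthesised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "LabelVolume",
    "IntensityVolume",
    "LateralPairs",
    "read_volume",
    "write_volume",
    "remap_labels",
    "random_flip",
    "random_crop",
    "drop_extracerebral",
    "paste_lesions",
]


@dataclass
class LabelVolume:
    """Integer 3D label map with voxel spacing (mm) and world affine.

    Background is label 0 and is always permitted. ``label_set`` is the sorted
    array of labels actually present in ``data``.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default=None)
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if np.max(np.abs(self.data - rounded)) > 1e-6:
                raise ValueError("label data contains non-integral values")
            self.data = rounded.astype(np.int32)
        else:
            self.data = self.data.astype(np.int32, copy=False)
        if np.any(self.data < 0):
            raise ValueError("label values must be non-negative")
        if self.spacing is None:
            self.spacing = np.ones(3)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 strictly positive components")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def label_set(self) -> np.ndarray:
        return np.unique(self.data)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.spacing.copy(), self.affine.copy())


@dataclass
class IntensityVolume:
    """Real-valued 3D volume with voxel spacing (mm) and world affine."""

    data: np.ndarray
    spacing: np.ndarray = field(default=None)
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"intensity volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity values must be finite")
        if self.spacing is None:
            self.spacing = np.ones(3)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 strictly positive components")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.data.copy(), self.spacing.copy(), self.affine.copy())


@dataclass
class LateralPairs:
    """Left/right label pairs whose identities swap under a mirror flip."""

    pairs: list

    def __post_init__(self):
        self.pairs = [(int(a), int(b)) for a, b in self.pairs]
        seen = set()
        for left, right in self.pairs:
            if left == right:
                raise ValueError(f"left and right labels must differ, got {left}")
            for lab in (left, right):
                if lab in seen:
                    raise ValueError(f"label {lab} appears in more than one pair")
                seen.add(lab)

    def swap_mapping(self) -> dict:
        mapping = {}
        for left, right in self.pairs:
            mapping[left] = right
            mapping[right] = left
        return mapping

    @classmethod
    def from_csv(cls, path) -> "LateralPairs":
        pairs = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lstrip("-").isdigit() is False:
                    continue  # header or blank line
                pairs.append((int(row[0]), int(row[1])))
        return cls(pairs)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["left_label", "right_label"])
            writer.writerows(self.pairs)


def read_volume(path, as_labels: bool = False):
    """Read a 3D NIfTI volume as a :class:`LabelVolume` or :class:`IntensityVolume`.

    Label volumes are cast to integers; values further than 1e-6 from an
    integer raise. 4D (or higher) files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    if as_labels:
        return LabelVolume(data, spacing, affine)
    return IntensityVolume(data, spacing, affine)


def write_volume(vol, path) -> None:
    """Write a volume to NIfTI; integer dtype for labels, float32 otherwise."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int32)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def remap_labels(vol: LabelVolume, mapping: Mapping[int, int], default: int = 0) -> LabelVolume:
    """Apply an integer label-to-label map; unmapped labels receive ``default``.

    Voxel count is conserved: every voxel is assigned exactly one output label.
    """
    if any(v < 0 for v in mapping.values()) or default < 0:
        raise ValueError("target labels must be non-negative")
    max_label = int(vol.data.max()) if vol.data.size else 0
    lut = np.full(max_label + 1, default, dtype=np.int32)
    for src, dst in mapping.items():
        if 0 <= src <= max_label:
            lut[src] = dst
    return LabelVolume(lut[vol.data], vol.spacing.copy(), vol.affine.copy())


def random_flip(
    vol: LabelVolume,
    pairs: LateralPairs,
    rng: np.random.Generator,
    p: float = 0.5,
    axis: int = 0,
    info: dict | None = None,
) -> LabelVolume:
    """Mirror the map along the left-right axis and swap lateral labels, w.p. ``p``."""
    flipped = bool(rng.random() < p)
    if info is not None:
        info["flipped"] = flipped
    if not flipped:
        return vol
    mirrored = LabelVolume(np.flip(vol.data, axis=axis).copy(), vol.spacing.copy(), vol.affine.copy())
    if pairs.pairs:
        mirrored = remap_labels_partial(mirrored, pairs.swap_mapping())
    return mirrored


def remap_labels_partial(vol: LabelVolume, mapping: Mapping[int, int]) -> LabelVolume:
    """Like :func:`remap_labels` but labels absent from ``mapping`` keep their value."""
    max_label = int(vol.data.max()) if vol.data.size else 0
    lut = np.arange(max_label + 1, dtype=np.int32)
    for src, dst in mapping.items():
        if dst < 0:
            raise ValueError("target labels must be non-negative")
        if 0 <= src <= max_label:
            lut[src] = dst
    return LabelVolume(lut[vol.data], vol.spacing.copy(), vol.affine.copy())


def random_crop(
    vol: LabelVolume,
    shape: Sequence[int],
    rng: np.random.Generator,
    info: dict | None = None,
) -> LabelVolume:
    """Crop a contiguous block of the requested shape at a uniform random offset."""
    shape = tuple(int(s) for s in shape)
    if any(s > t for s, t in zip(shape, vol.shape)):
        raise ValueError(f"crop shape {shape} exceeds volume shape {vol.shape}")
    offset = tuple(int(rng.integers(0, t - s + 1)) for s, t in zip(shape, vol.shape))
    if info is not None:
        info["crop_offset"] = offset
    sl = tuple(slice(o, o + s) for o, s in zip(offset, shape))
    return LabelVolume(vol.data[sl].copy(), vol.spacing.copy(), vol.affine.copy())


def drop_extracerebral(
    vol: LabelVolume,
    extracerebral_labels: Sequence[int],
    rng: np.random.Generator,
    p: float = 0.5,
    info: dict | None = None,
) -> LabelVolume:
    """With probability ``p``, reset all listed labels to background.

    Emulates a skull-stripped input, so the network also learns to segment
    scans whose surrounding tissue has been masked away.
    """
    dropped = bool(rng.random() < p) and len(extracerebral_labels) > 0
    if info is not None:
        info["extracerebral_dropped"] = dropped
    if not dropped:
        return vol
    return remap_labels_partial(vol, {int(lab): 0 for lab in extracerebral_labels})


def paste_lesions(
    vol: LabelVolume,
    lesion_masks: Sequence[LabelVolume],
    lesion_label: int,
    host_labels: Sequence[int],
    rng: np.random.Generator,
    p: float = 0.5,
    info: dict | None = None,
) -> LabelVolume:
    """With probability ``p``, overlay one randomly placed binary lesion mask.

    Only voxels currently carrying a host label (e.g. the white-matter
    analogue) are replaced by ``lesion_label``; the lesion is clipped to the
    volume if its random offset puts it near the border.
    """
    do_paste = bool(rng.random() < p)
    if do_paste and not lesion_masks:
        raise ValueError("no lesion masks supplied")
    if info is not None:
        info["lesion_pasted"] = do_paste
    if not do_paste:
        return vol
    idx = int(rng.integers(0, len(lesion_masks)))
    mask = np.asarray(lesion_masks[idx].data) > 0
    offset = tuple(
        int(rng.integers(0, max(t - s, 0) + 1)) for s, t in zip(mask.shape, vol.shape)
    )
    if info is not None:
        info["lesion_index"] = idx
        info["lesion_offset"] = offset
    out = vol.data.copy()
    sl = tuple(slice(o, min(o + s, t)) for o, s, t in zip(offset, mask.shape, vol.shape))
    sub = out[sl]
    mask_clip = mask[tuple(slice(0, s.stop - s.start) for s in sl)]
    host = np.isin(sub, np.asarray(list(host_labels), dtype=np.int32))
    sub[mask_clip & host] = lesion_label
    return LabelVolume(out, vol.spacing.copy(), vol.affine.copy())
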