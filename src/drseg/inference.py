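"""Test-time pipeline: resample, rescale, flip-augmented prediction, postprocess.

Input scans of any resolution are trilinearly resampled to the isotropic
working resolution r_HR (so the network output is always a crisp HR
segmentation, whatever the acquisition grid), robustly rescaled to [0, 1]
using the 1st and 99th intensity percentiles, and segmented twice: once as-is
and once left/right mirrored. The mirrored soft prediction is un-mirrored
with its lateral label channels swapped back and averaged with the direct
one. The final labelling is the per-voxel argmax followed by
largest-connected-component filtering per foreground label.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .training import Checkpoint, channel_labels
from .volumes import IntensityVolume, LabelVolume, LateralPairs, read_volume, write_volume

__all__ = [
    "preprocess",
    "predict_flip_augmented",
    "predict_soft",
    "postprocess",
    "segment",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def preprocess(scan: IntensityVolume, r_hr: float = 1.0) -> IntensityVolume:
    """Resample to isotropic r_hr and percentile-rescale to [0, 1].

    The 1st percentile maps to 0 and the 99th to 1; values beyond are clipped.
    """
    data = scan.data
    factors = scan.spacing / r_hr
    if not np.allclose(factors, 1.0):
        data = ndimage.zoom(data, factors, order=1, mode="nearest", grid_mode=False)
    p1, p99 = np.percentile(data, [1.0, 99.0])
    if p99 <= p1:
        raise ValueError("cannot rescale a (near-)constant scan")
    data = np.clip((data - p1) / (p99 - p1), 0.0, 1.0)
    affine = scan.affine.copy()
    affine[:3, :3] /= factors  # voxel size is now r_hr along each axis
    return IntensityVolume(data, np.full(3, r_hr), affine)


def _pad_to_multiple(x: np.ndarray, div: int):
    pads = [(0, (-s) % div) for s in x.shape]
    if any(p[1] for p in pads):
        return np.pad(x, pads, mode="edge"), pads
    return x, pads


def _predict_padded(net, data: np.ndarray) -> np.ndarray:
    div = 2 ** (net.config.n_levels - 1)
    padded, pads = _pad_to_multiple(data.astype(np.float32), div)
    y = net.predict_proba(padded[None])
    crop = tuple(slice(0, s) for s in data.shape)
    return y[(slice(None),) + crop]


def _swap_lateral_channels(y: np.ndarray, seg_labels, pairs: LateralPairs) -> np.ndarray:
    chans = channel_labels(seg_labels)
    index = {lab: c for c, lab in enumerate(chans)}
    order = list(range(len(chans)))
    for left, right in pairs.pairs:
        if left in index and right in index:
            order[index[left]], order[index[right]] = index[right], index[left]
    return y[order]


def predict_soft(model, scan: IntensityVolume) -> np.ndarray:
    """Single-pass soft prediction ``(K'+1, D, H, W)`` on the scan grid."""
    net, _ = _as_net(model)
    return _predict_padded(net, scan.data)


def _as_net(model):
    if isinstance(model, Checkpoint):
        return model.build(), model.segmentation_labels
    # a (net, segmentation_labels) tuple is also accepted
    net, seg_labels = model
    return net, tuple(seg_labels)


def predict_flip_augmented(
    model, scan: IntensityVolume, pairs: LateralPairs, lr_axis: int = 0,
    flip_augment: bool = True,
) -> np.ndarray:
    """Average the soft predictions of the scan and its left/right mirror.

    The mirrored prediction is flipped back to native orientation and its
    lateral label channels are swapped so left/right structures land on the
    correct side. Per-voxel probabilities still sum to 1 (convex average).
    """
    net, seg_labels = _as_net(model)
    y = _predict_padded(net, scan.data)
    if not flip_augment:
        return y
    flipped = np.flip(scan.data, axis=lr_axis).copy()
    y_flip = _predict_padded(net, flipped)
    y_flip = np.flip(y_flip, axis=lr_axis + 1)  # channel axis leads
    y_flip = _swap_lateral_channels(y_flip, seg_labels, pairs)
    return 0.5 * (y + y_flip)


def postprocess(y: np.ndarray, segmentation_labels, spacing=None) -> LabelVolume:
    """Argmax labelling followed by largest-connected-component filtering.

    Argmax ties resolve to the lowest channel (hence lowest label); for each
    foreground label, all but its largest 26-connected component are reset to
    background, equal-sized candidates resolving to the component containing
    the lexicographically smallest voxel.
    """
    chans = np.asarray(channel_labels(segmentation_labels))
    hard = chans[y.argmax(axis=0)]
    for lab in chans[1:]:
        mask = hard == lab
        if not mask.any():
            continue
        comps, n = ndimage.label(mask, structure=_CONNECTIVITY_26)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1  # argmax keeps the earliest on ties
        hard[mask & (comps != keep)] = 0
    spacing = np.ones(3) if spacing is None else np.asarray(spacing, dtype=float)
    return LabelVolume(hard.astype(np.int32), spacing)


def segment(
    model, scan, pairs: LateralPairs | None = None, out_path=None,
    r_hr: float = 1.0, lr_axis: int = 0, flip_augment: bool = True,
    save_soft: bool = False, native_grid: bool = False,
):
    """Full test-time pipeline; returns the HR segmentation (and writes it).

    ``model`` is a :class:`~drseg.training.Checkpoint` (or a path to a saved
    one); ``scan`` an :class:`IntensityVolume` or NIfTI path. The output lives
    on the preprocessed isotropic r_hr grid; ``native_grid=True`` additionally
    resamples the labelling back to the input grid with nearest neighbours.
    """
    if isinstance(model, (str, bytes)) or hasattr(model, "__fspath__"):
        model = load_checkpoint(model)
    if isinstance(scan, (str, bytes)) or hasattr(scan, "__fspath__"):
        scan = read_volume(scan, as_labels=False)
    pairs = pairs if pairs is not None else LateralPairs([])
    pre = preprocess(scan, r_hr=r_hr)
    _, seg_labels = _as_net(model)
    y = predict_flip_augmented(model, pre, pairs, lr_axis=lr_axis,
                               flip_augment=flip_augment)
    out = postprocess(y, seg_labels, spacing=pre.spacing)
    out.affine = pre.affine.copy()
    if native_grid:
        factors = np.asarray(scan.shape) / np.asarray(out.shape)
        coords = np.meshgrid(
            *[np.arange(s) / f for s, f in zip(scan.shape, factors)], indexing="ij"
        )
        native = ndimage.map_coordinates(out.data, np.stack(coords), order=0,
                                         mode="nearest")
        out = LabelVolume(native, scan.spacing.copy(), scan.affine.copy())
    if out_path is not None:
        write_volume(out, out_path)
        if save_soft:
            np.savez(str(out_path) + ".soft.npz", soft=y.astype(np.float32))
    return out


def load_checkpoint(path) -> Checkpoint:
    """Load a checkpoint saved by :meth:`Checkpoint.save`."""
    from .nn import ModelConfig

    with np.load(path, allow_pickle=False) as data:
        n_arrays = len([k for k in data.files if k.startswith("arr_")])
        weights = [data[f"arr_{i}"] for i in range(n_arrays)]
        step = int(data["step"])
        seg_labels = tuple(int(l) for l in data["segmentation_labels"])
        config = ModelConfig(n_levels=int(data["n_levels"]),
                             first_features=int(data["first_features"]))
    ckpt = Checkpoint(step, weights, config, seg_labels)
    ckpt.build()  # validates that shapes match the stored architecture
    ckpt.path = path
    return ckpt
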