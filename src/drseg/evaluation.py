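"""Segmentation metrics and group-study statistics.

Dice overlap and the 95th-percentile surface distance (SD95, mm) score
segmentations against references. For volumetric group studies, structure
volumes are obtained by summing soft predictions (which propagates
segmentation uncertainty into the volume estimate), corrected for nuisance
covariates (age, sex, intracranial volume analogues) with a pooled ordinary
least squares model, and compared between groups with Cohen's d,

    d = (mu_C - mu_AD) / s,
    s^2 = [(n_C - 1) s_C^2 + (n_AD - 1) s_AD^2] / (n_C + n_AD - 2),

using unbiased (n-1) group variances. A 1-D expectation-maximisation
intensity clustering subdivides labels into finer sub-labels (e.g. blood
pools inside cardiac chambers, a random number of background regions) so a
coarse label map can drive the generative model for images whose tissues it
does not describe; sub-labels always merge back to their parents exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "GroupStudyTable",
    "hard_dice",
    "surface_distance_95",
    "soft_volume",
    "covariate_correct",
    "cohens_d",
    "em_subdivide",
    "EMResult",
]


@dataclass
class GroupStudyTable:
    """Per-subject volumes with group membership and nuisance covariates.

    ``table`` must contain a ``group`` column (two levels, control first in
    sorted order unless ``control``/``case`` are given), a ``volume`` column
    (mm^3), and any number of covariate columns.
    """

    table: pd.DataFrame
    control: str = "C"
    case: str = "AD"
    volume_col: str = "volume"

    def __post_init__(self):
        if "group" not in self.table.columns or self.volume_col not in self.table.columns:
            raise ValueError("table needs 'group' and volume columns")
        for grp in (self.control, self.case):
            if not (self.table["group"] == grp).any():
                raise ValueError(f"group '{grp}' is empty")

    def covariate_columns(self):
        return [c for c in self.table.columns if c not in ("group", self.volume_col)]


def _mask(vol: LabelVolume, label: int) -> np.ndarray:
    return vol.data == int(label)


def hard_dice(a: LabelVolume, b: LabelVolume, label: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of one label; 1 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError("volumes must share one grid")
    ma, mb = _mask(a, label), _mask(b, label)
    s = int(ma.sum()) + int(mb.sum())
    if s == 0:
        return 1.0
    return 2.0 * int(np.logical_and(ma, mb).sum()) / s


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask voxels with a 6-neighbour outside the mask."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def surface_distance_95(
    a: LabelVolume, b: LabelVolume, label: int, spacing=None
) -> float:
    """95th percentile of the pooled symmetric surface distance (mm)."""
    if a.shape != b.shape:
        raise ValueError("volumes must share one grid")
    spacing = a.spacing if spacing is None else np.asarray(spacing, dtype=float)
    ma, mb = _mask(a, label), _mask(b, label)
    if not ma.any() or not mb.any():
        raise ValueError(f"label {label} is empty in one of the volumes")
    sa, sb = _boundary(ma), _boundary(mb)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    pooled = np.concatenate([dist_to_b[sa], dist_to_a[sb]])
    return float(np.percentile(pooled, 95.0))


def soft_volume(y: np.ndarray, channel: int, spacing=(1.0, 1.0, 1.0)) -> float:
    """Volume (mm^3) of one soft channel: sum of probabilities x voxel volume."""
    spacing = np.asarray(spacing, dtype=float)
    return float(y[channel].sum() * spacing.prod())


def covariate_correct(study: GroupStudyTable) -> GroupStudyTable:
    """Residualise volumes on the covariates (pooled OLS with intercept).

    Corrected volume = OLS residual + grand mean, so the corrected values keep
    the original scale but are orthogonal to every covariate.
    """
    covs = study.covariate_columns()
    if not covs:
        return study
    df = study.table
    if len(df) < len(covs) + 2:
        raise ValueError("need at least 2 more subjects than covariates")
    x = sm.add_constant(df[covs].to_numpy(dtype=float))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    yv = df[study.volume_col].to_numpy(dtype=float)
    fit = sm.OLS(yv, x).fit()
    corrected = fit.resid + yv.mean()
    out = df.copy()
    out[study.volume_col] = corrected
    return GroupStudyTable(out, study.control, study.case, study.volume_col)


def cohens_d(study: GroupStudyTable) -> float:
    """Standardised mean difference (control minus case) with pooled s."""
    df = study.table
    vc = df.loc[df["group"] == study.control, study.volume_col].to_numpy(dtype=float)
    va = df.loc[df["group"] == study.case, study.volume_col].to_numpy(dtype=float)
    if len(vc) < 2 or len(va) < 2:
        raise ValueError("each group needs at least 2 subjects")
    nc, na = len(vc), len(va)
    pooled_var = ((nc - 1) * vc.var(ddof=1) + (na - 1) * va.var(ddof=1)) / (nc + na - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    return float((vc.mean() - va.mean()) / np.sqrt(pooled_var))


# ----------------------------------------------------------------- EM clustering


@dataclass
class EMResult:
    """Subdivided label map, sub-label-to-parent mapping, EM diagnostics."""

    labels: LabelVolume
    parents: dict  # sub-label -> parent label
    log_likelihoods: dict  # parent label -> per-iteration log-likelihood trace

    def merge_by_parent(self) -> LabelVolume:
        from .volumes import remap_labels

        return remap_labels(self.labels, self.parents, default=0)


def _em_1d(values: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 100, tol: float = 1e-6):
    """1-D Gaussian mixture EM with k-means-style initialisation.

    Returns hard assignments (0..k-1) and the log-likelihood trace, which is
    non-decreasing up to the convergence tolerance.
    """
    n = values.size
    if n < k:
        raise ValueError(f"cannot split {n} voxels into {k} clusters")
    if k == 1:
        return np.zeros(n, dtype=np.int64), [float(-np.inf)]
    spread = float(values.max() - values.min())
    floor = max(1e-3 * spread, 1e-12)
    # init: centroids at evenly spaced quantiles, then a few k-means sweeps
    centers = np.quantile(values, (np.arange(k) + 0.5) / k)
    centers = centers + rng.normal(0.0, 1e-9, k)  # break exact ties
    for _ in range(10):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        for j in range(k):
            sel = values[assign == j]
            if sel.size:
                centers[j] = sel.mean()
    weights = np.full(k, 1.0 / k)
    stds = np.full(k, max(np.std(values), floor))
    means = centers.copy()
    lls: list[float] = []
    for _ in range(max_iter):
        # E-step in log domain
        log_pdf = (
            -0.5 * ((values[:, None] - means[None, :]) / stds[None, :]) ** 2
            - np.log(stds[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(weights[None, :])
        )
        m = log_pdf.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        lls.append(float(log_norm.sum()))
        resp = np.exp(log_pdf - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp * values[:, None]).sum(axis=0) / nk
        var = (resp * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        stds = np.sqrt(np.maximum(var, floor ** 2))
        if len(lls) > 1 and lls[-1] - lls[-2] < tol:
            break
    # final hard assignment by posterior
    log_pdf = (
        -0.5 * ((values[:, None] - means[None, :]) / stds[None, :]) ** 2
        - np.log(stds[None, :])
        + np.log(weights[None, :])
    )
    assign = np.argmax(log_pdf, axis=1)
    return assign, lls


def em_subdivide(
    scan: IntensityVolume,
    vol: LabelVolume,
    n_sub_fg: int = 2,
    n_sub_bg_range: tuple = (3, 10),
    rng: np.random.Generator | None = None,
) -> EMResult:
    """Split each label into intensity clusters; background into N ~ U{range}.

    Foreground labels are split into ``n_sub_fg`` clusters each (2 models the
    bright blood pool inside cardiac chambers); the background is split into a
    random number of regions drawn uniformly from the inclusive range. Fresh
    consecutive sub-labels are assigned, and merging sub-labels by parent
    reproduces the input map exactly.
    """
    if scan.shape != vol.shape:
        raise ValueError("scan and label map must share one grid")
    rng = np.random.default_rng() if rng is None else rng
    out = np.zeros(vol.shape, dtype=np.int32)
    parents: dict = {}
    traces: dict = {}
    next_label = 1
    for parent in [int(l) for l in vol.label_set]:
        mask = vol.data == parent
        k = int(rng.integers(n_sub_bg_range[0], n_sub_bg_range[1] + 1)) if parent == 0 \
            else int(n_sub_fg)
        values = scan.data[mask].astype(float)
        assign, lls = _em_1d(values, k, rng)
        traces[parent] = lls
        subs = next_label + np.arange(k)
        out[mask] = subs[assign]
        for s in subs:
            parents[int(s)] = parent
        next_label += k
    return EMResult(LabelVolume(out, vol.spacing.copy(), vol.affine.copy()),
                    parents, traces)
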