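"""Voxelwise cohort inference on lFCD maps.

Given one lFCD map per subject, the module provides the two inference routes
of a classic expertise study: a pooled-variance two-sample t contrast between
a "top" (expert) and a "lower" group, and a Pearson correlation of lFCD with
a per-subject covariate (the expertise rank level), each within a subset of
the cohort. Multiplicity is handled by Benjamini–Hochberg FDR over in-mask
voxelwise two-sided p-values, followed by a cluster-extent threshold
(components with voxel count strictly greater than a minimum survive).
Surviving clusters are reported with voxel count, peak statistic, peak world
coordinate and optional atlas labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .lfcd import connectivity_structure
from .volumeio import (
    CLUSTER_REPORT_COLUMNS,
    BrainMask,
    GridCompatibilityError,
    voxel_to_world,
)

logger = logging.getLogger(__name__)

GROUPS = ("top", "lower")


@dataclass
class Cohort:
    """Per-subject records plus the stacked lFCD maps.

    ``table`` columns: ``subject_id`` (unique), ``group`` in {"top", "lower"},
    ``rank_level`` (scalar covariate), optionally ``map_path``. ``maps`` is the
    (N, X, Y, Z) array of per-subject maps aligned with the table rows.
    """

    table: pd.DataFrame
    maps: np.ndarray | None = None

    def __post_init__(self) -> None:
        for col in ("subject_id", "group", "rank_level"):
            if col not in self.table.columns:
                raise ValueError(f"cohort table is missing column {col!r}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("subject_id values must be unique")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        if self.maps is not None:
            self.maps = np.asarray(self.maps, dtype=np.float64)
            if self.maps.ndim != 4 or self.maps.shape[0] != len(self.table):
                raise ValueError("maps must be (n_subjects, X, Y, Z)")

    def subset(self, group: str) -> "Cohort":
        sel = (self.table["group"] == group).to_numpy()
        return Cohort(
            table=self.table.loc[sel].reset_index(drop=True),
            maps=None if self.maps is None else self.maps[sel],
        )


@dataclass
class StatMap:
    """Voxelwise statistic plus two-sided p-values."""

    data: np.ndarray  # t or r field
    p: np.ndarray
    df: int
    kind: str  # "t_two_sample" | "pearson_r"


@dataclass
class ThresholdSpec:
    """FDR + cluster-extent control.

    ``min_cluster_voxels`` is applied as strictly greater-than (the default
    k > 20); ``cluster_connectivity`` defines which voxels touch.
    """

    fdr_q: float = 0.05
    min_cluster_voxels: int = 20
    cluster_connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.min_cluster_voxels < 0:
            raise ValueError("min_cluster_voxels must be >= 0")
        if self.cluster_connectivity not in (6, 18, 26):
            raise ValueError("cluster_connectivity must be 6, 18 or 26")


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance Student t (a minus b) along axis 0, with two-sided p.

    Voxels with zero pooled variance get t = 0, p = 1.
    """
    import warnings

    with warnings.catch_warnings():
        # near-constant voxels trigger scipy's precision-loss warning; they are
        # remapped to t = 0, p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(res.statistic, dtype=np.float64)
    p = np.asarray(res.pvalue, dtype=np.float64)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return t, p


def t_contrast(cohort: Cohort, mask: BrainMask) -> StatMap:
    """Voxelwise pooled two-sample t, oriented top − lower.

    Positive values mean higher lFCD in the top group; two-sided p from the
    Student t distribution with ``n_top + n_lower − 2`` degrees of freedom.
    """
    if cohort.maps is None:
        raise ValueError("cohort carries no maps")
    groups = cohort.table["group"].to_numpy()
    a = cohort.maps[groups == "top"]
    b = cohort.maps[groups == "lower"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 subjects, got top={len(a)}, lower={len(b)}"
        )
    m = mask.data
    t_vals, p_vals = two_sample_t(a[:, m], b[:, m])
    n_degenerate = int((p_vals == 1.0).sum())
    if n_degenerate:
        logger.info("%d voxel(s) had zero pooled variance", n_degenerate)
    t_map = np.zeros(m.shape)
    p_map = np.ones(m.shape)
    t_map[m] = t_vals
    p_map[m] = p_vals
    return StatMap(data=t_map, p=p_map, df=len(a) + len(b) - 2, kind="t_two_sample")


def pearson_r_vector(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of ``x`` (N, V) against ``y`` (N,), with
    two-sided p via the t transform ``t = r sqrt((n−2)/(1−r²))``.

    Zero-variance columns get r = 0, p = 1.
    """
    n = len(y)
    yc = y - y.mean()
    ynorm = float(np.sqrt(yc @ yc))
    if ynorm <= 0:
        raise ValueError("covariate is constant")
    xc = x - x.mean(axis=0, keepdims=True)
    xnorm = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    ok = xnorm > 0
    r = np.zeros(x.shape[1])
    r[ok] = (yc @ xc[:, ok]) / (xnorm[ok] * ynorm)
    r = np.clip(r, -1.0, 1.0)
    p = np.ones_like(r)
    with np.errstate(divide="ignore"):
        t = r[ok] * np.sqrt((n - 2) / np.maximum(1.0 - r[ok] ** 2, 0.0))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[ok & (np.abs(r) >= 1.0)] = 0.0
    return r, p


def r_map(cohort: Cohort, mask: BrainMask, subset: str | None = None) -> StatMap:
    """Voxelwise Pearson correlation of lFCD with ``rank_level``.

    ``subset`` restricts to one group (e.g. "top", mirroring a correlation
    within the expert group only); requires >= 3 subjects and a non-constant
    covariate in the subset.
    """
    if cohort.maps is None:
        raise ValueError("cohort carries no maps")
    sub = cohort if subset is None else cohort.subset(subset)
    n = len(sub.table)
    if n < 3:
        raise ValueError(f"correlation requires >= 3 subjects, got {n}")
    y = sub.table["rank_level"].to_numpy(dtype=np.float64)
    if np.ptp(y) == 0:
        raise ValueError("rank_level is constant in the analysis subset")
    m = mask.data
    r, p = pearson_r_vector(sub.maps[:, m], y)
    n_degenerate = int((r == 0).sum())
    if n_degenerate:
        logger.info("%d voxel(s) had zero variance across subjects", n_degenerate)
    r_vol = np.zeros(m.shape)
    p_vol = np.ones(m.shape)
    r_vol[m] = r
    p_vol[m] = p
    return StatMap(data=r_vol, p=p_vol, df=n - 2, kind="pearson_r")


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up: per-input rejection flags, original order."""
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def significance_mask(stat: StatMap, mask: BrainMask, q: float = 0.05) -> np.ndarray:
    """FDR-corrected voxelwise significance over the in-mask p-values."""
    m = mask.data
    sig = np.zeros(m.shape, dtype=bool)
    sig[m] = fdr_bh(stat.p[m], q)
    return sig


def cluster_filter(sig: np.ndarray, spec: ThresholdSpec | None = None) -> np.ndarray:
    """Label connected components of a binary field and drop the small ones.

    Components with voxel count <= ``min_cluster_voxels`` are removed;
    survivors are relabelled 1..C in order of descending size (ties broken by
    the original scan-order label, for determinism).
    """
    spec = spec or ThresholdSpec()
    structure = connectivity_structure(spec.cluster_connectivity)
    labels, n = ndimage.label(np.asarray(sig, dtype=bool), structure=structure)
    out = np.zeros_like(labels)
    if n == 0:
        return out
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    order = sorted(range(1, n + 1), key=lambda lab: (-sizes[lab - 1], lab))
    new_id = 0
    for lab in order:
        if sizes[lab - 1] > spec.min_cluster_voxels:
            new_id += 1
            out[labels == lab] = new_id
    return out


def report_clusters(
    stat: StatMap,
    clusters: np.ndarray,
    affine: np.ndarray,
    atlas: np.ndarray | None = None,
    atlas_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """One row per cluster: extent, peak statistic, peak world coordinate, labels.

    The peak is the voxel maximizing |statistic| within the cluster (ties go
    to the smallest linear index); ``region_labels`` lists the atlas labels
    overlapping the cluster, ordered by overlap count (ties by label value).
    """
    clusters = np.asarray(clusters)
    if clusters.shape != stat.data.shape:
        raise GridCompatibilityError("cluster field does not match the statistic grid")
    if atlas is not None and np.asarray(atlas).shape != stat.data.shape:
        raise GridCompatibilityError("atlas does not match the statistic grid")
    rows = []
    for cid in range(1, int(clusters.max()) + 1):
        coords = np.argwhere(clusters == cid)  # C order == ascending linear index
        vals = stat.data[tuple(coords.T)]
        peak_i = int(np.argmax(np.abs(vals)))  # first occurrence: smallest linear index
        peak_xyz = voxel_to_world(coords[peak_i], affine, shape=stat.data.shape)
        labels: list[str] = []
        if atlas is not None:
            lab_vals = np.asarray(atlas)[tuple(coords.T)]
            lab_vals = lab_vals[lab_vals != 0]
            if lab_vals.size:
                uniq, counts = np.unique(lab_vals, return_counts=True)
                order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
                labels = [
                    atlas_names.get(int(uniq[i]), str(int(uniq[i])))
                    if atlas_names
                    else str(int(uniq[i]))
                    for i in order
                ]
        rows.append(
            {
                "cluster_id": cid,
                "region_labels": labels,
                "voxel_count": int(len(coords)),
                "peak_value": float(vals[peak_i]),
                "peak_x_mm": float(peak_xyz[0]),
                "peak_y_mm": float(peak_xyz[1]),
                "peak_z_mm": float(peak_xyz[2]),
            }
        )
    return pd.DataFrame(rows, columns=CLUSTER_REPORT_COLUMNS)
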