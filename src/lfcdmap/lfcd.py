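"""Local functional connectivity density (lFCD) mapping.

For every in-mask seed voxel x0 the searching algorithm grows a spatially
contiguous cluster: the seed's spatial neighbours are examined first, any
candidate whose time course has Pearson correlation with the *seed* series
strictly greater than the threshold R joins the cluster, and the neighbours
of accepted voxels are examined in turn, until no unexamined neighbour
remains. The cluster size (seed excluded by default) is the seed's lFCD.

The per-subject map is then normalized to its in-mask mean and smoothed with
a Gaussian kernel of given FWHM. Smoothing uses mask-renormalized weights
(the kernel is renormalized over in-mask support at every voxel) so that the
brain boundary does not attenuate the map and uniform fields are fixed
points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volumeio import BrainMask, FunctionalImage, require_grid_compatible

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian = sigma * 2 sqrt(2 ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """Integer offsets of the 6-, 18-, or 26-neighbourhood (3x3x3 minus centre)."""
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d2 = dx * dx + dy * dy + dz * dz
                if d2 == 0:
                    continue
                if connectivity == 6 and d2 > 1:
                    continue
                if connectivity == 18 and d2 > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=np.int64)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 boolean structuring element matching :func:`neighbor_offsets`."""
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1, 1, 1] = True
    for dx, dy, dz in neighbor_offsets(connectivity):
        s[dx + 1, dy + 1, dz + 1] = True
    return s


@dataclass
class LFCDParams:
    """Parameters of the lFCD search and the map post-processing.

    Attributes
    ----------
    r_threshold : float
        Pearson correlation threshold R in (0, 1); membership requires r > R
        (strict). Default 0.6.
    connectivity : {6, 18, 26}
        Spatial neighbourhood defining "closest neighbouring voxels".
        Default 26 (full 3x3x3 cube minus the centre).
    count_includes_seed : bool
        When True the seed itself is counted, shifting every value by +1.
    smooth_fwhm_mm : float
        Gaussian smoothing width; 0 disables smoothing. Default 8 mm.
    normalize : bool
        Divide each map by its in-mask mean before smoothing. Default True.
    """

    r_threshold: float = 0.6
    connectivity: int = 26
    count_includes_seed: bool = False
    smooth_fwhm_mm: float = 8.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError(f"r_threshold must lie in (0, 1), got {self.r_threshold}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")


@dataclass
class LFCDMap:
    """A 3D lFCD field plus provenance flags.

    Before normalization/smoothing every in-mask value is a non-negative
    integer count; out-of-mask voxels are zero.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: BrainMask
    params: LFCDParams
    normalized: bool = False
    smoothed: bool = False
    n_dropped_voxels: int = 0

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask_mean(self) -> float:
        return float(self.data[self.mask.data].mean())


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean rows and scale to unit norm; returns (z, keep) where ``keep``
    flags rows with nonzero variance. Row dot products of ``z`` are Pearson r."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    keep = norms > np.finfo(np.float64).tiny ** 0.5
    z = np.zeros_like(xc)
    z[keep] = xc[keep] / norms[keep, None]
    return z, keep


def _neighbor_table(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """(N, K) table of compact in-mask neighbour indices, -1 where absent."""
    coords = np.argwhere(mask)
    n = len(coords)
    idx_vol = np.full(mask.shape, -1, dtype=np.int64)
    idx_vol[tuple(coords.T)] = np.arange(n)
    offs = neighbor_offsets(connectivity)
    table = np.full((n, len(offs)), -1, dtype=np.int64)
    shape = np.asarray(mask.shape)
    for k, off in enumerate(offs):
        p = coords + off
        ok = np.all((p >= 0) & (p < shape), axis=1)
        table[ok, k] = idx_vol[tuple(p[ok].T)]
    return table


def compute_lfcd(img: FunctionalImage, mask: BrainMask, params: LFCDParams | None = None) -> LFCDMap:
    """Seed-anchored region-growing lFCD for every in-mask voxel.

    Correlations are always evaluated against the seed's series (not against
    the neighbour that contributed the candidate), each candidate is examined
    at most once per seed, and growth stops when the frontier empties. Voxels
    whose series has zero variance are dropped from the analysis mask with a
    logged count; they receive lFCD 0 and cannot join any cluster.
    """
    params = params or LFCDParams()
    require_grid_compatible(img, mask, "image and mask")
    if img.n_volumes < 3:
        raise ValueError("lFCD requires at least 3 time points")

    m = mask.data
    z, keep = _zscore_rows(img.data[m])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance voxel(s) from the mask", n_dropped)
        coords = np.argwhere(m)
        m = m.copy()
        m[tuple(coords[~keep].T)] = False
        if not m.any():
            raise ValueError("no voxel with nonzero variance remains in the mask")
        z = z[keep]

    nbr = _neighbor_table(m, params.connectivity)
    n = z.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    stamp = np.full(n, -1, dtype=np.int64)  # visited marker, one pass per seed
    r_thr = params.r_threshold

    for seed in range(n):
        zs = z[seed]
        stamp[seed] = seed
        frontier = nbr[seed]
        frontier = frontier[frontier >= 0]
        stamp[frontier] = seed
        total = 0
        while frontier.size:
            r = z[frontier] @ zs
            accepted = frontier[r > r_thr]
            total += accepted.size
            if not accepted.size:
                break
            cand = nbr[accepted].ravel()
            cand = cand[cand >= 0]
            cand = np.unique(cand)
            frontier = cand[stamp[cand] != seed]
            stamp[frontier] = seed
        counts[seed] = total

    if params.count_includes_seed:
        counts += 1

    out = np.zeros(mask.data.shape, dtype=np.float64)
    out[m] = counts
    return LFCDMap(
        data=out,
        affine=img.affine,
        mask=mask,
        params=params,
        n_dropped_voxels=n_dropped,
    )


def normalize_map(m: LFCDMap, mask: BrainMask | None = None) -> LFCDMap:
    """Divide every in-mask value by the in-mask mean (mask-mean becomes 1)."""
    mask = mask or m.mask
    mm = mask.data
    mean = float(m.data[mm].mean())
    if mean <= 0:
        raise ValueError(
            "map mean is zero — no voxel exceeded the correlation threshold; "
            "review r_threshold/connectivity"
        )
    out = m.data.copy()
    out[mm] = out[mm] / mean
    return replace(m, data=out, normalized=True)


def smooth_map(m: LFCDMap, mask: BrainMask | None = None, fwhm_mm: float | None = None) -> LFCDMap:
    """Gaussian smoothing with mask-renormalized weights.

    ``sigma_vox = fwhm_mm / (2 sqrt(2 ln 2) * voxel_size)`` per axis; at each
    voxel the kernel is renormalized over in-mask support, so a uniform
    in-mask field is a fixed point and ``fwhm_mm = 0`` is the identity.
    """
    mask = mask or m.mask
    if fwhm_mm is None:
        fwhm_mm = m.params.smooth_fwhm_mm
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return replace(m, data=m.data.copy(), smoothed=True)
    voxel_size = np.linalg.norm(m.affine[:3, :3], axis=0)
    sigma = fwhm_mm / (FWHM_PER_SIGMA * voxel_size)
    mm = mask.data
    num = ndimage.gaussian_filter(np.where(mm, m.data, 0.0), sigma=sigma)
    den = ndimage.gaussian_filter(mm.astype(np.float64), sigma=sigma)
    out = np.zeros_like(m.data)
    inside = mm & (den > 0)
    out[inside] = num[inside] / den[inside]
    return replace(m, data=out, smoothed=True)


def lfcd_chain(img: FunctionalImage, mask: BrainMask, params: LFCDParams | None = None) -> LFCDMap:
    """compute -> (normalize) -> (smooth), honouring the params flags."""
    params = params or LFCDParams()
    out = compute_lfcd(img, mask, params)
    if params.normalize:
        out = normalize_map(out, mask)
    if params.smooth_fwhm_mm > 0:
        out = smooth_map(out, mask, params.smooth_fwhm_mm)
    return out
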