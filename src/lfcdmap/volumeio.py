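"""Volumetric image I/O and spatial bookkeeping.

Functional images and brain masks are light wrappers around numpy arrays plus
the NIfTI affine. Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` tuples;
* world coordinates are continuous millimetres obtained through the affine
  (the NIfTI convention, so coordinates are MNI mm when the input volumes are
  MNI-registered);
* masks are boolean, binarized at ``value > 0`` on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: absolute per-entry tolerance when comparing affines of two grids (mm).
#: Absorbs float32 header round-trip noise without hiding real misregistration.
AFFINE_ATOL = 1e-4

CLUSTER_REPORT_COLUMNS = [
    "cluster_id",
    "region_labels",
    "voxel_count",
    "peak_value",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
]


class VolumeError(ValueError):
    """Base class for volume-related errors."""


class VolumeKindError(VolumeError):
    """A 3D volume was found where 4D was expected, or vice versa."""


class GridCompatibilityError(VolumeError):
    """Two volumes do not share a spatial grid (shape + affine)."""


@dataclass
class FunctionalImage:
    """One subject's 4D BOLD volume: ``data`` has shape (X, Y, Z, T).

    Parameters
    ----------
    data : ndarray
        4D scalar field, arbitrary signal units.
    affine : ndarray
        4x4 voxel-index -> world-mm transform.
    tr_sec : float
        Repetition time (sampling interval) in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_sec: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise VolumeKindError(f"FunctionalImage requires 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise VolumeError("FunctionalImage requires at least 2 time points")
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeError("affine is singular")
        if not self.tr_sec > 0:
            raise VolumeError(f"tr_sec must be positive, got {self.tr_sec}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Column norms of the linear part of the affine, per spatial axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class BrainMask:
    """3D boolean field of analyzable voxels sharing a grid with the images."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeKindError(f"BrainMask requires 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if not self.data.any():
            raise VolumeError("mask contains no in-mask voxel")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ScalarVolume:
    """A 3D scalar field (e.g. an lFCD map or statistic image) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeKindError(f"ScalarVolume requires 3D data, got {self.data.ndim}D")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_scalar_volume(path: str | Path) -> ScalarVolume:
    """Load a 3D NIfTI as continuous values (no mask binarization)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeKindError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return ScalarVolume(data=data, affine=img.affine)


def read_volume(
    path: str | Path,
    expect: str | None = None,
    tr_sec: float | None = None,
) -> FunctionalImage | BrainMask:
    """Load a NIfTI volume as a :class:`FunctionalImage` (4D) or :class:`BrainMask` (3D).

    Parameters
    ----------
    path : str or Path
        NIfTI-1/2 file, optionally gzip-compressed.
    expect : {"image", "mask", None}
        Raise :class:`VolumeKindError` when the file dimensionality does not
        match the expectation; ``None`` accepts either.
    tr_sec : float, optional
        Override for the repetition time; by default it is taken from the
        header (``pixdim[4]``), and a missing/zero header TR is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if expect == "mask":
            raise VolumeKindError(f"{path}: expected a 3D mask, found a 4D image")
        if tr_sec is None:
            zooms = img.header.get_zooms()
            tr_sec = float(zooms[3]) if len(zooms) > 3 else 0.0
            if not tr_sec > 0:
                raise VolumeError(f"{path}: header carries no repetition time; pass tr_sec")
        return FunctionalImage(data=data, affine=img.affine, tr_sec=tr_sec)
    if data.ndim == 3:
        if expect == "image":
            raise VolumeKindError(f"{path}: expected a 4D image, found a 3D volume")
        return BrainMask(data=data > 0, affine=img.affine)
    raise VolumeKindError(f"{path}: expected a 3D or 4D volume, got {data.ndim}D")


def write_volume(vol: FunctionalImage | BrainMask | np.ndarray, path: str | Path,
                 affine: np.ndarray | None = None, tr_sec: float | None = None) -> None:
    """Write a volume to NIfTI; data is stored as float32 (uint8 for masks).

    A bare ndarray may be passed together with ``affine`` (and ``tr_sec`` for
    4D data) when writing derived maps.
    """
    if isinstance(vol, FunctionalImage):
        data, affine, tr_sec = vol.data.astype(np.float32), vol.affine, vol.tr_sec
    elif isinstance(vol, BrainMask):
        data, affine = vol.data.astype(np.uint8), vol.affine
    else:
        data = np.asarray(vol)
        if affine is None:
            raise ValueError("affine is required when writing a bare array")
        data = data.astype(np.uint8) if data.dtype == bool else data.astype(np.float32)
    out = nib.Nifti1Image(data, affine)
    if data.ndim == 4:
        if tr_sec is None:
            raise ValueError("tr_sec is required when writing 4D data")
        out.header.set_zooms(out.header.get_zooms()[:3] + (tr_sec,))
        out.header.set_xyzt_units("mm", "sec")
    else:
        out.header.set_xyzt_units("mm")
    nib.save(out, str(path))


def check_grid_compatible(a, b, atol: float = AFFINE_ATOL) -> bool:
    """True iff the two volumes share spatial shape and affine (within ``atol``)."""
    return a.spatial_shape == b.spatial_shape and bool(
        np.allclose(a.affine, b.affine, rtol=0.0, atol=atol)
    )


def require_grid_compatible(a, b, what: str = "volumes") -> None:
    if not check_grid_compatible(a, b):
        raise GridCompatibilityError(
            f"{what} are not on the same grid: shapes {a.spatial_shape} vs "
            f"{b.spatial_shape}, max affine deviation "
            f"{np.abs(a.affine - b.affine).max():.3g} mm"
        )


def voxel_to_world(index, affine: np.ndarray, shape=None) -> np.ndarray:
    """Map a 0-based voxel index to world millimetres via the affine.

    Negative indices are always rejected; the upper bound is checked when
    ``shape`` is provided.
    """
    idx = np.asarray(index, dtype=np.int64)
    if idx.shape != (3,):
        raise ValueError("index must be a 3-vector")
    if (idx < 0).any():
        raise IndexError(f"voxel index {tuple(idx)} is out of bounds")
    if shape is not None and (idx >= np.asarray(shape[:3])).any():
        raise IndexError(f"voxel index {tuple(idx)} is out of bounds for shape {tuple(shape[:3])}")
    return (np.asarray(affine, dtype=np.float64) @ np.append(idx, 1.0))[:3]


def _fmt(x) -> str:
    """Render a scalar with 4 significant digits; integers pass through."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.4g}"


def write_cluster_report(report: pd.DataFrame, path: str | Path) -> None:
    """Serialize a cluster report to TSV.

    Rows are ordered by descending ``voxel_count``, ties broken by ascending
    ``cluster_id``; floating values are printed with 4 significant digits;
    ``region_labels`` lists are joined with ``", "``. An empty report yields a
    header-only file.
    """
    df = report.copy()
    for col in CLUSTER_REPORT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cluster report is missing column {col!r}")
    if len(df):
        if (df["voxel_count"] < 1).any():
            raise ValueError("every cluster must contain at least one voxel")
        df = df.sort_values(
            ["voxel_count", "cluster_id"], ascending=[False, True], kind="mergesort"
        )
    lines = ["\t".join(CLUSTER_REPORT_COLUMNS)]
    for _, row in df.iterrows():
        labels = row["region_labels"]
        labels_str = ", ".join(str(s) for s in labels) if isinstance(labels, (list, tuple)) else str(labels)
        lines.append(
            "\t".join(
                [
                    str(int(row["cluster_id"])),
                    labels_str,
                    str(int(row["voxel_count"])),
                    _fmt(row["peak_value"]),
                    _fmt(row["peak_x_mm"]),
                    _fmt(row["peak_y_mm"]),
                    _fmt(row["peak_z_mm"]),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cluster_report(path: str | Path) -> pd.DataFrame:
    """Read a TSV cluster report back into a DataFrame (labels as lists)."""
    df = pd.read_csv(path, sep="\t", dtype={"region_labels": str}, keep_default_na=False)
    if len(df):
        df["region_labels"] = [
            [] if s == "" else [t.strip() for t in s.split(",")] for s in df["region_labels"]
        ]
    else:
        df["region_labels"] = pd.Series([], dtype=object)
    return df


def read_label_names(path: str | Path) -> dict[int, str]:
    """Read a two-column TSV mapping integer atlas labels to region names."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label", "name"], comment="#")
    return {int(row.label): str(row.name) for row in df.itertuples()}
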