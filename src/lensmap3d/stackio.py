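"""Image-stack and point-table I/O with explicit physical units.

All analysis in this package is carried out in micrometres.  The one
place where units enter is here: a :class:`VoxelGrid` couples a raw
``(z, y, x)`` intensity array to its physical voxel spacing in
nanometres, and point tables are CSV files whose coordinate columns are
micrometres.  Voxel indices are 0-based and refer to voxel centres, so
the physical coordinate of voxel ``(k, j, i)`` is
``(i*sx, j*sy, k*sz) / 1000`` micrometres.

Spacing is mandatory metadata for real images: a TIFF without spacing
information is rejected unless the caller supplies an override.  The
package never silently assumes isotropic voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGrid",
    "MissingSpacingError",
    "PointTableFormatError",
    "POINT_COLUMNS",
    "read_stack",
    "write_stack",
    "read_points",
    "write_points",
    "empty_point_table",
]

#: Fixed header of a point-table CSV.  Coordinates are micrometres,
#: angles degrees; ``zone`` is one of CZ/GZ/MR/unassigned.
POINT_COLUMNS = (
    "id",
    "x_um",
    "y_um",
    "z_um",
    "intensity",
    "circularity",
    "theta_deg",
    "phi_deg",
    "zone",
)

#: Columns that must be present in every point-table CSV.
REQUIRED_POINT_COLUMNS = ("id", "x_um", "y_um", "z_um")

_DESCRIPTION_KEY = "lensmap3d_spacing_nm"


class MissingSpacingError(ValueError):
    """Raised when a stack carries no voxel-spacing metadata."""


class PointTableFormatError(ValueError):
    """Raised when a point-table CSV lacks a required column."""


@dataclass
class VoxelGrid:
    """A 3D intensity image with physical voxel spacing.

    Parameters
    ----------
    data
        Scalar intensity array indexed ``(z, y, x)``.
    spacing_nm
        Voxel spacing ``(sx, sy, sz)`` in nanometres per voxel.
    """

    data: np.ndarray
    spacing_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        sx, sy, sz = (float(s) for s in self.spacing_nm)
        if min(sx, sy, sz) <= 0:
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_nm}")
        self.spacing_nm = (sx, sy, sz)

    @property
    def spacing_um(self) -> np.ndarray:
        """Spacing ``(sx, sy, sz)`` in micrometres."""
        return np.asarray(self.spacing_nm) / 1000.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_to_physical(self, indices) -> np.ndarray:
        """Map ``(k, j, i)`` voxel indices to ``(x, y, z)`` micrometres.

        Accepts a single triple or an ``(n, 3)`` array; fractional
        indices are allowed (voxel-centre convention).
        """
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        sx, sy, sz = self.spacing_um
        xyz = np.column_stack([idx[:, 2] * sx, idx[:, 1] * sy, idx[:, 0] * sz])
        return xyz if np.asarray(indices).ndim > 1 else xyz[0]

    def physical_to_voxel(self, xyz) -> np.ndarray:
        """Inverse of :meth:`voxel_to_physical` (returns float indices)."""
        pts = np.atleast_2d(np.asarray(xyz, dtype=float))
        sx, sy, sz = self.spacing_um
        idx = np.column_stack([pts[:, 2] / sz, pts[:, 1] / sy, pts[:, 0] / sx])
        return idx if np.asarray(xyz).ndim > 1 else idx[0]


def write_stack(grid: VoxelGrid, path) -> None:
    """Write a :class:`VoxelGrid` as a multi-page grayscale TIFF.

    Integer data are stored losslessly; float data are stored as 32-bit
    float pages.  The exact spacing is embedded as JSON in the image
    description, and standard resolution tags are written as well so
    generic viewers pick up the pixel size.
    """
    data = grid.data
    if data.dtype.kind == "f" and data.dtype != np.float32:
        data = data.astype(np.float32)
    sx, sy, sz = grid.spacing_nm
    description = json.dumps({_DESCRIPTION_KEY: [sx, sy, sz]})
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",  # 3-slice stacks must not become RGB
        description=description,
        resolution=(1000.0 / sx, 1000.0 / sy),
        metadata=None,
    )


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    page = tif.pages[0]
    desc = page.description or ""
    if _DESCRIPTION_KEY in desc:
        spacing = json.loads(desc)[_DESCRIPTION_KEY]
        return tuple(float(s) for s in spacing)
    # ImageJ-style: XResolution/YResolution in pixels per unit, z step in
    # the ImageJ metadata 'spacing' field (assumed micrometres).
    z_um = None
    if tif.is_imagej and tif.imagej_metadata is not None:
        z_um = tif.imagej_metadata.get("spacing")
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None or z_um is None:
        return None
    def _per_pixel_um(tag) -> float:
        num, den = tag.value
        if num == 0:
            raise MissingSpacingError("zero resolution tag in TIFF")
        return den / num
    sx = _per_pixel_um(xres) * 1000.0
    sy = _per_pixel_um(yres) * 1000.0
    return (sx, sy, float(z_um) * 1000.0)


def read_stack(path, spacing_override_nm: tuple[float, float, float] | None = None) -> VoxelGrid:
    """Read a multi-page grayscale TIFF into a :class:`VoxelGrid`.

    Spacing is taken from the file's own metadata (this package's JSON
    description, or ImageJ resolution/spacing tags) unless
    ``spacing_override_nm`` is given, which always wins.

    Raises
    ------
    MissingSpacingError
        If the file carries no spacing metadata and no override is given.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        spacing = _spacing_from_tiff(tif)
    if spacing_override_nm is not None:
        spacing = tuple(float(s) for s in spacing_override_nm)
    if spacing is None:
        raise MissingSpacingError(
            f"{path} carries no voxel spacing metadata; pass spacing_override_nm "
            "(never assume isotropy)"
        )
    if data.ndim == 2:
        data = data[None, :, :]
    return VoxelGrid(data=data, spacing_nm=spacing)


def empty_point_table(extra_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """An empty point table with the canonical header."""
    cols = list(POINT_COLUMNS) + [c for c in extra_columns if c not in POINT_COLUMNS]
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    df["id"] = df["id"].astype(int)
    df["zone"] = df["zone"].astype(object)
    return df


def _normalise_points(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    for col in REQUIRED_POINT_COLUMNS:
        if col not in df.columns:
            raise PointTableFormatError(f"point table is missing required column '{col}'")
    for col in POINT_COLUMNS:
        if col not in df.columns:
            df[col] = "unassigned" if col == "zone" else np.nan
    if df["zone"].isna().all():
        df["zone"] = "unassigned"
    else:
        df["zone"] = df["zone"].fillna("unassigned")
    ids = df["id"].to_numpy()
    if len(ids) != len(np.unique(ids)):
        raise PointTableFormatError("point table ids are not unique")
    extra = [c for c in df.columns if c not in POINT_COLUMNS]
    return df[list(POINT_COLUMNS) + extra]


def write_points(table: pd.DataFrame, path) -> None:
    """Write a point table as CSV with the fixed canonical header.

    Extra columns (e.g. ground-truth ``true_theta_deg``) are preserved
    after the canonical ones.  Floats are written with 6-decimal
    precision (sub-nanometre for micrometre coordinates).
    """
    df = _normalise_points(table)
    df.to_csv(path, index=False, float_format="%.6f")


def read_points(path) -> pd.DataFrame:
    """Read a point-table CSV written by :func:`write_points`.

    Missing optional columns are filled (``zone`` as ``unassigned``,
    numeric columns as NaN); a missing required column is a
    :class:`PointTableFormatError` naming the column.
    """
    df = pd.read_csv(path)
    df = _normalise_points(df)
    if len(df):
        df["id"] = df["id"].astype(int)
    return df
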