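"""Volume, mesh and feature-table I/O.

All grids are kept in (Z, Y, X) axis order with index 0 at the volume
origin; voxel centers sit at ``(i + 0.5) * spacing_mm`` along each axis.
Only isotropic spacing is supported, and exported artifacts always carry
physical millimetre coordinates, never voxel indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
import trimesh
from skimage import measure

__all__ = [
    "VoxelVolume",
    "read_volume",
    "write_volume",
    "export_mesh",
    "write_feature_table",
    "read_feature_table",
]

_SPACING_KEY = "corallum_spacing_mm"


@dataclass
class VoxelVolume:
    """A 3D occupancy or label grid with isotropic physical spacing.

    ``values`` is binary ({0, 1}) for skeletons and integer (0 = background)
    for chamber label maps.
    """

    values: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"degenerate shape {self.values.shape}")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def voxel_centers_mm(self, index_array: np.ndarray) -> np.ndarray:
        """Physical (z, y, x) centers of voxels given an (n, 3) index array."""
        return (np.asarray(index_array, dtype=float) + 0.5) * self.spacing_mm + self.origin_mm


def _check_binary(vol: VoxelVolume) -> None:
    if not vol.is_binary():
        raise ValueError("binary volume expected, found values outside {0, 1}")


def read_volume(
    path: str | Path,
    format: str | None = None,
    spacing_mm: float | None = None,
) -> VoxelVolume:
    """Read a TIFF stack or NRRD volume into (Z, Y, X) order.

    Spacing is taken from the file header when present; otherwise
    ``spacing_mm`` must be given explicitly (mm-scale measurements depend on
    it, so it is never silently defaulted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "nrrd" if path.suffix.lower() == ".nrrd" else "tiff_stack"
    if format == "tiff_stack":
        return _read_tiff(path, spacing_mm)
    if format == "nrrd":
        return _read_nrrd(path, spacing_mm)
    raise ValueError(f"unknown volume format {format!r}")


def _read_tiff(path: Path, spacing_mm: float | None) -> VoxelVolume:
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed slice shapes in TIFF stack: {sorted(shapes)}")
        values = tif.asarray()
        desc = tif.pages[0].description or ""
    if values.ndim == 2:
        values = values[None]
    header_spacing = None
    if _SPACING_KEY in desc:
        try:
            header_spacing = float(json.loads(desc)[_SPACING_KEY])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ValueError(f"unreadable spacing metadata in {path}: {desc!r}") from exc
    spacing = header_spacing if header_spacing is not None else spacing_mm
    if spacing is None:
        raise ValueError(
            f"{path} carries no spacing metadata; pass spacing_mm explicitly"
        )
    return VoxelVolume(values=values, spacing_mm=float(spacing))


def _read_nrrd(path: Path, spacing_mm: float | None) -> VoxelVolume:
    image = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(image)  # (z, y, x)
    sp = image.GetSpacing()  # (x, y, z)
    if max(sp) - min(sp) > 1e-9:
        raise ValueError(f"anisotropic spacing {sp} not supported")
    spacing = float(sp[0])
    if spacing == 1.0 and spacing_mm is not None:
        # 1.0 is SimpleITK's placeholder default; trust the explicit value.
        spacing = float(spacing_mm)
    origin = np.asarray(image.GetOrigin(), dtype=float)[::-1]
    return VoxelVolume(values=values, spacing_mm=spacing, origin_mm=origin)


def write_volume(vol: VoxelVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume as a multi-page TIFF or NRRD file (lossless round-trip)."""
    path = Path(path)
    if format is None:
        format = "nrrd" if path.suffix.lower() == ".nrrd" else "tiff_stack"
    values = vol.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    elif np.issubdtype(values.dtype, np.integer):
        # Label maps can exceed 16-bit; never truncate.
        if values.max(initial=0) > np.iinfo(np.uint8).max or values.min(initial=0) < 0:
            values = values.astype(np.int32)
    if format == "tiff_stack":
        desc = json.dumps({_SPACING_KEY: vol.spacing_mm})
        tifffile.imwrite(path, values, description=desc)
    elif format == "nrrd":
        image = sitk.GetImageFromArray(np.ascontiguousarray(values))
        image.SetSpacing((vol.spacing_mm,) * 3)
        image.SetOrigin(tuple(float(v) for v in vol.origin_mm[::-1]))
        sitk.WriteImage(image, str(path), useCompression=False)
    else:
        raise ValueError(f"unknown volume format {format!r}")
    return path


def export_mesh(vol: VoxelVolume, label: int, path: str | Path, format: str | None = None) -> Path:
    """Export the 0.5-isosurface of one label as a watertight STL/PLY mesh.

    Vertices are in physical mm. The label volume is padded by one background
    voxel so the marching-cubes surface always closes.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "stl"
    if format not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format {format!r}")
    mask = vol.values == label if label != 1 or not vol.is_binary() else vol.values == 1
    if not mask.any():
        raise ValueError(f"label {label} absent from volume")
    from scipy import ndimage

    padded = np.pad(mask, 2).astype(np.float32)
    # smoothing the indicator field removes the voxel staircase, which would
    # otherwise bias the isosurface area upward by several percent
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    if smoothed.max() <= 0.5:  # tiny label: fall back to the raw surface
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5)
    # Undo the pad, shift to voxel centers, scale to mm.
    verts = (verts - 2.0 + 0.5) * vol.spacing_mm + vol.origin_mm
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()
    mesh.export(path, file_type=format)
    return path


def write_feature_table(records: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write per-chamber records as CSV, one row per chamber."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a chamber feature table; duplicated chamber_id is an error."""
    df = pd.read_csv(path)
    if "chamber_id" in df.columns and df["chamber_id"].duplicated().any():
        dupes = df.loc[df["chamber_id"].duplicated(), "chamber_id"].tolist()
        raise ValueError(f"duplicate chamber_id values on read: {dupes}")
    return df
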