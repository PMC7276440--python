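"""Per-chamber morphometric features and surface-calice measurements.

The feature set per chamber: equivalent-sphere diameter, volume, surface
area, surface-to-volume ratio, centroid coordinates (X, Y, Z), projection
distances along the three axes (bounding-box extents), and projected areas
on the XY, XZ and YZ planes -- thirteen quantities, plus the direct calice
measurements (oral/aboral opening diameter and height along the growth
axis) for chambers that open at the colony surface.

All quantities are physical (mm); voxel centers sit at
``(i + 0.5) * spacing + origin``.  The "diameter" feature is the
equivalent-sphere diameter from volume so it exists for sealed internal
spaces as well; the opening diameter of a calice is reported separately by
:func:`measure_calice`.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .segmentation import ChamberLabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "compute_features",
    "measure_calice",
    "standardize_features",
]

# the thirteen clustering features, in report order
FEATURE_COLUMNS = [
    "eq_diameter_mm",
    "volume_mm3",
    "surface_area_mm2",
    "sa_to_vol_per_mm",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "extent_x_mm",
    "extent_y_mm",
    "extent_z_mm",
    "proj_area_xy_mm2",
    "proj_area_xz_mm2",
    "proj_area_yz_mm2",
]

MIN_CALICE_VOXELS = 8


def _face_count_area(mask: np.ndarray, sp: float) -> float:
    """Exact exposed-face surface area of a voxel set (faces x spacing^2)."""
    padded = np.pad(mask, 1)
    faces = 0
    for axis in range(3):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        faces += int(np.abs(diff).sum())
    return faces * sp * sp


def _marching_cubes_area(mask: np.ndarray, sp: float) -> float:
    padded = np.pad(mask, 2).astype(np.float32)
    # smooth the indicator field first: a raw binary isosurface carries the
    # voxel staircase and overestimates area by ~7%
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=(sp, sp, sp))
    return float(measure.mesh_surface_area(verts, faces))


def compute_features(
    chambers: ChamberLabelVolume,
    spacing_mm: float | None = None,
    sa_method: str = "marching_cubes",
    include_truncated: bool = False,
) -> pd.DataFrame:
    """Compute the 13 morphometric features for every labeled chamber.

    volume = voxel count x spacing^3; eq_diameter = (6 V / pi)^(1/3);
    centroid = mean voxel center; extents = index range + 1 voxel, in mm;
    projected areas = occupied pixels of the axis projection x spacing^2;
    surface area by ``face_count`` (exact voxel faces) or ``marching_cubes``
    (triangulated 0.5-isosurface, the default for reported values).
    Chambers touching the volume border are flagged ``truncated`` and
    excluded unless ``include_truncated``.
    """
    if sa_method not in ("face_count", "marching_cubes"):
        raise ValueError(f"unknown sa_method {sa_method!r}")
    sp = spacing_mm if spacing_mm is not None else chambers.spacing_mm
    labels = chambers.labels
    ids = chambers.chamber_ids
    objects = ndimage.find_objects(labels)
    missing = [int(i) for i in ids if objects[int(i) - 1] is None]
    if missing:
        raise ValueError(f"labels absent from volume: {missing}")

    origin = chambers.origin_mm
    rows = []
    for cid in ids:
        cid = int(cid)
        sl = objects[cid - 1]
        mask = labels[sl] == cid
        n_vox = int(mask.sum())
        volume = n_vox * sp**3
        zz, yy, xx = np.nonzero(mask)
        cz = (zz.mean() + sl[0].start + 0.5) * sp + origin[0]
        cy = (yy.mean() + sl[1].start + 0.5) * sp + origin[1]
        cx = (xx.mean() + sl[2].start + 0.5) * sp + origin[2]
        ext_z = (zz.max() - zz.min() + 1) * sp
        ext_y = (yy.max() - yy.min() + 1) * sp
        ext_x = (xx.max() - xx.min() + 1) * sp
        proj_xy = int(mask.any(axis=0).sum()) * sp * sp  # project along z
        proj_xz = int(mask.any(axis=1).sum()) * sp * sp  # along y
        proj_yz = int(mask.any(axis=2).sum()) * sp * sp  # along x
        if sa_method == "face_count":
            area = _face_count_area(mask, sp)
        else:
            area = _marching_cubes_area(mask, sp)
        rows.append(
            {
                "chamber_id": cid,
                "class": chambers.classes.get(cid, ""),
                "truncated": cid in chambers.truncated,
                "n_voxels": n_vox,
                "eq_diameter_mm": (6.0 * volume / math.pi) ** (1.0 / 3.0),
                "volume_mm3": volume,
                "surface_area_mm2": area,
                "sa_to_vol_per_mm": area / volume,
                "centroid_x_mm": cx,
                "centroid_y_mm": cy,
                "centroid_z_mm": cz,
                "extent_x_mm": ext_x,
                "extent_y_mm": ext_y,
                "extent_z_mm": ext_z,
                "proj_area_xy_mm2": proj_xy,
                "proj_area_xz_mm2": proj_xz,
                "proj_area_yz_mm2": proj_yz,
                "region_id": 0,
                "layer_index": 0,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) and not include_truncated:
        df = df[~df["truncated"]].reset_index(drop=True)
    return df


def measure_calice(
    chamber_id: int,
    chambers: ChamberLabelVolume,
    skeleton=None,
    growth_axis: np.ndarray = (1.0, 0.0, 0.0),
    sheet_voxels: float | None = 1.5,
) -> tuple[float | None, float | None, float | None]:
    """Oral/aboral opening diameters and height of one chamber.

    The oral cross-section is the chamber's up-facing boundary surface (the
    opening of the hole, or its ceiling when roofed), the aboral the
    down-facing one; "up" is the growth axis ((z, y, x) components).  Each
    surface is projected onto the plane perpendicular to the axis and its
    equivalent-circle diameter ``2 sqrt(A / pi)`` reported; height is the
    axial extent plus one voxel.

    With ``sheet_voxels`` set (default 1.5), only boundary voxels within that
    many voxels of the axial extreme count -- the exact opening/floor plane,
    appropriate when the axis is accurately known (for an axis-aligned
    chamber this is the top/bottom voxel slab).  With ``sheet_voxels=None``
    the whole facing surface is projected (the silhouette of the opening),
    which is robust to a misestimated axis and is used by the batch
    pipeline on estimated per-calice axes.  Degenerate chambers
    (< 8 voxels) give ``(None, None, None)``.
    """
    axis = np.asarray(growth_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("growth_axis must be nonzero")
    axis = axis / nrm
    sp = chambers.spacing_mm
    labels = chambers.labels
    pts = np.argwhere(labels == chamber_id)
    if pts.shape[0] == 0:
        raise ValueError(f"chamber {chamber_id} absent from label volume")
    if pts.shape[0] < MIN_CALICE_VOXELS:
        logger.warning("chamber %d degenerate (%d voxels)", chamber_id, len(pts))
        return None, None, None

    e_dom = np.zeros(3, dtype=int)
    k = int(np.argmax(np.abs(axis)))
    e_dom[k] = 1 if axis[k] >= 0 else -1

    def _facing(step: np.ndarray) -> np.ndarray:
        nb = pts + step
        inside = np.all((nb >= 0) & (nb < np.array(labels.shape)), axis=1)
        out = np.ones(len(pts), dtype=bool)
        out[inside] = labels[nb[inside, 0], nb[inside, 1], nb[inside, 2]] != chamber_id
        return pts[out]

    t = ((pts.astype(float) + 0.5) * sp) @ axis
    height = float(t.max()) - float(t.min()) + sp

    e1 = np.zeros(3)
    k2 = int(np.argmin(np.abs(axis)))
    e1[k2] = 1.0
    e1 = e1 - (e1 @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def _projected_area(points: np.ndarray) -> float:
        if len(points) == 0:
            return 0.0
        q = points.astype(float)
        cells = np.rint(np.column_stack([q @ e1, q @ e2])).astype(np.int64)
        return len(np.unique(cells, axis=0)) * sp * sp

    up, down = _facing(e_dom), _facing(-e_dom)
    if sheet_voxels is not None:
        if len(up):
            tu = (up.astype(float) @ axis) * sp
            up = up[tu >= tu.max() - sheet_voxels * sp]
        if len(down):
            td = (down.astype(float) @ axis) * sp
            down = down[td <= td.min() + sheet_voxels * sp]
    oral_d = 2.0 * math.sqrt(_projected_area(up) / math.pi)
    aboral_d = 2.0 * math.sqrt(_projected_area(down) / math.pi)
    return oral_d, aboral_d, height


def _stack_normal(chamber_id: int, chambers: ChamberLabelVolume):
    """Least-variance principal axis and eigenvalues of one chamber."""
    mask = chambers.labels == chamber_id
    pts = np.argwhere(mask).astype(float)
    pts -= pts.mean(axis=0)
    w, v = np.linalg.eigh(pts.T @ pts / len(pts))
    return v[:, 0], w


def chamber_growth_axis(
    chamber_id: int,
    chambers: ChamberLabelVolume,
    records: pd.DataFrame,
) -> np.ndarray:
    """Per-calice growth-axis estimate from the surrounding stack.

    The stacking normal of the nearest clearly flat neighbour chamber (an
    inter-septal space of the same corallite is a tabula-bounded disk) gives
    the axis to a few degrees; the step direction toward the calice fixes
    the sign and guards against picking a lateral same-ring neighbour.
    Falls back to the raw step direction when no oriented neighbour exists.
    """
    cents = records.set_index("chamber_id")[
        ["centroid_z_mm", "centroid_y_mm", "centroid_x_mm"]
    ]
    c0 = cents.loc[chamber_id].to_numpy(float)
    others = cents.drop(chamber_id)
    if len(others) == 0:
        return np.array([1.0, 0.0, 0.0])
    d = np.linalg.norm(others.to_numpy(float) - c0, axis=1)
    order = np.argsort(d)[:4]
    cos_gate = math.cos(math.radians(40.0))
    for oi in order:
        nid = int(others.index[oi])
        nrm, w = _stack_normal(nid, chambers)
        step = c0 - others.to_numpy(float)[oi]
        step = step / np.linalg.norm(step)
        if w[1] > 1.44 * w[0] and abs(float(nrm @ step)) >= cos_gate:
            return nrm if float(nrm @ step) >= 0 else -nrm
    step = c0 - others.to_numpy(float)[order[0]]
    return step / np.linalg.norm(step)


def measure_all_calices(
    records: pd.DataFrame,
    chambers: ChamberLabelVolume,
    growth_axis: np.ndarray | None = None,
) -> pd.DataFrame:
    """measure_calice over every surface calice in the record table; adds
    oral_diameter_mm / aboral_diameter_mm / height_mm columns.

    Branches lean away from the colony axis, so each calice is measured
    along its own estimated growth axis (the stacking normal of its
    corallite, see :func:`chamber_growth_axis`) in silhouette mode, which
    tolerates the residual axis error; passing an explicit common
    ``growth_axis`` switches to the exact sheet measurement along it.
    """
    out = records.copy()
    for col in ("oral_diameter_mm", "aboral_diameter_mm", "height_mm"):
        out[col] = np.nan
    surface = out["class"] == "surface_calice"
    for idx in out.index[surface]:
        cid = int(out.at[idx, "chamber_id"])
        if growth_axis is None:
            axis = chamber_growth_axis(cid, chambers, out)
            sheet = None
        else:
            axis = np.asarray(growth_axis, dtype=float)
            sheet = 1.5
        oral, aboral, height = measure_calice(
            cid, chambers, growth_axis=axis, sheet_voxels=sheet
        )
        if oral is not None:
            out.at[idx, "oral_diameter_mm"] = oral
            out.at[idx, "aboral_diameter_mm"] = aboral
            out.at[idx, "height_mm"] = height
    return out


def standardize_features(
    records: pd.DataFrame, feature_subset: list[str] | None = None
) -> tuple[np.ndarray, pd.DataFrame, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Column-wise z-scores of the chosen features (sample sd, ddof=1).

    Constant columns are dropped with a warning; an all-constant subset is
    an error.  Returns (matrix, the records aligned to its rows,
    (means, sds, kept column names)) so the transform can be inverted.
    """
    cols = list(feature_subset) if feature_subset is not None else list(FEATURE_COLUMNS)
    if len(records) < 2:
        raise ValueError("need at least 2 records to standardize")
    X = records[cols].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all selected features are constant")
    for name in np.asarray(cols)[~keep]:
        logger.warning("dropping constant feature column %s", name)
    kept_cols = [c for c, k in zip(cols, keep) if k]
    Z = (X[:, keep] - means[keep]) / sds[keep]
    return Z, records.reset_index(drop=True), (means[keep], sds[keep], kept_cols)


def destandardize(Z: np.ndarray, transform) -> np.ndarray:
    means, sds, _ = transform
    return Z * sds + means
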