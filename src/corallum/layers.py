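"""Layer decomposition of a branchlet along its growth axis.

Polyps grow synchronously, so chambers built at the same time form a
stratified growth ring.  Cutting a branchlet into N equal-thickness layers
along its growth axis (N = 48 by default) and collecting the chambers of
each layer approximates these rings; per-layer mean diameters and volumes
profile the growth history from base to tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import ChamberLabelVolume

__all__ = ["LayerProfile", "assign_layers", "ring_masks", "layer_profile_curves"]


@dataclass
class LayerProfile:
    n_layers: int
    axis: np.ndarray  # unit (z, y, x)
    boundaries_mm: np.ndarray  # n_layers + 1 ascending, equal widths
    table: pd.DataFrame  # per layer: count, means, sds
    ring_masks: dict[int, np.ndarray] | None = field(default=None, repr=False)


def principal_axis(records: pd.DataFrame) -> np.ndarray:
    """First principal direction of the chamber centroids (the growth axis
    of an unbent branchlet).  Sign fixed so the largest component is
    positive."""
    pts = records[["centroid_z_mm", "centroid_y_mm", "centroid_x_mm"]].to_numpy(float)
    pts = pts - pts.mean(axis=0)
    if len(pts) < 2:
        return np.array([1.0, 0.0, 0.0])
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[0]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def assign_layers(
    records: pd.DataFrame,
    axis: np.ndarray | None = None,
    n_layers: int = 48,
) -> tuple[pd.DataFrame, LayerProfile]:
    """Bin chambers into ``n_layers`` equal-width layers along the axis.

    A chamber belongs to the layer containing its centroid's axial
    coordinate (half-open bins, last bin closed), so layer counts are
    additive.  Layer indices are 1-based from the aboral (basal) end.
    Returns the records with a ``layer_index`` column and the profile.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if axis is None:
        axis = principal_axis(records)
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("axis must be nonzero")
    axis = axis / nrm
    out = records.reset_index(drop=True).copy()
    t = out[["centroid_z_mm", "centroid_y_mm", "centroid_x_mm"]].to_numpy(float) @ axis
    t_lo, t_hi = float(t.min()), float(t.max())
    if t_hi == t_lo:
        t_hi = t_lo + 1e-9
    boundaries = np.linspace(t_lo, t_hi, n_layers + 1)
    idx = np.minimum(
        ((t - t_lo) / (t_hi - t_lo) * n_layers).astype(int), n_layers - 1
    )
    out["layer_index"] = idx + 1
    rows = []
    for k in range(1, n_layers + 1):
        sel = out["layer_index"] == k
        n = int(sel.sum())
        row = {"layer_index": k, "count": n}
        for feat, name in (("eq_diameter_mm", "diameter"), ("volume_mm3", "volume")):
            vals = out.loc[sel, feat]
            row[f"mean_{name}"] = float(vals.mean()) if n else np.nan
            row[f"sd_{name}"] = float(vals.std(ddof=1)) if n > 1 else np.nan
        rows.append(row)
    profile = LayerProfile(
        n_layers=n_layers,
        axis=axis,
        boundaries_mm=boundaries,
        table=pd.DataFrame(rows),
    )
    return out, profile


def ring_masks(
    chambers: ChamberLabelVolume, records: pd.DataFrame, profile: LayerProfile
) -> dict[int, np.ndarray]:
    """Per-layer growth-ring masks: the union of the voxels of the chambers
    assigned to each layer.  Masks are pairwise disjoint and jointly cover
    exactly the assigned chambers' voxels."""
    masks: dict[int, np.ndarray] = {}
    by_layer = records.groupby("layer_index")["chamber_id"]
    for k, ids in by_layer:
        masks[int(k)] = np.isin(chambers.labels, ids.to_numpy())
    profile.ring_masks = masks
    return masks


def layer_profile_curves(profile: LayerProfile, plot_path=None) -> pd.DataFrame:
    """One row per layer (mean diameter / mean volume, NaN when empty),
    optionally rendered as a line chart."""
    table = profile.table[["layer_index", "count", "mean_diameter", "mean_volume"]].copy()
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax1 = plt.subplots(figsize=(7, 4))
        ax1.plot(table["layer_index"], table["mean_diameter"], "o-", label="mean diameter (mm)")
        ax1.set_xlabel("layer (base to tip)")
        ax1.set_ylabel("mean equivalent diameter (mm)")
        ax2 = ax1.twinx()
        ax2.plot(
            table["layer_index"], table["mean_volume"], "s--", color="tab:red",
            label="mean volume (mm$^3$)",
        )
        ax2.set_ylabel("mean chamber volume (mm$^3$)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table
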