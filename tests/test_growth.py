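"""Trajectory tracing, growth types, budding cones and axis-tree recovery."""

import numpy as np
import pandas as pd
import pytest

from corallum.growth import (
    GrowthTrajectory,
    build_axis_tree,
    classify_growth_type,
    detect_budding_origin,
    trace_trajectories,
)
from corallum.segmentation import ChamberLabelVolume


def _stack_volume(stacks, spacing=0.05, shape=(120, 80, 80)):
    """Rasterize chamber stacks: each stack is (origin_vox, axis, n, pitch,
    radius); returns (ChamberLabelVolume, records DataFrame, list of id lists)."""
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    next_id = 1
    chains = []
    for origin, axis, n_chambers, pitch, radius in stacks:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        ids = []
        for k in range(n_chambers):
            center = np.asarray(origin, float) + axis * (k * pitch)
            zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
            d = (
                (zz - center[0]) * axis[0]
                + (yy - center[1]) * axis[1]
                + (xx - center[2]) * axis[2]
            )
            rad2 = (
                (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
            ) - d**2
            mask = (np.abs(d) <= pitch * 0.3) & (rad2 <= radius**2)
            labels[mask] = next_id
            pts = np.argwhere(labels == next_id)
            c = (pts.mean(axis=0) + 0.5) * spacing
            ext = (pts.max(axis=0) - pts.min(axis=0) + 1) * spacing
            rows.append(
                {
                    "chamber_id": next_id,
                    "class": "surface_calice" if k == n_chambers - 1 else "internal_space",
                    "truncated": False,
                    "eq_diameter_mm": 2 * radius * spacing,
                    "volume_mm3": len(pts) * spacing**3,
                    "centroid_z_mm": c[0],
                    "centroid_y_mm": c[1],
                    "centroid_x_mm": c[2],
                    "extent_z_mm": ext[0],
                    "extent_y_mm": ext[1],
                    "extent_x_mm": ext[2],
                }
            )
            ids.append(next_id)
            next_id += 1
        chains.append(ids)
    chambers = ChamberLabelVolume(labels=labels, spacing_mm=spacing)
    chambers.classes = {r["chamber_id"]: r["class"] for r in rows}
    return chambers, pd.DataFrame(rows), chains


class TestTrace:
    def test_single_straight_corallite_ordered_floor_to_surface(self):
        chambers, records, chains = _stack_volume(
            [((10, 40, 40), (1, 0, 0), 6, 12, 8)]
        )
        trajectories = trace_trajectories(chambers, records)
        assert len(trajectories) == 1
        assert trajectories[0].chamber_ids == chains[0]
        assert trajectories[0].ends_at_surface

    def test_parallel_corallites_not_cross_linked(self):
        chambers, records, chains = _stack_volume(
            [((10, 20, 20), (1, 0, 0), 5, 12, 8), ((10, 60, 60), (1, 0, 0), 5, 12, 8)]
        )
        trajectories = trace_trajectories(chambers, records)
        assert sorted(tuple(t.chamber_ids) for t in trajectories) == sorted(
            tuple(c) for c in chains
        )

    def test_phantom_trajectories_match_truth(self, small_segmented, small_records):
        volume, truth, chambers = small_segmented
        trajectories = trace_trajectories(chambers, small_records)
        # map predicted labels back to true chamber ids via majority overlap
        pred_to_true = {}
        for c in truth.chambers:
            ids, counts = np.unique(
                chambers.labels[truth.chamber_labels == c.chamber_id], return_counts=True
            )
            sel = ids > 0
            if sel.any():
                pred_to_true[int(ids[sel][np.argmax(counts[sel])])] = c.chamber_id
        recovered = {
            tuple(pred_to_true.get(cid) for cid in t.chamber_ids) for t in trajectories
        }
        hits = sum(
            1 for cor in truth.corallites if tuple(cor.chamber_ids) in recovered
        )
        assert hits / len(truth.corallites) >= 0.9

    def test_every_chamber_in_exactly_one_trajectory(self, small_segmented, small_records):
        _, _, chambers = small_segmented
        trajectories = trace_trajectories(chambers, small_records)
        seen = [c for t in trajectories for c in t.chamber_ids]
        expected = set(small_records.loc[~small_records["truncated"], "chamber_id"])
        assert len(seen) == len(set(seen))
        assert set(seen) == expected


class TestGrowthTypes:
    def _traj(self, ids, **kw):
        return GrowthTrajectory(
            corallite_id=kw.pop("corallite_id", 1),
            chamber_ids=list(ids),
            axis_directions=[np.array([1.0, 0, 0])] * (len(ids) - 1),
            **kw,
        )

    def test_budding_when_daughter_originates_on_chamber(self):
        traj = self._traj([1, 2, 3, 4, 5, 6, 7])
        assert classify_growth_type(traj, {2: 3}) == "budding"

    def test_stunted_when_short_and_childless(self):
        traj = self._traj([1, 2, 3, 4])
        assert classify_growth_type(traj, {}) == "stunted"

    def test_nonbudding_when_long_and_childless(self):
        traj = self._traj(list(range(1, 13)))
        assert classify_growth_type(traj, {}) == "nonbudding"

    def test_budding_cone_detection_rules(self):
        diam = pd.DataFrame(
            {
                "chamber_id": [1, 2, 3, 4, 5],
                "eq_diameter_mm": [0.3, 0.45, 0.6, 0.8, 0.8],
            }
        )
        ramp = self._traj([1, 2, 3, 4, 5])
        assert detect_budding_origin(ramp, diam, cone_chambers=3) is True
        flat = pd.DataFrame(
            {"chamber_id": [1, 2, 3, 4], "eq_diameter_mm": [0.6, 0.6, 0.6, 0.6]}
        )
        assert detect_budding_origin(self._traj([1, 2, 3, 4]), flat, 3) is False
        assert detect_budding_origin(self._traj([1, 2]), flat, 3) is None

    def test_phantom_new_buds_detected(self, small_segmented, small_records):
        volume, truth, chambers = small_segmented
        trajectories = trace_trajectories(chambers, small_records)
        pred_to_true = {}
        for c in truth.chambers:
            ids, counts = np.unique(
                chambers.labels[truth.chamber_labels == c.chamber_id], return_counts=True
            )
            sel = ids > 0
            if sel.any():
                pred_to_true[int(ids[sel][np.argmax(counts[sel])])] = c.chamber_id
        truth_first = {
            cor.chamber_ids[0]: cor for cor in truth.corallites
        }
        checked = hits = 0
        cone = truth.spec.budding_cone_chambers
        diam = {c.chamber_id: c for c in truth.chambers}
        for t in trajectories:
            first_true = pred_to_true.get(t.origin_chamber)
            cor = truth_first.get(first_true)
            if cor is None or len(cor.chamber_ids) < cone:
                continue
            # realized truth flag: did the cone survive rasterization?
            d = [diam[c].true_volume_mm3 ** (1 / 3) for c in cor.chamber_ids[:cone]]
            want = all(b > a for a, b in zip(d[:-1], d[1:])) and (d[-1] / d[0]) ** 3 >= 1.2**3
            got = detect_budding_origin(t, small_records, cone_chambers=cone)
            if cor.is_new_bud and want:
                checked += 1
                hits += got is True
        assert checked >= 5
        assert hits / checked >= 0.9


class TestAxisTree:
    def test_phantom_tree_depth1_recovered(self, small_segmented, small_records):
        volume, truth, chambers = small_segmented
        trajectories = trace_trajectories(chambers, small_records)
        tree, bundles, report = build_axis_tree(trajectories, small_records)
        assert report.n_roots == 1
        assert report.n_internal == 1
        assert not report.violations

    def test_single_corallite_trivial_tree(self):
        chambers, records, _ = _stack_volume([((10, 40, 40), (1, 0, 0), 6, 12, 8)])
        trajectories = trace_trajectories(chambers, records)
        tree, bundles, report = build_axis_tree(
            trajectories, records, bundle_min_size=1
        )
        assert len(tree.nodes) == 1
        assert report.n_internal == 0
        assert not report.violations

    def test_triple_branch_flagged_not_corrected(self):
        """A trifurcation must be reported as a dichotomy violation."""
        stacks = [((6, 40, 40), (1, 0, 0), 4, 10, 7)]
        for dy, dx in ((-26, 0), (26, 0), (0, 26)):
            stacks.append(((48, 40 + dy, 40 + dx), (1, 0, 0), 4, 10, 7))
        chambers, records, chains = _stack_volume(stacks, shape=(110, 90, 90))
        trajectories = trace_trajectories(chambers, records)
        # force budding links: all three upper stacks bud from the lower stack
        lower = next(t for t in trajectories if t.chamber_ids == chains[0])
        for t in trajectories:
            if t is not lower:
                t.budded_from_chamber = chains[0][-1]
                t.budded_from_corallite = lower.corallite_id
        tree, bundles, report = build_axis_tree(
            trajectories, records, bundle_min_size=1
        )
        assert report.violations
        assert 3 in report.violations.values()
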