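"""End-to-end pipeline: phantom/volume -> chambers -> features -> sections
-> growth topology -> layers -> summary report.

Configured by a flat TOML file (unknown keys rejected); every run writes
the fully resolved configuration next to its outputs so it can be re-run
identically.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import isodata as isodata_mod
from . import layers as layers_mod
from . import morphometrics as morpho
from . import phantom as phantom_mod
from . import segmentation as seg_mod
from . import volume_io

logger = logging.getLogger("corallum.pipeline")

__all__ = ["RunConfig", "run_pipeline", "load_config", "write_config"]


@dataclass
class RunConfig:
    # input: either an existing volume or a generated phantom
    input_volume: str = ""  # empty -> generate a phantom
    out_dir: str = "corallum_out"
    spacing_mm: float = 0.025
    seed: int = 1
    log_level: str = "INFO"
    # phantom
    phantom_tree_depth: int = 3
    phantom_corallites_per_ring: int = 4
    phantom_bifurcation_angle_deg: float = 25.0
    # segmentation
    closing_radius_mm: float = 0.6
    split: str = "watershed"
    h_min_mm: float = 0.05
    binarize_threshold: float = 0.5
    # morphometrics
    sa_method: str = "marching_cubes"
    # clustering
    k_init: int = 2
    k_desired: int = 4
    n_min: int = 20
    sigma_split: float = 1.25
    d_merge: float = 1.0
    max_merge_pairs: int = 1
    max_iter: int = 100
    # growth
    cone_half_angle_deg: float = 45.0
    gap_factor: float = 2.0
    stunted_max: int = 5
    budding_cone_chambers: int = 3
    # layers
    n_layers: int = 48
    layer_axis: str = "z"  # "z" (scan growth axis) or "principal"
    write_ring_masks: bool = True
    # outputs
    export_meshes: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: str | Path) -> Path:
    lines = []
    for key, value in asdict(config).items():
        if isinstance(value, bool):
            rep = "true" if value else "false"
        elif isinstance(value, (int, float)):
            rep = repr(value)
        else:
            rep = json.dumps(str(value))
        lines.append(f"{key} = {rep}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # partial outputs stay on disk
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Outputs: ``labels.nrrd``, ``chambers.csv``, ``clustered.csv``,
    ``trajectories.csv``, ``tree.json``, ``dichotomy.json``,
    ``layer_profile.csv``, ``rings.nrrd`` (per-voxel layer index),
    ``summary.json`` and the resolved ``config.toml``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    level = getattr(logging, config.log_level.upper(), logging.INFO)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("corallum")
    root.addHandler(handler)
    root.setLevel(level)
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> Path:
    write_config(config, out_dir / "config.toml")
    truth = None

    @_stage("input")
    def load_input():
        nonlocal truth
        if config.input_volume:
            vol = volume_io.read_volume(config.input_volume, spacing_mm=config.spacing_mm)
            if not vol.is_binary():
                vol.values = (vol.values > config.binarize_threshold).astype(np.uint8)
            return vol
        spec = phantom_mod.PhantomSpec(
            voxel_spacing_mm=config.spacing_mm,
            tree_depth=config.phantom_tree_depth,
            corallites_per_ring=config.phantom_corallites_per_ring,
            bifurcation_angle_deg=config.phantom_bifurcation_angle_deg,
            rng_seed=config.seed,
        )
        vol, truth = phantom_mod.generate_phantom(spec)
        volume_io.write_volume(vol, out_dir / "skeleton.nrrd")
        return vol

    skeleton = load_input()

    @_stage("segmentation")
    def segment():
        chambers = seg_mod.segment_volume(
            skeleton,
            closing_radius_mm=config.closing_radius_mm,
            split=config.split,
            h_min_mm=config.h_min_mm,
        )
        volume_io.write_volume(
            volume_io.VoxelVolume(chambers.labels, skeleton.spacing_mm, skeleton.origin_mm),
            out_dir / "labels.nrrd",
        )
        return chambers

    chambers = segment()

    @_stage("morphometrics")
    def measure():
        records = morpho.compute_features(chambers, sa_method=config.sa_method)
        records = morpho.measure_all_calices(records, chambers)
        volume_io.write_feature_table(records, out_dir / "chambers.csv")
        return records

    records = measure()

    @_stage("clustering")
    def cluster():
        Z, recs, _ = morpho.standardize_features(records)
        params = isodata_mod.ISODATAParams(
            k_init=config.k_init,
            k_desired=config.k_desired,
            n_min=config.n_min,
            sigma_split=config.sigma_split,
            d_merge=config.d_merge,
            max_merge_pairs=config.max_merge_pairs,
            max_iter=config.max_iter,
            seed=config.seed,
        )
        result = isodata_mod.isodata_fit(Z, params)
        if result.k_final == 4:
            clustered = isodata_mod.map_clusters_to_sections(result, recs)
        else:
            logger.warning("k_final=%d != 4; sections not mapped", result.k_final)
            clustered = recs.copy()
            clustered["cluster"] = result.assignments
        volume_io.write_feature_table(clustered, out_dir / "clustered.csv")
        with open(out_dir / "cluster_log.json", "w") as fh:
            json.dump(
                {
                    "k_final": result.k_final,
                    "converged": result.converged,
                    "iterations": result.iteration_log,
                },
                fh,
                indent=1,
            )
        return result, clustered

    cluster_result, clustered = cluster()

    @_stage("growth")
    def growth():
        trajectories = growth_mod.trace_trajectories(
            chambers,
            clustered,
            cone_half_angle_deg=config.cone_half_angle_deg,
            gap_factor=config.gap_factor,
        )
        budded_from = {
            t.corallite_id: t.budded_from_chamber
            for t in trajectories
            if t.budded_from_chamber is not None
        }
        for traj in trajectories:
            traj.growth_type = growth_mod.classify_growth_type(
                traj, budded_from, stunted_max=config.stunted_max
            )
            traj.origin_is_budding_cone = growth_mod.detect_budding_origin(
                traj, clustered, cone_chambers=config.budding_cone_chambers
            )
        tree, bundles, report = growth_mod.build_axis_tree(trajectories, clustered)
        rows = [
            {
                "corallite_id": t.corallite_id,
                "n_chambers": len(t.chamber_ids),
                "chamber_ids": " ".join(str(c) for c in t.chamber_ids),
                "growth_type": t.growth_type,
                "origin_is_budding_cone": t.origin_is_budding_cone,
                "ends_at_surface": t.ends_at_surface,
                "budded_from_chamber": t.budded_from_chamber,
            }
            for t in trajectories
        ]
        pd.DataFrame(rows).to_csv(out_dir / "trajectories.csv", index=False)
        with open(out_dir / "tree.json", "w") as fh:
            json.dump(tree.to_dict(), fh, indent=1)
        with open(out_dir / "dichotomy.json", "w") as fh:
            json.dump(
                {
                    "out_degree": {str(k): v for k, v in report.out_degree.items()},
                    "violations": {str(k): v for k, v in report.violations.items()},
                    "n_internal": report.n_internal,
                    "n_roots": report.n_roots,
                    "all_dichotomous": report.all_dichotomous,
                },
                fh,
                indent=1,
            )
        return trajectories, tree, report

    trajectories, tree, report = growth()

    @_stage("layers")
    def layer_stage():
        axis = (1.0, 0.0, 0.0) if config.layer_axis == "z" else None
        with_layers, profile = layers_mod.assign_layers(
            clustered, axis=axis, n_layers=config.n_layers
        )
        table = layers_mod.layer_profile_curves(profile, plot_path=out_dir / "layer_profile.png")
        table.to_csv(out_dir / "layer_profile.csv", index=False, float_format="%.12g")
        if config.write_ring_masks:
            masks = layers_mod.ring_masks(chambers, with_layers, profile)
            rings = np.zeros_like(chambers.labels, dtype=np.int32)
            for k, mask in masks.items():
                rings[mask] = k
            volume_io.write_volume(
                volume_io.VoxelVolume(rings, chambers.spacing_mm, chambers.origin_mm),
                out_dir / "rings.nrrd",
            )
        return with_layers, profile

    with_layers, profile = layer_stage()

    @_stage("report")
    def report_stage():
        summary: dict = {
            "n_chambers": int(len(records)),
            "n_surface_calices": int((records["class"] == "surface_calice").sum()),
            "k_final": cluster_result.k_final,
            "growth_type_counts": pd.Series(
                [t.growth_type for t in trajectories]
            ).value_counts().to_dict(),
            "n_trajectories": len(trajectories),
            "bifurcations": report.n_internal,
            "all_dichotomous": report.all_dichotomous,
        }
        surf = records[records["class"] == "surface_calice"]
        if len(surf):
            summary["median_oral_diameter_mm"] = float(surf["oral_diameter_mm"].median())
            summary["median_height_mm"] = float(surf["height_mm"].median())
        if "region_id" in with_layers and with_layers["region_id"].nunique() == 4:
            sections = {}
            tests = {}
            for rid in (1, 2, 3, 4):
                sel = with_layers["region_id"] == rid
                sections[str(rid)] = {
                    "n": int(sel.sum()),
                    "mean_volume_mm3": float(with_layers.loc[sel, "volume_mm3"].mean()),
                    "sd_volume_mm3": float(with_layers.loc[sel, "volume_mm3"].std(ddof=1)),
                }
            for a, b in ((1, 2), (3, 4), (2, 3), (1, 4)):
                cmp = isodata_mod.compare_sections(with_layers, "volume_mm3", (a, b))
                tests[f"{a}v{b}"] = {
                    "t": cmp.t_statistic,
                    "p": cmp.p_value,
                    "significant": cmp.significant,
                }
            summary["sections"] = sections
            summary["t_tests_volume"] = tests
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=str)
        return summary

    report_stage()
    logger.info("pipeline complete: %s", out_dir)
    return out_dir
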