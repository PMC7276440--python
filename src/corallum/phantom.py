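"""Synthetic *Pocillopora*-like skeleton phantoms with complete ground truth.

The generator emulates the morphology of a branching pocilloporid colony:

* a rooted, strictly dichotomous branch tree (every split is binary);
* each branch hosts a ring of corallites, each corallite a stack of chamber
  voids (calices / inter-septal spaces) separated by tabula plates;
* chamber oral/aboral diameters 0.5-1.0 mm, heights 0.1-0.6 mm;
* corallite walls thicker than the coenosteum between corallites;
* newly budded corallites start with an inverted-cone ramp of small chambers;
* one short "stunted" corallite per branch that stops after a few chambers;
* four region archetypes (low-light/light x growth/mineralization);
  mineralization regions are partially refilled from the chamber floor up;
* the last chamber of every corallite that reaches the colony surface is an
  open calice (its mouth is punched through the skeletal cap).

Coordinates are (z, y, x) in mm, growth along +z, light along +x.  Voxel
centers sit at ``(i + 0.5) * spacing``.  All randomness flows from
``PhantomSpec.rng_seed`` through two documented child streams (tree stream,
rasterization stream), so identical (spec, seed) gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .growth import BranchNode, BranchTree
from .volume_io import VoxelVolume

__all__ = [
    "RegionArchetype",
    "PhantomSpec",
    "TrueChamber",
    "TrueCorallite",
    "PhantomTruth",
    "generate_branch_tree",
    "rasterize_colony",
    "assign_regions",
    "generate_phantom",
]

GROWTH_AXIS = np.array([1.0, 0.0, 0.0])  # +z in (z, y, x)
LIGHT_AXIS = np.array([0.0, 0.0, 1.0])  # +x in (z, y, x)

# Section ids in the conventional order.
REGION_LOWLIGHT_MINERALIZATION = 1
REGION_LOWLIGHT_GROWTH = 2
REGION_LIGHT_GROWTH = 3
REGION_LIGHT_MINERALIZATION = 4


@dataclass(frozen=True)
class RegionArchetype:
    """Growth conditions of one colony section.

    ``volume_scale`` multiplies chamber volume (diameter scales by its cube
    root); ``mineral_fill_fraction`` is the fraction of chamber height
    refilled with mineral from the floor upward.
    """

    volume_scale: float
    mineral_fill_fraction: float


def _default_archetypes() -> tuple[RegionArchetype, ...]:
    return (
        RegionArchetype(volume_scale=0.85, mineral_fill_fraction=0.65),  # 1 low-light mineralization
        RegionArchetype(volume_scale=0.85, mineral_fill_fraction=0.0),  # 2 low-light growth
        RegionArchetype(volume_scale=1.25, mineral_fill_fraction=0.0),  # 3 light growth
        RegionArchetype(volume_scale=1.25, mineral_fill_fraction=0.65),  # 4 light mineralization
    )


@dataclass
class PhantomSpec:
    """Parameters of a synthetic colony."""

    voxel_spacing_mm: float = 0.025
    tree_depth: int = 3
    segment_length_mm: tuple[float, ...] = (2.0, 1.5, 1.4, 2.4)
    bifurcation_angle_deg: float = 20.0
    corallites_per_ring: int = 4
    chamber_oral_diameter_range_mm: tuple[float, float] = (0.5, 1.0)
    chamber_height_range_mm: tuple[float, float] = (0.1, 0.6)
    tabula_thickness_mm: float = 0.1
    wall_thickness_corallite_mm: float = 0.15
    wall_thickness_coenosteum_mm: float = 0.075
    budding_cone_chambers: int = 3
    stunted_max_chambers: int = 5
    region_archetypes: tuple[RegionArchetype, ...] = field(default_factory=_default_archetypes)
    rng_seed: int = 1
    # Secondary geometry knobs (held fixed in the study conditions).
    aboral_taper_range: tuple[float, float] = (0.85, 1.0)
    min_calice_height_mm: float = 0.45
    basal_offset_mm: float = 0.5
    stunted_diameter_range_mm: tuple[float, float] = (0.5, 0.6)
    azimuth_jitter_deg: float = 10.0
    margin_mm: float = 0.5
    branch_clearance_factor: float = 1.25
    max_grid_voxels: int = 120_000_000

    def validate(self) -> None:
        def _interval(name: str, iv, strict: bool = True) -> None:
            lo, hi = iv
            if not (lo > 0 and hi > 0):
                raise ValueError(f"{name}: bounds must be positive, got {iv}")
            if strict and not lo < hi:
                raise ValueError(f"{name}: min must be < max, got {iv}")
            if not strict and not lo <= hi:
                raise ValueError(f"{name}: min must be <= max, got {iv}")

        if not self.voxel_spacing_mm > 0:
            raise ValueError("voxel_spacing_mm: must be positive")
        if self.tree_depth < 0:
            raise ValueError("tree_depth: must be >= 0")
        if len(self.segment_length_mm) < 1 or any(s <= 0 for s in self.segment_length_mm):
            raise ValueError("segment_length_mm: needs positive lengths per generation")
        if not 0.0 < self.bifurcation_angle_deg < 90.0:
            raise ValueError("bifurcation_angle_deg: must lie in (0, 90)")
        if self.corallites_per_ring < 1:
            raise ValueError("corallites_per_ring: must be >= 1")
        _interval("chamber_oral_diameter_range_mm", self.chamber_oral_diameter_range_mm, strict=False)
        _interval("chamber_height_range_mm", self.chamber_height_range_mm, strict=False)
        if not self.tabula_thickness_mm > 0:
            raise ValueError("tabula_thickness_mm: must be positive")
        if not self.wall_thickness_corallite_mm > self.wall_thickness_coenosteum_mm > 0:
            raise ValueError(
                "wall_thickness_corallite_mm must exceed wall_thickness_coenosteum_mm > 0"
            )
        if self.budding_cone_chambers < 1:
            raise ValueError("budding_cone_chambers: must be >= 1")
        if len(self.region_archetypes) != 4:
            raise ValueError("region_archetypes: exactly 4 archetypes required (regions 1-4)")
        for arch in self.region_archetypes:
            if not arch.volume_scale > 0:
                raise ValueError("region_archetypes: volume_scale must be positive")
            if not 0.0 <= arch.mineral_fill_fraction <= 1.0:
                raise ValueError("region_archetypes: mineral_fill_fraction must lie in [0, 1]")

    def segment_length(self, generation: int, depth: int | None = None) -> float:
        """Length of a branch at ``generation``; the last list entry always
        describes the terminal branchlets (the colony's growth front),
        whatever the tree depth."""
        lengths = self.segment_length_mm
        depth = self.tree_depth if depth is None else depth
        if generation >= depth:
            return lengths[-1]
        return lengths[min(generation, len(lengths) - 2)] if len(lengths) > 1 else lengths[0]

    def max_diameter_scale(self) -> float:
        return max(a.volume_scale for a in self.region_archetypes) ** (1.0 / 3.0)


@dataclass
class TrueChamber:
    chamber_id: int
    corallite_id: int
    chamber_index_from_origin: int
    region_id: int
    true_center_mm: np.ndarray
    true_volume_mm3: float
    true_oral_diameter_mm: float
    true_aboral_diameter_mm: float
    true_height_mm: float
    is_surface_calice: bool


@dataclass
class TrueCorallite:
    corallite_id: int
    branch_node_id: int
    slot: int
    axis: np.ndarray
    base_mm: np.ndarray
    tube_radius_mm: float
    is_new_bud: bool
    is_stunted: bool
    reaches_surface: bool
    budded_from_corallite: int | None
    chamber_ids: list[int] = field(default_factory=list)


@dataclass
class PhantomTruth:
    chamber_labels: np.ndarray
    chambers: list[TrueChamber]
    corallites: list[TrueCorallite]
    tree: BranchTree
    spec: PhantomSpec
    light_reference_mm: np.ndarray


# --------------------------------------------------------------------------
# branch tree


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = LIGHT_AXIS if abs(float(d @ LIGHT_AXIS)) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _ring_layout(
    radii: np.ndarray, wall_coenosteum: float, wall_corallite: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Seat corallite axes inside a branch cylinder.

    Each corallite sits at its own ring radius so its outer wall to the
    branch surface is exactly the corallite-wall thickness, and the branch
    radius is solved so the mineral between adjacent corallites equals the
    coenosteum-wall thickness.  Returns (branch radius, per-slot ring radii,
    per-slot angles).
    """
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    if n == 1:
        return radii[0] + wall_corallite, np.zeros(1), np.zeros(1)
    chords = np.array(
        [radii[i] + radii[(i + 1) % n] + wall_coenosteum for i in range(n)]
    )

    def steps(R: float) -> np.ndarray:
        rho = R - wall_corallite - radii
        out = np.zeros(n)
        for i in range(n):
            j = (i + 1) % n
            a, b = rho[i], rho[j]
            if a <= 0 or b <= 0:
                out[i] = math.pi
                continue
            arg = (a * a + b * b - chords[i] * chords[i]) / (2.0 * a * b)
            out[i] = math.acos(min(max(arg, -1.0), 1.0))
        return out

    lo = wall_corallite + radii.max() + 1e-9
    hi = wall_corallite + radii.max() + chords.sum()
    if steps(lo).sum() < 2.0 * math.pi:
        R = lo  # cannot close the ring tighter; gaps exceed the wall slightly
    else:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if steps(mid).sum() > 2.0 * math.pi:
                lo = mid
            else:
                hi = mid
        R = 0.5 * (lo + hi)
    step = steps(R)
    angles = np.zeros(n)
    angles[1:] = np.cumsum(step[:-1])
    return R, R - wall_corallite - radii, angles


def _slot_radii_bound(spec: PhantomSpec) -> np.ndarray:
    """Largest possible slot radii, used to bound branch thickness."""
    smax = spec.max_diameter_scale()
    n_reg, has_stunted = _slot_plan(spec)
    radii = [spec.chamber_oral_diameter_range_mm[1] / 2.0 * smax] * n_reg
    if has_stunted:
        radii.append(spec.stunted_diameter_range_mm[1] / 2.0 * smax)
    return np.asarray(radii)


def _slot_plan(spec: PhantomSpec) -> tuple[int, bool]:
    """(number of regular slots, whether a stunted slot exists)."""
    if spec.corallites_per_ring >= 3:
        return spec.corallites_per_ring - 1, True
    return spec.corallites_per_ring, False


def branch_radius_bound(spec: PhantomSpec) -> float:
    radii = _slot_radii_bound(spec)
    R, _, _ = _ring_layout(
        radii, spec.wall_thickness_coenosteum_mm, spec.wall_thickness_corallite_mm
    )
    return R


def generate_branch_tree(spec: PhantomSpec) -> BranchTree:
    """Grow the dichotomous branch scaffold.

    Nodes are branch tips; the edge from a node's ``base_mm`` to its
    ``position_mm`` is the branch axis.  Every internal node has exactly two
    children ("all the branches split into two" -- there is no tripartite
    increase).  Each generation fans out around the colony axis at exactly
    even azimuths (children take their parent's azimuth plus or minus half
    the generation's angular spacing, with a small bounded jitter) on a ring
    wide enough that all branches keep coenosteum clearance, like a living
    corymbose corallum; children lean outward toward their own sector by
    half the bifurcation angle.
    """
    spec.validate()
    rng = np.random.default_rng([spec.rng_seed, 0])
    R_bound = branch_radius_bound(spec)
    wall = spec.wall_thickness_coenosteum_mm
    # clearance needed between the AXES of two branches whose chambers may
    # face each other; the factor keeps neighbouring arms further apart than
    # the bare sealing minimum
    clearance = (
        2.0 * (R_bound - spec.wall_thickness_corallite_mm) + wall
    ) * spec.branch_clearance_factor

    tree = BranchTree()
    trunk_dir = GROWTH_AXIS.copy()
    base = np.zeros(3)
    tip = base + trunk_dir * spec.segment_length(0)
    root = BranchNode(node_id=0, position_mm=tip, base_mm=base, parent_id=None, generation=0)
    tree.add_node(root)

    frontier = [(root, trunk_dir, 0.0)]  # (node, direction, azimuth)
    next_id = 1
    theta = math.radians(spec.bifurcation_angle_deg) / 2.0
    for gen in range(spec.tree_depth):
        n_children = 2 ** (gen + 1)
        ang_spacing = 2.0 * math.pi / n_children
        ring_radius = max(n_children * clearance / (2.0 * math.pi), R_bound + wall)
        new_frontier = []
        for node, d, phi_p in frontier:
            for sign in (+1.0, -1.0):
                jit = ang_spacing * 0.1 * float(rng.uniform(-1.0, 1.0))
                phi_c = phi_p + sign * ang_spacing / 2.0 + jit
                child_base = np.array(
                    [
                        node.position_mm[0],
                        ring_radius * math.sin(phi_c),
                        ring_radius * math.cos(phi_c),
                    ]
                )
                lean = np.array([0.0, math.sin(phi_c), math.cos(phi_c)])
                child_dir = math.cos(theta) * d + math.sin(theta) * lean
                child_dir /= np.linalg.norm(child_dir)
                child_tip = child_base + child_dir * spec.segment_length(gen + 1)
                child = BranchNode(
                    node_id=next_id,
                    position_mm=child_tip,
                    base_mm=child_base,
                    parent_id=node.node_id,
                    generation=gen + 1,
                )
                tree.add_node(child)
                new_frontier.append((child, child_dir, phi_c))
                next_id += 1
        frontier = new_frontier
    return tree


# --------------------------------------------------------------------------
# region assignment


def assign_regions(
    tree: BranchTree, spec: PhantomSpec, light_direction: np.ndarray = LIGHT_AXIS
) -> dict[int, int]:
    """Assign each branch node a region id 1-4.

    Lit vs low-light comes from the sign of (position - colony centroid)
    projected on the light direction; growth vs mineralization from depth:
    branch tips (youngest skeleton) are growth areas, interior nodes are
    mineralization areas.
    """
    light = np.asarray(light_direction, dtype=float)
    norm = np.linalg.norm(light)
    if norm == 0:
        raise ValueError("light_direction must be a nonzero vector")
    light = light / norm
    centroid = np.mean([n.position_mm for n in tree.nodes.values()], axis=0)
    regions: dict[int, int] = {}
    for node in tree.nodes.values():
        lit = float((node.position_mm - centroid) @ light) >= 0.0
        is_tip = len(tree.children_of(node.node_id)) == 0
        if is_tip:
            regions[node.node_id] = REGION_LIGHT_GROWTH if lit else REGION_LOWLIGHT_GROWTH
        else:
            regions[node.node_id] = (
                REGION_LIGHT_MINERALIZATION if lit else REGION_LOWLIGHT_MINERALIZATION
            )
    return regions


def _chamber_region(lit: bool, is_growth: bool) -> int:
    if is_growth:
        return REGION_LIGHT_GROWTH if lit else REGION_LOWLIGHT_GROWTH
    return REGION_LIGHT_MINERALIZATION if lit else REGION_LOWLIGHT_MINERALIZATION


# --------------------------------------------------------------------------
# rasterization

_MIN_CHAMBER_VOXELS = 64


@dataclass
class _ChamberPlan:
    corallite: "_CorallitePlan"
    index: int  # 1-based along the corallite
    t_bottom: float  # axial offset of chamber floor from slot base
    height: float
    r_oral: float
    r_aboral: float
    fill_fraction: float
    is_surface: bool
    region_id: int
    label: int = 0
    voxel_indices: tuple[np.ndarray, ...] | None = None


@dataclass
class _CorallitePlan:
    corallite_id: int
    node_id: int
    slot: int
    base: np.ndarray  # slot base point (mm)
    axis: np.ndarray  # unit growth direction
    radius: float  # full tube radius (scaled)
    is_new_bud: bool
    is_stunted: bool
    reaches_surface: bool
    on_leaf_branch: bool
    lit: bool
    budded_from: int | None
    chambers: list[_ChamberPlan] = field(default_factory=list)


def _plan_chambers(
    cor: _CorallitePlan, span: float, spec: PhantomSpec, rng: np.random.Generator
) -> None:
    """Lay out the chamber stack of one corallite within [0, span] axial mm.

    Heights scatter log-normally about a typical inter-septal spacing and
    stay clipped inside the species' stated height range.  For a
    corallite reaching the colony surface, the final calice is placed so its
    roof coincides with the branch tip, where it is punched open.
    """
    hmin, hmax = spec.chamber_height_range_mm
    h_typ = hmin + 0.4 * (hmax - hmin)
    tab = spec.tabula_thickness_mm
    cone = spec.budding_cone_chambers if cor.is_new_bud else 0
    taper_lo, taper_hi = spec.aboral_taper_range

    def draw_h() -> float:
        if hmax <= hmin:
            return hmin
        return min(max(h_typ * math.exp(float(rng.normal(0.0, 0.18))), hmin), hmax)

    def draw_taper() -> float:
        return float(rng.uniform(taper_lo, taper_hi))

    placed: list[tuple[float, float, float, float]] = []  # (t_bottom, h, r_or, r_ab)
    calice: tuple[float, float, float, float] | None = None
    cap = spec.wall_thickness_corallite_mm
    top = span
    if cor.reaches_surface:
        c_lo = max(min(spec.min_calice_height_mm, hmax), hmin)
        calice_h = float(rng.uniform(c_lo, hmax)) if hmax > c_lo else hmax
        calice_h = min(calice_h, span + cap)
        r_or = cor.radius
        # the living calice is an open cup: its roof coincides with the
        # outer tip surface (span + cap), where it is punched open
        calice = (span + cap - calice_h, calice_h, r_or, r_or * draw_taper())
        top = span + cap - calice_h - tab

    t = 0.0
    i = 0
    h_base = draw_h()
    max_lower = (spec.stunted_max_chambers - 1) if cor.is_stunted else None
    while True:
        if max_lower is not None and i >= max_lower:
            break
        if i < cone:
            frac = i / max(cone - 1, 1)
            h = h_base * (0.6 + 0.4 * frac)
            r_or = cor.radius * (0.5 + 0.5 * frac)
        else:
            h = draw_h()
            r_or = cor.radius
        if t + h > top:
            break
        placed.append((t, h, r_or, r_or * draw_taper()))
        t += h + tab
        i += 1
    if calice is not None:
        placed.append(calice)
    if not placed:
        return

    n = len(placed)
    for i, (t_bot, h, r_or, r_ab) in enumerate(placed):
        # sections are contiguous zones of the colony: the terminal
        # branchlets are the growth areas, the older interior branches the
        # mineralization areas
        region = _chamber_region(cor.lit, cor.on_leaf_branch)
        arch = spec.region_archetypes[region - 1]
        is_surface = cor.reaches_surface and i == n - 1
        fill = 0.0 if is_surface else arch.mineral_fill_fraction
        cor.chambers.append(
            _ChamberPlan(
                corallite=cor,
                index=i + 1,
                t_bottom=t_bot,
                height=h,
                r_oral=r_or,
                r_aboral=r_ab,
                fill_fraction=fill,
                is_surface=is_surface,
                region_id=region,
            )
        )


def _plan_colony(
    tree: BranchTree, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[list[_CorallitePlan], dict[int, dict], np.ndarray]:
    """Draw corallite layouts for every branch (deterministic draw order:
    branches in node-id order; per branch: diameters, taper seeds, azimuth
    phase, then chamber stacks slot by slot)."""
    # light reference: the colony's central axis (root base); corallites on
    # the +x side of it are the lit half
    root_id = [nid for nid, n in tree.nodes.items() if n.parent_id is None][0]
    light_ref = tree.nodes[root_id].base_mm
    smax_lit = spec.region_archetypes[REGION_LIGHT_GROWTH - 1].volume_scale ** (1 / 3)
    smax_dark = spec.region_archetypes[REGION_LOWLIGHT_GROWTH - 1].volume_scale ** (1 / 3)

    n_reg, has_stunted = _slot_plan(spec)
    corallites: list[_CorallitePlan] = []
    branch_geom: dict[int, dict] = {}
    cid = 0
    dmin, dmax = spec.chamber_oral_diameter_range_mm
    for node_id in sorted(tree.nodes):
        node = tree.nodes[node_id]
        axis = node.position_mm - node.base_mm
        length = float(np.linalg.norm(axis))
        axis = axis / length
        lit = float((node.position_mm - light_ref) @ LIGHT_AXIS) >= 0.0
        scale = smax_lit if lit else smax_dark
        is_leaf = len(tree.children_of(node_id)) == 0

        # sections have characteristic chamber sizes: diameters scatter
        # log-normally about the section's typical value and stay clipped
        # inside the species' stated range
        d_mid = 0.5 * (dmin + dmax)
        radii = [
            min(max(d_mid * scale * math.exp(float(rng.normal(0.0, 0.10))), dmin), dmax) / 2.0
            for _ in range(n_reg)
        ]
        if has_stunted:
            slo, shi = spec.stunted_diameter_range_mm
            s_mid = 0.5 * (slo + shi)
            radii.append(
                min(max(s_mid * scale * math.exp(float(rng.normal(0.0, 0.10))), slo), shi) / 2.0
            )
        radii_arr = np.asarray(radii)
        R_b, rho_slots, angles = _ring_layout(
            radii_arr, spec.wall_thickness_coenosteum_mm, spec.wall_thickness_corallite_mm
        )
        angles = angles + float(rng.uniform(0.0, 2.0 * math.pi))
        e1, e2 = _perp_basis(axis)
        branch_geom[node_id] = {
            "axis": axis,
            "length": length,
            "radius": R_b,
            "base": node.base_mm,
        }

        t0 = 0.25 if node.parent_id is None else spec.basal_offset_mm
        span_end = length - spec.wall_thickness_corallite_mm
        for slot in range(len(radii)):
            is_stunted = has_stunted and slot == len(radii) - 1
            slot_base = (
                node.base_mm
                + float(rho_slots[slot])
                * (math.cos(angles[slot]) * e1 + math.sin(angles[slot]) * e2)
            )
            is_new_bud = is_stunted or (node.parent_id is not None and slot % 2 == 0)
            reaches_surface = is_leaf and not is_stunted
            lit_slot = float((slot_base - light_ref) @ LIGHT_AXIS) >= 0.0
            cid += 1
            cor = _CorallitePlan(
                corallite_id=cid,
                node_id=node_id,
                slot=slot,
                base=slot_base,
                axis=axis,
                radius=float(radii_arr[slot]),
                is_new_bud=is_new_bud,
                is_stunted=is_stunted,
                reaches_surface=reaches_surface,
                on_leaf_branch=is_leaf,
                lit=lit_slot,
                budded_from=None,
            )
            if is_stunted:
                # short stack tucked just below the branch top (near-surface,
                # then mineralized over)
                est = (spec.budding_cone_chambers + 1) * (
                    0.5 * (spec.chamber_height_range_mm[0] + spec.chamber_height_range_mm[1])
                    + spec.tabula_thickness_mm
                )
                start = max(t0, span_end - 0.1 - est)
                base_pt = cor.base + axis * start
                cor = replace(cor, base=base_pt)
                _plan_chambers(cor, span_end - 0.1 - start, spec, rng)
            else:
                base_pt = cor.base + axis * t0
                cor = replace(cor, base=base_pt)
                _plan_chambers(cor, span_end - t0, spec, rng)
            corallites.append(cor)
    _assign_budding_parents(corallites, tree)
    return corallites, branch_geom, light_ref


def _assign_budding_parents(corallites: list[_CorallitePlan], tree: BranchTree) -> None:
    by_node: dict[int, list[_CorallitePlan]] = {}
    for cor in corallites:
        by_node.setdefault(cor.node_id, []).append(cor)
    for cor in corallites:
        if not cor.is_new_bud:
            continue
        node = tree.nodes[cor.node_id]
        if cor.is_stunted:
            pool = [c for c in by_node[cor.node_id] if c is not cor and not c.is_stunted]
        elif node.parent_id is not None:
            pool = [c for c in by_node[node.parent_id] if not c.is_stunted]
        else:
            pool = []
        if not pool:
            continue
        dists = [float(np.linalg.norm(c.base - cor.base)) for c in pool]
        cor.budded_from = pool[int(np.argmin(dists))].corallite_id


def _frustum_mask(
    shape: tuple[int, int, int],
    origin_mm: np.ndarray,
    spacing: float,
    base: np.ndarray,
    axis: np.ndarray,
    s0: float,
    s1: float,
    r0: float,
    r1: float,
    s_ref0: float,
    s_ref1: float,
) -> tuple[np.ndarray, tuple[slice, slice, slice]] | None:
    """Boolean mask of the (possibly truncated) frustum between axial offsets
    [s0, s1) whose radius interpolates linearly from r0 at s_ref0 to r1 at
    s_ref1, restricted to its bounding crop.  Returns (mask, crop slices)."""
    rmax = max(r0, r1)
    p_lo = base + axis * s0
    p_hi = base + axis * s1
    bb_lo = np.minimum(p_lo, p_hi) - rmax
    bb_hi = np.maximum(p_lo, p_hi) + rmax
    i_lo = np.maximum(np.floor((bb_lo - origin_mm) / spacing).astype(int), 0)
    i_hi = np.minimum(np.ceil((bb_hi - origin_mm) / spacing).astype(int) + 1, shape)
    if np.any(i_lo >= i_hi):
        return None
    sl = tuple(slice(int(a), int(b)) for a, b in zip(i_lo, i_hi))
    coords = [
        (np.arange(a, b, dtype=np.float32) + 0.5) * spacing + origin_mm[k]
        for k, (a, b) in enumerate(zip(i_lo, i_hi))
    ]
    dz = coords[0][:, None, None] - base[0]
    dy = coords[1][None, :, None] - base[1]
    dx = coords[2][None, None, :] - base[2]
    s = dz * axis[0] + dy * axis[1] + dx * axis[2]
    rad2 = (dz - s * axis[0]) ** 2 + (dy - s * axis[1]) ** 2 + (dx - s * axis[2]) ** 2
    denom = max(s_ref1 - s_ref0, 1e-12)
    frac = np.clip((s - s_ref0) / denom, 0.0, 1.0)
    radius = r0 + (r1 - r0) * frac
    mask = (s >= s0) & (s < s1) & (rad2 <= radius**2)
    return mask, sl


def _clip_foreign_branches(
    mask: np.ndarray,
    sl: tuple[slice, slice, slice],
    origin: np.ndarray,
    sp: float,
    ch: "_ChamberPlan",
    branch_geom: dict[int, dict],
    lineage: dict[int, set[int]],
    spec: PhantomSpec,
) -> None:
    """Remove chamber voxels that intrude into another branch's corallite
    zone, so chamber voids of different branches always keep at least a
    coenosteum wall between them.  A branch's own lineage is exempt (its
    axial clearance is built in)."""
    if not mask.any():
        return
    own = ch.corallite.node_id
    center = ch.corallite.base + ch.corallite.axis * (ch.t_bottom + 0.5 * ch.height)
    reach = max(ch.r_oral, ch.r_aboral) + ch.height
    coords = None
    for nb_id, geom in branch_geom.items():
        if nb_id == own or nb_id in lineage.get(own, set()):
            continue
        thresh = geom["radius"] - spec.wall_thickness_corallite_mm + spec.wall_thickness_coenosteum_mm
        if _point_segment_distance(center, geom) > thresh + reach:
            continue
        if coords is None:
            coords = [
                (np.arange(s.start, s.stop, dtype=np.float32) + 0.5) * sp + origin[k]
                for k, s in enumerate(sl)
            ]
        base, axis, length = geom["base"], geom["axis"], geom["length"]
        dz = coords[0][:, None, None] - base[0]
        dy = coords[1][None, :, None] - base[1]
        dx = coords[2][None, None, :] - base[2]
        t = np.clip(dz * axis[0] + dy * axis[1] + dx * axis[2], -spec.wall_thickness_corallite_mm, length)
        d2 = (dz - t * axis[0]) ** 2 + (dy - t * axis[1]) ** 2 + (dx - t * axis[2]) ** 2
        mask &= d2 > thresh * thresh


def _point_segment_distance(p: np.ndarray, geom: dict) -> float:
    v = p - geom["base"]
    t = float(np.clip(v @ geom["axis"], 0.0, geom["length"]))
    return float(np.linalg.norm(v - t * geom["axis"]))


def rasterize_colony(
    tree: BranchTree, spec: PhantomSpec
) -> tuple[VoxelVolume, PhantomTruth]:
    """Voxelize the colony and carve its chamber voids, recording truth.

    The mineral phase is the union of per-branch cylinders (with end caps of
    corallite-wall thickness); chamber frusta are carved out of it, tabulae
    are left standing between consecutive chambers, mineralization-region
    chambers are partially refilled from the floor, and every surface
    corallite's final calice is punched open through the tip cap.
    """
    spec.validate()
    rng = np.random.default_rng([spec.rng_seed, 1])
    sp = spec.voxel_spacing_mm
    corallites, branch_geom, light_ref = _plan_colony(tree, spec, rng)

    cap = spec.wall_thickness_corallite_mm
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for geom in branch_geom.values():
        for s in (-cap, geom["length"]):
            p = geom["base"] + geom["axis"] * s
            lo = np.minimum(lo, p - geom["radius"])
            hi = np.maximum(hi, p + geom["radius"])
    lo -= spec.margin_mm
    hi += spec.margin_mm
    shape = tuple(int(math.ceil(v)) for v in (hi - lo) / sp)
    n_vox = int(np.prod(shape))
    if n_vox > spec.max_grid_voxels:
        raise ValueError(
            f"phantom grid {shape} ({n_vox} voxels) exceeds max_grid_voxels="
            f"{spec.max_grid_voxels}; required extent {hi - lo} mm"
        )
    origin = lo

    mineral = np.zeros(shape, dtype=bool)
    for node_id in sorted(branch_geom):
        geom = branch_geom[node_id]
        res = _frustum_mask(
            shape, origin, sp, geom["base"], geom["axis"],
            -cap, geom["length"], geom["radius"], geom["radius"], 0.0, 1.0,
        )
        if res is None:
            continue
        mask, sl = res
        mineral[sl] |= mask

    # ancestor/descendant sets: axial clearance between a branch and its own
    # lineage is enforced by basal collars and tip caps; the radial guard
    # below applies to all OTHER branches
    lineage: dict[int, set[int]] = {}
    for node_id in branch_geom:
        anc = set()
        cur = tree.nodes[node_id].parent_id
        while cur is not None:
            anc.add(cur)
            cur = tree.nodes[cur].parent_id
        lineage[node_id] = anc
    for node_id, anc in lineage.items():
        for a in anc:
            lineage[a].add(node_id)  # symmetric exemption

    labels = np.zeros(shape, dtype=np.int32)
    plans: list[_ChamberPlan] = [ch for cor in corallites for ch in cor.chambers]
    next_label = 0
    for ch in plans:
        cor = ch.corallite
        s_bot = ch.t_bottom + ch.fill_fraction * ch.height
        s_top = ch.t_bottom + ch.height
        if s_top - s_bot < sp:
            continue
        res = _frustum_mask(
            shape, origin, sp, cor.base, cor.axis,
            s_bot, s_top, ch.r_aboral, ch.r_oral,
            ch.t_bottom, ch.t_bottom + ch.height,
        )
        if res is None:
            continue
        mask, sl = res
        mask &= mineral[sl]
        _clip_foreign_branches(mask, sl, origin, sp, ch, branch_geom, lineage, spec)
        if int(mask.sum()) < _MIN_CHAMBER_VOXELS:
            continue
        if np.any(labels[sl][mask] != 0):
            raise RuntimeError(
                f"phantom chamber collision at corallite {cor.corallite_id}"
            )
        next_label += 1
        ch.label = next_label
        sub = labels[sl]
        sub[mask] = next_label
        mineral_sl = mineral[sl]
        mineral_sl[mask] = False
        if ch.is_surface:
            # make sure the calice mouth is open to the exterior
            res2 = _frustum_mask(
                shape, origin, sp, cor.base, cor.axis,
                s_top, s_top + 2.0 * sp, ch.r_oral, ch.r_oral, 0.0, 1.0,
            )
            if res2 is not None:
                pmask, psl = res2
                msl = mineral[psl]
                msl[pmask] = False

    # keep only the largest 6-connected component of each chamber
    struct = ndimage.generate_binary_structure(3, 1)
    objects = ndimage.find_objects(labels)
    for ch in plans:
        if ch.label == 0:
            continue
        sl = objects[ch.label - 1]
        if sl is None:
            ch.label = 0
            continue
        sub = labels[sl] == ch.label
        comp, ncomp = ndimage.label(sub, structure=struct)
        if ncomp > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, ncomp + 1))
            keep = int(np.argmax(sizes)) + 1
            drop = sub & (comp != keep)
            lab_sub = labels[sl]
            lab_sub[drop] = 0
            min_sub = mineral[sl]
            min_sub[drop] = True
            sub = sub & (comp == keep)
        if int(sub.sum()) < _MIN_CHAMBER_VOXELS:
            lab_sub = labels[sl]
            min_sub = mineral[sl]
            was = lab_sub == ch.label
            lab_sub[was] = 0
            min_sub[was] = True
            ch.label = 0

    # renumber labels contiguously in (corallite, chamber index) order
    survivors = [ch for ch in plans if ch.label != 0]
    remap = np.zeros(max((ch.label for ch in survivors), default=0) + 1, dtype=np.int32)
    for new_id, ch in enumerate(survivors, start=1):
        remap[ch.label] = new_id
        ch.label = new_id
    labels = remap[labels]

    chambers: list[TrueChamber] = []
    truth_corallites: list[TrueCorallite] = []
    cor_map: dict[int, TrueCorallite] = {}
    objects = ndimage.find_objects(labels)
    for cor in corallites:
        kept = [ch for ch in cor.chambers if ch.label != 0]
        if not kept:
            continue
        tc = TrueCorallite(
            corallite_id=cor.corallite_id,
            branch_node_id=cor.node_id,
            slot=cor.slot,
            axis=cor.axis,
            base_mm=cor.base,
            tube_radius_mm=cor.radius,
            is_new_bud=cor.is_new_bud,
            is_stunted=cor.is_stunted,
            reaches_surface=cor.reaches_surface and kept[-1].is_surface,
            budded_from_corallite=cor.budded_from,
        )
        for idx, ch in enumerate(kept, start=1):
            sl = objects[ch.label - 1]
            sub = labels[sl] == ch.label
            count = int(sub.sum())
            zz, yy, xx = np.nonzero(sub)
            center = (
                np.array(
                    [
                        zz.mean() + sl[0].start,
                        yy.mean() + sl[1].start,
                        xx.mean() + sl[2].start,
                    ]
                )
                + 0.5
            ) * sp + origin
            chambers.append(
                TrueChamber(
                    chamber_id=ch.label,
                    corallite_id=cor.corallite_id,
                    chamber_index_from_origin=idx,
                    region_id=ch.region_id,
                    true_center_mm=center,
                    true_volume_mm3=count * sp**3,
                    true_oral_diameter_mm=2.0 * ch.r_oral,
                    true_aboral_diameter_mm=2.0 * ch.r_aboral,
                    true_height_mm=(1.0 - ch.fill_fraction) * ch.height,
                    is_surface_calice=ch.is_surface,
                )
            )
            tc.chamber_ids.append(ch.label)
        truth_corallites.append(tc)
        cor_map[cor.corallite_id] = tc

    chambers.sort(key=lambda c: c.chamber_id)
    volume = VoxelVolume(values=mineral.astype(np.uint8), spacing_mm=sp, origin_mm=origin.copy())
    truth = PhantomTruth(
        chamber_labels=labels,
        chambers=chambers,
        corallites=truth_corallites,
        tree=tree,
        spec=spec,
        light_reference_mm=light_ref,
    )
    return volume, truth


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[VoxelVolume, PhantomTruth]:
    """Convenience wrapper: tree + rasterization in one call."""
    spec = spec if spec is not None else PhantomSpec()
    tree = generate_branch_tree(spec)
    return rasterize_colony(tree, spec)
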