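"""Growth-axis topology: trajectories, budding, bundles and the branch tree.

A corallite's chambers record the path of one polyp from its budding point
to the colony surface.  Chaining chamber centroids reconstructs these
*growth trajectories*; trajectories that share an origin form *growth
bundles* (groups of polyps with synchronized growth); budding links between
bundles, aggregated to branch level, recover the colony's dichotomous
growth-axis tree.  Deviations from strict dichotomy are reported, never
silently corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

__all__ = [
    "BranchNode",
    "BranchTree",
    "GrowthTrajectory",
    "GrowthBundle",
    "DichotomyReport",
    "trace_trajectories",
    "classify_growth_type",
    "detect_budding_origin",
    "build_axis_tree",
]


# --------------------------------------------------------------------------
# tree types


@dataclass
class BranchNode:
    node_id: int
    position_mm: np.ndarray  # branch tip, (z, y, x) mm
    base_mm: np.ndarray  # branch base
    parent_id: int | None
    generation: int


@dataclass
class BranchTree:
    """Rooted branch scaffold; every internal node of a healthy colony has
    exactly two children."""

    nodes: dict[int, BranchNode] = field(default_factory=dict)
    _children: dict[int, list[int]] = field(default_factory=dict)

    def add_node(self, node: BranchNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id}")
        self.nodes[node.node_id] = node
        self._children.setdefault(node.node_id, [])
        if node.parent_id is not None:
            if node.parent_id not in self.nodes:
                raise ValueError(f"parent {node.parent_id} unknown for node {node.node_id}")
            self._children.setdefault(node.parent_id, []).append(node.node_id)

    def children_of(self, node_id: int) -> list[int]:
        return list(self._children.get(node_id, []))

    @property
    def root_ids(self) -> list[int]:
        return [nid for nid, n in self.nodes.items() if n.parent_id is None]

    @property
    def root_id(self) -> int:
        roots = self.root_ids
        if len(roots) != 1:
            raise ValueError(f"tree has {len(roots)} roots")
        return roots[0]

    def internal_node_ids(self) -> list[int]:
        return [nid for nid in self.nodes if len(self._children.get(nid, [])) > 0]

    def tip_ids(self) -> list[int]:
        return [nid for nid in self.nodes if len(self._children.get(nid, [])) == 0]

    def out_degrees(self) -> dict[int, int]:
        return {nid: len(self._children.get(nid, [])) for nid in self.nodes}

    def n_bifurcations(self) -> int:
        return sum(1 for nid in self.internal_node_ids())

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "node_id": n.node_id,
                    "position_mm": [float(v) for v in n.position_mm],
                    "base_mm": [float(v) for v in n.base_mm],
                    "parent_id": n.parent_id,
                    "generation": n.generation,
                }
                for n in self.nodes.values()
            ]
        }


@dataclass
class GrowthTrajectory:
    corallite_id: int
    chamber_ids: list[int]
    axis_directions: list[np.ndarray]  # unit step directions, len = n-1 (or 1 estimate)
    growth_type: str | None = None  # budding | nonbudding | stunted
    origin_is_budding_cone: bool | None = None
    initial_axis: np.ndarray | None = None  # robust growth-axis estimate
    ends_at_surface: bool = False
    terminated: bool = False
    budded_from_chamber: int | None = None
    budded_from_corallite: int | None = None

    @property
    def origin_chamber(self) -> int:
        return self.chamber_ids[0]

    @property
    def mean_axis(self) -> np.ndarray:
        if self.axis_directions:
            v = np.sum(self.axis_directions, axis=0)
            n = np.linalg.norm(v)
            if n > 0:
                return v / n
        return np.array([1.0, 0.0, 0.0])


@dataclass
class GrowthBundle:
    bundle_id: int
    originating_node: int | None
    member_corallite_ids: list[int]
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    is_major: bool = True


@dataclass
class DichotomyReport:
    out_degree: dict[int, int]
    violations: dict[int, int]  # internal nodes with out-degree != 2
    n_internal: int
    n_roots: int

    @property
    def all_dichotomous(self) -> bool:
        return not self.violations


# --------------------------------------------------------------------------
# trajectory tracing


def _chamber_normals(labels: np.ndarray, records: pd.DataFrame, spacing: float) -> dict[int, np.ndarray]:
    """Per-chamber stacking direction: the least-variance principal axis of
    the chamber's voxels (tabula-bounded chambers are flat disks, so their
    normal is the growth direction).  Near-isotropic chambers get a null
    normal and are linked by distance alone."""
    normals: dict[int, np.ndarray] = {}
    objects = ndimage.find_objects(labels)
    for cid in records["chamber_id"].astype(int):
        sl = objects[cid - 1] if cid - 1 < len(objects) else None
        if sl is None:
            normals[cid] = np.zeros(3)
            continue
        pts = np.argwhere(labels[sl] == cid).astype(float)
        if len(pts) < 8:
            normals[cid] = np.zeros(3)
            continue
        pts -= pts.mean(axis=0)
        cov = pts.T @ pts / len(pts)
        w, v = np.linalg.eigh(cov)
        # eigh sorts ascending: column 0 = least variance
        if w[1] < 1.44 * w[0] + 1e-12:  # extents within ~20%: isotropic
            normals[cid] = np.zeros(3)
        else:
            normals[cid] = v[:, 0]
    # near-isotropic chambers (deep calices, budding-cone starters) inherit
    # the stacking direction of the nearest clearly oriented chamber, so
    # lateral same-ring neighbours cannot masquerade as stack successors
    oriented = [c for c, nrm in normals.items() if np.linalg.norm(nrm) > 0]
    if oriented:
        cent = records.set_index("chamber_id")[
            ["centroid_z_mm", "centroid_y_mm", "centroid_x_mm"]
        ]
        opos = cent.loc[oriented].to_numpy(float)
        for cid, nrm in list(normals.items()):
            if np.linalg.norm(nrm) > 0:
                continue
            d = np.linalg.norm(opos - cent.loc[cid].to_numpy(float), axis=1)
            normals[cid] = normals[oriented[int(np.argmin(d))]]
    return normals


def trace_trajectories(
    chambers,
    records: pd.DataFrame,
    cone_half_angle_deg: float = 45.0,
    gap_factor: float = 2.0,
    barrier_factor: float = 2.0,
) -> list[GrowthTrajectory]:
    """Chain chambers into per-corallite growth trajectories.

    Chambers are linked when their centroid gap is below ``gap_factor`` times
    the mean chamber thickness and the link direction lies within the linkage
    cone around the chamber's stacking normal; each chamber keeps at most one
    link per side (minimal angular deviation, then distance), and only
    reciprocal links survive, so trajectories are simple chains.  Chains are
    oriented from origin to surface (a chain ending in a surface calice runs
    toward it; otherwise away from the colony centroid) and unlinkable
    chambers become singleton trajectories.

    A third gate rejects links whose straight path crosses more than
    ``barrier_factor`` mean thicknesses of non-chamber material: successive
    chambers of one corallite are separated only by a thin dissepiment,
    whereas chambers of converging foreign branches have thick walls (or
    open space) between them.
    """
    recs = records[~records.get("truncated", pd.Series(False, index=records.index))]
    recs = recs.reset_index(drop=True)
    if len(recs) == 0:
        return []
    ids = recs["chamber_id"].astype(int).to_numpy()
    cents = recs[["centroid_z_mm", "centroid_y_mm", "centroid_x_mm"]].to_numpy(float)
    classes = (
        recs["class"].to_numpy()
        if "class" in recs
        else np.array(["internal_space"] * len(recs))
    )
    # mean chamber thickness: smallest bounding extent is a robust proxy for
    # the axial height of tabula-bounded chambers
    thick = recs[["extent_z_mm", "extent_y_mm", "extent_x_mm"]].to_numpy(float).min(axis=1)
    gap = gap_factor * float(thick.mean())
    labels = chambers.labels if hasattr(chambers, "labels") else chambers
    spacing = getattr(chambers, "spacing_mm", 1.0)
    origin_mm = np.asarray(getattr(chambers, "origin_mm", np.zeros(3)), dtype=float)
    normals = _chamber_normals(labels, recs, spacing)
    cos_lim = math.cos(math.radians(cone_half_angle_deg))

    n = len(recs)
    from scipy.spatial import cKDTree

    tree = cKDTree(cents)
    pairs = tree.query_pairs(r=gap + float(thick.max()), output_type="ndarray")
    # candidate scored links: (i, side, score, j)
    best: dict[tuple[int, int], tuple[float, float, int]] = {}
    for i, j in pairs:
        d = cents[j] - cents[i]
        dist = float(np.linalg.norm(d))
        if dist == 0:
            continue
        # the linkage gap is the free space between the chamber faces, not
        # the centroid spacing: a tall chamber may hold its centroid far
        # from a tabula it sits directly on
        if dist - 0.5 * (thick[i] + thick[j]) > gap:
            continue
        if _barrier_length(
            labels, cents[i], cents[j], spacing, origin_mm
        ) > barrier_factor * float(thick.mean()):
            continue
        u = d / dist
        ok = True
        dev = 0.0
        for k, vec in ((i, u), (j, -u)):
            nk = normals[ids[k]]
            if np.linalg.norm(nk) > 0:
                c = abs(float(nk @ vec))  # normal is orientation-free
                if c < cos_lim:
                    ok = False
                    break
                dev = max(dev, 1.0 - c)
        if not ok:
            continue
        for k, vec in ((i, u), (j, -u)):
            nk = normals[ids[k]]
            if np.linalg.norm(nk) > 0:
                side = 0 if float(nk @ vec) >= 0 else 1
            else:
                side = 0 if vec[0] >= 0 else 1  # fall back to global growth axis
            other = j if k == i else i
            key = (int(k), side)
            # nearest first: a perfectly coaxial skip-over-one link must not
            # outrank the adjacent chamber
            cand = (dist, dev, int(other))
            if key not in best or cand < best[key]:
                best[key] = cand

    # reciprocal filter
    edges: set[tuple[int, int]] = set()
    chosen = {key: val[2] for key, val in best.items()}
    for (k, _side), other in chosen.items():
        if any(chosen.get((other, s)) == k for s in (0, 1)):
            edges.add((min(k, other), max(k, other)))

    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in sorted(edges):
        if len(adj[a]) < 2 and len(adj[b]) < 2:
            adj[a].append(b)
            adj[b].append(a)

    colony_centroid = cents.mean(axis=0)
    surface_pts = cents[classes == "surface_calice"]
    seen = np.zeros(n, dtype=bool)
    trajectories: list[GrowthTrajectory] = []
    order = np.argsort(ids)
    for start in order:
        if seen[start] or len(adj[start]) == 2:
            continue
        chain = [int(start)]
        seen[start] = True
        prev = int(start)
        nxt = adj[start][0] if adj[start] else None
        while nxt is not None and not seen[nxt]:
            chain.append(int(nxt))
            seen[nxt] = True
            nbrs = [m for m in adj[nxt] if m != prev]
            prev, nxt = int(nxt), (nbrs[0] if nbrs else None)
        trajectories.append(
            _orient_chain(chain, ids, cents, classes, colony_centroid, surface_pts)
        )
    # isolated cycles (degenerate): break at smallest id
    for start in order:
        if seen[start]:
            continue
        chain = [int(start)]
        seen[start] = True
        prev = int(start)
        nxt = adj[start][0]
        while not seen[nxt]:
            chain.append(int(nxt))
            seen[nxt] = True
            nbrs = [m for m in adj[nxt] if m != prev]
            prev, nxt = int(nxt), nbrs[0]
        logger.warning("cycle of %d chambers broken into a chain", len(chain))
        trajectories.append(
            _orient_chain(chain, ids, cents, classes, colony_centroid, surface_pts)
        )

    for t_i, traj in enumerate(trajectories, start=1):
        traj.corallite_id = t_i
        if len(traj.chamber_ids) == 1:
            logger.debug("singleton trajectory for chamber %d", traj.chamber_ids[0])
        # robust axis estimate: stacking normals of the member chambers,
        # sign-aligned with the chain direction (single centroid steps are
        # noisy for two-chamber trajectories)
        ref = traj.mean_axis
        acc = np.zeros(3)
        for cid in traj.chamber_ids:
            nrm = normals.get(cid, np.zeros(3))
            if np.linalg.norm(nrm) > 0:
                acc += nrm if float(nrm @ ref) >= 0 else -nrm
        nacc = np.linalg.norm(acc)
        traj.initial_axis = acc / nacc if nacc > 0 else ref
    _link_budding(trajectories, ids, cents, float(thick.mean()))
    return trajectories


def _barrier_length(
    labels: np.ndarray,
    a_mm: np.ndarray,
    b_mm: np.ndarray,
    spacing: float,
    origin_mm: np.ndarray,
) -> float:
    """Length of non-chamber material along the straight path between two
    chamber centroids (half-voxel sampling)."""
    a = (a_mm - origin_mm) / spacing - 0.5
    b = (b_mm - origin_mm) / spacing - 0.5
    dist = float(np.linalg.norm(b - a))
    n = max(int(dist / 0.5), 1)
    ts = (np.arange(n) + 0.5) / n
    pts = np.rint(a[None, :] + ts[:, None] * (b - a)[None, :]).astype(int)
    shape = np.array(labels.shape)
    inside = np.all((pts >= 0) & (pts < shape), axis=1)
    vals = np.zeros(n, dtype=bool)
    vals[inside] = labels[pts[inside, 0], pts[inside, 1], pts[inside, 2]] == 0
    return float(vals.sum()) / n * dist * spacing


def _orient_chain(
    chain, ids, cents, classes, colony_centroid, surface_pts=None
) -> GrowthTrajectory:
    first_surface = classes[chain[0]] == "surface_calice"
    last_surface = classes[chain[-1]] == "surface_calice"
    if first_surface and not last_surface:
        chain = chain[::-1]
    elif not (first_surface or last_surface) and len(chain) > 1:
        if surface_pts is not None and len(surface_pts):
            # interior chains grew toward the colony surface: the origin is
            # the end deepest inside the skeleton
            d0 = np.linalg.norm(surface_pts - cents[chain[0]], axis=1).min()
            d1 = np.linalg.norm(surface_pts - cents[chain[-1]], axis=1).min()
            if d0 < d1:
                chain = chain[::-1]
        else:
            d0 = np.linalg.norm(cents[chain[0]] - colony_centroid)
            d1 = np.linalg.norm(cents[chain[-1]] - colony_centroid)
            if d0 > d1:
                chain = chain[::-1]
    dirs = []
    for a, b in zip(chain[:-1], chain[1:]):
        v = cents[b] - cents[a]
        nv = np.linalg.norm(v)
        dirs.append(v / nv if nv > 0 else np.zeros(3))
    ends_surface = classes[chain[-1]] == "surface_calice"
    return GrowthTrajectory(
        corallite_id=0,
        chamber_ids=[int(ids[c]) for c in chain],
        axis_directions=dirs,
        ends_at_surface=bool(ends_surface),
        terminated=not bool(ends_surface),
    )


def _link_budding(
    trajectories: list[GrowthTrajectory],
    ids: np.ndarray,
    cents: np.ndarray,
    mean_thickness: float,
    radius_factor: float = 10.0,
) -> None:
    """Assign each trajectory the parent chamber it budded from: the nearest
    chamber of another trajectory lying behind the origin along the initial
    growth axis (within a 55-degree cone around the reverse axis -- a parent
    sits beneath its bud, a lateral neighbour does not), within a search
    radius."""
    pos = {int(i): cents[k] for k, i in enumerate(ids)}
    owner: dict[int, int] = {}
    for traj in trajectories:
        for c in traj.chamber_ids:
            owner[c] = traj.corallite_id
    radius = radius_factor * mean_thickness
    eps = mean_thickness
    for traj in trajectories:
        origin = pos[traj.origin_chamber]
        axis = traj.axis_directions[0] if traj.axis_directions else traj.mean_axis
        if np.linalg.norm(axis) == 0:
            axis = np.array([1.0, 0.0, 0.0])
        best = None
        cone = math.cos(math.radians(55.0))
        for cid, p in pos.items():
            if owner[cid] == traj.corallite_id:
                continue
            d = p - origin
            dist = float(np.linalg.norm(d))
            if dist > radius or float(d @ axis) > -eps:
                continue
            if float(-(d @ axis)) < cone * dist:
                continue
            if best is None or dist < best[0]:
                best = (dist, cid)
        if best is not None:
            traj.budded_from_chamber = best[1]
            traj.budded_from_corallite = owner[best[1]]


# --------------------------------------------------------------------------
# growth types and budding cones


def classify_growth_type(
    traj: GrowthTrajectory,
    budded_from: dict[int, int],
    stunted_max: int = 5,
) -> str:
    """budding if another trajectory originates from one of this trajectory's
    chambers; else stunted if the chamber count is at most ``stunted_max``
    (polyps deviating from the growth axis stop after four or five
    inter-septal spaces); else nonbudding."""
    has_daughter = any(
        parent in traj.chamber_ids for parent in budded_from.values()
    )
    if has_daughter:
        return "budding"
    if len(traj.chamber_ids) <= stunted_max:
        return "stunted"
    return "nonbudding"


def detect_budding_origin(
    traj: GrowthTrajectory, records: pd.DataFrame, cone_chambers: int = 3
) -> bool | None:
    """True iff the trajectory starts with an inverted-cone ramp: equivalent
    diameter strictly increasing over the first ``cone_chambers`` chambers
    with a total relative rise of at least 20%."""
    if len(traj.chamber_ids) < cone_chambers:
        return None
    diam = records.set_index("chamber_id")["eq_diameter_mm"]
    d = [float(diam.loc[c]) for c in traj.chamber_ids[:cone_chambers]]
    increasing = all(b > a for a, b in zip(d[:-1], d[1:]))
    rise = (d[-1] - d[0]) / d[0] if d[0] > 0 else 0.0
    return bool(increasing and rise >= 0.20)


# --------------------------------------------------------------------------
# axis tree


def build_axis_tree(
    trajectories: list[GrowthTrajectory],
    records: pd.DataFrame,
    bundle_cutoff_mm: float = 1.5,
    direction_scale_mm: float = 5.0,
    parent_scale: float = 0.5,
    bundle_min_size: int = 3,
) -> tuple[BranchTree, list[GrowthBundle], DichotomyReport]:
    """Aggregate trajectories into growth bundles and recover the branch tree.

    Trajectories are clustered on (origin position, scaled initial
    direction, scaled budding-parent position) by single linkage: polyps of
    one branch share an origin zone, a growth direction, and parents within
    the same mother branch, while branches of different bifurcations differ
    in at least one of the three (branches born far apart on neighbouring
    arms can converge in both position and direction, but never in
    parentage).  Bundles with at least ``bundle_min_size`` members are
    branch-level nodes; smaller bundles are minor buds.  Tree edges follow
    the majority of member budding links; the report lists every internal
    node's out-degree and flags departures from dichotomy.
    """
    if not trajectories:
        raise ValueError("no trajectories to aggregate")
    cent = records.set_index("chamber_id")[
        ["centroid_z_mm", "centroid_y_mm", "centroid_x_mm"]
    ]
    origins = np.array([cent.loc[t.origin_chamber].to_numpy(float) for t in trajectories])
    axes = np.array([
        (
            t.initial_axis
            if t.initial_axis is not None
            else (t.axis_directions[0] if t.axis_directions else np.zeros(3))
        )
        for t in trajectories
    ])
    parents = np.array([
        (
            cent.loc[t.budded_from_chamber].to_numpy(float)
            if t.budded_from_chamber is not None
            else cent.loc[t.origin_chamber].to_numpy(float)
        )
        for t in trajectories
    ])
    feats = np.hstack([origins, direction_scale_mm * axes, parent_scale * parents])
    if len(trajectories) == 1:
        memb = np.array([1])
    else:
        memb = fcluster(
            linkage(feats, method="single"), t=bundle_cutoff_mm, criterion="distance"
        )

    traj_by_id = {t.corallite_id: t for t in trajectories}
    bundle_of_traj: dict[int, int] = {}
    bundles: list[GrowthBundle] = []
    for b_id in sorted(set(memb)):
        members = [trajectories[k].corallite_id for k in np.flatnonzero(memb == b_id)]
        origin = origins[np.flatnonzero(memb == b_id)].mean(axis=0)
        bundles.append(
            GrowthBundle(
                bundle_id=int(b_id),
                originating_node=None,
                member_corallite_ids=members,
                origin_mm=origin,
                is_major=len(members) >= bundle_min_size,
            )
        )
        for m in members:
            bundle_of_traj[m] = int(b_id)

    owner: dict[int, int] = {}
    for t in trajectories:
        for c in t.chamber_ids:
            owner[c] = t.corallite_id

    # bundle -> parent bundle by majority vote of member budding links
    parent_votes: dict[int, dict[int, int]] = {}
    for t in trajectories:
        if t.budded_from_corallite is None:
            continue
        b = bundle_of_traj[t.corallite_id]
        pb = bundle_of_traj[t.budded_from_corallite]
        if pb == b:
            continue
        parent_votes.setdefault(b, {})[pb] = parent_votes.setdefault(b, {}).get(pb, 0) + 1
    parent_of: dict[int, int | None] = {}
    for bundle in bundles:
        votes = parent_votes.get(bundle.bundle_id, {})
        parent_of[bundle.bundle_id] = (
            max(sorted(votes), key=lambda k: votes[k]) if votes else None
        )

    major = [b for b in bundles if b.is_major]
    major_ids = {b.bundle_id for b in major}

    def major_ancestor(b_id: int | None) -> int | None:
        seen = set()
        while b_id is not None and b_id not in major_ids:
            if b_id in seen:
                return None
            seen.add(b_id)
            b_id = parent_of.get(b_id)
        return b_id

    tree = BranchTree()
    order = sorted(major, key=lambda b: (float(b.origin_mm[0]), b.bundle_id))
    placed: set[int] = set()
    # insert parents before children
    pending = list(order)
    guard = 0
    while pending and guard < 10 * len(order) + 10:
        guard += 1
        b = pending.pop(0)
        par = major_ancestor(parent_of.get(b.bundle_id))
        if par == b.bundle_id:
            par = None
        if par is not None and par not in placed:
            pending.append(b)
            continue
        mean_tip = np.mean(
            [
                cent.loc[traj_by_id[m].chamber_ids[-1]].to_numpy(float)
                for m in b.member_corallite_ids
            ],
            axis=0,
        )
        tree.add_node(
            BranchNode(
                node_id=b.bundle_id,
                position_mm=mean_tip,
                base_mm=b.origin_mm,
                parent_id=par,
                generation=0,
            )
        )
        b.originating_node = b.bundle_id
        placed.add(b.bundle_id)
    for b in [x for x in order if x.bundle_id not in placed]:
        # unresolved parent chain: attach as extra root, reported below
        tree.add_node(
            BranchNode(
                node_id=b.bundle_id,
                position_mm=b.origin_mm,
                base_mm=b.origin_mm,
                parent_id=None,
                generation=0,
            )
        )
        placed.add(b.bundle_id)

    degrees = tree.out_degrees()
    internal = {nid: d for nid, d in degrees.items() if d > 0}
    report = DichotomyReport(
        out_degree=degrees,
        violations={nid: d for nid, d in internal.items() if d != 2},
        n_internal=len(internal),
        n_roots=len(tree.root_ids),
    )
    return tree, bundles, report
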