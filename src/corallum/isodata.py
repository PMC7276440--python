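"""ISODATA clustering of chamber features and section statistics.

ISODATA (Iterative Self-Organizing Data Analysis) is k-means with
data-driven cluster management: undersized clusters are discarded, diffuse
clusters are split along their widest dimension, and near-coincident
clusters are merged.  It is used here to partition chambers into the four
colony sections (low-light/light x growth/mineralization), followed by
independent-samples t tests between sections.

The algorithm (classic Ball-Hall formulation):

1. assign every point to the nearest centroid (Euclidean distance);
2. discard clusters smaller than ``n_min`` and reassign their members;
3. recompute centroids;
4. on odd iterations, split clusters by perturbing the centroid by
   ``+-eps`` along the widest dimension (``eps = 0.5 sigma_split``): while
   ``k`` is below ``k_desired`` the most diffuse splittable cluster is
   split unconditionally (the classic drive toward the desired count);
   beyond that a cluster splits only if its largest per-dimension standard
   deviation exceeds ``sigma_split``, its mean intra-cluster distance
   exceeds the overall mean, it can spare ``n_min`` members to each half,
   and ``k < 2 k_desired``;
5. on even iterations, merge up to ``max_merge_pairs`` disjoint pairs of
   clusters with centroid distance below ``d_merge`` (closest first);
6. stop when an assignment pass changes nothing, or after ``max_iter``.

Deterministic for a fixed seed (initial centroids are points sampled
without replacement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "ISODATAParams",
    "ClusterResult",
    "SectionComparison",
    "isodata_fit",
    "map_clusters_to_sections",
    "compare_sections",
]


@dataclass
class ISODATAParams:
    k_init: int = 2
    k_desired: int = 4
    n_min: int = 20
    sigma_split: float = 1.25  # standardized units; a z-scored feature
    # carrying no cluster signal has within-cluster sd ~ 1, so the split
    # threshold must sit above that noise floor
    d_merge: float = 1.0
    max_merge_pairs: int = 1
    max_iter: int = 100
    seed: int = 0
    enable_split: bool = True
    enable_merge: bool = True

    def validate(self) -> None:
        if self.k_init < 1 or self.k_desired < 1:
            raise ValueError("k_init and k_desired must be >= 1")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if not (self.sigma_split > 0 and self.d_merge > 0):
            raise ValueError("sigma_split and d_merge must be positive")
        if self.max_merge_pairs < 1 or self.max_iter < 1:
            raise ValueError("max_merge_pairs and max_iter must be >= 1")


@dataclass
class ClusterResult:
    assignments: np.ndarray
    centroids: np.ndarray
    k_final: int
    iteration_log: list[dict] = field(default_factory=list)
    converged: bool = False

    def wss(self, X: np.ndarray) -> float:
        d = X - self.centroids[self.assignments]
        return float((d * d).sum())


def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return np.argmin(cdist(X, centroids), axis=1)


def _recompute(X: np.ndarray, assign: np.ndarray, k: int) -> np.ndarray:
    return np.vstack([X[assign == j].mean(axis=0) for j in range(k)])


def isodata_fit(X: np.ndarray, params: ISODATAParams) -> ClusterResult:
    """Run ISODATA on an (n, p) feature matrix (standardized upstream)."""
    params.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if n < params.k_init:
        raise ValueError(f"n={n} points < k_init={params.k_init}")
    rng = np.random.default_rng(params.seed)
    idx = rng.choice(n, size=params.k_init, replace=False)
    centroids = X[np.sort(idx)].copy()
    assign = np.full(n, -1)
    log: list[dict] = []
    converged = False

    for it in range(1, params.max_iter + 1):
        entry = {"iteration": it, "splits": 0, "merges": 0, "discards": 0}
        new_assign = _assign(X, centroids)
        # drop empty clusters
        used = np.unique(new_assign)
        if len(used) < len(centroids):
            centroids = centroids[used]
            new_assign = _assign(X, centroids)
        # discard undersized clusters, reassign members
        while len(centroids) > 1:
            sizes = np.bincount(new_assign, minlength=len(centroids))
            small = np.flatnonzero(sizes < params.n_min)
            if small.size == 0:
                break
            drop = small[np.argmin(sizes[small])]
            centroids = np.delete(centroids, drop, axis=0)
            new_assign = _assign(X, centroids)
            entry["discards"] += 1
        k = len(centroids)
        centroids = _recompute(X, new_assign, k)
        changed = not np.array_equal(new_assign, assign)
        assign = new_assign

        structural = 0
        if params.enable_split and it % 2 == 1:
            structural = _split_pass(X, assign, centroids, params, entry)
            if structural:
                centroids = entry.pop("_centroids")
        elif params.enable_merge and it % 2 == 0:
            structural = _merge_pass(X, assign, centroids, params, entry)
            if structural:
                centroids = entry.pop("_centroids")
        entry["k"] = len(centroids)
        log.append(entry)
        if not changed and structural == 0 and it > 1:
            converged = True
            break

    final_assign = _assign(X, centroids)
    used = np.unique(final_assign)
    centroids = _recompute(X, final_assign, len(centroids))[used]
    final_assign = _assign(X, centroids)
    return ClusterResult(
        assignments=final_assign,
        centroids=centroids,
        k_final=len(centroids),
        iteration_log=log,
        converged=converged,
    )


def _split_pass(X, assign, centroids, params: ISODATAParams, entry) -> int:
    k = len(centroids)
    if k >= 2 * params.k_desired:
        return 0
    dists = np.linalg.norm(X - centroids[assign], axis=1)
    overall_mean = float(dists.mean())
    eps = 0.5 * params.sigma_split
    new_centroids = [c for c in centroids]
    n_split = 0
    stats = []
    for j in range(k):
        members = assign == j
        if int(members.sum()) < 2 * (params.n_min + 1):
            continue
        sds = X[members].std(axis=0, ddof=0)
        dim = int(np.argmax(sds))
        stats.append((float(sds[dim]), dim, j, float(dists[members].mean())))
    stats.sort(reverse=True)  # most diffuse first
    for sd_max, dim, j, mean_intra in stats:
        if len(new_centroids) >= 2 * params.k_desired:
            break
        force = len(new_centroids) < params.k_desired
        if force:
            if sd_max <= 1e-12:
                continue
        else:
            if sd_max <= params.sigma_split or mean_intra <= overall_mean:
                continue
        c = new_centroids[j].copy()
        delta = np.zeros_like(c)
        delta[dim] = eps
        new_centroids[j] = c + delta
        new_centroids.append(c - delta)
        n_split += 1
        if force and len(new_centroids) >= params.k_desired:
            break
    if n_split:
        entry["splits"] = n_split
        entry["_centroids"] = np.vstack(new_centroids)
    return n_split


def _merge_pass(X, assign, centroids, params: ISODATAParams, entry) -> int:
    k = len(centroids)
    if k <= 1:
        return 0
    d = cdist(centroids, centroids)
    pairs = [
        (d[i, j], i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if d[i, j] < params.d_merge
    ]
    pairs.sort()
    sizes = np.bincount(assign, minlength=k)
    used: set[int] = set()
    merged_into: dict[int, int] = {}
    n_merge = 0
    for _, i, j in pairs:
        if n_merge >= params.max_merge_pairs:
            break
        if i in used or j in used:
            continue
        used.update((i, j))
        merged_into[j] = i
        n_merge += 1
    if not n_merge:
        return 0
    new_centroids = []
    for i in range(k):
        if i in merged_into:
            continue
        if i in used:  # survivor of a merge
            j = next(jj for jj, ii in merged_into.items() if ii == i)
            w = sizes[i] + sizes[j]
            c = (centroids[i] * sizes[i] + centroids[j] * sizes[j]) / max(w, 1)
            new_centroids.append(c)
        else:
            new_centroids.append(centroids[i])
    entry["merges"] = n_merge
    entry["_centroids"] = np.vstack(new_centroids)
    return n_merge


# --------------------------------------------------------------------------
# section mapping and comparison


def map_clusters_to_sections(
    result: ClusterResult,
    records,
    light_axis_column: str = "centroid_x_mm",
    light_sign: float = 1.0,
) -> "pd.DataFrame":
    """Label the four clusters as colony sections 1-4.

    The two lowest-mean-volume clusters are the mineralization areas
    (accumulating mineral fills the inter-septal spaces), the two highest
    are the growth areas; within each pair, the cluster whose mean position
    along the light axis is higher is the lit one.  Sections: (1) low-light
    mineralization, (2) low-light growth, (3) light growth, (4) light
    mineralization.  Requires ``k_final == 4``.
    """
    import pandas as pd

    if result.k_final != 4:
        raise ValueError(
            f"section mapping needs exactly 4 clusters, got {result.k_final}; "
            "adjust ISODATA parameters (k_desired, n_min, sigma_split, d_merge)"
        )
    records = records.reset_index(drop=True)
    if len(records) != len(result.assignments):
        raise ValueError("records and assignments length mismatch")
    vol = np.array(
        [records.loc[result.assignments == j, "volume_mm3"].mean() for j in range(4)]
    )
    light = np.array(
        [
            light_sign * records.loc[result.assignments == j, light_axis_column].mean()
            for j in range(4)
        ]
    )
    order = np.argsort(vol)
    mineral_pair, growth_pair = order[:2], order[2:]
    mapping = {}
    m_lo, m_hi = sorted(mineral_pair, key=lambda j: light[j])
    g_lo, g_hi = sorted(growth_pair, key=lambda j: light[j])
    mapping[m_lo], mapping[m_hi] = 1, 4
    mapping[g_lo], mapping[g_hi] = 2, 3
    out = records.copy()
    out["cluster"] = result.assignments
    out["region_id"] = [mapping[int(j)] for j in result.assignments]
    return out


@dataclass
class SectionComparison:
    feature: str
    region_a: int
    region_b: int
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    df: float
    p_value: float
    significant: bool
    test: str


def compare_sections(
    records,
    feature: str,
    groups: tuple[int, int],
    test: str = "student",
) -> SectionComparison:
    """Independent-samples t test of one feature between two sections.

    ``student`` is the pooled-variance test (the classic independent-samples
    t test); ``welch`` drops the equal-variance assumption.  Two-sided p;
    ``significant`` flags p < 0.05.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    a_id, b_id = groups
    a = np.asarray(records.loc[records["region_id"] == a_id, feature], dtype=float)
    b = np.asarray(records.loc[records["region_id"] == b_id, feature], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 points per group, got {len(a)} (region {a_id}) "
            f"and {len(b)} (region {b_id})"
        )
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    if test == "student":
        df = len(a) + len(b) - 2
    else:
        df = float(res.df)
    return SectionComparison(
        feature=feature,
        region_a=a_id,
        region_b=b_id,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < 0.05),
        test=test,
    )
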