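"""SNV-frequency profile clustering.

Position/frequency filtering, pairwise distances under pluggable metrics
(euclidean, manhattan, canberra, pearson), agglomerative clustering
(single, complete, average/UPGMA) and neighbor joining, all with
deterministic smallest-label-pair tie-breaking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ngsdesk import core_io
from ngsdesk.profile import SNVProfile
from ngsdesk.tree import TreeNode

METRICS = ("euclidean", "manhattan", "canberra", "pearson")
LINKAGES = ("single", "complete", "average", "neighbor_joining")

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class ClusterParams:
    metric: str = "euclidean"
    linkage: str = "average"
    min_depth: int = 1
    min_freq: float = 0.0
    position_whitelist: Optional[list[Interval]] = None
    position_blacklist: Optional[list[Interval]] = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if not 0.0 <= self.min_freq <= 1.0:
            raise ValueError("min_freq must be in [0, 1]")
        if self.position_whitelist and self.position_blacklist:
            for ws, we in self.position_whitelist:
                for bs, be in self.position_blacklist:
                    if ws < be and bs < we:
                        raise ValueError(
                            f"whitelist [{ws},{we}) overlaps blacklist [{bs},{be})"
                        )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _in_intervals(pos: int, intervals: Sequence[Interval]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def filter_profile(snv_profile: SNVProfile, params: ClusterParams) -> SNVProfile:
    """Apply depth, frequency and position filters to one profile.

    Frequencies below ``min_freq`` and positions below ``min_depth``,
    outside the whitelist or inside the blacklist are dropped.  The depth
    map keeps only positions passing the depth and position filters, so a
    filtered-out position counts as uncovered downstream.
    """
    out = SNVProfile(ref_id=snv_profile.ref_id)
    for pos, depth in snv_profile.depths.items():
        if depth < params.min_depth:
            continue
        if params.position_whitelist is not None and not _in_intervals(
            pos, params.position_whitelist
        ):
            continue
        if params.position_blacklist is not None and _in_intervals(
            pos, params.position_blacklist
        ):
            continue
        out.depths[pos] = depth
    for pos, freq in snv_profile.freqs.items():
        if pos in out.depths and freq >= params.min_freq:
            out.freqs[pos] = freq
    return out


def _pair_vectors(a: SNVProfile, b: SNVProfile) -> tuple[np.ndarray, np.ndarray]:
    """Union-of-positions frequency vectors for one pair.

    A position enters the comparison only when covered in both samples;
    a covered position absent from a sample's sparse map contributes 0.
    """
    union = sorted(set(a.freqs) | set(b.freqs))
    kept = [p for p in union if p in a.depths and p in b.depths]
    va = np.array([a.freqs.get(p, 0.0) for p in kept])
    vb = np.array([b.freqs.get(p, 0.0) for p in kept])
    return va, vb


def profile_distance(a: SNVProfile, b: SNVProfile, metric: str) -> float:
    if a.ref_id != b.ref_id:
        raise ValueError(f"profiles on different references: {a.ref_id!r} vs {b.ref_id!r}")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    va, vb = _pair_vectors(a, b)
    if va.size == 0:
        return 0.0
    if metric == "euclidean":
        return float(math.sqrt(((va - vb) ** 2).sum()))
    if metric == "manhattan":
        return float(np.abs(va - vb).sum())
    if metric == "canberra":
        denom = va + vb
        mask = denom > 0
        return float((np.abs(va - vb)[mask] / denom[mask]).sum())
    # pearson: 1 - r, with r := 0 for constant vectors
    if va.std() == 0.0 or vb.std() == 0.0:
        return 1.0
    r = float(np.corrcoef(va, vb)[0, 1])
    return 1.0 - r


def distance_matrix(
    profiles: dict[str, SNVProfile] | Sequence[tuple[str, SNVProfile]],
    params: ClusterParams,
) -> DistanceMatrix:
    items = list(profiles.items()) if isinstance(profiles, dict) else list(profiles)
    if len(items) < 2:
        raise ValueError("need at least 2 profiles")
    labels = [label for label, _ in items]
    filtered = [filter_profile(p, params) for _, p in items]
    n = len(items)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = profile_distance(filtered[i], filtered[j], params.metric)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def _check_matrix(matrix: DistanceMatrix) -> None:
    if np.isnan(matrix.values).any():
        raise ValueError("distance matrix contains NaN")
    if (matrix.values < 0).any():
        raise ValueError("distance matrix contains negative values")


def _agglomerative(matrix: DistanceMatrix, linkage: str) -> TreeNode:
    """Standard agglomerative merging with Lance-Williams updates.

    Node heights are half the merge distance, so branch lengths are merge
    height differences and UPGMA output is ultrametric.  Ties break on the
    smallest (min-leaf-label, min-leaf-label) pair, making the result
    invariant to input order.
    """
    n = len(matrix.labels)
    clusters: dict[int, TreeNode] = {}
    sizes: dict[int, int] = {}
    minlab: dict[int, str] = {}
    for i, label in enumerate(matrix.labels):
        clusters[i] = TreeNode(label=label, height=0.0)
        sizes[i] = 1
        minlab[i] = label
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(matrix.values[i, j])

    next_id = n
    while len(clusters) > 1:
        active = sorted(clusters)
        best_pair, best_key = None, None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                d = dist[frozenset((i, j))]
                key = (d, tuple(sorted((minlab[i], minlab[j]))))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        d_merge = best_key[0]
        height = d_merge / 2.0
        left, right = clusters[i], clusters[j]
        left.length = max(height - left.height, 0.0)
        right.length = max(height - right.height, 0.0)
        parent = TreeNode(children=[left, right], height=height)
        new_id = next_id
        next_id += 1
        del clusters[i], clusters[j]
        for m in clusters:
            dmi = dist.pop(frozenset((m, i)))
            dmj = dist.pop(frozenset((m, j)))
            if linkage == "single":
                dnew = min(dmi, dmj)
            elif linkage == "complete":
                dnew = max(dmi, dmj)
            else:  # average / UPGMA
                dnew = (sizes[i] * dmi + sizes[j] * dmj) / (sizes[i] + sizes[j])
            dist[frozenset((m, new_id))] = dnew
        dist.pop(frozenset((i, j)))
        clusters[new_id] = parent
        sizes[new_id] = sizes[i] + sizes[j]
        minlab[new_id] = min(minlab[i], minlab[j])
    return clusters[next_id - 1] if n > 1 else clusters[0]


def _neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with a final two-node join.

    Negative branch lengths are clamped to 0; ties break on the smallest
    (min-leaf-label, min-leaf-label) pair.  The returned tree is rooted at
    the final join.
    """
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=lab) for i, lab in enumerate(matrix.labels)
    }
    minlab = {i: lab for i, lab in enumerate(matrix.labels)}
    dist: dict[frozenset, float] = {}
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(matrix.values[i, j])
    next_id = n
    active = set(nodes)

    while len(active) > 2:
        r = len(active)
        totals = {
            i: sum(dist[frozenset((i, j))] for j in active if j != i) for i in active
        }
        best_pair, best_key = None, None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                q = (r - 2) * dist[frozenset((i, j))] - totals[i] - totals[j]
                key = (q, tuple(sorted((minlab[i], minlab[j]))))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        dij = dist[frozenset((i, j))]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_id = next_id
        next_id += 1
        for m in active:
            if m in (i, j):
                continue
            dmi = dist.pop(frozenset((m, i)))
            dmj = dist.pop(frozenset((m, j)))
            dist[frozenset((m, new_id))] = 0.5 * (dmi + dmj - dij)
        dist.pop(frozenset((i, j)))
        active -= {i, j}
        active.add(new_id)
        nodes[new_id] = parent
        minlab[new_id] = min(minlab[i], minlab[j])

    i, j = sorted(active)
    d_final = dist[frozenset((i, j))]
    nodes[i].length = max(d_final / 2.0, 0.0)
    nodes[j].length = max(d_final - nodes[i].length, 0.0)
    return TreeNode(children=[nodes[i], nodes[j]])


def hierarchical_cluster(matrix: DistanceMatrix, linkage: str) -> TreeNode:
    """Build a tree from a distance matrix under the requested linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(matrix.labels) < 2:
        raise ValueError("need at least 2 samples")
    _check_matrix(matrix)
    if linkage == "neighbor_joining":
        return _neighbor_joining(matrix)
    return _agglomerative(matrix, linkage)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    header = ["sample"] + list(matrix.labels)
    rows = (
        [label] + [f"{v:.10g}" for v in matrix.values[i]]
        for i, label in enumerate(matrix.labels)
    )
    core_io.write_tsv(path, header, rows)


def read_distance_matrix(path) -> DistanceMatrix:
    header, rows = core_io.read_tsv(path)
    labels = header[1:]
    values = np.array([[float(v) for v in row[1:]] for row in rows])
    return DistanceMatrix(labels=labels, values=values)
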