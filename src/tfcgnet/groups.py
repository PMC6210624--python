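"""Coordinated TF group (TFCG) extraction and cross-network matching.

A TFCG is a set of Key TFs that mutually share at least a threshold
percentage (70% by default) of their high-confidence network-unique target
genes.  The directed overlap from TF i to TF j is
``100 * |T_i intersect T_j| / |T_i|`` — generally asymmetric — and the
membership predicate requires the overlap in *both* directions for every
pair.  Extraction builds the undirected "mutual overlap" graph and greedily
accepts maximal cliques (largest first, ties broken by lexicographically
smallest member set), removing accepted TFs, so the output groups are
disjoint and deterministic.  An overlapping TFCG (oTFCG) links a group in
one network to a group in another when they share at least two Key TFs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import ValidationError

__all__ = [
    "TargetOverlapMatrix",
    "TFCG",
    "OTfcgPair",
    "OTfcgMatch",
    "compute_overlap_matrix",
    "find_tfcgs",
    "match_otfcgs",
    "cluster_overlap_heatmap_order",
]


@dataclass
class TargetOverlapMatrix:
    """Directed percent target overlaps between Key TFs.

    ``overlap[i][j] = 100 * |T_i ∩ T_j| / |T_i|``.  When built from target
    sets the integer intersection counts and set sizes are kept so
    threshold comparisons can be done in exact integer arithmetic.
    """

    tf_ids: list[str]
    overlap: np.ndarray
    intersections: np.ndarray | None = None  # integer |T_i ∩ T_j|
    set_sizes: np.ndarray | None = None  # integer |T_i|
    target_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.overlap = np.asarray(self.overlap, dtype=float)
        n = len(self.tf_ids)
        if self.overlap.shape != (n, n):
            raise ValidationError("overlap matrix must be square over tf_ids")
        if np.any(self.overlap < 0) or np.any(self.overlap > 100):
            raise ValidationError("overlaps are percentages in [0, 100]")

    def mutual_at_least(self, i: int, j: int, threshold: float) -> bool:
        """Reciprocal >= threshold, exact when counts are available."""
        if self.intersections is not None and self.set_sizes is not None:
            inter = int(self.intersections[i, j])
            return (
                100 * inter >= threshold * int(self.set_sizes[i])
                and 100 * inter >= threshold * int(self.set_sizes[j])
            )
        return (
            self.overlap[i, j] >= threshold and self.overlap[j, i] >= threshold
        )


@dataclass
class TFCG:
    """A disjoint group of >= 2 Key TFs with its shared target core."""

    group_id: str
    members: set
    core_targets: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("a TFCG needs at least 2 members")


@dataclass
class OTfcgPair:
    group_a_id: str
    group_b_id: str
    shared_tfs: set


@dataclass
class OTfcgMatch:
    pairs: list[OTfcgPair]
    matched_fraction_b: float


def compute_overlap_matrix(target_sets: dict) -> TargetOverlapMatrix:
    """Directed percent overlaps from a TF -> target-set map.

    TFs with empty target sets are dropped with a warning; TF order is
    canonicalized by sorting so the result is input-order invariant.
    """
    empty = sorted(t for t, s in target_sets.items() if not s)
    if empty:
        warnings.warn(f"dropping TFs with empty target sets: {empty}")
    tfs = sorted(t for t, s in target_sets.items() if s)
    if not tfs:
        raise ValidationError("no TFs with non-empty target sets")
    sets = [set(target_sets[t]) for t in tfs]
    n = len(tfs)
    inter = np.zeros((n, n), dtype=int)
    sizes = np.array([len(s) for s in sets], dtype=int)
    for i in range(n):
        for j in range(i, n):
            c = len(sets[i] & sets[j])
            inter[i, j] = inter[j, i] = c
    overlap = 100.0 * inter / sizes[:, None]
    return TargetOverlapMatrix(
        tfs, overlap, inter, sizes, {t: set(target_sets[t]) for t in tfs}
    )


def _best_clique(graph: nx.Graph):
    """Largest maximal clique; ties broken by lexicographically smallest
    sorted member tuple."""
    best = None
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        key = (-len(clique), tuple(sorted(clique)))
        if best is None or key < best[0]:
            best = (key, clique)
    return None if best is None else sorted(best[1])


def find_tfcgs(
    overlaps: TargetOverlapMatrix, threshold: float = 70.0
) -> list[TFCG]:
    """Extract disjoint TFCGs from the mutual-overlap graph.

    Edge (i, j) exists iff both directed overlaps are >= threshold;
    maximal cliques are accepted greedily (size descending, then
    lexicographic member tie-break), with accepted TFs removed, until no
    clique of size >= 2 remains.  Every emitted group is re-checked
    against the reciprocal-threshold predicate.
    """
    n = len(overlaps.tf_ids)
    graph = nx.Graph()
    graph.add_nodes_from(overlaps.tf_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if overlaps.mutual_at_least(i, j, threshold):
                graph.add_edge(overlaps.tf_ids[i], overlaps.tf_ids[j])

    idx = {t: i for i, t in enumerate(overlaps.tf_ids)}
    groups: list[TFCG] = []
    remaining = graph.copy()
    while True:
        members = _best_clique(remaining)
        if members is None:
            break
        for a in members:  # defensive re-check of the membership predicate
            for b in members:
                if a < b and not overlaps.mutual_at_least(idx[a], idx[b], threshold):
                    raise AssertionError(
                        f"clique {members} violates the reciprocal predicate"
                    )
        core: set = set()
        if overlaps.target_sets:
            core = set.intersection(
                *(overlaps.target_sets[m] for m in members)
            )
        groups.append(
            TFCG(f"TFCG{len(groups) + 1:02d}", set(members), core)
        )
        remaining.remove_nodes_from(members)
    return groups


def match_otfcgs(
    groups_a: list[TFCG], groups_b: list[TFCG], min_shared: int = 2
) -> OTfcgMatch:
    """All cross-network group pairs sharing >= min_shared Key TFs, plus
    the fraction of B groups matched by at least one A group."""
    pairs: list[OTfcgPair] = []
    matched_b: set[str] = set()
    for ga in groups_a:
        for gb in groups_b:
            shared = ga.members & gb.members
            if len(shared) >= min_shared:
                pairs.append(OTfcgPair(ga.group_id, gb.group_id, shared))
                matched_b.add(gb.group_id)
    frac = len(matched_b) / len(groups_b) if groups_b else 0.0
    return OTfcgMatch(pairs, frac)


def cluster_overlap_heatmap_order(overlaps: TargetOverlapMatrix) -> list[str]:
    """Leaf order of complete-linkage clustering of the symmetrized
    overlap dissimilarity (100 minus the lesser of the two directions);
    one ordering for both heatmap axes."""
    n = len(overlaps.tf_ids)
    if n == 1:
        return list(overlaps.tf_ids)
    dis = 100.0 - np.minimum(overlaps.overlap, overlaps.overlap.T)
    np.fill_diagonal(dis, 0.0)
    Z = linkage(squareform(dis, checks=False), method="complete")
    return [overlaps.tf_ids[i] for i in leaves_list(Z)]


def plot_overlap_heatmap(overlaps: TargetOverlapMatrix, path) -> None:
    """Optional heatmap of directed overlaps in clustered order
    (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cluster_overlap_heatmap_order(overlaps)
    idx = [overlaps.tf_ids.index(t) for t in order]
    M = overlaps.overlap[np.ix_(idx, idx)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, cmap="RdBu_r", vmin=0, vmax=100)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="% target overlap")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
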