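"""Differential comparison of two inferred networks.

Edge z-scores from paired condition networks are converted to the
probability that an interaction is *unique to, and strongly supported in*,
network A relative to network B,

    P_ij = Phi(zA_ij) * Phi((zA_ij - zB_ij) / sqrt(2)),

with Phi the standard normal CDF: the first factor asks for strong support
in A on the z-scale, the second for A-specific support (the difference of
two unit-variance scores has sd sqrt(2)).  Edges with probability strictly
above a cut (0.90 by default) are the high-confidence unique edges.  TFs
significantly enriched for unique targets under the hypergeometric law
with Bonferroni correction are the Key TFs, and a sample-label permutation
null checks that unique edges vanish when condition structure is
destroyed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .io import ExpressionMatrix, MotifPrior, PPINetwork, ValidationError
from .panda import (
    PandaConfig,
    RegulatoryNetwork,
    compute_coexpression,
    filter_tfs,
    normalize_expression,
    panda_infer,
)

__all__ = [
    "DifferentialEdgeSet",
    "KeyTfTable",
    "unique_edge_probability",
    "call_unique_edges",
    "hypergeometric_pvalue",
    "identify_key_tfs",
    "permutation_null",
    "PROBABILITY_FORMULAS",
]


def _anchored_difference(z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
    return ndtr(z_a) * ndtr((z_a - z_b) / np.sqrt(2.0))


def _independent_tails(z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
    return ndtr(z_a) * (1.0 - ndtr(z_b))


# Swappable probability laws; "anchored_difference" is the default reading
# of "unique to, and strongly supported in, one network".
PROBABILITY_FORMULAS = {
    "anchored_difference": _anchored_difference,
    "independent_tails": _independent_tails,
}


def unique_edge_probability(z_a, z_b, formula: str = "anchored_difference"):
    """Probability that an edge is unique to network A (elementwise)."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    try:
        fn = PROBABILITY_FORMULAS[formula]
    except KeyError:
        raise ValidationError(f"unknown probability formula {formula!r}") from None
    return fn(z_a, z_b)


@dataclass
class DifferentialEdgeSet:
    """Paired z-scores, unique-interaction probabilities and the
    high-confidence mask for an A-vs-B network comparison."""

    tf_ids: list[str]
    gene_ids: list[str]
    z_a: np.ndarray
    z_b: np.ndarray
    probability: np.ndarray
    threshold: float = 0.90
    unique_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        shape = (len(self.tf_ids), len(self.gene_ids))
        for name in ("z_a", "z_b", "probability"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            if m.shape != shape:
                raise ValidationError(f"{name} shape {m.shape} != {shape}")
        if np.any(self.probability < 0) or np.any(self.probability > 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        if not (0 <= self.threshold <= 1):
            raise ValidationError("threshold must lie in [0, 1]")
        self.unique_mask = self.probability > self.threshold  # strictly above

    @property
    def n_unique(self) -> int:
        return int(self.unique_mask.sum())

    def unique_targets_of(self, tf: str) -> set[str]:
        i = self.tf_ids.index(tf)
        return {g for j, g in enumerate(self.gene_ids) if self.unique_mask[i, j]}

    def unique_target_sets(self, tfs=None) -> dict[str, set[str]]:
        tfs = list(self.tf_ids) if tfs is None else list(tfs)
        return {tf: self.unique_targets_of(tf) for tf in tfs}


def call_unique_edges(
    net_a: RegulatoryNetwork,
    net_b: RegulatoryNetwork,
    threshold: float = 0.90,
    formula: str = "anchored_difference",
) -> DifferentialEdgeSet:
    """Compare two networks over identical id spaces."""
    if net_a.tf_ids != net_b.tf_ids or net_a.gene_ids != net_b.gene_ids:
        missing_tf = sorted(set(net_a.tf_ids) ^ set(net_b.tf_ids))
        missing_g = sorted(set(net_a.gene_ids) ^ set(net_b.gene_ids))
        raise ValidationError(
            "networks must share id spaces; mismatched TFs: "
            f"{missing_tf}, genes: {missing_g}"
        )
    prob = unique_edge_probability(net_a.z, net_b.z, formula=formula)
    return DifferentialEdgeSet(
        list(net_a.tf_ids), list(net_a.gene_ids), net_a.z, net_b.z, prob, threshold
    )


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K successes,
    n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"infeasible parameters K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"k={k} outside [0, min(n={n}, K={K})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class KeyTfTable:
    """Per-TF unique-target enrichment with Bonferroni-corrected calls."""

    table: pd.DataFrame  # columns: tf, unique_target_count, p_value, is_key
    tested_tf_count: int
    critical_p: float

    def key_tfs(self) -> list[str]:
        return list(self.table.loc[self.table["is_key"], "tf"])


def identify_key_tfs(edges: DifferentialEdgeSet, alpha: float = 0.05) -> KeyTfTable:
    """Hypergeometric enrichment of each TF for network-unique targets.

    Universe N = all TF x gene pairs, successes K = all unique edges,
    draws n = the TF's gene universe, observed k = the TF's unique-target
    count.  A TF is Key when p < alpha / (number of TFs tested).
    """
    n_tfs, n_genes = len(edges.tf_ids), len(edges.gene_ids)
    N = n_tfs * n_genes
    K = edges.n_unique
    critical_p = alpha / n_tfs
    rows = []
    for i, tf in enumerate(edges.tf_ids):
        k = int(edges.unique_mask[i, :].sum())
        p = hypergeometric_pvalue(k, K, n_genes, N) if K > 0 else 1.0
        rows.append((tf, k, p, p < critical_p))
    table = pd.DataFrame(
        rows, columns=["tf", "unique_target_count", "p_value", "is_key"]
    )
    return KeyTfTable(table, tested_tf_count=n_tfs, critical_p=critical_p)


def permutation_null(
    prior: MotifPrior,
    ppi: PPINetwork,
    expr_all: ExpressionMatrix,
    labels: dict[str, str],
    config: PandaConfig | None = None,
    n_permutations: int = 10,
    seed: int = 0,
    threshold: float = 0.90,
    formula: str = "anchored_difference",
) -> np.ndarray:
    """Unique-edge counts under sample-label permutation.

    For each permutation the condition labels are reshuffled across the
    samples of ``expr_all`` (normalized counts, both conditions), both
    networks are rebuilt, and the number of probability > threshold edges
    is counted.  Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    conds = sorted(set(labels.values()))
    if len(conds) < 2:
        raise ValidationError("need >= 2 conditions in labels")
    config = config or PandaConfig()
    prior_f, ppi_f = filter_tfs(prior, ppi, expr_all, config)
    logged = normalize_expression(expr_all, pseudocount=config.pseudocount)
    cond_a, cond_b = conds[0], conds[1]
    label_values = [labels[s] for s in expr_all.sample_ids]

    rng = np.random.default_rng(seed)
    counts = np.empty(n_permutations, dtype=int)
    for p in range(n_permutations):
        permuted = [label_values[i] for i in rng.permutation(len(label_values))]
        shuffled = ExpressionMatrix(
            list(logged.gene_ids),
            list(logged.sample_ids),
            logged.values,
            dict(zip(logged.sample_ids, permuted)),
            "log2_median_centered",
        )
        net_a = panda_infer(prior_f, ppi_f, shuffled, cond_a, config)
        net_b = panda_infer(prior_f, ppi_f, shuffled, cond_b, config)
        edges = call_unique_edges(net_a, net_b, threshold, formula)
        counts[p] = edges.n_unique
    return counts
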