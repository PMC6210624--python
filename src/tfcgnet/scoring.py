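"""Subtype-signature scoring and impact-group stratification.

The subtype fraction of a sample against a gene signature is the fraction
of the signature's measured genes whose expression in that sample is
strictly greater than twice (configurable) the gene's median across all
samples — a robust per-gene baseline.  A declared simplified paired
differential-expression stand-in (paired log2 fold change + exact Wilcoxon
signed-rank + Benjamini-Hochberg) feeds hierarchical clustering that
splits post-treatment samples into high- and low-impact response groups;
group comparisons use an exact Mann-Whitney test for small samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

__all__ = [
    "subtype_fraction",
    "summarize_fractions",
    "simple_paired_de",
    "DeGeneTable",
    "stratify_impact_groups",
    "mann_whitney",
]


def subtype_fraction(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    fold: float = 2.0,
    scale: str = "linear",
) -> pd.DataFrame:
    """Per-(sample, signature) fraction of genes > fold x across-sample median.

    ``scale`` declares the scale of ``expr.values``: "linear" applies the
    fold rule directly, "log2" exponentiates first so the fold is always a
    linear-scale ratio.  The comparison is strict, so a gene constant
    across samples never scores as overexpressed.  Invariant to gene and
    sample order.
    """
    if scale not in ("linear", "log2"):
        raise ValidationError(f"scale must be 'linear' or 'log2', got {scale!r}")
    values = np.exp2(expr.values) if scale == "log2" else expr.values
    gidx = expr.gene_index()
    med = np.median(values, axis=1)
    over = values > fold * med[:, None]
    out = {}
    for name in sets.names():
        rows = [gidx[g] for g in sets[name] if g in gidx]
        if not rows:
            raise ValidationError(
                f"signature {name!r} has no genes measured in the matrix"
            )
        out[name] = over[rows, :].mean(axis=0)
    return pd.DataFrame(out, index=expr.sample_ids)


def summarize_fractions(
    fractions: pd.DataFrame, group_of: dict[str, str]
) -> pd.DataFrame:
    """Mean fraction per (group, signature), plus percent change between the
    first two groups in sorted order when exactly two are present."""
    groups = sorted(set(group_of.values()))
    rows = []
    for g in groups:
        samples = [s for s in fractions.index if group_of.get(s) == g]
        rows.append(fractions.loc[samples].mean())
    summary = pd.DataFrame(rows, index=groups)
    if len(groups) == 2:
        a, b = groups
        base = summary.loc[a].replace(0, np.nan)
        summary.loc["percent_change"] = 100.0 * (summary.loc[b] - summary.loc[a]) / base
    return summary


@dataclass
class DeGeneTable:
    """Per-gene paired differential-expression results (simplified
    stand-in for a count-model GLM; see docs)."""

    table: pd.DataFrame  # gene, log2_fold_change, p_value, q_value, passes
    fc_threshold: float
    q_threshold: float

    def passing_genes(self) -> list[str]:
        return list(self.table.loc[self.table["passes"], "gene"])

    def downregulated(self) -> list[str]:
        m = self.table["passes"] & (self.table["log2_fold_change"] < 0)
        return list(self.table.loc[m, "gene"])

    def upregulated(self) -> list[str]:
        m = self.table["passes"] & (self.table["log2_fold_change"] > 0)
        return list(self.table.loc[m, "gene"])


def simple_paired_de(
    expr: ExpressionMatrix,
    pre_samples: list[str],
    post_samples: list[str],
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> DeGeneTable:
    """Paired log2 fold change + Wilcoxon signed-rank + BH q-values.

    ``pre_samples[i]`` is paired with ``post_samples[i]``.  The Wilcoxon
    test is exact for n <= 25 pairs without ties or zero differences, the
    normal approximation otherwise; identical pre/post profiles give
    p = 1.  This is a deliberately simple surrogate for a negative-
    binomial count model, adequate for feeding the clustering stage.
    """
    if len(pre_samples) != len(post_samples):
        orphans = sorted(
            set(pre_samples).symmetric_difference(post_samples)
            - (set(pre_samples) & set(post_samples))
        )
        raise ValidationError(
            f"pre/post lists differ in length; unpaired samples: {orphans}"
        )
    known = set(expr.sample_ids)
    orphans = [s for s in list(pre_samples) + list(post_samples) if s not in known]
    if orphans:
        raise ValidationError(f"samples absent from the matrix: {orphans}")
    n = len(pre_samples)
    if n < 5:
        raise ValidationError(f"need >= 5 pairs, got {n}")

    sidx = {s: j for j, s in enumerate(expr.sample_ids)}
    if expr.transform_state == "log2_median_centered":
        V = expr.values
    else:
        if np.any(expr.values < 0):
            raise ValidationError("counts must be non-negative")
        V = np.log2(expr.values + pseudocount)
    pre = V[:, [sidx[s] for s in pre_samples]]
    post = V[:, [sidx[s] for s in post_samples]]
    diffs = post - pre

    log2fc = diffs.mean(axis=1)
    pvals = np.empty(expr.n_genes)
    for i, d in enumerate(diffs):
        if np.allclose(d, 0):
            pvals[i] = 1.0
            continue
        if n <= 12:
            # sign-permutation enumeration handles tied |differences|
            pvals[i] = _wilcoxon_exact_signflip(d)
        elif n <= 25 and not _has_wilcoxon_ties(d):
            pvals[i] = stats.wilcoxon(d, zero_method="wilcox",
                                      method="exact").pvalue
        else:
            pvals[i] = stats.wilcoxon(d, zero_method="wilcox",
                                      method="approx").pvalue
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    passes = (np.abs(log2fc) >= np.log2(fc_threshold)) & (qvals < q_threshold)
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "passes": passes,
        }
    )
    return DeGeneTable(table, fc_threshold, q_threshold)


def _wilcoxon_exact_signflip(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign flips.

    Zero differences are dropped (the classic "wilcox" zero rule); tied
    absolute differences take midranks, which the enumeration handles
    without any approximation.
    """
    nz = d[d != 0]
    if len(nz) == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(nz))
    t_minus_obs = float(ranks[nz < 0].sum())
    m = len(nz)
    le = ge = 0
    for signs in range(1 << m):
        t = sum(ranks[b] for b in range(m) if (signs >> b) & 1)
        if t <= t_minus_obs + 1e-9:
            le += 1
        if t >= t_minus_obs - 1e-9:
            ge += 1
    total = 1 << m
    return min(1.0, 2.0 * min(le, ge) / total)


def _has_wilcoxon_ties(d: np.ndarray) -> bool:
    nz = d[d != 0]
    return len(nz) == 0 or len(np.unique(np.abs(nz))) < len(nz) or np.any(d == 0)


def stratify_impact_groups(
    expr_post: ExpressionMatrix,
    de_genes: DeGeneTable,
    k: int = 2,
) -> dict[str, str]:
    """Split post-treatment samples into high/low impact groups.

    Complete-linkage Euclidean clustering of samples on the passing DE
    genes, cut at ``k`` (escalating if the cut yields fewer than two
    non-singleton clusters).  Among non-singleton clusters the one with
    the lowest mean expression of the downregulated DE genes is labeled
    ``"high"`` (the strongest repression = the strongest response), the
    rest ``"low"``; singleton clusters are flagged ``"outlier"``.
    Deterministic: samples are processed in sorted-id order.
    """
    genes = de_genes.passing_genes()
    gidx = expr_post.gene_index()
    genes = [g for g in genes if g in gidx]
    if len(genes) < 2:
        raise ValidationError("need >= 2 DE genes measured in the matrix")
    samples = sorted(expr_post.sample_ids)
    if len(samples) < 2:
        raise ValidationError("need >= 2 samples to stratify")
    sidx = {s: j for j, s in enumerate(expr_post.sample_ids)}
    X = expr_post.values[np.ix_([gidx[g] for g in genes], [sidx[s] for s in samples])].T
    if np.allclose(pdist(X), 0):
        raise ValidationError("no structure: all samples identical on DE genes")

    Z = linkage(X, method="complete", metric="euclidean")
    n = len(samples)
    kk = min(k, n)
    while True:
        assign = fcluster(Z, t=kk, criterion="maxclust")
        sizes = pd.Series(assign).value_counts()
        if (sizes >= 2).sum() >= 2 or kk >= n:
            break
        kk += 1

    down = [g for g in de_genes.downregulated() if g in gidx]
    ref_genes, pick_lowest = (down, True) if down else (
        [g for g in de_genes.upregulated() if g in gidx], False
    )
    if not ref_genes:
        ref_genes, pick_lowest = genes, True
    ref_rows = [gidx[g] for g in ref_genes]

    cluster_ids = sorted(set(assign))
    nonsingle = [c for c in cluster_ids if (assign == c).sum() >= 2]
    scored = nonsingle if nonsingle else cluster_ids
    means = {}
    for c in scored:
        cols = [sidx[samples[i]] for i in range(n) if assign[i] == c]
        means[c] = float(expr_post.values[np.ix_(ref_rows, cols)].mean())
    extreme = min(means, key=lambda c: (means[c], c)) if pick_lowest else max(
        means, key=lambda c: (-means[c], c)
    )

    labels: dict[str, str] = {}
    for i, s in enumerate(samples):
        c = assign[i]
        if c not in scored:
            labels[s] = "outlier"
        elif c == extreme:
            labels[s] = "high"
        else:
            labels[s] = "low"
    return labels


def mann_whitney(group_x, group_y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U of the first group).

    Exact by permutation enumeration when min(n) <= 8 and combined
    n <= 20 (ties handled with midranks); normal approximation with tie
    correction otherwise.  Returns (U, p); all-tied inputs give p = 1.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    nx, ny = len(x), len(y)
    ranks = stats.rankdata(combined)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if np.all(combined == combined[0]):
        return u_obs, 1.0
    if min(nx, ny) <= 8 and nx + ny <= 20:
        const = nx * (nx + 1) / 2.0
        total = comb(nx + ny, nx)
        le = ge = 0
        eps = 1e-9
        for idx in combinations(range(nx + ny), nx):
            u = ranks[list(idx)].sum() - const
            if u <= u_obs + eps:
                le += 1
            if u >= u_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_obs, p
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)
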