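"""Synthetic regulatory scenarios with planted ground truth.

Two kinds of datasets are generated, both pure functions of a seed
(numpy PCG64 via ``default_rng``):

* :func:`generate_scenario` plants groups of TFs that co-target shared
  gene sets in one condition only.  Co-regulation follows a latent-factor
  model: in the signal condition each planted group draws one standard
  normal factor per sample and its target genes (and member TFs, so the
  expression filter is exercised) load on that factor; in the other
  condition the same genes are independent noise.  The motif prior holds
  the true edges minus Bernoulli false negatives plus uniform false
  positives; the PPI carries within-group support over a sparse uniform
  background.  Latent values are emitted as normalized counts
  ``baseline * 2**latent`` so the downstream count filter and log2
  median-centering operate on a realistic scale.

* :func:`generate_signature_dataset` plants per-sample overexpression of
  signature genes in a minority "high" group so the fraction-of-genes
  >2-fold-above-median score can be recovered exactly.

Every generator returns the planted truth alongside the data so
downstream stages can be scored against it.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    MotifPrior,
    PPINetwork,
    ValidationError,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "generate_scenario",
    "generate_signature_dataset",
]


@dataclass
class ScenarioConfig:
    """Parameters of a planted-group regulatory scenario.

    ``planted_groups`` is a list of (tf_count, shared_target_count) pairs;
    members and targets are allocated disjointly.  ``signal_strength`` is
    the latent-factor loading of co-regulated targets, on the log2 scale,
    against Gaussian noise of sd ``expression_noise_sd``.
    """

    n_tfs: int = 30
    n_genes: int = 300
    n_samples_per_condition: int = 20
    planted_groups: tuple = ((4, 40), (3, 30))
    prior_false_positive_rate: float = 0.01
    prior_false_negative_rate: float = 0.05
    ppi_within_group_weight: float = 1.0
    ppi_background_rate: float = 0.05
    ppi_background_weight: float = 0.2
    expression_noise_sd: float = 0.5
    signal_strength: float = 1.0
    baseline_count: float = 100.0
    seed: int = 0
    rng_algorithm: str = field(default="numpy.random.PCG64", init=False)

    def __post_init__(self) -> None:
        groups = [tuple(g) for g in self.planted_groups]
        self.planted_groups = tuple(groups)
        if any(t < 2 for t, _ in groups):
            raise ValidationError("each planted group needs >= 2 TFs")
        if sum(t for t, _ in groups) > self.n_tfs:
            raise ValidationError("planted TF allocation exceeds n_tfs")
        if sum(g for _, g in groups) > self.n_genes:
            raise ValidationError("planted target allocation exceeds n_genes")
        for r in (self.prior_false_positive_rate, self.prior_false_negative_rate):
            if not (0 <= r <= 1):
                raise ValidationError(f"rate {r} outside [0, 1]")
        if self.expression_noise_sd < 0:
            raise ValidationError("expression_noise_sd must be >= 0")
        if self.n_samples_per_condition < 3:
            raise ValidationError("need >= 3 samples per condition")


@dataclass
class ScenarioTruth:
    """Planted structure emitted next to the data."""

    group_members: list[set]
    group_targets: list[set]
    condition_with_signal: list[str]
    true_edges: set

    def to_json(self) -> str:
        return json.dumps(
            {
                "group_members": [sorted(m) for m in self.group_members],
                "group_targets": [sorted(t) for t in self.group_targets],
                "condition_with_signal": list(self.condition_with_signal),
                "true_edges": sorted(list(e) for e in self.true_edges),
            },
            indent=1,
        )


def _expression_for_condition(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    condition: str,
    with_signal: bool,
    tf_ids: list[str],
    gene_ids: list[str],
    member_idx: list[np.ndarray],
    target_idx: list[np.ndarray],
) -> ExpressionMatrix:
    n_rows = cfg.n_tfs + cfg.n_genes
    n_s = cfg.n_samples_per_condition
    latent = rng.normal(0.0, cfg.expression_noise_sd, size=(n_rows, n_s))
    if with_signal:
        for tf_rows, gene_rows in zip(member_idx, target_idx):
            factor = rng.standard_normal(n_s)
            latent[tf_rows, :] += cfg.signal_strength * factor
            latent[cfg.n_tfs + gene_rows, :] += cfg.signal_strength * factor
    counts = cfg.baseline_count * np.exp2(latent)
    samples = [f"{condition}{j + 1:02d}" for j in range(n_s)]
    return ExpressionMatrix(
        tf_ids + gene_ids,
        samples,
        counts,
        {s: condition for s in samples},
        "normalized",
    )


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[MotifPrior, PPINetwork, ExpressionMatrix, ExpressionMatrix, ScenarioTruth]:
    """Generate (motif prior, PPI, expression A, expression B, truth).

    Condition "A" carries the planted co-regulation signal for every
    group; condition "B" holds independent noise for the same genes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]

    member_idx: list[np.ndarray] = []
    target_idx: list[np.ndarray] = []
    t_off = g_off = 0
    for tf_count, target_count in cfg.planted_groups:
        member_idx.append(np.arange(t_off, t_off + tf_count))
        target_idx.append(np.arange(g_off, g_off + target_count))
        t_off += tf_count
        g_off += target_count

    # motif prior: truth minus false negatives plus uniform false positives
    truth_mask = np.zeros((cfg.n_tfs, cfg.n_genes), dtype=bool)
    for tf_rows, gene_rows in zip(member_idx, target_idx):
        truth_mask[np.ix_(tf_rows, gene_rows)] = True
    W0 = truth_mask.astype(float)
    W0[truth_mask & (rng.random(W0.shape) < cfg.prior_false_negative_rate)] = 0.0
    fp = (~truth_mask) & (rng.random(W0.shape) < cfg.prior_false_positive_rate)
    W0[fp] = 1.0
    for i in range(cfg.n_tfs):  # every TF must retain some motif support
        if not W0[i].any():
            W0[i, rng.integers(cfg.n_genes)] = 1.0

    # PPI: within-group weight over a sparse uniform background
    P0 = np.zeros((cfg.n_tfs, cfg.n_tfs))
    bg = rng.random((cfg.n_tfs, cfg.n_tfs)) < cfg.ppi_background_rate
    bg = np.triu(bg, k=1)
    P0[bg | bg.T] = cfg.ppi_background_weight
    for tf_rows in member_idx:
        P0[np.ix_(tf_rows, tf_rows)] = cfg.ppi_within_group_weight
    np.fill_diagonal(P0, 1.0)

    expr_a = _expression_for_condition(
        cfg, rng, "A", True, tf_ids, gene_ids, member_idx, target_idx
    )
    expr_b = _expression_for_condition(
        cfg, rng, "B", False, tf_ids, gene_ids, member_idx, target_idx
    )

    truth = ScenarioTruth(
        group_members=[{tf_ids[i] for i in rows} for rows in member_idx],
        group_targets=[{gene_ids[i] for i in rows} for rows in target_idx],
        condition_with_signal=["A"] * len(member_idx),
        true_edges={
            (tf_ids[i], gene_ids[j], "A")
            for rows, cols in zip(member_idx, target_idx)
            for i in rows
            for j in cols
        },
    )
    prior = MotifPrior(tf_ids, gene_ids, W0)
    ppi = PPINetwork(tf_ids, P0)
    return prior, ppi, expr_a, expr_b, truth


def generate_signature_dataset(
    config: ScenarioConfig,
    signature_sizes: Mapping[str, int],
    overexpression_fold: float = 4.0,
    fraction_high: float = 0.5,
) -> tuple[ExpressionMatrix, GeneSetCollection, dict]:
    """Plant per-sample signature overexpression in a minority "high" group.

    The "high" group holds ``n_samples_per_condition`` samples against a
    "low" group twice that size, so planting cannot move a gene's
    across-sample median: with at most a third of samples elevated, the
    median stays on the baseline and every planted value
    ``overexpression_fold x median`` clears the 2x-median detection rule
    whenever ``overexpression_fold > 2.5`` (baseline noise is +-10%).

    Each high sample overexpresses the same ceil(fraction_high x |set|)
    leading genes of each signature.  Returns the expression matrix (linear
    normalized scale), the signatures, and a truth map
    ``{signature: {sample: expected_fraction}}``.
    """
    if overexpression_fold <= 1:
        raise ValidationError("overexpression_fold must exceed 1")
    if not (0 <= fraction_high <= 1):
        raise ValidationError("fraction_high must be in [0, 1]")
    if sum(signature_sizes.values()) > config.n_genes:
        raise ValidationError("signature sizes exceed n_genes")

    rng = np.random.default_rng(config.seed)
    n_high = config.n_samples_per_condition
    n_low = 2 * config.n_samples_per_condition
    samples = [f"high{j + 1:02d}" for j in range(n_high)] + [
        f"low{j + 1:02d}" for j in range(n_low)
    ]
    condition_of = {s: ("high" if s.startswith("high") else "low") for s in samples}
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    baseline = rng.lognormal(mean=5.0, sigma=1.0, size=config.n_genes)
    noise = rng.uniform(0.9, 1.1, size=(config.n_genes, len(samples)))
    values = baseline[:, None] * noise

    sets: dict[str, list[str]] = {}
    offset = 0
    for name, size in signature_sizes.items():
        sets[name] = gene_ids[offset : offset + size]
        offset += size

    truth: dict[str, dict[str, float]] = {}
    for name, genes in sets.items():
        k = math.ceil(fraction_high * len(genes))
        planted = genes[:k]
        for g in planted:
            gi = gene_ids.index(g)
            med = float(np.median(values[gi, :]))
            values[gi, :n_high] = overexpression_fold * med
        frac = k / len(genes)
        truth[name] = {
            s: (frac if condition_of[s] == "high" else 0.0) for s in samples
        }

    expr = ExpressionMatrix(gene_ids, samples, values, condition_of, "normalized")
    return expr, GeneSetCollection(sets), truth
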