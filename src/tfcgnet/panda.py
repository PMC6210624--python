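"""Message-passing inference of condition-specific TF->gene networks.

The inference reconciles three evidence sources — a TF binding-site motif
prior W0, a TF-TF protein interaction network P0, and a per-condition
gene-gene coexpression matrix C0 — by iteratively passing "responsibility"
and "availability" messages between them (the PANDA scheme).  Each matrix
is first brought to a common z-score scale; then, per iteration,

    R_ij = T(P row i, W col j)        (does TF i's interaction profile
                                       agree with gene j's regulators?)
    A_ij = T(W row i, C col j)        (does TF i's target profile agree
                                       with gene j's coexpression?)
    W <- (1 - alpha) W + alpha (R + A) / 2

with T the continuous Tanimoto similarity, after which P and C are relaxed
toward the cooperativity (TF-TF over target profiles) and co-regulation
(gene-gene over regulator profiles) implied by the updated W.  The loop
stops when the mean absolute change of W (the "hamming distance" in the
PANDA sense) falls below tolerance.  The final W entries are edge z-scores:
the support that a TF targets a gene in that condition.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, MotifPrior, PPINetwork, ValidationError

__all__ = [
    "PandaConfig",
    "RegulatoryNetwork",
    "filter_tfs",
    "normalize_expression",
    "compute_coexpression",
    "zscore_normalize_matrix",
    "tanimoto",
    "panda_infer",
]

log = logging.getLogger(__name__)


@dataclass
class PandaConfig:
    """Tuning knobs for the message-passing loop.

    alpha is the update (mixing) rate, hamming_tolerance the convergence
    threshold on the mean absolute edge-weight change, and
    tf_expression_min the normalized-count floor below which a TF is
    considered unexpressed and dropped before inference.
    """

    alpha: float = 0.2
    hamming_tolerance: float = 1e-5
    max_iterations: int = 200
    tf_expression_min: float = 1.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.hamming_tolerance <= 0:
            raise ValidationError("hamming_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class RegulatoryNetwork:
    """Final TF x gene edge z-scores with convergence metadata."""

    tf_ids: list[str]
    gene_ids: list[str]
    z: np.ndarray
    iterations_run: int
    final_hamming: float
    config: PandaConfig = field(default_factory=PandaConfig)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("network z-scores must be finite")

    @property
    def converged(self) -> bool:
        return self.final_hamming < self.config.hamming_tolerance


def filter_tfs(
    prior: MotifPrior,
    ppi: PPINetwork,
    expr: ExpressionMatrix,
    config: PandaConfig | None = None,
) -> tuple[MotifPrior, PPINetwork]:
    """Drop TFs absent from the PPI or not expressed above the count floor.

    ``expr`` must hold normalized (pre-log) counts; a TF is retained when it
    appears in the PPI id list, is measured in the expression matrix, and
    its mean normalized count across all samples exceeds
    ``config.tf_expression_min``.
    """
    config = config or PandaConfig()
    if expr.transform_state != "normalized":
        raise ValidationError(
            "TF filtering needs normalized (pre-log) counts, got state "
            f"{expr.transform_state!r}"
        )
    gidx = expr.gene_index()
    ppi_ids = set(ppi.tf_ids)
    kept = []
    for tf in prior.tf_ids:
        if tf not in ppi_ids or tf not in gidx:
            continue
        if expr.values[gidx[tf], :].mean() > config.tf_expression_min:
            kept.append(tf)
    if not kept:
        raise ValidationError("empty TF set after expression/PPI filtering")
    return prior.subset_tfs(kept), ppi.subset_tfs(kept)


def normalize_expression(
    expr: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count + pseudocount), then center each gene by its median
    across all samples."""
    if expr.transform_state != "normalized":
        raise ValidationError(
            f"expected transform_state 'normalized', got {expr.transform_state!r}"
        )
    if np.any(expr.values < 0):
        raise ValidationError("normalized counts must be non-negative")
    logged = np.log2(expr.values + pseudocount)
    centered = logged - np.median(logged, axis=1, keepdims=True)
    return ExpressionMatrix(
        list(expr.gene_ids),
        list(expr.sample_ids),
        centered,
        dict(expr.condition_of),
        "log2_median_centered",
    )


def compute_coexpression(expr: ExpressionMatrix, condition: str) -> np.ndarray:
    """Pearson gene-gene correlation over one condition's samples.

    Zero-variance genes get correlation 0 off-diagonal and 1 on the
    diagonal so degenerate rows cannot propagate NaN into the message
    passing.
    """
    if expr.transform_state != "log2_median_centered":
        raise ValidationError(
            "coexpression needs log2 median-centered values, got state "
            f"{expr.transform_state!r}"
        )
    samples = expr.samples_in(condition)
    if len(samples) < 3:
        raise ValidationError(
            f"condition {condition!r} has {len(samples)} samples; need >= 3"
        )
    sidx = {s: j for j, s in enumerate(expr.sample_ids)}
    X = expr.values[:, [sidx[s] for s in samples]]
    sd = X.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(X)
    if C.ndim == 0:  # single gene
        C = np.array([[1.0]])
    C[~np.isfinite(C)] = 0.0
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def zscore_normalize_matrix(M: np.ndarray) -> np.ndarray:
    """Average of row-wise and column-wise z-scores, scaled by 1/sqrt(2).

    Population standard deviations; any direction with zero spread
    contributes 0, so constant matrices map to all zeros and vectors fall
    back to their single informative direction.
    """
    M = np.asarray(M, dtype=float)
    rm, rs = M.mean(axis=1, keepdims=True), M.std(axis=1, keepdims=True)
    cm, cs = M.mean(axis=0, keepdims=True), M.std(axis=0, keepdims=True)
    rz = np.divide(M - rm, rs, out=np.zeros_like(M), where=rs > 0)
    cz = np.divide(M - cm, cs, out=np.zeros_like(M), where=cs > 0)
    return (rz + cz) / np.sqrt(2.0)


def tanimoto(x: np.ndarray, y: np.ndarray) -> float:
    """Continuous Tanimoto similarity x.y / sqrt(|x|^2 + |y|^2 - |x.y|).

    Defined as 0 when both vectors are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("tanimoto requires equal-length vectors")
    dot = float(x @ y)
    den = float(x @ x) + float(y @ y) - abs(dot)
    if den <= 0:
        return 0.0
    return dot / np.sqrt(den)


def _tanimoto_rows_cols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Matrix of T(X row i, Y column j); the workhorse of every message."""
    num = X @ Y
    xn = np.einsum("ij,ij->i", X, X)
    yn = np.einsum("ij,ij->j", Y, Y)
    den = xn[:, None] + yn[None, :] - np.abs(num)
    out = np.zeros_like(num)
    np.divide(num, np.sqrt(den, where=den > 0, out=np.ones_like(den)),
              out=out, where=den > 0)
    return out


def _update_diagonal(M: np.ndarray, alpha: float, step: int) -> np.ndarray:
    """Refill the diagonal of a cooperativity/co-regulation message.

    The continuous Tanimoto grows with vector norms (|T| <= sqrt(|x||y|)),
    so leaving raw self-similarities on the diagonal lets the iteration's
    amplitude grow without bound.  Following the reference message-passing
    scheme, the diagonal is replaced by each row's off-diagonal standard
    deviation scaled by n * exp(2 * alpha * step): the geometrically
    growing self-weight progressively turns the messages into identity
    maps, which is what drives the hamming distance to zero.
    """
    M = M.copy()
    n = M.shape[0]
    if n == 1:
        return M
    off = M.copy()
    np.fill_diagonal(off, np.nan)
    row_sd = np.nanstd(off, axis=1)
    np.fill_diagonal(M, row_sd * n * np.exp(2.0 * alpha * step))
    return M


def panda_infer(
    prior: MotifPrior,
    ppi: PPINetwork,
    expr: ExpressionMatrix,
    condition: str,
    config: PandaConfig | None = None,
) -> RegulatoryNetwork:
    """Run the message-passing loop for one condition.

    ``prior`` and ``ppi`` must share the same TF list (apply
    :func:`filter_tfs` first) and every prior gene must be measured in
    ``expr``, which must already be log2 median-centered.
    """
    config = config or PandaConfig()
    if prior.tf_ids != ppi.tf_ids:
        raise ValidationError("prior and PPI must be over the same TF list")
    expr_genes = expr.subset_genes(prior.gene_ids)
    C0 = compute_coexpression(expr_genes, condition)

    W = zscore_normalize_matrix(prior.weights)
    P = zscore_normalize_matrix(ppi.weights)
    C = zscore_normalize_matrix(C0)
    a = config.alpha

    hamming = np.inf
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        R = _tanimoto_rows_cols(P, W)
        A = _tanimoto_rows_cols(W, C)
        W_new = (1 - a) * W + a * (R + A) / 2.0
        coop = _update_diagonal(
            _tanimoto_rows_cols(W_new, W_new.T), a, iterations - 1
        )
        coreg = _update_diagonal(
            _tanimoto_rows_cols(W_new.T, W_new), a, iterations - 1
        )
        P = (1 - a) * P + a * coop
        C = (1 - a) * C + a * coreg
        hamming = float(np.abs(W_new - W).mean())
        W = W_new
        if hamming < config.hamming_tolerance:
            break

    net = RegulatoryNetwork(
        list(prior.tf_ids), list(prior.gene_ids), W, iterations, hamming, config
    )
    if not net.converged:
        log.warning(
            "message passing did not converge in %d iterations "
            "(final hamming %.3g >= %.3g)",
            iterations, hamming, config.hamming_tolerance,
        )
    return net
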