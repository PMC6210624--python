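"""Readers and writers for the pipeline's external representations.

Expression matrices travel as TSV with genes in rows and a header of sample
ids; motif priors and protein--protein interaction (PPI) networks as
3-column ``source<TAB>target<TAB>weight`` edge lists; gene signatures as
GMT; result tables as deterministic, lexicographically sorted TSV.  Edge
lists are the on-disk network format because they are sparse, diff-friendly
and match the conventions of common regulatory-network tooling.

All readers preserve file order of identifiers and validate on
construction; absent (source, target) pairs in edge lists are implicit
zeros.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MotifPrior",
    "PPINetwork",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_condition_map",
    "read_edge_list",
    "write_edge_list",
    "read_gene_sets",
    "write_gene_sets",
    "write_network_zscores",
    "read_network_zscores",
    "write_result_tables",
    "concat_expression",
]

TRANSFORM_STATES = ("raw_counts", "normalized", "log2_median_centered")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample condition labels.

    ``transform_state`` tracks where the matrix sits in the normalization
    state machine: ``raw_counts`` -> ``normalized`` (library-size corrected,
    linear scale) -> ``log2_median_centered``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, str] = field(default_factory=dict)
    transform_state: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(
                f"unknown transform_state {self.transform_state!r}"
            )
        for s in self.condition_of:
            if s not in set(self.sample_ids):
                raise ValidationError(f"condition map names unknown sample {s!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.condition_of.get(s)
            if c is not None and c not in seen:
                seen.append(c)
        return seen

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of.get(s) == condition]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from expression matrix: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes),
            list(self.sample_ids),
            self.values[rows, :],
            dict(self.condition_of),
            self.transform_state,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        sidx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [sidx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids),
            list(samples),
            self.values[:, cols],
            {s: self.condition_of[s] for s in samples if s in self.condition_of},
            self.transform_state,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class MotifPrior:
    """TF x gene prior regulatory evidence (TF binding-site scan weights)."""

    tf_ids: list[str]
    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _check_unique(self.tf_ids, "TF")
        _check_unique(self.gene_ids, "gene")
        if self.weights.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValidationError("motif prior shape does not match id lists")
        if np.any(self.weights < 0):
            raise ValidationError("motif prior weights must be non-negative")
        empty = [t for t, row in zip(self.tf_ids, self.weights) if not row.any()]
        if empty:
            raise ValidationError(f"TFs with no motif support: {empty}")

    def subset_tfs(self, tfs: Sequence[str]) -> "MotifPrior":
        idx = {t: i for i, t in enumerate(self.tf_ids)}
        rows = [idx[t] for t in tfs]
        return MotifPrior(list(tfs), list(self.gene_ids), self.weights[rows, :])


@dataclass
class PPINetwork:
    """Symmetric TF-TF protein interaction weights with unit diagonal."""

    tf_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _check_unique(self.tf_ids, "TF")
        n = len(self.tf_ids)
        if self.weights.shape != (n, n):
            raise ValidationError("PPI matrix must be square over tf_ids")
        if np.any(self.weights < 0):
            raise ValidationError("PPI weights must be non-negative")
        if not np.allclose(self.weights, self.weights.T):
            raise ValidationError("PPI matrix must be symmetric")
        if not np.allclose(np.diag(self.weights), 1.0):
            raise ValidationError("PPI diagonal must be 1")

    def subset_tfs(self, tfs: Sequence[str]) -> "PPINetwork":
        idx = {t: i for i, t in enumerate(self.tf_ids)}
        rows = np.array([idx[t] for t in tfs])
        return PPINetwork(list(tfs), self.weights[np.ix_(rows, rows)])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. PCS1/2/3 subtype signatures), order-preserving."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression


def read_condition_map(source) -> dict[str, str]:
    """Read a sample -> condition map from a 2-column TSV, or pass a dict through."""
    if isinstance(source, Mapping):
        return dict(source)
    cmap: dict[str, str] = {}
    for lineno, line in enumerate(Path(source).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{source}: line {lineno}: expected 'sample<TAB>condition'"
            )
        sample, cond = parts
        if sample in cmap:
            raise ValidationError(f"{source}: duplicate sample {sample!r}")
        cmap[sample] = cond
    return cmap


def read_expression(
    path,
    condition_map=None,
    transform_state: str = "normalized",
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix.

    The first column holds gene ids, the header row sample ids.
    ``condition_map`` may be a dict or the path of a 2-column TSV.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    _check_unique(genes, "gene")
    _check_unique(samples, "sample")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric value {raw[i, j]!r} at gene "
                    f"{genes[i]!r}, sample {samples[j]!r}"
                ) from None
    cmap = read_condition_map(condition_map) if condition_map is not None else {}
    return ExpressionMatrix(genes, samples, values, cmap, transform_state)


def write_expression(expr: ExpressionMatrix, path, condition_path=None) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")
    if condition_path is not None:
        lines = [
            f"{s}\t{expr.condition_of[s]}"
            for s in expr.sample_ids
            if s in expr.condition_of
        ]
        Path(condition_path).write_text("\n".join(lines) + "\n")


def concat_expression(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two matrices over identical gene lists."""
    if a.gene_ids != b.gene_ids:
        raise ValidationError("cannot concatenate: gene id lists differ")
    if a.transform_state != b.transform_state:
        raise ValidationError("cannot concatenate: transform states differ")
    cond = dict(a.condition_of)
    cond.update(b.condition_of)
    return ExpressionMatrix(
        list(a.gene_ids),
        list(a.sample_ids) + list(b.sample_ids),
        np.hstack([a.values, b.values]),
        cond,
        a.transform_state,
    )


# ---------------------------------------------------------------------------
# edge lists


def _parse_edges(path) -> list[tuple[str, str, float]]:
    rows: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValidationError(
                f"{path}: line {lineno}: expected 'source<TAB>target<TAB>weight'"
            )
        try:
            w = float(parts[2])
        except ValueError:
            raise ValidationError(
                f"{path}: line {lineno}: non-numeric weight {parts[2]!r}"
            ) from None
        if w < 0:
            raise ValidationError(f"{path}: line {lineno}: negative weight {w}")
        rows.append((parts[0], parts[1], w))
    return rows


def read_edge_list(path, kind: str):
    """Read a 3-column edge list as a :class:`MotifPrior` or :class:`PPINetwork`.

    Ids are taken in order of first appearance; absent pairs are weight 0.
    For ``kind='ppi'`` the matrix is symmetrized with max(w_ij, w_ji) and the
    diagonal forced to 1 (a self-edge with weight != 1 triggers a warning).
    """
    if kind not in ("motif", "ppi"):
        raise ValueError(f"kind must be 'motif' or 'ppi', got {kind!r}")
    rows = _parse_edges(path)
    if not rows:
        raise ValidationError(f"{path}: empty edge list")
    if kind == "motif":
        tfs: list[str] = []
        genes: list[str] = []
        tf_seen: dict[str, int] = {}
        gene_seen: dict[str, int] = {}
        for s, t, _ in rows:
            if s not in tf_seen:
                tf_seen[s] = len(tfs)
                tfs.append(s)
            if t not in gene_seen:
                gene_seen[t] = len(genes)
                genes.append(t)
        W = np.zeros((len(tfs), len(genes)))
        for s, t, w in rows:
            W[tf_seen[s], gene_seen[t]] = w
        return MotifPrior(tfs, genes, W)
    ids: list[str] = []
    seen: dict[str, int] = {}
    for s, t, _ in rows:
        for x in (s, t):
            if x not in seen:
                seen[x] = len(ids)
                ids.append(x)
    P = np.zeros((len(ids), len(ids)))
    for s, t, w in rows:
        i, j = seen[s], seen[t]
        if i == j:
            if w != 1.0:
                warnings.warn(
                    f"{path}: self-interaction weight {w} for {s!r} overridden to 1"
                )
            continue
        P[i, j] = max(P[i, j], w)
    P = np.maximum(P, P.T)
    np.fill_diagonal(P, 1.0)
    return PPINetwork(ids, P)


def write_edge_list(obj, path) -> None:
    """Write nonzero entries of a prior or PPI network, lexicographically sorted."""
    lines: list[str] = []
    if isinstance(obj, MotifPrior):
        pairs = [
            (t, g, obj.weights[i, j])
            for i, t in enumerate(obj.tf_ids)
            for j, g in enumerate(obj.gene_ids)
            if obj.weights[i, j] != 0
        ]
    elif isinstance(obj, PPINetwork):
        pairs = [
            (a, b, obj.weights[i, j])
            for i, a in enumerate(obj.tf_ids)
            for j, b in enumerate(obj.tf_ids)
            if i <= j and obj.weights[i, j] != 0
        ]
    else:
        raise TypeError(f"cannot write edge list for {type(obj).__name__}")
    for s, t, w in sorted(pairs):
        lines.append(f"{s}\t{t}\t{float(w)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}: line {lineno}: gene set with no genes"
            )
        name = parts[0]
        if name in sets:
            raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
        if not sets[name]:
            raise ValidationError(f"{path}: line {lineno}: gene set with no genes")
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, "na"] + list(genes))
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# inferred networks


def write_network_zscores(tf_ids, gene_ids, z, path) -> None:
    """Write a dense TF->gene z-score matrix as a sorted 3-column edge list."""
    z = np.asarray(z, dtype=float)
    order = sorted(
        (t, g, z[i, j])
        for i, t in enumerate(tf_ids)
        for j, g in enumerate(gene_ids)
    )
    Path(path).write_text(
        "\n".join(f"{t}\t{g}\t{float(w)!r}" for t, g, w in order) + "\n"
    )


def read_network_zscores(path) -> tuple[list[str], list[str], np.ndarray]:
    rows = _parse_edges_signed(path)
    tfs = sorted({s for s, _, _ in rows})
    genes = sorted({t for _, t, _ in rows})
    ti = {t: i for i, t in enumerate(tfs)}
    gi = {g: j for j, g in enumerate(genes)}
    z = np.zeros((len(tfs), len(genes)))
    for s, t, w in rows:
        z[ti[s], gi[t]] = w
    return tfs, genes, z


def _parse_edges_signed(path) -> list[tuple[str, str, float]]:
    rows: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValidationError(
                f"{path}: line {lineno}: expected 'source<TAB>target<TAB>weight'"
            )
        rows.append((parts[0], parts[1], float(parts[2])))
    return rows


# ---------------------------------------------------------------------------
# result tables


def write_result_tables(edges, key_tfs, tfcgs, otfcgs, outdir) -> dict[str, Path]:
    """Write the four result tables with deterministic lexicographic row order.

    ``edges`` is a DifferentialEdgeSet, ``key_tfs`` a KeyTfTable, ``tfcgs`` a
    list of TFCG, ``otfcgs`` a list of OTfcgPair (duck-typed to avoid import
    cycles).  Returns the paths written, keyed by table name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edge_rows = sorted(
        (
            t,
            g,
            edges.z_a[i, j],
            edges.z_b[i, j],
            edges.probability[i, j],
            int(edges.unique_mask[i, j]),
        )
        for i, t in enumerate(edges.tf_ids)
        for j, g in enumerate(edges.gene_ids)
    )
    paths["edges"] = outdir / "edges.tsv"
    with open(paths["edges"], "w") as fh:
        fh.write("tf\tgene\tz_a\tz_b\tprobability\tunique\n")
        for t, g, za, zb, p, u in edge_rows:
            fh.write(f"{t}\t{g}\t{float(za)!r}\t{float(zb)!r}\t{float(p)!r}\t{u}\n")

    paths["key_tfs"] = outdir / "key_tfs.tsv"
    tab = key_tfs.table.sort_values("tf")
    with open(paths["key_tfs"], "w") as fh:
        fh.write("tf\tunique_target_count\tp_value\tsignificant\n")
        for _, r in tab.iterrows():
            fh.write(
                f"{r['tf']}\t{int(r['unique_target_count'])}\t"
                f"{float(r['p_value'])!r}\t{int(r['is_key'])}\n"
            )

    paths["tfcgs"] = outdir / "tfcgs.tsv"
    with open(paths["tfcgs"], "w") as fh:
        fh.write("group_id\tmembers\tcore_targets\n")
        for grp in tfcgs:
            fh.write(
                f"{grp.group_id}\t{';'.join(sorted(grp.members))}\t"
                f"{';'.join(sorted(grp.core_targets))}\n"
            )

    paths["otfcgs"] = outdir / "otfcgs.tsv"
    with open(paths["otfcgs"], "w") as fh:
        fh.write("group_a\tgroup_b\tshared_tfs\n")
        for pair in otfcgs:
            fh.write(
                f"{pair.group_a_id}\t{pair.group_b_id}\t"
                f"{';'.join(sorted(pair.shared_tfs))}\n"
            )
    return paths
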