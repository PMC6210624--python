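"""End-to-end orchestration: data -> two networks -> differential edges ->
Key TFs -> TFCGs -> oTFCGs -> subtype fractions -> report.

A run is driven by a single :class:`RunConfig` (YAML-loadable).  Inputs are
either a synthetic scenario (fully seeded) or paths to an expression
matrix, motif prior, PPI edge list and optional GMT signatures.  Every
stage's parameters and counts are echoed into a ``manifest.json`` that is
sufficient to reproduce the run exactly; output tables are written in
deterministic order so repeated runs are byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diffnet import (
    call_unique_edges,
    identify_key_tfs,
    permutation_null,
)
from .groups import compute_overlap_matrix, find_tfcgs, match_otfcgs
from .io import (
    ValidationError,
    concat_expression,
    read_edge_list,
    read_expression,
    read_gene_sets,
    write_edge_list,
    write_expression,
    write_gene_sets,
    write_network_zscores,
    write_result_tables,
)
from .panda import PandaConfig, filter_tfs, normalize_expression, panda_infer
from .scoring import mann_whitney, subtype_fraction
from .simulate import ScenarioConfig, generate_scenario, generate_signature_dataset

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: str = "tfcgnet_run"
    seed: int = 7
    # synthetic mode
    scenario: ScenarioConfig | None = None
    signature_sizes: dict = field(default_factory=lambda: {"PCS1": 40, "PCS2": 40, "PCS3": 40})
    signature_fraction_high: float = 0.5
    signature_fold: float = 4.0
    # file mode
    expression: str | None = None
    condition_map: str | None = None
    motif: str | None = None
    ppi: str | None = None
    signatures: str | None = None
    condition_a: str = "A"
    condition_b: str = "B"
    # analysis parameters
    panda: PandaConfig = field(default_factory=PandaConfig)
    probability_threshold: float = 0.90
    probability_formula: str = "anchored_difference"
    overlap_threshold: float = 70.0
    min_shared_tfs: int = 2
    bonferroni_alpha: float = 0.05
    subtype_fold: float = 2.0
    n_permutations: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.probability_threshold <= 1):
            raise ValidationError("probability_threshold must be in [0, 1]")
        if not (0 <= self.overlap_threshold <= 100):
            raise ValidationError("overlap_threshold must be in [0, 100]")
        if self.min_shared_tfs < 1:
            raise ValidationError("min_shared_tfs must be >= 1")
        if isinstance(self.panda, dict):
            self.panda = PandaConfig(**self.panda)
        if isinstance(self.scenario, dict):
            self.scenario = ScenarioConfig(**self.scenario)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _stage(name: str):
    log.info("stage: %s", name)
    return name


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tfcgnet",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "panda": asdict(config.panda),
            "probability_threshold": config.probability_threshold,
            "probability_formula": config.probability_formula,
            "overlap_threshold": config.overlap_threshold,
            "min_shared_tfs": config.min_shared_tfs,
            "bonferroni_alpha": config.bonferroni_alpha,
            "subtype_fold": config.subtype_fold,
            "n_permutations": config.n_permutations,
        },
        "stages": {},
        "outputs": {},
    }
    stage = manifest["stages"]

    try:
        # ------------------------------------------------------------ inputs
        name = _stage("inputs")
        truth = None
        if config.scenario is not None:
            scen = config.scenario
            if scen.seed != config.seed:
                scen = ScenarioConfig(**{**asdict_scenario(scen), "seed": config.seed})
            prior, ppi, expr_a, expr_b, truth = generate_scenario(scen)
            expr_all = concat_expression(expr_a, expr_b)
            cond_a, cond_b = "A", "B"
            manifest["parameters"]["scenario"] = asdict_scenario(scen)
            write_edge_list(prior, outdir / "motif_prior.tsv")
            write_edge_list(ppi, outdir / "ppi.tsv")
            write_expression(expr_all, outdir / "expression.tsv",
                             outdir / "conditions.tsv")
            (outdir / "truth.json").write_text(truth.to_json())
        else:
            if not (config.expression and config.motif and config.ppi):
                raise ValidationError(
                    "file mode needs expression, motif and ppi paths"
                )
            expr_all = read_expression(config.expression, config.condition_map)
            prior = read_edge_list(config.motif, "motif")
            ppi = read_edge_list(config.ppi, "ppi")
            cond_a, cond_b = config.condition_a, config.condition_b
        stage[name] = {
            "n_tfs": len(prior.tf_ids),
            "n_genes": len(prior.gene_ids),
            "n_samples": expr_all.n_samples,
            "conditions": [cond_a, cond_b],
        }

        # ------------------------------------------------- filter + normalize
        name = _stage("filter_and_normalize")
        prior_f, ppi_f = filter_tfs(prior, ppi, expr_all, config.panda)
        logged = normalize_expression(expr_all, config.panda.pseudocount)
        stage[name] = {"tfs_kept": len(prior_f.tf_ids),
                       "tfs_dropped": len(prior.tf_ids) - len(prior_f.tf_ids)}

        # ------------------------------------------------------ two networks
        name = _stage("network_inference")
        net_a = panda_infer(prior_f, ppi_f, logged, cond_a, config.panda)
        net_b = panda_infer(prior_f, ppi_f, logged, cond_b, config.panda)
        write_network_zscores(net_a.tf_ids, net_a.gene_ids, net_a.z,
                              outdir / "network_a.tsv")
        write_network_zscores(net_b.tf_ids, net_b.gene_ids, net_b.z,
                              outdir / "network_b.tsv")
        stage[name] = {
            "a": {"iterations": net_a.iterations_run,
                  "final_hamming": net_a.final_hamming,
                  "converged": net_a.converged},
            "b": {"iterations": net_b.iterations_run,
                  "final_hamming": net_b.final_hamming,
                  "converged": net_b.converged},
        }

        # ------------------------------------------------- differential edges
        name = _stage("differential_edges")
        edges_ab = call_unique_edges(net_a, net_b, config.probability_threshold,
                                     config.probability_formula)
        edges_ba = call_unique_edges(net_b, net_a, config.probability_threshold,
                                     config.probability_formula)
        stage[name] = {"unique_edges_a": edges_ab.n_unique,
                       "unique_edges_b": edges_ba.n_unique}

        # -------------------------------------------------------------- key TFs
        name = _stage("key_tfs")
        key_a = identify_key_tfs(edges_ab, config.bonferroni_alpha)
        key_b = identify_key_tfs(edges_ba, config.bonferroni_alpha)
        stage[name] = {
            "tested_tf_count": key_a.tested_tf_count,
            "critical_p": key_a.critical_p,
            "key_tfs_a": len(key_a.key_tfs()),
            "key_tfs_b": len(key_b.key_tfs()),
        }

        # ------------------------------------------------------------- TFCGs
        name = _stage("tfcgs")
        groups_a: list = []
        groups_b: list = []
        if key_a.key_tfs():
            sets_a = {t: s for t, s in
                      edges_ab.unique_target_sets(key_a.key_tfs()).items() if s}
            if sets_a:
                groups_a = find_tfcgs(compute_overlap_matrix(sets_a),
                                      config.overlap_threshold)
        if key_b.key_tfs():
            sets_b = {t: s for t, s in
                      edges_ba.unique_target_sets(key_b.key_tfs()).items() if s}
            if sets_b:
                groups_b = find_tfcgs(compute_overlap_matrix(sets_b),
                                      config.overlap_threshold)
        stage[name] = {"tfcgs_a": len(groups_a), "tfcgs_b": len(groups_b)}

        # ------------------------------------------------------------ oTFCGs
        name = _stage("otfcgs")
        match = match_otfcgs(groups_a, groups_b, config.min_shared_tfs)
        stage[name] = {"pairs": len(match.pairs),
                       "matched_fraction_b": match.matched_fraction_b}

        # ---------------------------------------------------- subtype scoring
        name = _stage("subtype_fractions")
        frac_info = None
        if config.scenario is not None:
            sig_cfg = ScenarioConfig(
                **{**asdict_scenario(config.scenario), "seed": config.seed}
            )
            sizes = dict(config.signature_sizes)
            if sum(sizes.values()) > sig_cfg.n_genes:
                # shrink proportionally so signatures fit small scenarios
                per = max(2, sig_cfg.n_genes // (2 * len(sizes)))
                sizes = {name: per for name in sizes}
            sig_expr, sig_sets, sig_truth = generate_signature_dataset(
                sig_cfg, sizes,
                config.signature_fold, config.signature_fraction_high,
            )
            write_expression(sig_expr, outdir / "signature_expression.tsv")
            write_gene_sets(sig_sets, outdir / "signatures.gmt")
            fractions = subtype_fraction(sig_expr, sig_sets, config.subtype_fold)
            frac_info = _score_fractions(fractions, sig_expr.condition_of)
            fractions.to_csv(outdir / "subtype_fractions.tsv", sep="\t",
                             index_label="sample")
        elif config.signatures is not None:
            sig_sets = read_gene_sets(config.signatures)
            fractions = subtype_fraction(expr_all, sig_sets, config.subtype_fold)
            frac_info = _score_fractions(fractions, expr_all.condition_of)
            fractions.to_csv(outdir / "subtype_fractions.tsv", sep="\t",
                             index_label="sample")
        stage[name] = frac_info or {"skipped": True}

        # -------------------------------------------------------- permutations
        name = _stage("permutation_null")
        if config.n_permutations > 0:
            counts = permutation_null(
                prior, ppi, expr_all, dict(expr_all.condition_of),
                config.panda, config.n_permutations, config.seed,
                config.probability_threshold, config.probability_formula,
            )
            stage[name] = {
                "counts": [int(c) for c in counts],
                "median": float(np.median(counts)),
                "observed": edges_ab.n_unique,
            }
        else:
            stage[name] = {"skipped": True}

        # -------------------------------------------------------------- report
        paths = write_result_tables(edges_ab, key_a, groups_a, match.pairs, outdir)
        manifest["outputs"] = {k: str(v) for k, v in paths.items()}
        manifest["outputs"]["manifest"] = str(outdir / "manifest.json")
    except Exception as exc:  # annotate the failing stage, then re-raise
        manifest["failed_stage"] = name
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest


def _score_fractions(fractions, condition_of) -> dict:
    info: dict = {"mean_fraction": {}}
    groups = sorted(set(condition_of.values()))
    for g in groups:
        samples = [s for s in fractions.index if condition_of.get(s) == g]
        info["mean_fraction"][g] = {
            sig: float(fractions.loc[samples, sig].mean())
            for sig in fractions.columns
        }
    if len(groups) == 2:
        a, b = groups
        sa = [s for s in fractions.index if condition_of.get(s) == a]
        sb = [s for s in fractions.index if condition_of.get(s) == b]
        info["mann_whitney_p"] = {}
        for sig in fractions.columns:
            _, p = mann_whitney(fractions.loc[sa, sig], fractions.loc[sb, sig])
            info["mann_whitney_p"][sig] = float(p)
    return info


def asdict_scenario(scen: ScenarioConfig) -> dict:
    d = asdict(scen)
    d.pop("rng_algorithm", None)
    d["planted_groups"] = [list(g) for g in scen.planted_groups]
    return d
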