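# tfcgnet

Condition-specific transcription-factor (TF) regulatory network inference
and coordinated TF group discovery.

## The problem

Tumors responding to a perturbation — androgen deprivation therapy in
prostate cancer is the motivating setting — rewire their transcriptional
programs, and the interesting biology often lives not in single genes but
in *which TFs gain regulatory targets in one condition and not another*,
and in *groups of TFs that gain the same targets together*.  `tfcgnet`
implements that full analysis for computational biologists:

1. **Network inference** per condition by message passing (the PANDA
   scheme): a TF→gene motif prior `W₀`, a TF–TF protein-interaction
   network `P₀` and a per-condition gene–gene Pearson coexpression matrix
   `C₀` are brought to a common z-score scale and iteratively reconciled,

   * responsibility `R_ij = T(P_i·, W·_j)`
   * availability `A_ij = T(W_i·, C·_j)`
   * `W ← (1−α) W + α (R + A)/2`, with `α = 0.2`,

   where `T(x, y) = x·y / √(‖x‖² + ‖y‖² − |x·y|)` is the continuous
   Tanimoto similarity, until the mean absolute change of `W` (the hamming
   distance) falls below `10⁻⁵`.  The final `W` entries are edge z-scores:
   the support that a TF targets a gene in that condition.
2. **Differential edges**: paired z-scores become the probability that an
   edge is *unique to and strongly supported in* network A,
   `P = Φ(z_A) · Φ((z_A − z_B)/√2)`; edges with `P > 0.90` are the
   high-confidence A-unique interactions.
3. **Key TFs**: TFs enriched for unique targets under the hypergeometric
   distribution, Bonferroni-corrected at family-wise α = 0.05.
4. **TFCGs** (TF coordinated groups): Key TFs whose unique target sets
   *reciprocally* overlap by ≥ 70 % (directed overlap
   `100·|Tᵢ∩Tⱼ|/|Tᵢ|` in both directions), extracted as disjoint maximal
   cliques with a deterministic greedy order.
5. **oTFCGs**: TFCG pairs across two network comparisons sharing ≥ 2 Key
   TFs.
6. **Subtype scoring**: per sample, the fraction of a gene signature
   (e.g. PCS1/2/3 prostate-cancer subtypes) whose genes exceed 2× their
   across-sample median expression, with exact Mann–Whitney group
   comparisons, plus a simplified paired differential-expression stand-in
   and hierarchical stratification into high/low-impact response groups.
7. **Permutation null**: rebuild both networks under shuffled sample
   labels and count surviving unique edges.

A fully seeded synthetic-scenario generator plants coordinated TF groups
with known ground truth (latent-factor co-regulation in one condition
only), so every stage is testable without external data.

## Worked example

```python
from tfcgnet import (ScenarioConfig, generate_scenario, concat_expression,
                     filter_tfs, normalize_expression, panda_infer,
                     call_unique_edges, identify_key_tfs,
                     compute_overlap_matrix, find_tfcgs)

prior, ppi, expr_a, expr_b, truth = generate_scenario(ScenarioConfig(seed=7))
expr_all = concat_expression(expr_a, expr_b)
prior_f, ppi_f = filter_tfs(prior, ppi, expr_all)
logged = normalize_expression(expr_all)
net_a = panda_infer(prior_f, ppi_f, logged, "A")
net_b = panda_infer(prior_f, ppi_f, logged, "B")
edges = call_unique_edges(net_a, net_b, threshold=0.90)
key = identify_key_tfs(edges, alpha=0.05)
sets = {t: s for t, s in edges.unique_target_sets(key.key_tfs()).items() if s}
for g in find_tfcgs(compute_overlap_matrix(sets), threshold=70):
    print(g.group_id, sorted(g.members))
```

prints

```
TFCG01 ['TF001', 'TF002', 'TF003', 'TF004']
TFCG02 ['TF005', 'TF006', 'TF007']
```

— exactly the two planted groups.  Along the way (see
`examples/01`–`03`): both networks converge in 28 iterations with final
hamming ≈ 9.4×10⁻⁶; 303 edges exceed probability 0.90; all 7 planted TFs
(and only those) are Key at critical p = 0.05/30 ≈ 1.7×10⁻³; mean z on
planted edges is 6.85 against −0.19 elsewhere.  The `examples/` scripts
are short narrative walks through each capability; `tfcgnet --help`
exposes the same stages as a CLI (`simulate`, `infer`, `diffnet`, `tfcg`,
`score`, `stratify`, `permute`, `run`).

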