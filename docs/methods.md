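# Methods

## Network inference by message passing

Each condition network starts from three evidence sources over shared id
spaces: a TF×gene motif prior `W₀` (binding-site scan hits, weights ≥ 0),
a symmetric TF×TF protein-interaction matrix `P₀` with unit diagonal, and
the gene×gene Pearson coexpression `C₀` of that condition's samples.
Expression enters as normalized (library-size-corrected, linear-scale)
counts; TFs absent from the PPI or with mean normalized count ≤ 1 across
samples are removed before inference, and values are log2-transformed
with pseudocount 1 and centered by each gene's median across *all*
samples of the dataset (both conditions), so the per-condition
coexpression is computed on a common scale.

All three matrices are mapped to z-scores by averaging row-wise and
column-wise standardization, `Z = (Z_rows + Z_cols)/√2`, with population
standard deviations; a direction with zero spread contributes 0, so
constant matrices map to zeros and vectors fall back to their informative
direction.  The iteration then alternates, with mixing rate `α = 0.2`:

    R_ij = T(P row i, W column j)          # TF-level agreement
    A_ij = T(W row i, C column j)          # coexpression-level agreement
    W   ←  (1−α) W + α (R + A)/2
    P   ←  (1−α) P + α Coop(W)             # TF–TF Tanimoto over rows of W
    C   ←  (1−α) C + α Coreg(W)            # gene–gene Tanimoto over columns

with `T(x,y) = x·y/√(‖x‖²+‖y‖²−|x·y|)` (defined 0 when both vectors are
zero).  Convergence is declared when the hamming distance — the mean
absolute change of `W` between iterations — falls below `10⁻⁵`
(200-iteration backstop, non-convergence flagged on the returned
network).

**Diagonal handling.** The continuous Tanimoto is not bounded by 1: it
grows with vector norms (`|T| ≤ √(‖x‖‖y‖)`), so if the raw
self-similarities are kept on the diagonals of the Coop/Coreg messages —
or replaced by any value of the off-diagonal scale — the amplitude of the
system grows by a constant factor per iteration and the loop diverges.
The diagonals are therefore refilled with each row's off-diagonal
standard deviation scaled by `n·exp(2·α·step)`.  The geometrically
growing self-weight progressively turns the responsibility/availability
messages into identity maps, which is precisely the mechanism that drives
the hamming distance to zero; it is the convergence device of the
published message-passing scheme, and the straight-line reference
implementation in the test suite reproduces it independently to 1e-10.

Degenerate inputs: zero-variance genes receive coexpression 0
off-diagonal and 1 on the diagonal so NaN cannot propagate; conditions
need ≥ 3 samples; the core loop contains no randomness, so identical
inputs give identical outputs, and permuting the gene order of all inputs
permutes the output columns identically.

## Differential edges and Key TFs

For networks A and B over identical id spaces, the probability that an
edge is unique to and strongly supported in A is

    P = Φ(z_A) · Φ((z_A − z_B)/√2),

the first factor demanding strong support in A on the z scale, the second
A-specific support (a difference of two unit-variance scores has sd √2).
The law is monotone increasing in `z_A`, decreasing in `z_B`, equals 0.25
at (0,0), and makes the A-unique and B-unique sets disjoint at any
threshold above 0.5.  It is one entry in a swappable registry
(`PROBABILITY_FORMULAS`); an independent-tails alternative
`Φ(z_A)(1−Φ(z_B))` is available.  High-confidence unique edges are those
with probability *strictly* greater than 0.90.

Key TFs are called by the hypergeometric upper tail: universe
`N = n_TFs × n_genes` pairs, successes `K` = all unique edges, draws
`n = n_genes` (the TF's own row), observed `k` = the TF's unique-target
count.  The universe choice is our reading of the enrichment test — the
method literature names only the distribution — and is reported
explicitly.  Bonferroni correction divides the family-wise α = 0.05 by
the number of TFs actually tested after filtering (strict inequality at
the critical p), and that divisor is echoed in every output table rather
than assumed to match any particular catalog size.

## TFCG extraction and cross-network matching

For each Key TF, the target set is its *unique high-confidence* target
set, not its prior targets.  Directed percent overlap is
`100·|Tᵢ∩Tⱼ|/|Tᵢ|`; membership in a coordinated group requires ≥ 70 % in
*both* directions for every member pair (comparisons done in exact
integer arithmetic, `100·|Tᵢ∩Tⱼ| ≥ 70·|Tᵢ|`, so boundary cases cannot
drift through floats).  Extraction builds the mutual-overlap graph and
greedily accepts maximal cliques — largest first, ties broken by the
lexicographically smallest sorted member tuple — removing accepted TFs
until no clique of size ≥ 2 remains.  Groups are therefore disjoint and
the output is invariant to input order (TFs are canonically sorted).  The
predicate, not any dendrogram, defines membership; the complete-linkage
ordering of the symmetrized dissimilarity `100 − min(Oᵢⱼ, Oⱼᵢ)` is kept
only to lay out heatmaps.  Every emitted group is re-checked against the
reciprocal predicate at runtime.  An oTFCG links groups from two network
comparisons sharing ≥ 2 Key TFs; the matched fraction of the second list
is reported alongside the pairs.

## Subtype scoring and stratification

A gene is overexpressed in a sample when its linear-scale value is
strictly greater than `fold` (default 2) times that gene's median across
all samples; the subtype fraction of a (sample, signature) pair is the
share of the signature's measured genes that are overexpressed.  Log2
input is exponentiated first so the fold is always a linear-scale ratio.

The paired differential-expression step is a deliberately simple
surrogate for a negative-binomial count model: per-gene paired log2 fold
change (mean of within-pair differences), a Wilcoxon signed-rank test —
exact by full sign-flip enumeration for ≤ 12 pairs (ties via midranks),
scipy's exact method for ≤ 25 pairs without ties, the normal
approximation otherwise — and Benjamini–Hochberg q-values; genes pass at
|FC| ≥ 2 and q < 0.05.  It exists to feed the stratification stage on
synthetic data and is not a reimplementation of count-model inference.

Stratification clusters post-treatment samples on the passing DE genes
(complete linkage, Euclidean), cutting at k = 2 and escalating k until at
least two non-singleton clusters exist.  Among non-singleton clusters the
one with the lowest mean expression of the *downregulated* DE genes is
labeled high-impact (strongest repression = strongest response); the rest
are low-impact; singletons are flagged outliers.  With only two samples
each forms its own cluster and the mean rule labels them directly.

Mann–Whitney comparisons are exact by enumerating all `C(nx+ny, nx)`
group assignments (midranks for ties) when `min(n) ≤ 8` and combined
`n ≤ 20`, using the two-sided doubling convention
`p = min(1, 2·min(P(U≤u), P(U≥u)))`; larger samples use the normal
approximation with tie correction.  All-tied inputs give p = 1.

## Synthetic scenarios

`generate_scenario` emulates the study design the pipeline targets: two
conditions in which planted groups of TFs co-target shared gene sets in
condition A only.  Per group, one standard-normal latent factor is drawn
per sample; target genes and member TFs load on it with weight
`signal_strength` (default 1.0, log2 scale) over Gaussian noise of sd 0.5
— giving within-group target correlation `s²/(s²+σ²) = 0.8` in A and 0 in
B.  Latents become normalized counts `100·2^latent`, so the count filter
and log2 median-centering are exercised on a realistic scale.  The motif
prior holds the planted edges minus Bernoulli false negatives (rate 0.05)
plus uniform false positives (rate 0.01) over non-planted pairs — uniform
to avoid accidental secondary structure — and any TF left without support
receives one random edge so the prior invariant holds.  The PPI carries
weight 1.0 on within-group pairs over a Bernoulli(0.05) background at
weight 0.2.  Generation is a pure function of the seed (numpy PCG64,
recorded in the config).

The default problem size (30 TFs, 300 genes, groups of 4×40 and 3×30,
20 samples per condition) runs each network in well under a second, so
the recovery studies over many seeds finish in minutes on one CPU.

What the generator does *not* emulate: read-count overdispersion
(negative-binomial sampling), batch effects, correlated background
structure, or indirect regulation.  Passing the recovery tests therefore
shows that the pipeline identifies planted factor-driven co-regulation
through the motif/PPI/coexpression route — not that it would have equal
power on RNA-seq data with those additional noise sources.

A known, quantified limitation: with 20 samples the null sd of a Pearson
correlation is ≈ 0.22, so a handful of the 230 background genes correlate
with a planted factor at r ≥ 0.5 by chance and are genuinely
indistinguishable from weak targets at the coexpression level.  These
produce planted-TF → background-gene unique edges (precision ≈ 0.7 at
recall ≈ 0.95) and, equivalently, a nonzero floor of unique edges under
label permutation (tens, versus ≈ 300 observed).  The permutation null
still separates cleanly — every permuted count sits strictly below the
observed count — but a zero permuted median is not achievable at this
sample size without sacrificing sensitivity.

`generate_signature_dataset` plants per-sample signature overexpression
at `overexpression_fold` (default 4) times the gene's across-sample
median.  The high group is deliberately a *minority* (one third of
samples: `n_high = n_samples_per_condition`, `n_low = 2×`): if half or
more of the samples were elevated, the planting itself would raise the
across-sample median to `(m + fold·m)/2` and the planted values would
fall below the `2×median` detection rule — with a minority group the
median stays on the ±10 % baseline and recovery is exact whenever
`fold > 2.5`.  The truth map records the planted fraction per sample.

## Pipeline

`run_pipeline` executes: inputs (scenario or files) → TF filter +
normalization → two networks → differential edges (both directions) →
Key TFs → TFCGs per direction → oTFCG matching → signature fractions →
optional permutation null → result tables.  All tables are sorted
deterministically (TF then gene, lexicographic) and the manifest contains
no timestamps, so runs with the same config are byte-identical.  The
manifest echoes every parameter, the seed, and per-stage counts, and is
sufficient to reproduce the run.  A stage failure is annotated in the
manifest (`failed_stage`) before the error propagates.
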