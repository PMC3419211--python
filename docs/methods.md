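# Methods

## Problem and model

A horizontally transferred gene often carries the compositional
signature of its donor rather than its host. `hgtident` treats HGT
detection in a single genome as supervised binary classification: each
coding sequence (CDS) is summarized by 15 scalar divergences from the
genome-wide background composition, and an SVM with a radial basis
function kernel separates transferred from native genes in that feature
space. The assumptions are those of every parametric detector: the
host genome has one reasonably homogeneous background composition,
transferred genes have not fully ameliorated toward it, and the
annotated CDS set is what gets scored (no gene calling is performed).

## The background model

`features.build_composition` accumulates, over all genes of a bundle:

* word counts for k = 1..7, strand-symmetrized (each gene's sequence and
  its reverse complement counted separately, so no junction words), and
  coding-strand-only counts alongside;
* codon counts over the 61 sense codons (stop codons excluded), only
  from genes whose length is a multiple of 3; conditional synonymous
  codon frequencies per amino acid;
* G+C fractions at the three codon positions.

Ambiguity codes other than N are mapped to N at load; any word or codon
containing N is excluded from counts, which keeps every frequency
denominator exact.

## The 15 features and their numerical policies

Canonical order (frozen in `hgtident.dataset.FEATURE_NAMES`): Karlin-DN,
Karlin-CB, GC1-GC3, Chi2-DN, Chi2-CB, JS-N, JS-DN, JS-CB, 1-mer..7-mer.

* **Strand handling.** The Karlin dinucleotide difference δ\* and the
  k-mer deviations use strand-symmetrized frequencies (Karlin's own
  convention). The chi-square and Jensen–Shannon features compare the
  coding strand directly: this preserves the defining identities — a
  gene is exactly self-identical to a background built from it alone,
  and JS reaches its 1-bit maximum on disjoint supports (an all-A gene
  against an all-T background), which symmetrization would destroy.
  Codon features are strand-specific by definition.
* **GC1–GC3 as one unit.** The three positional G+C fractions are
  collapsed into a single selectable feature, the mean absolute
  deviation from the genome's positional G+C. This keeps the GA
  chromosome at 15 bits with one bit per named signature and gives the
  feature the same gene-vs-genome divergence semantics as all others;
  the raw (gc1, gc2, gc3) triple remains available via
  `gc_by_position`.
* **Pseudocounts.** Wherever a ratio would divide by a zero frequency
  (a mononucleotide absent from a short gene in δ\*; a background unit
  unobserved but present in the gene for chi-square), 0.5 is added to
  every cell of the affected count vector (Jeffreys). An amino acid
  present in a gene but absent from the background falls back to
  uniform synonymous usage. JS needs no pseudocount (0·log 0 = 0).
* **Chi-square normalization.** The Pearson statistic is divided by the
  gene's unit count so genes of different length are comparable
  (`chi2_normalize=False` restores the raw statistic). The residual
  length dependence is O(1/n) from sequence edges.
* **JS weights** are fixed at 1/2, 1/2 so the divergence depends only on
  the two distributions and stays in [0, 1] bits
  (`js_weights="length"` switches to length-proportional weights for
  sensitivity analysis).

Every feature is validated against an independently coded brute-force
recomputation (pure-Python dictionaries, `tests/oracle.py`) to 1e-9 on
100 random genes over random backgrounds, including degenerate
compositions that exercise the pseudocount paths.

## Classifier protocol

Features are scaled per column to (−1, +1) by the training minimum and
maximum (constant columns map to 0; test values may fall outside the
interval). The (c, g) grid — default c ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
g ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}, the libsvm recommendation — is searched by
stratified 5-fold inner cross-validation, selecting the point with the
highest Recall, ties broken by lower Mean error, then smaller c, then
smaller g, so the choice is independent of grid ordering. Recall as the
selection objective mirrors the fitness used for feature selection: the
detector's stated goal is the detection rate, with the balanced error
recorded at that optimum.

**Leakage policy.** The scaler is fitted on training partitions only.
Scaling the complete dataset before cross-validation (as the original
protocol did) is available behind `scale_full_dataset=True` and off by
default because it inflates estimates. Likewise the GA can run once on
the full dataset (`global_ga=True`) instead of per training fold.

## Class imbalance: SMOTE

HGT genes are a small minority (10% in the benchmarks). SMOTE creates
synthetic minority rows x + u·(x′ − x), u ~ U[0,1], x′ one of the k = 5
nearest minority neighbors (Euclidean, in the scaled space), up to
minority:majority parity. Neither k nor the oversampling amount is
prescribed by the original study; the defaults follow the technique's
source, and both are configurable.

Placement matters more than either parameter. Oversampling the whole
training fold *before* the grid search puts interpolants of
inner-validation points into inner-training data; the selection then
favors hyper-parameters that exploit those copies and generalize worse —
in our experiments this reliably made SMOTE *hurt* held-out Recall.
`grid_search` therefore oversamples each inner training partition only
and validates on untouched imbalanced data; the final fold model is then
trained on the oversampled outer-training fold at the selected (c, g).
Outer test folds always stay imbalanced.

## GA feature selection

15-bit chromosomes (1 = feature selected); fitness 10000·Recall with
Recall as a fraction, estimated by stratified 5-fold CV of the
classifier restricted to the mask (scaler and grid search per fold,
training rows only). Selection is classical fitness-proportional
roulette; crossover is single-point with probability 0.9; mutation
flips each bit with probability 0.1 (per-bit chosen where the original
description is ambiguous; configurable); the top two individuals pass
unchanged (elitism), making the best-ever fitness trace monotone.
Defaults are 100 individuals and 200 generations; evaluations are
memoized by bit pattern, and an all-zero chromosome is repaired by
setting one random bit. The Mean error of every evaluated subset is
recorded so the error at the highest Recall is always reportable; it
also breaks fitness ties (then fewer bits).

## Threshold baseline

The comparison arm is a transparent single-feature detector: genes
scoring at or above the p-th percentile of the genome-wide score
distribution are called HGT, for p ∈ {80, 85, 90, 92.5, 95, 97.5, 99}.
Per feature the sweep reports every cutoff's confusion counts and
highlights the best-Recall cutoff with its Mean error. This is a
deliberate simplification of published multiple-threshold detectors
(whose exact rules are not public in detail), labelled as such; it is a
baseline, not a reimplementation.

## Synthetic genomes

The generator provides ground truth where no download can. A genome
model couples a 16×4 order-2 Markov nucleotide transition table
(multiplicative log-normal noise around a base composition,
`context_sigma=0.6`, giving the background real dinucleotide structure)
with Dirichlet-sampled synonymous codon usage (concentration 2.0).
Genes are built codon by codon: amino acids i.i.d. uniform over the 20
residues, the codon drawn with probability ∝ usage(c|aa) × the Markov
weight of its three nucleotides given the previous two; ATG prepended,
TAA appended, no internal stop possible. Gene lengths are uniform over
100–400 codons; 200 genes per genome with a 10% planted fraction
mirrors a realistically imbalanced detection problem.

The donor model diverges from the recipient in two independently
tunable ways: `codon_eps` perturbs codon usage and transitions
multiplicatively, and `delta_gc` shifts the donor's G+C content by
exponentially tilting codon usage toward G+C-rich codons. The tilt is
solved with Brent's method against the *exact* stationary composition
of the generative chain (computed from the 16-state codon-level Markov
chain), and the recipient is calibrated the same way so `gc=0.45` is
exact; a generated class difference of Δ=0.15 lands within ±0.02 of
target. Under a uniform amino-acid distribution the reachable coding
G+C is bounded (≈0.30–0.63); an infeasible shift raises a clear error.

Benchmark tiers fix the study conditions: **easy** (Δgc 0.15,
ε 1.2) where detection saturates, **medium** (0.04, 0.3) where Recall
sits mid-range and the SMOTE / feature-selection / baseline contrasts
are visible, **hard** (0.02, 0.15) near the floor. What the generator
does *not* emulate: post-transfer amelioration, operon and
mobile-element context, length-biased transfer, genome-scale
heterogeneity (e.g. leading/lagging strand skew). Passing tests
therefore demonstrate correct machinery and the direction of each
effect, not field performance on real genomes.

## Problem sizes and seeds

The test suite and the acceptance script run the experiments at reduced
(c, g) grids — 4×4 for the outer experiments, 3×3 wherever the GA
re-runs the grid per subset — and with GA populations of 8–16 over 3–6
generations; these sizes keep a full run in minutes while leaving every
protocol element (nested stratified CV, in-fold SMOTE, memoized GA)
intact. All randomness flows from explicit seeds through
`numpy.random.SeedSequence`, with child seeds spawned in a fixed order
(CV split, then per-fold GA / SMOTE / grid-search seeds), so every stage
is independently reproducible and every reported number is a pure
function of the seed.

## Published reference values

The six-genome evaluation tables of the original study are bundled as
data (`reference_tables.py`) so their cross-table arithmetic — the mean
Recall gain and Mean-error reduction of feature selection (6.50 / 4.67),
of SMOTE (6.53 / 6.02), and of the combined classifier over the best
single-signature threshold rows (2.81 / 26.32) — can be recomputed
exactly by `metrics.table_deltas`. Reproducing the per-genome values
themselves would require the HGT-DB genome annotations and is out of
scope.

## Known limitations

* The per-genome published values are inputs, not reproduced outputs.
* The threshold baseline is a simplified stand-in for the cited
  multiple-threshold algorithm.
* The classifier-vs-baseline Mean-error advantage on the mid-tier
  benchmark is directional but with a modest margin; at weak donor
  divergence individual seeds can favor a lucky single-feature sweep.
* Genes shorter than ~30 codons give noisy features; codon-based
  features require in-frame sequences, and out-of-frame genes are
  dropped with a warning rather than rescued.
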