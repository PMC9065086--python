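# Methods

`repliboot` generates and evaluates *artificial replicates* of an RNA-seq
experiment.  A true technical replicate — the same RNA libraries sequenced
a second time — is the gold standard for asking "would my list of
differentially expressed genes survive a re-run of the experiment?", but
is almost never budgeted.  The package implements three computational
substitutes and a framework for judging how faithfully each one mimics a
true technical replicate.

## The three replicate strategies

**FB — FASTQ bootstrap.** From a FASTQ file of `k` reads, draw
`m = round(π·k)` reads *with replacement* (`π ∈ (0, 1]`, default 1, so the
replicate is as deep as the original).  Re-quantifying the bootstrap file
yields a new count column per sample: an artificial technical replicate at
the level of individual samples.  The sampler is a two-pass stream
(count, then emit each record as many times as its index was drawn), so
memory use is constant and the output preserves input-file read order.
Repeated reads get a `/bsN` id suffix (N = 2, 3, …) because downstream
aligners often require unique read names; this can be disabled.  Quality
strings are copied verbatim, never resimulated.  For paired-end data a
single index sample is applied to both mate files — the only choice that
preserves pairing.  `π·k` is rounded half-to-even, with a floor of one
read for non-empty input.

**CB — column bootstrap.** Resample whole columns of the `d × n` count
matrix with replacement.  No new expression values are created; the
replicate is a new arrangement of existing samples, a replicate of the
*experiment* rather than of any sample.  By default resampling is
stratified within condition groups so that every artificial experiment
retains both conditions with the original group sizes (unstratified mode
is available; it can produce unbalanced or single-condition draws).  A
singleton group cannot be resampled and is copied unchanged with a
warning.

**MO — mixing observations.** Each new column is a weighted mean
`x_new = Σ_i w_i x_i` with `w_i ≥ 0, Σ w_i = 1` — the data-augmentation
trick from machine learning.  By default each output column mixes only
columns of its own condition group (mixing across groups would average
away the treatment effect and make downstream DE degenerate) and fresh
weights are drawn per output column from a symmetric Dirichlet(α = 1);
fixed weight vectors are also accepted.  Mixed values are rounded
half-to-even back to integers so the result is a valid count matrix.

All three generators are deterministic given their seed, and a pipeline
run records every derived seed in its manifest.

## Differential expression engine

The DE stage is a self-contained negative-binomial analog of the standard
count-based pipeline, with the count of gene *g* in sample *j* modelled as

    c_gj ~ NB(μ_gj, α_g),   μ_gj = s_j · q_g(level(j)),
    Var(c) = μ + α_g μ²

* **Size factors** `s_j`: median-of-ratios — per sample, the median over
  genes with positive counts in every sample of count / per-gene
  geometric mean.  The median is taken on the ratio scale (for an even
  number of reference genes this differs in the fourth decimal from
  exponentiating a log-scale median; the ratio-scale definition is the
  package's contract and what the brute-force oracle in the test suite
  evaluates).  If no gene is positive everywhere the estimator falls back
  to total-count scaling with a warning.
* **Dispersion** `α_g`: per-gene method of moments on normalized counts
  with level means removed — pooled within-level variance `s²` minus the
  shot-noise term `ξ·μ` (ξ = mean reciprocal size factor), divided by
  `μ²`, truncated at zero.  No trend fitting and no shrinkage; the
  estimate is intentionally the raw gene-wise quantity.  All-zero genes
  get NaN.
* **Wald test**: log2FC is the ratio of normalized level means, with the
  alphabetically first level as reference; a pseudocount of 0.5 is added
  to both level means only when one of them is zero, so the fold change
  of expressed genes is exactly invariant to depth rescaling.  The
  standard error comes from the NB Fisher information at the fitted
  means, `w = μ/(1 + αμ)` summed per level (level means moderated by the
  same 0.5 so empty levels keep a finite SE).  The two-sided p value
  refers the Wald statistic to a **t distribution with n − 2 degrees of
  freedom**, not a standard normal: because the plug-in dispersion is
  estimated from only n − 2 residual degrees of freedom without
  shrinkage, the statistic has t-like tails, and with a normal reference
  the raw-p type-I error at the 0.05 level measures 0.07–0.09 in the null
  simulation below instead of the nominal 0.05.  With the t reference it
  measures ≈ 0.04–0.05.  (DESeq2 can afford the normal reference because
  its dispersion shrinkage adds information; this engine deliberately has
  no shrinkage.)
* **BH adjustment**: textbook step-up, `padj_(i) = min_{j≥i} p_(j)·m/j`
  capped at 1, with `m` the number of testable (non-NaN) genes.
* **Selection**: `padj < 0.05` and `|log2FC| > 2` by default.

Results from an external DE tool (e.g. DESeq2) can be substituted through
a DESeq2-column-compatible TSV; the engine itself omits LFC shrinkage,
independent filtering, and outlier refitting by design.

## Gene-set over-representation

The set-level stage is a deterministic offline ORA: for each GMT set,
the one-sided hypergeometric upper tail of the overlap between the
selected genes and the set, both intersected with the universe (all genes
with a computable p value), followed by BH across sets.  This is a
functional stand-in for web-service enrichment tools whose ranking is not
reproducible offline; any deterministic set-level selector suffices for
the overlap analyses.

## Evaluation layer

* **Result-list similarity**: Spearman's rank correlation ρ between
  per-gene vectors (raw p values, or |log2FC| so that ranking ignores the
  direction of regulation), turned into the distance `1 − ρ ∈ [0, 2]`.
  Genes with a NaN in *any* compared vector are dropped listwise so every
  pairwise correlation uses one shared complete-case gene set.
* **Cluster trees**: agglomerative Ward linkage on the `1 − ρ` matrix in
  the Ward.D2 convention (scipy's `ward`, equivalent to R's
  `hclust(method = "ward.D2")`), exported as Newick with branch lengths
  derived from merge heights.
* **Overlap matrices**: entry (row A, column B) = `100·|A∩B|/|A|` — the
  share of the *reference* selection A recovered by comparison selection
  B.  Deliberately asymmetric; the diagonal is 100 for non-empty sets,
  and an empty reference yields a zero row plus a warning.  Files carry
  one decimal; displays round to integers.
* **Dispersion comparison**: gene-wise dispersion distributions per data
  set, estimated under the two-group condition design ("biological"
  variance) or, after column-binding replicate data sets, with the
  biological sample id as the design factor ("technical" variance between
  replicates of the same sample).  Distributions are compared by the
  two-sample Kolmogorov–Smirnov statistic.
* **Stability report**: for B artificial replicates, the per-gene count
  of runs that re-selected it, cross-tabulated against the reference
  selection (rows TRUE/FALSE × columns 0…B), plus the reference raw p
  values for rank-versus-stability scatter plots.

## Synthetic data generator

The generator emulates the structure of a two-condition bulk experiment
in which every biological sample was sequenced twice: groups of 5
("infected") and 4 ("control") biological samples; baseline means drawn
log2-uniform over [4, 10] (≈ 4–1024 counts); NB biological variability
with dispersion α = 0.1 (a typical bulk value for independent cell
cultures); a fraction (default 10%) of genes truly DE at |log2FC| = 3
with random sign.  Each biological sample has one latent Gamma-distributed
expression level; R1 and R2 are two conditionally independent Poisson
draws from that same level (alternatively, binomial thinning of a shared
deeper count).  Sharing the latent level is what makes counts of the same
sample correlate more strongly across R1/R2 than counts of different
samples — the defining property of technical replicates, asserted by a
property test.

A toy transcriptome (random, pairwise distinct sequences; default 300
bases) and a read simulator (uniform start positions, optional uniform
substitution errors, constant Q40 qualities, read ids that do not leak
the source transcript) let simulated counts be realized as FASTQ files;
an exact-substring quantifier (per-read-length k-mer index; ambiguous and
unmatched reads counted separately) closes the loop, and with zero error
rate the round trip recovers the simulated counts exactly.

What the generator does *not* emulate — and therefore what passing tests
cannot certify about real data: lane and flow-cell effects, GC and
positional bias, adapter contamination, PCR duplication, multi-mapping
ambiguity of real transcriptomes, mean-dependent (trended) dispersion,
and library-size variation beyond what resampling induces.

## Benchmark configuration

The strategy-comparison benchmark (also run by `scripts/acceptance.py`)
simulates R1/R2, realizes R1 as reads (50-mers over 300-base
transcripts), builds B = 10 replicates per strategy — FB at the read
level with π = 1, CB and MO at the count level — and scores each
replicate's p-value list against the held-out R2 (Spearman ρ) and its
biological-dispersion distribution against R2's (KS distance), over 10
seeds.  The benchmark uses d = 250 genes with baseline means 16–1024 so
the read-level loop stays small while keeping most genes in the
deep-coverage regime (α·μ ≳ 1) where biological variability dominates
shot noise — the regime of the bulk experiments these strategies target.
At shallow counts (α·μ ≪ 1) the extra multinomial noise of a read-level
bootstrap inflates dispersion estimates by roughly 1/μ and the contrast
between strategies is governed by shot noise rather than by the
strategies themselves.

Observed orderings on this benchmark (10 seeds): FB's p-value lists
correlate more strongly with R2 than MO's in 10/10 runs and CB's in
10/10; median dispersion-KS to R2 is FB ≈ 0.09 < CB ≈ 0.25 < MO ≈ 0.87.
MO's heavy KS distance reflects its variance-shrinking averaging; CB's
reflects the downward bias of resampled within-group variance.  These
numbers are recomputed, not stored, by the test suite and the acceptance
script.

## Numerical choices and degenerate inputs

* Rounding is half-to-even everywhere an integer is needed (π·k, mixed
  counts).
* Spearman uses average ranks for ties; fewer than 3 complete-case genes
  is an error.
* Dispersion truncation at 0 biases individual estimates but keeps the
  NB variance valid; all-zero genes carry NaN and are excluded from BH's
  m and from selections.
* `DesignSpec` orders levels alphabetically; the first is the reference
  level, so swapping condition labels negates every log2FC and leaves
  p values unchanged.
* Empty selections yield zero overlap rows (with a warning) rather than
  NaN, keeping downstream tables rectangular.
* Pipeline runs are not resumable: any stage error aborts with the stage
  name, and a rerun with the same config is bit-identical for the
  builtin DE backend.

## Known limitations

The DE engine is a deliberately minimal DESeq2 analog; its p values
agree with DESeq2 qualitatively, not numerically.  The FB strategy
underestimates true technical variance (resampling one library cannot
recreate library-preparation noise) — visible in the technical-dispersion
mode — and is the most expensive strategy in I/O.  The exact-match
quantifier is a testing device, not an aligner; real data should be
quantified externally and fed in as count TSVs.
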