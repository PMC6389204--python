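# Methods

This note documents the models and procedures implemented in `tekit`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real data.

## Integrant assembly from RepeatMasker hits

RepeatMasker reports endogenous retroviruses piecewise: internal coding
fragments (names suffixed `-int` or `_I`) and LTRs as independent alignment
rows, with 1-based inclusive coordinates and orientation `C` for the minus
strand. `tekit.repeats.merge_integrants` reassembles integrants as the
connected components of a pairwise *chainable* relation between hits:

- same chromosome and strand, separated by a gap of at most `max_gap`
  (default **400 bp**; a gap of exactly 400 chains, 401 does not; the gap
  between 1-based inclusive hits is `next.start − prev.end − 1`);
- name-compatible: two internal fragments chain only if they carry the same
  name; an internal chains with an LTR if the internal's name stem (suffix
  stripped) prefixes the LTR name and both share a RepeatMasker
  class/family, or if the pair appears in an explicit two-column pairing
  table (needed for real pairs like `MERVL-int`/`MT2_Mm`, where homonymy
  does not hold lexically). Two LTRs never chain directly — this is what
  lets tandem solitary LTRs remain separate single-part `LTR_SOLO`
  integrants — though they may join one component through a shared internal.

Chaining is transitive (union-find over a sorted sweep), so a full provirus
merges even though its two LTRs never touch. Nested or overlapping
same-name hits are unioned before chaining; the 1-based → 0-based half-open
conversion happens exactly once, at integrant construction, which keeps all
off-by-one logic in one place. LTR roles are positional relative to the
internal block and strand-aware (upstream on the integrant's 5′ side →
`LTR5`). The family label is the stem of the internal fragment contributing
the most aligned bases; LTR-only integrants keep the LTR name.

Solo-LTR versus multi-internal representation is genuinely ambiguous in
merged repeat tracks; we expose the structure through subpart roles rather
than collapsing it, so downstream code can apply its own rule.

## Interval logic

All intervals are 0-based half-open. Touching intervals (`a.end ==
b.start`) share 0 bp — they are *not* flagged by any-overlap — and lie at
distance 0, matching bedtools `intersect`/`closest` semantics. KAP1
occupancy uses 25% reciprocal overlap (the shared length must cover ≥ 25% of
both the feature and the peak); histone marks use the 1-bp default. Strand
is ignored in occupancy tests, peaks flag every feature they qualify
against, and flags are monotone in the peak set. Genome coverage is the
merged-union length over the genome length, as `bedtools genomecov` reports
it. Features on a chromosome with no target have undefined (NaN) distance.

## Quantification

Multi-mapping reads are removed by the `NH == 1` rule (absent NH tags count
as unique, logged once). Counting is read-level with multicov semantics: a
read overlapping k features increments each; gene counting is
reverse-stranded on exon unions with a MAPQ ≥ 10 floor, TE counting is
split-aware (any CIGAR block may provide the ≥ 1 bp overlap) and
same-stranded, defaulting to unique reads only with an `all_alignments`
switch for multi-mapper analyses. Features keep a count row only if their
total across samples is at least the number of samples.

Coverage profiles scale per-base signal to reads per 100 million mapped
reads, reverse minus-strand features, and resample each feature onto a
common grid by linear interpolation at bin midpoints ("resampling" admits
several readings; midpoint interpolation commutes exactly with strand
reversal, which the mirror-symmetry test exploits). The band is the
normal-approximation 95% CI, mean ± 1.96·SEM across features; with one
feature the band collapses to the point estimate by convention (logged).

## Normalization and the moderated t

Log expression is `log2((count + 0.5)/(lib + 1) × 1e6)`. TE matrices are
normalized with the **gene** library sizes of the same samples (column sums
of the filtered gene count matrix), so TE CPM is comparable across
libraries dominated by genic reads. Genes and TEs are low-count-filtered
separately before their library sizes are taken.

The two-group moderated t shrinks per-feature residual variances toward a
prior: `s̃² = (d0·s0² + d·s²)/(d0 + d)`, `t = log2FC / (s̃·√(1/n1 + 1/n2))`
referred to t with `d0 + d` degrees of freedom. The prior `(d0, s0²)` is
estimated by moment-matching `log s²` against its theoretical scaled-log-F
distribution (digamma mean, trigamma variance, trigamma inverted by Newton
iteration at tolerance 1e-8); non-positive excess variance caps `d0` at 1e6,
effectively infinite shrinkage with a normal reference. Zero-variance
features are excluded from the moment fit but still shrunk, so their
posterior variance is bounded away from zero. A test cross-checks the whole
chain — `d0`, `s0²`, t and p — against limma's `lmFit`/`eBayes` at 1e-6
relative tolerance. Observation-level precision weights (voom's
mean–variance weighting) are deliberately omitted: they change efficiency,
not the definition of the statistic; this is the one documented deviation
from the weighted pipeline the statistic originates from.

BH adjustment delegates to statsmodels (`fdr_bh`), with the step-up
definition kept as an independent oracle in the tests. Calls: `up` iff
`log2FC ≥ log2(2)` **and** `p_adj < 0.05` (strict), `down` symmetric,
otherwise `stable`. PCA is feature-centered SVD of the logCPM matrix with
explained-variance fractions from the squared singular values.

## (h)MeDIP enrichment and RRBS summaries

Enrichment per region is `logcpm(IP) − logcpm(input)` with the same 0.5
pseudocount (comparability with the expression scale), replicates averaged
on the log-enrichment scale; the knockdown effect is the per-region
difference of enrichments. When two groups differ in size by more than
1,000, the t-test is replaced by 10,000 cross-validation rounds that each
draw 1,000 values per group without replacement; the **median** p across
rounds is returned — median rather than mean because it is
order-preserving and robust; only the round counts, not the aggregator, are
externally fixed, so this is flagged as an interpretation. Expression–5hmC
relations use Spearman rank correlation (mid-ranks for ties), computed
separately for occupancy-defined groups, with constant vectors reported as
missing. RRBS methylation per feature is the third quartile across
overlapping CpGs, computed as the type-7 (linear-interpolation) quantile —
numpy's default and the convention of mainstream statistical software.

## The Gamma–Gamma pattern model

A *pattern* is a partition of the condition groups into equal-mean blocks;
with six groups there are Bell(6) = 203 patterns. Within one feature and
one block, observations are `x ~ Gamma(α, β)` (rate parameterization) with
a conjugate `β ~ Gamma(a0, ν)`, so the block marginal is closed-form (see
README); a pattern's likelihood is the product over its blocks, and a
feature's posterior over patterns follows from mixture weights π.

Design choices, where the modelling space was genuinely open:

- **Shared observation shape α across features.** Richer formulations give
  every feature its own shape under a hyperprior; a single shared α keeps
  every marginal closed-form and directly testable against numerical
  quadrature, and suffices for posterior-best pattern assignment, which is
  the quantity consumed downstream.
- **The model consumes unlogged positive CPM** (logCPM back-transformed),
  matching a Gamma observation model; low-coverage features (fewer than 20
  reads in total) are discarded first.
- **Fitting** is EM: responsibilities in the E-step; π as mean
  responsibility in the M-step; (α, a0, ν) by Nelder–Mead maximization of
  the observed mixture log-likelihood in log-parameter space, accepted only
  when it improves, so the log-likelihood trace is monotone non-decreasing
  by construction (asserted on every run). Convergence at relative change
  < 1e-6, cap 500 iterations with a warning. Initialization is
  deterministic and seed-free: α by method of moments on within-group
  replicates, a0 = 2, ν = a0/mean(x).
- **Sufficient statistics** (per-feature n, Σx, Σlog x for each distinct
  block across the candidate patterns — at most 63 subsets of six groups)
  are precomputed once, so a full 203-pattern fit on 2,000 features takes
  seconds.
- **Ties** in the posterior break toward the earlier pattern in canonical
  (restricted-growth) order, logged when they occur.

The shipped P0–P5 preset encodes one reading of the qualitative
six-condition narratives (stable; uniform knockdown response; response
modulated in TET-TKO or DNMT-TKO cells; altered basal level in
hypomethylated cells). It is a convenience, not ground truth: equality
structures cannot distinguish narratives that differ only in effect
magnitude, so two of the published-style narratives collapse onto one
partition.

Family over-representation per pattern is the upper-tail hypergeometric
`P(X ≥ k)` for k family members among the n features of a pattern, drawn
from N classified features containing K family members; raw p-values are
reported (heatmap display convention), with fold = (k/n)/(K/N). Heatmap
ordering clusters the top-N features by smallest adjusted p with complete
linkage under Pearson distance (1 − r); constant rows are excluded with a
warning and rows are pre-sorted by id so leaf order is deterministic.

## Synthetic data: what it emulates, what it does not

Generators are deterministic functions of (config, seed); independent
sub-streams come from hashing purpose strings, so adding a simulator never
perturbs another's stream.

- **RepeatMasker fixtures** place proviruses (LTR5–internal–LTR3 at gaps
  drawn from a configurable set), fragmented internals, solitary LTRs, and
  "detached" 3′ LTRs at 500 bp; the planted truth splits a grouping
  wherever a drawn gap exceeds 400 bp, so truth and merge semantics agree
  by construction even when gap settings straddle the threshold.
- **Counts** follow the study design — six groups (WT/DNMT-TKO/TET-TKO ×
  ctrl/kd), 3 replicates, 20 M-read libraries, shape α = 10, pattern
  mixture 40/25/10/10/10/5% over P0–P5 — with per-block means either drawn
  from the Gamma prior (a0 = 5, ν = 0.5) or geometrically separated at a
  controlled ratio (default 4), then Poisson-sampled into counts. The
  Gamma→Poisson mixing means the classifier sees mildly misspecified data
  (negative-binomial-like marginals), as it would in real use; pattern
  recovery is tested under this misspecification. Hyperparameter recovery,
  by contrast, is tested on draws from the model's own process
  (`simulate_gg_expression`, no Poisson layer): at ~1 CPM the Poisson layer
  contributes dispersion comparable to 1/α itself, so count-level shape
  estimates reflect total dispersion rather than an estimator defect —
  a property worth knowing when interpreting fitted α on shallow libraries.
- **IP/input pairs** plant a +1 log2 IP gain at bound regions in the
  knockdown only, at 100× input coverage; **RRBS tables** draw percent
  methylation from Beta distributions (means 80% bound / 10% unbound,
  concentration 10); **peaks** cover bound integrants with a centered
  sub-interval spanning 30% of their length, so reciprocal classification
  at 25% flags exactly the planted set.

Not emulated: read-level sequence artifacts, mappability and alignment
error, batch effects, fragment-length effects in IP data, biological
covariation between methylation, occupancy and expression beyond the single
planted bound flag. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative
conditions, not robustness to every artifact of real libraries.

## Problem sizes and numerical conventions

Test and acceptance workloads use 500 random merge fixtures (4–30 hits
each), 10,000 × 1,000 interval pairs, 2,000 features for pattern recovery
over all 203 partitions, 5,000 for hyperparameter recovery, 500-feature
nulls, and 25-integrants-per-family pipeline runs — sizes chosen so the
whole suite runs in well under a minute per component on one CPU while
keeping Monte-Carlo margins comfortable. Tolerances: 1e-6 relative against
quadrature for the block marginal (the oracle integrates the peak-factored
integrand split at its mode); 1e-10 for the d0 = 0 t-statistic limit; 1e-12
for BH against the step-up definition. Degenerate inputs are defined
explicitly: empty blocks have log-marginal 0, single-feature coverage bands
collapse, constant vectors yield missing correlations, features without
CpGs are omitted, and the q75 of a single CpG is itself.

## Known limitations

- Two-group contrasts only; no multi-factor designs or TMM normalization.
- The moderated t omits voom precision weights (documented above).
- The Gamma–Gamma model shares one α across features and does not implement
  MCMC fitting or classification-error control.
- Peak calling and read alignment are upstream and out of scope; peaks are
  consumed as BED, alignments as SAM/BAM or count tables.
- How replicate (h)MeDIP experiments are averaged (here: mean of
  log-enrichments) and whether mark stratification should be exclusive when
  two marks hit one element are exposed as options rather than fixed, since
  both conventions are defensible.
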