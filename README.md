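# tekit — integrant-level analysis of transposable-element regulation

`tekit` is a Python toolkit for studying how the KRAB/KAP1 corepressor
system, DNA methylation and TET-dependent hydroxymethylation control
transposable elements (TEs) in mouse embryonic stem cells — at the level of
individual genomic copies ("integrants") rather than aggregated families.
It is aimed at computational epigenomics groups who have RepeatMasker
annotations, peak BEDs, count tables and per-CpG methylation calls, and want
a tested, reproducible path from those inputs to integrant-level biology.

The toolkit covers:

- **Integrant assembly** — RepeatMasker annotates an endogenous retrovirus as
  separate hits (an internal fragment such as `IAPEz-int` plus flanking LTRs
  such as `IAPLTR1a_Mm`). `tekit.repeats` merges homonymous internal
  fragments with their attributed LTRs whenever compatible hits lie within
  400 bp, yielding one annotation per provirus with ordered
  `LTR5/INTERNAL/LTR3` subparts and `LTR_SOLO` records for solitary LTRs.
- **Occupancy classification** — KAP1 binding by 25% *reciprocal* overlap
  with ChIP peaks (the overlap must cover ≥ 25% of **both** intervals);
  histone-mark domains (H3K9me3, H3K4me3, H3K27me3) by the 1-bp any-overlap
  rule; plus genome-coverage fractions and distance-to-nearest-feature
  statistics.
- **Quantification** — unique-read (`NH == 1`) filtering, reverse-stranded
  exon counting for genes, split-aware same-strand multicov-style counting
  for TE integrants, and metagene coverage profiles normalized to reads per
  100 million mapped reads with a 95% confidence band.
- **Differential expression** — log2 CPM with a 0.5 pseudocount
  (`log2((c + 0.5)/(N + 1)·10⁶)`, TE matrices normalized by the **gene**
  library sizes of the same samples), the empirical-Bayes moderated *t*
  statistic

  $$\tilde s_g^2 = \frac{d_0 s_0^2 + d\, s_g^2}{d_0 + d},\qquad
    t_g = \frac{\widehat{\beta}_g}{\tilde s_g\sqrt{1/n_1 + 1/n_2}}
    \sim t_{d_0 + d},$$

  with $(d_0, s_0^2)$ estimated by digamma/trigamma moment matching of
  $\log s_g^2$; Benjamini–Hochberg FDR control; and up/down/stable calls at
  two-fold change with adjusted $p < 0.05$.
- **(h)MeDIP enrichment** — per-region log2 IP-over-input on the same CPM
  scale, knockdown-minus-control deltas, a subsampled cross-validated
  *t*-test (10,000 rounds of 1,000-element subsets when group sizes differ
  by more than 1,000), Spearman correlations of expression change versus
  5hmC change stratified by KAP1 occupancy, and per-feature q75 summaries of
  RRBS percent methylation.
- **Expression patterns** — each integrant's behaviour across the six
  conditions (wild-type, DNMT TKO, TET TKO × control/*Kap1*-knockdown) is
  classified into a *pattern*: a partition of the condition groups into
  blocks of equal mean expression. Within a block, observations are
  $x_i \sim \Gamma(\alpha, \beta)$ with $\beta \sim \Gamma(a_0, \nu)$, giving
  the closed-form marginal

  $$m(x_{1..n}) = \frac{\prod_i x_i^{\alpha-1}}{\Gamma(\alpha)^n}\cdot
    \frac{\nu^{a_0}\,\Gamma(a_0 + n\alpha)}
         {\Gamma(a_0)\,(\nu + \sum_i x_i)^{a_0 + n\alpha}}.$$

  A mixture over all 203 set partitions of six groups (or a curated preset
  P0–P5) is fitted by EM and each integrant is assigned its posterior-best
  pattern; repeat-family composition per pattern is scored with an
  upper-tail hypergeometric test.
- **Synthetic data** — every stage has a generator with planted ground truth
  (`tekit.simulate`), so the full pipeline is testable without any
  sequencing download.

## Worked example

`examples/` contains one short script per capability. For instance the
pattern classifier (`python examples/05_expression_patterns.py`):

```
fitted hyperparameters: alpha=9.50 a0=0.95 nu=0.898
EM iterations: 6, final log-likelihood -69824.2

integrants per pattern (P0 stable, P1 uniform kd response, ...):
best_pattern
P0    434
P1    296
P2    182
P3    133
P4    101
P5     54

planted pattern recovered for 94.8% of integrants
```

1,200 integrants were simulated from the Gamma–Gamma model (shape
$\alpha = 10$, four-fold separation between blocks, three replicates per
condition, 20 M-read libraries), low-coverage integrants (< 20 reads total)
discarded, the mixture refitted from scratch, and 94.8% of integrants were
returned to their planted pattern. The hypergeometric table in the same
script shows how family over-representation per pattern is reported
(raw p and fold over-representation).

The end-to-end pipeline runs from a shell:

```bash
tekit run --config pipeline.yaml            # or: --stage simulate --stage annotate ...
tekit validate pipeline.yaml
```

writing TSV/JSON tables and a `manifest.json` of parameters and output
hashes; the same seed reproduces byte-identical outputs.

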