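"""(h)MeDIP IP-over-input enrichment, subsampled t-tests, RRBS q75 summaries.

Methylated/hydroxymethylated-DNA immunoprecipitation is quantified per region
as the log2 ratio of library-normalized IP signal over total input, using the
same logcpm transform (0.5 pseudocount) as the expression analyses so the two
are comparable.  The knockdown effect is the per-region difference of
enrichments (knockdown minus control).  Group comparisons with very unequal
sizes use a subsampled cross-validated t-test to avoid sample-size bias, and
expression/5hmC relationships are tested with Spearman rank correlation,
stratified by occupancy (e.g. KAP1-bound vs unbound).  RRBS methylation is
summarized per feature as the third quartile (q75) across its CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from intervaltree import IntervalTree

from .expression import normalize_logcpm
from .intervals import GenomicInterval
from .quantify import CountMatrix

__all__ = [
    "EnrichmentResult",
    "MethylationSummary",
    "ip_over_input",
    "enrichment_change",
    "subsampled_ttest",
    "expression_hydroxymethylation_correlation",
    "rrbs_feature_q75",
]


@dataclass
class EnrichmentResult:
    """Per-region log2 IP-over-input enrichment for one condition."""

    log2_ip_over_input: pd.Series  # indexed by region id
    condition: str = ""


@dataclass
class MethylationSummary:
    """Per-feature q75 of percent CpG methylation and the number of CpGs used."""

    table: pd.DataFrame  # columns: q75, n_cpgs


def ip_over_input(
    ip_counts: CountMatrix,
    input_counts: CountMatrix,
    condition: str = "",
) -> EnrichmentResult:
    """log2 enrichment of IP over input per region: logcpm(IP) - logcpm(input).

    Both matrices must share region ids; samples (replicates) are averaged on
    the log-enrichment scale after per-sample normalization.
    """
    if list(ip_counts.counts.index) != list(input_counts.counts.index):
        raise ValueError("IP and input matrices must cover the same regions in the same order")
    if ip_counts.counts.shape[1] != input_counts.counts.shape[1]:
        raise ValueError("IP and input matrices must have matching sample columns")
    ip_lc = normalize_logcpm(ip_counts).logcpm.to_numpy()
    in_lc = normalize_logcpm(input_counts).logcpm.to_numpy()
    enr = (ip_lc - in_lc).mean(axis=1)
    return EnrichmentResult(
        log2_ip_over_input=pd.Series(enr, index=ip_counts.counts.index, name="log2_enrichment"),
        condition=condition,
    )


def enrichment_change(kd: EnrichmentResult, ctrl: EnrichmentResult) -> pd.Series:
    """Per-region delta = knockdown enrichment - control enrichment."""
    if not kd.log2_ip_over_input.index.equals(ctrl.log2_ip_over_input.index):
        raise ValueError("knockdown and control regions do not match")
    delta = kd.log2_ip_over_input - ctrl.log2_ip_over_input
    delta.name = "delta_log2_enrichment"
    return delta


def subsampled_ttest(
    group_a,
    group_b,
    size_gap_trigger: int = 1000,
    n_cv: int = 10_000,
    subset_size: int = 1000,
    seed: int | None = None,
) -> float:
    """Two-sided two-sample t-test p-value, subsampled when group sizes differ.

    When the sizes differ by at most ``size_gap_trigger`` the plain Student
    t-test is returned.  Otherwise, ``n_cv`` rounds each draw ``subset_size``
    values without replacement from each group (groups smaller than the
    subset are used whole), and the median p across rounds is returned —
    a cross-validation that removes the sample-size advantage of the larger
    group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if abs(len(a) - len(b)) <= size_gap_trigger:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("plain t-test needs at least 2 values per group")
        return float(stats.ttest_ind(a, b).pvalue)
    rng = np.random.default_rng(seed)
    ps = np.empty(n_cv)
    for i in range(n_cv):
        sa = a if len(a) <= subset_size else rng.choice(a, size=subset_size, replace=False)
        sb = b if len(b) <= subset_size else rng.choice(b, size=subset_size, replace=False)
        ps[i] = stats.ttest_ind(sa, sb).pvalue
    return float(np.median(ps))


def expression_hydroxymethylation_correlation(
    delta_expr: pd.Series,
    delta_5hmc: pd.Series,
    bound_flags: pd.Series,
) -> pd.DataFrame:
    """Spearman correlation of expression change vs 5hmC change per occupancy group.

    Computed separately for bound (True) and unbound (False) features; ties
    are mid-ranked.  Groups with fewer than 3 features, or with a constant
    vector (undefined rank correlation), report NaN.
    """
    common = delta_expr.index.intersection(delta_5hmc.index).intersection(bound_flags.index)
    rows = {}
    for label, flag in (("bound", True), ("unbound", False)):
        idx = common[bound_flags.loc[common].astype(bool) == flag]
        x = delta_expr.loc[idx].to_numpy(dtype=float)
        y = delta_5hmc.loc[idx].to_numpy(dtype=float)
        if len(idx) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            rows[label] = {"rho": np.nan, "p": np.nan, "n": len(idx)}
        else:
            res = stats.spearmanr(x, y)
            rows[label] = {"rho": float(res.statistic), "p": float(res.pvalue), "n": len(idx)}
    return pd.DataFrame(rows).T


def rrbs_feature_q75(
    cpg_table: pd.DataFrame,
    features: list[GenomicInterval],
) -> MethylationSummary:
    """Per-feature third quartile of percent CpG methylation.

    ``cpg_table`` has columns (chrom, start, end, percent) with one row per
    CpG (half-open, typically 1 bp).  CpGs are assigned to features by
    any-overlap; the q75 uses linear interpolation between order statistics
    (numpy default, the type-7 quantile).  Features without CpGs are omitted.
    """
    pct = cpg_table["percent"].to_numpy(dtype=float)
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("percent methylation must lie in [0, 100]")
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(cpg_table.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(int(row.start), int(row.end), i)
    rows = {}
    for f in features:
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        idx = [node.data for node in tree.overlap(f.start, f.end)]
        if not idx:
            continue
        fid = f.name or f"{f.chrom}:{f.start}-{f.end}"
        rows[fid] = {"q75": float(np.quantile(pct[idx], 0.75)), "n_cpgs": len(idx)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if not table.empty:
        table["n_cpgs"] = table["n_cpgs"].astype(int)
        table.index.name = "feature_id"
    return MethylationSummary(table=table)
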