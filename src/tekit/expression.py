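"""Normalization, empirical-Bayes moderated-t differential expression, PCA.

Counts are transformed to log2 counts-per-million with a 0.5 pseudocount,
``logcpm = log2((count + 0.5) / (lib_size + 1) * 1e6)``; TE count matrices are
normalized with the GENE library sizes of the same samples, so that TE CPMs
are comparable across libraries dominated by genic reads.  Two-group tests
use the moderated t statistic: per-feature residual variances are shrunk
toward a common prior value estimated by moment-matching the scaled
F-distribution of sample variances (digamma/trigamma matching), and the
statistic is referred to a t distribution with the augmented degrees of
freedom.  Benjamini-Hochberg controls the FDR, and up/down/stable calls
require a two-fold change and adjusted p below 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

__all__ = [
    "ExprMatrix",
    "DEResult",
    "normalize_logcpm",
    "fit_variance_prior",
    "moderated_t_test",
    "bh_adjust",
    "call_de",
    "pca_scores",
]


@dataclass
class ExprMatrix:
    """log2 counts-per-million, features x samples, with the library sizes used."""

    logcpm: pd.DataFrame
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.logcpm.to_numpy()).all():
            raise ValueError("logcpm must be finite")

    @property
    def cpm(self) -> pd.DataFrame:
        """Strictly positive CPM values (2**logcpm), e.g. for the pattern model."""
        return 2.0 ** self.logcpm


@dataclass
class DEResult:
    """Per-feature moderated-t differential expression table.

    ``table`` columns: log2FC, t_mod, p, p_adj, call; plus the shrinkage
    hyperparameters actually used.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_residual: float


def normalize_logcpm(counts: CountMatrix, gene_lib_sizes: pd.Series | None = None) -> ExprMatrix:
    """log2 CPM with a 0.5 pseudocount.

    ``gene_lib_sizes`` overrides the matrix's own library sizes; pass the gene
    library sizes when normalizing TE counts.
    """
    libs = counts.lib_sizes if gene_lib_sizes is None else gene_lib_sizes.loc[counts.sample_ids]
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    mat = counts.counts.to_numpy(dtype=float)
    lc = np.log2((mat + 0.5) / (libs.to_numpy(dtype=float) + 1.0) * 1e6)
    return ExprMatrix(
        logcpm=pd.DataFrame(lc, index=counts.counts.index, columns=counts.counts.columns),
        lib_sizes=pd.Series(libs, index=counts.counts.columns),
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def fit_variance_prior(s_sq: np.ndarray, df: float, d0_cap: float = 1e6) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-inverse-chi-square variance prior.

    Moment-matches ``log s_g^2`` to the log-F distribution implied by the
    hierarchical model: with ``e_g = log s_g^2 - digamma(df/2) + log(df/2)``,
    the mean of e estimates ``log s0^2 + digamma(d0/2) - log(d0/2)`` and its
    excess variance over ``trigamma(df/2)`` estimates ``trigamma(d0/2)``,
    inverted by Newton iteration.  Features with zero variance are excluded
    from the moment fit; d0 is capped (effectively infinite shrinkage) when
    the excess variance is non-positive.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq[s_sq > 0]
    if len(pos) < 2:
        return d0_cap, float(np.mean(s_sq)) if len(s_sq) else 1.0
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = d0_cap
    else:
        d0 = min(2.0 * _trigamma_inverse(e_var), d0_cap)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    expr: ExprMatrix,
    group_labels: pd.Series | dict,
    d0_override: float | None = None,
) -> DEResult:
    """Two-group empirical-Bayes moderated t test on logcpm values.

    log2FC is the group-2 minus group-1 mean logcpm (groups in sorted label
    order unless ``group_labels`` is an ordered dict/Series with exactly two
    levels).  ``d0_override = 0`` disables shrinkage and reproduces the
    ordinary equal-variance two-sample t statistic.
    """
    labels = pd.Series(group_labels)
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g1 = labels.index[labels == levels[0]]
    g2 = labels.index[labels == levels[1]]
    n1, n2 = len(g1), len(g2)
    if n1 == 0 or n2 == 0:
        raise ValueError("each group needs at least one sample")
    if n1 + n2 < 3:
        raise ValueError("need at least 3 samples for a residual degree of freedom")

    x1 = expr.logcpm[g1].to_numpy(dtype=float)
    x2 = expr.logcpm[g2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = m2 - m1
    df = float(n1 + n2 - 2)
    rss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s_sq = rss / df

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.mean(s_sq[s_sq > 0])) if (s_sq > 0).any() else 1.0
    else:
        d0, s0_sq = fit_variance_prior(s_sq, df)

    if np.isfinite(d0) and d0 > 0:
        s_post = (d0 * s0_sq + df * s_sq) / (d0 + df)
        df_total = df + d0
    elif d0 == 0:
        s_post = s_sq
        df_total = df
    else:  # infinite prior df: all features share s0^2
        s_post = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {"log2FC": log2fc, "t_mod": t_mod, "p": p, "p_adj": bh_adjust(p)},
        index=expr.logcpm.index,
    )
    return DEResult(table=table, d0=d0, s0_sq=s0_sq, df_residual=df)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(result: DEResult, fc_threshold: float = 2.0, alpha: float = 0.05) -> DEResult:
    """Annotate up/down/stable calls: |log2FC| >= log2(fc_threshold) AND p_adj < alpha."""
    lfc = np.log2(fc_threshold)
    t = result.table
    call = np.where(
        (t["log2FC"] >= lfc) & (t["p_adj"] < alpha),
        "up",
        np.where((t["log2FC"] <= -lfc) & (t["p_adj"] < alpha), "down", "stable"),
    )
    out = t.copy()
    out["call"] = call
    return DEResult(table=out, d0=result.d0, s0_sq=result.s0_sq, df_residual=result.df_residual)


def pca_scores(expr: ExprMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates from feature-centered SVD of the logcpm matrix.

    Returns (scores: samples x components, explained variance fractions).
    """
    n_samples = expr.logcpm.shape[1]
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_components > n_samples:
        raise ValueError("n_components cannot exceed the number of samples")
    x = expr.logcpm.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    frac = (s**2 / total) if total > 0 else np.zeros_like(s)
    scores = u[:, :n_components] * s[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=expr.logcpm.columns, columns=cols), frac[:n_components]
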