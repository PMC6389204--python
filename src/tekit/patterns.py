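"""Cross-condition expression-pattern classification with a Gamma-Gamma model.

Each TE integrant's normalized expression across the six condition groups
(wild-type, DNMT TKO and TET TKO cells, each control or Kap1-knockdown) is
classified into an expression *pattern*: a partition of the groups into
blocks of equal mean expression.  Within one feature, every block carries its
own latent rate beta ~ Gamma(a0, nu) (rate parameterization), and each
observation in the block is x ~ Gamma(alpha, beta).  Integrating beta out
gives a closed-form block marginal,

    m(x_1..x_n) = [prod x_i^(alpha-1) / Gamma(alpha)^n] * nu^a0
                  * Gamma(a0 + n*alpha) / [Gamma(a0) * (nu + sum x_i)^(a0 + n*alpha)],

so a pattern's likelihood is the product of its block marginals and features
are assigned to the posterior-best pattern under mixture weights pi fitted by
EM.  The observation shape alpha is shared across features, which keeps every
marginal closed-form and testable against numerical integration.

Family composition of the resulting pattern classes is scored with an
upper-tail hypergeometric over-representation test, and the most deregulated
features can be ordered by complete-linkage clustering under Pearson
distance for heatmap display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.special import gammaln, logsumexp

__all__ = [
    "PatternSpec",
    "GGHyper",
    "PatternAssignment",
    "SIX_GROUPS",
    "enumerate_patterns",
    "preset_patterns",
    "min_reads_filter",
    "gg_block_marginal_loglik",
    "fit_gg_em",
    "assign_patterns",
    "family_enrichment",
    "cluster_top_deregulated",
]

log = logging.getLogger(__name__)

SIX_GROUPS = ("WT.ctrl", "WT.kd", "DNMT.ctrl", "DNMT.kd", "TET.ctrl", "TET.kd")


@dataclass(frozen=True)
class PatternSpec:
    """A partition of condition groups into equal-mean blocks."""

    id: str
    blocks: tuple[frozenset, ...]

    def validate(self, groups) -> None:
        groups = set(groups)
        seen: set = set()
        for b in self.blocks:
            if not b:
                raise ValueError(f"pattern {self.id}: empty block")
            if b & seen:
                raise ValueError(f"pattern {self.id}: blocks overlap")
            seen |= b
        if seen != groups:
            raise ValueError(f"pattern {self.id}: blocks must cover exactly {sorted(groups)}")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class GGHyper:
    """Hyperparameters of the Gamma-Gamma mixture.

    alpha: observation Gamma shape (> 0); a0, nu: shape and rate of the
    Gamma prior on each block's rate beta; pi: per-pattern mixture weights.
    """

    alpha: float
    a0: float
    nu: float
    pi: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self) -> None:
        if min(self.alpha, self.a0, self.nu) <= 0:
            raise ValueError("alpha, a0 and nu must be positive")
        self.pi = np.asarray(self.pi, dtype=float)
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a probability vector")


@dataclass
class PatternAssignment:
    """Posterior pattern probabilities and the best pattern per feature."""

    posterior: pd.DataFrame  # features x patterns
    best_pattern: pd.Series  # pattern id per feature


# ---------------------------------------------------------------------------
# pattern enumeration
# ---------------------------------------------------------------------------

def enumerate_patterns(groups, mode: str = "all_partitions", user_list=None) -> list[PatternSpec]:
    """All set partitions of the condition groups (canonical restricted-growth
    order), or a validated user-supplied list.

    Bell numbers grow fast; the group count is capped at 10.
    """
    groups = tuple(groups)
    if not (1 <= len(groups) <= 10):
        raise ValueError("need between 1 and 10 groups")
    if mode == "user_list":
        if not user_list:
            raise ValueError("user_list mode requires patterns")
        for p in user_list:
            p.validate(groups)
        return list(user_list)
    if mode != "all_partitions":
        raise ValueError(f"unknown mode {mode!r}")

    patterns: list[PatternSpec] = []

    def grow(assign: list[int], next_block: int) -> None:
        i = len(assign)
        if i == len(groups):
            blocks: list[set] = [set() for _ in range(next_block)]
            for g, b in zip(groups, assign):
                blocks[b].add(g)
            patterns.append(
                PatternSpec(id=f"S{len(patterns) + 1}", blocks=tuple(frozenset(b) for b in blocks))
            )
            return
        for b in range(next_block):
            grow(assign + [b], next_block)
        grow(assign + [next_block], next_block + 1)

    grow([], 0)
    return patterns


def preset_patterns(groups=SIX_GROUPS) -> list[PatternSpec]:
    """A curated set of interpretable six-condition patterns.

    These encode one reading of the qualitative pattern narratives (stable;
    uniform knockdown response; TET- or DNMT-modulated responses; altered
    basal level in hypomethylated cells); they are a convenience preset, not
    ground truth.
    """
    wt_c, wt_k, dn_c, dn_k, te_c, te_k = groups
    ctrl = frozenset({wt_c, dn_c, te_c})
    specs = [
        ("P0", (frozenset(groups),)),  # stable across everything
        ("P1", (ctrl, frozenset({wt_k, dn_k, te_k}))),  # uniform kd response
        ("P2", (ctrl, frozenset({wt_k, dn_k}), frozenset({te_k}))),  # kd response differs in TET TKO
        ("P3", (frozenset({wt_c, te_c}), frozenset({dn_c}), frozenset({wt_k, dn_k, te_k}))),
        ("P4", (frozenset({wt_c, dn_c, te_c, te_k}), frozenset({wt_k, dn_k}))),  # response lost in TET TKO
        ("P5", (ctrl, frozenset({wt_k, te_k}), frozenset({dn_k}))),  # kd response differs in DNMT TKO
    ]
    out = [PatternSpec(id=i, blocks=b) for i, b in specs]
    for p in out:
        p.validate(groups)
    return out


def min_reads_filter(counts: pd.DataFrame, min_total: int = 20) -> pd.DataFrame:
    """Drop low-coverage features (fewer than ``min_total`` reads in total)."""
    return counts.loc[counts.sum(axis=1) >= min_total]


# ---------------------------------------------------------------------------
# block marginal
# ---------------------------------------------------------------------------

def gg_block_marginal_loglik(x, hyper: GGHyper) -> float:
    """Log marginal likelihood of one equal-mean block under the Gamma-Gamma model.

    With x_i ~ Gamma(alpha, beta) i.i.d. and beta ~ Gamma(a0, nu) integrated
    out analytically.  An empty block has marginal 1 (log 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    if (x <= 0).any():
        raise ValueError("block values must be strictly positive")
    n = x.size
    a, a0, nu = hyper.alpha, hyper.a0, hyper.nu
    return float(
        (a - 1.0) * np.log(x).sum()
        - n * gammaln(a)
        + a0 * np.log(nu)
        + gammaln(a0 + n * a)
        - gammaln(a0)
        - (a0 + n * a) * np.log(nu + x.sum())
    )


class _SuffStats:
    """Per-feature sufficient statistics for every distinct block in a pattern set."""

    def __init__(self, expr: pd.DataFrame, groups: pd.Series, patterns: list[PatternSpec]):
        groups = pd.Series(groups)
        x = expr.to_numpy(dtype=float)
        if (x <= 0).any():
            raise ValueError("the Gamma-Gamma model needs strictly positive expression values")
        blocks = sorted({b for p in patterns for b in p.blocks}, key=lambda b: sorted(b))
        self.block_index = {b: i for i, b in enumerate(blocks)}
        n_feat, n_blk = x.shape[0], len(blocks)
        self.n_obs = np.zeros(n_blk)
        self.sum_x = np.zeros((n_feat, n_blk))
        self.sum_logx = np.zeros((n_feat, n_blk))
        logx = np.log(x)
        for b, i in self.block_index.items():
            cols = [j for j, s in enumerate(expr.columns) if groups[s] in b]
            if not cols:
                raise ValueError(f"no samples for block {sorted(b)}")
            self.n_obs[i] = len(cols)
            self.sum_x[:, i] = x[:, cols].sum(axis=1)
            self.sum_logx[:, i] = logx[:, cols].sum(axis=1)
        # pattern membership: patterns x blocks incidence
        self.membership = np.zeros((len(patterns), n_blk))
        for pi_, p in enumerate(patterns):
            for b in p.blocks:
                self.membership[pi_, self.block_index[b]] = 1.0

    def pattern_loglik(self, alpha: float, a0: float, nu: float) -> np.ndarray:
        """Features x patterns log likelihood matrix."""
        n = self.n_obs[None, :]
        block_ll = (
            (alpha - 1.0) * self.sum_logx
            - n * gammaln(alpha)
            + a0 * np.log(nu)
            + gammaln(a0 + n * alpha)
            - gammaln(a0)
            - (a0 + n * alpha) * np.log(nu + self.sum_x)
        )
        return block_ll @ self.membership.T


def _observed_loglik(stats_: _SuffStats, alpha, a0, nu, log_pi) -> float:
    ll = stats_.pattern_loglik(alpha, a0, nu) + log_pi[None, :]
    return float(logsumexp(ll, axis=1).sum())


def _moment_init(expr: pd.DataFrame, groups: pd.Series) -> GGHyper:
    """Method-of-moments start: alpha from within-group replicate dispersion,
    a0 = 2, nu = a0 / mean(x)."""
    groups = pd.Series(groups)
    shapes = []
    for g in pd.unique(groups):
        cols = [s for s in expr.columns if groups[s] == g]
        if len(cols) < 2:
            continue
        sub = expr[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = v > 0
        shapes.extend((m[ok] ** 2 / v[ok]).tolist())
    alpha = float(np.median(shapes)) if shapes else 1.0
    alpha = min(max(alpha, 0.1), 1e4)
    a0 = 2.0
    nu = a0 / float(expr.to_numpy().mean())
    return GGHyper(alpha=alpha, a0=a0, nu=nu)


def fit_gg_em(
    expr: pd.DataFrame,
    groups: pd.Series | dict,
    patterns: list[PatternSpec],
    init: GGHyper | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[GGHyper, pd.DataFrame, list[float]]:
    """Fit the Gamma-Gamma pattern mixture by EM.

    E-step: responsibilities r_gp proportional to pi_p times the product of
    block marginals.  M-step: pi_p = mean responsibility; (alpha, a0, nu) by
    Nelder-Mead maximization of the observed marginal log-likelihood in
    log-parameter space (accepted only when it improves, so the trace is
    monotone non-decreasing).  Stops when the relative log-likelihood change
    drops below ``tol``.

    Returns (fitted hyperparameters, responsibilities, log-likelihood trace).
    """
    groups = pd.Series(groups)
    ss = _SuffStats(expr, groups, patterns)
    hyper = init or _moment_init(expr, groups)
    n_pat = len(patterns)
    pi = hyper.pi if len(hyper.pi) == n_pat else np.full(n_pat, 1.0 / n_pat)
    theta = np.log([hyper.alpha, hyper.a0, hyper.nu])

    def log_pi_of(p):
        with np.errstate(divide="ignore"):
            return np.log(p)

    trace: list[float] = []
    resp = np.full((expr.shape[0], n_pat), 1.0 / n_pat)
    for it in range(max_iter):
        # E-step
        ll_mat = ss.pattern_loglik(*np.exp(theta)) + log_pi_of(pi)[None, :]
        norm = logsumexp(ll_mat, axis=1)
        resp = np.exp(ll_mat - norm[:, None])
        # M-step: mixture weights
        pi = resp.mean(axis=0)
        lp = log_pi_of(pi)
        current = _observed_loglik(ss, *np.exp(theta), lp)

        def neg(th):
            a, a0, nu = np.exp(th)
            return -_observed_loglik(ss, a, a0, nu, lp)

        res = optimize.minimize(neg, theta, method="Nelder-Mead",
                                options={"maxiter": 200, "xatol": 1e-6, "fatol": 1e-9})
        if -res.fun >= current:
            theta = res.x
            current = -res.fun
        trace.append(current)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * max(1.0, abs(trace[-2])):
            break
    else:
        warnings.warn("EM did not converge within max_iter; returning last iterate")

    alpha, a0, nu = np.exp(theta)
    fitted = GGHyper(alpha=float(alpha), a0=float(a0), nu=float(nu), pi=pi / pi.sum())
    resp_df = pd.DataFrame(resp, index=expr.index, columns=[p.id for p in patterns])
    return fitted, resp_df, trace


def assign_patterns(
    expr: pd.DataFrame,
    groups: pd.Series | dict,
    hyper: GGHyper,
    patterns: list[PatternSpec],
) -> PatternAssignment:
    """Posterior pattern probabilities per feature and the posterior-best pattern.

    Ties (identical posteriors) break toward the earlier pattern in the
    supplied (canonical) order, which is logged when it happens.
    """
    groups = pd.Series(groups)
    ss = _SuffStats(expr, groups, patterns)
    pi = hyper.pi if len(hyper.pi) == len(patterns) else np.full(len(patterns), 1.0 / len(patterns))
    with np.errstate(divide="ignore"):
        ll = ss.pattern_loglik(hyper.alpha, hyper.a0, hyper.nu) + np.log(pi)[None, :]
    post = np.exp(ll - logsumexp(ll, axis=1)[:, None])
    best_idx = post.argmax(axis=1)  # argmax takes the first maximum: canonical tie-break
    n_ties = int((np.abs(post - post.max(axis=1, keepdims=True)) < 1e-15).sum(axis=1).max() > 1)
    if n_ties:
        log.info("posterior ties broken toward canonical pattern order")
    ids = [p.id for p in patterns]
    return PatternAssignment(
        posterior=pd.DataFrame(post, index=expr.index, columns=ids),
        best_pattern=pd.Series([ids[i] for i in best_idx], index=expr.index, name="best_pattern"),
    )


# ---------------------------------------------------------------------------
# family over-representation
# ---------------------------------------------------------------------------

def family_enrichment(assignment: PatternAssignment, family_labels: pd.Series) -> pd.DataFrame:
    """Hypergeometric over-representation of each repeat family in each pattern.

    For a family of size K among N classified features, with n features in a
    pattern of which k belong to the family: p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).  Raw p-values (no multiplicity adjustment,
    matching heatmap display) plus the fold over-representation (k/n)/(K/N).
    """
    fam = family_labels.loc[assignment.best_pattern.index]
    if fam.isna().any():
        raise ValueError("every feature needs a family label")
    N = len(fam)
    rows = []
    for pattern in assignment.posterior.columns:
        in_pat = assignment.best_pattern == pattern
        n = int(in_pat.sum())
        for family, K in fam.value_counts().items():
            k = int((in_pat & (fam == family)).sum())
            if k > min(K, n):
                raise ValueError("inconsistent counts: k exceeds min(K, n)")
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            fold = (k / n) / (K / N) if n > 0 else np.nan
            rows.append(
                {"family": family, "pattern": pattern, "N": N, "K": int(K), "n": n, "k": k,
                 "p": p, "fold": fold}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heatmap ordering
# ---------------------------------------------------------------------------

def cluster_top_deregulated(
    expr: pd.DataFrame,
    de_table: pd.DataFrame,
    top_n: int = 5000,
):
    """Order the most deregulated features for heatmap display.

    Takes the ``top_n`` features with smallest adjusted p, clusters rows and
    columns by complete linkage under Pearson distance (1 - r), and returns
    (row_linkage, col_linkage, ordered expression matrix).  Constant rows have
    undefined correlation and are excluded with a warning.  Leaf order is
    deterministic: input rows are sorted by id before clustering.
    """
    if top_n > len(de_table):
        top_n = len(de_table)
    chosen = de_table["p_adj"].nsmallest(top_n).index
    sub = expr.loc[sorted(chosen)]
    const = sub.std(axis=1, ddof=0) == 0
    if const.any():
        warnings.warn(f"excluding {int(const.sum())} constant feature(s) with undefined correlation")
        sub = sub.loc[~const]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 non-constant features to cluster")

    def pearson_linkage(mat: np.ndarray):
        r = np.corrcoef(mat)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        from scipy.spatial.distance import squareform

        return hierarchy.linkage(squareform(d, checks=False), method="complete")

    row_link = pearson_linkage(sub.to_numpy(dtype=float))
    col_mat = sub.to_numpy(dtype=float).T
    col_const = col_mat.std(axis=1) == 0
    if col_const.any():
        raise ValueError("constant sample column: correlation undefined")
    col_link = pearson_linkage(col_mat)
    ordered = sub.iloc[hierarchy.leaves_list(row_link), :].iloc[:, hierarchy.leaves_list(col_link)]
    return row_link, col_link, ordered
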