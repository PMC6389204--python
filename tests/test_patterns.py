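"""Gamma-Gamma pattern model, family enrichment and heatmap clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import gammaln
from scipy.cluster import hierarchy

from tekit.patterns import (
    GGHyper,
    PatternSpec,
    SIX_GROUPS,
    assign_patterns,
    cluster_top_deregulated,
    enumerate_patterns,
    family_enrichment,
    fit_gg_em,
    gg_block_marginal_loglik,
    min_reads_filter,
    preset_patterns,
)
from tekit.simulate import simulate_gg_expression


def groups_of(columns):
    return pd.Series({c: c.rsplit(".r", 1)[0] for c in columns})


class TestEnumeratePatterns:
    def bell(self, n):
        # Bell-triangle recurrence oracle: Bell(n) is the head of triangle row n
        row = [1]
        for _ in range(n):
            new = [row[-1]]
            for v in row:
                new.append(new[-1] + v)
            row = new
        return row[0]

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 6])
    def test_counts_match_bell_numbers(self, n):
        groups = [f"g{i}" for i in range(n)]
        pats = enumerate_patterns(groups)
        assert len(pats) == self.bell(n)
        for p in pats:
            p.validate(groups)
        # no duplicates
        assert len({p.blocks for p in pats}) == len(pats)

    def test_six_groups_give_203_partitions(self):
        assert len(enumerate_patterns(SIX_GROUPS)) == 203

    def test_user_list_validated(self):
        bad = PatternSpec(id="X", blocks=(frozenset({"a"}),))
        with pytest.raises(ValueError):
            enumerate_patterns(["a", "b"], mode="user_list", user_list=[bad])

    def test_preset_patterns_are_valid_partitions(self):
        for p in preset_patterns():
            p.validate(SIX_GROUPS)


def quadrature_marginal(x, hyper):
    """Independent oracle: numerically integrate the Gamma likelihood over the
    Gamma prior on the rate.  The log-integrand is factored at its mode and
    the integral split there, so sharply peaked cases stay accurate."""
    x = np.asarray(x, dtype=float)
    n, a, a0, nu = len(x), hyper.alpha, hyper.a0, hyper.nu
    const = (a - 1) * np.log(x).sum() - n * gammaln(a) + a0 * np.log(nu) - gammaln(a0)
    shape, rate = n * a + a0 - 1, nu + x.sum()

    def logf(beta):
        return shape * np.log(beta) - beta * rate + const

    mode = max(shape, 1e-6) / rate
    peak = logf(mode)

    def integrand(beta):
        return np.exp(logf(beta) - peak)

    lo, _ = integrate.quad(integrand, 0, mode, limit=400)
    hi, _ = integrate.quad(integrand, mode, np.inf, limit=400)
    return np.log(lo + hi) + peak


class TestBlockMarginal:
    def test_empty_block_has_log_marginal_zero(self):
        assert gg_block_marginal_loglik([], GGHyper(alpha=2, a0=3, nu=1)) == 0.0

    def test_unit_hyper_single_observation_closed_form(self):
        # alpha=a0=nu=1, x={1}: integral of beta * exp(-2 beta) = 1/4
        got = gg_block_marginal_loglik([1.0], GGHyper(alpha=1, a0=1, nu=1))
        assert got == pytest.approx(np.log(0.25), abs=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            gg_block_marginal_loglik([1.0, 0.0], GGHyper(alpha=1, a0=1, nu=1))

    def test_matches_quadrature_on_random_cases(self, rng):
        for _ in range(25):
            hyper = GGHyper(alpha=float(rng.uniform(0.5, 20)), a0=float(rng.uniform(0.5, 10)),
                            nu=float(rng.uniform(0.1, 5)))
            x = rng.gamma(2.0, 2.0, size=int(rng.integers(1, 8))) + 0.05
            got = gg_block_marginal_loglik(x, hyper)
            assert got == pytest.approx(quadrature_marginal(x, hyper), rel=1e-6)


class TestEmFit:
    def test_loglik_trace_monotone_and_init_at_truth_is_fixed_point(self):
        pattern = PatternSpec(id="ONE", blocks=(frozenset(SIX_GROUPS),))
        x = simulate_gg_expression(800, pattern, alpha=10, a0=5, nu=0.5, seed=21)
        truth = GGHyper(alpha=10, a0=5, nu=0.5)
        hyper, _, trace = fit_gg_em(x, groups_of(x.columns), [pattern], init=truth)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        # starting at the generating values moves the log-likelihood very little
        assert abs(trace[-1] - trace[0]) < 1e-4 * abs(trace[0])

    def test_nonpositive_expression_rejected(self):
        x = pd.DataFrame(np.zeros((2, 18)), columns=[f"{g}.r{r}" for g in SIX_GROUPS for r in (1, 2, 3)])
        with pytest.raises(ValueError):
            fit_gg_em(x, groups_of(x.columns), [PatternSpec(id="ONE", blocks=(frozenset(SIX_GROUPS),))])

    def test_mixture_weights_concentrate_on_used_patterns(self):
        split = PatternSpec(id="SPLIT", blocks=(
            frozenset({"WT.ctrl", "DNMT.ctrl", "TET.ctrl"}), frozenset({"WT.kd", "DNMT.kd", "TET.kd"})))
        x = simulate_gg_expression(600, split, alpha=10, a0=5, nu=0.5, seed=22)
        specs = [PatternSpec(id="ONE", blocks=(frozenset(SIX_GROUPS),)), split]
        hyper, resp, _ = fit_gg_em(x, groups_of(x.columns), specs)
        assert hyper.pi[1] > 0.9


class TestAssignPatterns:
    def test_single_candidate_gets_posterior_one(self):
        pattern = PatternSpec(id="ONE", blocks=(frozenset(SIX_GROUPS),))
        x = simulate_gg_expression(10, pattern, seed=1)
        out = assign_patterns(x, groups_of(x.columns), GGHyper(alpha=10, a0=5, nu=0.5), [pattern])
        np.testing.assert_allclose(out.posterior["ONE"], 1.0)

    def test_posteriors_sum_to_one(self):
        pattern = PatternSpec(id="ONE", blocks=(frozenset(SIX_GROUPS),))
        x = simulate_gg_expression(50, pattern, seed=2)
        specs = preset_patterns()
        hyper = GGHyper(alpha=10, a0=5, nu=0.5, pi=np.full(len(specs), 1 / len(specs)))
        out = assign_patterns(x, groups_of(x.columns), hyper, specs)
        np.testing.assert_allclose(out.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_well_separated_two_block_data_prefers_split_pattern(self):
        cols = ["a.r1", "a.r2", "a.r3", "b.r1", "b.r2", "b.r3"]
        x = pd.DataFrame([[1.0, 1.1, 0.9, 100.0, 105.0, 95.0]], columns=cols, index=["f"])
        groups = pd.Series({c: c.split(".")[0] for c in cols})
        one = PatternSpec(id="ONE", blocks=(frozenset({"a", "b"}),))
        split = PatternSpec(id="SPLIT", blocks=(frozenset({"a"}), frozenset({"b"})))
        hyper = GGHyper(alpha=10, a0=2, nu=1.0, pi=np.array([0.5, 0.5]))
        out = assign_patterns(x, groups, hyper, [one, split])
        assert out.posterior.loc["f", "SPLIT"] > 0.99
        assert out.best_pattern["f"] == "SPLIT"


def exhaustive_hypergeom_upper_tail(N, K, n, k):
    """Enumerate all C(N, n) draws by composition counting with math.comb."""
    total = math.comb(N, n)
    favourable = sum(math.comb(K, j) * math.comb(N - K, n - j)
                     for j in range(k, min(K, n) + 1))
    return favourable / total


class TestFamilyEnrichment:
    def make_assignment(self, patterns_per_feature):
        idx = [f"f{i}" for i in range(len(patterns_per_feature))]
        post = pd.get_dummies(pd.Series(patterns_per_feature, index=idx)).astype(float)
        return type("A", (), {"posterior": post, "best_pattern": pd.Series(patterns_per_feature, index=idx)})()

    def test_reference_urn(self):
        # N=10 features, family of 4, pattern holds 5, all 4 family members inside
        patterns = ["P1"] * 5 + ["P2"] * 5
        families = ["fam"] * 4 + ["other"] * 6
        assignment = self.make_assignment(patterns)
        fam = pd.Series(families, index=assignment.best_pattern.index)
        out = family_enrichment(assignment, fam).set_index(["family", "pattern"])
        got = out.loc[("fam", "P1"), "p"]
        assert got == pytest.approx(6 / 252, abs=1e-12)
        assert got == pytest.approx(exhaustive_hypergeom_upper_tail(10, 4, 5, 4), abs=1e-12)

    def test_zero_members_in_pattern_gives_p_one(self):
        assignment = self.make_assignment(["P1"] * 3 + ["P2"] * 3)
        fam = pd.Series(["fam"] * 3 + ["other"] * 3, index=assignment.best_pattern.index)
        out = family_enrichment(assignment, fam).set_index(["family", "pattern"])
        assert out.loc[("fam", "P2"), "p"] == pytest.approx(1.0)
        assert out.loc[("fam", "P2"), "k"] == 0

    def test_family_spanning_all_features_gives_p_one(self):
        assignment = self.make_assignment(["P1", "P1", "P2"])
        fam = pd.Series(["only"] * 3, index=assignment.best_pattern.index)
        out = family_enrichment(assignment, fam)
        np.testing.assert_allclose(out["p"], 1.0)


class TestClusterTopDeregulated:
    def de_table(self, index):
        return pd.DataFrame({"p_adj": np.linspace(0.001, 0.5, len(index))}, index=index)

    def test_identical_rows_merge_at_distance_zero(self, rng):
        base = rng.normal(size=8)
        x = pd.DataFrame([base, base, rng.normal(size=8) + 5], index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(8)])
        row_link, _, _ = cluster_top_deregulated(x, self.de_table(x.index), top_n=3)
        assert row_link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_row_and_its_negation_merge_at_distance_two(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        x = pd.DataFrame([v, -v, v * 2 + 1], index=["a", "b", "c"], columns=list("wxyz"))
        row_link, _, _ = cluster_top_deregulated(x, self.de_table(x.index), top_n=3)
        assert row_link[:, 2].max() == pytest.approx(2.0, abs=1e-12)

    def test_constant_row_excluded_with_warning(self, rng):
        x = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"),
                         columns=[f"s{i}" for i in range(6)])
        x.loc["a"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            _, _, ordered = cluster_top_deregulated(x, self.de_table(x.index), top_n=4)
        assert "a" not in ordered.index

    def test_merge_heights_match_naive_complete_linkage(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 10)), index=[f"f{i:02d}" for i in range(20)],
                         columns=[f"s{i}" for i in range(10)])
        row_link, _, _ = cluster_top_deregulated(x, self.de_table(x.index), top_n=20)
        # O(n^3) naive agglomeration oracle on the same Pearson distance
        d = 1 - np.corrcoef(x.to_numpy())
        clusters = [[i] for i in range(20)]
        heights = []
        while len(clusters) > 1:
            best = (np.inf, None, None)
            for i, j in itertools.combinations(range(len(clusters)), 2):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, i, j)
            h, i, j = best
            heights.append(h)
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
        np.testing.assert_allclose(np.sort(row_link[:, 2]), np.sort(heights), atol=1e-10)


def test_min_reads_filter_boundary():
    counts = pd.DataFrame({"a": [10, 10], "b": [10, 9]}, index=["keep", "drop"])
    kept = min_reads_filter(counts, 20)
    assert list(kept.index) == ["keep"]
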