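"""Tests of the cohort statistics: routing, exact tests, power.

The exact-test checks compare the implementation against independent
enumeration oracles written here (rank-assignment enumeration for
Mann-Whitney, hypergeometric table enumeration for Fisher, the closed
2x2 form for chi-square).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ffmf import (
    PowerSpec,
    binarize_by_median,
    build_comparison_table,
    dichotomous_test,
    mann_whitney_u,
    normality_route,
    spearman,
    student_t,
    t_test_power,
)
from ffmf.stats import format_percent


# -- independent oracles -----------------------------------------------------

def mw_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    u_min = min(u_obs, n1 * len(y) - u_obs)
    return np.mean((us <= u_min) | (us >= n1 * len(y) - u_min))


def fisher_exact_oracle(table):
    """Two-sided Fisher p: sum over tables (fixed margins) whose
    hypergeometric probability is <= that of the observed table."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    pmf = sps.hypergeom(n, r1, c1).pmf
    p_obs = pmf(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(aa)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def chi2_2x2_closed_form(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


# -- median split ------------------------------------------------------------

class TestBinarize:
    def test_even_split(self):
        labels, cutoff = binarize_by_median([60, 70, 80, 90])
        assert cutoff == 75
        assert list(labels) == ["low", "low", "high", "high"]

    def test_tie_at_median_goes_high(self):
        labels, cutoff = binarize_by_median([60, 70, 80])
        assert cutoff == 70
        assert list(labels) == ["low", "high", "high"]

    def test_group_sizes_balanced_up_to_ties(self):
        rng = np.random.default_rng(5)
        x = rng.normal(70, 10, size=66)
        labels, cutoff = binarize_by_median(x)
        n_ties = int(np.sum(x == cutoff))
        n_low = int(np.sum(labels == "low"))
        n_high = int(np.sum(labels == "high"))
        assert abs(n_low - n_high) <= max(n_ties, 1)
        assert n_low == int(np.sum(x < cutoff))

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            binarize_by_median([5.0, 5.0, 5.0])


# -- routing -----------------------------------------------------------------

class TestRouting:
    def test_normal_samples_route_to_t(self):
        rng = np.random.default_rng(1)
        assert normality_route(rng.normal(size=200), rng.normal(size=200)) == "t"

    def test_two_point_sample_routes_to_mannwhitney(self):
        rng = np.random.default_rng(1)
        x = rng.choice([0.0, 1.0], size=50)
        assert normality_route(x, rng.normal(size=50)) == "mannwhitney"

    def test_small_group_is_an_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            normality_route([1.0, 2.0], [1.0, 2.0, 3.0])


# -- t test ------------------------------------------------------------------

class TestStudentT:
    def test_identical_samples(self):
        t, df, p = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == 1 and df == 4

    def test_strong_separation(self):
        t, _, p = student_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(t) > 5 and p < 0.001

    def test_zero_variance_unequal_means_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            student_t([1.0, 1.0], [2.0, 2.0])

    def test_moment_matched_summary_equivalence(self):
        """Raw samples constructed to given moments reproduce the textbook
        summary-statistic t (platelet-count-style comparison, n=33 each)."""
        def construct(mean, sd, n, seed):
            z = np.random.default_rng(seed).normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        m1, s1, m2, s2, n = 207.0, 59.0, 254.0, 112.0, 33
        x, y = construct(m1, s1, n, 0), construct(m2, s2, n, 1)
        t_raw, df, p_raw = student_t(x, y)
        sp2 = ((n - 1) * s1**2 + (n - 1) * s2**2) / (2 * n - 2)
        t_summary = (m1 - m2) / math.sqrt(sp2 * (2 / n))
        assert t_raw == pytest.approx(t_summary, rel=1e-10)
        assert p_raw < 0.05  # the separation is detectable at this n


# -- Mann-Whitney ------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation_small_n(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 rank assignments as extreme

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney_u(x, x)
        assert p > 0.99

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (2, 5), (4, 4), (3, 5)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        """Exact p equals full rank-assignment enumeration (ties-free)."""
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        """At n1=n2=12 (asymptotic regime) the normal approximation with
        continuity correction stays within 0.02 of the exact enumeration."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            x = rng.normal(size=12)
            y = rng.normal(0.5, 1.0, size=12)
            _, p_impl = mann_whitney_u(x, y)  # asymptotic branch (n=24)
            p_exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p_impl == pytest.approx(p_exact, abs=0.02)


# -- dichotomous -------------------------------------------------------------

class TestDichotomous:
    def test_chi2_closed_form_value(self):
        """[[24, 9], [9, 24]] gives the closed-form chi-square 13.64."""
        name, stat, oratio, p = dichotomous_test([[24, 9], [9, 24]])
        assert name == "chi2"
        assert stat == pytest.approx(13.636363636, abs=1e-9)
        assert round(stat, 2) == 13.64

    def test_fisher_small_counts(self):
        """[[3, 0], [0, 3]]: only 2 of the 20 equally-likely tables are as
        extreme -> p = 0.1; zero cells trigger the Haldane odds ratio."""
        name, _, oratio, p = dichotomous_test([[3, 0], [0, 3]])
        assert name == "fisher"
        assert p == pytest.approx(0.1)
        assert oratio == 49.0  # (3.5 * 3.5) / (0.5 * 0.5)

    def test_independence(self):
        name, stat, oratio, p = dichotomous_test([[10, 10], [10, 10]])
        assert p == pytest.approx(1.0) and oratio == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            dichotomous_test([[0, 0], [3, 4]])

    def test_expected_count_rule_selects_test(self):
        # min expected = 30*30/60 = 15 > 5 -> chi2
        assert dichotomous_test([[20, 10], [10, 20]])[0] == "chi2"
        # min expected = 8*10/20 = 4 <= 5 -> fisher
        assert dichotomous_test([[2, 6], [8, 4]])[0] == "fisher"

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 5, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            name, _, _, p = dichotomous_test(t)
            if name == "fisher":
                assert p == pytest.approx(fisher_exact_oracle(t.tolist()), abs=1e-10)

    def test_chi2_matches_closed_form_everywhere(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(8, 40, size=(2, 2))
            name, stat, _, _ = dichotomous_test(t)
            assert name == "chi2"
            assert stat == pytest.approx(chi2_2x2_closed_form(t.tolist()), abs=1e-10)


# -- Spearman ----------------------------------------------------------------

class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -np.exp(x / 3))[0] == pytest.approx(-1.0)

    def test_formula_oracle_ties_free(self):
        """rho equals 1 - 6*sum(d^2)/(n(n^2-1)) on ties-free data."""
        rng = np.random.default_rng(8)
        x = rng.permutation(np.arange(1.0, 13.0))
        y = rng.normal(size=12)
        rho, _ = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        d2 = np.sum((rx - ry) ** 2)
        n = len(x)
        assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# -- power -------------------------------------------------------------------

class TestPower:
    def test_null_effect_gives_alpha(self):
        assert t_test_power(PowerSpec(0.0, 25, alpha=0.05)) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_effect_and_n(self):
        powers_d = [t_test_power(PowerSpec(d, 30)) for d in (0.2, 0.4, 0.6, 0.8)]
        assert all(a < b for a, b in zip(powers_d, powers_d[1:]))
        powers_n = [t_test_power(PowerSpec(0.5, n)) for n in (10, 20, 40, 80)]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))

    def test_analytic_matches_monte_carlo(self):
        """Noncentral-t power within 0.01 of simulation at d=0.5, n=20."""
        d, n, alpha, reps = 0.5, 20, 0.05, 20_000
        rng = np.random.default_rng(123)
        x = rng.normal(0.0, 1.0, size=(reps, n))
        y = rng.normal(d, 1.0, size=(reps, n))
        sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2
        t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(sp2 * 2 / n)
        tcrit = sps.t.ppf(1 - alpha / 2, 2 * n - 2)
        mc = np.mean(np.abs(t) > tcrit)
        assert t_test_power(PowerSpec(d, n, alpha)) == pytest.approx(mc, abs=0.01)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PowerSpec(0.5, 1)
        with pytest.raises(ValueError):
            PowerSpec(0.5, 10, alpha=1.5)


# -- table rendering & routing ----------------------------------------------

class TestComparisonTable:
    def test_percent_rendering(self):
        assert format_percent(24, 33) == "24 (73%)"
        assert format_percent(52, 66) == "52 (79%)"
        assert format_percent(12, 33) == "12 (36%)"

    def test_identical_column_p_is_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=66)
        df = pd.DataFrame({"g": ["a"] * 33 + ["b"] * 33, "v": np.concatenate([v[:33], v[:33]])})
        rows = build_comparison_table(df, "g", continuous=["v"])
        assert rows[0].p_value == pytest.approx(1.0)

    def test_planted_difference_is_detected(self):
        """A 1.5-pooled-SD group difference at n=33/group is significant at
        p < 0.001 in at least 95% of seeded replicates."""
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "g": ["a"] * 33 + ["b"] * 33,
                    "v": np.concatenate(
                        [rng.normal(0, 1, 33), rng.normal(1.5, 1, 33)]
                    ),
                }
            )
            rows = build_comparison_table(df, "g", continuous=["v"])
            hits += rows[0].p_value < 0.001
        assert hits / reps >= 0.95

    def test_dichotomous_summary_format(self):
        df = pd.DataFrame(
            {"g": ["low"] * 33 + ["high"] * 33,
             "af": [1] * 24 + [0] * 9 + [1] * 9 + [0] * 24}
        )
        rows = build_comparison_table(df, "g", dichotomous=["af"], group_order=("low", "high"))
        assert rows[0].summary_a == "24 (73%)"
        assert rows[0].summary_b == "9 (27%)"
        assert rows[0].test == "chi2"

    def test_grouping_must_be_binary(self):
        df = pd.DataFrame({"g": ["a", "b", "c"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="two levels"):
            build_comparison_table(df, "g", continuous=["v"])


class TestTypeIError:
    def test_null_cohort_false_positive_rate(self):
        """With no planted group differences (beta = 0, no AF link), the
        fraction of comparison-table variables significant at 0.05 across
        500 simulated cohorts stays within [0.03, 0.07] — the discrete
        Fisher comparisons are slightly conservative, the rest nominal."""
        from ffmf import CohortSpec, generate_cohort
        from ffmf.pipeline import CONTINUOUS_VARS, DICHOTOMOUS_VARS

        sig = tot = 0
        for seed in range(500):
            cohort, _ = generate_cohort(
                CohortSpec(
                    n_patients=66, beta_mrs_per_ffmf=0.0,
                    af_ffmf_association=0.0, seed=seed,
                )
            )
            labels, _ = binarize_by_median(cohort.ffmf_percent.to_numpy())
            cohort = cohort.assign(g=labels)
            rows = build_comparison_table(
                cohort, "g", continuous=CONTINUOUS_VARS,
                dichotomous=DICHOTOMOUS_VARS, group_order=("low", "high"),
            )
            sig += sum(r.p_value < 0.05 for r in rows)
            tot += len(rows)
        assert 0.03 <= sig / tot <= 0.07
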