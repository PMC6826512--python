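"""Rank/permutation statistics against brute force and SciPy oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from indivevol.core import categorize_clock
from indivevol.stats import (
    chisq_permutation,
    kruskal_wallis,
    mann_whitney,
    midranks,
    rho_from_S,
    run_trait_contrasts,
    spearman,
)


def brute_force_u(x, y):
    """O(n1*n2) pair-counting oracle with the 0.5 tie rule."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


class TestMannWhitney:
    def test_table4_bias_contrast(self, table4):
        df = table4.df
        biased = df[df["sex_biased"].astype(bool)]["rate"].to_numpy()
        unbiased = df[~df["sex_biased"].astype(bool)]["rate"].to_numpy()
        res = mann_whitney(biased, unbiased)
        assert res.n_per_group == (7, 34)
        assert res.statistics["U_min"] == 52.0

    def test_table4_duplication_contrast(self, table4):
        df = table4.df
        dup = df[df["duplicated"].astype(bool)]["rate"].to_numpy()
        single = df[~df["duplicated"].astype(bool)]["rate"].to_numpy()
        res = mann_whitney(dup, single)
        assert res.n_per_group == (15, 26)
        assert res.statistics["U_min"] == 183.0

    def test_identical_samples_fully_tied(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistics["U_x"] == res.statistics["U_y"] == 4.5

    def test_u_sum_invariant_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(1, 12, 2)
            x = rng.integers(0, 6, n1).astype(float)  # many ties
            y = rng.integers(0, 6, n2).astype(float)
            res = mann_whitney(x, y)
            assert res.statistics["U_x"] + res.statistics["U_y"] == pytest.approx(n1 * n2)
            assert res.statistics["U_x"] == pytest.approx(brute_force_u(x, y))

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n1, n2 = rng.integers(2, 9, 2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney(x, y)
            assert res.p_method == "exact"
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert res.statistics["U_x"] == ref.statistic

    def test_normal_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 8, 25).astype(float)
        y = rng.integers(0, 8, 30).astype(float)
        res = mann_whitney(x, y)
        assert res.p_method == "normal_approx"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_close_to_normal_for_moderate_n(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=9)
        y = rng.normal(size=10)
        exact = mann_whitney(x, y).p_value
        # force the asymptotic route by scaling past the exact-size cap
        big = mann_whitney(np.repeat(x, 6), np.repeat(y, 6))
        assert big.p_method == "normal_approx"
        ref = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(exact - ref) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_matches_scipy_three_groups(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=5) for _ in range(3)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistics["H"] == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_matches_midrank_formula_oracle(self):
        rng = np.random.default_rng(9)
        groups = [rng.integers(0, 5, 5).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups)
        # direct recomputation from midranks
        pooled = np.concatenate(groups)
        r = midranks(pooled)
        n = len(pooled)
        start, h = 0, 0.0
        for g in groups:
            rg = r[start : start + len(g)]
            h += len(g) * (rg.mean() - (n + 1) / 2) ** 2
            start += len(g)
        h *= 12 / (n * (n + 1))
        ties = np.unique(pooled, return_counts=True)[1]
        h /= 1 - ((ties**3 - ties).sum()) / (n**3 - n)
        assert res.statistics["H"] == pytest.approx(h)

    def test_two_groups_consistent_with_mann_whitney(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(size=15)
        h = kruskal_wallis([x, y]).statistics["H"]
        res = mann_whitney(x, y)
        n1, n2 = 12, 15
        mean_u = n1 * n2 / 2
        var_u = n1 * n2 * (n1 + n2 + 1) / 12
        z = (res.statistics["U_x"] - mean_u) / np.sqrt(var_u)
        assert h == pytest.approx(z**2, abs=1e-6)

    def test_all_identical_values(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistics["H"] == 0.0 and res.p_value == 1.0


class TestSpearman:
    def test_perfect_concordance(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistics["rho"] == pytest.approx(1.0)
        assert res.statistics["S"] == pytest.approx(0.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=19), rng.normal(size=19)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistics["rho"] == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_s_rho_identity_always_holds(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(3, 25))
            x = rng.integers(0, 10, n).astype(float)
            y = rng.integers(0, 10, n).astype(float)
            try:
                res = spearman(x, y)
            except ValueError:
                continue
            assert res.statistics["rho"] == pytest.approx(
                rho_from_S(res.statistics["S"], n), abs=1e-9
            )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @pytest.mark.parametrize(
        "S, n, rho",
        [
            (0.0, 10, 1.0),
            (712.6, 19, 0.3749),
            (956.6, 19, 0.1609),
            (1340.0, 19, -0.1754),
            (1054.0, 19, 0.0754),
            (1115.3, 21, 0.2758),
            (770.5, 21, 0.4997),
            (1520.0, 21, 0.0130),
            (1180.0, 21, 0.2338),
            (2127.7, 21, -0.3816),
            (1772.9, 21, -0.1512),
            (1368.7, 21, 0.1112),
            (1980.5, 21, -0.2860),
        ],
    )
    def test_published_s_rho_pairs(self, S, n, rho):
        assert rho_from_S(S, n) == pytest.approx(rho, abs=5e-5)


class TestChisqPermutation:
    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 3, 30)
        r1 = chisq_permutation(a, b, reps=499, seed=7)
        r2 = chisq_permutation(a, b, reps=499, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.statistics["chi2"] == r2.statistics["chi2"]

    def test_perfect_association_small_p(self):
        a = [0] * 10 + [1] * 10
        r = chisq_permutation(a, a, reps=9999, seed=1)
        assert r.p_value <= 0.01

    def test_observed_chi2_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        r = chisq_permutation(a, b, reps=99, seed=0)
        table = np.zeros((2, 2))
        np.add.at(table, (a, b), 1)
        ref = sps.chi2_contingency(table, correction=False)
        assert r.statistics["chi2"] == pytest.approx(ref.statistic)

    def test_single_level_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_permutation([0, 0, 0, 0], [0, 1, 0, 1], reps=99, seed=0)

    def test_add_one_estimator_never_zero(self):
        a = [0] * 15 + [1] * 15
        r = chisq_permutation(a, a, reps=999, seed=3)
        assert r.p_value >= 1 / 1000


class TestRunTraitContrasts:
    def test_table4_group_sizes(self, table4_clocked):
        out = run_trait_contrasts(
            table4_clocked,
            ["sex_biased", "duplicated", "in_network", "clock_like"],
            reps=199,
            seed=0,
        )
        sizes = {k: v.n_per_group for k, v in out["contrasts"].items()}
        assert sizes["sex_biased"] == (7, 34)
        assert sizes["duplicated"] == (15, 26)
        assert sizes["in_network"] == (19, 22)
        assert sizes["clock_like"] == (18, 23)
        assert len(out["independence"]) == 6  # all trait pairs

    def test_gene_lists_partition_the_table(self, table4_clocked):
        out = run_trait_contrasts(table4_clocked, ["sex_biased"], reps=99, seed=0)
        grp = out["groups"]["sex_biased"]
        assert len(grp["positive"]) + len(grp["negative"]) == 41

    def test_empty_level_skipped(self, table4_clocked):
        t = table4_clocked.with_columns(always_true=[True] * 41)
        out = run_trait_contrasts(t, ["always_true", "sex_biased"], reps=99, seed=0)
        assert "always_true" not in out["contrasts"]
        assert "sex_biased" in out["contrasts"]
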