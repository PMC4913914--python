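"""The three differential-expression tests and their consensus."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from progmark import diffexpr
from progmark.diffexpr import Thresholds
from progmark.synthetic import SimConfig, simulate_cohort

from conftest import make_matrix


def two_groups(n_a, n_b):
    return pd.Series(["a"] * n_a + ["b"] * n_b)


class TestWelchT:
    def test_identical_samples_give_t0_p1(self, rng):
        x = rng.normal(size=10)
        t, df, p = diffexpr.welch_t(x, x)
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(1, 2, size=rng.integers(3, 30))
            t, df, p = diffexpr.welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_cohort_mmse_summary_scale(self, rng):
        # raw data constructed to carry exactly the cognition-score
        # summaries 24.6 (SD 4.6, n 35) vs 27.5 (SD 2.9, n 35): the Welch
        # statistic must be ~3.16 with ~57.3 df
        def with_moments(mean, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        x = with_moments(24.6, 4.6, 35)
        y = with_moments(27.5, 2.9, 35)
        t, df, p = diffexpr.welch_t(x, y)
        assert abs(t) == pytest.approx(3.155, abs=0.005)
        assert df == pytest.approx(57.34, abs=0.05)

    def test_type_i_error_calibrated(self):
        # 10,000 null repetitions: rejection rate at alpha=.05 in [.045,.055]
        rng = np.random.default_rng(123)
        X = rng.normal(size=(10000, 8))
        Y = rng.normal(size=(10000, 8))
        t, _ = diffexpr._welch_from_moments(
            X.mean(1), X.var(1, ddof=1), 8, Y.mean(1), Y.var(1, ddof=1), 8
        )
        se2 = X.var(1, ddof=1) / 8 + Y.var(1, ddof=1) / 8
        df = se2**2 / ((X.var(1, ddof=1) / 8) ** 2 / 7
                       + (Y.var(1, ddof=1) / 8) ** 2 / 7)
        p = 2 * stats.t.sf(np.abs(t), df)
        assert 0.045 <= (p <= 0.05).mean() <= 0.055

    def test_degenerate_conventions(self):
        assert diffexpr.welch_t([1, 1, 1], [1, 1, 1])[2] == 1.0
        assert diffexpr.welch_t([1, 1, 1], [2, 2, 2])[2] == 0.0

    def test_rejects_single_value_group(self):
        with pytest.raises(ValueError):
            diffexpr.welch_t([1.0], [1.0, 2.0])


class TestAnovaF:
    def test_two_groups_equal_pooled_ttest(self, rng):
        m = make_matrix(rng.normal(size=(30, 12)))
        groups = two_groups(5, 7)
        p = diffexpr.anova_f(m, groups)
        ref = stats.ttest_ind(
            m.to_numpy()[:, :5], m.to_numpy()[:, 5:], axis=1, equal_var=True
        ).pvalue
        assert np.abs(p.to_numpy() - ref).max() < 1e-12

    def test_constant_row_gets_p1(self):
        m = make_matrix(np.ones((3, 8)))
        p = diffexpr.anova_f(m, two_groups(4, 4))
        assert (p == 1.0).all()

    def test_null_rejection_rate_within_binomial_ci(self, null_cohort):
        matrix, sheet, _ = null_cohort
        g = sheet.set_index("sample_id")["group"]
        p = diffexpr.anova_f(matrix, g)
        frac = (p <= 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / len(p))
        assert 0.05 - half <= frac <= 0.05 + half

    def test_power_on_planted_effects(self):
        # beta = 2 * noise_sd at n = 33/34: nearly every planted gene
        # clears p <= 0.05
        cfg = SimConfig(n_genes=1000, frac_de=0.1, effect_size=1.0,
                        noise_sd=0.5, batch_shift_sd=0.0, age_effect_sd=0.0,
                        gender_effect_sd=0.0, n_outliers=0, n_low_rin=0,
                        seed=21)
        matrix, sheet, truth = simulate_cohort(cfg)
        p = diffexpr.anova_f(matrix, sheet.set_index("sample_id")["group"])
        planted = sorted(truth.de_gene_ids)
        assert (p[planted] <= 0.05).sum() >= 95


class TestBootstrapTtest:
    def test_identical_groups_give_large_p(self):
        # group B's values duplicate group A's exactly: t_obs = 0
        m = make_matrix(np.tile(np.arange(3.0), (3, 2)))
        p = diffexpr.bootstrap_ttest(m, two_groups(3, 3), B=200, seed=0)
        assert (p >= 0.5).all()

    def test_huge_separation_hits_resolution_floor(self, rng):
        x = np.hstack([rng.normal(0, 1, 20), rng.normal(30, 1, 20)])
        m = make_matrix(x[None, :])
        B = 1000
        p = diffexpr.bootstrap_ttest(m, two_groups(20, 20), B=B, seed=1)
        assert p.iloc[0] == pytest.approx(1.0 / (B + 1))

    def test_null_rejection_rate_within_wide_band(self, null_cohort):
        matrix, sheet, _ = null_cohort
        g = sheet.set_index("sample_id")["group"]
        p = diffexpr.bootstrap_ttest(matrix, g, B=1000, seed=2)
        assert 0.035 <= (p <= 0.05).mean() <= 0.065

    def test_same_seed_identical_output(self, small_matrix):
        groups = two_groups(5, 5)
        p1 = diffexpr.bootstrap_ttest(small_matrix, groups, B=200, seed=5)
        p2 = diffexpr.bootstrap_ttest(small_matrix, groups, B=200, seed=5)
        assert p1.equals(p2)

    def test_rejects_tiny_b(self, small_matrix):
        with pytest.raises(ValueError, match="B"):
            diffexpr.bootstrap_ttest(small_matrix, two_groups(5, 5), B=50)


class TestPermutationTtest:
    def test_exhaustive_3v3_matches_brute_force(self, rng):
        # independent oracle: enumerate all C(6,3)=20 label assignments
        # with scalar Welch t per assignment
        for _ in range(10):
            X = rng.normal(size=(4, 6))
            m = make_matrix(X)
            p = diffexpr.permutation_ttest(m, two_groups(3, 3))
            for gi in range(4):
                row = X[gi]
                t_obs = abs(diffexpr.welch_t(row[:3], row[3:])[0])
                count = 0
                for comb in combinations(range(6), 3):
                    rest = [i for i in range(6) if i not in comb]
                    t = abs(diffexpr.welch_t(row[list(comb)], row[rest])[0])
                    count += t >= t_obs - 1e-12
                assert p.iloc[gi] == pytest.approx(count / 20, abs=1e-12)

    def test_maximally_separated_3v3_gives_one_tenth(self):
        m = make_matrix(np.array([[0.0, 0.1, 0.2, 10.0, 10.1, 10.2]]))
        p = diffexpr.permutation_ttest(m, two_groups(3, 3))
        assert p.iloc[0] == pytest.approx(0.1)

    def test_null_rejection_rate_within_binomial_ci(self, null_cohort):
        matrix, sheet, _ = null_cohort
        g = sheet.set_index("sample_id")["group"]
        p = diffexpr.permutation_ttest(matrix, g, B=1000, seed=3)
        frac = (p <= 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / len(p))
        assert 0.05 - half <= frac <= 0.05 + half

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        # fixed small dataset: |MC - exact| < 0.01 at B = 100,000
        m = make_matrix(rng.normal(size=(1, 8)) + np.array([[1.0] * 4 + [0.0] * 4]))
        groups = two_groups(4, 4)
        exact = diffexpr.permutation_ttest(m, groups, exhaustive=True)
        mc = diffexpr.permutation_ttest(m, groups, B=100_000, seed=4,
                                        exhaustive=False)
        assert abs(mc.iloc[0] - exact.iloc[0]) < 0.01

    def test_min_p_bounded_by_permutation_count(self, rng):
        m = make_matrix(np.array([[0, 0, 0, 9, 9, 9, 9.1, 9.2]], dtype=float))
        B = 500
        p = diffexpr.permutation_ttest(m, two_groups(3, 5), B=B,
                                       exhaustive=False, seed=5)
        assert p.iloc[0] >= 1.0 / (B + 1)

    def test_rejects_small_b_in_monte_carlo_mode(self, small_matrix):
        with pytest.raises(ValueError, match="B"):
            diffexpr.permutation_ttest(small_matrix, two_groups(5, 5), B=50,
                                       exhaustive=False)


class TestInvariances:
    @given(shift=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=20)
    def test_row_shift_invariance(self, shift):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(3, 10))
        groups = two_groups(5, 5)
        base = make_matrix(X)
        shifted = make_matrix(X + np.array([[shift], [0], [0]]))
        for fn in (
            lambda m: diffexpr.anova_f(m, groups),
            lambda m: diffexpr.bootstrap_ttest(m, groups, B=200, seed=0),
            lambda m: diffexpr.permutation_ttest(m, groups, seed=0),
        ):
            assert np.allclose(fn(base).to_numpy(), fn(shifted).to_numpy(),
                               atol=1e-9)

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(6, 12))
        groups = two_groups(6, 6)
        m = make_matrix(X)
        perm = list(rng.permutation(m.index))
        for fn in (
            lambda mm: diffexpr.anova_f(mm, groups),
            lambda mm: diffexpr.bootstrap_ttest(mm, groups, B=200, seed=1),
            lambda mm: diffexpr.permutation_ttest(mm, groups, B=200, seed=1,
                                                  exhaustive=False),
        ):
            assert np.allclose(fn(m).loc[perm].to_numpy(),
                               fn(m.loc[perm]).to_numpy(), atol=1e-12)

    def test_larger_effects_never_raise_mean_pvalues(self):
        # monotonicity in expectation: mean p over 20 seeds decreases as
        # the planted shift grows
        betas = [0.0, 0.6, 1.2]
        mean_ps = {"anova": [], "boot": [], "perm": []}
        for beta in betas:
            ps = {"anova": [], "boot": [], "perm": []}
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                x = rng.normal(size=12)
                x[6:] += beta
                m = make_matrix(x[None, :])
                groups = two_groups(6, 6)
                ps["anova"].append(diffexpr.anova_f(m, groups).iloc[0])
                ps["boot"].append(
                    diffexpr.bootstrap_ttest(m, groups, B=200, seed=seed).iloc[0]
                )
                ps["perm"].append(
                    diffexpr.permutation_ttest(m, groups, seed=seed).iloc[0]
                )
            for k in mean_ps:
                mean_ps[k].append(np.mean(ps[k]))
        for k, series in mean_ps.items():
            assert series[0] >= series[1] >= series[2], (k, series)


class TestConsensus:
    def test_all_p_one_gives_empty_lists(self):
        table = pd.DataFrame(
            {"p_anova": [1.0, 1.0], "p_boot": [1.0, 1.0], "p_perm": [1.0, 1.0]},
            index=["g1", "g2"],
        )
        calls = diffexpr.consensus(table)
        assert calls.anova == calls.boot == calls.perm == calls.intersection == []

    def test_thresholds_of_one_admit_everything(self):
        table = pd.DataFrame(
            {"p_anova": [0.9, 0.2], "p_boot": [0.99, 0.5], "p_perm": [1.0, 0.7]},
            index=["g1", "g2"],
        )
        calls = diffexpr.consensus(table, Thresholds(1, 1, 1))
        assert calls.intersection == ["g1", "g2"]

    def test_intersection_bounded_by_smallest_list(self, rng):
        table = pd.DataFrame(
            {
                "p_anova": rng.uniform(size=100),
                "p_boot": rng.uniform(size=100),
                "p_perm": rng.uniform(size=100),
            },
            index=[f"g{i}" for i in range(100)],
        )
        calls = diffexpr.consensus(table)
        assert len(calls.intersection) <= min(
            len(calls.anova), len(calls.boot), len(calls.perm)
        )

    def test_recovers_planted_genes_end_to_end(self):
        cfg = SimConfig(n_genes=600, frac_de=0.1, effect_size=1.0, noise_sd=0.5,
                        batch_shift_sd=0.0, age_effect_sd=0.0,
                        gender_effect_sd=0.0, n_outliers=0, n_low_rin=0,
                        seed=30)
        matrix, sheet, truth = simulate_cohort(cfg)
        g = sheet.set_index("sample_id")["group"]
        table = diffexpr.de_table(matrix, g, B_boot=1000, B_perm=1000, seed=30)
        called = set(diffexpr.consensus(table).intersection)
        recovered = len(called & truth.de_gene_ids) / len(truth.de_gene_ids)
        assert recovered >= 0.9

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="p_perm"):
            diffexpr.consensus(pd.DataFrame({"p_anova": [], "p_boot": []}))
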