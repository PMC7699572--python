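import numpy as np
import pytest
from scipy import stats as sps

from aircine.phantom import CohortSpec, PhantomSpec, simulate_cohort_measurements
from aircine.power import PowerQuery, paired_t_power
from aircine.stats import (
    dunnett_compare,
    fit_lmm,
    lmm_results_table,
    multiplicity_adjust,
    paired_compare,
    paired_results_table,
)


class TestPairedCompare:
    def test_symmetric_differences_give_null_result(self):
        base = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        follow = base + np.array([1.0, -1.0, 2.0, -2.0, 0.0])
        res = paired_compare(base, follow)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.cohens_d == pytest.approx(0.0)
        assert res.ci[0] <= res.mean_diff <= res.ci[1]

    def test_identical_vectors(self):
        base = np.array([5.0, 6.0, 7.0, 8.0])
        res = paired_compare(base, base)
        assert res.cohens_d == 0.0
        assert res.pct_change == 0.0
        assert res.p_value == 1.0

    def test_zero_baseline_excluded_from_percent_change(self, caplog):
        base = np.array([0.0, 10.0, 10.0, 10.0])
        follow = np.array([1.0, 11.0, 11.0, 11.0])
        with caplog.at_level("WARNING"):
            res = paired_compare(base, follow)
        assert res.pct_change == pytest.approx(10.0)
        assert "zero baseline" in caplog.text

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(5)
        base = rng.normal(50, 5, 30)
        follow = base + rng.exponential(2.0, 30) ** 3  # heavily skewed shifts
        res = paired_compare(base, follow)
        assert res.test == "wilcoxon"
        assert res.ci[0] <= res.mean_diff or res.ci[0] <= np.median(follow - base)

    def test_rejection_rate_matches_noncentral_t_power(self):
        """Monte-Carlo power at d=0.7, n=22, alpha=0.025 matches closed form."""
        n, d, alpha, reps = 22, 0.7, 0.025, 2000
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(reps):
            diffs = rng.normal(d, 1.0, n)
            res = paired_compare(np.zeros(n), diffs)
            rejections += res.p_value < alpha
        expected = paired_t_power(PowerQuery(n, d, alpha))
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(rejections / reps - expected) < 3 * se

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2.0], [1.0, 2.0])


class TestMultiplicityAdjust:
    def test_singleton_family_unchanged(self):
        assert multiplicity_adjust([0.01])[0] == pytest.approx(0.01)

    def test_bonferroni_family_of_24(self):
        """A 0.0184 raw p in a 24-measure family is far from significant."""
        p = multiplicity_adjust([0.0184] + [0.5] * 23)[0]
        assert p == pytest.approx(0.4416)
        assert p > 0.05

    def test_holm_dominates_bonferroni(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(2, 20))
            holm = multiplicity_adjust(p, "holm")
            bonf = multiplicity_adjust(p, "bonferroni")
            assert np.all(holm <= bonf + 1e-12)
            assert np.all(holm >= p - 1e-12)

    def test_empty_family(self):
        assert multiplicity_adjust([]).size == 0


class TestDunnett:
    def test_identical_groups_not_significant(self):
        base = np.arange(10, dtype=float)
        res = dunnett_compare(base, [base, base, base])
        assert np.allclose(res.p_adjusted, 1.0)

    def test_single_comparison_reduces_to_paired_t(self):
        rng = np.random.default_rng(3)
        base = rng.normal(100, 10, 22)
        follow = base + rng.normal(1, 2, 22)
        res = dunnett_compare(base, [follow])
        t_p = sps.ttest_rel(follow, base).pvalue
        assert res.p_adjusted[0] == pytest.approx(t_p, rel=1e-9)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        base = rng.normal(100, 10, 22)
        fu = base + rng.normal(0.5, 2, (3, 22))
        res = dunnett_compare(base, fu)
        assert np.all(res.p_adjusted >= res.p_raw - 1e-12)
        assert np.all((res.p_adjusted >= 0) & (res.p_adjusted <= 1))

    def test_detects_large_shift(self):
        rng = np.random.default_rng(11)
        base = rng.normal(100, 5, 22)
        fu = np.stack([base + rng.normal(0, 1, 22),
                       base + 10 + rng.normal(0, 1, 22)])
        res = dunnett_compare(base, fu, labels=("5", "10"))
        assert res.p_adjusted[1] < 0.001
        assert res.p_adjusted[0] > 0.1


def _measured_cohort(effects=(1.0, 1.0, 1.0, 1.0), seed=0, cv=0.04, n_subjects=22):
    cohort = CohortSpec(n_subjects=n_subjects, planes=("NP",),
                        condition_effects=effects, seed=seed)
    base = PhantomSpec(noise_sd=0, psf_sigma=0)
    return simulate_cohort_measurements(cohort, base, measurement_cv=cv, seed=seed + 1)


class TestFitLmm:
    def test_zero_noise_recovers_injected_change_exactly(self):
        """With no noise and no between-subject spread the LSM change equals
        the deterministic injected change at every time level."""
        cohort = CohortSpec(n_subjects=5, planes=("NP",),
                            condition_effects=(1.0, 0.9, 0.8, 0.7),
                            between_subject_sd=0.0, seed=1)
        base = PhantomSpec(noise_sd=0, psf_sigma=0)
        table = simulate_cohort_measurements(cohort, base, measurement_cv=0.0)
        res = fit_lmm(table, "ap_mean", plane="NP")
        baseline_ap = table[(table.measure == "ap_mean")
                            & (table.condition == "00")]["value"].iloc[0]
        assert res.random_effect_dropped  # no residual noise: singular mixed fit
        for t, eff in (("5", 0.9), ("10", 0.8), ("15", 0.7)):
            assert res.lsm[t]["estimate"] == pytest.approx((eff - 1) * baseline_ap,
                                                           abs=1e-8)

    def test_recovers_negative_condition_effect(self):
        table = _measured_cohort(effects=(1.0, 0.9, 0.9, 0.9), seed=4)
        res = fit_lmm(table, "ap_mean", plane="NP")
        for t in res.times:
            e = res.lsm[t]
            assert e["estimate"] < 0
            assert e["ci_lo"] <= e["estimate"] <= e["ci_hi"]
            assert e["p"] < 0.05

    def test_null_cohort_mostly_covers_zero(self):
        table = _measured_cohort(seed=6)
        res = fit_lmm(table, "area_mean", plane="NP")
        covered = sum(res.lsm[t]["ci_lo"] <= 0 <= res.lsm[t]["ci_hi"]
                      for t in res.times)
        assert covered >= 2

    def test_unbalanced_missing_condition_tolerated(self):
        table = _measured_cohort(seed=8)
        table = table[~((table.subject == 0) & (table.condition == "10"))]
        res = fit_lmm(table, "ap_mean", plane="NP")
        assert set(res.times) == {"5", "10", "15"}


class TestResultTables:
    def test_paired_table_layout(self):
        table = _measured_cohort(seed=12)
        out = paired_results_table(table)
        assert len(out) == 9  # 1 plane x 3 measures x 3 summaries
        for col in ("measure", "n", "mean_00", "sd_00", "mean_15", "sd_15", "diff",
                    "ci_lo", "ci_hi", "pct_change", "cohens_d", "test", "p_raw", "p_adj"):
            assert col in out.columns
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        assert (out["n"] == 22).all()

    def test_lmm_table_adjusted_monotone(self):
        out = lmm_results_table(_measured_cohort(seed=13))
        assert len(out) == 27  # 9 measures x 3 time levels
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        assert out["converged"].all() or out["random_effect_dropped"].any()

    def test_null_cohort_not_significant_after_adjustment(self):
        out = paired_results_table(_measured_cohort(seed=14))
        assert (out["p_adj"] > 0.05).all()
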