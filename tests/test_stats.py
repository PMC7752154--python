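"""Association battery: Wilcoxon, Fisher, logistic, Kaplan-Meier/log-rank, Cox."""

import numpy as np
import pandas as pd
import pytest

from oracles import (conditional_or_enumeration, fisher_p_enumeration,
                     km_survival_no_censoring, logrank_oe,
                     ranksum_p_enumeration)

from immunosig import (ConfigurationError, SimulationConfig,
                       compare_groups_wilcoxon, cox_adjusted, dichotomize,
                       fisher_or, km_logrank, logistic_adjusted,
                       simulate_cohort, simulate_single_cells)
from immunosig.cohort import GROUP_COLUMN, SCORE_COLUMN, StratifiedCohort


def _strat_from_frame(df):
    return StratifiedCohort(table=df, threshold=0.0, method="manual")


def _surv_frame(times, events, groups, extra=None):
    df = pd.DataFrame({"surv_time": times, "event": events,
                       GROUP_COLUMN: groups})
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        scores = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        resp = pd.Series([1, 1, 1, 0, 0, 0])
        (res,) = compare_groups_wilcoxon(scores, resp)
        assert res.p == pytest.approx(1.0)

    def test_small_groups_exact_p_matches_enumeration(self):
        scores = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        resp = pd.Series([1, 1, 1, 0, 0, 0])
        (res,) = compare_groups_wilcoxon(scores, resp)
        assert res.p == pytest.approx(0.1)
        assert res.p == pytest.approx(
            ranksum_p_enumeration([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]))

    def test_equal_family_p_unchanged_by_bh(self, rng):
        x = rng.normal(size=20)
        scores = pd.DataFrame({f"s{j}": x for j in range(1, 6)})
        resp = pd.Series((np.arange(20) < 10).astype(int))
        results = compare_groups_wilcoxon(scores, resp)
        for r in results:
            assert r.p_adj == pytest.approx(results[0].p)

    def test_empty_group_raises(self):
        scores = pd.DataFrame({"s1": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError):
            compare_groups_wilcoxon(scores, pd.Series([1, 1, 1]))


class TestFisher:
    def test_balanced_table_is_null(self):
        res = fisher_or(np.array([[10, 10], [10, 10]]))
        assert res.effect == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_p_and_or_match_enumeration(self):
        res = fisher_or(np.array([[8, 2], [1, 9]]))
        assert res.p == pytest.approx(fisher_p_enumeration(8, 2, 1, 9), abs=1e-12)
        assert res.effect == pytest.approx(conditional_or_enumeration(8, 2, 1, 9),
                                           rel=1e-6)

    def test_perfect_split_or_flagged_infinite(self):
        res = fisher_or(np.array([[5, 0], [0, 5]]))
        assert np.isinf(res.effect)
        assert res.note != ""
        assert res.p == pytest.approx(fisher_p_enumeration(5, 0, 0, 5), abs=1e-12)
        assert res.p == pytest.approx(1 / 126, abs=1e-12)  # both one-cell tails

    def test_zero_margin_flagged_not_corrected(self):
        res = fisher_or(np.array([[0, 0], [3, 4]]))
        assert np.isnan(res.effect)
        assert "margin" in res.note

    def test_random_tables_match_enumeration(self, rng):
        """Spot-check p and conditional OR against full enumeration (the
        exhaustive n<=30 sweep runs in the acceptance suite)."""
        for _ in range(50):
            t = rng.integers(0, 9, size=4)
            a, b, c, d = (int(v) for v in t)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            res = fisher_or(np.array([[a, b], [c, d]]))
            assert res.p == pytest.approx(fisher_p_enumeration(a, b, c, d),
                                          abs=1e-9)
            oracle = conditional_or_enumeration(a, b, c, d)
            if np.isfinite(oracle) and oracle > 0:
                assert res.effect == pytest.approx(oracle, rel=1e-4)


class TestLogistic:
    @staticmethod
    def _synthetic_cohort(n=5000, beta=np.log(1.3), seed=3):
        cfg = SimulationConfig(n_genes=40, n_cells=50, immuno_set_size=8,
                               n_patients=n, beta_signature=beta, seed=seed)
        _, truth = simulate_single_cells(cfg)
        _, cohort = simulate_cohort(cfg, truth)
        cohort[SCORE_COLUMN] = truth.patient_signature_scores
        return cohort

    def test_recovers_planted_odds_ratio(self):
        res = logistic_adjusted(self._synthetic_cohort())
        assert 1.2 <= res.effect <= 1.4
        assert res.ci_low <= res.effect <= res.ci_high
        assert "or_per_sd" in res.extras

    def test_constant_score_raises_naming_column(self):
        cohort = self._synthetic_cohort(n=200)
        cohort[SCORE_COLUMN] = 0.0
        with pytest.raises(ConfigurationError, match=SCORE_COLUMN):
            logistic_adjusted(cohort)

    def test_unadjusted_binary_score_equals_cross_product_ratio(self):
        """Saturated-model identity: logistic OR of a binary exposure with no
        covariates equals ad/bc of the 2x2 table."""
        cohort = self._synthetic_cohort(n=800)
        strat = dichotomize(cohort)
        t = strat.table.copy()
        t["high"] = (t[GROUP_COLUMN] == "high").astype(float)
        res = logistic_adjusted(t, score_column="high", covariates=())
        hi = t["high"] == 1
        resp = t["response"] == 1
        a, b = (hi & resp).sum(), (hi & ~resp).sum()
        c, d = (~hi & resp).sum(), (~hi & ~resp).sum()
        assert res.effect == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_affine_score_rescaling_transforms_coefficient(self):
        cohort = self._synthetic_cohort(n=2000)
        res1 = logistic_adjusted(cohort)
        cohort2 = cohort.copy()
        cohort2[SCORE_COLUMN] = 2.0 * cohort2[SCORE_COLUMN] + 7.0
        res2 = logistic_adjusted(cohort2)
        assert res2.extras["beta"] == pytest.approx(res1.extras["beta"] / 2.0,
                                                    rel=1e-4)


class TestKMLogrank:
    def test_identical_groups_null(self):
        times = [1.0, 2.0, 3.0, 4.0]
        df = _surv_frame(times + times, [1] * 8, ["high"] * 4 + ["low"] * 4)
        curves, res = km_logrank(_strat_from_frame(df))
        assert res.effect == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_statistic_matches_hand_computed_oe(self):
        df = _surv_frame([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                         ["high", "high", "low", "low"])
        _, res = km_logrank(_strat_from_frame(df))
        oracle = logrank_oe([1.0, 2.0], [1, 1], [3.0, 4.0], [1, 1])
        assert res.effect == pytest.approx(oracle, rel=1e-9)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(5.0, size=40)
        df = _surv_frame(np.concatenate([times, times + 1.0]), [1] * 80,
                         ["high"] * 40 + ["low"] * 40)
        curves, _ = km_logrank(_strat_from_frame(df))
        high = next(c for c in curves if c.group == "high")
        emp = km_survival_no_censoring(times, high.times)
        np.testing.assert_allclose(high.survival, emp, atol=1e-12)

    def test_all_censored_flagged(self):
        df = _surv_frame([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0],
                         ["high", "high", "low", "low"])
        _, res = km_logrank(_strat_from_frame(df))
        assert np.isnan(res.p)
        assert "no events" in res.note

    def test_single_group_raises(self):
        df = _surv_frame([1.0, 2.0], [1, 1], ["high", "high"])
        with pytest.raises(ConfigurationError):
            km_logrank(_strat_from_frame(df))


class TestCox:
    @staticmethod
    def _cohort(n=5000, hr=0.6, seed=4):
        cfg = SimulationConfig(n_genes=40, n_cells=50, immuno_set_size=8,
                               n_patients=n, hr_signature=hr, seed=seed)
        _, truth = simulate_single_cells(cfg)
        _, cohort = simulate_cohort(cfg, truth)
        cohort[SCORE_COLUMN] = truth.patient_signature_scores
        return cohort

    def test_recovers_planted_hazard_ratio(self):
        res = cox_adjusted(self._cohort(), score_column=SCORE_COLUMN,
                           covariates=())
        assert 0.52 <= res.effect <= 0.69
        assert res.ci_low <= res.effect <= res.ci_high

    def test_duplicated_cohort_same_hr_tighter_ci(self):
        cohort = self._cohort(n=400)
        doubled = pd.concat([cohort, cohort], ignore_index=True)
        r1 = cox_adjusted(cohort, score_column=SCORE_COLUMN, covariates=())
        r2 = cox_adjusted(doubled, score_column=SCORE_COLUMN, covariates=())
        # duplication makes every event time tied, so Efron's tie correction
        # perturbs the otherwise exact replication invariance slightly
        assert r2.effect == pytest.approx(r1.effect, rel=5e-3)
        assert (r2.ci_high - r2.ci_low) < (r1.ci_high - r1.ci_low)

    def test_adjusted_fit_with_categorical_covariates(self):
        cohort = self._cohort(n=1000)
        strat = dichotomize(cohort)
        res = cox_adjusted(strat.table)
        assert np.isfinite(res.effect)
        assert res.effect < 1.0  # high-score group is protected
        assert any(c.startswith("sex") for c in res.covariates)

    def test_affine_score_rescaling_transforms_log_hr(self):
        cohort = self._cohort(n=1500)
        r1 = cox_adjusted(cohort, score_column=SCORE_COLUMN, covariates=())
        cohort2 = cohort.copy()
        cohort2[SCORE_COLUMN] = 3.0 * cohort2[SCORE_COLUMN] - 1.0
        r2 = cox_adjusted(cohort2, score_column=SCORE_COLUMN, covariates=())
        assert r2.extras["log_hr"] == pytest.approx(r1.extras["log_hr"] / 3.0,
                                                    rel=1e-4)

    def test_missing_tmb_reduces_n_used_only_when_adjusted(self):
        cohort = self._cohort(n=600)
        cohort.loc[cohort.index[:100], "tmb"] = np.nan
        strat = dichotomize(cohort)
        adj = cox_adjusted(strat.table)
        unadj = cox_adjusted(strat.table, covariates=())
        assert adj.n_used == 500
        assert unadj.n_used == 600
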