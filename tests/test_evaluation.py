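"""Metric and statistical-harness contracts: cv-r2, logistic enrichment,
rank correlations and the locus/conservation regressions."""

import numpy as np
import pandas as pd
import pytest

from peabrain import evaluation as ev


class TestCvR2:
    def test_perfect_prediction_is_one(self):
        y = np.array([1.0, 2.0, 5.0])
        assert ev.cv_r2(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ev.cv_r2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_worked_negative_case(self):
        # SSE = 0 + 1 + 4 = 5, SST = 2 -> 1 - 5/2 = -1.5
        assert ev.cv_r2([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(-1.5)

    def test_constant_y_errors(self):
        with pytest.raises(ValueError):
            ev.cv_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        y, f = rng.normal(size=20), rng.normal(size=20)
        assert ev.cv_r2(y + 7, f + 7) == pytest.approx(ev.cv_r2(y, f))


class TestSummarizeCvR2:
    def test_hand_computed_ci(self):
        vals = [0.2, 0.3, 0.25, 0.28, 0.22]
        res = ev.summarize_cv_r2(vals)
        mean = sum(vals) / 5
        se = np.std(vals, ddof=1) / np.sqrt(5)
        assert res.mean == pytest.approx(mean)
        assert res.ci_low == pytest.approx(mean - 1.96 * se)
        assert res.ci_high == pytest.approx(mean + 1.96 * se)
        assert res.ci_low == pytest.approx(0.214, abs=5e-3)
        assert res.ci_high == pytest.approx(0.286, abs=5e-3)
        assert res.captured

    def test_symmetric_about_zero_not_captured(self):
        assert not ev.summarize_cv_r2([-0.2, 0.2, -0.1, 0.1]).captured

    def test_degenerate_equal_values_captured(self):
        res = ev.summarize_cv_r2([0.4, 0.4, 0.4])
        assert res.ci_low == pytest.approx(0.4)
        assert res.ci_high == pytest.approx(0.4)
        assert res.captured

    def test_too_few_repeats_errors(self):
        with pytest.raises(ValueError):
            ev.summarize_cv_r2([0.1, 0.2])


class TestLogisticEnrichment:
    def test_recovers_planted_coefficient(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=2000)
        labels = (rng.random(2000) < 1 / (1 + np.exp(-2 * s))).astype(int)
        res = ev.logistic_enrichment(s, labels)
        assert res.coefficient == pytest.approx(2.0, abs=0.3)
        assert res.ci_low < res.coefficient < res.ci_high
        assert res.p_value < 1e-10

    def test_profile_ci_matches_wald_closely_on_regular_data(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=800)
        labels = (rng.random(800) < 1 / (1 + np.exp(-s))).astype(int)
        res = ev.logistic_enrichment(s, labels)
        import statsmodels.api as sm
        fit = sm.GLM(labels, np.column_stack([np.ones(800), s]),
                     family=sm.families.Binomial()).fit()
        lo, hi = fit.conf_int()[1]
        assert res.ci_low == pytest.approx(lo, abs=0.05)
        assert res.ci_high == pytest.approx(hi, abs=0.05)

    def test_monotone_transform_invariance_when_rank_normalized(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=400)
        labels = (rng.random(400) < 1 / (1 + np.exp(-s))).astype(int)
        a = ev.logistic_enrichment(s, labels, rank_normalize=True)
        b = ev.logistic_enrichment(np.exp(s), labels, rank_normalize=True)
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-8)

    def test_duplicate_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=300)
        labels = (rng.random(300) < 0.5).astype(int)
        with pytest.warns(UserWarning, match="collinear"):
            res = ev.logistic_enrichment(s, labels, covariates=s.copy())
        assert np.isfinite(res.coefficient)

    def test_missing_covariates_excluded_and_counted(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=200)
        labels = (rng.random(200) < 0.5).astype(int)
        cov = rng.normal(size=200)
        cov[:25] = np.nan
        res = ev.logistic_enrichment(s, labels, covariates=cov)
        assert res.n_excluded == 25 and res.n_used == 175

    def test_perfect_separation_flagged(self):
        s = np.linspace(-2, 2, 60)
        labels = (s > 0).astype(int)
        res = ev.logistic_enrichment(s, labels)
        assert res.separable
        assert res.ci_low == -np.inf and res.ci_high == np.inf

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ev.logistic_enrichment([1.0, 2.0], [1, 1])


class TestSpearmanCompare:
    def _series(self, vals, n0=0):
        keys = [f"1_{i+n0}_A_G_b37" for i in range(len(vals))]
        return pd.Series(vals, index=keys)

    def test_identical_gives_one(self):
        est = self._series(np.arange(20.0))
        rho, p = ev.spearman_compare(est, est.copy())
        assert rho == pytest.approx(1.0)

    def test_negated_gives_minus_one(self):
        est = self._series(np.arange(20.0))
        rho, _ = ev.spearman_compare(est, -est)
        assert rho == pytest.approx(-1.0)

    def test_permuted_near_zero(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=1000)
        est = self._series(vals)
        ref = self._series(rng.permutation(vals))
        rho, _ = ev.spearman_compare(est, ref)
        assert abs(rho) < 0.1

    def test_empty_intersection_reports_keys(self):
        est = self._series([1.0] * 12)
        ref = self._series([1.0] * 12, n0=100)
        with pytest.raises(ValueError, match="intersecting"):
            ev.spearman_compare(est, ref)


class TestLocusRegression:
    def _loci(self, n, rng):
        scores = pd.Series(rng.uniform(0, 1, n),
                           index=[f"L{i}" for i in range(n)])
        return scores

    def test_planted_monotone_relation_detected(self):
        rng = np.random.default_rng(9)
        scores = self._loci(60, rng)
        h2 = scores ** 2 + 0.01 * rng.normal(size=60)  # monotone in score
        df = ev.locus_tissue_regression({"liver": scores}, h2)
        assert df.loc["liver", "slope"] > 0
        assert df.loc["liver", "p_value"] < 1e-4

    def test_shuffled_null_mostly_insignificant(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(50):
            scores = self._loci(40, rng)
            h2 = pd.Series(rng.permutation(scores.values), index=scores.index)
            df = ev.locus_tissue_regression({"t": scores}, h2)
            hits += df.loc["t", "p_value"] < 0.05
        assert hits <= 5  # ~5% type-I at alpha = 0.05

    def test_single_tissue_bonferroni_factor_one(self):
        rng = np.random.default_rng(11)
        scores = self._loci(30, rng)
        h2 = scores + 0.1 * rng.normal(size=30)
        df = ev.locus_tissue_regression({"t": scores}, h2)
        assert df.loc["t", "adjusted_p"] == pytest.approx(
            min(df.loc["t", "p_value"], 1.0))

    def test_bonferroni_never_decreases_p(self):
        rng = np.random.default_rng(12)
        locus_scores = {f"t{k}": self._loci(30, rng) for k in range(4)}
        h2 = self._loci(30, rng)
        df = ev.locus_tissue_regression(locus_scores, h2)
        assert (df["adjusted_p"] >= df["p_value"] - 1e-15).all()


class TestConservationRegression:
    def test_exact_linear_construction_recovers_slope(self):
        rng = np.random.default_rng(13)
        impact = pd.Series(rng.uniform(0, 1, 200))
        cons = 8.95 * impact
        raw, ranked = ev.impact_conservation_regression(impact, cons)
        assert raw.slope == pytest.approx(8.95, abs=1e-8)
        assert ranked.slope > 0

    def test_independent_conservation_null(self):
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(40):
            impact = pd.Series(rng.uniform(0, 1, 120))
            cons = pd.Series(rng.normal(size=120))
            raw, _ = ev.impact_conservation_regression(impact, cons)
            hits += raw.p_value < 0.05
        assert hits <= 5

    def test_constant_impact_errors(self):
        impact = pd.Series(np.ones(150))
        cons = pd.Series(np.arange(150.0))
        with pytest.raises(ValueError, match="constant"):
            ev.impact_conservation_regression(impact, cons)
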