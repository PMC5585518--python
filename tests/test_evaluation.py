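import numpy as np
import pandas as pd
import pytest

from impscore.evaluation import (
    EvaluationError,
    _bc_interval,
    aic,
    auc,
    bernoulli_loglik,
    bootstrap_ci,
    calibration_curve,
    compare_models,
    evaluate_predictions,
    hosmer_lemeshow,
    report_frame,
)


def brute_force_auc(pred, y):
    """O(n^2) pairwise enumeration with ties counted one half."""
    pos = pred[y.astype(bool)]
    neg = pred[~y.astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0

    def test_constant_score_is_half(self):
        y = np.array([0, 1, 0, 1])
        assert auc(np.full(4, 0.3), y) == 0.5

    def test_matches_pairwise_enumeration(self, rng):
        pred = np.round(rng.random(30), 1)  # rounding forces ties
        y = rng.random(30) < 0.4
        assert auc(pred, y) == pytest.approx(brute_force_auc(pred, y))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pred = rng.random(200)
        y = rng.random(200) < 0.3
        assert auc(pred, y) == pytest.approx(roc_auc_score(y, pred))

    def test_invariant_under_monotone_transform(self, rng):
        pred = rng.random(100)
        y = rng.random(100) < 0.5
        assert auc(pred, y) == pytest.approx(auc(np.exp(3 * pred), y))

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestHosmerLemeshow:
    def test_zero_when_groupwise_calibrated(self):
        # two risk groups whose observed rates equal their predictions exactly
        pred = np.array([0.2] * 10 + [0.4] * 10)
        y = np.array([1] * 2 + [0] * 8 + [1] * 4 + [0] * 6)
        stat, tab = hosmer_lemeshow(pred, y, groups=2)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert len(tab) == 2

    def test_matches_two_bin_hand_computation(self):
        pred = np.array(
            [0.05, 0.1, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45,
             0.5, 0.55, 0.6, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9]
        )
        y = np.array([0, 0, 1, 0, 0, 0, 1, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1])
        stat, _ = hosmer_lemeshow(pred, y, groups=2)
        # independent hand computation of the two-bin formula
        expected = 0.0
        for lo, hi in ((0, 10), (10, 20)):
            O, E, n = y[lo:hi].sum(), pred[lo:hi].sum(), hi - lo
            expected += (O - E) ** 2 / (E * (1 - E / n))
        assert stat == pytest.approx(expected)

    def test_statistic_nonnegative(self, rng):
        pred = rng.uniform(0.05, 0.95, 500)
        y = rng.random(500) < pred
        stat, _ = hosmer_lemeshow(pred, y)
        assert stat >= 0

    def test_mean_tracks_exact_binomial_expectation(self, rng):
        """With outcomes drawn from their own (known) predictions the HL
        statistic's mean equals the exact Poisson-binomial expectation
        sum_bins sum_i p_i(1-p_i) / (E(1-E/n)); 500 replications, n=10,000."""
        n, reps, g = 10_000, 500, 10
        pred = rng.uniform(0.02, 0.5, n)
        edges = np.quantile(pred, np.linspace(0, 1, g + 1)[1:-1])
        bins = np.searchsorted(edges, pred, side="left")
        expected = 0.0
        for b in range(g):
            p = pred[bins == b]
            E, nb = p.sum(), len(p)
            expected += (p * (1 - p)).sum() / (E * (1 - E / nb))
        stats = [
            hosmer_lemeshow(pred, rng.random(n) < pred, groups=g)[0]
            for _ in range(reps)
        ]
        assert np.mean(stats) == pytest.approx(expected, rel=0.10)

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(EvaluationError):
            hosmer_lemeshow(np.array([0.0, 0.5] * 10), np.zeros(20), groups=2)

    def test_tie_collapse_reduces_groups(self):
        pred = np.array([0.2] * 30 + [0.8] * 10)
        y = (pred > 0.5).astype(float) * np.tile([1, 0], 20)
        stat, tab = hosmer_lemeshow(pred, y, groups=10)
        assert len(tab) == 2  # only two distinct risk levels survive


class TestAIC:
    def test_values(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-10.0, 2) == 24.0

    def test_monotone_in_loglik(self):
        assert aic(-100.0, 3) > aic(-90.0, 3)

    def test_negative_k_rejected(self):
        with pytest.raises(EvaluationError):
            aic(0.0, -1)


class TestBootstrapCI:
    def test_constant_metric_collapses_to_point(self):
        lo, hi = bootstrap_ci(lambda x: 0.7, np.arange(50.0), n_boot=100, seed=1)
        assert lo == hi == 0.7

    def test_symmetric_replicates_reduce_to_percentile(self):
        reps = np.concatenate([np.linspace(0, 0.499, 500), np.linspace(0.501, 1, 500)])
        lo, hi = _bc_interval(reps, point=0.5, level=0.95)
        assert lo == pytest.approx(np.quantile(reps, 0.025), abs=1e-9)
        assert hi == pytest.approx(np.quantile(reps, 0.975), abs=1e-9)

    def test_reproducible_under_seed(self, rng):
        x = rng.normal(size=300)
        a = bootstrap_ci(np.mean, x, n_boot=200, seed=7)
        b = bootstrap_ci(np.mean, x, n_boot=200, seed=7)
        assert a == b

    def test_interval_contains_point_estimate(self, rng):
        x = rng.normal(size=500)
        y = rng.random(500) < 0.3
        lo, hi = bootstrap_ci(auc, x, y, n_boot=300, seed=3)
        assert lo <= auc(x, y) <= hi

    def test_excess_failures_raise(self):
        def sometimes(x):
            if x.sum() % 2 < 1:
                raise ValueError
            return float(x.mean())

        with pytest.raises(EvaluationError, match="failed"):
            bootstrap_ci(sometimes, np.arange(10.0), n_boot=100, seed=0)


class TestCalibrationCurve:
    def test_two_bin_closed_form_ols(self):
        pred = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 0.5, 0.5])
        y = np.array([0, 0, 0, 0, 1, 0, 0, 1, 1, 1])
        cal = calibration_curve(pred, y, bins=2)
        # two points: (0.1, 0.2) and (0.5, 0.6) -> slope 1, intercept 0.1, R^2 1
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.1)
        assert cal.r_squared == pytest.approx(1.0)

    def test_binomial_intervals_bracket_observed(self, rng):
        pred = rng.uniform(0.05, 0.6, 2000)
        y = rng.random(2000) < pred
        cal = calibration_curve(pred, y, bins=10)
        t = cal.table
        assert ((t["ci_lo"] <= t["observed_rate"]) & (t["observed_rate"] <= t["ci_hi"])).all()

    def test_degenerate_single_bin_rejected(self):
        with pytest.raises(EvaluationError):
            calibration_curve(np.full(100, 0.3), np.zeros(100), bins=5)


@pytest.fixture(scope="module")
def fitted_pair(small_splits, derived_small):
    from impscore.models import MortalityModel

    _, estimation, validation = small_splits
    table = derived_small.severity_table
    imp = MortalityModel.from_patients(estimation, table, kind="imp").fit()
    swi = MortalityModel.from_patients(estimation, table, kind="swi").fit()
    return validation, table, imp, swi


class TestCompareModels:
    def test_identical_model_yields_identical_rows(self, fitted_pair):
        validation, table, imp, _ = fitted_pair
        reports = compare_models(
            validation,
            {"A": (imp, table), "B": (imp, table)},
            n_boot=50,
            seed=4,
        )
        rows = report_frame(reports).drop(columns="model")
        assert rows.iloc[0].equals(rows.iloc[1])

    def test_row_count_and_aic_ranking(self, fitted_pair):
        validation, table, imp, swi = fitted_pair
        reports = compare_models(
            validation,
            {"IMP": (imp, table), "SWI": (swi, table)},
            n_boot=50,
            seed=4,
        )
        assert len(reports) == 2
        aics = [r.aic for r in reports]
        assert aics == sorted(aics)

    def test_deterministic_report(self, fitted_pair):
        validation, table, imp, swi = fitted_pair
        kw = dict(n_boot=50, seed=9)
        r1 = compare_models(validation, {"IMP": (imp, table), "SWI": (swi, table)}, **kw)
        r2 = compare_models(validation, {"IMP": (imp, table), "SWI": (swi, table)}, **kw)
        assert report_frame(r1).equals(report_frame(r2))

    def test_single_model_rejected(self, fitted_pair):
        validation, table, imp, _ = fitted_pair
        with pytest.raises(EvaluationError):
            compare_models(validation, {"IMP": (imp, table)}, n_boot=10, seed=0)


def test_bernoulli_loglik_matches_manual():
    p = np.array([0.2, 0.7])
    y = np.array([0, 1])
    assert bernoulli_loglik(p, y) == pytest.approx(np.log(0.8) + np.log(0.7))


def test_evaluate_predictions_bundles_consistently(rng):
    pred = rng.uniform(0.02, 0.6, 1500)
    y = rng.random(1500) < pred
    rep = evaluate_predictions("demo", pred, y, k_params=3, n_boot=100, seed=2)
    assert rep.auc == pytest.approx(auc(pred, y))
    assert rep.aic == pytest.approx(aic(bernoulli_loglik(pred, y), 3))
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
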