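"""Threshold-search classifier: closed-form threshold, fitting, evaluation."""

import numpy as np
import pandas as pd
import pytest

from mcclearn import (
    MCCClassifierModel,
    PopulationRates,
    SplitError,
    SyntheticTabularConfig,
    ThresholdClassifier,
    confusion_from_labels,
    default_grid,
    evaluate,
    fit_mcc_bayes,
    fit_mcc_classifier,
    gaussian_population_optimum,
    generate_tabular,
    mcc,
    metric_table,
    repeat_protocol,
    theorem_threshold,
)
from mcclearn.model import LogisticProbabilityEstimator, NotFittedError


class ConstantEstimator:
    """Stub probability estimator returning a fixed eta for every input."""

    def __init__(self, value):
        self.value = value

    def fit(self, X, y, seed=0):
        return self

    def predict_proba1(self, X):
        return np.full(np.asarray(X).shape[0], self.value)


class TestTheoremThreshold:
    def test_uncorrelated_classifier_gives_prevalence(self):
        # TP = gamma*pi simplifies the formula to delta* = pi
        for g, p in [(0.3, 0.2), (0.5, 0.5), (0.8, 0.1)]:
            r = PopulationRates(tp=g * p, gamma=g, pi=p)
            assert theorem_threshold(r) == pytest.approx(p, abs=1e-12)

    def test_perfect_classifier_gives_half(self):
        for p in (0.1, 0.3, 0.5):
            r = PopulationRates(tp=p, gamma=p, pi=p)
            assert theorem_threshold(r) == pytest.approx(0.5, abs=1e-12)

    def test_direct_substitution(self):
        r = PopulationRates(tp=0.15, gamma=0.3, pi=0.2)
        assert theorem_threshold(r) == pytest.approx(0.12 / 0.42, abs=1e-12)

    def test_degenerate_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            theorem_threshold(PopulationRates(tp=0.0, gamma=0.0, pi=0.2))


class TestFitMCCClassifier:
    def test_separable_data_reaches_mcc_one(self, rng):
        n = 400
        y = np.repeat([0, 1], n // 2)
        X = (y * 10.0 - 5.0).reshape(-1, 1) + 0.01 * rng.standard_normal((n, 1))
        clf, report = fit_mcc_classifier(X, y, seed=0)
        preds = clf.predict(X)
        assert mcc(confusion_from_labels(y, preds)).value == pytest.approx(1.0)
        assert report.mcc_on_s2.max() == pytest.approx(1.0)

    def test_uninformative_features_give_near_zero_mcc(self, rng):
        n = 10_000
        X = rng.standard_normal((n, 3))
        y = rng.integers(0, 2, size=n)
        clf, _ = fit_mcc_classifier(X, y, seed=1)
        Xt = rng.standard_normal((n, 3))
        yt = rng.integers(0, 2, size=n)
        val = mcc(confusion_from_labels(yt, clf.predict(Xt))).value
        assert abs(val) <= 3 / np.sqrt(n)

    def test_logistic_link_data_approaches_population_optimum(self):
        cfg = SyntheticTabularConfig(n=20_000, pi=0.1, separation=1.5, seed=11)
        X, y, optimum = generate_tabular(cfg)
        clf, _ = fit_mcc_classifier(X, y, seed=11)
        test_cfg = SyntheticTabularConfig(n=50_000, pi=0.1, separation=1.5, seed=12)
        Xt, yt, _ = generate_tabular(test_cfg)
        val = mcc(confusion_from_labels(yt, clf.predict(Xt))).value
        assert abs(val - optimum) < 0.05

    def test_chosen_pair_maximizes_recorded_s2_matrix(self, rng):
        for seed in range(5):
            cfg = SyntheticTabularConfig(n=600, pi=0.3, separation=1.0, seed=seed)
            X, y, _ = generate_tabular(cfg)
            clf, report = fit_mcc_classifier(X, y, seed=seed)
            best = report.mcc_on_s2.max()
            row = 0 if clf.orientation == 1 else 1
            col = int(np.where(report.grid == clf.delta)[0][0])
            assert report.mcc_on_s2[row, col] == pytest.approx(best, abs=1e-15)

    def test_single_class_labels_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(SplitError):
            fit_mcc_classifier(X, np.ones(20, dtype=int), seed=0)

    def test_empty_or_out_of_range_grid_rejected(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.tile([0, 1], 20)
        with pytest.raises(ValueError, match="grid"):
            fit_mcc_classifier(X, y, grid=[], seed=0)
        with pytest.raises(ValueError, match="grid"):
            fit_mcc_classifier(X, y, grid=[0.0, 0.5], seed=0)


class TestPredictRule:
    def make(self, orientation, delta, eta):
        est = ConstantEstimator(0.0)
        clf = ThresholdClassifier(orientation=orientation, delta=delta, estimator=est)
        est.predict_proba1 = lambda X: np.asarray(eta)
        return clf

    def test_positive_orientation(self):
        clf = self.make(+1, 0.5, [0.9, 0.1])
        assert clf.predict(np.zeros((2, 1))).tolist() == [1, 0]

    def test_reversed_orientation(self):
        clf = self.make(-1, 0.5, [0.9, 0.1])
        assert clf.predict(np.zeros((2, 1))).tolist() == [0, 1]

    def test_exact_tie_predicts_zero(self):
        for orientation in (+1, -1):
            clf = self.make(orientation, 0.5, [0.5, 0.5])
            assert clf.predict(np.zeros((2, 1))).tolist() == [0, 0]

    def test_delta_bounds_enforced(self):
        with pytest.raises(ValueError, match="delta"):
            ThresholdClassifier(orientation=1, delta=1.0, estimator=ConstantEstimator(0.5))
        with pytest.raises(ValueError, match="orientation"):
            ThresholdClassifier(orientation=0, delta=0.5, estimator=ConstantEstimator(0.5))

    def test_unfitted_estimator_raises(self):
        clf = ThresholdClassifier(
            orientation=1, delta=0.5, estimator=LogisticProbabilityEstimator()
        )
        with pytest.raises(NotFittedError):
            clf.predict(np.zeros((2, 1)))


class TestBayesBaseline:
    def test_constant_eta_below_threshold_predicts_all_zero(self):
        y = np.tile([0, 1], 10)
        X = np.zeros((20, 1))
        clf = fit_mcc_bayes(X, y, estimator=ConstantEstimator(0.4))
        assert clf.delta == 0.5 and clf.orientation == 1
        assert not clf.predict(X).any()

    def test_matches_threshold_search_on_balanced_separable_data(self, rng):
        y = np.tile([0, 1], 300)
        X = (y * 6.0 - 3.0).reshape(-1, 1) + 0.1 * rng.standard_normal((600, 1))
        bayes = fit_mcc_bayes(X, y, seed=0)
        search, _ = fit_mcc_classifier(X, y, seed=0)
        vb = mcc(confusion_from_labels(y, bayes.predict(X))).value
        vs = mcc(confusion_from_labels(y, search.predict(X))).value
        assert vb == pytest.approx(vs, abs=0.02)
        assert vb > 0.95

    def test_threshold_search_beats_bayes_on_average_under_imbalance(self):
        # overlapping classes at pi = 0.05: the 0.5 threshold predicts too
        # few positives; the searched threshold should do at least as well
        diffs = []
        for seed in range(10):
            tr = SyntheticTabularConfig(n=4000, pi=0.05, separation=1.5, seed=100 + seed)
            te = SyntheticTabularConfig(n=8000, pi=0.05, separation=1.5, seed=200 + seed)
            X, y, _ = generate_tabular(tr)
            Xt, yt, _ = generate_tabular(te)
            search, _ = fit_mcc_classifier(X, y, seed=seed)
            bayes = fit_mcc_bayes(X, y, seed=seed)
            vs = mcc(confusion_from_labels(yt, search.predict(Xt))).value
            vb = mcc(confusion_from_labels(yt, bayes.predict(Xt))).value
            diffs.append(vs - vb)
        assert np.mean(diffs) >= 0.0


class TestEvaluate:
    def test_perfect_classifier_row(self, rng):
        y = np.tile([0, 1], 50)
        X = (y * 8.0 - 4.0).reshape(-1, 1)
        clf = fit_mcc_bayes(X, y, seed=0)
        tab = evaluate(clf, X, y).set_index("metric")
        assert tab.loc["mcc", "value"] == pytest.approx(1.0)

    def test_constant_classifier_flags_mcc_without_raising(self):
        y = np.tile([0, 1], 10)
        X = np.zeros((20, 1))
        clf = fit_mcc_bayes(X, y, estimator=ConstantEstimator(0.1))
        tab = evaluate(clf, X, y).set_index("metric")
        assert not tab.loc["mcc", "defined"]
        assert tab.loc["mcc", "value"] == 0.0

    def test_agrees_with_direct_metric_calls(self):
        cfg = SyntheticTabularConfig(n=800, pi=0.2, separation=1.2, seed=4)
        X, y, _ = generate_tabular(cfg)
        clf, _ = fit_mcc_classifier(X, y, seed=4)
        tab = evaluate(clf, X, y)
        counts = confusion_from_labels(y, clf.predict(X))
        scores = clf.decision_scores(X)
        if clf.orientation == -1:
            scores = 1.0 - scores
        direct = metric_table(counts, y_true=y, scores=scores)
        pd.testing.assert_frame_equal(tab, direct)


class TestRepeatProtocol:
    def test_single_repeat_has_zero_sd(self):
        cfg = SyntheticTabularConfig(n=400, pi=0.3, separation=1.5, seed=9)
        X, y, _ = generate_tabular(cfg)
        tab = repeat_protocol(X, y, repeats=1, seed=9)
        assert (tab["sd"] == 0.0).all()

    def test_fixed_seed_is_deterministic(self):
        cfg = SyntheticTabularConfig(n=400, pi=0.3, separation=1.5, seed=9)
        X, y, _ = generate_tabular(cfg)
        t1 = repeat_protocol(X, y, repeats=3, seed=42)
        t2 = repeat_protocol(X, y, repeats=3, seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sd_matches_recomputation_from_stored_repeats(self):
        cfg = SyntheticTabularConfig(n=600, pi=0.25, separation=1.5, seed=2)
        X, y, _ = generate_tabular(cfg)
        tab = repeat_protocol(X, y, repeats=10, seed=7)
        per = tab.attrs["repeats"]
        for _, row in tab.iterrows():
            vals = per[(per["method"] == row["method"]) & (per["metric"] == row["metric"])]["value"]
            assert row["sd"] == pytest.approx(float(np.std(vals, ddof=1)), abs=1e-12)
            assert row["mean"] == pytest.approx(float(np.mean(vals)), abs=1e-12)


class TestMonotoneSeparation:
    def test_more_separation_never_hurts_within_one_sd(self):
        seps = [0.5, 1.5, 3.0]
        means, sds = [], []
        for sep in seps:
            vals = []
            for seed in range(10):
                tr = SyntheticTabularConfig(n=2000, pi=0.2, separation=sep, seed=300 + seed)
                te = SyntheticTabularConfig(n=4000, pi=0.2, separation=sep, seed=400 + seed)
                X, y, _ = generate_tabular(tr)
                Xt, yt, _ = generate_tabular(te)
                clf, _ = fit_mcc_classifier(X, y, seed=seed)
                vals.append(mcc(confusion_from_labels(yt, clf.predict(Xt))).value)
            means.append(np.mean(vals))
            sds.append(np.std(vals, ddof=1))
        for i in range(len(seps) - 1):
            assert means[i + 1] >= means[i] - sds[i]


class TestModelResultsInterface:
    def test_from_dataframe_and_summary(self):
        cfg = SyntheticTabularConfig(n=500, pi=0.3, separation=2.0, seed=5)
        X, y, _ = generate_tabular(cfg)
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        frame["cls"] = y
        model = MCCClassifierModel.from_dataframe(frame, label_column="cls", positive_label=1)
        res = model.fit(seed=5)
        text = res.summary()
        assert "threshold (delta)" in text
        assert f"{res.delta:.4f}" in text
        assert res.report is not None

    def test_results_evaluate_matches_function(self):
        cfg = SyntheticTabularConfig(n=500, pi=0.3, separation=2.0, seed=6)
        X, y, _ = generate_tabular(cfg)
        res = MCCClassifierModel(X, y).fit(seed=6)
        pd.testing.assert_frame_equal(res.evaluate(X, y), evaluate(res.classifier, X, y))

    def test_bayes_results_have_fixed_threshold(self):
        cfg = SyntheticTabularConfig(n=500, pi=0.3, separation=2.0, seed=6)
        X, y, _ = generate_tabular(cfg)
        res = MCCClassifierModel(X, y).fit_bayes(seed=6)
        assert res.delta == 0.5 and res.orientation == 1 and res.report is None


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        cfg = SyntheticTabularConfig(n=500, pi=0.3, separation=2.0, seed=8)
        X, y, _ = generate_tabular(cfg)
        res = MCCClassifierModel(X, y).fit(seed=8)
        path = tmp_path / "model.json"
        res.save(path)
        loaded = ThresholdClassifier.load(path)
        assert loaded.delta == res.delta
        assert loaded.orientation == res.orientation
        np.testing.assert_array_equal(loaded.predict(X), res.predict(X))


def test_default_grid_covers_unit_interval_interior():
    grid = default_grid()
    assert grid[0] == pytest.approx(0.01)
    assert grid[-1] == pytest.approx(0.99)
    assert len(grid) == 99
    assert (grid > 0).all() and (grid < 1).all()
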