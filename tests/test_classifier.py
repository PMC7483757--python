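"""One-vs-rest logistic decoding, cross-validation, and accuracy statistics."""
import numpy as np
import pytest
from scipy.optimize import minimize

from embody import (
    CONDITIONS,
    MissingClassError,
    crossval_pipeline,
    decide,
    evaluate,
    group_accuracy_test,
    group_rating_test,
    rating_correlation,
    train,
)
from embody.classifier import per_trial_accuracy
from embody.containers import LabelSeries, VoxelTimeSeries
from embody.simulate import simulate_ratings


def _toy_problem(seed=0, n=40, v=5):
    rng = np.random.default_rng(seed)
    labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
    centers = {"A": rng.normal(0, 1, v), "B": rng.normal(0, 1, v)}
    data = np.stack([centers[l] + rng.normal(0, 1.5, v) for l in labels], axis=1)
    return VoxelTimeSeries(data), LabelSeries(labels)


def test_default_penalty():
    ts, lab = _toy_problem()
    model = train(ts, lab, conditions=("A", "B"))
    assert model.penalty == 0.01
    assert model.training_volume_count == 40


def test_train_matches_direct_likelihood_maximization():
    """Fitted decisions agree with brute-force penalized ML on a toy problem."""
    ts, lab = _toy_problem(seed=1)
    penalty = 0.01
    model = train(ts, lab, penalty=penalty, conditions=("A", "B"))

    def fit_direct(target):
        y = (lab.labels == target).astype(float)
        X = ts.data.T

        def nll(params):
            w, b = params[:-1], params[-1]
            z = X @ w + b
            return np.sum(np.logaddexp(0, z) - y * z) + penalty * np.dot(w, w)

        res = minimize(nll, np.zeros(X.shape[1] + 1), method="BFGS",
                       options={"gtol": 1e-10})
        return res.x[:-1], res.x[-1]

    for i, cond in enumerate(("A", "B")):
        w, b = fit_direct(cond)
        np.testing.assert_allclose(model.weights[i], w, atol=1e-3)
        np.testing.assert_allclose(model.intercepts[i], b, atol=1e-3)
    # decisions coincide exactly
    ev = model.evidence(ts)
    direct_scores = np.stack(
        [ts.data.T @ fit_direct(c)[0] + fit_direct(c)[1] for c in ("A", "B")], axis=1
    )
    np.testing.assert_array_equal(
        decide(ev, ("A", "B"), ("A", "B")),
        np.array(["A", "B"], dtype=object)[np.argmax(direct_scores, axis=1)],
    )


def test_train_guards():
    ts, lab = _toy_problem()
    with pytest.raises(MissingClassError):
        train(ts, lab)  # default five conditions absent
    with pytest.raises(ValueError):
        train(VoxelTimeSeries(ts.data[:, :5]), LabelSeries(lab.labels[:5]),
              conditions=("A", "B"))


def test_evidence_strictly_in_unit_interval():
    res = crossval_pipeline(2, n_voxels=50, snr=3.0)
    assert np.all(res.cv.evidence > 0.0)
    assert np.all(res.cv.evidence < 1.0)


class TestDecide:
    def test_argmax(self):
        ev = np.array([[0.7, 0.1, 0.1, 0.05, 0.05]])
        assert decide(ev, CONDITIONS)[0] == "Breath"

    def test_tie_broken_by_declaration_order_with_warning(self):
        ev = np.array([[0.5, 0.5, 0.1, 0.1, 0.1]])
        with pytest.warns(UserWarning, match="tied"):
            out = decide(ev, CONDITIONS)
        assert out[0] == "Breath"

    def test_restriction_and_shape(self):
        rng = np.random.default_rng(0)
        ev = rng.uniform(size=(50, 5))
        out = decide(ev, ("MW", "Self"))
        assert out.shape == (50,)
        assert set(out.tolist()) <= {"MW", "Self"}

    def test_empty_allowed(self):
        with pytest.raises(ValueError):
            decide(np.zeros((1, 5)), ())


def test_cross_validation_partition(cv_mid):
    """Each labeled volume is tested exactly once, by a held-out-block model."""
    cv = cv_mid.cv
    assert cv.n_decisions == 2160
    pairs = set(zip(cv.block_id.tolist(), cv.volume_index.tolist()))
    assert len(pairs) == 2160
    for b in range(6):
        assert int((cv.block_id == b).sum()) == 360


def test_high_snr_accuracy_above_90():
    for seed in (1, 2, 3):
        res = crossval_pipeline(seed, n_voxels=50, snr=2.0)
        assert all(a > 90.0 for a in res.report.per_condition_accuracy.values())
        assert res.report.included


class TestEvaluate:
    def test_all_correct(self):
        labels = np.repeat(np.array(CONDITIONS, dtype=object), 30)
        report = evaluate(labels.copy(), labels)
        assert all(v == 100.0 for v in report.per_condition_accuracy.values())
        assert np.all(np.diag(report.confusion.to_numpy()) == 30)
        assert all(p < 0.001 for _, p in report.chi_square.values())
        assert report.included

    def test_chi_square_worked_example(self):
        """130 correct of 432 gives the goodness-of-fit statistic ~27.5."""
        labels = np.repeat(np.array(CONDITIONS, dtype=object), 432)
        decisions = labels.copy()
        breath = np.flatnonzero(labels == "Breath")
        decisions[breath[130:]] = "Feet"  # 130 correct, 302 wrong
        report = evaluate(decisions, labels)
        stat, p = report.chi_square["Breath"]
        assert stat == pytest.approx(27.50, abs=0.01)
        assert p < 0.001
        assert report.per_condition_accuracy["Breath"] == pytest.approx(130 / 432 * 100)

    def test_confusion_rows_sum_to_tested_counts(self, cv_mid):
        report = cv_mid.report
        rows = report.confusion.sum(axis=1)
        for cond in CONDITIONS:
            assert rows[cond] == report.n_per_condition[cond] == 432

    def test_missing_condition_errors(self):
        labels = np.array(["Breath"] * 20, dtype=object)
        with pytest.raises(ValueError):
            evaluate(labels.copy(), labels)


class TestGroupAccuracy:
    def test_all_at_chance_gives_zero_t_and_d(self):
        res = group_accuracy_test(np.full(8, 20.0))
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_matches_scipy(self):
        from scipy.stats import ttest_1samp

        accs = np.array([45.0, 50.0, 38.0, 61.0, 44.0])
        res = group_accuracy_test(accs)
        t, p = ttest_1samp(accs, 20.0)
        assert res.t == pytest.approx(float(t))
        assert res.p == pytest.approx(float(p))
        assert res.cohens_d == pytest.approx((accs.mean() - 20) / accs.std(ddof=1))


class TestRatingCorrelation:
    def test_fisher_z_of_half(self):
        res = group_rating_test(np.array([0.5, 0.5, 0.5]))
        assert res.mean_z == pytest.approx(0.5493, abs=1e-4)

    def test_all_zero_correlations(self):
        res = group_rating_test(np.zeros(6))
        assert res.mean_z == 0.0 and res.t == 0.0

    def test_constant_ratings_dropped_with_warning(self):
        import pandas as pd

        trials = pd.DataFrame(
            {
                "condition": ["Breath"] * 5,
                "rating": [2] * 5,
                "accuracy": [10.0, 50.0, 30.0, 80.0, 20.0],
            }
        )
        with pytest.warns(UserWarning, match="zero variance"):
            r = rating_correlation(trials)
        assert np.isnan(r)
        with pytest.warns(UserWarning, match="excluding"):
            res = group_rating_test(np.array([0.3, 0.2, r]))
        assert res.n_excluded == 1 and res.n_subjects == 2

    def test_too_few_trials(self):
        import pandas as pd

        trials = pd.DataFrame(
            {"condition": ["Breath"] * 2, "rating": [1, 2], "accuracy": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            rating_correlation(trials)


def test_accuracy_rating_coupling_positive():
    """With ratings tightly coupled to pattern fidelity, trial-level accuracy
    correlates positively with ratings at moderate signal strength."""
    rs = []
    for seed in (1, 2, 3):
        res = crossval_pipeline(seed, n_voxels=40, snr=0.6,
                                fidelity_range=(0.1, 1.0))
        rated = simulate_ratings(res.design, res.truth, coupling=5.0,
                                 noise_sd=0.01, seed=seed)
        trials = per_trial_accuracy(res.cv, rated)
        rs.append(rating_correlation(trials))
    assert np.mean(rs) > 0.2
    assert group_rating_test(np.array(rs)).mean_z > 0.0
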