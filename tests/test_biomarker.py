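"""ROC/AUC, DeLong intervals, bivariate logistic models, benefit score."""

import itertools

import numpy as np
import pytest

import cytoscore as cs


def brute_force_auc(scores, labels):
    """Pairwise concordance with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


class TestRocAuc:
    def test_perfect_separation(self):
        res = cs.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0

    def test_half_concordant_pairs(self):
        assert cs.roc_auc([0.9, 0.2, 0.8, 0.3], [1, 1, 0, 0]).auc == 0.5

    def test_all_tied_scores(self):
        assert cs.roc_auc([0.5, 0.5], [1, 0]).auc == 0.5

    def test_matches_brute_force_concordance(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 60))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = cs.roc_auc(scores, labels)
            assert res.auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_trapezoid_of_curve_equals_concordance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.normal(size=50).round(1)
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = cs.roc_auc(scores, labels)
            assert np.trapezoid(res.tpr, res.fpr) == pytest.approx(
                res.auc, abs=1e-12
            )

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = cs.roc_auc(scores, labels).auc
        b = cs.roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_orientations_sum_to_one(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=31)
        labels = rng.integers(0, 2, 31)
        labels[:2] = [0, 1]
        hi = cs.roc_auc(scores, labels, orientation="higher").auc
        lo = cs.roc_auc(scores, labels, orientation="lower").auc
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_auto_orientation_never_below_half(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            scores = rng.normal(size=20)
            labels = rng.integers(0, 2, 20)
            labels[:2] = [0, 1]
            res = cs.roc_auc(scores, labels, orientation="auto")
            assert res.auc >= 0.5
            assert res.orientation in {"higher", "lower"}

    def test_ci_brackets_auc_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(1, 1, 25), rng.normal(0, 1, 25)]
        labels = np.r_[np.ones(25, int), np.zeros(25, int)]
        for method in ("delong", "hanley-mcneil"):
            res = cs.roc_auc(scores, labels, ci_method=method)
            assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
            assert res.ci_method == method

    def test_strong_marker_rejects_null(self):
        rng = np.random.default_rng(6)
        scores = np.r_[rng.normal(2, 1, 30), rng.normal(0, 1, 30)]
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        assert cs.roc_auc(scores, labels).p_value < 0.001

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cs.roc_auc([0.1, 0.2], [1, 1])


class TestBivariateLogistic:
    def test_null_coefficients_rarely_significant(self):
        rng = np.random.default_rng(0)
        calm = 0
        reps = 40
        for _ in range(reps):
            x1, x2 = rng.normal(size=(2, 500))
            y = rng.integers(0, 2, 500)
            model = cs.fit_bivariate_logistic(x1, x2, y)
            calm += abs(model.z_values[0]) < 3 and abs(model.z_values[1]) < 3
        assert calm >= 0.95 * reps

    def test_symmetric_data_has_zero_intercept(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=300)
        x2 = rng.normal(size=300)
        z = x1 + x2
        y = (rng.random(300) < 1 / (1 + np.exp(-z))).astype(int)
        X1 = np.r_[x1, -x1]
        X2 = np.r_[x2, -x2]
        Y = np.r_[y, 1 - y]
        model = cs.fit_bivariate_logistic(X1, X2, Y)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_signal_recovered_with_good_auc(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=400)
        x2 = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(2 * x1 - x2)))).astype(int)
        model = cs.fit_bivariate_logistic(x1, x2, y)
        assert model.coef[0] > 0 > model.coef[1]
        assert model.roc.auc > 0.75

    def test_separable_data_flagged(self):
        x1 = np.r_[np.zeros(10), np.ones(10) * 5]
        x2 = np.r_[np.linspace(0, 1, 10), np.linspace(0, 1, 10)]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.warns(UserWarning, match="separation"):
            model = cs.fit_bivariate_logistic(x1, x2, y)
        assert model.separation

    def test_constant_predictor_named_in_error(self):
        with pytest.raises(ValueError, match="x2"):
            cs.fit_bivariate_logistic(
                [0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]
            )


class TestBenefitScore:
    THRESHOLDS = (1.219, 0.025, 1.238)

    def test_all_above_scores_four_points(self):
        card = cs.benefit_score(2.0, 0.03, 1.5)
        assert card.total == 4 and card.decision == "beneficial"
        assert card.points == {"rc19": 2, "c22": 1, "ccr6_c07": 1}

    def test_all_below_scores_zero(self):
        card = cs.benefit_score(1.0, 0.01, 1.0)
        assert card.total == 0 and card.decision == "discouraging"

    def test_exact_thresholds_score_nothing(self):
        card = cs.benefit_score(*self.THRESHOLDS)
        assert card.total == 0 and card.decision == "discouraging"

    @pytest.mark.parametrize(
        "above, expected_total",
        [(s, 2 * s[0] + s[1] + s[2]) for s in itertools.product((0, 1), repeat=3)],
    )
    def test_full_truth_table(self, above, expected_total):
        lo = (1.0, 0.01, 1.0)
        hi = (2.0, 0.05, 2.0)
        args = [hi[i] if above[i] else lo[i] for i in range(3)]
        card = cs.benefit_score(*args)
        assert card.total == expected_total
        assert card.decision == (
            "beneficial" if expected_total >= 2 else "discouraging"
        )

    def test_total_nondecreasing_in_each_input(self):
        grid = np.linspace(0.0, 3.0, 13)
        base = (1.0, 0.01, 1.0)
        for i in range(3):
            totals = []
            for v in grid:
                args = list(base)
                args[i] = v
                totals.append(cs.benefit_score(*args).total)
            assert all(a <= b for a, b in zip(totals, totals[1:]))

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            cs.benefit_score(-0.1, 0.0, 0.0)

    def test_custom_thresholds_respected(self):
        thr = cs.ScoreThresholds(rc19_freq=0.5, c22_freq=0.5, ccr6_c07=0.5,
                                 beneficial_min=3)
        card = cs.benefit_score(1.0, 1.0, 0.4, thresholds=thr)
        assert card.total == 3 and card.decision == "beneficial"


def test_youden_threshold_separates_clean_groups():
    scores = np.r_[np.zeros(10), np.ones(10)]
    labels = np.r_[np.zeros(10, int), np.ones(10, int)]
    thr = cs.youden_threshold(scores, labels)
    assert 0.0 < thr <= 1.0
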