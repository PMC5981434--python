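"""Discriminant fitting, noise injection, and forward selection."""

import numpy as np
import pytest

from migrasleep import (FitError, ValidationError, fit_discriminant,
                        inject_noise, predict_labels, sfs_select)
from migrasleep.model import TIE_BREAK_LABEL, balanced_accuracy_score

NON = "non_migraine_comparison"
MIG = "migraine_comparison"


def _two_gaussians(rng, n, mu_a=0.0, mu_b=2.0, sd_a=1.0, sd_b=1.0, d=1):
    Xa = rng.normal(mu_a, sd_a, size=(n, d))
    Xb = rng.normal(mu_b, sd_b, size=(n, d))
    X = np.vstack([Xa, Xb])
    y = np.array([NON] * n + [MIG] * n)
    return X, y


class TestInjectNoise:
    def test_zero_strength_doubles_with_exact_copies(self):
        rng = np.random.default_rng(0)
        X, y = _two_gaussians(rng, 50, d=3)
        X2, y2 = inject_noise(X, y, 0.0, seed=1)
        assert X2.shape == (200, 3)
        assert np.array_equal(X2[:100], X)
        assert np.array_equal(X2[100:], X)
        assert np.array_equal(y2[:100], y)

    def test_injected_sd_scales_with_strength(self):
        """Monte-Carlo: the SD of the injected deltas approximates
        strength x per-feature SD within 5% at n = 10,000."""
        rng = np.random.default_rng(1)
        X = rng.normal(0.0, [1.0, 4.0], size=(10_000, 2))
        y = np.array([NON] * 10_000)
        X2, _ = inject_noise(X, y, 0.3, seed=2)
        deltas = X2[10_000:] - X
        target = 0.3 * X.std(axis=0, ddof=1)
        assert np.allclose(deltas.std(axis=0), target, rtol=0.05)

    def test_empty_input_empty_output(self):
        X2, y2 = inject_noise(np.empty((0, 4)), np.empty(0, dtype=str), 0.1, 0)
        assert len(X2) == 0 and len(y2) == 0

    def test_negative_strength_rejected(self):
        with pytest.raises(ValidationError):
            inject_noise(np.zeros((2, 1)), np.array([NON, MIG]), -0.1, 0)


class TestFitPredict:
    def test_lda_threshold_at_midpoint(self):
        rng = np.random.default_rng(3)
        X, y = _two_gaussians(rng, 10_000)
        m = fit_discriminant(X, y, "lda")
        grid = np.linspace(-2, 4, 6001)[:, None]
        pred = predict_labels(m, grid)
        boundary = grid[np.flatnonzero(pred != pred[0])[0], 0]
        assert boundary == pytest.approx(1.0, abs=0.1)

    def test_qda_boundary_matches_closed_form_roots(self):
        """Equal means, SDs 1 vs 3: the score difference has roots at
        +-sqrt((9/8) ln 9), symmetric about the mean; the fitted QDA must
        disagree with that closed-form rule on <1% of 10,000 points."""
        rng = np.random.default_rng(4)
        X, y = _two_gaussians(rng, 10_000, mu_b=0.0, sd_b=3.0)
        m = fit_discriminant(X, y, "qda", lam=1e-9)
        root = np.sqrt(9.0 / 8.0 * np.log(9.0))
        fresh = rng.normal(0.0, 2.0, size=(10_000, 1))
        closed_form = np.where(np.abs(fresh[:, 0]) < root, NON, MIG)
        disagreement = np.mean(predict_labels(m, fresh) != closed_form)
        assert disagreement < 0.01

    def test_separable_clusters_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        X, y = _two_gaussians(rng, 200, mu_a=0.0, mu_b=50.0, d=2)
        for kind in ("lda", "qda"):
            m = fit_discriminant(X, y, kind)
            assert np.all(predict_labels(m, X) == y)

    def test_observation_at_class_mean_classified_to_it(self):
        rng = np.random.default_rng(6)
        X, y = _two_gaussians(rng, 500, mu_a=0.0, mu_b=3.0)
        m = fit_discriminant(X, y, "lda")
        assert predict_labels(m, m.means[m.classes.index(MIG)][None, :])[0] == MIG

    def test_exact_score_tie_goes_to_non_migraine(self):
        # perfectly symmetric training data => midpoint scores exactly tied
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([NON, NON, MIG, MIG])
        m = fit_discriminant(X, y, "lda")
        s = m.scores(np.array([[0.0]]))
        assert s[0, 0] == pytest.approx(s[0, 1])
        assert predict_labels(m, np.array([[0.0]]))[0] == TIE_BREAK_LABEL

    def test_class_with_single_observation_is_fit_error(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([NON, NON, MIG])
        with pytest.raises(FitError):
            fit_discriminant(X, y, "lda")

    def test_qda_converges_to_lda_with_equal_covariances(self):
        """With equal class covariances QDA and LDA decisions coincide on
        all but <=1% of 10,000 Gaussian points."""
        rng = np.random.default_rng(7)
        X, y = _two_gaussians(rng, 5_000, mu_b=1.5, d=3)
        lda = fit_discriminant(X, y, "lda", lam=1e-9)
        qda = fit_discriminant(X, y, "qda", lam=1e-9)
        fresh = rng.normal(0.75, 1.0, size=(10_000, 3))
        assert np.mean(predict_labels(lda, fresh)
                       != predict_labels(qda, fresh)) <= 0.01

    def test_prediction_invariant_under_feature_rescaling(self):
        rng = np.random.default_rng(8)
        X, y = _two_gaussians(rng, 300, mu_b=1.0, d=4)
        test = rng.normal(0.5, 1.0, size=(500, 4))
        scale = np.array([1.0, 10.0, 0.1, 1.0])
        for kind in ("lda", "qda"):
            a = predict_labels(fit_discriminant(X, y, kind, lam=1e-9), test)
            b = predict_labels(fit_discriminant(X * scale, y, kind, lam=1e-9),
                               test * scale)
            assert np.mean(a != b) < 0.005

    def test_agrees_with_reference_implementation(self):
        """Independent cross-check against scikit-learn's discriminant
        classifiers on the same data."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(9)
        X, y = _two_gaussians(rng, 2_000, mu_b=1.0, d=5)
        fresh = rng.normal(0.5, 1.0, size=(4_000, 5))
        ref_lda = sklearn_da.LinearDiscriminantAnalysis().fit(X, y)
        ours_lda = fit_discriminant(X, y, "lda", lam=1e-12)
        assert np.mean(ref_lda.predict(fresh)
                       != predict_labels(ours_lda, fresh)) < 0.005
        ref_qda = sklearn_da.QuadraticDiscriminantAnalysis().fit(X, y)
        ours_qda = fit_discriminant(X, y, "qda", lam=1e-12)
        assert np.mean(ref_qda.predict(fresh)
                       != predict_labels(ours_qda, fresh)) < 0.005


class TestForwardSelection:
    def _selection_problem(self, rng, n=120, d=20):
        X = rng.normal(0.0, 1.0, size=(n, d))
        y = np.where(rng.random(n) < 0.5, MIG, NON)
        X[y == MIG, 7] += 8.0  # feature 7 separates perfectly
        return X, y

    def test_perfectly_separating_feature_selected_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = self._selection_problem(rng)
            Xv, yv = self._selection_problem(rng)
            sel = sfs_select(X, y, Xv, yv, kind="lda")
            hits += sel[0] == 7
        assert hits >= 19  # >= 95% of runs

    def test_max_features_one_returns_single_feature(self):
        rng = np.random.default_rng(0)
        X, y = self._selection_problem(rng)
        sel = sfs_select(X, y, X, y, kind="lda", max_features=1)
        assert len(sel) == 1

    def test_duplicate_feature_never_selected(self):
        rng = np.random.default_rng(1)
        X, y = self._selection_problem(rng, d=10)
        X = np.column_stack([X, X[:, 7]])  # exact duplicate of the winner
        sel = sfs_select(X, y, X, y, kind="lda")
        assert not (7 in sel and 10 in sel)

    def test_feature_names_returned_when_given(self):
        rng = np.random.default_rng(2)
        X, y = self._selection_problem(rng, d=10)
        names = [f"f{j}" for j in range(10)]
        sel = sfs_select(X, y, X, y, kind="lda", feature_names=names)
        assert sel[0] == "f7"

    def test_selection_matches_explicit_refit_route(self):
        """The submatrix-sliced candidate models must equal refitting from
        scratch on each candidate subset (dual-route check)."""
        rng = np.random.default_rng(3)
        X, y = self._selection_problem(rng, n=80, d=8)
        Xv, yv = self._selection_problem(rng, n=80, d=8)
        sel = sfs_select(X, y, Xv, yv, kind="qda", max_features=3)
        # brute-force first step
        scores = []
        for j in range(8):
            m = fit_discriminant(X[:, [j]], y, "qda")
            scores.append(balanced_accuracy_score(
                yv, predict_labels(m, Xv[:, [j]])))
        assert sel[0] == int(np.argmax(scores))
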