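"""Classifiers and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from admri.classify import (
    ci_from_runs,
    compare_runs,
    evaluate,
    lda_decision,
    lda_fit,
    lda_predict,
    svm_decision,
    svm_fit,
    svm_predict,
)


class TestLda:
    def test_1d_boundary_at_midpoint(self, rng):
        """mu 0/2, shared variance, equal priors: boundary at x = 1."""
        n = 5000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])[:, None]
        y = np.array(["HC"] * n + ["AD"] * n)
        model = lda_fit(X, y)
        grid = np.linspace(0, 2, 4001)[:, None]
        d = lda_decision(model, grid)
        cross = grid[np.argmin(np.abs(d[:, 0] - d[:, 1]))][0]
        assert abs(cross - 1.0) < 0.05

    def test_duplicated_training_set_identical_model(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array(["HC"] * 20 + ["AD"] * 20)
        m1 = lda_fit(X, y)
        m2 = lda_fit(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(m1.means, m2.means)
        pred1 = lda_predict(m1, X)
        pred2 = lda_predict(m2, X)
        assert np.array_equal(pred1, pred2)

    def test_predictions_match_bruteforce_discriminant(self, rng):
        """Predictions equal the plug-in argmax of delta_k on a 2D grid."""
        X = np.vstack(
            [rng.normal([0, 0], 1, (100, 2)), rng.normal([2, 1], 1, (100, 2))]
        )
        y = np.array(["HC"] * 100 + ["AD"] * 100)
        model = lda_fit(X, y)
        g = np.linspace(-3, 5, 100)
        grid = np.array(np.meshgrid(g, g)).reshape(2, -1).T  # 10^4 points
        pred = lda_predict(model, grid)
        # independent evaluation of the discriminant formula
        Sinv = model.cov_inv
        deltas = []
        for k in range(2):
            mu = model.means[k]
            deltas.append(grid @ Sinv @ mu - 0.5 * mu @ Sinv @ mu + np.log(0.5))
        brute = np.where(
            deltas[model.classes.index(model.positive)]
            >= deltas[1 - model.classes.index(model.positive)],
            model.positive,
            [c for c in model.classes if c != model.positive][0],
        )
        assert (pred == brute).all()

    def test_tie_goes_to_positive_class(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["HC", "AD"])
        model = lda_fit(X, y)
        assert lda_predict(model, np.array([[0.0]]))[0] == "AD"

    def test_feature_permutation_consistency(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array(["HC", "AD"] * 30)
        perm = [2, 0, 3, 1]
        m1 = lda_fit(X, y)
        m2 = lda_fit(X[:, perm], y)
        T = rng.normal(size=(10, 4))
        assert np.array_equal(lda_predict(m1, T), lda_predict(m2, T[:, perm]))

    def test_dimension_mismatch_raises(self, rng):
        model = lda_fit(rng.normal(size=(20, 3)), np.array(["a", "b"] * 10))
        with pytest.raises(ValueError, match="dimension"):
            lda_predict(model, rng.normal(size=(5, 2)))


class TestSvm:
    def test_two_point_problem_matches_qp_oracle(self):
        """Separable 2-point instance: dual coefficients from a closed form.

        With one point per class and RBF kernel, the dual reduces to
        maximizing 2a - a^2 (1 - K12) * 2 ... the optimum is
        a = 1 / (1 - K12) for both points (if below C).
        """
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array(["N", "P"])
        gamma = 0.5
        model = svm_fit(X, y, C=100.0, gamma=gamma, tol=1e-8)
        assert (svm_predict(model, X) == y).all()
        K12 = np.exp(-gamma * 4.0)
        a_expect = 1.0 / (1.0 - K12)
        a_fit = np.abs(model.svc.dual_coef_).ravel()
        assert np.allclose(a_fit, a_expect, atol=1e-5)
        # margin constraints satisfied: |f(x_i)| >= 1
        assert (np.abs(svm_decision(model, X)) >= 1 - 1e-6).all()

    def test_label_flip_negates_decision(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array(["N", "P"] * 15)
        flip = {"N": "P", "P": "N"}
        m1 = svm_fit(X, y, C=1.0, gamma=0.7)
        m2 = svm_fit(X, np.array([flip[v] for v in y]), C=1.0, gamma=0.7)
        assert np.allclose(svm_decision(m1, X), -svm_decision(m2, X), atol=1e-3)

    def test_xor_solved_by_rbf_kernel(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array(["A", "A", "B", "B"])
        model = svm_fit(X, y, C=100.0, gamma=1.0)
        assert (svm_predict(model, X) == y).all()


class TestEvaluate:
    def test_perfect(self):
        assert evaluate(["P", "N"], ["P", "N"], "P") == (100.0, 100.0, 100.0)

    def test_hand_counts(self):
        ccr, sen, spe = evaluate(
            ["P", "N", "N", "N"], ["P", "P", "N", "N"], "P"
        )
        assert (ccr, sen, spe) == (75.0, 50.0, 100.0)

    def test_majority_predictor(self):
        truth = ["P"] * 6 + ["N"] * 4
        pred = ["P"] * 10
        assert evaluate(pred, truth, "P") == (60.0, 100.0, 0.0)

    def test_unknown_positive_class_raises(self):
        with pytest.raises(ValueError, match="positive"):
            evaluate(["A"], ["A"], "Z")

    @given(
        st.lists(st.sampled_from(["P", "N"]), min_size=2, max_size=30),
        st.lists(st.sampled_from(["P", "N"]), min_size=1, max_size=29),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_bounds(self, pred, truth):
        n = min(len(pred), len(truth) + 1)
        truth = truth[: n - 1] + ["P"]  # the declared positive class must occur
        ccr, sen, spe = evaluate(pred[:n], truth, "P")
        for v in (ccr, sen, spe):
            assert np.isnan(v) or 0.0 <= v <= 100.0


class TestCi:
    def test_constant_runs_degenerate(self):
        assert ci_from_runs([80.0, 80.0, 80.0]) == (80.0, 80.0)

    def test_percentile_example(self):
        assert ci_from_runs([60, 70, 80, 90, 100]) == (61.0, 99.0)

    def test_width_shrinks_with_test_size(self, rng):
        """Larger test sets give tighter CCR run distributions."""
        widths = []
        for n_test in (10, 40, 160):
            runs = [
                100.0 * rng.binomial(n_test, 0.8) / n_test for _ in range(300)
            ]
            lo, hi = ci_from_runs(runs)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="2 runs"):
            ci_from_runs([80.0])


class TestCompareRuns:
    def test_identical_not_significant(self):
        runs = [70.0, 75.0, 80.0, 85.0]
        t, p, sig, ks = compare_runs(runs, list(runs))
        assert t == 0.0 and not sig

    def test_scalar_t_oracle(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        t, p, _, _ = compare_runs(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_expect = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert t == pytest.approx(t_expect, abs=1e-10)

    def test_separated_normals_significant(self, rng):
        hits = 0
        for _ in range(20):
            a = rng.normal(70, 1, 300)
            b = rng.normal(80, 1, 300)
            _, _, sig, ks = compare_runs(a, b, alpha=1e-4)
            hits += sig and ks
        assert hits == 20

    def test_ks_flags_non_normal(self, rng):
        a = np.concatenate([rng.normal(0, 0.05, 200), rng.normal(10, 0.05, 200)])
        b = rng.normal(5, 1, 200)
        _, _, _, ks = compare_runs(a, b)
        assert not ks
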