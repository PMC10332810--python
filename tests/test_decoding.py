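"""Logistic-regression decoder: formula oracles, optimizer behavior, LOOCV
structure and the transfer protocols."""
import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from mbflex import decoding as dec
from mbflex.decoding import FitSettings


def separable_toy(n_per=6, gap=2.0, seed=0):
    """Two 2-cell clusters separated along the first feature."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per, 2)) * 0.2 + [gap, 0.0]
    b = rng.normal(size=(n_per, 2)) * 0.2 + [-gap, 0.0]
    X = np.vstack([a, b])
    y = np.concatenate([np.ones(n_per), np.zeros(n_per)])
    return X, y


class TestPredict:
    def test_zero_weights_give_half(self, rng):
        X = rng.normal(size=(7, 4))
        np.testing.assert_allclose(dec.predict(np.zeros(4), X), 0.5)

    def test_saturation(self):
        assert dec.predict(np.array([20.0]), np.array([[1.0]]))[0] > 0.999999
        assert dec.predict(np.array([-20.0]), np.array([[1.0]]))[0] < 1e-6

    def test_hand_evaluated_trial(self):
        h = dec.predict(np.array([0.5, -0.25]), np.array([[1.0, 2.0]]))
        assert h[0] == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dec.predict(np.ones(3), np.ones((2, 4)))

    def test_joint_cell_permutation_invariance(self, rng):
        X = rng.normal(size=(5, 6))
        theta = rng.normal(size=6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            dec.predict(theta, X), dec.predict(theta[perm], X[:, perm])
        )


class TestCostAndGradient:
    def test_zero_weights_cost_is_ln2(self, rng):
        X = rng.normal(size=(9, 5))
        y = (rng.uniform(size=9) > 0.5).astype(float)
        assert dec.cost(np.zeros(5), X, y) == pytest.approx(np.log(2))

    def test_hand_worked_regularized_example(self):
        # m=1, y=1, h=0.5, lambda=2, theta=[1,1]:
        # -log(0.5) + (2 / (2*1)) * 2 = 0.6931... + 2
        c = dec.cost(np.array([1.0, 1.0]), np.array([[1.0, -1.0]]),
                     np.array([1.0]), lam=2.0)
        assert c == pytest.approx(np.log(2) + 2.0, abs=1e-4)
        assert c == pytest.approx(2.6931, abs=1e-4)

    def test_nonbinary_targets_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            dec.cost(np.zeros(2), np.ones((1, 2)), np.array([0.5]))

    @pytest.mark.parametrize("lam", [0.0, 1.0, 3.7])
    def test_gradient_matches_finite_differences(self, lam):
        rng = np.random.default_rng(77)
        eps = 1e-6
        worst = 0.0
        for _ in range(20):
            X = rng.normal(size=(5, 4))
            y = (rng.uniform(size=5) > 0.5).astype(float)
            theta = rng.normal(size=4)
            g = dec.gradient(theta, X, y, lam=lam)
            fd = np.empty(4)
            for j in range(4):
                e = np.zeros(4)
                e[j] = eps
                fd[j] = (dec.cost(theta + e, X, y, lam=lam)
                         - dec.cost(theta - e, X, y, lam=lam)) / (2 * eps)
            worst = max(worst, np.abs(g - fd).max() / max(np.abs(fd).max(), 1e-12))
        assert worst < 1e-6

    def test_regularization_term_isolated(self):
        # paired +/- targets at identical features cancel the data term
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        y = np.array([0.0, 1.0])
        theta = np.array([0.0, 0.0])
        theta2 = np.array([0.3, -0.4])
        g = dec.gradient(theta2, X, y, lam=5.0) - dec.gradient(theta2, X, y, lam=0.0)
        np.testing.assert_allclose(g, 5.0 / 2 * theta2)
        np.testing.assert_allclose(dec.gradient(theta, X, y, lam=5.0), 0.0)


class TestFit:
    def test_separable_training_accuracy_and_monotone_cost(self):
        X, y = separable_toy()
        model = dec.fit(X, y, np.ones(2), lam=0.0)
        h = dec.predict(model, X)
        assert np.all((h >= 0.5) == (y == 1))
        assert np.all(np.diff(model.cost_history) <= 1e-15)

    def test_huge_regularization_shrinks_weights(self):
        X, y = separable_toy()
        theta0 = np.ones(2)
        model = dec.fit(X, y, theta0, lam=1e6)
        assert np.linalg.norm(model.theta) < np.linalg.norm(theta0)
        np.testing.assert_allclose(dec.predict(model, X), 0.5, atol=0.01)

    def test_determinism(self):
        X, y = separable_toy(seed=4)
        m1 = dec.fit(X, y, np.ones(2), lam=0.5)
        m2 = dec.fit(X, y, np.ones(2), lam=0.5)
        np.testing.assert_array_equal(m1.theta, m2.theta)

    def test_norm_nonincreasing_in_lambda(self):
        X, y = separable_toy(seed=2)
        norms = [
            np.linalg.norm(dec.fit(X, y, np.ones(2), lam=lam).theta)
            for lam in (0.0, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_gradient_small_at_regularized_optimum(self):
        X, y = separable_toy(seed=6)
        model = dec.fit(X, y, np.zeros(2), lam=2.0,
                        settings=FitSettings(cost_tolerance=1e-14))
        g = dec.gradient(model, X, y)
        assert np.abs(g).max() < 1e-4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            dec.fit(np.ones((3, 2)), np.ones(3), np.zeros(2))

    def test_agrees_with_sklearn_reference(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X, y = separable_toy(n_per=8, gap=0.8, seed=9)
        ours = dec.fit(
            X, y, np.zeros(2), lam=1.0,
            settings=FitSettings(learning_rate=0.5, max_iter=200_000,
                                 cost_tolerance=1e-15),
        )
        # m * our_cost = sum(loss) + (lambda/2)||theta||^2, so sklearn C = 1/lambda
        ref = sklearn_lm.LogisticRegression(
            C=1.0, fit_intercept=False, tol=1e-12
        ).fit(X, y)
        np.testing.assert_allclose(ours.theta, ref.coef_.ravel(), atol=1e-3)


class TestInitSchemes:
    def test_ones(self):
        np.testing.assert_array_equal(dec.init_weights_ones(3), [1.0, 1.0, 1.0])
        assert dec.init_weights_ones(1).shape == (1,)

    def test_connectome_normalization_support(self):
        theta0 = dec.init_weights_connectome(np.array([10, 20, 40]), 200, seed=0)
        assert set(np.unique(theta0)) <= {0.25, 0.5, 1.0}
        assert np.all((theta0 > 0) & (theta0 <= 1))

    def test_equal_counts_give_all_ones(self):
        np.testing.assert_array_equal(
            dec.init_weights_connectome(np.full(5, 7), 4, seed=1), np.ones(4)
        )

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            dec.init_weights_connectome(np.array([]), 3)


class TestLoocv:
    def features(self, seed=0, n_cells=10, n_per=4, odors=("A", "B")):
        rng = np.random.default_rng(seed)
        X, labels = [], []
        for i, odor in enumerate(odors):
            center = np.zeros(n_cells)
            center[i::len(odors)] = 2.0
            X.append(rng.normal(size=(n_per, n_cells)) * 0.1 + center)
            labels += [odor] * n_per
        return np.vstack(X), np.array(labels)

    def test_every_trial_held_out_once_vs_enumeration(self):
        X, labels = self.features()
        res = dec.loocv_odor_accuracy(X, labels, "A", lam=1.0)
        assert res.n_folds_evaluated == len(labels)
        np.testing.assert_array_equal(res.folds["fold"], np.arange(len(labels)))
        # enumeration oracle: refit each fold explicitly through fit/predict
        theta0 = dec.init_weights_ones(X.shape[1])
        for i in res.folds["fold"]:
            mask = np.ones(len(labels), dtype=bool)
            mask[i] = False
            model = dec.fit(X[mask], (labels[mask] == "A").astype(float),
                            theta0, lam=1.0)
            h = float(dec.predict(model, X[i]))
            assert h == pytest.approx(
                float(res.folds.loc[res.folds["fold"] == i, "output"].iloc[0]),
                abs=1e-12,
            )

    def test_separable_minimal_two_trials(self):
        X = np.array([[2.0, 0.0], [2.1, 0.0], [0.0, 2.0], [0.0, 1.9]])
        labels = np.array(["A", "A", "B", "B"])
        res = dec.loocv_odor_accuracy(X, labels, "A", lam=0.0)
        assert res.accuracy == 1.0
        assert (res.folds["target"] == 1).sum() == 2

    def test_balanced_mode_scores_negatives(self):
        X, labels = self.features()
        res = dec.loocv_odor_accuracy(X, labels, "A", lam=1.0, mode="balanced")
        assert 0.0 <= res.accuracy <= 1.0

    def test_too_few_target_trials_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError):
            dec.loocv_odor_accuracy(X, np.array(["A", "B", "B"]), "A")


class TestProtocols:
    def toy_features(self, eps=0.6, noise=0.05, n_per=4, n_cells=30, seed=0):
        rng = np.random.default_rng(seed)
        amp_a = np.zeros(n_cells); amp_a[:6] = 1.0
        amp_ap = np.zeros(n_cells); amp_ap[2:8] = 1.0
        amp_b = np.zeros(n_cells); amp_b[20:26] = 1.0
        pert = rng.normal(size=n_cells) * eps
        means = {
            "A": amp_a, "A_prime": amp_ap, "B": amp_b,
            "A>A_prime": amp_ap + pert, "A_prime>A": amp_a - pert,
        }
        return {
            s: m + rng.normal(size=(n_per, n_cells)) * noise
            for s, m in means.items()
        }

    def test_pulse_trained_keeps_transitions_low(self):
        feats = self.toy_features(eps=0.0)
        res = dec.protocol_mbon_emulation(feats)
        assert res.mean_output("A") < 0.5
        assert res.mean_output("A_prime") < 0.5
        assert res.mean_output("B") > 0.5
        assert res.mean_output("A>A_prime") < 0.5
        assert res.mean_output("A_prime>A") < 0.5

    def test_transition_training_separates_orders(self):
        feats = self.toy_features(eps=0.8)
        res = dec.protocol_transition_trained(feats)
        assert res.mean_output("A>A_prime") > 0.5 > res.mean_output("A_prime>A")
        assert res.mean_output("A") < 0.5 and res.mean_output("A_prime") < 0.5

    def test_missing_class_rejected(self):
        feats = self.toy_features()
        feats.pop("A_prime")
        with pytest.raises(ValueError, match="missing"):
            dec.protocol_mbon_emulation(feats)
        feats2 = self.toy_features()
        feats2.pop("A_prime>A")
        with pytest.raises(ValueError, match="A_prime>A"):
            dec.protocol_mbon_emulation(feats2)


class TestWeightResponseCorrelation:
    def test_perfect_anticorrelation(self, rng):
        amp = rng.uniform(size=12)
        assert dec.weight_response_correlation(-amp, amp) == pytest.approx(-1.0)

    def test_independent_weights_near_zero(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            rs.append(dec.weight_response_correlation(
                rng.normal(size=50), rng.uniform(size=50)
            ))
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dec.weight_response_correlation(np.ones(5), np.arange(5.0))


@hyp_settings(max_examples=40, deadline=None, derandomize=True)
@given(
    m=st.integers(2, 8), n=st.integers(1, 6),
    seed=st.integers(0, 1000), lam=st.floats(0.0, 10.0),
)
def test_predict_and_cost_always_valid(m, n, seed, lam):
    """h stays inside (0,1) and the cost is finite for any finite inputs."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(m, n)) * 3
    theta = rng.normal(size=n) * 3
    y = (rng.uniform(size=m) > 0.5).astype(float)
    h = dec.predict(theta, X)
    assert np.all((h > 0) & (h < 1))
    assert np.isfinite(dec.cost(theta, X, y, lam=lam))
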