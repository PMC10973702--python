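"""Linear separator and MLP: decision contract, forward rule, determinism."""

import numpy as np
import pytest

from sulcalml import (
    LinearSeparator,
    MlpClassifier,
    MlpSpec,
    fit_linear_svm,
    fit_mlp,
)
from sulcalml.validation import compute_metrics, confusion_from_predictions


@pytest.fixture
def blobs(rng):
    X = np.vstack([rng.normal(-2, 0.5, (30, 3)), rng.normal(2, 0.5, (30, 3))])
    y = np.repeat([0, 1], 30)
    return X, y


class TestLinearSeparator:
    def test_symmetric_1d_boundary_at_zero(self):
        X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        m = fit_linear_svm(X, y)
        assert abs(m.b / m.w[0]) < 1e-6  # boundary at origin
        assert (m.predict(X) == y).all()

    def test_separable_blobs_resubstitution_perfect(self, blobs):
        X, y = blobs
        m = fit_linear_svm(X, y)
        assert (m.predict(X) == y).mean() == 1.0

    def test_xor_at_most_three_of_four(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([0, 0, 1, 1])
        m = fit_linear_svm(X, y)
        assert (m.predict(X) == y).mean() <= 0.75

    def test_decision_value_formula(self):
        m = LinearSeparator()
        m.w, m.b = np.array([1.0, 0.0]), 0.0
        assert m.decision_values(np.array([[2.0, 5.0]]))[0] == 2.0
        # symmetric points give opposite-sign values
        vals = m.decision_values(np.array([[3.0, 1.0], [-3.0, -1.0]]))
        assert vals[0] == -vals[1]

    def test_auc_on_separable_data(self, blobs):
        X, y = blobs
        m = fit_linear_svm(X, y)
        cm = confusion_from_predictions(y, m.predict(X))
        assert compute_metrics(cm, m.decision_values(X), y).auc == 1.0

    def test_theta_norm_recomputation(self, blobs):
        X, y = blobs
        m = fit_linear_svm(X, y)
        assert m.theta_norm_sq() == pytest.approx(
            float(np.sum(m.w**2) + m.b**2), abs=1e-12
        )

    def test_feature_scaling_shrinks_weights_inversely(self, blobs):
        """On separable data, scaling X by c scales ||w|| by ~1/c with
        predictions unchanged."""
        X, y = blobs
        m1 = fit_linear_svm(X, y)
        m2 = fit_linear_svm(10 * X, y)
        assert (m1.predict(X) == m2.predict(10 * X)).all()
        ratio = np.linalg.norm(m1.w) / np.linalg.norm(m2.w)
        assert ratio == pytest.approx(10.0, rel=0.05)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            fit_linear_svm(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_dimension_mismatch(self, blobs):
        X, y = blobs
        m = fit_linear_svm(X, y)
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 5)))

    def test_json_round_trip(self, blobs):
        X, y = blobs
        m = fit_linear_svm(X, y)
        m2 = LinearSeparator.from_dict(m.to_dict())
        np.testing.assert_allclose(m.decision_values(X), m2.decision_values(X))


class TestMlpForward:
    def _crafted(self, W1, b1):
        """Network whose first hidden layer is (W1, b1), the second hidden
        layer passes activation through, and the output contrasts it with 0."""
        m = MlpClassifier(MlpSpec(hidden=(1, 1)))
        m.weights = [np.asarray(W1, float), np.array([[1.0]]),
                     np.array([[1.0, 0.0]])]
        m.biases = [np.asarray(b1, float), np.zeros(1), np.zeros(2)]
        return m

    def test_perceptron_rule_by_hand(self):
        # w=(1,2), b=0.5, input (1,1): w.y + b = 3.5 propagated to the output
        m = self._crafted([[1.0], [2.0]], [0.5])
        probs = m.forward_single(np.array([1.0, 1.0]))
        z = 3.5
        expected = np.exp([z, 0]) / np.exp([z, 0]).sum()
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_relu_blocks_negative_preactivation(self):
        m = self._crafted([[1.0], [2.0]], [0.5])
        probs = m.forward_single(np.array([-5.0, 0.0]))  # pre-act -4.5 -> 0
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)

    def test_zero_hidden_weights_give_constant_output(self):
        m = self._crafted([[0.0], [0.0]], [0.0])
        out = m.predict_proba(np.random.default_rng(0).normal(size=(5, 2)))
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_positive_regime_composes_linearly(self):
        """Where every pre-activation is positive, ReLU is the identity and
        the network equals the composed linear map."""
        m = self._crafted([[0.3], [0.4]], [1.0])
        x = np.array([2.0, 1.0])
        z = 0.3 * 2 + 0.4 * 1 + 1.0
        probs = m.forward_single(x)
        expected = np.exp([z, 0]) / np.exp([z, 0]).sum()
        np.testing.assert_allclose(probs, expected, atol=1e-12)


class TestMlpTraining:
    def test_zero_epochs_equals_seeded_init(self, blobs):
        X, y = blobs
        trained = fit_mlp(X, y, MlpSpec(epochs=0, seed=7))
        fresh = MlpClassifier(MlpSpec(epochs=0, seed=7))
        fresh._init_params(X.shape[1])
        np.testing.assert_array_equal(trained.weights[0], fresh.weights[0])
        np.testing.assert_allclose(trained.predict_proba(X),
                                   fresh.predict_proba(X))

    def test_separable_blobs_high_accuracy_across_seeds(self, blobs):
        X, y = blobs
        for seed in range(3):
            m = fit_mlp(X, y, MlpSpec(seed=seed))
            assert (m.predict(X) == y).mean() >= 0.95

    def test_seed_reproducibility(self, blobs):
        X, y = blobs
        m1 = fit_mlp(X, y, MlpSpec(seed=5))
        m2 = fit_mlp(X, y, MlpSpec(seed=5))
        for W1, W2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(W1, W2)

    def test_decision_values_match_predictions(self, blobs):
        X, y = blobs
        m = fit_mlp(X, y, MlpSpec(seed=1))
        np.testing.assert_array_equal(m.predict(X),
                                      (m.decision_values(X) > 0).astype(int))

    def test_theta_norm_recomputation(self, blobs):
        X, y = blobs
        m = fit_mlp(X, y, MlpSpec(seed=2))
        manual = sum(float(np.sum(W**2)) for W in m.weights) + sum(
            float(np.sum(c**2)) for c in m.biases
        )
        assert m.theta_norm_sq() == pytest.approx(manual, rel=1e-12)

    def test_non_finite_input_rejected(self):
        X = np.array([[1.0, np.nan], [0, 1], [1, 0], [0, 0]])
        with pytest.raises(ValueError):
            fit_mlp(X, np.array([0, 0, 1, 1]))

    def test_json_round_trip(self, blobs):
        X, y = blobs
        m = fit_mlp(X, y, MlpSpec(seed=3))
        m2 = MlpClassifier.from_dict(m.to_dict())
        np.testing.assert_allclose(m.predict_proba(X), m2.predict_proba(X))
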