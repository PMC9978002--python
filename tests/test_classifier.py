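"""One-vs-All non-linear logistic regression: math, training, decisions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import graspsense as gs
from graspsense.classifier import _cost, decide
from graspsense.dataset import Normalization
from graspsense.errors import (
    InsufficientData,
    InvalidLabel,
    LearningRateTooHigh,
    ModelInputMismatch,
    TraceTooShort,
)

IDENTITY3 = Normalization(mean=np.zeros(3), scale=np.ones(3))


def make_binary(weights, bias, threshold=0.5, degree=1, norm=IDENTITY3):
    return gs.BinaryNLR(
        weights=np.asarray(weights, float), bias=bias, threshold=threshold,
        feature_degree=degree, positive_class=1, normalization=norm,
    )


class TestSigmoid:
    def test_symmetry_point(self):
        assert gs.sigmoid(0.0) == 0.5

    def test_log_three(self):
        assert gs.sigmoid(math.log(3)) == pytest.approx(0.75)

    @given(st.floats(min_value=-700, max_value=700))
    def test_complement_identity(self, z):
        assert gs.sigmoid(z) + gs.sigmoid(-z) == pytest.approx(1.0)

    def test_extreme_arguments_stay_finite(self):
        assert gs.sigmoid(700.0) == pytest.approx(1.0)
        assert gs.sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)


class TestExpandFeatures:
    def test_degree_one_is_identity(self):
        x = np.array([1.5, -2.0, 3.0])
        np.testing.assert_array_equal(gs.expand_features(x, 1)[0], x)

    def test_degree_two_term_count_and_values(self):
        out = gs.expand_features(np.array([[2.0, 3.0, 5.0]]), 2)[0]
        assert out.size == 9  # 3 linear + 3 squares + 3 cross products
        assert set(np.round(out, 9)) == {2, 3, 5, 4, 6, 10, 9, 15, 25}

    def test_degree_two_sparsity(self):
        out = gs.expand_features(np.array([[1.0, 0.0, 0.0]]), 2)[0]
        assert np.count_nonzero(out) == 2  # a and a²


class TestPredictProba:
    def test_zero_model_is_half(self):
        m = make_binary([0, 0, 0], 0.0)
        assert gs.predict_proba(m, [123.0, -4.0, 9.0]) == 0.5

    def test_large_bias_saturates(self):
        m = make_binary([0, 0, 0], 500.0)
        assert gs.predict_proba(m, [0, 0, 0]) == pytest.approx(1.0)

    def test_single_weight_closed_form(self):
        m = make_binary([1, 0, 0], 0.0)
        assert gs.predict_proba(m, [math.log(3), 7.0, -2.0]) == pytest.approx(0.75)

    def test_dimension_mismatch_signals(self):
        m = make_binary([1.0, 1.0], 0.0)  # wrong length for 3 raw features
        with pytest.raises(ModelInputMismatch):
            gs.predict_proba(m, [1.0, 2.0, 3.0])

    def test_probabilities_strictly_inside_unit_interval(self, default_model, table2_dataset):
        P = default_model.probabilities(table2_dataset.features("validation")[:500])
        assert np.all(P > 0.0) and np.all(P < 1.0)


class TestCrossEntropy:
    def test_perfect_fit_limit(self):
        m = make_binary([50, 0, 0], 0.0)
        X = np.array([[10.0, 0, 0], [-10.0, 0, 0]])
        assert gs.cross_entropy(m, X, np.array([1, 0])) <= 1e-6

    def test_zero_model_gives_ln2(self):
        m = make_binary([0, 0, 0], 0.0)
        X = np.zeros((7, 3))
        y = np.array([1, 0, 1, 1, 0, 0, 1])
        assert gs.cross_entropy(m, X, y) == pytest.approx(math.log(2))

    def test_matches_per_sample_loop_oracle(self):
        rng = np.random.default_rng(0)
        m = make_binary(rng.normal(size=3), 0.3)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        p = np.array([gs.predict_proba(m, x) for x in X])
        manual = -np.mean([yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for yi, pi in zip(y, p)])
        assert gs.cross_entropy(m, X, y) == pytest.approx(manual, abs=1e-12)

    def test_invalid_labels_rejected(self):
        m = make_binary([0, 0, 0], 0.0)
        with pytest.raises(InvalidLabel):
            gs.cross_entropy(m, np.zeros((2, 3)), np.array([0, 2]))


class TestFitBinary:
    def test_separable_toy_is_perfect(self):
        X = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        y = np.array([1, 0])
        m = gs.fit_binary(X, y, gs.TrainConfig(feature_degree=1), normalization=IDENTITY3)
        p = gs.predict_proba(m, X)
        assert np.array_equal((p >= 0.5).astype(int), y)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, size=30).astype(float)
        Xe = gs.expand_features(X, 2)
        h = 1e-6
        from graspsense.classifier import _grad, sigmoid

        for _ in range(10):
            w = rng.normal(size=Xe.shape[1])
            b = rng.normal()
            p = sigmoid(Xe @ w + b)
            gw, gb = _grad(Xe, p, y, w, l2=0.0)
            for j in range(w.size):
                wp, wm = w.copy(), w.copy()
                wp[j] += h
                wm[j] -= h
                num = (
                    _cost(sigmoid(Xe @ wp + b), y, wp, 0.0)
                    - _cost(sigmoid(Xe @ wm + b), y, wm, 0.0)
                ) / (2 * h)
                assert gw[j] == pytest.approx(num, abs=1e-6)
            num_b = (
                _cost(sigmoid(Xe @ w + b + h), y, w, 0.0)
                - _cost(sigmoid(Xe @ w + b - h), y, w, 0.0)
            ) / (2 * h)
            assert gb == pytest.approx(num_b, abs=1e-6)

    def test_cost_trajectory_non_increasing(self, default_model):
        for c, m in default_model.binaries.items():
            assert np.all(np.diff(m.j_history) <= 1e-12)

    def test_boundary_matches_reference_implementation(self):
        # 2-feature Gaussian clusters; compare the degree-1 boundary with
        # an unpenalized scikit-learn fit of the same model.
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal([-1, 0], 1, (300, 2)), rng.normal([1, 1], 1, (300, 2))])
        y = np.r_[np.zeros(300), np.ones(300)]
        norm = Normalization.fit(X)
        cfg = gs.TrainConfig(
            feature_degree=1, learning_rate=1.0, max_iterations=20000, convergence_tol=1e-14
        )
        ours = gs.fit_binary(X, y, cfg, normalization=norm)
        ref = LogisticRegression(C=np.inf, tol=1e-10, max_iter=10000).fit(norm.apply(X), y)
        np.testing.assert_allclose(ours.weights, ref.coef_[0], rtol=0.02, atol=0.01)
        assert ours.bias == pytest.approx(ref.intercept_[0], rel=0.02, abs=0.01)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientData):
            gs.fit_binary(np.zeros((4, 3)), np.ones(4), gs.TrainConfig())

    def test_runaway_learning_rate_signals(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3)) * 100
        y = rng.integers(0, 2, size=50)
        with pytest.raises(LearningRateTooHigh):
            gs.fit_binary(
                X, y, gs.TrainConfig(learning_rate=1e6, feature_degree=2),
                normalization=IDENTITY3,
            )

    def test_parameter_recovery_degree_one(self):
        # data generated from a known logistic model must be re-fitted to
        # within 10% relative weight error at n = 10,000
        rng = np.random.default_rng(4)
        w_true = np.array([1.5, -2.0, 0.8])
        b_true = 0.3
        X = rng.normal(size=(10_000, 3))
        y = (rng.random(10_000) < gs.sigmoid(X @ w_true + b_true)).astype(int)
        cfg = gs.TrainConfig(
            feature_degree=1, learning_rate=1.0, max_iterations=20000, convergence_tol=1e-13
        )
        m = gs.fit_binary(X, y, cfg, normalization=IDENTITY3)
        rel_err = np.linalg.norm(m.weights - w_true) / np.linalg.norm(w_true)
        assert rel_err <= 0.10


class TestOptimizeThreshold:
    def grid(self):
        return np.round(np.arange(0.05, 0.9501, 0.01), 4)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        m = make_binary(rng.normal(size=3), 0.1)
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]  # both classes guaranteed
        grid = self.grid()
        got = gs.optimize_threshold(m, X, y, grid)
        p = gs.predict_proba(m, X)
        best = None
        for th in grid:  # exhaustive oracle with the same tie-break
            tp = np.sum((y == 1) & (p >= th)); fp = np.sum((y == 0) & (p >= th))
            fn = np.sum((y == 1) & (p < th))
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            key = (-f1, abs(th - 0.5), th)
            if best is None or key < best[0]:
                best = (key, th)
        assert got == pytest.approx(best[1])

    def test_separated_scores_tie_break_toward_half(self):
        m = make_binary([20.0, 0, 0], 0.0)
        X = np.array([[-1.0, 0, 0]] * 5 + [[1.0, 0, 0]] * 5)
        y = np.array([0] * 5 + [1] * 5)
        assert gs.optimize_threshold(m, X, y, self.grid()) == pytest.approx(0.5)

    def test_flat_objective_returns_half(self):
        m = make_binary([0.0, 0, 0], 0.0)  # p == 0.5 everywhere
        X = np.zeros((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        assert gs.optimize_threshold(m, X, y, self.grid()) == pytest.approx(0.5)

    def test_empty_grid_rejected(self):
        m = make_binary([1.0, 0, 0], 0.0)
        with pytest.raises(ValueError):
            gs.optimize_threshold(m, np.zeros((2, 3)), np.array([0, 1]), [])

    def test_never_worse_than_default_threshold(self, default_model, table2_dataset):
        from graspsense.classifier import _binary_f1, sigmoid

        X_val = table2_dataset.features("validation")
        y_val = table2_dataset.labels("validation")
        for c, m in default_model.binaries.items():
            p = sigmoid(m.decision_values(X_val))
            yb = (y_val == c).astype(int)
            assert _binary_f1(yb, (p >= m.threshold).astype(int)) >= _binary_f1(
                yb, (p >= 0.5).astype(int)
            )


class TestDecisionRule:
    def test_single_firing_class(self):
        assert decide(np.array([0.9, 0.1, 0.1]), np.full(3, 0.5)) == 0

    def test_fallback_to_argmax_when_none_fires(self):
        assert decide(np.array([0.4, 0.3, 0.2]), np.full(3, 0.5)) == 0

    def test_margin_beats_raw_probability(self):
        # class 2 fires with the larger margin even though class 1 is more probable
        assert decide(np.array([0.1, 0.6, 0.55]), np.array([0.5, 0.58, 0.3])) == 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = rng.random(3)
            th = rng.uniform(0.05, 0.95, 3)
            fired = [k for k in range(3) if p[k] >= th[k]]
            if fired:
                expected = max(fired, key=lambda k: (p[k] - th[k], -k))
            else:
                expected = int(np.argmax(p))
            assert decide(p, th) == expected

    def test_vectorized_predict_agrees_with_scalar(self, default_model, table2_dataset):
        X = table2_dataset.features("validation")[:100]
        vec = gs.predict_sample(default_model, X)
        scalar = [gs.predict_sample(default_model, x) for x in X]
        assert vec.tolist() == scalar


class TestPredictClosure:
    def current_gate_model(self):
        """Hand-built ensemble voting purely on the current feature:
        class 1 for current > 1, class 2 for current < -1, else class 0."""
        norm = IDENTITY3
        b = {
            0: make_binary([0, 0, 0], -20.0, norm=norm),
            1: make_binary([30, 0, 0], -30.0, norm=norm),
            2: make_binary([-30, 0, 0], -30.0, norm=norm),
        }
        return gs.OvAClassifier(binaries=b, normalization=norm, feature_degree=1)

    def trace_from_currents(self, currents):
        n = len(currents)
        return gs.GraspTrace(
            t=np.arange(n) / 100.0,
            theta_ref=np.zeros(n),
            theta_out=np.zeros(n),
            current=np.asarray(currents, float),
            sample_rate=100.0,
        )

    def test_unanimous_window(self):
        model = self.current_gate_model()
        tr = self.trace_from_currents([-5.0] * 100)
        assert gs.predict_closure(model, tr) == 2

    def test_majority_vote(self):
        model = self.current_gate_model()
        # final 50 samples: 26 votes for class 1, 24 for class 2
        tr = self.trace_from_currents([0.0] * 50 + [5.0] * 26 + [-5.0] * 24)
        assert gs.predict_closure(model, tr) == 1

    def test_tie_prefers_current_consistent_class(self):
        model = self.current_gate_model()
        tr = self.trace_from_currents([5.0] * 25 + [-5.0] * 25)
        assert gs.predict_closure(model, tr) == 1  # rigid over soft on a tie

    def test_short_trace_rejected(self):
        model = self.current_gate_model()
        tr = self.trace_from_currents([0.0] * 10)
        with pytest.raises(TraceTooShort):
            gs.predict_closure(model, tr)

    def test_void_simulation_classified_void(self, default_model, cfg):
        tr = gs.simulate_closure(
            cfg.motor, cfg.gains, cfg.object("void"), cfg.reference("emg_like"),
            cfg.duration, seed=77,
        )
        assert gs.predict_closure(default_model, tr) == 0


class TestOvA:
    def test_well_separated_clusters_perfect_f1(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        frames = []
        centers = {0: [0, 0, 0], 1: [20, 0, 0], 2: [0, 20, 0]}
        cid = 0
        for label, center in centers.items():
            for _ in range(10):
                pts = rng.normal(center, 0.5, size=(20, 3))
                frames.append(
                    pd.DataFrame(
                        {
                            "current_mA": pts[:, 0],
                            "theta_ref_deg": pts[:, 1],
                            "theta_out_deg": pts[:, 2],
                            "label": label,
                            "closure_id": cid,
                            "split": "unassigned",
                        }
                    )
                )
                cid += 1
        ds = gs.split_dataset(gs.LabeledDataset(frame=pd.concat(frames, ignore_index=True)), seed=0)
        model = gs.fit_ova(ds, gs.TrainConfig(max_iterations=2000))
        pred = gs.predict_sample(model, ds.features("validation"))
        assert gs.f1_score(gs.confusion(ds.labels("validation"), pred)) == 100.0

    def test_missing_class_rejected(self):
        from test_dataset import fabricated_dataset

        ds = gs.split_dataset(fabricated_dataset([0] * 5 + [1] * 5), seed=0)
        with pytest.raises(InsufficientData):
            gs.fit_ova(ds, gs.TrainConfig())

    def test_serialization_round_trip(self, default_model, table2_dataset, tmp_path):
        path = tmp_path / "model.json"
        default_model.to_json(path)
        back = gs.OvAClassifier.from_json(path)
        X = table2_dataset.features("validation")[:200]
        np.testing.assert_array_equal(
            gs.predict_sample(back, X), gs.predict_sample(default_model, X)
        )
        np.testing.assert_allclose(back.thresholds, default_model.thresholds)
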