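import itertools

import numpy as np
import pytest

from bsma.accuracy import brier_score, window_outcomes
from bsma.averaging import (
    WeightVector,
    average_predictions,
    estimate_weights,
    prediction_se,
)
from bsma.prediction import RiskMatrix
from tests.test_accuracy import toy_study


def make_instance(rng, K, n, s=0.5, t=1.0):
    """Uncensored toy: predictions (n, K) and aligned outcomes."""
    T = s + 0.05 + rng.exponential(1.0, n)
    study = toy_study(T, np.ones(n, int))
    out = window_outcomes(study, s, t)
    pi = rng.uniform(0, 1, (out.n_risk, K))
    rm = RiskMatrix(s, t, [f"mod{k}" for k in range(K)], out.ids, pi,
                    np.zeros_like(pi), 0)
    return rm, out


def grid_search_bs(rm, out, step=0.01):
    """Exhaustive simplex search oracle for the minimal weighted Brier score."""
    K = rm.n_models
    order = {sid: i for i, sid in enumerate(rm.ids)}
    perm = np.array([order[sid] for sid in out.ids])
    P = rm.pi[perm]
    d = out.event.astype(float)
    psi = out.weight
    n = out.n_risk
    m = round(1 / step)
    best = np.inf
    for comb in itertools.combinations_with_replacement(range(K), m):
        w = np.bincount(comb, minlength=K) / m
        bs = float(np.sum(psi * (d - P @ w) ** 2) / n)
        best = min(best, bs)
    return best


class TestEstimateWeights:
    def test_single_model_gets_unit_weight(self):
        rng = np.random.default_rng(0)
        rm, out = make_instance(rng, 1, 20)
        wv = estimate_weights(rm, out)
        assert wv.weights == pytest.approx([1.0])
        order = {sid: i for i, sid in enumerate(rm.ids)}
        perm = np.array([order[sid] for sid in out.ids])
        assert wv.achieved_bs == pytest.approx(brier_score(rm.pi[perm, 0], out))

    def test_oracle_dominates_coin_flip(self):
        rng = np.random.default_rng(1)
        rm, out = make_instance(rng, 2, 30)
        order = {sid: i for i, sid in enumerate(rm.ids)}
        perm_inv = np.empty(out.n_risk, int)
        for i, sid in enumerate(out.ids):
            perm_inv[order[sid]] = i
        rm.pi[:, 0] = out.event.astype(float)[perm_inv]  # oracle column
        rm.pi[:, 1] = 0.5
        wv = estimate_weights(rm, out)
        assert wv.weights[0] == pytest.approx(1.0, abs=1e-6)
        assert wv.achieved_bs == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search(self):
        rng = np.random.default_rng(2)
        rm, out = make_instance(rng, 3, 20)
        wv = estimate_weights(rm, out)
        oracle = grid_search_bs(rm, out, step=0.01)
        assert wv.achieved_bs <= oracle + 1e-6

    def test_identical_columns_share_weight(self):
        rng = np.random.default_rng(3)
        rm, out = make_instance(rng, 2, 25)
        rm.pi[:, 1] = rm.pi[:, 0]
        wv = estimate_weights(rm, out)
        assert wv.weights == pytest.approx([0.5, 0.5], abs=1e-4)

    def test_dominance_over_every_single_model(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            K = int(rng.integers(2, 5))
            rm, out = make_instance(rng, K, int(rng.integers(10, 50)))
            wv = estimate_weights(rm, out)
            order = {sid: i for i, sid in enumerate(rm.ids)}
            perm = np.array([order[sid] for sid in out.ids])
            for k in range(K):
                assert wv.achieved_bs <= brier_score(rm.pi[perm, k], out) + 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        rm, out = make_instance(rng, 3, 30)
        w1 = estimate_weights(rm, out).weights
        w2 = estimate_weights(rm, out).weights
        assert np.array_equal(w1, w2)

    def test_interior_unconstrained_minimizer_recovered(self):
        """When the generative mix is an interior simplex point, the solver
        finds it (the closed-form least-squares solution lies in the simplex)."""
        rng = np.random.default_rng(6)
        n, K = 4000, 3
        P = rng.uniform(0, 1, (n, K))
        w_true = np.array([0.5, 0.3, 0.2])
        d = (rng.uniform(0, 1, n) < P @ w_true).astype(float)
        T = np.where(d == 1, 1.5, 3.0)
        study = toy_study(T, np.ones(n, int))
        out = window_outcomes(study, 1.0, 1.0)
        rm = RiskMatrix(1.0, 1.0, ["a", "b", "c"], out.ids, P, np.zeros_like(P), 0)
        wv = estimate_weights(rm, out)
        assert np.allclose(wv.weights, w_true, atol=0.06)

    def test_misaligned_risk_set_rejected(self):
        rng = np.random.default_rng(7)
        rm, out = make_instance(rng, 2, 20)
        rm2 = RiskMatrix(rm.s, rm.t, rm.model_labels, rm.ids[:-1],
                         rm.pi[:-1], rm.mc_var[:-1], 0)
        with pytest.raises(ValueError, match="align"):
            estimate_weights(rm2, out)


class TestAveragePredictions:
    def test_convex_combination(self):
        rng = np.random.default_rng(8)
        rm, out = make_instance(rng, 2, 10)
        rm.pi[0, :] = [0.2, 0.6]
        wv = WeightVector(rm.s, rm.t, rm.model_labels, np.array([0.5, 0.5]), 0.1)
        avg = average_predictions(rm, wv, compute_se=False)
        assert avg.pi[0] == pytest.approx(0.4)
        assert np.all(avg.pi >= rm.pi.min(axis=1) - 1e-12)
        assert np.all(avg.pi <= rm.pi.max(axis=1) + 1e-12)

    def test_one_hot_reproduces_column(self):
        rng = np.random.default_rng(9)
        rm, _ = make_instance(rng, 3, 15)
        wv = WeightVector(rm.s, rm.t, rm.model_labels, np.array([0.0, 1.0, 0.0]), 0.1)
        avg = average_predictions(rm, wv, compute_se=False)
        assert np.array_equal(avg.pi, rm.pi[:, 1])

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        rm, _ = make_instance(rng, 2, 10)
        wv = WeightVector(rm.s, rm.t, ["x", "y"], np.array([0.5, 0.5]), 0.1)
        with pytest.raises(ValueError, match="labels"):
            average_predictions(rm, wv)

    def test_many_column_matrix_stays_in_unit_interval(self):
        rng = np.random.default_rng(11)
        rm, out = make_instance(rng, 21, 40)
        wv = estimate_weights(rm, out)
        avg = average_predictions(rm, wv, compute_se=False)
        assert np.all((avg.pi >= 0) & (avg.pi <= 1))


class TestPredictionSe:
    def _rm(self, pi, var=None):
        pi = np.asarray(pi, float)
        var = np.zeros_like(pi) if var is None else np.asarray(var, float)
        return RiskMatrix(0.5, 0.5, [f"m{k}" for k in range(pi.shape[1])],
                          np.arange(len(pi)), pi, var, 0)

    def test_identical_models_zero_variance(self):
        rm = self._rm([[0.3, 0.3], [0.6, 0.6]])
        wv = WeightVector(0.5, 0.5, rm.model_labels, np.array([0.4, 0.6]), 0.1)
        se_b, se_p = prediction_se(rm, wv, rm.mc_var)
        assert np.allclose(se_b, 0.0) and np.allclose(se_p, 0.0)

    def test_single_model_returns_root_variance(self):
        rm = self._rm([[0.3], [0.6]], var=[[0.04], [0.09]])
        wv = WeightVector(0.5, 0.5, rm.model_labels, np.array([1.0]), 0.1)
        se_b, se_p = prediction_se(rm, wv, rm.mc_var)
        assert se_b == pytest.approx([0.2, 0.3])
        assert se_p == pytest.approx([0.2, 0.3])

    def test_two_model_direct_evaluation(self):
        rm = self._rm([[0.2, 0.6]])
        wv = WeightVector(0.5, 0.5, rm.model_labels, np.array([0.5, 0.5]), 0.1)
        se_b, se_p = prediction_se(rm, wv, rm.mc_var)
        # pi_bar = 0.4, biases (-0.2, 0.2): both formulas give 0.2 here
        assert se_b[0] == pytest.approx(0.2)
        assert se_p[0] == pytest.approx(0.2)

    def test_jensen_ordering(self):
        """sum_k w_k sqrt(x_k) <= sqrt(sum_k w_k x_k): the Buckland-style
        error never exceeds the pooled one."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            n, K = 15, 4
            rm = self._rm(rng.uniform(0, 1, (n, K)), var=rng.uniform(0, 0.01, (n, K)))
            w = rng.dirichlet(np.ones(K))
            wv = WeightVector(0.5, 0.5, rm.model_labels, w, 0.1)
            se_b, se_p = prediction_se(rm, wv, rm.mc_var)
            assert np.all(se_b <= se_p + 1e-12)

    def test_negative_variance_rejected(self):
        rm = self._rm([[0.2, 0.6]])
        wv = WeightVector(0.5, 0.5, rm.model_labels, np.array([0.5, 0.5]), 0.1)
        with pytest.raises(ValueError, match="negative"):
            prediction_se(rm, wv, np.array([[-0.1, 0.0]]))


def test_weight_vector_validates_simplex():
    with pytest.raises(ValueError, match="sum"):
        WeightVector(0.5, 0.5, ["a", "b"], np.array([0.5, 0.4]), 0.1)
    with pytest.raises(ValueError, match="negative"):
        WeightVector(0.5, 0.5, ["a", "b"], np.array([1.2, -0.2]), 0.1)
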