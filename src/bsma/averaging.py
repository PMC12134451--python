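"""Brier-score-minimizing model averaging of dynamic risk predictions.

Given per-model predictions pi_ik(s,t) for the subjects at risk at a
landmark s, the averaged prediction is the convex combination

    pi_i(s,t) = sum_k w_k(s,t) pi_ik(s,t),

with the weight vector w on the probability simplex chosen, per (s, t)
pair, to minimize the IPCW Brier score of the averaged prediction on the
learning data.  The objective is a convex quadratic in w, solved with a
constrained solver restarted from each vertex and the barycenter; a tiny
ridge resolves non-identifiable (collinear-prediction) ties toward the
minimum-norm weights, so identical prediction columns share their weight
equally.

Standard errors of the averaged prediction combine each model's bias
Z_ik = pi_ik - pi_i and Monte-Carlo variance V_ik either as
sum_k w_k sqrt(Z^2 + V) (Buckland-style) or sqrt(sum_k w_k (Z^2 + V)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .accuracy import WindowOutcomes, brier_score
from .prediction import RiskMatrix

_TIE_RIDGE = 1e-10


@dataclass
class WeightVector:
    """Simplex weights for one (s, t) pair, with the achieved Brier score."""

    s: float
    t: float
    model_labels: list[str]
    weights: np.ndarray
    achieved_bs: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if (w < -1e-9).any():
            raise ValueError("negative weight")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights do not sum to one")
        self.weights = np.clip(w, 0.0, None)
        self.weights /= self.weights.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s": self.s,
                "t": self.t,
                "model_label": self.model_labels,
                "weight": self.weights,
                "achieved_bs": self.achieved_bs,
            }
        )


@dataclass
class AveragedPrediction:
    """Model-averaged predictions with per-subject standard errors."""

    s: float
    t: float
    ids: np.ndarray
    pi: np.ndarray           # averaged prediction per subject
    se_buckland: np.ndarray | None = None   # sum_k w_k sqrt(Z^2+V)
    se_pooled: np.ndarray | None = None     # sqrt(sum_k w_k (Z^2+V))


def _quadratic_pieces(risk_matrix: RiskMatrix, outcomes: WindowOutcomes):
    """BS_w(s,t) = w' Q w - 2 c' w + const as a function of the weights."""
    order = {sid: i for i, sid in enumerate(risk_matrix.ids)}
    if set(outcomes.ids) != set(risk_matrix.ids):
        raise ValueError("risk matrix rows do not align with the outcome risk set")
    perm = np.array([order[sid] for sid in outcomes.ids])
    P = risk_matrix.pi[perm]                     # (n, K) aligned to outcomes
    psi = outcomes.weight
    d = outcomes.event.astype(float)
    n = outcomes.n_risk
    Q = (P.T * psi) @ P / n
    c = P.T @ (psi * d) / n
    const = float(np.sum(psi * d * d) / n)
    return P, Q, c, const


def estimate_weights(
    risk_matrix: RiskMatrix, outcomes: WindowOutcomes
) -> WeightVector:
    """Simplex weights minimizing the IPCW Brier score of the average.

    The achieved score never exceeds any single model's score (one-hot
    weight vectors are feasible points).
    """
    P, Q, c, const = _quadratic_pieces(risk_matrix, outcomes)
    K = P.shape[1]
    psi = outcomes.weight
    d = outcomes.event.astype(float)
    n = outcomes.n_risk

    def direct_bs(w):
        # same arithmetic as accuracy.brier_score on the combined column
        return float(np.sum(psi * (d - P @ w) ** 2) / n)

    if psi.sum() <= 0:
        raise ValueError("degenerate risk set: no events and no survivors")
    if K == 1:
        return WeightVector(
            risk_matrix.s, risk_matrix.t, list(risk_matrix.model_labels),
            np.array([1.0]), direct_bs(np.array([1.0])),
            {"restarts": 0, "converged": True},
        )

    def objective(w):
        return float(w @ Q @ w - 2.0 * c @ w + const + _TIE_RIDGE * w @ w)

    def gradient(w):
        return 2.0 * (Q @ w - c + _TIE_RIDGE * w)

    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                    "jac": lambda w: np.ones_like(w)}]
    bounds = [(0.0, 1.0)] * K
    starts = [np.full(K, 1.0 / K)] + [np.eye(K)[k] for k in range(K)]
    best = None
    n_ok = 0
    for w0 in starts:
        res = optimize.minimize(
            objective, w0, jac=gradient, method="SLSQP",
            bounds=bounds, constraints=constraints,
            options={"maxiter": 400, "ftol": 1e-14},
        )
        if not np.isfinite(res.fun):
            continue
        n_ok += int(res.success)
        if best is None or res.fun < best.fun - 1e-15:
            best = res
    if best is None:
        raise RuntimeError("weight optimization failed on every restart")
    w = np.clip(best.x, 0.0, None)
    w[w < 1e-10] = 0.0          # snap solver dust so one-hot solutions are exact
    w /= w.sum()
    bs = direct_bs(w)
    # exact dominance: never worse than the best single model
    single = [direct_bs(np.eye(K)[k]) for k in range(K)]
    k_best = int(np.argmin(single))
    if single[k_best] < bs:
        w = np.eye(K)[k_best]
        bs = single[k_best]
    return WeightVector(
        risk_matrix.s, risk_matrix.t, list(risk_matrix.model_labels), w, bs,
        {"restarts": len(starts), "converged": n_ok > 0},
    )


def average_predictions(
    risk_matrix: RiskMatrix,
    weights: WeightVector,
    compute_se: bool = True,
) -> AveragedPrediction:
    """Convex combination of the per-model predictions under given weights."""
    if list(weights.model_labels) != list(risk_matrix.model_labels):
        raise ValueError("weight labels do not match risk-matrix model labels")
    w = weights.weights
    pi = risk_matrix.pi @ w
    out = AveragedPrediction(risk_matrix.s, risk_matrix.t, risk_matrix.ids, pi)
    if compute_se:
        se_b, se_p = prediction_se(risk_matrix, weights, risk_matrix.mc_var)
        out.se_buckland = se_b
        out.se_pooled = se_p
    return out


def prediction_se(
    risk_matrix: RiskMatrix,
    weights: WeightVector,
    model_variances: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject standard errors of the averaged prediction.

    ``model_variances`` holds V_ik >= 0 (Monte-Carlo variances of pi_ik).
    Returns (Buckland-style sum of square roots, pooled square root); by
    concavity of the square root the first never exceeds the second.
    """
    V = np.asarray(model_variances, float)
    if V.shape != risk_matrix.pi.shape:
        raise ValueError("variance matrix shape mismatch")
    if (V < 0).any():
        raise ValueError("negative model variance")
    w = weights.weights
    pi_bar = risk_matrix.pi @ w
    Z = risk_matrix.pi - pi_bar[:, None]
    inner = Z ** 2 + V
    se_buckland = np.sqrt(inner) @ w
    se_pooled = np.sqrt(inner @ w)
    return se_buckland, se_pooled
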