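"""Time-dependent predictive-accuracy metrics under right censoring.

For a landmark s and horizon t, subjects at risk at s (T* > s) fall into
three groups: observed events in (s, s+t], subjects still at risk at s+t,
and subjects censored inside the window. Censoring is handled by inverse
probability of censoring weighting (IPCW): each contribution is reweighted
by the conditional probability of remaining uncensored, estimated by the
Kaplan-Meier curve G of the censoring distribution (event roles reversed).

The weights are

    Psi_i(s,t) = 1{T*_i > s+t} / G(s+t | s)  +  1{s < T*_i <= s+t, delta_i=1} / G(T*_i- | s)

with G(u|s) = G(u)/G(s); in-window censored subjects get weight zero but
still count in the size N(s) of the risk set.  The Brier score is the
Psi-weighted mean squared error between the in-window event indicator and
the predicted probability; the AUC is the Psi-weighted probability that an
in-window case is ranked above an event-free subject (strict inequality;
ties optionally count 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .datamodel import StudyData


@dataclass
class CensoringCurve:
    """Right-continuous Kaplan-Meier step estimate of P(C > u)."""

    times: np.ndarray    # sorted unique censoring times
    values: np.ndarray   # G at those times (post-jump)

    def __call__(self, u) -> np.ndarray:
        """G(u), right-continuous."""
        idx = np.searchsorted(self.times, np.asarray(u, float), side="right") - 1
        return np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])

    def left_limit(self, u) -> np.ndarray:
        """G(u-), the value just before u."""
        idx = np.searchsorted(self.times, np.asarray(u, float), side="left") - 1
        return np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])

    def conditional(self, u, s: float) -> np.ndarray:
        """G(u | s) = G(u) / G(s), probability of staying uncensored past u given s."""
        gs = float(self(s))
        if gs <= 0:
            raise ValueError(f"G({s}) = 0: no subject uncensored past the landmark")
        return np.minimum(self(u) / gs, 1.0)

    def conditional_left(self, u, s: float) -> np.ndarray:
        gs = float(self(s))
        if gs <= 0:
            raise ValueError(f"G({s}) = 0: no subject uncensored past the landmark")
        return np.minimum(self.left_limit(u) / gs, 1.0)


def censoring_curve(study: StudyData) -> CensoringCurve:
    """Kaplan-Meier estimate of the censoring survival function G(u)=P(C>u).

    Built by reversing the event indicator; subjects failing at u remain in
    the risk set for censorings at u (events precede censorings at ties).
    """
    T = study.subjects["time_obs"].to_numpy(float)
    delta = study.subjects["status"].to_numpy(int)
    if len(T) == 0:
        raise ValueError("empty study")
    km = KaplanMeierFitter()
    km.fit(T, event_observed=1 - delta)
    sf = km.survival_function_
    return CensoringCurve(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))


@dataclass
class WindowOutcomes:
    """Outcome decomposition of the risk set at s over the window (s, s+t]."""

    ids: np.ndarray          # subjects with T* > s
    event: np.ndarray        # D*_i: observed event in window
    censored: np.ndarray     # censored in window
    survivor: np.ndarray     # T* > s+t
    weight: np.ndarray       # IPCW weight Psi_i (0 for in-window censored)
    s: float
    t: float

    @property
    def n_risk(self) -> int:
        return len(self.ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def window_outcomes(
    study: StudyData, s: float, t: float, curve: CensoringCurve | None = None
) -> WindowOutcomes:
    """IPCW-weighted outcome flags for every subject at risk at s.

    The event-term weight uses the left limit G(T*-|s), so an event tied
    with a censoring time keeps positive weight.
    """
    if s < 0 or t <= 0:
        raise ValueError("require s >= 0 and t > 0")
    if curve is None:
        curve = censoring_curve(study)
    T = study.subjects["time_obs"].to_numpy(float)
    delta = study.subjects["status"].to_numpy(int)
    at_risk = T > s
    ids = study.subjects.index.to_numpy()[at_risk]
    T, delta = T[at_risk], delta[at_risk]

    in_window = T <= s + t
    event = in_window & (delta == 1)
    censored = in_window & (delta == 0)
    survivor = ~in_window

    g_end = float(curve.conditional(s + t, s))
    if survivor.any() and g_end <= 0:
        raise ValueError(
            f"G({s + t}|{s}) = 0: window too wide for the censoring distribution"
        )
    weight = np.zeros(len(T))
    if survivor.any():
        weight[survivor] = 1.0 / g_end
    g_ev = np.asarray(curve.conditional_left(T[event], s), float)
    if (g_ev <= 0).any():
        raise ValueError("zero censoring-survival at an event time inside the window")
    weight[event] = 1.0 / g_ev
    if weight.sum() <= 0:
        raise ValueError(
            f"every subject at risk at s={s} is censored inside the window: "
            "use a smaller horizon t"
        )
    return WindowOutcomes(ids, event, censored, survivor, weight, s, t)


def _check_predictions(pred: np.ndarray, out: WindowOutcomes) -> np.ndarray:
    pred = np.asarray(pred, float)
    if pred.shape != (out.n_risk,):
        raise ValueError(
            f"predictions must align with the {out.n_risk}-subject risk set"
        )
    if (pred < -1e-12).any() or (pred > 1 + 1e-12).any():
        raise ValueError("predictions outside [0, 1]")
    return np.clip(pred, 0.0, 1.0)


def brier_score(predictions: np.ndarray, outcomes: WindowOutcomes) -> float:
    """IPCW time-dependent Brier score over the risk set at s.

    (1/N(s)) * sum_i Psi_i (D*_i - pi_i)^2; in-window censored subjects
    contribute zero to the sum but count in N(s).
    """
    pred = _check_predictions(predictions, outcomes)
    d = outcomes.event.astype(float)
    return float(np.sum(outcomes.weight * (d - pred) ** 2) / outcomes.n_risk)


def auc(
    predictions: np.ndarray, outcomes: WindowOutcomes, ties: str = "strict"
) -> float | None:
    """IPCW time-dependent AUC: weighted share of concordant (case, control) pairs.

    Cases are observed in-window events; controls are all other risk-set
    subjects (in-window censored ones drop out via zero weight). Ties in the
    predictions contribute 0 under ``ties="strict"`` and 1/2 under
    ``ties="half"``. Returns None when there is no weighted case or control.
    """
    if ties not in ("strict", "half"):
        raise ValueError("ties must be 'strict' or 'half'")
    pred = _check_predictions(predictions, outcomes)
    case = outcomes.event
    ctrl = ~outcomes.event
    w_case = outcomes.weight[case]
    w_ctrl = outcomes.weight[ctrl]
    if w_case.sum() <= 0 or w_ctrl.sum() <= 0:
        return None
    pi_case = pred[case]
    pi_ctrl = pred[ctrl]
    gt = (pi_case[:, None] > pi_ctrl[None, :]).astype(float)
    if ties == "half":
        gt += 0.5 * (pi_case[:, None] == pi_ctrl[None, :])
    ww = w_case[:, None] * w_ctrl[None, :]
    return float(np.sum(gt * ww) / np.sum(ww))


def mse_vs_truth(predictions: np.ndarray, true_probabilities: np.ndarray) -> float:
    """Mean squared error of predicted vs generative event probabilities."""
    pred = np.asarray(predictions, float)
    truth = np.asarray(true_probabilities, float)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean((pred - truth) ** 2))
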