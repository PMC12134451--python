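"""Individual dynamic risk predictions pi_i(s, t) from a fitted joint model.

The probability of the event in (s, s+t], given survival to the landmark s
and the marker history collected up to s, is

    pi_i(s,t) = 1 - E[ S(s+t | b_i) / S(s | b_i) | T_i > s, Y_i(s) ],

approximated by Monte Carlo: parameters xi^(m) are drawn from the
asymptotic normal of the estimates, the subject's random effects b_i^(m)
are drawn from their conditional distribution given the history and
survival to s (Metropolis-Hastings with an independence proposal from a
multivariate t centered at the conditional mode and scaled by the curvature
there), and the survival ratios are averaged over draws.  M = 0 is the
deterministic plug-in mode: point estimates and conditional modes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import StudyData, SubjectHistory
from .joint_model import (
    FittedJointModel,
    JointDesign,
    JointParameters,
    _prior_terms,
    draw_parameters,
    piecewise_cumhaz,
)

MH_STEPS = 50          # independence-proposal chain length per draw
PROPOSAL_DF = 4.0      # degrees of freedom of the multivariate-t proposal


@dataclass
class RiskPrediction:
    """One subject's predicted event probability over (s, s+t]."""

    subject_id: object
    s: float
    t: float
    pi_hat: float
    mc_se: float
    M: int

    def __post_init__(self):
        assert -1e-12 <= self.pi_hat <= 1 + 1e-12


@dataclass
class RiskMatrix:
    """Predicted probabilities for every risk-set subject x candidate model."""

    s: float
    t: float
    model_labels: list[str]
    ids: np.ndarray              # subjects with T* > s, row order
    pi: np.ndarray               # (n, K) point predictions
    mc_var: np.ndarray           # (n, K) Monte-Carlo variances of pi
    M: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(self.model_labels)

    def column(self, label: str) -> np.ndarray:
        return self.pi[:, self.model_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, lab in enumerate(self.model_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "id": self.ids,
                        "s": self.s,
                        "t": self.t,
                        "model_label": lab,
                        "pi_hat": self.pi[:, j],
                        "mc_se": np.sqrt(self.mc_var[:, j]),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _conditional_design(
    fit: FittedJointModel, study: StudyData, ids, s: float
) -> JointDesign:
    """Design conditioning on survival to s with histories truncated at s."""
    return JointDesign(
        study,
        fit.spec,
        fit.breaks,
        ids=ids,
        t_eval=np.full(len(ids), float(s)),
        delta_eval=np.zeros(len(ids)),
        time_cap=float(s),
        allow_empty=True,
    )


def _survival_ratio(
    fit_breaks, params: JointParameters, design: JointDesign, b: np.ndarray,
    s: float, t: float
) -> np.ndarray:
    """S(s+t | b) / S(s | b) for b of shape (n, d), clipped to [0, 1]."""
    A, Bs = design._surv_ab(params, b)
    L_s = piecewise_cumhaz(fit_breaks, params.log_lambda, s, A, Bs)
    L_st = piecewise_cumhaz(fit_breaks, params.log_lambda, s + t, A, Bs)
    return np.clip(np.exp(-(L_st - L_s)), 0.0, 1.0)


def _mvt_logpdf(x: np.ndarray, mean: np.ndarray, chol: np.ndarray, df: float):
    """Multivariate-t log-density per subject; x, mean (n,d), chol (n,d,d)."""
    from scipy.special import gammaln

    d = x.shape[-1]
    diff = x - mean
    sol = np.linalg.solve(chol, diff[..., None])[..., 0]
    quad = np.sum(sol * sol, axis=-1)
    logdet = np.sum(np.log(np.diagonal(chol, axis1=-2, axis2=-1)), axis=-1)
    return (
        gammaln((df + d) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * d * np.log(df * np.pi)
        - logdet
        - 0.5 * (df + d) * np.log1p(quad / df)
    )


def _mvt_draw(rng, mean: np.ndarray, chol: np.ndarray, df: float) -> np.ndarray:
    n, d = mean.shape
    z = rng.standard_normal((n, d))
    g = rng.chisquare(df, size=n) / df
    return mean + np.matmul(chol, z[..., None])[..., 0] / np.sqrt(g)[:, None]


def _mode_and_scale(design: JointDesign, params: JointParameters, prior):
    modes, _, hess = design.find_modes(params, prior)
    H = -hess
    eye = np.eye(design.d)
    for ridge in (0.0, 1e-8, 1e-4, 1e-2):
        try:
            Lh = np.linalg.cholesky(H + ridge * eye[None])
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise FloatingPointError("non-PD curvature in conditional posterior")
    Linv = np.linalg.inv(Lh)
    Sig = np.matmul(Linv.transpose(0, 2, 1), Linv)
    return modes, np.linalg.cholesky(Sig)


def sample_random_effects(
    fit: FittedJointModel,
    study: StudyData,
    ids,
    s: float,
    n_draws: int,
    seed: int,
    params: JointParameters | None = None,
) -> tuple[np.ndarray, float]:
    """Draw b_i | T_i > s, Y_i(s) for each subject by Metropolis-Hastings.

    Returns samples of shape (n_draws, n_subjects, d) and the overall
    acceptance rate. Each retained sample is the endpoint of a fresh
    ``MH_STEPS``-step independence chain started at the conditional mode.
    """
    params = fit.params if params is None else params
    design = _conditional_design(fit, study, ids, s)
    prior = _prior_terms(params.B)
    modes, chol = _mode_and_scale(design, params, prior)
    rng = np.random.default_rng(seed)
    out = np.empty((n_draws, len(ids), design.d))
    acc = 0
    tot = 0
    for m in range(n_draws):
        b, a, t_ = _mh_chain(design, params, prior, modes, chol, rng)
        out[m] = b
        acc += a
        tot += t_
    return out, acc / max(tot, 1)


def _mh_chain(design, params, prior, modes, chol, rng):
    b = modes.copy()
    logp = design.g_value(params, b[:, None, :], prior)[:, 0]
    logq = _mvt_logpdf(b, modes, chol, PROPOSAL_DF)
    n_acc = 0
    for _ in range(MH_STEPS):
        prop = _mvt_draw(rng, modes, chol, PROPOSAL_DF)
        logp_prop = design.g_value(params, prop[:, None, :], prior)[:, 0]
        logq_prop = _mvt_logpdf(prop, modes, chol, PROPOSAL_DF)
        log_ratio = (logp_prop - logp) + (logq - logq_prop)
        accept = np.log(rng.random(len(b))) < log_ratio
        b[accept] = prop[accept]
        logp[accept] = logp_prop[accept]
        logq[accept] = logq_prop[accept]
        n_acc += int(accept.sum())
    return b, n_acc, MH_STEPS * len(b)


def _predict_ids(
    fit: FittedJointModel,
    study: StudyData,
    ids,
    s: float,
    t: float,
    M: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Point predictions and MC variances for the given subjects."""
    ids = np.asarray(ids)
    design = _conditional_design(fit, study, ids, s)
    if t < 0:
        raise ValueError("horizon t must be nonnegative")
    if M == 0:
        prior = _prior_terms(fit.params.B)
        modes, _, _ = design.find_modes(fit.params, prior)
        ratio = _survival_ratio(fit.breaks, fit.params, design, modes, s, t)
        return 1.0 - ratio, np.zeros(len(ids)), {"mode": "plug-in"}
    rng = np.random.default_rng(seed)
    param_draws = draw_parameters(fit, M, int(rng.integers(2 ** 31 - 1)))
    ratios = np.empty((M, len(ids)))
    acc = tot = 0
    for m, pm in enumerate(param_draws):
        prior = _prior_terms(pm.B)
        modes, chol = _mode_and_scale(design, pm, prior)
        b, a, t_ = _mh_chain(design, pm, prior, modes, chol, rng)
        acc += a
        tot += t_
        ratios[m] = _survival_ratio(fit.breaks, pm, design, b, s, t)
    pi = 1.0 - ratios.mean(axis=0)
    mc_var = ratios.var(axis=0, ddof=1) / M if M > 1 else np.zeros(len(ids))
    return pi, mc_var, {"mode": "monte-carlo", "mh_acceptance": acc / max(tot, 1)}


def predict_risk(
    fit: FittedJointModel,
    history: SubjectHistory,
    s: float | None = None,
    t: float = 0.5,
    M: int = 500,
    seed: int = 0,
) -> RiskPrediction:
    """Predict one subject's event probability over (s, s+t] from their history.

    The subject is assumed event-free at s (the caller's responsibility).
    ``M=0`` gives the deterministic plug-in approximation.
    """
    s = history.landmark if s is None else s
    if abs(s - history.landmark) > 1e-9:
        raise ValueError("history landmark does not match s")
    subj = pd.DataFrame(
        {"time_obs": [s], "status": [0], **{c: [history.covariates[c]] for c in history.covariates.index}},
        index=pd.Index([history.subject_id], name="id"),
    )
    # catalog restricted to the model's markers; the history may lack some
    from .datamodel import MarkerCatalog, StudyData as _SD

    catalog = MarkerCatalog(
        tuple((m, f) for m, f in zip(fit.spec.markers, fit.families))
    )
    lng = history.long[history.long["marker"].isin(fit.spec.markers)].reset_index(drop=True)
    mini = _SD(subj, lng, catalog)
    pi, var, _ = _predict_ids(fit, mini, [history.subject_id], s, t, M, seed)
    return RiskPrediction(
        history.subject_id, s, t, float(np.clip(pi[0], 0.0, 1.0)),
        float(np.sqrt(var[0])), M,
    )


def risk_matrix(
    fits: list[FittedJointModel],
    study: StudyData,
    s: float,
    t: float,
    M: int = 500,
    seed: int = 0,
) -> RiskMatrix:
    """Predictions for every subject at risk at s, for every candidate model.

    Column order follows the order of ``fits`` (the model enumeration
    order). Subjects lacking measurements of a model's markers are predicted
    from the random-effect prior.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fitted model")
    ids = study.at_risk_ids(s)
    if len(ids) == 0:
        raise ValueError(f"no subjects at risk at s={s}")
    pi = np.empty((len(ids), len(fits)))
    var = np.empty_like(pi)
    diag = {}
    for j, fit in enumerate(fits):
        pi[:, j], var[:, j], dj = _predict_ids(
            fit, study, ids, s, t, M, seed + 104729 * j
        )
        diag[fit.spec.label] = dj
    return RiskMatrix(
        s, t, [f.spec.label for f in fits], ids, np.clip(pi, 0.0, 1.0), var, M, diag
    )
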