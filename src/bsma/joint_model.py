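"""Shared-random-effect joint models fitted by maximum marginal likelihood.

A model couples, for each marker k in a chosen subset, a generalized linear
mixed sub-model with random intercept and slope,

    eta_ik(t) = beta0_k + beta1_k t + b0_ik + b1_ik t,
    Gaussian:  Y_ik(t) = eta_ik(t) + eps,   eps ~ N(0, sigma_k^2)
    Bernoulli: logit P(Y_ik(t)=1) = eta_ik(t),

with stacked random effects b_i ~ N(0, B), to a proportional-hazards
sub-model whose log-hazard depends on the current values of the markers:

    lambda_i(t | b_i) = lambda0(t) exp( x_i' gamma + sum_k alpha_k eta_ik(t) ).

The baseline hazard lambda0 is piecewise-constant on Q intervals cut at
event-time quantiles, so the cumulative hazard has a closed form per
interval (the exponent is linear in t).  The marginal likelihood integrates
the random effects out by adaptive Gauss-Hermite quadrature centered, for
each subject, at the conditional posterior mode of b_i with scale from the
curvature there.  Estimation maximizes the marginal log-likelihood over an
unconstrained parameterization (log variances, log-Cholesky of B, log
baseline heights) with a quasi-Newton optimizer; the covariance of the
estimates is the inverse observed information obtained by numerical
differentiation.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess1

from .datamodel import StudyData, StudyValidationError

_SQRT2 = math.sqrt(2.0)
_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which markers (and survival covariates) a joint model includes.

    ``n_nodes`` is the number of Gauss-Hermite nodes per random-effect
    dimension; by default 9, dropping to 3 when the dimension exceeds 4.
    """

    markers: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    baseline_intervals: int = 5
    n_nodes: int | None = None

    def __post_init__(self):
        if len(self.markers) == 0:
            raise ValueError("a model needs at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate markers in model spec")
        if self.baseline_intervals < 1:
            raise ValueError("baseline_intervals must be >= 1")

    @property
    def n_random(self) -> int:
        return 2 * len(self.markers)

    @property
    def label(self) -> str:
        return "+".join(self.markers)

    def nodes_per_dim(self) -> int:
        if self.n_nodes is not None:
            return self.n_nodes
        return 9 if self.n_random <= 4 else 3


@dataclass
class JointParameters:
    """Natural-scale parameter set xi of a joint model."""

    beta: np.ndarray      # (p, 2) fixed intercept/slope per marker
    sigma2: np.ndarray    # (p,) residual variances; NaN for Bernoulli markers
    B: np.ndarray         # (2p, 2p) random-effect covariance
    alpha: np.ndarray     # (p,) association parameters
    gamma: np.ndarray     # (q,) survival covariate effects
    log_lambda: np.ndarray  # (Q,) log piecewise baseline-hazard heights

    def copy(self) -> "JointParameters":
        return JointParameters(
            self.beta.copy(), self.sigma2.copy(), self.B.copy(),
            self.alpha.copy(), self.gamma.copy(), self.log_lambda.copy(),
        )


@lru_cache(maxsize=32)
def _gh_grid(nn: int, d: int):
    """Tensor Gauss-Hermite grid: nodes (J, d), log-weights + |z|^2 (J,)."""
    x, w = np.polynomial.hermite.hermgauss(nn)
    idx = np.array(list(itertools.product(range(nn), repeat=d)))
    z = x[idx]
    logw = np.log(w)[idx].sum(axis=1)
    z2 = np.sum(z * z, axis=1)
    return z, logw + z2


def _exp_int_012(bs: np.ndarray, lo: np.ndarray, hi: np.ndarray, order: int):
    """J_r = d^r/db^r of integral exp(b u) du over [lo, hi], r = 0..order.

    Stable at b -> 0 via the polynomial limits (hi-lo), (hi^2-lo^2)/2, ...
    """
    small = np.abs(bs) < 1e-8
    b = np.where(small, 1.0, bs)
    ehi = np.exp(b * hi)
    elo = np.exp(b * lo)
    j0 = np.where(small, hi - lo, (ehi - elo) / b)
    out = [j0]
    if order >= 1:
        j1 = np.where(small, (hi * hi - lo * lo) / 2.0, (hi * ehi - lo * elo - j0) / b)
        out.append(j1)
    if order >= 2:
        j2 = np.where(
            small,
            (hi ** 3 - lo ** 3) / 3.0,
            (hi * hi * ehi - lo * lo * elo - 2.0 * out[1]) / b,
        )
        out.append(j2)
    return out


def piecewise_cumhaz(
    breaks: np.ndarray, log_lambda: np.ndarray, u, A, Bs, order: int = 0
):
    """Cumulative hazard of lambda0(t) e^{A + Bs t} up to time(s) u.

    ``breaks`` are the Q-1 interior cut points (interval q spans
    [c_{q-1}, c_q) with c_0 = 0, c_Q = inf). ``u`` broadcasts against A/Bs.
    Returns Lambda (and dLambda/dBs, d2Lambda/dBs2 when order > 0).
    """
    u = np.asarray(u, float)
    A = np.asarray(A, float)
    Bs = np.asarray(Bs, float)
    edges = np.concatenate(([0.0], np.asarray(breaks, float), [np.inf]))
    lam = np.exp(np.asarray(log_lambda, float))
    accs = [np.zeros(np.broadcast_shapes(u.shape, Bs.shape)) for _ in range(order + 1)]
    for q in range(len(lam)):
        lo = np.minimum(u, edges[q])
        hi = np.minimum(u, edges[q + 1])
        js = _exp_int_012(Bs, np.broadcast_to(lo, accs[0].shape),
                          np.broadcast_to(hi, accs[0].shape), order)
        for r in range(order + 1):
            accs[r] = accs[r] + lam[q] * js[r]
    eA = np.exp(A)
    result = [eA * acc for acc in accs]
    return result[0] if order == 0 else tuple(result)


def _interval_index(breaks: np.ndarray, u: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.asarray(breaks, float), np.asarray(u, float), side="right")


class JointDesign:
    """Per-subject data arrays and likelihood machinery for one model spec.

    ``t_eval``/``delta_eval`` are the survival evaluation time and event
    flag: the observed (T*, delta) when fitting, or (s, 0) when forming the
    conditional distribution of b given survival to a landmark s.
    """

    def __init__(
        self,
        study: StudyData,
        spec: ModelSpec,
        breaks: np.ndarray,
        ids=None,
        t_eval: np.ndarray | None = None,
        delta_eval: np.ndarray | None = None,
        time_cap: float | None = None,
        allow_empty: bool = False,
    ):
        self.spec = spec
        self.breaks = np.asarray(breaks, float)
        subj = study.subjects if ids is None else study.subjects.loc[list(ids)]
        self.ids = subj.index.to_numpy()
        self.N = len(self.ids)
        self.d = spec.n_random
        self.t_eval = (
            subj["time_obs"].to_numpy(float) if t_eval is None else np.broadcast_to(
                np.asarray(t_eval, float), (self.N,)
            ).copy()
        )
        self.delta = (
            subj["status"].to_numpy(float) if delta_eval is None else np.broadcast_to(
                np.asarray(delta_eval, float), (self.N,)
            ).copy()
        )
        self.X = (
            subj[list(spec.covariates)].to_numpy(float)
            if spec.covariates
            else np.zeros((self.N, 0))
        )
        self.families = [study.catalog.family(m) for m in spec.markers]

        pos = {sid: i for i, sid in enumerate(self.ids)}
        cap = self.t_eval if time_cap is None else np.minimum(self.t_eval, time_cap)
        self.marker_t, self.marker_y, self.marker_mask = [], [], []
        lng = study.long
        for m in spec.markers:
            rows = lng[lng["marker"] == m]
            rows = rows[rows["id"].isin(pos)]
            tl = [[] for _ in range(self.N)]
            yl = [[] for _ in range(self.N)]
            for sid, tt, vv in zip(rows["id"], rows["time"], rows["value"]):
                i = pos[sid]
                if tt <= cap[i] + 1e-12:
                    tl[i].append(tt)
                    yl[i].append(vv)
            nmax = max(1, max(len(x) for x in tl))
            tmat = np.zeros((self.N, nmax))
            ymat = np.zeros((self.N, nmax))
            mask = np.zeros((self.N, nmax), bool)
            empty = []
            for i in range(self.N):
                n = len(tl[i])
                if n == 0:
                    empty.append(self.ids[i])
                    continue
                tmat[i, :n] = tl[i]
                ymat[i, :n] = yl[i]
                mask[i, :n] = True
            if empty and not allow_empty:
                raise StudyValidationError(
                    f"subjects {empty[:10]!r} have no measurements of marker {m!r}"
                )
            self.marker_t.append(tmat)
            self.marker_y.append(ymat)
            self.marker_mask.append(mask)

        # Per-subject sufficient statistics for the Gaussian markers: their
        # conditional log-likelihood is quadratic in b, so node evaluations
        # never need the raw measurement arrays.
        self._suff = []
        for k, fam in enumerate(self.families):
            if fam != "gaussian":
                self._suff.append(None)
                continue
            t, y, mk = self.marker_t[k], self.marker_y[k], self.marker_mask[k]
            self._suff.append(
                {
                    "n": mk.sum(axis=1).astype(float),
                    "St": (t * mk).sum(axis=1),
                    "St2": (t * t * mk).sum(axis=1),
                    "Sy": (y * mk).sum(axis=1),
                    "Syt": (y * t * mk).sum(axis=1),
                    "Sy2": (y * y * mk).sum(axis=1),
                }
            )

        # Per-interval survival bounds truncated at t_eval: (N, Q).
        edges = np.concatenate(([0.0], self.breaks, [np.inf]))
        Q = spec.baseline_intervals
        self.surv_lo = np.minimum(self.t_eval[:, None], edges[:-1][None, :])
        self.surv_hi = np.minimum(self.t_eval[:, None], edges[1:][None, :])
        self.q_idx = _interval_index(self.breaks, self.t_eval)
        assert self.surv_lo.shape == (self.N, Q)

        # Constant pieces of the marker Hessians (Gaussian case).
        self._mode_cache = np.zeros((self.N, self.d))

    # -- linear predictor helpers ------------------------------------------
    def _eta(self, params: JointParameters, k: int, b) -> np.ndarray:
        """Marker-k linear predictor at measurement times.

        b (N, d) -> (N, J); b (N, M, d) -> (N, M, J).
        """
        t = self._expand(self.marker_t[k], b.ndim)
        base = params.beta[k, 0] + params.beta[k, 1] * t
        b0 = b[..., 2 * k][..., None]
        b1 = b[..., 2 * k + 1][..., None]
        return base + b0 + b1 * t

    @staticmethod
    def _expand(arr: np.ndarray, b_ndim: int) -> np.ndarray:
        """Insert middle axes so an (N, J) array broadcasts with (N, M, J)."""
        if b_ndim == 2:
            return arr
        idx = (slice(None),) + (None,) * (b_ndim - 2) + (slice(None),)
        return arr[idx]

    def _surv_ab(self, params: JointParameters, b):
        """Exponent pieces: A = x'gamma + sum_k alpha_k(beta0k + b0k), Bs likewise."""
        xg = self.X @ params.gamma if self.X.shape[1] else np.zeros(self.N)
        extra = (slice(None),) + (None,) * (b.ndim - 2)
        A = xg[extra] + params.alpha @ params.beta[:, 0] + b[..., 0::2] @ params.alpha
        Bs = params.alpha @ params.beta[:, 1] + b[..., 1::2] @ params.alpha
        return A, Bs

    def _cumhaz_eval(self, params: JointParameters, A, Bs, order: int = 0):
        """Lambda(t_eval | b) using the precomputed truncated bounds."""
        lam = np.exp(params.log_lambda)
        shape = np.broadcast_shapes(A.shape, Bs.shape)
        accs = [np.zeros(shape) for _ in range(order + 1)]
        extra = (slice(None),) + (None,) * (len(shape) - 1)
        for q in range(len(lam)):
            lo = np.broadcast_to(self.surv_lo[:, q][extra], shape)
            hi = np.broadcast_to(self.surv_hi[:, q][extra], shape)
            js = _exp_int_012(Bs, lo, hi, order)
            for r in range(order + 1):
                accs[r] = accs[r] + lam[q] * js[r]
        eA = np.exp(A)
        out = [eA * a for a in accs]
        return out[0] if order == 0 else tuple(out)

    # -- complete-data log-density g(b) ------------------------------------
    def g_value(self, params: JointParameters, b: np.ndarray, prior: dict) -> np.ndarray:
        """log[ L_Y(Y|b) lambda(T|b)^delta S(T|b) f_b(b) ]; b (N, M, d) -> (N, M)."""
        out = np.zeros(b.shape[:-1])
        extra1 = (slice(None),) + (None,) * (b.ndim - 2)
        for k, fam in enumerate(self.families):
            if fam == "gaussian":
                # quadratic in b via per-subject sufficient statistics
                s2 = params.sigma2[k]
                b0k, b1k = params.beta[k]
                st = self._suff[k]
                n = st["n"][extra1]
                St = st["St"][extra1]
                St2 = st["St2"][extra1]
                r1 = (st["Sy"] - b0k * st["n"] - b1k * st["St"])[extra1]
                r2 = (st["Syt"] - b0k * st["St"] - b1k * st["St2"])[extra1]
                rss = (
                    st["Sy2"]
                    - 2 * b0k * st["Sy"] - 2 * b1k * st["Syt"]
                    + b0k * b0k * st["n"] + 2 * b0k * b1k * st["St"]
                    + b1k * b1k * st["St2"]
                )[extra1]
                b0 = b[..., 2 * k]
                b1 = b[..., 2 * k + 1]
                quad = rss - 2 * (r1 * b0 + r2 * b1) + n * b0 * b0 + 2 * St * b0 * b1 + St2 * b1 * b1
                out += -0.5 * (n * math.log(2 * math.pi * s2) + quad / s2)
            else:
                eta = self._eta(params, k, b)
                y = self._expand(self.marker_y[k], b.ndim)
                mask = self._expand(self.marker_mask[k], b.ndim)
                ll = y * eta - np.logaddexp(0.0, eta)
                out += np.sum(np.where(mask, ll, 0.0), axis=-1)
        A, Bs = self._surv_ab(params, b)
        Lam = self._cumhaz_eval(params, A, Bs)
        # b is (N, d) or (N, M, d); broadcast the per-subject survival columns
        extra = (slice(None),) + (None,) * (b.ndim - 2)
        t_ev = self.t_eval[extra]
        log_haz = params.log_lambda[self.q_idx][extra] + A + Bs * t_ev
        out += self.delta[extra] * log_haz - Lam
        # random-effect prior (flattened matmul: BLAS beats generic einsum here)
        flat = b.reshape(-1, self.d)
        dev = ((flat @ prior["Binv"]) * flat).sum(axis=1).reshape(b.shape[:-1])
        out += -0.5 * (dev + prior["logdetB"] + self.d * math.log(2 * math.pi))
        return out

    def g_grad_hess(self, params: JointParameters, b: np.ndarray, prior: dict):
        """Value, gradient, Hessian of g at b (N, d)."""
        N, d = b.shape
        val = np.zeros(N)
        grad = np.zeros((N, d))
        hess = np.zeros((N, d, d))
        for k, fam in enumerate(self.families):
            if fam == "gaussian":
                s2 = params.sigma2[k]
                b0k, b1k = params.beta[k]
                st = self._suff[k]
                n, St, St2 = st["n"], st["St"], st["St2"]
                r1 = st["Sy"] - b0k * n - b1k * St
                r2 = st["Syt"] - b0k * St - b1k * St2
                rss = (
                    st["Sy2"] - 2 * b0k * st["Sy"] - 2 * b1k * st["Syt"]
                    + b0k * b0k * n + 2 * b0k * b1k * St + b1k * b1k * St2
                )
                b0 = b[:, 2 * k]
                b1 = b[:, 2 * k + 1]
                quad = rss - 2 * (r1 * b0 + r2 * b1) + n * b0 * b0 + 2 * St * b0 * b1 + St2 * b1 * b1
                val += -0.5 * (n * math.log(2 * math.pi * s2) + quad / s2)
                grad[:, 2 * k] += (r1 - n * b0 - St * b1) / s2
                grad[:, 2 * k + 1] += (r2 - St * b0 - St2 * b1) / s2
                hess[:, 2 * k, 2 * k] -= n / s2
                hess[:, 2 * k, 2 * k + 1] -= St / s2
                hess[:, 2 * k + 1, 2 * k] -= St / s2
                hess[:, 2 * k + 1, 2 * k + 1] -= St2 / s2
                continue
            eta = self._eta(params, k, b)
            y, t, mask = self.marker_y[k], self.marker_t[k], self.marker_mask[k]
            p = 1.0 / (1.0 + np.exp(-eta))
            val += np.sum(np.where(mask, y * eta - np.logaddexp(0.0, eta), 0.0), axis=1)
            resid = np.where(mask, y - p, 0.0)
            grad[:, 2 * k] += resid.sum(axis=1)
            grad[:, 2 * k + 1] += (resid * t).sum(axis=1)
            w = np.where(mask, p * (1 - p), 0.0)
            hess[:, 2 * k, 2 * k] -= w.sum(axis=1)
            ht = (w * t).sum(axis=1)
            hess[:, 2 * k, 2 * k + 1] -= ht
            hess[:, 2 * k + 1, 2 * k] -= ht
            hess[:, 2 * k + 1, 2 * k + 1] -= (w * t * t).sum(axis=1)

        A, Bs = self._surv_ab(params, b)
        Lam, dLam, d2Lam = self._cumhaz_eval(params, A, Bs, order=2)
        log_haz = params.log_lambda[self.q_idx] + A + Bs * self.t_eval
        val += self.delta * log_haz - Lam
        u = np.zeros(d)
        v = np.zeros(d)
        u[0::2] = params.alpha
        v[1::2] = params.alpha
        grad += (self.delta[:, None]) * (u[None, :] + self.t_eval[:, None] * v[None, :])
        grad -= Lam[:, None] * u[None, :] + dLam[:, None] * v[None, :]
        hess -= (
            Lam[:, None, None] * np.outer(u, u)[None]
            + dLam[:, None, None] * (np.outer(u, v) + np.outer(v, u))[None]
            + d2Lam[:, None, None] * np.outer(v, v)[None]
        )

        Binv = prior["Binv"]
        val += -0.5 * (
            ((b @ Binv) * b).sum(axis=1)
            + prior["logdetB"] + d * math.log(2 * math.pi)
        )
        grad -= b @ Binv
        hess -= Binv[None]
        return val, grad, hess

    # -- posterior modes and adaptive quadrature ---------------------------
    def find_modes(self, params: JointParameters, prior: dict, tol: float = 1e-9,
                   max_iter: int = 60):
        """Vectorized Newton ascent of g(b) per subject; warm-started."""
        b = self._mode_cache.copy()
        val, grad, hess = self.g_grad_hess(params, b, prior)
        eye = np.eye(self.d)
        for _ in range(max_iter):
            gn = np.abs(grad).max(axis=1)
            active = gn > tol
            if not active.any():
                break
            H = -hess + 1e-10 * eye[None]
            try:
                step = np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-6 * eye[None], grad[..., None])[..., 0]
            scale = np.where(active, 1.0, 0.0)[:, None]
            for _ in range(25):
                b_new = b + scale * step
                val_new = self.g_value(params, b_new[:, None, :], prior)[:, 0]
                worse = active & (val_new < val - 1e-12)
                if not worse.any():
                    break
                scale[worse] *= 0.5
            b = b + scale * step
            val, grad, hess = self.g_grad_hess(params, b, prior)
        self._mode_cache = b.copy()
        return b, val, hess

    def log_marginal(self, params: JointParameters, node_chunk: int = 1024) -> np.ndarray:
        """Per-subject marginal log-likelihood by adaptive Gauss-Hermite."""
        prior = _prior_terms(params.B)
        modes, _, hess = self.find_modes(params, prior)
        H = -hess
        # curvature must be PD; ridge the rare non-PD subject
        for ridge in (0.0, 1e-8, 1e-4, 1e-2):
            try:
                Lh = np.linalg.cholesky(H + ridge * np.eye(self.d)[None])
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise FloatingPointError("non-PD curvature at posterior modes")
        # Sigma = H^{-1}; chol(Sigma) from chol(H): Sigma = Lh^{-T} Lh^{-1}
        Linv = np.linalg.inv(Lh)
        Sig = np.matmul(Linv.transpose(0, 2, 1), Linv)
        Ls = np.linalg.cholesky(Sig)
        logdetLs = np.sum(np.log(np.diagonal(Ls, axis1=1, axis2=2)), axis=1)

        z, logwz2 = _gh_grid(self.spec.nodes_per_dim(), self.d)
        J = len(z)
        li = np.full((self.N,), -np.inf)
        pieces = []
        for start in range(0, J, node_chunk):
            zc = z[start : start + node_chunk]
            bc = modes[:, None, :] + _SQRT2 * np.matmul(Ls, zc.T).transpose(0, 2, 1)
            g = self.g_value(params, bc, prior)
            pieces.append(g + logwz2[None, start : start + node_chunk])
        li = logsumexp(np.concatenate(pieces, axis=1), axis=1)
        return li + 0.5 * self.d * _LOG2 + logdetLs


def _prior_terms(B: np.ndarray) -> dict:
    sign, logdet = np.linalg.slogdet(B)
    if sign <= 0:
        raise np.linalg.LinAlgError("B not positive definite")
    return {"Binv": np.linalg.inv(B), "logdetB": logdet}


# ---------------------------------------------------------------------------
# parameter packing


class ParameterPacking:
    """Bijection between JointParameters and an unconstrained vector."""

    def __init__(self, families: list[str], n_cov: int, Q: int):
        self.families = families
        self.p = len(families)
        self.d = 2 * self.p
        self.n_cov = n_cov
        self.Q = Q
        self.n_gauss = sum(f == "gaussian" for f in families)
        self.tril = np.tril_indices(self.d)
        self.n_chol = len(self.tril[0])
        self.size = 2 * self.p + self.n_gauss + self.n_chol + self.p + n_cov + Q

    def pack(self, params: JointParameters) -> np.ndarray:
        x = [params.beta.ravel()]
        x.append(np.log(params.sigma2[[f == "gaussian" for f in self.families]]))
        L = np.linalg.cholesky(params.B)
        L = L.copy()
        diag = np.arange(self.d)
        L[diag, diag] = np.log(L[diag, diag])
        x.append(L[self.tril])
        x.extend([params.alpha, params.gamma, params.log_lambda])
        return np.concatenate(x)

    def unpack(self, x: np.ndarray) -> JointParameters:
        i = 0
        beta = x[i : i + 2 * self.p].reshape(self.p, 2); i += 2 * self.p
        sigma2 = np.full(self.p, np.nan)
        for k, f in enumerate(self.families):
            if f == "gaussian":
                sigma2[k] = math.exp(x[i]); i += 1
        L = np.zeros((self.d, self.d))
        L[self.tril] = x[i : i + self.n_chol]; i += self.n_chol
        diag = np.arange(self.d)
        L[diag, diag] = np.exp(L[diag, diag])
        B = L @ L.T
        alpha = x[i : i + self.p]; i += self.p
        gamma = x[i : i + self.n_cov]; i += self.n_cov
        log_lambda = x[i : i + self.Q]; i += self.Q
        return JointParameters(beta, sigma2, B, alpha.copy(), gamma.copy(), log_lambda.copy())

    def labels(self, markers: tuple[str, ...], covariates: tuple[str, ...]) -> list[str]:
        lab = []
        for m in markers:
            lab += [f"beta0[{m}]", f"beta1[{m}]"]
        for k, m in enumerate(markers):
            if self.families[k] == "gaussian":
                lab.append(f"log_sigma2[{m}]")
        for r, c in zip(*self.tril):
            lab.append(f"cholB[{r},{c}]")
        lab += [f"alpha[{m}]" for m in markers]
        lab += [f"gamma[{c}]" for c in covariates]
        lab += [f"log_lambda[{q}]" for q in range(self.Q)]
        return lab


# ---------------------------------------------------------------------------
# public API


def baseline_breaks(study: StudyData, Q: int) -> np.ndarray:
    """Interior cut points of the piecewise baseline at event-time quantiles."""
    ev = study.subjects.loc[study.subjects["status"] == 1, "time_obs"].to_numpy(float)
    if len(ev) == 0:
        raise StudyValidationError("no events in study: survival sub-model unidentified")
    if Q == 1:
        return np.array([])
    qs = np.quantile(ev, np.linspace(0, 1, Q + 1)[1:-1])
    return np.unique(qs)


def log_marginal_likelihood(
    spec: ModelSpec,
    params: JointParameters,
    study: StudyData,
    breaks: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood of a parameter set on a study.

    Each subject contributes log of the integral over its random effects of
    (conditional marker likelihood) x (hazard^delta) x (survival) x (prior),
    evaluated by adaptive Gauss-Hermite quadrature.
    """
    if breaks is None:
        breaks = baseline_breaks(study, spec.baseline_intervals)
    design = JointDesign(study, spec, breaks)
    li = design.log_marginal(params)
    if not np.all(np.isfinite(li)):
        bad = design.ids[~np.isfinite(li)]
        raise FloatingPointError(f"non-finite likelihood for subjects {bad[:10]!r}")
    return float(li.sum())


@dataclass
class FittedJointModel:
    """A maximized joint model: estimates, uncertainty and diagnostics."""

    spec: ModelSpec
    params: JointParameters
    breaks: np.ndarray
    x_hat: np.ndarray                 # unconstrained estimate
    covariance: np.ndarray | None     # inverse observed information (unconstrained)
    log_likelihood: float
    converged: bool
    n_iter: int
    grad_norm: float
    families: list[str] = field(default_factory=list)
    covariance_ok: bool = True

    @property
    def packing(self) -> ParameterPacking:
        return ParameterPacking(self.families, len(self.spec.covariates),
                                self.spec.baseline_intervals)

    @property
    def labels(self) -> list[str]:
        return self.packing.labels(self.spec.markers, self.spec.covariates)

    def se_unconstrained(self) -> np.ndarray:
        if self.covariance is None:
            raise ValueError("no valid covariance available")
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def wald_ci(self, label: str, level: float = 0.95) -> tuple[float, float]:
        """Natural-scale Wald interval (log-scale params are exp-transformed)."""
        from scipy.stats import norm

        idx = self.labels.index(label)
        se = self.se_unconstrained()[idx]
        zq = norm.ppf(0.5 + level / 2.0)
        lo = self.x_hat[idx] - zq * se
        hi = self.x_hat[idx] + zq * se
        if label.startswith(("log_sigma2", "log_lambda")):
            return math.exp(lo), math.exp(hi)
        return lo, hi

    def estimate(self, label: str) -> float:
        val = self.x_hat[self.labels.index(label)]
        if label.startswith(("log_sigma2", "log_lambda")):
            return math.exp(val)
        return float(val)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "bsma-joint-model-v1",
                "markers": list(self.spec.markers),
                "covariates": list(self.spec.covariates),
                "baseline_intervals": self.spec.baseline_intervals,
                "n_nodes": self.spec.n_nodes,
                "families": self.families,
                "breaks": self.breaks.tolist(),
                "x_hat": self.x_hat.tolist(),
                "covariance": None if self.covariance is None else self.covariance.tolist(),
                "log_likelihood": self.log_likelihood,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "grad_norm": self.grad_norm,
                "covariance_ok": self.covariance_ok,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedJointModel":
        d = json.loads(text)
        if d.get("format") != "bsma-joint-model-v1":
            raise ValueError("unrecognized model artifact format")
        spec = ModelSpec(
            tuple(d["markers"]), tuple(d["covariates"]),
            d["baseline_intervals"], d["n_nodes"],
        )
        packing = ParameterPacking(d["families"], len(spec.covariates),
                                   spec.baseline_intervals)
        x = np.array(d["x_hat"])
        return cls(
            spec=spec,
            params=packing.unpack(x),
            breaks=np.array(d["breaks"]),
            x_hat=x,
            covariance=None if d["covariance"] is None else np.array(d["covariance"]),
            log_likelihood=d["log_likelihood"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            grad_norm=d["grad_norm"],
            families=d["families"],
            covariance_ok=d["covariance_ok"],
        )


def _initial_parameters(design: JointDesign, packing: ParameterPacking,
                        study: StudyData, spec: ModelSpec) -> JointParameters:
    """Moment-based starting values: pooled GLM per marker, crude hazard."""
    p = packing.p
    beta = np.zeros((p, 2))
    sigma2 = np.full(p, np.nan)
    B = np.zeros((2 * p, 2 * p))
    for k, fam in enumerate(design.families):
        t = design.marker_t[k][design.marker_mask[k]]
        y = design.marker_y[k][design.marker_mask[k]]
        Xd = np.column_stack([np.ones_like(t), t])
        if fam == "gaussian":
            coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            resid = y - Xd @ coef
            tot = float(np.var(resid))
            beta[k] = coef
            sigma2[k] = max(0.4 * tot, 1e-3)
            B[2 * k, 2 * k] = max(0.5 * tot, 0.05)
            B[2 * k + 1, 2 * k + 1] = max(0.25 * tot, 0.05)
        else:
            pbar = min(max(float(np.mean(y)), 0.02), 0.98)
            beta[k] = [math.log(pbar / (1 - pbar)), 0.0]
            B[2 * k, 2 * k] = 0.5
            B[2 * k + 1, 2 * k + 1] = 0.25
    # crude piecewise-exponential baseline: events / person-time per interval
    edges = np.concatenate(([0.0], design.breaks, [np.inf]))
    T = design.t_eval
    delta = design.delta
    log_lam = np.zeros(packing.Q)
    for q in range(packing.Q):
        lo, hi = edges[q], edges[q + 1]
        exposure = np.clip(np.minimum(T, hi) - lo, 0.0, None).sum()
        events = ((T > lo) & (T <= hi) & (delta == 1)).sum()
        log_lam[q] = math.log(max(events, 0.5) / max(exposure, 1e-8))
    return JointParameters(
        beta, sigma2, B, np.zeros(p), np.zeros(packing.n_cov), log_lam
    )


def _staged_init(
    spec: ModelSpec, study: StudyData, breaks: np.ndarray
) -> JointParameters:
    """Initial values for a multi-marker fit from one-marker sub-fits.

    Marker blocks of B, beta, sigma2 and alpha come from the separate fits;
    cross-blocks start at zero and the baseline at the sub-fits' average.
    """
    p = len(spec.markers)
    beta = np.zeros((p, 2))
    sigma2 = np.full(p, np.nan)
    B = np.zeros((2 * p, 2 * p))
    alpha = np.zeros(p)
    log_lam = np.zeros(spec.baseline_intervals)
    gamma = np.zeros(len(spec.covariates))
    for k, m in enumerate(spec.markers):
        sub = ModelSpec((m,), spec.covariates, spec.baseline_intervals, spec.n_nodes)
        fit = fit_joint_model(sub, study, compute_covariance=False,
                              max_iter=150, _allow_staged=False)
        beta[k] = fit.params.beta[0]
        sigma2[k] = fit.params.sigma2[0]
        B[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = fit.params.B
        alpha[k] = fit.params.alpha[0]
        log_lam += fit.params.log_lambda / p
        gamma += fit.params.gamma / p
    return JointParameters(beta, sigma2, B, alpha, gamma, log_lam)


def fit_joint_model(
    spec: ModelSpec,
    study: StudyData,
    init: JointParameters | None = None,
    max_iter: int = 300,
    gtol: float = 1e-4,
    compute_covariance: bool = True,
    _allow_staged: bool = True,
) -> FittedJointModel:
    """Fit a joint model by maximum marginal likelihood.

    Quasi-Newton (L-BFGS-B) maximization on the unconstrained scale; a
    multi-marker fit initializes from its one-marker sub-fits. The
    covariance of the estimates is the inverse observed information from a
    finite-difference Hessian at the optimum. Convergence means the relative
    likelihood change fell below tolerance with the scaled gradient
    max|g|/max(1,|loglik|) below ``gtol``. Non-convergence is flagged on the
    returned object, never raised.
    """
    for m in spec.markers:
        if m not in study.catalog.names:
            raise StudyValidationError(f"marker {m!r} not in study catalog")
    breaks = baseline_breaks(study, spec.baseline_intervals)
    design = JointDesign(study, spec, breaks)
    packing = ParameterPacking(design.families, len(spec.covariates),
                               spec.baseline_intervals)
    if init is None:
        if len(spec.markers) > 1 and _allow_staged:
            init = _staged_init(spec, study, breaks)
        else:
            init = _initial_parameters(design, packing, study, spec)
    x0 = packing.pack(init)

    def nll(x: np.ndarray) -> float:
        try:
            params = packing.unpack(x)
            return -float(design.log_marginal(params).sum())
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e12

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter * packing.size,
                 "ftol": 1e-9, "gtol": 1e-6, "eps": 1e-6},
    )
    scale = max(1.0, abs(float(res.fun)))
    grad_norm = float(np.max(np.abs(res.jac)) / scale) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm < gtol)

    cov = None
    cov_ok = False
    if compute_covariance:
        try:
            H = approx_hess1(res.x, nll)
            H = 0.5 * (H + H.T)
            w = np.linalg.eigvalsh(H)
            if w.min() > 0:
                cov = np.linalg.inv(H)
                cov_ok = True
            else:  # singular information: pseudo-inverse, flagged
                cov = np.linalg.pinv(H)
        except (np.linalg.LinAlgError, FloatingPointError):
            cov = None

    return FittedJointModel(
        spec=spec,
        params=packing.unpack(res.x),
        breaks=breaks,
        x_hat=res.x.copy(),
        covariance=cov,
        log_likelihood=float(-res.fun),
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        families=design.families,
        covariance_ok=cov_ok,
    )


def draw_parameters(
    fit: FittedJointModel, M: int, seed: int
) -> list[JointParameters]:
    """M draws from the asymptotic normal of the estimates (natural scale).

    M = 0 is the degenerate plug-in mode returning just the point estimate.
    """
    packing = fit.packing
    if M == 0:
        return [fit.params]
    if fit.covariance is None or not fit.covariance_ok:
        raise ValueError(
            "fit has no valid covariance; use M=0 (plug-in) instead"
        )
    rng = np.random.default_rng(seed)
    cov = 0.5 * (fit.covariance + fit.covariance.T)
    w, V = np.linalg.eigh(cov)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    draws = fit.x_hat[None, :] + rng.standard_normal((M, packing.size)) @ root.T
    return [packing.unpack(x) for x in draws]
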