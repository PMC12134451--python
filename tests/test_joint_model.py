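import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from bsma.datamodel import MarkerCatalog, StudyData, StudyValidationError
from bsma.joint_model import (
    FittedJointModel,
    JointParameters,
    ModelSpec,
    ParameterPacking,
    baseline_breaks,
    draw_parameters,
    fit_joint_model,
    log_marginal_likelihood,
    piecewise_cumhaz,
)
from bsma.simulator import builtin_scenario, simulate
from tests.conftest import one_marker_scenario


def closed_form_loglik_alpha0(study, params, breaks, marker="m1", gamma_col=None):
    """Independent oracle at alpha=0: exact LMM marginal + piecewise-exponential
    survival log-likelihoods (no quadrature anywhere)."""
    tot = 0.0
    lng = study.long[study.long["marker"] == marker]
    for sid, grp in lng.groupby("id"):
        t = grp["time"].to_numpy()
        y = grp["value"].to_numpy()
        Z = np.column_stack([np.ones_like(t), t])
        mean = params.beta[0, 0] + params.beta[0, 1] * t
        cov = Z @ params.B @ Z.T + params.sigma2[0] * np.eye(len(t))
        tot += multivariate_normal.logpdf(y, mean, cov)
    edges = np.concatenate(([0.0], breaks, [np.inf]))
    lam = np.exp(params.log_lambda)
    x = study.subjects[gamma_col].to_numpy(float) if gamma_col else np.zeros(len(study.subjects))
    for (Ti, di), xi in zip(
        zip(study.subjects["time_obs"], study.subjects["status"]), x
    ):
        shift = math.exp(xi * (params.gamma[0] if gamma_col else 0.0))
        q = int(np.searchsorted(breaks, Ti, side="right"))
        cum = sum(
            lam[j] * max(0.0, min(Ti, edges[j + 1]) - min(Ti, edges[j]))
            for j in range(len(lam))
        )
        tot += di * (math.log(lam[q]) + math.log(shift)) - shift * cum
    return tot


class TestLogMarginalLikelihood:
    def test_independence_limit_matches_closed_forms(self, study_k1):
        _, study, _ = study_k1
        spec = ModelSpec(markers=("m1",), baseline_intervals=3)
        breaks = baseline_breaks(study, 3)
        params = JointParameters(
            beta=np.array([[0.1, -0.9]]), sigma2=np.array([0.55]),
            B=np.array([[1.0, 0.4], [0.4, 0.9]]), alpha=np.array([0.0]),
            gamma=np.zeros(0), log_lambda=np.array([-1.0, -0.5, -0.3]),
        )
        ll = log_marginal_likelihood(spec, params, study, breaks=breaks)
        oracle = closed_form_loglik_alpha0(study, params, breaks)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_independence_limit_with_survival_covariate(self, study_k1):
        _, study, _ = study_k1
        study = StudyData(
            study.subjects.assign(age=np.linspace(-1, 1, study.n_subjects)),
            study.long, study.catalog,
        )
        spec = ModelSpec(markers=("m1",), covariates=("age",), baseline_intervals=2)
        breaks = baseline_breaks(study, 2)
        params = JointParameters(
            beta=np.array([[0.0, -1.0]]), sigma2=np.array([0.5]),
            B=np.array([[1.0, 0.5], [0.5, 1.0]]), alpha=np.array([0.0]),
            gamma=np.array([0.7]), log_lambda=np.array([-1.2, -0.8]),
        )
        ll = log_marginal_likelihood(spec, params, study, breaks=breaks)
        oracle = closed_form_loglik_alpha0(study, params, breaks, gamma_col="age")
        assert ll == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("family,value", [("gaussian", 1.3), ("bernoulli", 1.0)])
    def test_single_subject_matches_grid_integration(self, family, value):
        """Quadrature vs brute-force 2-D trapezoid over a wide grid of b."""
        catalog = MarkerCatalog((("m1", family),))
        subjects = pd.DataFrame(
            {"time_obs": [1.4], "status": [1]}, index=pd.Index([1], name="id")
        )
        long = pd.DataFrame(
            {"id": [1], "time": [0.6], "marker": ["m1"], "value": [value]}
        )
        study = StudyData(subjects, long, catalog)
        spec = ModelSpec(markers=("m1",), baseline_intervals=1)
        params = JointParameters(
            beta=np.array([[0.2, -0.6]]),
            sigma2=np.array([0.5 if family == "gaussian" else np.nan]),
            B=np.array([[0.8, 0.2], [0.2, 0.6]]), alpha=np.array([-0.5]),
            gamma=np.zeros(0), log_lambda=np.array([math.log(0.4)]),
        )
        ll = log_marginal_likelihood(spec, params, study, breaks=np.array([]))

        grid = np.linspace(-6, 6, 801)
        b0, b1 = np.meshgrid(grid, grid, indexing="ij")
        eta = params.beta[0, 0] + params.beta[0, 1] * 0.6 + b0 + b1 * 0.6
        if family == "gaussian":
            ly = -0.5 * ((value - eta) ** 2 / 0.5 + math.log(2 * math.pi * 0.5))
        else:
            ly = value * eta - np.logaddexp(0.0, eta)
        A = params.alpha[0] * (params.beta[0, 0] + b0)
        Bs = params.alpha[0] * (params.beta[0, 1] + b1)
        lam0 = 0.4
        with np.errstate(over="ignore"):
            Lam = np.where(
                np.abs(Bs) < 1e-12,
                lam0 * np.exp(A) * 1.4,
                lam0 * np.exp(A) * (np.exp(Bs * 1.4) - 1) / np.where(np.abs(Bs) < 1e-12, 1.0, Bs),
            )
        lhaz = math.log(lam0) + A + Bs * 1.4
        lprior = multivariate_normal.logpdf(
            np.dstack([b0, b1]).reshape(-1, 2), np.zeros(2), params.B
        ).reshape(b0.shape)
        integrand = np.exp(ly + lhaz - Lam + lprior)
        val = np.trapezoid(np.trapezoid(integrand, grid, axis=1), grid)
        assert ll == pytest.approx(math.log(val), abs=1e-5)

    def test_quadrature_self_convergence(self):
        spec_g = one_marker_scenario(seed=19, n_subjects=50)
        study, _ = simulate(spec_g)
        params = JointParameters(
            beta=spec_g.beta.copy(), sigma2=spec_g.sigma2.copy(), B=spec_g.B.copy(),
            alpha=spec_g.alpha0.copy(), gamma=np.zeros(0),
            log_lambda=np.array([math.log(spec_g.lambda0)]),
        )
        lls = [
            log_marginal_likelihood(
                ModelSpec(markers=("m1",), baseline_intervals=1, n_nodes=nn),
                params, study, breaks=np.array([]),
            )
            for nn in (3, 9, 15)
        ]
        assert abs(lls[1] - lls[2]) < 1e-6
        assert abs(lls[0] - lls[1]) < 1e-4  # 3-node grid is the coarse fallback

    def test_missing_marker_subject_rejected(self, study_k1):
        _, study, _ = study_k1
        lng = study.long[study.long["id"] != study.subject_ids[0]]
        broken = StudyData(study.subjects, lng.reset_index(drop=True), study.catalog)
        with pytest.raises(StudyValidationError, match="no measurements"):
            log_marginal_likelihood(
                ModelSpec(markers=("m1",), baseline_intervals=1),
                JointParameters(
                    beta=np.zeros((1, 2)), sigma2=np.array([0.5]),
                    B=np.eye(2), alpha=np.zeros(1), gamma=np.zeros(0),
                    log_lambda=np.zeros(1),
                ),
                broken,
            )


def test_marker_order_permutation_leaves_likelihood_unchanged(study_i1):
    """Swapping the two markers (and permuting the parameters to match)
    gives the identical marginal likelihood."""
    _, study, _ = study_i1
    breaks = baseline_breaks(study, 1)
    rng = np.random.default_rng(0)
    L = np.tril(rng.normal(0, 0.3, (4, 4))) + np.eye(4)
    B = L @ L.T
    params12 = JointParameters(
        beta=np.array([[0.1, -0.8], [-0.1, -1.1]]), sigma2=np.array([0.5, 0.6]),
        B=B, alpha=np.array([-0.4, -0.6]), gamma=np.zeros(0),
        log_lambda=np.array([-1.5]),
    )
    perm = [2, 3, 0, 1]
    params21 = JointParameters(
        beta=params12.beta[::-1].copy(), sigma2=params12.sigma2[::-1].copy(),
        B=B[np.ix_(perm, perm)], alpha=params12.alpha[::-1].copy(),
        gamma=np.zeros(0), log_lambda=params12.log_lambda.copy(),
    )
    spec12 = ModelSpec(markers=("m1", "m2"), baseline_intervals=1, n_nodes=5)
    spec21 = ModelSpec(markers=("m2", "m1"), baseline_intervals=1, n_nodes=5)
    ll12 = log_marginal_likelihood(spec12, params12, study, breaks=breaks)
    ll21 = log_marginal_likelihood(spec21, params21, study, breaks=breaks)
    # exact for the true integral; the tensor quadrature grid is very nearly
    # orientation-invariant, well inside the optimizer tolerance
    assert ll12 == pytest.approx(ll21, abs=1e-4)


class TestFit:
    def test_one_marker_recovery_single_replicate(self, fit_k1, study_k1):
        spec, _, _ = study_k1
        fit = fit_k1
        assert fit.converged and fit.covariance_ok
        assert fit.params.beta[0, 0] == pytest.approx(0.0, abs=0.25)
        assert fit.params.beta[0, 1] == pytest.approx(-1.0, abs=0.3)
        assert fit.params.sigma2[0] == pytest.approx(0.5, abs=0.12)
        assert fit.params.alpha[0] == pytest.approx(-0.5, abs=0.35)
        assert np.linalg.eigvalsh(fit.covariance).min() > 0

    def test_null_association_not_rejected(self):
        spec = one_marker_scenario(seed=23, n_subjects=400, alpha=0.0, lambda0=0.3)
        study, _ = simulate(spec)
        fit = fit_joint_model(ModelSpec(markers=("m1",), baseline_intervals=1), study)
        lo, hi = fit.wald_ci("alpha[m1]")
        # CI roughly centered on 0; allow the ~5% miss with slack
        assert lo < 0.15 and hi > -0.15

    def test_one_marker_association_attenuated_on_multi_marker_data(self):
        """Omitting two of three hazard-driving markers attenuates alpha."""
        spec = builtin_scenario("I.1", seed=41, n_subjects=400)
        study, _ = simulate(spec)
        fit = fit_joint_model(
            ModelSpec(markers=("m1",), baseline_intervals=1), study,
            compute_covariance=False,
        )
        assert -0.5 < fit.params.alpha[0] < 0.0

    def test_two_marker_fit_recovers_cross_covariance_sign(self):
        spec = builtin_scenario("D.1", seed=43, n_subjects=250)
        study, _ = simulate(spec)
        fit = fit_joint_model(
            ModelSpec(markers=("m1", "m2"), baseline_intervals=1, n_nodes=3),
            study, compute_covariance=False,
        )
        # generative cross-block (after PSD repair) is strongly positive
        assert fit.params.B[0, 2] > 0.1
        assert fit.params.B[1, 3] > 0.1

    def test_fit_beats_generating_parameters(self, study_k1):
        spec, study, _ = study_k1
        fit = fit_joint_model(
            ModelSpec(markers=("m1",), baseline_intervals=1), study,
            compute_covariance=False,
        )
        params_true = JointParameters(
            beta=spec.beta.copy(), sigma2=spec.sigma2.copy(), B=spec.B.copy(),
            alpha=spec.alpha0.copy(), gamma=np.zeros(0),
            log_lambda=np.array([math.log(spec.lambda0)]),
        )
        ll_true = log_marginal_likelihood(fit.spec, params_true, study,
                                          breaks=fit.breaks)
        assert fit.log_likelihood >= ll_true

    def test_requires_events(self, study_k1):
        _, study, _ = study_k1
        no_events = StudyData(
            study.subjects.assign(status=0), study.long, study.catalog
        )
        with pytest.raises(StudyValidationError, match="no events"):
            fit_joint_model(ModelSpec(markers=("m1",), baseline_intervals=1), no_events)

    def test_serialization_round_trip(self, fit_k1):
        text = fit_k1.to_json()
        back = FittedJointModel.from_json(text)
        assert np.allclose(back.x_hat, fit_k1.x_hat)
        assert np.allclose(back.covariance, fit_k1.covariance)
        assert back.spec == fit_k1.spec
        assert back.log_likelihood == pytest.approx(fit_k1.log_likelihood)


class TestParameterPacking:
    def test_round_trip(self):
        packing = ParameterPacking(["gaussian", "bernoulli"], 2, 3)
        rng = np.random.default_rng(1)
        L = np.tril(rng.normal(0, 0.4, (4, 4))) + np.eye(4)
        params = JointParameters(
            beta=rng.normal(size=(2, 2)),
            sigma2=np.array([0.7, np.nan]),
            B=L @ L.T,
            alpha=rng.normal(size=2),
            gamma=rng.normal(size=2),
            log_lambda=rng.normal(size=3),
        )
        back = packing.unpack(packing.pack(params))
        assert np.allclose(back.beta, params.beta)
        assert back.sigma2[0] == pytest.approx(0.7)
        assert np.isnan(back.sigma2[1])
        assert np.allclose(back.B, params.B)
        assert np.allclose(back.alpha, params.alpha)
        assert np.allclose(back.gamma, params.gamma)
        assert np.allclose(back.log_lambda, params.log_lambda)

    def test_labels_align_with_vector(self):
        packing = ParameterPacking(["gaussian"], 0, 2)
        labels = packing.labels(("m1",), ())
        assert len(labels) == packing.size
        assert labels[0] == "beta0[m1]" and "alpha[m1]" in labels


class TestDrawParameters:
    def test_plugin_mode(self, fit_k1):
        draws = draw_parameters(fit_k1, 0, seed=1)
        assert len(draws) == 1
        assert np.allclose(draws[0].beta, fit_k1.params.beta)

    def test_deterministic_under_seed(self, fit_k1):
        d1 = draw_parameters(fit_k1, 5, seed=11)
        d2 = draw_parameters(fit_k1, 5, seed=11)
        for a, b in zip(d1, d2):
            assert np.allclose(a.beta, b.beta) and np.allclose(a.B, b.B)

    def test_empirical_covariance_matches(self, fit_k1):
        packing = fit_k1.packing
        draws = draw_parameters(fit_k1, 50000, seed=3)
        X = np.array([packing.pack(p) for p in draws])
        emp = np.cov(X.T)
        rel = np.linalg.norm(emp - fit_k1.covariance) / np.linalg.norm(fit_k1.covariance)
        assert rel < 0.05

    def test_refuses_without_covariance(self, study_k1):
        _, study, _ = study_k1
        fit = fit_joint_model(
            ModelSpec(markers=("m1",), baseline_intervals=1), study,
            compute_covariance=False,
        )
        with pytest.raises(ValueError, match="M=0"):
            draw_parameters(fit, 10, seed=1)


def test_piecewise_cumhaz_closed_form():
    # two intervals, constant exponent: Lambda is lam1*u1 + lam2*u2
    breaks = np.array([1.0])
    lam = np.array([0.5, 1.5])
    L = piecewise_cumhaz(breaks, np.log(lam), 2.0, 0.0, 0.0)
    assert L == pytest.approx(0.5 * 1.0 + 1.5 * 1.0)
    # linear exponent: integral of lam*exp(b u)
    L2 = piecewise_cumhaz(np.array([]), np.array([0.0]), 1.0, 0.0, 2.0)
    assert L2 == pytest.approx((math.exp(2.0) - 1) / 2.0)
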