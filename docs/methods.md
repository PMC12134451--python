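# Methods

## Model

Each candidate model couples, for every marker k in its subset, a
generalized linear mixed sub-model to a proportional-hazards sub-model
through shared random effects. Markers carry a random intercept and a
random slope on the same time scale (study entry = 0 for every subject):

    eta_ik(t) = beta0_k + beta1_k t + b0_ik + b1_ik t
    Gaussian:  Y_ik(t) = eta_ik(t) + eps_ikt,  eps ~ N(0, sigma_k^2)
    Bernoulli: logit P(Y_ik(t) = 1 | b_ik) = eta_ik(t)

The stacked random effects b_i are N(0, B) with B unstructured within the
model's marker subset. The hazard uses the current value of each included
marker — for a Bernoulli marker the linear predictor on the logit scale,
not the probability:

    lambda_i(t | b_i) = lambda0(t) exp( x_i' gamma + sum_k alpha_k eta_ik(t) )

`lambda0` is piecewise-constant on Q intervals cut at event-time quantiles
(default Q = 5; Q = 1 reduces to a constant baseline). Because eta is
linear in t, the exponent of the hazard is linear in t within each
interval, so the cumulative hazard has the closed form
`lam_q e^a (e^{b t_hi} - e^{b t_lo}) / b` per interval (with the b -> 0
polynomial limit). A piecewise-constant baseline was chosen over splines
precisely for this closed form: the survival integral inside the
likelihood, the event-time inversion in the simulator and the prediction
ratios all reuse the same exact primitive, which makes oracle testing to
1e-8 possible.

## Estimation

Parameters are estimated by maximum marginal likelihood. Each subject's
likelihood integrates the conditional marker likelihood times
hazard^delta times survival times the random-effect prior over b_i. The
integral uses **adaptive Gauss–Hermite quadrature**: per subject, a
vectorized Newton ascent finds the conditional posterior mode of b_i and
its curvature, and a tensor Gauss–Hermite grid (9 nodes per dimension up to
dimension 4, 3 above) is centered and scaled there. For Gaussian markers
the conditional log-likelihood is quadratic in b, so node evaluations use
per-subject sufficient statistics (n, sum t, sum t^2, sum y, sum y t,
sum y^2) and never touch the raw measurement arrays — this is what makes
desk-scale fits take seconds.

The outer optimization is L-BFGS-B on an unconstrained parameterization
(log sigma^2, log-Cholesky of B, log baseline heights) with
finite-difference gradients (step 1e-6). A multi-marker fit initializes
from its one-marker sub-fits (marker blocks of B from the sub-fits,
cross-blocks at zero). "Converged" means the optimizer met its relative
function tolerance (1e-9) or the scaled gradient max|g|/max(1, |loglik|)
fell below 1e-4; the absolute gradient of a log-likelihood in the thousands
is not driven to 1e-4 by finite differences, so the scaled form is the
meaningful criterion. The covariance of the estimates is the inverse
observed information from a finite-difference Hessian; a non-positive
Hessian is flagged (`covariance_ok = False`) and parameter draws then
refuse to run (plug-in mode remains available).

Identifiability notes: one-marker fits on data whose hazard is driven by
additional, omitted markers estimate an **attenuated** association — this
is a property of the misspecified working model, not a defect, and the test
suite asserts the attenuation explicitly. Well-specified recovery (data
generated from the fitted model's own structure) achieves nominal Wald
coverage.

## Dynamic prediction

pi_i(s,t) = 1 - E[S(s+t|b)/S(s|b) | T>s, history(s)]. The expectation is
Monte Carlo over M parameter draws from N(xi_hat, Cov) (unconstrained
scale, mapped back) and, per draw, one draw of b_i from its conditional
distribution given the history up to s and survival to s. The conditional
draw uses Metropolis–Hastings with an **independence proposal**: a
multivariate t with 4 degrees of freedom centered at the conditional mode
and scaled by the curvature there; each retained sample is the endpoint of
a 50-step chain started at the mode (acceptance rates ~0.8 in the designs
here, so 50 steps give an effectively independent draw). Survival ratios
are clipped to [0,1] before averaging. M = 0 is the deterministic plug-in
mode (point estimates, conditional mode) used where determinism matters;
it agrees with the Monte-Carlo value to a few hundredths here and is the
default in the replicate pipeline. Subjects with an empty history at s are
predicted from the random-effect prior, which is what landmark-zero
predictions require.

## Accuracy under censoring

The censoring survival curve G(u) = P(C > u) is the Kaplan–Meier estimator
with event roles reversed (built on (T*, 1 - delta) via lifelines);
subjects failing at u stay in the risk set for censorings at u, i.e.,
events precede censorings at ties. Metrics over a window (s, s+t] use the
half-open window with "<=" at s+t throughout, a risk set of T* > s
(strict), and weights

    Psi_i = 1{T* > s+t} / G(s+t|s)  +  1{s < T* <= s+t, delta=1} / G(T*-|s)

with the **left limit** G(T*-|s) in the event term so a death tied with a
censoring keeps positive weight. In-window censored subjects get weight 0
but count in N(s). The AUC uses strict inequality for concordant pairs
(ties contribute 0; a documented option counts them 1/2). With no
censoring the Brier score reduces exactly to the plain mean squared error
and the AUC to the Mann–Whitney statistic — asserted as exact equalities.

## Weight estimation

BS_w(s,t) of the convex combination is a convex quadratic in w, minimized
over the probability simplex with SLSQP (analytic gradient) restarted from
every vertex and the barycenter. A ridge of 1e-10 inside the solver
objective resolves collinear-column ties toward the minimum-norm weights
(identical columns share weight equally); the reported score drops the
ridge and is evaluated with the same arithmetic as the Brier score itself,
and the solution is clamped to the best single model whenever rounding
would let any one-hot vector score lower — so dominance (averaged score <=
every single model's score on the learning risk set) holds exactly, always.
Weights are estimated per (s, t) on the learning split only and are not
transferable across (s, t) pairs. Standard errors of the averaged
prediction combine each model's bias Z_ik = pi_ik - pi_bar_i and
Monte-Carlo variance V_ik as `sum_k w_k sqrt(Z^2+V)` or
`sqrt(sum_k w_k (Z^2+V))`; by Jensen's inequality the first never exceeds
the second. V_ik is the total Monte-Carlo variance of the prediction
(parameter draws plus chain noise).

## Simulator

The generator reproduces the designs used throughout the tests: K in
{1, 2, 3, 7} markers on visit grid t = 0, 0.2, ..., 2, administrative
censoring at tau = 2, N = 1000 by default, beta_k = (0, -1), sigma_k^2 =
0.5, within-marker random-effect covariance B* = [[1, .5], [.5, 1]], and
association sets (-0.5, -0.5, -0.5) / (0, -0.5, -0.5) / (0, -0.5, -1). The
dependent designs add a cross-marker block B-dagger = [[0.5, 1], [1, 1]];
the printed source for that block is ambiguous, the full matrix under this
reading is indefinite, and it is repaired by eigenvalue clipping at 1e-8
(flagged in `ScenarioSpec.psd_repaired` and easy to change in one place).
The time-varying design uses two Gaussian markers with alpha_1(t) = -0.8 +
0.4 t and alpha_2(t) = -0.4 t, beta = (0.13, -0.76) / (0.18, -0.62),
residual SDs 0.56 / 0.65 (read as sigma, not sigma^2, since the constant
designs print the square explicitly) and block-diagonal B1 =
[[.69, .01], [.01, .26]], B2 = [[.74, -.01], [-.01, .20]].

Event times invert Lambda(T) = E, E ~ Exp(1): in closed form when the
log-hazard is linear in t, by bracketed root-finding on the quadrature of
the quadratic-exponent hazard in the time-varying design; draws whose
cumulative hazard never reaches E are administratively censored at tau.
Two constants are not derivable from the designs themselves and are this
package's choices, recorded in the simulation metadata: baseline hazard
lambda0 = 0.06, calibrated by direct Monte-Carlo so the reference
three-marker design yields ~45–50% observed events by tau = 2; and Weibull
censoring with shape 1.5 and scale 5.5, giving P(C < tau) ~ 0.2 on top of
the administrative cutoff. Both are ordinary `ScenarioSpec` fields.

What the generator emulates: informative truncation of marker series at
the observed time, marker-driven hazards, mixed Gaussian/binary panels,
cross-marker correlation, time-varying association. What it does not:
measurement-schedule irregularity and missed visits, covariate-dependent
censoring, non-linear trajectories, competing risks. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
behavior of the averaging under these mechanisms, not robustness to
real-data pathologies beyond them.

## Problem sizes in the tests

The replicate experiments in the test suite and acceptance script run at
N = 500–1000 subjects with 5–10 replicates and plug-in predictions — sizes
chosen so the full suite completes in minutes while keeping every
qualitative comparison (averaged vs single-model accuracy per landmark)
well resolved; the two-marker recovery check asserts the cross-covariance
sign at a single N = 250 fit with a 3-node-per-dimension grid. Monte-Carlo
prediction checks use M in the hundreds against self-consistency bounds of
three standard errors.

## Known limitations

- Association is current-value only; slope or cumulative-effect forms are
  not implemented.
- One event type; no competing risks or recurrent events.
- The all-marker fit at K = 7 (random-effect dimension 14) is outside the
  intended envelope of the tensor-grid quadrature; the averaging of one-
  and two-marker models is the supported route at that scale, which is the
  method's point.
- Wald-type uncertainty everywhere; no profile likelihood or bootstrap.
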