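import numpy as np
import pytest

from bsma.joint_model import ModelSpec, fit_joint_model
from bsma.simulator import B_STAR, ScenarioSpec, builtin_scenario, simulate


def one_marker_scenario(seed: int, n_subjects: int = 500, alpha: float = -0.5,
                        lambda0: float = 0.06) -> ScenarioSpec:
    """Single-Gaussian-marker generative model with the three-marker designs'
    per-marker parameter values (beta=(0,-1), sigma2=0.5, B=B*)."""
    return ScenarioSpec(
        name="one-marker",
        families=["gaussian"],
        beta=[[0.0, -1.0]],
        sigma2=[0.5],
        B=B_STAR,
        alpha0=[alpha],
        alpha1=[0.0],
        lambda0=lambda0,
        n_subjects=n_subjects,
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_i1():
    """A moderate three-marker study (independent random effects)."""
    spec = builtin_scenario("I.1", seed=7, n_subjects=200)
    study, truth = simulate(spec)
    return spec, study, truth


@pytest.fixture(scope="session")
def study_k1():
    """A one-marker study from the matching generative model."""
    spec = one_marker_scenario(seed=31, n_subjects=300)
    study, truth = simulate(spec)
    return spec, study, truth


@pytest.fixture(scope="session")
def fit_k1(study_k1):
    """One-marker joint model fitted to the one-marker study."""
    _, study, _ = study_k1
    return fit_joint_model(ModelSpec(markers=("m1",), baseline_intervals=1), study)


@pytest.fixture(scope="session")
def fits_i1(study_i1):
    """The three one-marker fits on the three-marker study."""
    _, study, _ = study_i1
    return [
        fit_joint_model(ModelSpec(markers=(m,), baseline_intervals=1), study,
                        compute_covariance=False)
        for m in ("m1", "m2", "m3")
    ]
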