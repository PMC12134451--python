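"""End-to-end experiments: enumeration, splits, weight estimation, evaluation.

A run enumerates candidate joint models (one per marker, one per marker
pair, or the all-marker model), fits them on a learning split, estimates
model-averaging weights per (landmark, horizon) on the learning split only,
and evaluates single-model and averaged predictions on the held-out test
split with time-dependent AUC, Brier score and — when the generative truth
is available — mean squared error against the true event probabilities.
Replicates either re-simulate a scenario or rotate the folds of a
cross-validation on a fixed study.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import auc, brier_score, censoring_curve, mse_vs_truth, window_outcomes
from .averaging import average_predictions, estimate_weights
from .datamodel import StudyData
from .joint_model import FittedJointModel, ModelSpec, fit_joint_model
from .prediction import risk_matrix
from .simulator import ScenarioSpec, SimulationTruth, simulate

logger = logging.getLogger(__name__)

MODES = ("one_marker_MA", "two_marker_MA", "single_models", "all_marker")


@dataclass
class ExperimentPlan:
    """What to run: candidate-model family, evaluation grid, splits, sizes."""

    mode: str = "one_marker_MA"
    landmarks: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    horizon: float = 0.5
    learning_fraction: float = 0.8
    folds: int | None = None          # k-fold CV on a fixed study instead
    replicates: int = 1
    draws: int = 0                    # M per prediction; 0 = plug-in
    seed: int = 0
    baseline_intervals: int = 5
    n_nodes: int | None = None
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if any(s < 0 for s in self.landmarks):
            raise ValueError("landmarks must be nonnegative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.folds is not None and self.folds < 2:
            raise ValueError("folds must be >= 2 for cross-validation")


def enumerate_models(
    marker_catalog,
    mode: str,
    baseline_intervals: int = 5,
    covariates: tuple[str, ...] = (),
    n_nodes: int | None = None,
) -> list[ModelSpec]:
    """Ordered candidate models for a marker catalog.

    one-marker: K models in catalog order; two-marker: all C(K,2) pairs in
    lexicographic catalog order; all-marker: the single full model.
    """
    names = marker_catalog.names if hasattr(marker_catalog, "names") else list(marker_catalog)
    K = len(names)
    if K < 1:
        raise ValueError("empty marker catalog")
    kw = dict(covariates=tuple(covariates), baseline_intervals=baseline_intervals,
              n_nodes=n_nodes)
    if mode in ("one_marker_MA", "single_models"):
        subsets = [(n,) for n in names]
    elif mode == "two_marker_MA":
        if K < 2:
            raise ValueError("two-marker enumeration needs at least 2 markers")
        subsets = list(itertools.combinations(names, 2))
    elif mode == "all_marker":
        subsets = [tuple(names)]
    else:
        raise ValueError(f"mode must be one of {MODES}")
    return [ModelSpec(markers=s, **kw) for s in subsets]


def _study_hash(study: StudyData) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(study.subjects, index=True).values.tobytes())
    h.update(pd.util.hash_pandas_object(study.long, index=False).values.tobytes())
    return h.hexdigest()[:16]


class FitCache:
    """In-memory cache of fitted models keyed by (data hash, model spec)."""

    def __init__(self):
        self._store: dict[tuple, FittedJointModel] = {}

    def get_or_fit(self, spec: ModelSpec, study: StudyData, **kw) -> FittedJointModel:
        key = (_study_hash(study), spec)
        if key not in self._store:
            self._store[key] = fit_joint_model(spec, study, **kw)
        return self._store[key]


@dataclass
class ExperimentReport:
    """Tidy metric rows plus weights and audit information."""

    plan: ExperimentPlan
    metrics: pd.DataFrame       # replicate, s, t, method, metric, value, n_risk, n_events
    weights: pd.DataFrame       # replicate, s, t, model_label, weight, achieved_bs
    learning_ids: dict          # replicate -> sorted learning-set ids
    dropped_models: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric across replicates."""
        g = self.metrics.groupby(["s", "t", "method", "metric"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.sort_values(["metric", "s", "method"]).reset_index(drop=True)

    def pivot(self, metric: str) -> pd.DataFrame:
        rows = self.metrics[self.metrics["metric"] == metric]
        return rows.pivot_table(index=["replicate", "s"], columns="method",
                                values="value").reset_index()


def _split_ids(ids: np.ndarray, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(len(ids))
    n_learn = int(round(fraction * len(ids)))
    return ids[perm[:n_learn]], ids[perm[n_learn:]]


def _evaluate(
    fits: list[FittedJointModel],
    learn: StudyData,
    test: StudyData,
    truth: SimulationTruth | None,
    plan: ExperimentPlan,
    rep: int,
    rng,
    use_ma: bool,
):
    metric_rows = []
    weight_rows = []
    t = plan.horizon
    for s in plan.landmarks:
        if len(learn.at_risk_ids(s)) == 0 or len(test.at_risk_ids(s)) == 0:
            warnings.warn(f"no subjects at risk at s={s}; landmark skipped")
            continue
        seed_l = int(rng.integers(2 ** 31 - 1))
        seed_t = int(rng.integers(2 ** 31 - 1))
        rm_test = risk_matrix(fits, test, s, t, M=plan.draws, seed=seed_t)
        out_test = window_outcomes(test, s, t, censoring_curve(test))
        order = {sid: i for i, sid in enumerate(rm_test.ids)}
        perm = np.array([order[sid] for sid in out_test.ids])

        columns = {lab: rm_test.pi[perm, j] for j, lab in enumerate(rm_test.model_labels)}
        if use_ma and len(fits) > 1:
            rm_learn = risk_matrix(fits, learn, s, t, M=plan.draws, seed=seed_l)
            out_learn = window_outcomes(learn, s, t, censoring_curve(learn))
            wv = estimate_weights(rm_learn, out_learn)
            weight_rows.append(wv.to_frame().assign(replicate=rep))
            avg = average_predictions(rm_test, wv, compute_se=False)
            columns["MA"] = avg.pi[perm]

        truth_pi = truth.risk(out_test.ids, s, t) if truth is not None else None
        for method, pred in columns.items():
            rows = {
                "replicate": rep, "s": s, "t": t, "method": method,
                "n_risk": out_test.n_risk, "n_events": out_test.n_events,
            }
            a = auc(pred, out_test)
            metric_rows.append({**rows, "metric": "auc",
                                "value": np.nan if a is None else a})
            metric_rows.append({**rows, "metric": "bs",
                                "value": brier_score(pred, out_test)})
            if truth_pi is not None:
                metric_rows.append({**rows, "metric": "mse",
                                    "value": mse_vs_truth(pred, truth_pi)})
    return metric_rows, weight_rows


def run_experiment(
    study_or_scenario: StudyData | ScenarioSpec,
    plan: ExperimentPlan,
    truth: SimulationTruth | None = None,
    cache: FitCache | None = None,
) -> ExperimentReport:
    """Run the full learn/weight/evaluate loop and aggregate over replicates.

    With a ScenarioSpec input, each replicate simulates a fresh study (the
    generative truth then feeds the MSE); with a StudyData input, replicates
    are either random learning/test splits or the folds of a k-fold CV.
    Weights and fits depend only on the learning split; the report records
    the learning ids per replicate for audit.
    """
    rng = np.random.default_rng(plan.seed)
    cache = cache or FitCache()
    use_ma = plan.mode in ("one_marker_MA", "two_marker_MA")

    metric_rows: list[dict] = []
    weight_frames: list[pd.DataFrame] = []
    learning_ids: dict[int, list] = {}
    dropped: list = []

    if isinstance(study_or_scenario, ScenarioSpec):
        reps = [("simulate", r) for r in range(plan.replicates)]
    elif plan.folds:
        all_ids = study_or_scenario.subject_ids
        perm = rng.permutation(len(all_ids))
        folds = np.array_split(perm, plan.folds)
        reps = [("fold", f) for f in range(plan.folds)]
    else:
        reps = [("split", r) for r in range(plan.replicates)]

    for kind, r in reps:
        if kind == "simulate":
            spec: ScenarioSpec = study_or_scenario
            sim_seed = int(rng.integers(2 ** 31 - 1))
            study, rep_truth = simulate(spec, seed=sim_seed)
            ids_l, ids_t = _split_ids(study.subject_ids, plan.learning_fraction, rng)
        else:
            study = study_or_scenario
            rep_truth = truth
            if kind == "fold":
                test_pos = folds[r]
                ids_t = study.subject_ids[test_pos]
                ids_l = np.setdiff1d(study.subject_ids, ids_t)
            else:
                ids_l, ids_t = _split_ids(study.subject_ids, plan.learning_fraction, rng)
        learn = study.subset(ids_l)
        test = study.subset(ids_t)
        learning_ids[r] = sorted(map(str, ids_l))

        specs = enumerate_models(
            study.catalog, plan.mode, plan.baseline_intervals,
            plan.covariates, plan.n_nodes,
        )
        fits = []
        for ms in specs:
            try:
                fit = cache.get_or_fit(ms, learn)
            except Exception as exc:  # noqa: BLE001 - model dropped, loudly
                warnings.warn(
                    f"model {ms.label} failed on replicate {r}: {exc}; "
                    "dropped from the average for this replicate"
                )
                dropped.append((r, ms.label, str(exc)))
                continue
            if not fit.converged:
                warnings.warn(f"model {ms.label} flagged non-converged on replicate {r}")
            fits.append(fit)
        if not fits:
            warnings.warn(f"replicate {r}: every model failed; skipped")
            continue

        mrows, wrows = _evaluate(fits, learn, test, rep_truth, plan, r, rng, use_ma)
        metric_rows.extend(mrows)
        weight_frames.extend(wrows)

    metrics = pd.DataFrame(metric_rows)
    weights = (
        pd.concat(weight_frames, ignore_index=True)
        if weight_frames
        else pd.DataFrame(columns=["replicate", "s", "t", "model_label",
                                   "weight", "achieved_bs"])
    )
    return ExperimentReport(plan, metrics, weights, learning_ids, dropped)
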