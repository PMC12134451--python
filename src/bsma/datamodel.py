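"""Core data containers for longitudinal-marker / time-to-event studies.

A study couples one-row-per-subject survival information (observed time
``T* = min(T, C)``, event indicator ``delta``, optional baseline covariates)
with long-format repeated measurements of one or more longitudinal markers.
Each marker belongs to a distributional family, either ``"gaussian"``
(continuous, identity link) or ``"bernoulli"`` (binary, logit link).

All times share a single origin: study entry is t = 0 for every subject.
Measurements recorded after a subject's observed time are rejected at load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAMILIES = ("gaussian", "bernoulli")

LONG_COLUMNS = ["id", "time", "marker", "value"]
SURV_COLUMNS = ["id", "time_obs", "status"]


class StudyFormatError(ValueError):
    """A study file is missing required columns or cannot be parsed."""


class StudyValidationError(ValueError):
    """Parsed study rows violate an invariant (with offending subjects named)."""


@dataclass(frozen=True)
class MarkerCatalog:
    """Ordered mapping of marker name -> family."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise StudyValidationError("duplicate marker names in catalog")
        for name, family in self.entries:
            if family not in FAMILIES:
                raise StudyValidationError(
                    f"marker {name!r}: unknown family {family!r}"
                )

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "MarkerCatalog":
        return cls(tuple(mapping.items()))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def family(self, marker: str) -> str:
        for n, f in self.entries:
            if n == marker:
                return f
        raise KeyError(marker)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class StudyData:
    """A validated study: survival table + long-format marker measurements.

    Attributes
    ----------
    subjects : pandas.DataFrame
        One row per subject, indexed by subject id, with columns
        ``time_obs`` (float), ``status`` (0/1 int) and any baseline
        covariate columns after those two.
    long : pandas.DataFrame
        Long-format measurements with columns ``id, time, marker, value``,
        sorted by (id, marker, time).
    catalog : MarkerCatalog
    """

    subjects: pd.DataFrame
    long: pd.DataFrame
    catalog: MarkerCatalog
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_study(self)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.subjects.columns if c not in ("time_obs", "status")]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects.index.to_numpy()

    def subset(self, ids) -> "StudyData":
        """Restrict to the given subject ids (order preserved as given)."""
        ids = list(ids)
        missing = set(ids) - set(self.subjects.index)
        if missing:
            raise StudyValidationError(f"unknown subject ids: {sorted(missing)!r}")
        sub = self.subjects.loc[ids]
        lng = self.long[self.long["id"].isin(set(ids))].reset_index(drop=True)
        return StudyData(sub, lng, self.catalog, dict(self.metadata))

    def at_risk_ids(self, s: float) -> np.ndarray:
        """Subjects with observed time strictly greater than s."""
        mask = self.subjects["time_obs"].to_numpy() > s
        return self.subjects.index.to_numpy()[mask]


@dataclass
class SubjectHistory:
    """One subject's marker measurements and covariates truncated at a landmark.

    Contains exactly the measurements with time <= s (ties at s included).
    A history may be empty: the subject then contributes only baseline
    covariates and the random-effect prior to a prediction.
    """

    subject_id: object
    landmark: float
    long: pd.DataFrame
    covariates: pd.Series

    def __post_init__(self) -> None:
        if len(self.long) and (self.long["time"] > self.landmark + 1e-12).any():
            raise StudyValidationError(
                f"history for {self.subject_id!r} has times beyond s={self.landmark}"
            )

    def series(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        rows = self.long[self.long["marker"] == marker]
        return rows["time"].to_numpy(float), rows["value"].to_numpy(float)


def validate_study(study: StudyData) -> None:
    """Check all StudyData invariants, raising with offending subjects named."""
    subj = study.subjects
    if subj.index.has_duplicates:
        dups = subj.index[subj.index.duplicated()].unique().tolist()
        raise StudyValidationError(f"duplicate subject ids: {dups!r}")
    if (subj["time_obs"].to_numpy() < 0).any():
        bad = subj.index[subj["time_obs"] < 0].tolist()
        raise StudyValidationError(f"negative observed times for subjects {bad!r}")
    status = subj["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        bad = subj.index[~np.isin(status, (0, 1))].tolist()
        raise StudyValidationError(f"status not in {{0,1}} for subjects {bad!r}")

    lng = study.long
    if len(lng) == 0:
        return
    unknown_m = set(lng["marker"]) - set(study.catalog.names)
    if unknown_m:
        raise StudyValidationError(f"unknown markers in data: {sorted(unknown_m)!r}")
    unknown_s = set(lng["id"]) - set(subj.index)
    if unknown_s:
        raise StudyValidationError(
            f"measurements for subjects without survival rows: {sorted(unknown_s)!r}"
        )
    tmax = subj["time_obs"].reindex(lng["id"]).to_numpy()
    late = lng["time"].to_numpy() > tmax + 1e-12
    if late.any():
        bad = sorted(set(lng["id"].to_numpy()[late]))
        rows = list(np.flatnonzero(late)[:10])
        raise StudyValidationError(
            f"measurements after observed time for subjects {bad!r} (rows {rows})"
        )
    if (lng["time"].to_numpy() < 0).any():
        raise StudyValidationError("negative measurement times")
    for name, family in study.catalog:
        if family == "bernoulli":
            vals = lng.loc[lng["marker"] == name, "value"].to_numpy()
            if len(vals) and not np.isin(vals, (0.0, 1.0)).all():
                raise StudyValidationError(
                    f"bernoulli marker {name!r} has non-binary values"
                )


def read_study(
    longitudinal_path,
    survival_path,
    marker_catalog: MarkerCatalog | dict[str, str],
    sep: str = ",",
) -> StudyData:
    """Read a study from two delimited text files.

    The longitudinal file needs columns ``id, time, marker, value``; the
    survival file needs ``id, time_obs, status`` plus optional covariate
    columns. Rows with a missing marker value are dropped per-marker.
    """
    if isinstance(marker_catalog, dict):
        marker_catalog = MarkerCatalog.from_dict(marker_catalog)
    try:
        lng = pd.read_csv(longitudinal_path, sep=sep)
        surv = pd.read_csv(survival_path, sep=sep)
    except (OSError, pd.errors.ParserError) as exc:
        raise StudyFormatError(str(exc)) from exc
    missing = [c for c in LONG_COLUMNS if c not in lng.columns]
    if missing:
        raise StudyFormatError(f"longitudinal file missing columns {missing!r}")
    missing = [c for c in SURV_COLUMNS if c not in surv.columns]
    if missing:
        raise StudyFormatError(f"survival file missing columns {missing!r}")

    lng = lng[LONG_COLUMNS + [c for c in lng.columns if c not in LONG_COLUMNS]]
    lng = lng.dropna(subset=["value"]).reset_index(drop=True)
    lng = lng.sort_values(["id", "marker", "time"], kind="stable").reset_index(drop=True)
    surv = surv.set_index("id")
    surv["status"] = surv["status"].astype(int)
    return StudyData(surv, lng[LONG_COLUMNS], marker_catalog)


def write_study(study: StudyData, longitudinal_path, survival_path, sep: str = ",") -> None:
    """Write a study back to the two delimited files ``read_study`` accepts."""
    study.long.to_csv(longitudinal_path, sep=sep, index=False)
    study.subjects.reset_index(names="id").to_csv(survival_path, sep=sep, index=False)


def history_at(study: StudyData, subject_id, s: float) -> SubjectHistory:
    """Restrict one subject's measurements to times <= s (inclusive at s)."""
    if subject_id not in study.subjects.index:
        raise KeyError(f"unknown subject {subject_id!r}")
    if s < 0:
        raise ValueError("landmark s must be nonnegative")
    rows = study.long[
        (study.long["id"] == subject_id) & (study.long["time"] <= s + 1e-12)
    ].reset_index(drop=True)
    cov = study.subjects.loc[subject_id, study.covariate_names]
    return SubjectHistory(subject_id, s, rows, cov)
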