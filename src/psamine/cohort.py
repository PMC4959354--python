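"""Cohort domain types and tabular I/O.

A cohort is a list of :class:`PatientRecord`, each holding a time-ordered
PSA measurement series (months since therapy start, ng/ml), a fixed set of
14 baseline demographic/clinical covariates, a dichotomous progression
(event) indicator and the time to event or censoring.

Input is two delimited text files (comma default, tab accepted):

* measurements — long format with header ``patient_id,time_months,psa_ng_ml``
* covariates — one row per patient with the 14 features plus ``event`` and
  ``event_time``

Measurements recorded after a patient's event are excluded at read time so
every downstream stage sees the same truncated series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 14 baseline covariates, in canonical column order.
COVARIATE_FIELDS = (
    "age",
    "alb",
    "plt",
    "hb",
    "ca",
    "intermittent_treatment",
    "drug_order",
    "bone_metastasis",
    "clinical_stage",
    "gleason",
    "mri_prostate_volume",
    "pretreatment_psa",
    "nadir_psa",
    "time_to_nadir",
)

#: Covariates treated as categorical (imputed by mode, one-hot encoded).
CATEGORICAL_FIELDS = ("drug_order", "clinical_stage", "gleason")

#: Valid Gleason score categories.
GLEASON_CATEGORIES = (6, 7, 8, 9, 10)

NUMERIC_FIELDS = tuple(f for f in COVARIATE_FIELDS if f not in CATEGORICAL_FIELDS)


@dataclass(frozen=True)
class Measurement:
    """One PSA measurement: time in months since therapy start, value in ng/ml."""

    time: float
    value: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"measurement time must be >= 0, got {self.time}")
        if self.value < 0:
            raise ValueError(f"PSA value must be >= 0, got {self.value}")


@dataclass
class Covariates:
    """The 14 baseline demographic and clinical features.

    ``None`` marks a missing value prior to imputation. ``gleason`` must lie
    in :data:`GLEASON_CATEGORIES` when present.
    """

    age: Optional[float] = None
    alb: Optional[float] = None
    plt: Optional[float] = None
    hb: Optional[float] = None
    ca: Optional[float] = None
    intermittent_treatment: Optional[int] = None
    drug_order: Optional[str] = None
    bone_metastasis: Optional[int] = None
    clinical_stage: Optional[str] = None
    gleason: Optional[int] = None
    mri_prostate_volume: Optional[float] = None
    pretreatment_psa: Optional[float] = None
    nadir_psa: Optional[float] = None
    time_to_nadir: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gleason is not None and int(self.gleason) not in GLEASON_CATEGORIES:
            raise ValueError(
                f"gleason must be one of {GLEASON_CATEGORIES}, got {self.gleason}"
            )

    def asdict(self) -> dict:
        return {f: getattr(self, f) for f in COVARIATE_FIELDS}

    def missing_fields(self) -> list[str]:
        out = []
        for f in COVARIATE_FIELDS:
            v = getattr(self, f)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                out.append(f)
        return out


@dataclass
class PatientRecord:
    """One patient: measurement series, covariates, outcome.

    ``event`` is True if progression occurred; ``event_time`` is the time to
    progression if so, otherwise the censoring/follow-up time (months).
    Measurement times are strictly increasing and never exceed ``event_time``
    for patients with an event.
    """

    id: str
    measurements: list[Measurement] = field(default_factory=list)
    covariates: Covariates = field(default_factory=Covariates)
    event: bool = False
    event_time: float = 1.0

    def __post_init__(self) -> None:
        if self.event_time <= 0:
            raise ValueError(f"patient {self.id}: event_time must be > 0")
        times = [m.time for m in self.measurements]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"patient {self.id}: measurement times not strictly increasing")
        if self.event and any(t > self.event_time for t in times):
            raise ValueError(f"patient {self.id}: measurement after event_time")

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.measurements], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements], dtype=float)


def _read_table(path, expected_cols: Sequence[str]) -> pd.DataFrame:
    # sep=None + python engine sniffs comma vs tab
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _to_float(raw: str, path, row: int, col: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"{path} row {row}: non-numeric value {raw!r} in column {col!r}")


def read_cohort(measurements_path, covariates_path) -> list[PatientRecord]:
    """Read a cohort from the two-file delimited format.

    Parameters
    ----------
    measurements_path : path
        Long-format file with header ``patient_id,time_months,psa_ng_ml``.
    covariates_path : path
        One row per patient: ``patient_id``, the 14 covariates, ``event``,
        ``event_time``.

    Returns
    -------
    list of PatientRecord
        One record per covariate row; measurements joined by id and sorted
        ascending by time. Patients with no measurements are retained with an
        empty series (logged). Measurements after a patient's event are
        dropped (logged).

    Raises
    ------
    ValueError
        On duplicate ``(patient_id, time)`` pairs, measurement ids absent
        from the covariates file, or non-numeric values (with row number).
    """
    mdf = _read_table(measurements_path, ["patient_id", "time_months", "psa_ng_ml"])
    cdf = _read_table(
        covariates_path, ["patient_id", *COVARIATE_FIELDS, "event", "event_time"]
    )

    meas_by_id: dict[str, list[Measurement]] = {}
    seen: set[tuple[str, float]] = set()
    for i, row in enumerate(mdf.itertuples(index=False), start=2):
        pid = str(row.patient_id)
        t = _to_float(row.time_months, measurements_path, i, "time_months")
        v = _to_float(row.psa_ng_ml, measurements_path, i, "psa_ng_ml")
        key = (pid, t)
        if key in seen:
            raise ValueError(
                f"{measurements_path}: duplicate measurement for patient {pid!r} at time {t}"
            )
        seen.add(key)
        meas_by_id.setdefault(pid, []).append(Measurement(time=t, value=v))

    cov_ids = set(str(x) for x in cdf["patient_id"])
    orphans = sorted(set(meas_by_id) - cov_ids)
    if orphans:
        raise ValueError(
            f"measurement patient ids absent from covariates file: {orphans}"
        )

    records: list[PatientRecord] = []
    n_dropped_post_event = 0
    for i, row in enumerate(cdf.itertuples(index=False), start=2):
        pid = str(row.patient_id)
        kwargs = {}
        for f in COVARIATE_FIELDS:
            raw = getattr(row, f)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                kwargs[f] = None
            elif f in ("drug_order", "clinical_stage"):
                kwargs[f] = str(raw)
            elif f == "gleason":
                kwargs[f] = int(_to_float(raw, covariates_path, i, f))
            else:
                kwargs[f] = _to_float(raw, covariates_path, i, f)
        event = str(row.event).strip().lower() in ("1", "true", "yes")
        event_time = _to_float(row.event_time, covariates_path, i, "event_time")

        series = sorted(meas_by_id.get(pid, []), key=lambda m: m.time)
        if event:
            kept = [m for m in series if m.time <= event_time]
            n_dropped_post_event += len(series) - len(kept)
            series = kept
        if not series:
            logger.info("patient %s has no measurements; retained with empty series", pid)
        records.append(
            PatientRecord(
                id=pid,
                measurements=series,
                covariates=Covariates(**kwargs),
                event=event,
                event_time=event_time,
            )
        )
    if n_dropped_post_event:
        logger.info("dropped %d post-event measurements", n_dropped_post_event)
    return records


def write_cohort(records: list[PatientRecord], measurements_path, covariates_path) -> None:
    """Write a cohort in the exact two-file format :func:`read_cohort` consumes."""
    mrows = [
        {"patient_id": r.id, "time_months": m.time, "psa_ng_ml": m.value}
        for r in records
        for m in r.measurements
    ]
    pd.DataFrame(mrows, columns=["patient_id", "time_months", "psa_ng_ml"]).to_csv(
        measurements_path, index=False
    )
    crows = []
    for r in records:
        row = {"patient_id": r.id}
        row.update(r.covariates.asdict())
        row["event"] = int(r.event)
        row["event_time"] = r.event_time
        crows.append(row)
    pd.DataFrame(
        crows, columns=["patient_id", *COVARIATE_FIELDS, "event", "event_time"]
    ).to_csv(covariates_path, index=False)


def impute_missing(records: list[PatientRecord], strategy: str = "median_mode") -> list[PatientRecord]:
    """Fill (or drop) missing covariate values.

    ``median_mode`` fills numeric gaps with the cohort median and categorical
    gaps with the cohort mode; ``none`` drops patients with any missing
    covariate (count logged).
    """
    if strategy not in ("median_mode", "none"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")

    if strategy == "none":
        kept = [r for r in records if not r.covariates.missing_fields()]
        logger.info("imputation=none: dropped %d/%d patients", len(records) - len(kept), len(records))
        return kept

    df = pd.DataFrame([r.covariates.asdict() for r in records])
    fills: dict[str, object] = {}
    for f in COVARIATE_FIELDS:
        col = df[f].dropna()
        if col.empty:
            raise ValueError(f"covariate column {f!r} is entirely missing; cannot impute")
        if f in CATEGORICAL_FIELDS:
            fills[f] = col.mode().iloc[0]
        else:
            fills[f] = float(col.median())

    out = []
    for r in records:
        missing = r.covariates.missing_fields()
        if not missing:
            out.append(r)
            continue
        kwargs = r.covariates.asdict()
        for f in missing:
            kwargs[f] = int(fills[f]) if f == "gleason" else fills[f]
        out.append(replace(r, covariates=Covariates(**kwargs)))
    return out


def cohort_summary(records: list[PatientRecord]) -> dict:
    """Cohort-level summary (counts, follow-up mean/sd, event fraction)."""
    n = len(records)
    times = np.array([r.event_time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    ev_times = times[events]
    return {
        "n_patients": n,
        "n_events": int(events.sum()),
        "event_fraction": float(events.mean()) if n else float("nan"),
        "followup_mean": float(times.mean()) if n else float("nan"),
        "followup_sd": float(times.std(ddof=1)) if n > 1 else float("nan"),
        "time_to_event_mean": float(ev_times.mean()) if ev_times.size else float("nan"),
        "time_to_event_sd": float(ev_times.std(ddof=1)) if ev_times.size > 1 else float("nan"),
        "n_measurements": int(sum(len(r.measurements) for r in records)),
    }
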