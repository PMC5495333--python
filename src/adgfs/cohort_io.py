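"""Cohort tables: reading, validation and time-landmarked views.

The pipeline's single data currency is the :class:`CohortTable`: one row per
transplanted patient (baseline covariates measured by month 12, event times for
de novo DSA / first acute rejection, and the right-censored graft outcome)
plus a long table of monthly serum-creatinine measurements over the first
post-transplant year.

Conventions
-----------
* Time origin is the transplantation date; event and follow-up times are in
  decimal years, creatinine visits in integer months 0..12.
* Graft failure means return to dialysis.  Death with a functioning graft is
  censoring: the table carries only the resulting ``(followup_time,
  graft_failure)`` pair.
* Missing event times (no dnDSA, no rejection) are empty CSV cells / NaN.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "LongitudinalSeries",
    "CohortTable",
    "CohortSchemaError",
    "CohortIntegrityError",
    "read_cohort",
    "write_cohort",
    "landmark_view",
    "PATIENT_COLUMNS",
    "SERIES_COLUMNS",
]

#: Mandatory columns of patients.csv, in canonical order.  Extra columns
#: (e.g. candidate predictors such as cold-ischemia time) are preserved.
PATIENT_COLUMNS = [
    "patient_id",
    "donor_age",
    "ndsa_pre",
    "scr_m12",
    "prot_m12",
    "dndsa_time",
    "rejection_time",
    "followup_time",
    "graft_failure",
]

#: Mandatory columns of scr_long.csv.
SERIES_COLUMNS = ["patient_id", "month", "scr"]


class CohortSchemaError(ValueError):
    """A mandatory column is missing or cannot be parsed."""


class CohortIntegrityError(ValueError):
    """A row violates a cohort invariant (duplicate id, bad event time...)."""


@dataclass(frozen=True)
class LongitudinalSeries:
    """Monthly serum-creatinine series (µmol/L) over the first year."""

    months: np.ndarray  # int, strictly increasing, within 0..12
    values: np.ndarray  # float > 0, aligned with months

    def __post_init__(self) -> None:
        m = np.asarray(self.months, dtype=int)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "months", m)
        object.__setattr__(self, "values", v)
        if m.shape != v.shape:
            raise ValueError("months and values must be aligned")
        if len(m) < 3:
            raise ValueError("a creatinine series needs at least 3 visits")
        if np.any(np.diff(m) <= 0):
            raise ValueError("visit months must be strictly increasing")
        if m.min() < 0 or m.max() > 12:
            raise ValueError("visit months must lie in 0..12")
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("creatinine values must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """Baseline covariates and outcome of a single transplant."""

    patient_id: str
    donor_age: float
    ndsa_pre: bool
    scr_m12: float
    prot_m12: float
    followup_time: float
    graft_failure: bool
    dndsa_time: Optional[float] = None
    rejection_time: Optional[float] = None
    scr_cluster: Optional[str] = None  # {A,B,C}, set after clustering
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.followup_time > 0):
            raise ValueError(f"{self.patient_id}: followup_time must be > 0")
        if not (self.donor_age >= 0):
            raise ValueError(f"{self.patient_id}: donor_age must be >= 0")
        if not (self.scr_m12 > 0):
            raise ValueError(f"{self.patient_id}: scr_m12 must be > 0")
        if not (self.prot_m12 >= 0):
            raise ValueError(f"{self.patient_id}: prot_m12 must be >= 0")
        for name in ("dndsa_time", "rejection_time"):
            t = getattr(self, name)
            if t is None:
                continue
            if not (t > 0):
                raise ValueError(f"{self.patient_id}: {name} must be > 0")
            if t > self.followup_time + 1e-12:
                raise ValueError(
                    f"{self.patient_id}: {name}={t} exceeds "
                    f"followup_time={self.followup_time}"
                )


class CohortTable:
    """Validated cohort: a patients frame plus per-patient creatinine series.

    Parameters
    ----------
    patients
        One row per patient with at least :data:`PATIENT_COLUMNS`.
    series
        Long-format creatinine table with :data:`SERIES_COLUMNS`; every
        ``patient_id`` must appear in ``patients``.
    latent
        Optional simulation-only ground truth (latent cluster, hazard
        stratum); never read by the estimation code.
    """

    def __init__(
        self,
        patients: pd.DataFrame,
        series: pd.DataFrame,
        latent: Optional[pd.DataFrame] = None,
    ) -> None:
        self.patients = patients.reset_index(drop=True)
        self.series = series.reset_index(drop=True)
        self.latent = latent
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        missing = [c for c in PATIENT_COLUMNS if c not in self.patients.columns]
        if missing:
            raise CohortSchemaError(f"patients table missing columns {missing}")
        missing = [c for c in SERIES_COLUMNS if c not in self.series.columns]
        if missing:
            raise CohortSchemaError(f"series table missing columns {missing}")

        ids = self.patients["patient_id"].astype(str)
        dup = ids[ids.duplicated()].tolist()
        if dup:
            raise CohortIntegrityError(f"duplicate patient_id: {sorted(set(dup))}")

        known = set(ids)
        stray = set(self.series["patient_id"].astype(str)) - known
        if stray:
            raise CohortIntegrityError(
                f"series for unknown patient_id: {sorted(stray)[:5]}"
            )

        problems = []
        for i, row in self.patients.iterrows():
            try:
                _record_from_row(row)
            except ValueError as exc:
                problems.append(f"row {i}: {exc}")
        if problems:
            raise CohortIntegrityError("; ".join(problems))

    # -- access --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return self.patients["patient_id"].astype(str).tolist()

    def record(self, patient_id: str) -> PatientRecord:
        sel = self.patients[self.patients["patient_id"].astype(str) == str(patient_id)]
        if sel.empty:
            raise KeyError(patient_id)
        return _record_from_row(sel.iloc[0])

    def records(self) -> Iterator[PatientRecord]:
        for _, row in self.patients.iterrows():
            yield _record_from_row(row)

    def scr_series(self, patient_id: str) -> LongitudinalSeries:
        sel = self.series[self.series["patient_id"].astype(str) == str(patient_id)]
        if sel.empty:
            raise KeyError(patient_id)
        sel = sel.sort_values("month")
        return LongitudinalSeries(
            months=sel["month"].to_numpy(dtype=int),
            values=sel["scr"].to_numpy(dtype=float),
        )

    def with_clusters(self, labels: dict[str, str]) -> "CohortTable":
        """Return a copy with the ``scr_cluster`` column filled from a mapping."""
        patients = self.patients.copy()
        patients["scr_cluster"] = [
            labels.get(str(pid)) for pid in patients["patient_id"].astype(str)
        ]
        return CohortTable(patients, self.series, latent=self.latent)


def _opt_float(x) -> Optional[float]:
    if x is None:
        return None
    if isinstance(x, str):
        x = x.strip()
        if x == "":
            return None
        x = float(x)
    x = float(x)
    return None if np.isnan(x) else x


def _record_from_row(row: pd.Series) -> PatientRecord:
    extras = {
        k: row[k]
        for k in row.index
        if k not in PATIENT_COLUMNS and k != "scr_cluster"
    }
    cluster = row.get("scr_cluster")
    if cluster is not None and (pd.isna(cluster) or cluster == ""):
        cluster = None
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        donor_age=float(row["donor_age"]),
        ndsa_pre=bool(int(row["ndsa_pre"])),
        scr_m12=float(row["scr_m12"]),
        prot_m12=float(row["prot_m12"]),
        followup_time=float(row["followup_time"]),
        graft_failure=bool(int(row["graft_failure"])),
        dndsa_time=_opt_float(row.get("dndsa_time")),
        rejection_time=_opt_float(row.get("rejection_time")),
        scr_cluster=cluster,
        extras=extras,
    )


# -- I/O ----------------------------------------------------------------------


def read_cohort(patients_path, series_path) -> CohortTable:
    """Read and validate a cohort from the two CSV files.

    CSV dialect: UTF-8, '.' decimal separator, mandatory header row, missing
    values as empty strings.  Any invariant violation raises with a message
    naming the offending row; nothing is imputed.
    """
    patients_path, series_path = Path(patients_path), Path(series_path)
    for p in (patients_path, series_path):
        if not p.exists():
            raise FileNotFoundError(p)
    patients = pd.read_csv(patients_path, dtype={"patient_id": str})
    series = pd.read_csv(series_path, dtype={"patient_id": str})
    return CohortTable(patients, series)


def write_cohort(cohort: CohortTable, patients_path, series_path) -> None:
    """Write the two CSVs; inverse of :func:`read_cohort` (floats to 1e-9)."""
    pat = cohort.patients.copy()
    # stable column order: canonical first, extras after
    extras = [c for c in pat.columns if c not in PATIENT_COLUMNS]
    pat = pat[PATIENT_COLUMNS + extras]
    pat.to_csv(patients_path, index=False, float_format="%.10g")
    cohort.series[SERIES_COLUMNS].to_csv(
        series_path, index=False, float_format="%.10g"
    )


def cohort_to_csv_strings(cohort: CohortTable) -> tuple[str, str]:
    """Serialize both tables to CSV text (used for determinism checks)."""
    b1, b2 = io.StringIO(), io.StringIO()
    pat = cohort.patients.copy()
    extras = [c for c in pat.columns if c not in PATIENT_COLUMNS]
    pat[PATIENT_COLUMNS + extras].to_csv(b1, index=False, float_format="%.10g")
    cohort.series[SERIES_COLUMNS].to_csv(b2, index=False, float_format="%.10g")
    return b1.getvalue(), b2.getvalue()


# -- landmarking --------------------------------------------------------------


def landmark_view(cohort: CohortTable, t: float) -> CohortTable:
    """Cohort "as known at time ``t``" (years post-transplant).

    Events with onset strictly after ``t`` are masked (treated as absent);
    an onset exactly at ``t`` counts as known.  Outcome fields are untouched.
    The score is undefined before one year post-transplant, hence ``t >= 1``.
    """
    if t < 1:
        raise ValueError("landmark time must be >= 1 year (score undefined earlier)")
    patients = cohort.patients.copy()
    for col in ("dndsa_time", "rejection_time"):
        v = pd.to_numeric(patients[col], errors="coerce")
        patients[col] = v.where(v <= t, other=np.nan)
    return CohortTable(patients, cohort.series, latent=cohort.latent)


def landmark_record(record: PatientRecord, t: float) -> PatientRecord:
    """Single-record analogue of :func:`landmark_view`."""
    if t < 1:
        raise ValueError("landmark time must be >= 1 year (score undefined earlier)")
    kw = {}
    for name in ("dndsa_time", "rejection_time"):
        v = getattr(record, name)
        if v is not None and v > t:
            kw[name] = None
    return replace(record, **kw) if kw else record
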