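"""Longitudinal patient series, cohort CSV round-tripping, segment extraction.

On-disk format: an observations CSV with header
``patient_id,day,psa,androgen,on_treatment`` (psa in ug/L, androgen in
nmol/L, empty cells = missing) plus a labels CSV ``patient_id,outcome``
with outcome ``failure`` or ``success`` (unlabeled patients omitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

OUTCOMES = ("failure", "success", "unlabeled")


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Observation:
    day: float
    psa: Optional[float]        # ug/L, None if not measured
    androgen: Optional[float]   # nmol/L, None if not measured
    on_treatment: bool


@dataclass
class PatientSeries:
    """One patient's irregular PSA/androgen record with outcome label.

    Treatment failure means discontinuation due to resistance or death from
    prostate cancer; every other outcome counts as a success.
    """

    patient_id: str
    observations: list[Observation]
    outcome: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise CohortValidationError(
                f"patient {self.patient_id}: unknown outcome {self.outcome!r}"
            )
        days = [o.day for o in self.observations]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: days must be strictly increasing"
            )
        if not any(o.psa is not None for o in self.observations):
            raise CohortValidationError(
                f"patient {self.patient_id}: needs at least one PSA observation"
            )

    @property
    def days(self) -> np.ndarray:
        return np.array([o.day for o in self.observations])

    def channel(self, name: str) -> np.ndarray:
        """Values of 'psa' or 'androgen' with NaN for missing entries."""
        return np.array(
            [getattr(o, name) if getattr(o, name) is not None else np.nan
             for o in self.observations]
        )

    @property
    def max_androgen(self) -> Optional[float]:
        a = self.channel("androgen")
        return None if np.all(np.isnan(a)) else float(np.nanmax(a))


@dataclass
class Segment:
    """A maximal run of observations with constant treatment state."""

    index: int
    on_treatment: bool
    observations: list[Observation]

    @property
    def start_day(self) -> float:
        return self.observations[0].day

    @property
    def end_day(self) -> float:
        return self.observations[-1].day

    @property
    def days(self) -> np.ndarray:
        return np.array([o.day for o in self.observations])

    def channel(self, name: str) -> np.ndarray:
        return np.array(
            [getattr(o, name) if getattr(o, name) is not None else np.nan
             for o in self.observations]
        )


@dataclass
class Cohort:
    patients: list[PatientSeries]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __getitem__(self, patient_id: str) -> PatientSeries:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def labels(self) -> dict[str, str]:
        return {p.patient_id: p.outcome for p in self.patients}


def extract_segments(series: PatientSeries) -> list[Segment]:
    """Split a series into maximal constant-treatment runs, in order.

    Concatenating the segments' observations recovers the series exactly.
    """
    segments: list[Segment] = []
    for obs in series.observations:
        if segments and segments[-1].on_treatment == obs.on_treatment:
            segments[-1].observations.append(obs)
        else:
            segments.append(Segment(len(segments), obs.on_treatment, [obs]))
    return segments


def _fmt(value: Optional[float]) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return repr(float(value))


def write_cohort(cohort: Cohort, path) -> Path:
    """Write observations CSV to ``path`` and labels CSV alongside it.

    ``path`` may be a directory (files ``cohort.csv``/``labels.csv``) or the
    observations CSV path (labels file derived by replacing the suffix).
    Numbers are written with ``repr`` so the round trip is bit-stable.
    """
    path = Path(path)
    if path.suffix == ".csv":
        obs_path = path
        labels_path = path.with_name(path.stem + "_labels.csv")
    else:
        path.mkdir(parents=True, exist_ok=True)
        obs_path = path / "cohort.csv"
        labels_path = path / "labels.csv"

    with open(obs_path, "w") as fh:
        fh.write("patient_id,day,psa,androgen,on_treatment\n")
        for p in cohort.patients:
            for o in p.observations:
                fh.write(
                    f"{p.patient_id},{_fmt(o.day)},{_fmt(o.psa)},"
                    f"{_fmt(o.androgen)},{int(o.on_treatment)}\n"
                )
    with open(labels_path, "w") as fh:
        fh.write("patient_id,outcome\n")
        for p in cohort.patients:
            if p.outcome != "unlabeled":
                fh.write(f"{p.patient_id},{p.outcome}\n")
    return obs_path


def read_cohort(path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Validates strictly: non-monotone days, duplicate (patient, day) rows and
    unknown outcome tokens raise :class:`CohortValidationError` naming the
    offending patient.  Empty numeric cells become missing values, never 0.
    """
    path = Path(path)
    if path.suffix == ".csv":
        obs_path = path
        labels_path = path.with_name(path.stem + "_labels.csv")
        if not labels_path.exists() and (path.parent / "labels.csv").exists():
            labels_path = path.parent / "labels.csv"
    else:
        obs_path = path / "cohort.csv"
        labels_path = path / "labels.csv"

    df = pd.read_csv(obs_path, dtype={"patient_id": str},
                     float_precision="round_trip")
    expected = ["patient_id", "day", "psa", "androgen", "on_treatment"]
    if list(df.columns) != expected:
        raise CohortValidationError(f"expected columns {expected}, got {list(df.columns)}")

    labels: dict[str, str] = {}
    if labels_path.exists():
        ldf = pd.read_csv(labels_path, dtype=str)
        for _, row in ldf.iterrows():
            token = str(row["outcome"]).strip().lower()
            if token not in ("failure", "success"):
                raise CohortValidationError(
                    f"patient {row['patient_id']}: unknown outcome {row['outcome']!r}"
                )
            labels[str(row["patient_id"])] = token

    patients: list[PatientSeries] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        days = grp["day"].to_numpy(dtype=float)
        if np.any(np.diff(days) < 0):
            raise CohortValidationError(f"patient {pid}: days not increasing")
        if np.any(np.diff(days) == 0):
            raise CohortValidationError(f"patient {pid}: duplicate day entries")
        obs = [
            Observation(
                day=float(row.day),
                psa=None if pd.isna(row.psa) else float(row.psa),
                androgen=None if pd.isna(row.androgen) else float(row.androgen),
                on_treatment=bool(int(row.on_treatment)),
            )
            for row in grp.itertuples()
        ]
        patients.append(PatientSeries(str(pid), obs, labels.get(str(pid), "unlabeled")))
    return Cohort(patients, provenance={"source": str(obs_path)})


def series_from_arrays(
    patient_id: str,
    days: Iterable[float],
    psa: Iterable[Optional[float]],
    androgen: Iterable[Optional[float]],
    on_treatment: Iterable[bool],
    outcome: str = "unlabeled",
) -> PatientSeries:
    """Convenience constructor from parallel arrays (NaN = missing)."""
    obs = []
    for t, p, a, on in zip(days, psa, androgen, on_treatment):
        p = None if p is None or (isinstance(p, float) and math.isnan(p)) else float(p)
        a = None if a is None or (isinstance(a, float) and math.isnan(a)) else float(a)
        obs.append(Observation(float(t), p, a, bool(on)))
    return PatientSeries(patient_id, obs, outcome)
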