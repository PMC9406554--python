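"""Treatment-failure indicators for intermittent androgen suppression.

Two per-patient scalars:

* **q2 ratio** — initial over final (most recent) estimate of the resistant
  clone's minimum cell quota from the segment-wise calibration.  Resistance
  evolution drives q2 down, so the ratio climbs above 1 as the tumor adapts;
  values above a threshold flag impending failure.
* **androgen/PSA ratio** — mean serum androgen divided by mean serum PSA
  over a treatment window, computed from raw data alone.  Resistant clones
  keep secreting PSA at castrate androgen, so the ratio collapses as
  resistance emerges; values below a threshold flag impending failure.
  Windows: ``early`` = the first 200 days of the record; ``final`` = the
  patient's final on-treatment segment truncated to its first 200 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .calibration import CalibrationResults
from .cohort import PatientSeries, extract_segments

AP_WINDOW_DAYS = 200.0
AP_PLOT_CAP = 5.0  # scatter display convention: ratios above 5 drawn at 5


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class BiomarkerValue:
    patient_id: str
    kind: str                    # q2_ratio | ap_ratio_final | ap_ratio_early
    value: float
    window: Optional[tuple[float, float]] = None   # days, ap_ratio kinds
    provenance: str = ""

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("biomarker values are non-negative")


def q2_ratio(trace: CalibrationResults | np.ndarray) -> float:
    """q2(first segment) / q2(last segment).

    Accepts a :class:`CalibrationResults` or a raw q2 sequence.  Needs at
    least two segment estimates; the calibration bounds keep q2 > 0.
    """
    seq = np.asarray(trace.q2_sequence if isinstance(trace, CalibrationResults) else trace,
                     dtype=float)
    if seq.size < 2:
        raise InsufficientDataError("q2 ratio needs at least two segment fits")
    return float(seq[0] / seq[-1])


def q2_trend(trace: CalibrationResults | np.ndarray) -> tuple[np.ndarray, float]:
    """Running ratios r_k = q2(first)/q2(k), k = 2..K, and the fraction of
    strictly increasing steps — the within-patient resistance trend."""
    seq = np.asarray(trace.q2_sequence if isinstance(trace, CalibrationResults) else trace,
                     dtype=float)
    if seq.size < 2:
        raise InsufficientDataError("q2 trend needs at least two segment fits")
    ratios = seq[0] / seq[1:]
    if ratios.size > 1:
        frac = float(np.mean(np.diff(ratios) > 0))
    else:
        frac = float(ratios[0] > 1.0)
    return ratios, frac


def androgen_psa_ratio(
    series: PatientSeries,
    mode: str = "final",
    window_days: float = AP_WINDOW_DAYS,
) -> BiomarkerValue:
    """Mean androgen / mean PSA over the early or final treatment window."""
    if mode not in ("final", "early"):
        raise ValueError(f"mode must be 'early' or 'final', got {mode!r}")
    days = series.days
    if mode == "early":
        t0 = days[0]
        t1 = t0 + window_days
    else:
        on_segments = [s for s in extract_segments(series) if s.on_treatment]
        if not on_segments:
            raise InsufficientDataError(
                f"patient {series.patient_id}: no on-treatment segment"
            )
        last = on_segments[-1]
        t0 = last.start_day
        t1 = min(last.end_day, t0 + window_days)

    mask = (days >= t0) & (days <= t1)
    psa = series.channel("psa")[mask]
    andr = series.channel("androgen")[mask]
    psa = psa[~np.isnan(psa)]
    andr = andr[~np.isnan(andr)]
    if psa.size == 0 or andr.size == 0:
        raise InsufficientDataError(
            f"patient {series.patient_id}: window [{t0}, {t1}] lacks "
            f"{'PSA' if psa.size == 0 else 'androgen'} observations"
        )
    mean_psa = float(psa.mean())
    if mean_psa == 0:
        raise InsufficientDataError(
            f"patient {series.patient_id}: mean PSA is zero in the window"
        )
    return BiomarkerValue(
        patient_id=series.patient_id,
        kind=f"ap_ratio_{mode}",
        value=float(andr.mean()) / mean_psa,
        window=(float(t0), float(t1)),
        provenance=f"{andr.size} androgen / {psa.size} PSA observations",
    )


def biomarker_table(values: list[BiomarkerValue]):
    """Tidy frame ``patient_id,kind,value,window_start,window_end``."""
    import pandas as pd

    rows = [
        {
            "patient_id": v.patient_id,
            "kind": v.kind,
            "value": v.value,
            "window_start": v.window[0] if v.window else np.nan,
            "window_end": v.window[1] if v.window else np.nan,
        }
        for v in values
    ]
    return pd.DataFrame(rows, columns=["patient_id", "kind", "value",
                                       "window_start", "window_end"])
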