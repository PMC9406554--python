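"""Shared fixtures: a default virtual cohort and its calibrated fits.

The cohort fixture is session-scoped because segment-wise calibration of 71
patients is the expensive step shared by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import iasmark as im

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """The default 71-patient virtual cohort (51 failures / 20 successes)."""
    cohort, truths = im.generate_cohort(71, seed=DEFAULT_SEED, return_truth=True)
    return cohort, truths


@pytest.fixture(scope="session")
def cohort_fits(default_cohort):
    """Segment-wise calibration results for every cohort patient."""
    cohort, _ = default_cohort
    cfg = im.FitConfig(seed=0)
    return {p.patient_id: im.fit_patient(p, cfg) for p in cohort}


@pytest.fixture(scope="session")
def cohort_biomarkers(default_cohort, cohort_fits):
    """Arrays (labels, q2 ratios, early/final androgen-PSA ratios)."""
    cohort, _ = default_cohort
    labels, q2r, ap_early, ap_final = [], [], [], []
    for p in cohort:
        labels.append(p.outcome == "failure")
        q2r.append(im.q2_ratio(cohort_fits[p.patient_id]))
        ap_early.append(im.androgen_psa_ratio(p, "early").value)
        ap_final.append(im.androgen_psa_ratio(p, "final").value)
    return {
        "labels": np.array(labels),
        "q2_ratio": np.array(q2r),
        "ap_early": np.array(ap_early),
        "ap_final": np.array(ap_final),
    }
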