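"""Virtual IAS patient generator with known resistance ground truth.

Each virtual patient is a draw of model parameters, simulated forward under
a PSA-triggered intermittent-suppression protocol: treatment stops once PSA
has stayed below a remission threshold (after a minimum on-duration) and
resumes when PSA regrows past a relapse threshold.  Two archetypes:

* **responder** — the resistant clone's minimum quota q2 is constant; PSA
  keeps cycling with treatment and androgen/PSA dynamics stay concordant;
* **resistant** — q2 declines geometrically (factor ``rho``) at every
  on->off boundary, emulating the selection of progressively
  androgen-independent clones; in late cycles PSA no longer falls at
  castrate androgen, the protocol's on-phase times out, and the record ends
  on treatment (trial exit = treatment failure).

Observations are the noise-free trajectory at irregular visit days under
multiplicative lognormal noise, with androgen left-censored at a detection
floor.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._core import integrate_piecewise
from .cohort import Cohort, Observation, PatientSeries
from .model import ModelParameters, TreatmentSchedule

#: Default parameter-draw ranges (uniform), inside the calibration bounds,
#: chosen to yield multi-cycle IAS dynamics with serum-like scales
#: (off-treatment androgen ~6-12 nmol/L, relapse PSA > 10 ug/L).
DEFAULT_DRAW_RANGES: dict[str, tuple[float, float]] = {
    "mu": (0.015, 0.04),
    "q1": (0.5, 0.8),
    "q2": (0.30, 0.41),      # initial resistance level, both archetypes
    "d": (0.01, 0.04),
    "gamma1": (0.3, 0.8),
    "delta": (0.03, 0.06),
    "b": (0.001, 0.01),
    "sigma1": (0.3, 0.9),
    "sigma2": (0.3, 0.9),
    "eps": (0.015, 0.04),
    "A0": (12.0, 30.0),
    "x1_init": (0.2, 0.8),
}

Q2_FLOOR = 0.01  # lower calibration bound for q2


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolConfig:
    """PSA-triggered on/off switching rules of the virtual trial."""

    psa_off_threshold: float = 4.0    # stop ADT once PSA sustained below this
    psa_on_threshold: float = 10.0    # resume ADT when PSA regrows past this
    min_on_days: float = 240.0
    min_off_days: float = 75.0        # off-phase reviewed no sooner than this
    sustained_days: float = 14.0      # remission must hold this long
    max_on_days: float = 540.0        # on-phase timeout => resistance exit
    horizon: float = 2000.0

    def __post_init__(self) -> None:
        if self.psa_on_threshold <= self.psa_off_threshold:
            raise ProtocolError(
                "relapse (off->on) threshold must exceed the remission "
                "(on->off) threshold"
            )
        if self.horizon < self.min_on_days:
            raise ProtocolError("horizon shorter than one on-treatment period")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Distribution of one virtual-patient archetype."""

    label: str                                   # "responder" | "resistant"
    draw_ranges: dict = field(default_factory=lambda: dict(DEFAULT_DRAW_RANGES))
    rho_range: tuple[float, float] = (1.0, 1.0)  # per-cycle q2 decline factor
    psa_noise_cv: float = 0.10
    androgen_noise_cv: float = 0.15
    visit_interval_days: float = 28.0
    visit_jitter_days: float = 7.0
    androgen_floor: float = 0.7                  # nmol/L detection limit
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def __post_init__(self) -> None:
        lo, hi = self.rho_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("rho range must lie in (0, 1]")


def responder_archetype(**overrides) -> ArchetypeSpec:
    return ArchetypeSpec(label="responder", rho_range=(1.0, 1.0), **overrides)


def resistant_archetype(**overrides) -> ArchetypeSpec:
    return ArchetypeSpec(label="resistant", rho_range=(0.5, 0.7), **overrides)


@dataclass
class SyntheticPatient:
    """A generated series plus its hidden ground truth."""

    series: PatientSeries
    params: ModelParameters          # initial-cycle parameter draw
    rho: float
    q2_per_cycle: list[float]        # hidden q2 value during each on/off cycle
    schedule: TreatmentSchedule
    trajectory_days: np.ndarray      # daily noise-free reference
    trajectory_states: np.ndarray

    @property
    def true_q2_ratio(self) -> float:
        return self.q2_per_cycle[0] / self.q2_per_cycle[-1]

    def truth_dict(self) -> dict:
        return {
            "patient_id": self.series.patient_id,
            "label": self.series.outcome,
            "params": self.params.to_dict(),
            "rho": self.rho,
            "q2_per_cycle": [float(q) for q in self.q2_per_cycle],
            "true_q2_ratio": float(self.true_q2_ratio),
            "schedule": [list(iv) for iv in self.schedule.intervals],
        }


def _adaptive_run(
    params: ModelParameters,
    init: np.ndarray,
    protocol: ProtocolConfig,
    rho: float,
    dt: float = 0.5,
):
    """Daily forward simulation with PSA-triggered switching and discrete q2
    evolution at each on->off boundary.

    Returns (intervals, q2_per_cycle, days, states, exited_on_treatment).
    """
    days = np.arange(0.0, protocol.horizon + 1.0)
    states = np.empty((days.size, 5))
    states[0] = init

    p = params
    y = np.asarray(init, dtype=float)
    on = True
    seg_start = 0.0
    below_since: Optional[float] = None
    intervals: list[tuple[float, float, bool]] = []
    q2_per_cycle = [p.q2]
    exited_on = False
    end_day = protocol.horizon

    for i in range(1, days.size):
        t_prev, t = days[i - 1], days[i]
        u = 0.0 if on else 1.0
        y = integrate_piecewise(
            y, t_prev, np.array([t]), np.array([t_prev]), np.array([u]),
            p.to_array(), dt,
        )[0]
        states[i] = y
        psa = y[4]

        if on:
            if psa < protocol.psa_off_threshold:
                if below_since is None:
                    below_since = t
            else:
                below_since = None
            long_enough = (t - seg_start) >= protocol.min_on_days
            sustained = (below_since is not None
                         and (t - below_since) >= protocol.sustained_days)
            if long_enough and sustained:
                intervals.append((seg_start, t, True))
                # selection during the treatment phase: resistance deepens
                p = p.replace(q2=max(p.q2 * rho, Q2_FLOOR))
                q2_per_cycle.append(p.q2)
                on, seg_start, below_since = False, t, None
            elif (t - seg_start) >= protocol.max_on_days:
                # PSA never reached remission: resistance-driven trial exit
                exited_on, end_day = True, t
                break
        else:
            if (psa > protocol.psa_on_threshold
                    and (t - seg_start) >= protocol.min_off_days):
                intervals.append((seg_start, t, False))
                on, seg_start = True, t

    intervals.append((seg_start, end_day, on))
    keep = days <= end_day
    return intervals, q2_per_cycle, days[keep], states[keep], exited_on


def schedule_from_psa(
    params: ModelParameters,
    init,
    protocol: Optional[ProtocolConfig] = None,
    q2_decline: float = 1.0,
) -> TreatmentSchedule:
    """Treatment schedule induced by the PSA-triggered protocol.

    Simulates forward from ``init`` (on treatment at day 0) and switches
    when the protocol rules fire; ``q2_decline`` optionally applies the
    resistant archetype's per-cycle q2 decay.  The schedule ends at the
    horizon, or on treatment if PSA fails to reach the remission threshold
    within the on-phase timeout.
    """
    protocol = protocol or ProtocolConfig()
    intervals, _, _, _, _ = _adaptive_run(
        params, np.asarray(init, dtype=float), protocol, q2_decline
    )
    return TreatmentSchedule.from_intervals(intervals)


def _draw_params(spec: ArchetypeSpec, rng: np.random.Generator) -> tuple[ModelParameters, float]:
    r = {k: rng.uniform(lo, hi) for k, (lo, hi) in spec.draw_ranges.items()}
    x1 = r.pop("x1_init")
    params = ModelParameters(**r)
    return params, x1


def _pretreatment_state(params: ModelParameters, x1: float) -> np.ndarray:
    """Quasi-steady ADT-naive state: androgen at its off-treatment
    equilibrium, PSA balancing production and clearance."""
    a_star = (params.gamma1 + params.gamma2) / (params.gamma1 / params.A0 + params.delta)
    q = a_star
    x2 = 0.01 * x1
    g1 = max(1.0 - params.q1 / q, 0.0)
    g2 = max(1.0 - params.q2 / q, 0.0)
    psa = (params.b * q + params.sigma1 * g1 * x1 + params.sigma2 * g2 * x2) / params.eps
    return np.array([x1, x2, q, a_star, psa])


def generate_patient(
    archetype: ArchetypeSpec,
    seed,
    patient_id: str = "P001",
    max_redraws: int = 5,
) -> SyntheticPatient:
    """Draw, simulate and observe one virtual patient.

    Redraws the parameters (up to ``max_redraws`` times) if the simulated
    record is degenerate — fewer than two on-treatment phases started, or a
    responder that never completes two cycles.
    """
    rng = np.random.default_rng(seed)
    last_err = None
    for _ in range(max_redraws + 1):
        try:
            params, x1 = _draw_params(archetype, rng)
            rho = float(rng.uniform(*archetype.rho_range))
            init = _pretreatment_state(params, x1)
            intervals, q2_cycles, days, states, exited_on = _adaptive_run(
                params, init, archetype.protocol, rho
            )
            n_on = sum(1 for iv in intervals if iv[2])
            if n_on < 2:
                raise RuntimeError("fewer than two on-treatment phases")
            if archetype.label == "responder" and len(intervals) < 4:
                raise RuntimeError("responder completed fewer than two cycles")
            schedule = TreatmentSchedule.from_intervals(intervals)
            series = _observe(archetype, schedule, days, states, rng, patient_id)
            return SyntheticPatient(
                series=series,
                params=params,
                rho=rho,
                q2_per_cycle=q2_cycles[:n_on],
                schedule=schedule,
                trajectory_days=days,
                trajectory_states=states,
            )
        except (RuntimeError, ValueError) as err:  # redraw on degenerate runs
            last_err = err
    raise RuntimeError(
        f"patient {patient_id}: no usable draw after {max_redraws + 1} attempts "
        f"({last_err})"
    )


def _observe(
    spec: ArchetypeSpec,
    schedule: TreatmentSchedule,
    days: np.ndarray,
    states: np.ndarray,
    rng: np.random.Generator,
    patient_id: str,
) -> PatientSeries:
    horizon = days[-1]
    visit_days = [0.0]
    while True:
        step = rng.normal(spec.visit_interval_days, spec.visit_jitter_days)
        nxt = visit_days[-1] + max(7.0, step)
        if nxt > horizon:
            break
        visit_days.append(round(nxt))

    sig_p = np.sqrt(np.log1p(spec.psa_noise_cv ** 2))
    sig_a = np.sqrt(np.log1p(spec.androgen_noise_cv ** 2))
    obs = []
    for day in visit_days:
        idx = int(day)
        psa_true, a_true = states[idx, 4], states[idx, 3]
        psa = psa_true * np.exp(rng.normal(-0.5 * sig_p ** 2, sig_p))
        andr = a_true * np.exp(rng.normal(-0.5 * sig_a ** 2, sig_a))
        andr = max(andr, spec.androgen_floor)  # left-censored at detection
        obs.append(Observation(
            day=float(day),
            psa=float(max(psa, 0.01)),
            androgen=float(andr),
            on_treatment=schedule.on_treatment(min(day, horizon)),
        ))
    outcome = "failure" if spec.label == "resistant" else "success"
    return PatientSeries(patient_id, obs, outcome)


def generate_cohort(
    n: int,
    failure_fraction: float = 51.0 / 71.0,
    seed: int = 0,
    resistant: Optional[ArchetypeSpec] = None,
    responder: Optional[ArchetypeSpec] = None,
    return_truth: bool = False,
):
    """Cohort of ``n`` virtual patients, ``round(n * failure_fraction)`` of
    them resistant (labelled failure), fully reproducible from ``seed``.

    The default composition, 51 failures / 20 successes at n = 71, mirrors
    the clinical cohort the biomarkers were originally evaluated on.
    """
    if not 0.0 <= failure_fraction <= 1.0:
        raise ValueError("failure_fraction must be in [0, 1]")
    resistant = resistant or resistant_archetype()
    responder = responder or responder_archetype()

    n_fail = int(round(n * failure_fraction))
    rng = np.random.default_rng(seed)
    archetypes = np.array([1] * n_fail + [0] * (n - n_fail))
    rng.shuffle(archetypes)

    seeds = np.random.SeedSequence(seed).spawn(n)
    patients, truths = [], []
    width = max(3, len(str(n)))
    for i, (flag, ss) in enumerate(zip(archetypes, seeds)):
        pid = f"P{i + 1:0{width}d}"
        spec = resistant if flag else responder
        sp = generate_patient(spec, ss, patient_id=pid)
        patients.append(sp.series)
        truths.append(sp)
    cohort = Cohort(patients, provenance={"source": "iasmark.synth", "seed": seed})
    return (cohort, truths) if return_truth else cohort
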