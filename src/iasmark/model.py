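"""Two-subclone cell-quota model of prostate cancer under androgen suppression.

The tumor is split into a castration-sensitive population ``x1`` and a
castration-resistant population ``x2`` (volumes, L).  Proliferation follows
Droop kinetics: each subclone grows only while the intracellular androgen
quota ``Q`` (bound androgen receptors, nmol) exceeds its minimum cell quota
(``q1`` for x1, ``q2`` for x2; a lower q2 means a more resistant clone).
Serum androgen ``A`` is produced by the testes under negative feedback —
shut off by androgen deprivation therapy (ADT) — plus a small constant
adrenal source, and diffuses into cells to build the quota.  Serum PSA ``P``
is secreted at baseline in proportion to the quota plus, under the
proliferation-gated law, in proportion to each subclone's proliferative
activity; an alternative law linear in tumor volume is also provided.

State order everywhere is ``(x1, x2, Q, A, P)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._core import N_PARAMS, PARAM_ORDER, Q_FLOOR, rhs_packed

STATE_VARS = ("x1", "x2", "Q", "A", "P")

#: Calibration bounds for the estimable parameters (per-day rates; quotas in
#: nmol).  A0 is patient-specific: its bound is the patient's maximum
#: recorded androgen +/- 10 nmol/L.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "mu": (0.001, 0.09),
    "q1": (0.41, 1.73),
    "q2": (0.01, 0.41),
    "d": (0.001, 0.30),
    "gamma1": (0.008, 0.8),
    "delta": (0.03, 0.15),
    "b": (0.0001, 0.1),
    "sigma1": (0.001, 1.0),
    "sigma2": (0.001, 1.0),
    "eps": (0.0001, 0.1),
}

#: Parameters held at fixed values during calibration.
FIXED_VALUES = {"c": 0.00015, "K": 1.0, "gamma2": 0.005}


class DegenerateStateError(ValueError):
    """Raised when the quota is non-positive and q/Q terms are undefined."""


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails on a schedule segment."""


@dataclass(frozen=True)
class ModelParameters:
    """The model constants, with calibration bounds and fixed/estimated roles.

    Units: rates 1/day; quotas and androgen nmol (serum concentrations as
    printed per L); PSA ug/L; volumes L.  ``psa_law`` selects the PSA
    production law: ``"quota_gated"`` (proliferation-proportional secretion,
    the default) or ``"linear"`` (secretion linear in subclone volume).
    """

    mu: float = 0.04        # max proliferation rate
    q1: float = 0.6         # CS minimum cell quota
    q2: float = 0.2         # CR minimum cell quota
    d: float = 0.02         # density-dependent death (competition)
    c: float = 0.00015      # max CS -> CR transformation rate
    K: float = 1.0          # transformation half-saturation
    gamma1: float = 0.2     # testicular androgen production
    gamma2: float = 0.005   # adrenal androgen production
    A0: float = 20.0        # homeostatic serum androgen
    delta: float = 0.08     # androgen degradation
    m: float = 0.9          # quota diffusion rate (fixed; never estimated)
    b: float = 0.001        # baseline PSA production
    sigma1: float = 0.2     # max PSA production by x1
    sigma2: float = 0.2     # max PSA production by x2
    eps: float = 0.05       # PSA clearance
    psa_law: str = "quota_gated"

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if self.q2 >= self.q1:
            raise ValueError(
                f"q2 ({self.q2}) must be below q1 ({self.q1}): the resistant "
                "clone proliferates at a lower androgen quota"
            )
        if self.psa_law not in ("quota_gated", "linear"):
            raise ValueError(f"unknown psa_law {self.psa_law!r}")

    def to_array(self) -> np.ndarray:
        p = np.empty(N_PARAMS)
        for i, name in enumerate(PARAM_ORDER):
            p[i] = getattr(self, name)
        p[-1] = 1.0 if self.psa_law == "linear" else 0.0
        return p

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = {name: getattr(self, name) for name in PARAM_ORDER}
        out["psa_law"] = self.psa_law
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered half-open [start, end) on/off-treatment intervals.

    Intervals must be contiguous, non-overlapping and cover the horizon.
    The Heaviside input u(t) of the androgen equation is 0 while ADT is
    applied (testicular production suppressed) and 1 off treatment.
    """

    intervals: tuple[tuple[float, float, bool], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule needs at least one interval")
        prev_end = None
        for start, end, _ in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval [{start}, {end})")
            if prev_end is not None and start != prev_end:
                raise ValueError("intervals must be contiguous")
            prev_end = end

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[float, float, bool]]
    ) -> "TreatmentSchedule":
        return cls(tuple((float(s), float(e), bool(on)) for s, e, on in intervals))

    @classmethod
    def cycles(cls, on_days: float, off_days: float, horizon: float) -> "TreatmentSchedule":
        """Periodic on/off schedule starting on treatment at day 0."""
        intervals, t, on = [], 0.0, True
        while t < horizon:
            dur = on_days if on else off_days
            intervals.append((t, min(t + dur, horizon), on))
            t += dur
            on = not on
        return cls.from_intervals(intervals)

    @property
    def start(self) -> float:
        return self.intervals[0][0]

    @property
    def horizon(self) -> float:
        return self.intervals[-1][1]

    def indicator(self, t: float) -> int:
        """u(t): 0 on treatment (ADT suppresses production), 1 off."""
        if t < self.start or t > self.horizon:
            raise ValueError(f"t={t} outside schedule horizon "
                             f"[{self.start}, {self.horizon}]")
        for start, end, on in self.intervals:
            if start <= t < end:
                return 0 if on else 1
        # t == horizon: attribute to the final interval
        return 0 if self.intervals[-1][2] else 1

    def on_treatment(self, t: float) -> bool:
        return self.indicator(t) == 0

    def switch_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(switch_times, u_values) arrays for the piecewise integrator."""
        times = np.array([iv[0] for iv in self.intervals])
        u = np.array([0.0 if iv[2] else 1.0 for iv in self.intervals])
        return times, u


def treatment_indicator(schedule: TreatmentSchedule, t: float) -> int:
    """Heaviside input u(t) of the androgen equation (0 = ADT on, 1 = off)."""
    return schedule.indicator(t)


def rhs(
    state: Sequence[float],
    t: float,
    params: ModelParameters,
    schedule: TreatmentSchedule,
) -> np.ndarray:
    """Time derivative of ``(x1, x2, Q, A, P)`` at time ``t``.

    Raises :class:`DegenerateStateError` if the quota is non-positive; at
    ``x1 + x2 = 0`` the population-weighted quota consumption is defined as
    its vanishing-population limit, 0.
    """
    x1, x2, Q, A, P = (float(v) for v in state)
    if Q <= 0:
        raise DegenerateStateError(f"non-positive quota Q={Q} at t={t}")
    u = float(schedule.indicator(t))
    return np.array(rhs_packed(x1, x2, Q, A, P, u, params.to_array()))


@dataclass
class Trajectory:
    """Simulated state paths on a time grid under a treatment schedule."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 5), columns STATE_VARS
    schedule: TreatmentSchedule
    params: ModelParameters
    hit_q_floor: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.states.shape != (self.t.size, 5):
            raise ValueError("states shape must be (len(t), 5)")

    def __getitem__(self, var: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(var)]

    @property
    def u(self) -> np.ndarray:
        return np.array([self.schedule.indicator(t) for t in self.t])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "day", self.t)
        df["u"] = self.u
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """PSA/androgen panel with shaded on-treatment periods."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        ax.plot(self.t, self["P"], label="PSA (ug/L)", color="tab:blue")
        ax.plot(self.t, self["A"], label="androgen (nmol/L)", color="tab:orange")
        for start, end, on in self.schedule.intervals:
            if on:
                ax.axvspan(max(start, self.t[0]), min(end, self.t[-1]),
                           color="0.9", zorder=0)
        ax.set_xlabel("day")
        ax.legend()
        return ax


def simulate(
    params: ModelParameters,
    schedule: TreatmentSchedule,
    init: Sequence[float],
    grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the model on ``grid``, restarting at treatment switches.

    ``init`` is ``(x1, x2, Q, A, P)`` at ``grid[0]``.  Integration is split
    at every on/off switch so the discontinuous androgen input is honored
    exactly.  States are clamped non-negative and the quota is floored at
    ``Q_FLOOR``; a trajectory that hits the floor is flagged.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(init, dtype=float)
    if y.shape != (5,):
        raise ValueError("init must have 5 components (x1, x2, Q, A, P)")
    if np.any(y < 0):
        raise ValueError("initial state components must be non-negative")
    if grid[0] < schedule.start or grid[-1] > schedule.horizon:
        raise ValueError("grid must lie within the schedule horizon")

    p = params.to_array()

    def f(t, y, u):
        Q = max(y[2], Q_FLOOR)
        return rhs_packed(y[0], y[1], Q, y[3], y[4], u, p)

    out = np.empty((grid.size, 5))
    hit_floor = False
    t_cur = grid[0]
    i = 0
    # emit the initial point if it is the first grid entry
    if grid[0] == t_cur:
        out[0] = y
        i = 1
    for start, end, on in schedule.intervals:
        if end <= t_cur or start >= grid[-1]:
            continue
        seg_end = min(end, grid[-1])
        u = 0.0 if on else 1.0
        t_eval = grid[(grid > t_cur) & (grid <= seg_end)]
        sol = solve_ivp(
            f, (t_cur, seg_end), y, method=method, t_eval=t_eval,
            rtol=rtol, atol=atol, args=(u,),
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed on segment [{t_cur}, {seg_end}] "
                f"(on_treatment={on}): {sol.message}; params={params.to_dict()}"
            )
        n = sol.t.size
        if n:
            vals = sol.y.T
            if np.any(vals[:, 2] <= Q_FLOOR):
                hit_floor = True
            out[i:i + n] = np.clip(vals, 0.0, None)
            out[i:i + n, 2] = np.maximum(out[i:i + n, 2], Q_FLOOR)
            i += n
        y = np.clip(sol.y[:, -1] if sol.y.size else y, 0.0, None)
        y[2] = max(y[2], Q_FLOOR)
        t_cur = seg_end
        if t_cur >= grid[-1]:
            break
    return Trajectory(grid, out, schedule, params, hit_q_floor=hit_floor)


def androgen_equilibrium(params: ModelParameters, u: float) -> float:
    """Steady serum androgen of the cell-free subsystem at constant u.

    A* = (gamma1 u + gamma2) / (gamma1 u / A0 + delta).
    """
    return (params.gamma1 * u + params.gamma2) / (
        params.gamma1 * u / params.A0 + params.delta
    )
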