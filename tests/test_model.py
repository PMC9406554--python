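"""Unit and property tests for the cell-quota ODE system."""

import numpy as np
import pytest

from iasmark.model import (
    DegenerateStateError,
    ModelParameters,
    PARAM_BOUNDS,
    TreatmentSchedule,
    Trajectory,
    androgen_equilibrium,
    rhs,
    simulate,
    treatment_indicator,
)

from _oracles import rk4_reference

EXAMPLE_PARAMS = ModelParameters(
    mu=0.05, q1=1.0, q2=0.3, d=0.01, c=1.5e-4, K=1.0,
    gamma1=0.08, gamma2=0.005, A0=30.0, delta=0.08, m=0.9,
    b=0.01, sigma1=0.1, sigma2=0.1, eps=0.05,
)
OFF = TreatmentSchedule.from_intervals([(0, 1000, False)])
ON = TreatmentSchedule.from_intervals([(0, 1000, True)])


class TestRhs:
    def test_term_by_term_oracle(self):
        """Derivatives at a reference state, expanded by hand term by term:
        dx1 = 0.05*(1-1/2)*1 - 0.01*1*2 - 1.5e-4/3 = 0.00495
        dx2 = 0.05*(1-0.3/2)*1 - 0.02 + 5e-5 = 0.02255
        dQ  = 0.9*(5-2) - (0.05*1 + 0.05*1.7)/2 = 2.6325
        dA  = 0.08*(1-5/30) + 0.005 - 0.4 = -0.32833...
        dP  = 0.01*2 + 0.05 + 0.085 - 0.5 = -0.345
        """
        d = rhs([1.0, 1.0, 2.0, 5.0, 10.0], 50.0, EXAMPLE_PARAMS, OFF)
        expected = [0.00495, 0.02255, 2.6325, 0.08 * 25 / 30 + 0.005 - 0.4, -0.345]
        np.testing.assert_allclose(d, expected, rtol=1e-12)

    def test_gate_closes_at_minimum_quota(self):
        """At Q = q1 = q2 neither clone proliferates nor secretes PSA."""
        p = EXAMPLE_PARAMS.replace(q1=0.5, q2=0.499999999)
        d = rhs([2.0, 3.0, 0.5, 1.0, 0.0], 0.0, p, ON)
        # dP reduces to the baseline b*Q term exactly
        assert d[4] == pytest.approx(p.b * 0.5, rel=1e-6)
        # proliferation shut: dx1/dx2 contain only death/transformation
        assert d[0] < 0 and d[1] < 0.01 * p.c

    def test_empty_source_population_has_no_transformation(self):
        d = rhs([0.0, 1.0, 2.0, 5.0, 1.0], 0.0, EXAMPLE_PARAMS, OFF)
        d_noc = rhs([0.0, 1.0, 2.0, 5.0, 1.0], 0.0,
                    EXAMPLE_PARAMS.replace(c=1e6 * EXAMPLE_PARAMS.c), OFF)
        np.testing.assert_allclose(d, d_noc, rtol=1e-12)

    def test_transformation_conservation(self):
        """The flux leaving x1 equals the flux entering x2 at any state."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            state = rng.uniform(0.01, 5.0, size=5)
            d_full = rhs(state, 0.0, EXAMPLE_PARAMS, OFF)
            d_zero = rhs(state, 0.0, EXAMPLE_PARAMS.replace(c=1e-300), OFF)
            flux_out = d_zero[0] - d_full[0]
            flux_in = d_full[1] - d_zero[1]
            assert flux_out == pytest.approx(flux_in, abs=1e-14)

    def test_gate_monotone_in_q2(self):
        """Lowering q2 never decreases the resistant clone's growth."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            state = rng.uniform(0.05, 5.0, size=5)
            q2s = np.sort(rng.uniform(0.01, 0.41, size=2))
            d_hi = rhs(state, 0.0, EXAMPLE_PARAMS.replace(q2=q2s[1]), OFF)
            d_lo = rhs(state, 0.0, EXAMPLE_PARAMS.replace(q2=q2s[0]), OFF)
            assert d_lo[1] >= d_hi[1] - 1e-14

    def test_degenerate_quota_raises(self):
        with pytest.raises(DegenerateStateError):
            rhs([1.0, 1.0, 0.0, 5.0, 10.0], 0.0, EXAMPLE_PARAMS, OFF)

    def test_linear_psa_law(self):
        p = EXAMPLE_PARAMS.replace(psa_law="linear")
        d = rhs([1.0, 1.0, 2.0, 5.0, 10.0], 0.0, p, OFF)
        assert d[4] == pytest.approx(0.01 * 2 + 0.1 + 0.1 - 0.5, rel=1e-12)


class TestParameters:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError, match="strictly positive"):
            ModelParameters(mu=0.0)

    def test_quota_ordering_enforced(self):
        with pytest.raises(ValueError, match="q2"):
            ModelParameters(q1=0.5, q2=0.6)

    def test_roundtrip_dict(self):
        p = ModelParameters(psa_law="linear")
        assert ModelParameters.from_dict(p.to_dict()) == p


class TestSchedule:
    def test_indicator_convention(self):
        """u = 0 during suppression, u = 1 off treatment; boundaries are
        half-open so a switch day belongs to the following interval."""
        s = TreatmentSchedule.from_intervals([(0, 100, True), (100, 200, False)])
        assert treatment_indicator(s, 50) == 0
        assert treatment_indicator(s, 150) == 1
        assert treatment_indicator(s, 100) == 1  # half-open boundary
        with pytest.raises(ValueError, match="horizon"):
            treatment_indicator(s, 250)

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            TreatmentSchedule.from_intervals([(0, 100, True), (150, 200, False)])


class TestSimulate:
    def test_tumor_free_invariant(self):
        """With no tumor the volumes and secreted PSA stay zero and
        androgen relaxes to its off-treatment equilibrium."""
        p = EXAMPLE_PARAMS.replace(b=1e-12)
        init = [0.0, 0.0, 1.0, 1.0, 0.0]
        traj = simulate(p, OFF, init, np.linspace(0, 400, 81))
        assert np.all(traj["x1"] == 0) and np.all(traj["x2"] == 0)
        assert np.all(traj["P"] <= 1e-6)
        a_star = androgen_equilibrium(p, u=1.0)
        assert traj["A"][-1] == pytest.approx(a_star, rel=1e-6)

    @pytest.mark.parametrize("u", [0.0, 1.0])
    def test_cell_free_androgen_equilibrium(self, u):
        """A(t) -> (gamma1 u + gamma2)/(gamma1 u / A0 + delta)."""
        p = ModelParameters(gamma1=0.8, gamma2=0.005, A0=30.0, delta=0.03)
        sched = ON if u == 0.0 else OFF
        traj = simulate(p, sched, [0, 0, 1.0, 5.0, 0.0], np.linspace(0, 900, 10))
        a_star = (p.gamma1 * u + p.gamma2) / (p.gamma1 * u / p.A0 + p.delta)
        assert traj["A"][-1] == pytest.approx(a_star, rel=1e-6)

    def test_matches_fixed_step_oracle(self):
        """Adaptive integration agrees with dt=0.001 RK4 through a switch."""
        sched = TreatmentSchedule.from_intervals([(0, 20, True), (20, 40, False)])
        grid = np.linspace(0, 40, 9)
        init = [0.3, 0.05, 5.0, 5.0, 10.0]
        traj = simulate(EXAMPLE_PARAMS, sched, init, grid)
        p = EXAMPLE_PARAMS.to_dict()
        p.pop("psa_law")
        p["m"] = EXAMPLE_PARAMS.m
        oracle = rk4_reference(p, init, grid, switch_day=20.0,
                               u_before=0.0, u_after=1.0)
        np.testing.assert_allclose(traj.states, oracle, rtol=1e-4, atol=1e-8)

    def test_non_negativity_and_androgen_bound(self):
        rng = np.random.default_rng(3)
        sched = TreatmentSchedule.cycles(200, 100, 900)
        for _ in range(5):
            draw = {k: rng.uniform(*v) for k, v in PARAM_BOUNDS.items()}
            draw["q2"] = min(draw["q2"], 0.98 * draw["q1"])
            p = ModelParameters(**draw, A0=rng.uniform(10, 30))
            init = [0.3, 0.01, 4.0, 4.0, 10.0]
            traj = simulate(p, sched, init, np.linspace(0, 900, 91))
            assert np.all(traj.states >= -1e-9)
            a_star = androgen_equilibrium(p, u=1.0)
            assert np.all(traj["A"] <= max(init[3], a_star) + 1e-6)

    def test_grid_outside_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            simulate(EXAMPLE_PARAMS, ON, [0, 0, 1, 1, 0], [0, 2000])


class TestTrajectory:
    def test_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(np.array([0.0, 0.0]), np.zeros((2, 5)), OFF, EXAMPLE_PARAMS)

    def test_csv_export(self, tmp_path):
        traj = simulate(EXAMPLE_PARAMS, ON, [0.1, 0.01, 2, 2, 5], np.arange(0, 10.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "day,x1,x2,Q,A,P,u"
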