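"""Parameters, rate functions, therapy schedules and the mean-field ODE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paccsim import (Parameters, PopulationState, TherapySchedule, drug_kill,
                     rates, ode_solve, equilibrium_no_drug, load_config,
                     save_config, EvolutionConfig)
from paccsim.model import _ode_rhs


class TestParameters:
    def test_defaults_are_the_standard_simulation_values(self):
        p = Parameters()
        assert (p.r, p.K, p.gamma, p.lam, p.b) == (0.6, 100.0, 0.02, 1.0, 1.0)
        assert (p.c21, p.c12, p.eta, p.mu) == (0.7, 0.2, 0.7, 0.05)
        assert (p.sigma1, p.sigma2) == (0.01, 0.05)

    @pytest.mark.parametrize("kwargs", [
        {"r": -1.0}, {"K": 0.0}, {"eta": 1.5}, {"mu": -0.1}, {"dt": 0.0},
        {"sigma1": -0.01},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Parameters(**kwargs)

    def test_round_trip_dict(self):
        p = Parameters(m=0.8, zeta=0.2)
        assert Parameters.from_dict(p.to_dict()) == p


class TestPopulationState:
    def test_extinct_iff_empty(self):
        assert PopulationState(0, 0).extinct
        assert not PopulationState(0, 1).extinct

    @pytest.mark.parametrize("kwargs", [
        {"x1": -1}, {"x2": -3}, {"v": -0.5}, {"x1": 1.5},
    ])
    def test_invalid_state_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationState(**{"x1": 1, "x2": 0, "v": 0.0, **kwargs})


class TestDrugKill:
    @pytest.mark.parametrize("v,m,expected", [
        (0.0, 0.8, 0.8),
        (1.0, 0.8, 0.4),
        (5.0, 0.0, 0.0),
    ])
    def test_michaelis_menten_values(self, v, m, expected, params):
        assert drug_kill(v, m, params) == pytest.approx(expected)

    def test_negative_arguments_rejected(self, params):
        with pytest.raises(ValueError):
            drug_kill(-0.1, 0.5, params)
        with pytest.raises(ValueError):
            drug_kill(0.1, -0.5, params)

    @settings(max_examples=50, deadline=None)
    @given(v1=st.floats(0, 50), v2=st.floats(0, 50),
           m=st.floats(0, 2))
    def test_monotone_non_increasing_in_resistance(self, v1, v2, m):
        p = Parameters()
        lo, hi = sorted((v1, v2))
        assert drug_kill(hi, m, p) <= drug_kill(lo, m, p)


class TestRates:
    def test_logistic_channel_below_capacity(self, params):
        r = rates(PopulationState(50, 0), 0.0, params)
        # net logistic flux 0.6*50*(100-50)/100 appears as birth only
        assert r.birth == pytest.approx(15.0)
        assert r.comp_death == 0.0
        assert r.obligate_out == pytest.approx(1.0)
        assert r.drug_death == r.facultative_out == r.depoly == 0.0

    def test_no_2n_cells_means_only_depoly(self, params):
        r = rates(PopulationState(0, 10), 1.0, params)
        assert r.depoly == pytest.approx(2.0)
        assert (r.birth, r.comp_death, r.drug_death, r.obligate_out,
                r.facultative_out) == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_drug_and_facultative_scale_with_kill(self, params):
        r = rates(PopulationState(10, 0), 0.8, params)
        assert r.drug_death == pytest.approx(8.0)
        assert r.facultative_out == pytest.approx(0.7 * 10 * 0.8)

    def test_above_capacity_crowding_death(self, params):
        r = rates(PopulationState(150, 100), 0.0, params)
        assert r.birth == 0.0
        assert r.comp_death == pytest.approx(0.6 * 150 * 150 / 100)

    @settings(max_examples=50, deadline=None)
    @given(x1=st.integers(0, 500), x2=st.integers(0, 500),
           v=st.floats(0, 10), m=st.floats(0, 2))
    def test_all_components_non_negative(self, x1, x2, v, m):
        p = Parameters()
        r = rates(PopulationState(x1, x2, v), m, p)
        for val in (r.birth, r.comp_death, r.drug_death, r.obligate_out,
                    r.facultative_out, r.depoly):
            assert val >= 0.0

    @settings(max_examples=50, deadline=None)
    @given(x1=st.integers(0, 300), x2=st.integers(0, 300),
           v=st.floats(0, 5), m=st.floats(0, 1))
    def test_net_flux_matches_ode_drift(self, x1, x2, v, m):
        """Netted channels reproduce dx1/dt of the mean-field system."""
        p = Parameters()
        r = rates(PopulationState(x1, x2, v), m, p)
        net = (r.birth - r.comp_death - r.drug_death - r.obligate_out
               - r.facultative_out + 2.0 * r.depoly)
        dx1 = _ode_rhs(0.0, np.array([float(x1), float(x2)]), m, v, p)[0]
        assert net == pytest.approx(dx1, abs=1e-9)


class TestTherapySchedule:
    def test_continuous_window_half_open(self):
        ts = TherapySchedule(kind="continuous", dose=0.8, start=200, stop=800)
        assert ts.dose_at(100.0) == 0.0
        assert ts.dose_at(200.0) == 0.8
        assert ts.dose_at(799.9) == 0.8
        assert ts.dose_at(800.0) == 0.0

    def test_intermittent_cycles(self):
        ts = TherapySchedule(kind="intermittent", dose=0.8, start=200,
                             on_len=100, off_len=100)
        # cycle enumeration: 200-300 on, 300-400 off, 400-500 on, ...
        assert ts.dose_at(350.0) == 0.0
        assert ts.dose_at(250.0) == 0.8
        assert ts.dose_at(420.0) == 0.8
        assert ts.dose_at(150.0) == 0.0

    def test_none_schedule_is_zero(self):
        assert TherapySchedule(kind="none").dose_at(123.0) == 0.0

    def test_breakpoints_cover_dose_changes(self):
        ts = TherapySchedule(kind="intermittent", dose=1.0, start=200,
                             on_len=100, off_len=100)
        pts = ts.breakpoints(0.0, 650.0)
        assert pts == [200.0, 300.0, 400.0, 500.0, 600.0]


class TestOdeSolve:
    def test_equilibrium_matches_closed_form(self, params, no_therapy):
        x1_star, x2_star = equilibrium_no_drug(params)
        traj = ode_solve(PopulationState(10, 0), no_therapy, params, 400.0)
        assert traj["x1"].iloc[-1] == pytest.approx(x1_star, rel=1e-5)
        assert traj["x2"].iloc[-1] == pytest.approx(x2_star, rel=1e-5)
        # PACC equilibrium is gamma*eta/c12 = 7% of the 2N+ level
        assert x2_star / x1_star == pytest.approx(0.07)

    def test_empty_population_stays_empty(self, params, continuous08):
        traj = ode_solve(PopulationState(0, 0), continuous08, params, 100.0)
        assert (traj["x1"] == 0).all() and (traj["x2"] == 0).all()

    def test_growth_slower_than_kill_drives_decline(self, params):
        # m/lam = 1 exceeds r = 0.6, so without evolution the population dies
        ts = TherapySchedule(kind="continuous", dose=1.0, start=0.0)
        traj = ode_solve(PopulationState(10, 0), ts, params, 1000.0)
        assert traj["x1"].iloc[-1] < 1e-3
        assert traj["x2"].iloc[-1] < 1e-3

    def test_reduces_to_logistic_without_transitions(self, no_therapy):
        p = Parameters(gamma=0.0)
        traj = ode_solve(PopulationState(10, 0), no_therapy, p, 50.0)
        t = traj["t"].to_numpy()
        expect = p.K * 10 * np.exp(p.r * t) / (p.K + 10 * (np.exp(p.r * t) - 1))
        np.testing.assert_allclose(traj["x1"], expect, rtol=1e-6)

    def test_equilibrium_derivatives_vanish(self, params):
        x1, x2 = equilibrium_no_drug(params)
        dx = _ode_rhs(0.0, np.array([x1, x2]), 0.0, 0.0, params)
        assert abs(dx[0]) < 1e-9 and abs(dx[1]) < 1e-9

    def test_t_end_must_exceed_start(self, params, no_therapy):
        with pytest.raises(ValueError):
            ode_solve(PopulationState(10, 0), no_therapy, params, 0.0)


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path):
        p = Parameters(m=0.8, zeta=0.2, dt=0.5)
        ts = TherapySchedule(kind="intermittent", dose=0.8, start=200,
                             on_len=100, off_len=100)
        evo = EvolutionConfig(engine="SGM", zeta=0.2,
                              sgm_proposal_rate_factor=1.5)
        path = tmp_path / "config.yaml"
        save_config(path, params=p, schedule=ts, evolution=evo)
        p2, ts2, evo2 = load_config(path)
        assert p2 == p and ts2 == ts and evo2 == evo

    def test_infinite_stop_serializes(self, tmp_path):
        ts = TherapySchedule(kind="continuous", dose=1.0, start=0.0)
        path = tmp_path / "c.yaml"
        save_config(path, schedule=ts)
        _, ts2, _ = load_config(path)
        assert math.isinf(ts2.stop)
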