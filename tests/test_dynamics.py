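"""Equations of motion: capstan cascade, accelerations, integration, energy balance."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallsim.dynamics import (
    ModelParams,
    SimulationConfig,
    UnreachableAngleError,
    angular_acceleration,
    balance_threshold_ratio,
    cable_tensions,
    capstan_factor,
    closed_form_speed,
    simulate_fall,
)

# frozen from term-by-term evaluation: sum of exp(k*0.18*pi), k=1..4
C1_AT_018 = (
    math.exp(0.18 * math.pi)
    + math.exp(0.36 * math.pi)
    + math.exp(0.54 * math.pi)
    + math.exp(0.72 * math.pi)
)


class TestCapstanFactor:
    def test_frictionless_limit_is_four(self):
        assert capstan_factor(0.0) == 4.0

    def test_matches_term_by_term_sum(self):
        assert capstan_factor(0.18) == pytest.approx(C1_AT_018, rel=1e-15)
        assert capstan_factor(0.18) == pytest.approx(19.9153, abs=5e-5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_strictly_increasing(self, mu):
        assert capstan_factor(mu + 0.01) > capstan_factor(mu)

    def test_negative_friction_rejected(self):
        with pytest.raises(ValueError):
            capstan_factor(-0.1)


class TestCableTensions:
    def test_no_counterweight_means_no_tension(self):
        p = ModelParams(L=1.2, m2=0.0, mu_F=0.3)
        t = cable_tensions(p, theta_ddot=5.0)
        assert t.F == 0.0 and t.F_P == 0.0 and all(f == 0.0 for f in t.Ff)

    def test_static_frictionless_weight(self):
        p = ModelParams(L=1.2, r=0.1875, mu_F=0.0, m2=10.0, g=9.81)
        t = cable_tensions(p, theta_ddot=0.0)
        assert t.F == pytest.approx(98.1)
        assert t.F_P == pytest.approx(392.4)

    def test_static_total_is_weight_times_capstan_factor(self):
        p = ModelParams(L=1.2, mu_F=0.18, m2=10.0, g=9.81)
        t = cable_tensions(p, theta_ddot=0.0)
        assert t.F_P == pytest.approx(98.1 * capstan_factor(0.18), rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        mu=st.floats(min_value=0.0, max_value=0.6),
        m2=st.floats(min_value=0.1, max_value=50.0),
        acc=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_wraps_amplify_tension_monotonically(self, mu, m2, acc):
        p = ModelParams(L=1.2, mu_F=mu, m2=m2)
        t = cable_tensions(p, acc)
        chain = (t.F,) + t.Ff
        assert all(a <= b for a, b in zip(chain, chain[1:]))
        assert t.F_P == pytest.approx(sum(t.Ff), rel=1e-12)


class TestAngularAcceleration:
    def test_horizontal_no_counterweight(self):
        p = ModelParams(L=1.21, m2=0.0)
        assert angular_acceleration(p, math.pi / 2) == pytest.approx(9.81 / 1.21, rel=1e-14)

    def test_upright_equilibrium(self):
        p = ModelParams(L=1.21, m2=0.0)
        assert angular_acceleration(p, 0.0) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(
        L=st.floats(min_value=0.5, max_value=2.0),
        theta=st.floats(min_value=0.0, max_value=math.pi / 2),
    )
    def test_reduces_to_inverted_pendulum_without_counterweight(self, L, theta):
        p = ModelParams(L=L, m2=0.0, mu_F=0.25)
        assert angular_acceleration(p, theta) == pytest.approx(
            9.81 * math.sin(theta) / L, rel=1e-13, abs=1e-15
        )

    def test_matches_independent_formula_with_counterweight(self):
        # one-line evaluation of the counterweight-ratio form, independent of
        # the capstan/tension code path
        L, r, mu, rho, g = 1.30, 0.1875, 0.18, 0.30, 9.81
        theta = math.radians(37.0)
        C1 = sum(math.exp(k * mu * math.pi) for k in range(1, 5))
        expected = (g * L * math.sin(theta) - C1 * r * g * rho) / (L**2 + 4 * C1 * r**2 * rho)
        p = ModelParams(L=L, r=r, mu_F=mu, m1=100.0, m2=rho * 100.0, g=g)
        assert angular_acceleration(p, theta) == pytest.approx(expected, rel=1e-13)

    def test_counterweight_can_reverse_sign(self):
        p = ModelParams(L=1.0, r=0.1875, mu_F=0.3, m1=90.0, m2=40.0)
        assert angular_acceleration(p, math.radians(10.0)) < 0

    def test_strictly_increasing_in_theta(self):
        p = ModelParams(L=1.3, r=0.1875, mu_F=0.18, m1=96.8, m2=10.0)
        thetas = np.linspace(0.01, math.pi / 2, 200)
        acc = angular_acceleration(p, thetas)
        assert np.all(np.diff(acc) > 0)


class TestClosedFormSpeed:
    def test_free_fall_textbook_form(self):
        p = ModelParams(L=1.21, m2=0.0)
        v = closed_form_speed(p, math.radians(65), math.radians(70))
        expected = math.sqrt(2 * 9.81 / 1.21 * (math.cos(math.radians(65)) - math.cos(math.radians(70))))
        assert v == pytest.approx(expected, rel=1e-14)
        assert v == pytest.approx(1.1432, abs=5e-5)

    def test_released_at_rest(self):
        p = ModelParams(L=1.21)
        assert closed_form_speed(p, 0.9, 0.9) == 0.0

    def test_unreachable_angle_signalled(self):
        # counterweight work exceeds the potential energy released by 70 deg
        p = ModelParams(L=1.3, r=0.1875, mu_F=0.28, m1=96.8, m2=10.0)
        with pytest.raises(UnreachableAngleError):
            closed_form_speed(p, math.radians(37), math.radians(70))

    def test_theta_before_release_rejected(self):
        p = ModelParams(L=1.21)
        with pytest.raises(ValueError):
            closed_form_speed(p, math.radians(50), math.radians(40))


class TestSimulateFall:
    def test_integrator_matches_energy_balance(self):
        p = ModelParams(L=1.21, m2=0.0)
        traj = simulate_fall(p, math.radians(65))
        v = closed_form_speed(p, math.radians(65), math.radians(70))
        assert abs(traj.event_speed("readout_70deg") - v) < 1e-6

    @pytest.mark.parametrize(
        "L,r,mu,rho,theta0_deg",
        [
            (0.9, 0.10, 0.0, 0.0, 35.0),
            (1.2, 0.1875, 0.18, 0.15, 37.0),
            (1.5, 0.25, 0.40, 0.01, 50.0),
            (1.0, 0.15, 0.10, 0.30, 45.0),
        ],
    )
    def test_oracle_equivalence_across_parameters(self, L, r, mu, rho, theta0_deg):
        p = ModelParams(L=L, r=r, mu_F=mu, m1=90.0, m2=rho * 90.0)
        theta0 = math.radians(theta0_deg)
        traj = simulate_fall(p, theta0)
        assert not traj.balanced
        for name, angle_deg in [("readout_70deg", 70.0), ("mat_contact_85deg", 85.0), ("horizontal_90deg", 90.0)]:
            v = closed_form_speed(p, theta0, math.radians(angle_deg))
            assert abs(traj.event_speed(name) - v) < 1e-6

    def test_balanced_flag_and_empty_events(self):
        p = ModelParams(L=1.0, r=0.1875, mu_F=0.3, m1=90.0, m2=45.0)
        theta0 = math.radians(20.0)
        assert angular_acceleration(p, theta0) <= 0
        traj = simulate_fall(p, theta0)
        assert traj.balanced
        assert set(traj.events) == {"release"}

    def test_landmark_times_strictly_ordered(self):
        p = ModelParams(L=1.3, m2=0.0)
        traj = simulate_fall(p, math.radians(37))
        t70 = traj.events["readout_70deg"][0]
        t85 = traj.events["mat_contact_85deg"][0]
        t90 = traj.events["horizontal_90deg"][0]
        assert 0.0 < t70 < t85 < t90

    def test_initial_state_is_rest_at_release_angle(self):
        p = ModelParams(L=1.1, m2=0.0)
        theta0 = math.radians(45)
        traj = simulate_fall(p, theta0)
        assert traj.theta[0] == theta0
        assert traj.theta_dot[0] == 0.0
        assert np.all(np.diff(traj.t) > 0)

    def test_release_angle_out_of_range_rejected(self):
        p = ModelParams(L=1.1)
        with pytest.raises(ValueError):
            simulate_fall(p, math.radians(95))
        with pytest.raises(ValueError):
            simulate_fall(p, 0.0)

    def test_energy_conserved_without_counterweight(self):
        p = ModelParams(L=1.21, m2=0.0)
        traj = simulate_fall(p, math.radians(40))
        # specific energy: L^2 w^2 / 2 + g L cos(theta)
        e = 0.5 * p.L**2 * traj.theta_dot**2 + p.g * p.L * np.cos(traj.theta)
        assert np.max(np.abs(e - e[0])) < 1e-7

    def test_speed_monotone_in_counterweight_friction_and_lean(self):
        base = dict(L=1.3, r=0.1875, m1=96.8)
        th0, th = math.radians(37), math.radians(70)
        v_rho = [
            closed_form_speed(ModelParams(mu_F=0.18, m2=rho * 96.8, **base), th0, th)
            for rho in np.linspace(0.0, 0.15, 30)
        ]
        assert np.all(np.diff(v_rho) < 0)
        v_mu = [
            closed_form_speed(ModelParams(mu_F=mu, m2=2.0, **base), th0, th)
            for mu in np.linspace(0.0, 0.4, 30)
        ]
        assert np.all(np.diff(v_mu) < 0)
        v_th0 = [
            closed_form_speed(ModelParams(mu_F=0.0, m2=0.0, **base), t0, th)
            for t0 in np.radians(np.linspace(35, 69, 30))
        ]
        assert np.all(np.diff(v_th0) < 0)


class TestBalanceThreshold:
    def test_flag_matches_analytic_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            L = rng.uniform(0.8, 1.6)
            r = rng.uniform(0.1, 0.25)
            mu = rng.uniform(0.0, 0.4)
            m1 = rng.uniform(70.0, 120.0)
            rho = rng.uniform(0.0, 0.5)
            theta0 = math.radians(rng.uniform(5.0, 65.0))
            p = ModelParams(L=L, r=r, mu_F=mu, m1=m1, m2=rho * m1)
            expected = p.g * L * math.sin(theta0) <= capstan_factor(mu) * r * p.g * rho
            assert simulate_fall(p, theta0).balanced == expected
            assert expected == (rho >= balance_threshold_ratio(p, theta0))


class TestSerialization:
    def test_params_round_trip(self):
        p = ModelParams(L=1.3, r=0.2, mu_F=0.18, m1=95.0, m2=12.0, g=9.80665)
        assert ModelParams.from_dict(p.to_dict()) == p

    def test_params_invariants_enforced(self):
        for bad in [dict(L=-1.0), dict(L=1.0, mu_F=-0.1), dict(L=1.0, m1=0.0), dict(L=1.0, m2=-5.0)]:
            with pytest.raises(ValueError):
                ModelParams(**bad)

    def test_trajectory_export(self, tmp_path):
        import pandas as pd

        p = ModelParams(L=1.21, m2=0.0)
        traj = simulate_fall(p, math.radians(50))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["t", "theta_deg", "theta_dot", "theta_ddot"]
        assert len(frame) == len(traj.t)
        block = json.loads(traj.events_json())
        assert block["events"]["readout_70deg"]["theta_dot"] == traj.event_speed("readout_70deg")
        assert block["params"]["L"] == 1.21
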