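"""The feedback chain: delay, PID forms, Ziegler-Nichols helper,
saturation, load-sharing distribution and activation dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omnineck.controller import (
    ActivationState,
    ControllerConfig,
    ControllerGains,
    NeckController,
    REFERENCE_CONTROLLERS,
    SensedKinematics,
    StandardFormGains,
    activation_dynamics_step,
    delay_signal,
    distribute,
    parallel_to_standard,
    pid_response,
    saturate,
    standard_to_parallel,
    ziegler_nichols_ki,
)
from omnineck.kinematics import AxisAngle, Orientation, matrix_from_axis_angle


class TestDelay:
    def test_constant_signal_passes_through(self):
        t = np.arange(0.0, 100.0, 1.0)
        e = np.full_like(t, 0.25)
        assert delay_signal(t, e, 80.0, 30.0) == 0.25

    def test_pre_history_is_zero(self):
        t = np.arange(0.0, 100.0, 1.0)
        e = np.full_like(t, 0.25)
        assert delay_signal(t, e, 10.0, 30.0) == 0.0

    def test_sinusoid_shifted_by_tau(self):
        t = np.arange(0.0, 1000.0, 1.0)
        e = np.sin(2 * np.pi * t / 200.0)
        tau = 37.0
        for tq in (300.0, 555.0, 812.0):
            expected = np.sin(2 * np.pi * (tq - tau) / 200.0)
            assert abs(delay_signal(t, e, tq, tau) - expected) < 1e-3

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            delay_signal(np.arange(3.0), np.zeros(3), 1.0, -1.0)


class TestPid:
    def test_proportional_only(self):
        t = np.arange(0.0, 50.0, 1.0)
        e = np.full_like(t, 0.25)
        u = pid_response(ControllerGains(2.0, 0.0, 0.0), t, e)
        assert np.allclose(u, 0.5)

    def test_integral_ramp(self):
        t = np.arange(0.0, 1001.0, 1.0)
        c, k = 0.3, 1e-3
        u = pid_response(ControllerGains(0.0, k, 0.0), t, np.full_like(t, c))
        assert np.allclose(u, k * c * t, atol=1e-12)

    def test_polynomial_against_refined_grid_oracle(self):
        gains = ControllerGains(1.2, 2e-4, 80.0)

        def err(t):
            return 1e-3 * t - 4e-7 * t**2 + 1e-10 * t**3

        t_coarse = np.arange(0.0, 500.0 + 1e-9, 1.0)
        u = pid_response(gains, t_coarse, err(t_coarse))

        t_fine = np.arange(0.0, 500.0 + 1e-9, 0.01)
        e_fine = err(t_fine)
        integral = np.concatenate(
            [[0.0], np.cumsum(0.005 * (e_fine[1:] + e_fine[:-1]))]
        )
        deriv = np.gradient(e_fine, t_fine)
        u_oracle = gains.kp * e_fine + gains.ki * integral + gains.kd * deriv
        oracle_at_coarse = np.interp(t_coarse, t_fine, u_oracle)
        assert np.allclose(u[5:], oracle_at_coarse[5:], atol=5e-4)


class TestGainForms:
    def test_definitional_example(self):
        g = standard_to_parallel(StandardFormGains(1.0, 1000.0, 100.0))
        assert (g.kp, g.ki, g.kd) == (1.0, 0.001, 100.0)

    def test_round_trip_identity(self, rng):
        for _ in range(50):
            g = ControllerGains(
                rng.uniform(0.1, 5.0), rng.uniform(1e-6, 0.1), rng.uniform(1.0, 1000.0)
            )
            back = standard_to_parallel(parallel_to_standard(g))
            assert np.allclose(
                [back.kp, back.ki, back.kd], [g.kp, g.ki, g.kd], rtol=1e-12
            )

    def test_zero_td_gives_zero_kd(self):
        assert standard_to_parallel(StandardFormGains(2.0, 500.0, 0.0)).kd == 0.0

    def test_inverse_undefined_without_integral_action(self):
        with pytest.raises(ValueError):
            parallel_to_standard(ControllerGains(0.0, 0.1, 1.0))
        with pytest.raises(ValueError):
            parallel_to_standard(ControllerGains(1.0, 0.0, 1.0))


class TestZieglerNichols:
    @pytest.mark.parametrize(
        "kp, kd, printed, ndigits",
        [
            (8.0, 300.0, 0.05, 2),  # THUMS
            (3.0, 250.0, 0.009, 3),  # GHBMC
            (1.301, 470.0, 9e-4, None),  # SAFER HBM v10, one significant figure
            (0.78, 483.27, 3e-4, None),  # GHBMC second tuning
        ],
    )
    def test_reproduces_published_theoretical_ki(self, kp, kd, printed, ndigits):
        ki = ziegler_nichols_ki(kp, kd)
        if ndigits is not None:
            assert round(ki, ndigits) == printed
        else:  # one significant figure
            exp = np.floor(np.log10(ki))
            assert round(ki / 10**exp) * 10**exp == pytest.approx(printed)

    def test_reference_registry_is_consistent(self):
        for ref in REFERENCE_CONTROLLERS:
            assert ref.theoretical_ki == ziegler_nichols_ki(ref.kp, ref.kd)

    def test_undefined_for_zero_kd(self):
        with pytest.raises(ValueError):
            ziegler_nichols_ki(1.0, 0.0)


class TestSaturateAndDistribute:
    @pytest.mark.parametrize("u, expected", [(1.5, 1.0), (-0.2, 0.0), (0.7, 0.7)])
    def test_clamp(self, u, expected):
        assert saturate(u) == expected

    def test_distribute_arithmetic(self):
        drive = distribute(0.5, np.array([0.8]), np.array([0.02]))
        assert np.isclose(drive[0], 0.42)

    def test_zero_drive_returns_baseline(self):
        b = np.array([0.02, 0.05])
        assert np.allclose(distribute(0.0, np.array([0.9, 0.3]), b), b)

    def test_cap_at_unity(self):
        assert distribute(1.0, np.array([1.0]), np.array([0.1]))[0] == 1.0


class TestActivationDynamics:
    def test_constant_drive_is_fixed_point(self):
        state = ActivationState(np.array([0.3]), np.array([0.3]))
        out = activation_dynamics_step(state, np.array([0.3]), 1.0, 30.0, 15.0)
        assert np.allclose(out.excitation, 0.3) and np.allclose(out.active, 0.3)

    def test_first_order_step_response_at_time_constant(self):
        tau = 30.0
        state = ActivationState(np.zeros(1), np.zeros(1))
        for _ in range(int(tau)):  # advance to t = tau with dt = 1 ms
            state = activation_dynamics_step(state, np.ones(1), 1.0, tau, 15.0)
        assert abs(state.excitation[0] - (1.0 - 1.0 / np.e)) < 5e-3

    def test_monotone_decay_to_zero(self):
        state = ActivationState(np.array([0.5]), np.array([0.5]))
        prev = 0.5
        for _ in range(200):
            state = activation_dynamics_step(state, np.zeros(1), 1.0, 30.0, 15.0)
            assert state.active[0] <= prev + 1e-15
            prev = state.active[0]
        assert prev < 0.01

    def test_dt_guard(self):
        state = ActivationState.zeros(1)
        with pytest.raises(ValueError):
            activation_dynamics_step(state, np.zeros(1), 20.0, 30.0, 15.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_states_bounded_for_bounded_drives(self, drives):
        state = ActivationState.zeros(1)
        for d in drives:
            state = activation_dynamics_step(state, np.array([d]), 1.0, 30.0, 15.0)
            assert 0.0 <= state.excitation[0] <= 1.0
            assert 0.0 <= state.active[0] <= 1.0


def _sensed(head=(0.02, 0.0, -0.15), orient=None):
    return SensedKinematics(
        head_orientation=orient or Orientation.identity(),
        head_cog=np.array(head),
        t1_pos=np.zeros(3),
        t1_yaw=0.0,
    )


class TestControllerStep:
    def test_zero_gains_yield_baseline_activation(self, stps):
        cfg = ControllerConfig(mode="translational", baseline_scale=0.1)
        ctrl = NeckController(cfg, ControllerGains(0, 0, 0), stps)
        ctrl.capture_reference(_sensed())
        for t in range(300):
            na = ctrl.step(float(t), _sensed(head=(0.08, 0.01, -0.14)))
        assert np.allclose(na, ctrl.baseline, atol=1e-6)

    def test_degenerate_rotation_gives_baseline_drive(self, stps):
        cfg = ControllerConfig(mode="rotational", baseline_scale=0.1)
        ctrl = NeckController(cfg, ControllerGains(2.0, 0.0, 0.0), stps)
        ctrl.capture_reference(_sensed())
        for t in range(300):
            na = ctrl.step(float(t), _sensed())  # no deviation at all
        assert np.allclose(na, ctrl.baseline, atol=1e-6)

    def test_forward_lean_recruits_extensors_over_flexors(self, stps):
        cfg = ControllerConfig(mode="translational", baseline_scale=0.0)
        ctrl = NeckController(cfg, ControllerGains(1.5, 0.0, 0.0), stps)
        ctrl.capture_reference(_sensed())
        leaned = _sensed(head=(0.08, 0.0, -0.14))
        for t in range(500):
            na = ctrl.step(float(t), leaned)
        idx = {c: i for i, c in enumerate(ctrl.channels)}
        extensor = na[idx[("semispinalis_capitis", "right")]]
        flexor = na[idx[("sternocleidomastoid", "right")]]
        assert extensor > 0.05
        assert extensor > flexor

    def test_rotational_mode_recruits_by_rotation_axis(self, stps):
        cfg = ControllerConfig(mode="rotational", baseline_scale=0.0)
        ctrl = NeckController(cfg, ControllerGains(1.5, 0.0, 0.0), stps)
        ctrl.capture_reference(_sensed())
        # flexion: rotation about -y
        flexed = matrix_from_axis_angle(AxisAngle(np.array([0.0, -1.0, 0.0]), 0.3))
        sensed = _sensed(orient=flexed)
        for t in range(500):
            na = ctrl.step(float(t), sensed)
        idx = {c: i for i, c in enumerate(ctrl.channels)}
        assert (
            na[idx[("semispinalis_capitis", "right")]]
            > na[idx[("sternocleidomastoid", "right")]]
        )

    def test_activations_bounded_under_randomized_inputs(self, stps, rng):
        cfg = ControllerConfig(mode="translational", baseline_scale=0.1)
        ctrl = NeckController(cfg, ControllerGains(5.0, 1e-3, 500.0), stps)
        ctrl.capture_reference(_sensed())
        for t in range(500):
            head = np.array([0.02, 0.0, -0.15]) + rng.normal(0, 0.05, 3)
            na = ctrl.step(float(t), _sensed(head=tuple(head)))
            assert np.all(na >= 0.0) and np.all(na <= 1.0)
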