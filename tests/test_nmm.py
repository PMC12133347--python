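"""Forward model: sigmoid, delay surrogate, vector field, Euler integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erpdcm import TRUE_PARAMETERS, integrate_euler
from erpdcm.nmm import (
    BLOWUP_BOUND,
    classify_dynamics,
    classify_stability,
    delayed_state,
    rhs,
    sigmoid,
)
from erpdcm.params import NMMParameters


class TestSigmoid:
    def test_zero_and_limits(self):
        assert sigmoid(0.0) == pytest.approx(0.0)
        assert sigmoid(1e4) == pytest.approx(0.5)
        assert sigmoid(-1e4) == pytest.approx(-0.5)

    def test_unit_value(self):
        # independent scalar evaluation of 1/(1+e^-0.56) - 0.5
        expected = 1.0 / (1.0 + math.exp(-0.56)) - 0.5
        assert sigmoid(1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.136453, abs=5e-6)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_odd(self, a, b):
        if a + 1e-9 < b:  # resolvable separation in double precision
            assert sigmoid(a) < sigmoid(b)
        assert sigmoid(-a) == pytest.approx(-sigmoid(a), abs=1e-12)


class TestDelayedState:
    def test_zero_delay_is_identity(self):
        x = np.arange(1.0, 10.0)
        p = TRUE_PARAMETERS.replace(delta=0.0)
        x1d, x7d, x9d = delayed_state(x, p)
        assert (x1d, x7d, x9d) == (x[0], x[6], x[8])

    def test_zero_state(self):
        assert delayed_state(np.zeros(9), TRUE_PARAMETERS) == (0.0, 0.0, 0.0)

    def test_substitution_rule(self):
        # x1 - delta * x1' with x1' = x4
        x = np.zeros(9)
        x[0], x[3] = 5.0, 1.0
        p = TRUE_PARAMETERS.replace(delta=12.13)
        x1d, _, _ = delayed_state(x, p)
        assert x1d == pytest.approx(5.0 - 12.13)


def _rhs_no_delay(x, p, input_active):
    """Independent oracle: the nine equations with instantaneous arguments."""
    u = p.u if input_active else 0.0
    s = sigmoid
    f = np.empty(9)
    f[0], f[1], f[2], f[6], f[8] = x[3], x[4], x[5], x[7], x[4] - x[5]
    f[3] = (p.h_e / p.tau_e) * (p.g1 * s(x[8]) + u) - x[0] / p.tau_e**2 - 2 * x[3] / p.tau_e
    f[4] = p.g2 * (p.h_e / p.tau_e) * s(x[0]) - x[1] / p.tau_e**2 - 2 * x[4] / p.tau_e
    f[5] = p.g4 * (p.h_i / p.tau_i) * s(x[6]) - x[2] / p.tau_i**2 - 2 * x[5] / p.tau_i
    f[7] = p.g3 * (p.h_e / p.tau_e) * s(x[8]) - x[6] / p.tau_e**2 - 2 * x[7] / p.tau_e
    return f


class TestRHS:
    def test_origin_is_input_free_equilibrium(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = NMMParameters.from_array(rng.uniform(0.05, 20.0, size=10))
            assert np.all(rhs(np.zeros(9), p, input_active=False) == 0.0)

    def test_input_drives_only_x4_at_origin(self):
        f = rhs(np.zeros(9), TRUE_PARAMETERS, input_active=True)
        expected = TRUE_PARAMETERS.h_e * TRUE_PARAMETERS.u / TRUE_PARAMETERS.tau_e
        assert f[3] == pytest.approx(expected)
        assert expected == pytest.approx(1.1130, abs=2e-4)
        mask = np.ones(9, bool)
        mask[3] = False
        assert np.all(f[mask] == 0.0)

    def test_zero_delay_matches_instantaneous_system(self):
        rng = np.random.default_rng(1)
        p = TRUE_PARAMETERS.replace(delta=0.0)
        for _ in range(5):
            x = rng.normal(size=9)
            np.testing.assert_allclose(rhs(x, p, True), _rhs_no_delay(x, p, True), rtol=1e-12)


class TestIntegrateEuler:
    def test_equilibrium_preserved(self):
        traj = integrate_euler(TRUE_PARAMETERS, dt=0.1, duration=10.0, input_active=False)
        assert traj.stable
        assert np.all(traj.states == 0.0)

    def test_default_window_has_2001_samples(self):
        traj = integrate_euler(TRUE_PARAMETERS)
        assert traj.states.shape == (2001, 9)
        np.testing.assert_allclose(traj.times, np.arange(2001) * 0.1)

    def test_matches_stepping_the_python_vector_field(self):
        # ten Euler steps against the pure-python rhs as oracle
        p = TRUE_PARAMETERS
        traj = integrate_euler(p, dt=0.1, duration=1.0)
        x = np.zeros(9)
        for k in range(10):
            x = x + 0.1 * rhs(x, p, True)
            np.testing.assert_allclose(traj.states[k + 1], x, rtol=1e-12, atol=1e-15)

    def test_first_order_convergence(self):
        # Richardson refinement: successive solution differences halve with dt
        vals = [
            integrate_euler(TRUE_PARAMETERS, dt=dt, duration=100.0).pyramidal[-1]
            for dt in (0.1, 0.05, 0.025, 0.0125)
        ]
        diffs = [abs(a - b) for a, b in zip(vals, vals[1:])]
        for d1, d2 in zip(diffs, diffs[1:]):
            assert 1.5 <= d1 / d2 <= 2.5

    @pytest.mark.parametrize("bad", [{"dt": 0.0}, {"dt": -0.1}, {"duration": 0.0}, {"duration": -5.0}])
    def test_rejects_nonpositive_grid(self, bad):
        with pytest.raises(ValueError):
            integrate_euler(TRUE_PARAMETERS, **bad)

    def test_gradient_matches_finite_differences(self):
        # the differentiability contract behind gradient-based inference
        from erpdcm import _kernels

        th = TRUE_PARAMETERS.to_array()
        y, sens, stable = _kernels.euler_observe_sens(th, 0.1, 2000, 10, BLOWUP_BOUND)
        assert stable
        for j in range(10):
            e = np.zeros(10)
            e[j] = 1e-6 * th[j]
            yp, _ = _kernels.euler_observe(th + e, 0.1, 2000, 10, BLOWUP_BOUND)
            ym, _ = _kernels.euler_observe(th - e, 0.1, 2000, 10, BLOWUP_BOUND)
            fd = (yp[-1] - ym[-1]) / (2 * e[j])
            assert fd == pytest.approx(sens[-1, j], rel=1e-3, abs=1e-9)


class TestStability:
    def test_zero_trajectory_is_stable(self):
        traj = integrate_euler(TRUE_PARAMETERS, duration=10.0, input_active=False)
        assert classify_stability(traj) == "stable"

    def test_nonfinite_sample_is_unstable(self):
        traj = integrate_euler(TRUE_PARAMETERS, duration=10.0)
        traj.states[5, 2] = np.nan
        assert classify_stability(traj) == "unstable"

    def test_blowup_bound(self):
        traj = integrate_euler(TRUE_PARAMETERS, duration=10.0)
        traj.states[3, 0] = 2e3
        assert classify_stability(traj) == "unstable"

    def test_truth_decays_back_to_rest(self):
        assert classify_dynamics(TRUE_PARAMETERS) == "decaying"

    def test_export_csv_roundtrip(self, tmp_path):
        traj = integrate_euler(TRUE_PARAMETERS, duration=5.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (51, 10)
        np.testing.assert_allclose(data[:, 1:], traj.states, rtol=1e-6)
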