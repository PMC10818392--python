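"""Stabilometry parameters: closed forms, oracles, and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import posturokit as pk
from posturokit.stabilometry import ELLIPSE_SCALE_95

from ._reference import (
    ref_dispersion,
    ref_ellipse_area,
    ref_mean_velocity,
    ref_path_length,
    ref_range,
    ref_total_displacement,
    ref_total_mean_velocity,
)
from .conftest import make_trajectory


class TestTotalDisplacement:
    def test_constant_radius(self):
        traj = make_trajectory([3.0] * 10, [4.0] * 10)
        assert pk.total_displacement(traj) == pytest.approx(50.0)

    def test_zero_trajectory(self):
        assert pk.total_displacement(make_trajectory([0] * 5, [0] * 5)) == 0.0

    def test_differs_from_path_length(self):
        # constant offset: radial sum is large, path length is zero
        traj = make_trajectory([3.0] * 10, [4.0] * 10)
        assert pk.path_length(traj) == 0.0
        assert pk.total_displacement(traj) == pytest.approx(50.0)


class TestEllipseArea:
    def test_collinear_points_zero_area(self):
        x = np.linspace(-1, 1, 20)
        traj = make_trajectory(x, 2 * x + 0.5)
        assert pk.ellipse_area_95(traj) == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_area(self):
        # 4 points at (+-1, +-1) scaled so the N-1 covariance is exactly I
        s = math.sqrt(3.0 / 4.0)
        ap = np.array([s, s, -s, -s])
        ml = np.array([s, -s, s, -s])
        traj = make_trajectory(ap, ml)
        assert pk.ellipse_area_95(traj) == pytest.approx(
            math.pi * ELLIPSE_SCALE_95**2, rel=1e-12
        )
        assert math.pi * ELLIPSE_SCALE_95**2 == pytest.approx(18.82, abs=0.01)

    def test_monte_carlo_coverage(self):
        r = np.random.default_rng(11)
        traj = make_trajectory(r.normal(0, 1.5, 10_000), r.normal(0, 1.5, 10_000))
        ell = pk.prediction_ellipse_95(traj)
        frac = float(np.mean(ell.contains(traj.cp_ap, traj.cp_ml)))
        assert 0.94 <= frac <= 0.96
        assert ell.area == pytest.approx(pk.ellipse_area_95(traj), rel=1e-12)

    def test_degenerate_single_point_warns(self):
        traj = make_trajectory([2.0] * 5, [3.0] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            assert pk.ellipse_area_95(traj) == 0.0

    def test_insufficient_data(self):
        with pytest.raises(pk.InsufficientDataError):
            pk.ellipse_area_95(make_trajectory([0, 1], [0, 1]))


class TestRangeAndDispersion:
    def test_sine_range_is_twice_amplitude(self):
        t = np.arange(400) / 200.0  # 2 s at 200 Hz: one full 0.5 Hz period
        sig = 3.5 * np.sin(2 * np.pi * 0.5 * t + np.pi / 2)  # hits +-A on grid
        traj = make_trajectory(sig, np.zeros_like(sig), rate=200.0)
        assert pk.cop_range(traj, "ap") == pytest.approx(7.0, rel=1e-12)

    def test_constant_signal_zero_range(self):
        traj = make_trajectory([2.0] * 10, [0.0] * 10)
        assert pk.cop_range(traj, "ap") == 0.0

    def test_dispersion_alternating(self):
        traj = make_trajectory([-1, 1, -1, 1], [0, 0, 0, 0])
        assert pk.cop_dispersion(traj, "ap", center=True) == pytest.approx(1.0)
        assert pk.cop_dispersion(traj, "ap", center=False) == pytest.approx(1.0)

    def test_centering_semantics_on_constant(self):
        traj = make_trajectory([-2.0] * 10, [0.0] * 10)
        assert pk.cop_dispersion(traj, "ap", center=True) == 0.0
        assert pk.cop_dispersion(traj, "ap", center=False) == pytest.approx(2.0)

    def test_gaussian_sd_recovery(self):
        r = np.random.default_rng(5)
        sigma = 1.7
        x = r.normal(3.0, sigma, 10_000)
        traj = make_trajectory(x, np.zeros_like(x))
        est = pk.cop_dispersion(traj, "ap", center=True)
        se = sigma / math.sqrt(2 * 10_000)  # SE of the SD estimator
        assert abs(est - sigma) < 3 * se


class TestVelocities:
    def test_constant_signal_zero_velocity(self):
        traj = make_trajectory([5.0] * 10, [5.0] * 10)
        assert pk.mean_velocity(traj, "ap") == 0.0
        assert pk.total_mean_velocity(traj) == 0.0

    def test_ramp_closed_form(self):
        # slope s sampled at rate f: each increment is s/f; v = s*(N-1)/N
        s, f, n = 2.0, 20.0, 50
        t = np.arange(n) / f
        traj = make_trajectory(s * t, np.zeros(n), rate=f)
        assert pk.mean_velocity(traj, "ap") == pytest.approx(s * (n - 1) / n)

    def test_sine_mean_abs_derivative(self):
        # mean |d/dt A sin(2 pi f0 t)| over whole periods = 4 A f0
        a, f0, rate, dur = 1.0, 0.5, 200.0, 10.0
        t = np.arange(int(rate * dur)) / rate
        traj = make_trajectory(a * np.sin(2 * np.pi * f0 * t), np.zeros_like(t),
                               rate=rate)
        assert pk.mean_velocity(traj, "ap") == pytest.approx(4 * a * f0, rel=0.01)

    def test_circular_motion_tmv(self):
        # uniform circular motion: speed = R * omega
        radius, omega, rate = 2.0, 2 * np.pi * 0.5, 400.0
        t = np.arange(int(rate * 10)) / rate
        traj = make_trajectory(
            radius * np.cos(omega * t), radius * np.sin(omega * t), rate=rate
        )
        assert pk.total_mean_velocity(traj) == pytest.approx(radius * omega, rel=0.01)

    def test_triangle_inequality(self, random_trajectory):
        tmv = pk.total_mean_velocity(random_trajectory)
        assert tmv <= (
            pk.mean_velocity(random_trajectory, "ap")
            + pk.mean_velocity(random_trajectory, "ml")
        ) * (1 + 1e-12)


class TestOracleEquivalence:
    def test_all_parameters_match_naive_loops(self, rng):
        for _ in range(20):
            ap = list(rng.normal(0, 2, 50))
            ml = list(rng.normal(0, 2, 50))
            traj = make_trajectory(ap, ml)
            f = traj.rate
            assert pk.total_displacement(traj) == pytest.approx(
                ref_total_displacement(ap, ml), rel=1e-12)
            assert pk.path_length(traj) == pytest.approx(
                ref_path_length(ap, ml), rel=1e-12)
            assert pk.ellipse_area_95(traj) == pytest.approx(
                ref_ellipse_area(ap, ml), rel=1e-9)
            assert pk.cop_range(traj, "ap") == pytest.approx(ref_range(ap), rel=1e-12)
            assert pk.cop_range(traj, "ml") == pytest.approx(ref_range(ml), rel=1e-12)
            for center in (True, False):
                assert pk.cop_dispersion(traj, "ap", center=center) == pytest.approx(
                    ref_dispersion(ap, center), rel=1e-12)
            assert pk.mean_velocity(traj, "ap") == pytest.approx(
                ref_mean_velocity(ap, f), rel=1e-12)
            assert pk.mean_velocity(traj, "ml") == pytest.approx(
                ref_mean_velocity(ml, f), rel=1e-12)
            assert pk.total_mean_velocity(traj) == pytest.approx(
                ref_total_mean_velocity(ap, ml, f), rel=1e-12)


class TestInvariances:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 2**16))
    def test_scale_equivariance(self, scale, seed):
        r = np.random.default_rng(seed)
        ap, ml = r.normal(0, 1, 30), r.normal(0, 1, 30)
        base = pk.analyze_trajectory(make_trajectory(ap, ml))
        scaled = pk.analyze_trajectory(make_trajectory(scale * ap, scale * ml))
        for name in ("dot_eq3", "path_length", "ap_rom", "ml_rom", "ap_sd",
                     "ml_sd", "ap_velocity", "ml_velocity", "tmv"):
            assert getattr(scaled, name) == pytest.approx(
                scale * getattr(base, name), rel=1e-9)
        assert scaled.ellipse_area == pytest.approx(
            scale**2 * base.ellipse_area, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(angle=st.floats(0, 2 * math.pi), seed=st.integers(0, 2**16))
    def test_rotation_invariance_of_planar_statistics(self, angle, seed):
        r = np.random.default_rng(seed)
        ap, ml = r.normal(0, 1, 30), r.normal(0, 1, 30)
        c, s = math.cos(angle), math.sin(angle)
        rotated = make_trajectory(c * ap - s * ml, s * ap + c * ml)
        plain = make_trajectory(ap, ml)
        assert pk.total_displacement(rotated) == pytest.approx(
            pk.total_displacement(plain), rel=1e-9)
        assert pk.ellipse_area_95(rotated) == pytest.approx(
            pk.ellipse_area_95(plain), rel=1e-9)
        assert pk.total_mean_velocity(rotated) == pytest.approx(
            pk.total_mean_velocity(plain), rel=1e-9)


class TestStaticBalanceProtocol:
    def _trial(self, seed, duration=10.0):
        return pk.simulate_sway(pk.SwaySimConfig(seed=seed, duration=duration))

    def test_three_identical_trials_mean_equals_single(self):
        t = self._trial(1)
        report = pk.run_static_balance_test([t, t, t])
        single = pk.analyze_trajectory(t)
        for name in pk.stabilometry.PARAMETER_NAMES:
            assert getattr(report.mean_across_trials, name) == pytest.approx(
                getattr(single, name))

    def test_zero_trials_all_parameters_zero(self):
        z = make_trajectory([0.0] * 200, [0.0] * 200)
        with pytest.warns(UserWarning):
            report = pk.run_static_balance_test([z, z, z])
        for name in pk.stabilometry.PARAMETER_NAMES:
            assert getattr(report.mean_across_trials, name) == 0.0

    def test_mean_is_elementwise_average(self):
        trials = [self._trial(s) for s in (1, 2, 3)]
        report = pk.run_static_balance_test(trials)
        singles = [pk.analyze_trajectory(t) for t in trials]
        for name in pk.stabilometry.PARAMETER_NAMES:
            expect = sum(getattr(s, name) for s in singles) / 3.0
            assert getattr(report.mean_across_trials, name) == pytest.approx(expect)

    def test_wrong_trial_count(self):
        t = self._trial(1)
        with pytest.raises(pk.ProtocolError, match="3 trials"):
            pk.run_static_balance_test([t, t])

    def test_out_of_tolerance_duration_names_trial(self):
        good = self._trial(1)
        short = self._trial(2, duration=8.0)
        with pytest.raises(pk.ProtocolError, match="trial 2"):
            pk.run_static_balance_test([good, short, good])

    def test_report_serializable(self):
        report = pk.run_static_balance_test([self._trial(s) for s in (1, 2, 3)])
        d = report.as_dict()
        assert len(d["trials"]) == 3
        assert set(pk.stabilometry.PARAMETER_NAMES) <= set(d["mean"])
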