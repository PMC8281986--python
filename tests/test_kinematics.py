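"""Velocity integration, detrending and TPV extraction: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachkin.kinematics import (
    MovementWindow,
    WindowTooShortError,
    detrend_linear,
    filter_tpv,
    integrate_velocity,
    process_window,
    speed_magnitude,
    tpv_percent,
    TPVResult,
)
from reachkin.profiles import STANDARD_GRAVITY, gen_asymmetric_reach, gen_min_jerk_reach


def _window(t, acc):
    return MovementWindow(t, acc, float(t[0]), float(t[-1]))


class TestIntegrateVelocity:
    def test_constant_acceleration_is_exact(self):
        t = np.arange(101) / 100
        acc = np.column_stack([np.full(101, 2.0), np.zeros(101), np.zeros(101)])
        v = integrate_velocity(_window(t, acc))
        assert v[-1, 0] == pytest.approx(2.0, abs=1e-12)
        assert v[0, 0] == 0.0  # integration constant C = 0 at release

    def test_linear_acceleration_is_exact_for_trapezoid(self):
        t = np.arange(101) / 100
        acc = np.column_stack([t, np.zeros(101), np.zeros(101)])
        v = integrate_velocity(_window(t, acc))
        assert v[-1, 0] == pytest.approx(0.5, abs=1e-12)

    def test_quadratic_acceleration_converges_at_h_squared(self):
        # closed form: int_0^1 t^2 dt = 1/3; trapezoid error ~ h^2/6
        errs = []
        for fs in (50, 100, 200):
            t = np.arange(fs + 1) / fs
            acc = np.column_stack([t**2, np.zeros(t.size), np.zeros(t.size)])
            v = integrate_velocity(_window(t, acc))
            errs.append(abs(v[-1, 0] - 1.0 / 3.0))
        assert errs[1] < 1e-4
        assert errs[2] == pytest.approx(errs[1] / 4, rel=0.1)

    def test_min_jerk_velocity_recovered(self):
        p = gen_min_jerk_reach(0.5, 0.3, 100)
        v = integrate_velocity(_window(p.t, p.acc))
        h = p.t[1] - p.t[0]
        # |error| <= h^2/12 * max|a''| * T ; a'' peaks at 720 A/T^4 here
        bound = h**2 / 12 * (720 * 0.3 / 0.5**4) * 0.5
        assert np.abs(v - p.vel).max() < bound

    def test_too_short_window_raises(self):
        with pytest.raises(WindowTooShortError):
            MovementWindow(np.array([0.0, 0.01]), np.zeros((2, 3)), 0.0, 0.01)


class TestSpeedMagnitude:
    def test_pythagorean_triple(self):
        v = np.array([[3.0, 4.0, 0.0]])
        assert speed_magnitude(v)[0] == 5.0

    def test_single_axis_motion(self):
        v = np.column_stack([np.array([-2.0, 1.5]), np.zeros(2), np.zeros(2)])
        assert speed_magnitude(v).tolist() == [2.0, 1.5]

    def test_matches_per_sample_norm_oracle(self, rng):
        v = rng.normal(size=(200, 3))
        brute = np.array([np.sqrt(a * a + b * b + c * c) for a, b, c in v])
        assert np.allclose(speed_magnitude(v), brute, atol=1e-14)


class TestDetrend:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(100) / 100
        y = 3.7 * t - 1.2
        assert np.abs(detrend_linear(y, t)).max() < 1e-12

    def test_agrees_with_explicit_least_squares(self, rng):
        t = np.arange(150) / 100
        y = rng.normal(size=150)
        A = np.column_stack([t, np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(detrend_linear(y, t), y - A @ coef, atol=1e-10)

    @pytest.mark.parametrize("slope", [0.0, 0.2, 0.5, 1.0, 2.0])
    def test_bell_plus_line_keeps_bell_argmax(self, slope):
        p = gen_min_jerk_reach(1.0, 0.5, 100)
        bell = p.speed  # peak 0.9375 m/s at t=0.5
        y = bell + slope * p.t
        detr = detrend_linear(y, p.t)
        assert abs(int(np.argmax(detr)) - int(np.argmax(bell))) <= 1

    def test_monotone_drifted_magnitude_recovers_interior_bell(self):
        """A velocity ramp from integrated bias buries the bell under a
        monotone curve with a false end peak; detrending restores an
        interior maximum."""
        p = gen_asymmetric_reach(1.5, 0.1, 0.45, 100)
        bias = np.array([0.0, 0.01, 0.01]) * STANDARD_GRAVITY
        win = _window(p.t, p.acc + bias)
        mag = speed_magnitude(integrate_velocity(win))
        assert np.argmax(mag) == mag.size - 1  # the pathology
        detr = detrend_linear(mag, p.t)
        peak = int(np.argmax(detr))
        assert 0 < peak < mag.size - 1


class TestTpvPercent:
    def test_min_jerk_is_fifty_percent(self):
        p = gen_min_jerk_reach(0.5, 0.3, 100)
        res = process_window(_window(p.t, p.acc), detrend=True)
        assert res.tpv_percent == pytest.approx(50.0, abs=100 * 0.5 / 50)

    @pytest.mark.parametrize("frac", [0.30, 0.40, 0.60])
    def test_recovers_constructed_mode_from_clean_speed(self, frac):
        p = gen_asymmetric_reach(1.0, 0.4, frac, 100)
        res = tpv_percent(p.speed, p.t, 0.0, 1.0)
        assert res.tpv_percent == pytest.approx(100 * frac, abs=100 * 1.0 / 100)

    def test_peak_at_first_sample_is_zero_percent(self):
        t = np.arange(10) / 100
        y = np.linspace(1.0, 0.1, 10)
        res = tpv_percent(y, t, 0.0, t[-1])
        assert res.tpv_percent == 0.0

    def test_flat_series_is_excluded(self):
        t = np.arange(10) / 100
        res = tpv_percent(np.ones(10), t, 0.0, t[-1])
        assert not res.retained
        assert res.exclusion_reason == "undefined_peak"

    def test_ties_break_to_earliest_sample(self):
        t = np.arange(5) / 100
        y = np.array([0.0, 1.0, 0.5, 1.0, 0.0])
        assert tpv_percent(y, t, 0.0, t[-1]).peak_index == 1


class TestFilterTpv:
    def test_boundary_enumeration(self):
        vals = [4.9, 5.0, 50.0, 95.0, 95.1]
        results = [TPVResult(v, 0) for v in vals]
        kept, dropped = filter_tpv(results)
        assert [r.tpv_percent for r in kept] == [5.0, 50.0, 95.0]
        assert all(r.exclusion_reason == "tpv_out_of_bounds" for r in dropped)

    def test_exhaustive_grid(self):
        grid = np.arange(0.0, 100.5, 0.5)
        kept, dropped = filter_tpv([TPVResult(v, 0) for v in grid])
        kept_vals = [r.tpv_percent for r in kept]
        assert min(kept_vals) == 5.0 and max(kept_vals) == 95.0
        assert len(kept) + len(dropped) == grid.size

    def test_interior_batch_has_no_exclusions(self):
        kept, dropped = filter_tpv([TPVResult(v, 0) for v in (20, 50, 80)])
        assert dropped == []


class TestInvariants:
    @pytest.mark.parametrize("bias_mg", [0, 2, 4, 6, 8, 10])
    def test_drift_robustness_with_detrend(self, bias_mg):
        """Per-axis bias up to 10 mg moves recovered TPV by at most 3 points
        when detrending is on."""
        p = gen_asymmetric_reach(1.5, 0.1, 0.45, 100)
        bias = np.array([bias_mg, bias_mg, bias_mg]) * 1e-3 * STANDARD_GRAVITY
        res = process_window(_window(p.t, p.acc + bias), detrend=True)
        assert abs(res.tpv_percent - 45.0) <= 3.0

    def test_scale_invariance_of_timing(self, rng):
        """TPV% is a pure timing index: rescaling acceleration by any
        positive constant leaves it unchanged."""
        p = gen_asymmetric_reach(1.0, 0.3, 0.4, 100)
        acc = p.acc + rng.normal(0, 0.02, p.acc.shape)
        base = process_window(_window(p.t, acc)).tpv_percent
        for c in (1e-3, 0.5, 7.0, 1e4):
            scaled = process_window(_window(p.t, acc * c)).tpv_percent
            assert scaled == pytest.approx(base, abs=1e-9)

    def test_recovery_error_shrinks_with_sample_rate(self):
        errs = []
        for fs in (25, 50, 100, 200):
            p = gen_asymmetric_reach(1.0, 0.3, 0.37, fs)
            res = process_window(_window(p.t, p.acc), detrend=False)
            errs.append(abs(res.tpv_percent - 37.0))
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi + 1e-9
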