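"""Velocity reconstruction and time-to-peak-velocity extraction.

The measurement chain for one valid trial:

1. restrict the effective acceleration to the movement window [R, A];
2. cumulative trapezoidal integration per axis with integration constant
   C = 0 (the hand rests on the start sensor until release);
3. Euclidean magnitude of the velocity components;
4. linear detrend of the magnitude — any residual constant acceleration bias
   integrates to a velocity ramp that can bury the true bell-shaped bump
   under a monotone curve and plant a false peak at the window end; removing
   the least-squares line restores the interior peak;
5. TPV% = 100·(t_peak − R)/(A − R), with an a-priori inclusion band of
   [5, 95]% to drop numerically degenerate or extra-task movements.

Only the *timing* of the peak is an endpoint: velocity values after
integration and detrending are not metrically trustworthy, and TPV% is by
construction invariant to any positive rescaling of the acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .preprocess import EffectiveAccel
from .segment import (
    VALID_CORRECT,
    VALID_INCORRECT,
    TrialEvents,
    classify_trial,
    timing,
)


class WindowTooShortError(ValueError):
    """Movement window with fewer than 3 samples cannot be integrated."""


@dataclass
class MovementWindow:
    """Effective acceleration restricted to [R, A] of one valid trial."""

    time_s: np.ndarray
    acc_ms2: np.ndarray
    R: float
    A: float

    def __post_init__(self):
        if self.time_s.size < 3:
            raise WindowTooShortError(
                f"movement window has {self.time_s.size} samples (<3)"
            )


@dataclass
class TPVResult:
    """Peak-velocity timing of one trial and its inclusion status."""

    tpv_percent: float
    peak_index: int
    retained: bool = True
    exclusion_reason: str | None = None


@dataclass
class KinematicsConfig:
    filter_lo: float = 5.0
    filter_hi: float = 95.0
    detrend: bool = True
    response_window_ms: float = 2000.0
    min_rest_s: float = 0.2


@dataclass
class TrialKinematics:
    """All per-trial endpoints plus processing flags."""

    trial: int
    condition: str
    validity: str
    rt_ms: float
    md_ms: float
    srt_ms: float
    tpv_pct: float
    retained: bool
    flags: tuple = ()


def extract_window(eff: EffectiveAccel, R: float, A: float) -> MovementWindow:
    """Snap [R, A] to the nearest samples of the effective-acceleration grid."""
    if A <= R:
        raise ValueError("A must follow R")
    i0 = int(np.argmin(np.abs(eff.time_s - R)))
    i1 = int(np.argmin(np.abs(eff.time_s - A)))
    if i1 - i0 < 2:
        raise WindowTooShortError("movement window shorter than 3 samples")
    return MovementWindow(eff.time_s[i0 : i1 + 1], eff.acc_ms2[i0 : i1 + 1], R, A)


def integrate_velocity(win: MovementWindow) -> np.ndarray:
    """Per-axis velocity by cumulative trapezoidal integration, v(R) = 0."""
    return cumulative_trapezoid(win.acc_ms2, win.time_s, axis=0, initial=0.0)


def speed_magnitude(velocity: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the velocity components."""
    return np.linalg.norm(np.atleast_2d(velocity.T).T, axis=1)


def detrend_linear(series: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
    """Subtract the least-squares straight line fitted over the whole window."""
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("detrend needs at least 3 samples")
    x = np.arange(y.size, dtype=float) if t is None else np.asarray(t, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def tpv_percent(detrended: np.ndarray, t: np.ndarray, R: float, A: float) -> TPVResult:
    """Timing of the global maximum as a percentage of movement duration.

    Ties are broken by the earliest sample.  A flat series has no defined
    peak and is excluded.
    """
    if A <= R:
        raise ValueError("A must follow R")
    y = np.asarray(detrended, dtype=float)
    if np.ptp(y) == 0.0:
        return TPVResult(tpv_percent=float("nan"), peak_index=-1,
                         retained=False, exclusion_reason="undefined_peak")
    idx = int(np.argmax(y))
    pct = 100.0 * (t[idx] - R) / (A - R)
    return TPVResult(tpv_percent=float(pct), peak_index=idx)


def filter_tpv(results, lo: float = 5.0, hi: float = 95.0):
    """Split TPV results into retained ([lo, hi] inclusive) and excluded."""
    retained, excluded = [], []
    for r in results:
        if not r.retained:
            excluded.append(r)
        elif lo <= r.tpv_percent <= hi:
            retained.append(r)
        else:
            excluded.append(
                TPVResult(r.tpv_percent, r.peak_index, retained=False,
                          exclusion_reason="tpv_out_of_bounds")
            )
    return retained, excluded


def process_window(win: MovementWindow, detrend: bool = True) -> TPVResult:
    """Integration → magnitude → (detrend) → peak timing for one window."""
    vel = integrate_velocity(win)
    mag = speed_magnitude(vel)
    series = detrend_linear(mag, win.time_s) if detrend else mag
    return tpv_percent(series, win.time_s, win.R, win.A)


def process_trial(
    trace,
    ev: TrialEvents,
    config: KinematicsConfig | None = None,
    fallback_gravity_g=None,
) -> TrialKinematics:
    """Full per-trial pipeline from a calibrated trace and one event record.

    Stage failures are converted into flags on the returned record; the batch
    never aborts on a single bad trial.
    """
    from .preprocess import CalibrationError, remove_gravity

    config = config or KinematicsConfig()
    tag = classify_trial(ev, config.response_window_ms)
    if tag not in (VALID_CORRECT, VALID_INCORRECT):
        srt = (ev.S - ev.P) * 1000.0 if ev.S is not None else float("nan")
        return TrialKinematics(ev.trial, ev.condition, tag,
                               float("nan"), float("nan"), srt,
                               float("nan"), False, (tag,))
    tm = timing(ev)
    flags: list[str] = []
    try:
        eff = remove_gravity(
            trace,
            trial_window=(ev.R, ev.A),
            rest_window=(ev.P, ev.S),
            min_rest_s=config.min_rest_s,
            fallback_gravity_g=fallback_gravity_g,
        )
        flags.extend(eff.flags)
        win = extract_window(eff, ev.R, ev.A)
        res = process_window(win, detrend=config.detrend)
        if res.retained:
            res_list, exc = filter_tpv([res], config.filter_lo, config.filter_hi)
            if exc:
                res = exc[0]
        if res.exclusion_reason:
            flags.append(res.exclusion_reason)
        return TrialKinematics(ev.trial, ev.condition, tag,
                               tm.rt_ms, tm.md_ms, tm.srt_ms,
                               res.tpv_percent, res.retained, tuple(flags))
    except (WindowTooShortError, CalibrationError, ValueError) as exc:
        flags.append(f"stage_error:{exc}")
        return TrialKinematics(ev.trial, ev.condition, tag,
                               tm.rt_ms, tm.md_ms, tm.srt_ms,
                               float("nan"), False, tuple(flags))
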