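"""Raw-trace calibration and gravity removal.

The raw record is in g and contains the gravity reaction plus sensor bias.
Calibration estimates per-axis offsets from rest windows (hand resting on the
start sensor), and gravity removal subtracts the per-trial rest-window mean
vector before converting to m/s².  Orientation is assumed fixed within a
trial — the device carries no gyroscope, so exact gravity tracking during the
reach is impossible and the residual shows up as the slow drift that the
downstream detrending stage is designed to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .profiles import STANDARD_GRAVITY
from .sensor import AccelTrace


class CalibrationError(RuntimeError):
    """No usable rest window, or rest data inconsistent with stillness."""


@dataclass
class CalibrationReport:
    """Estimated sensor offsets and the windows they came from."""

    bias_g: np.ndarray
    scale: float
    rest_windows: list
    residual_g: float  # | |mean rest vector| - 1 g | after correction

    def to_dict(self) -> dict:
        return dict(
            bias_g=[float(b) for b in self.bias_g],
            scale=float(self.scale),
            rest_windows=[[float(a), float(b)] for a, b in self.rest_windows],
            residual_g=float(self.residual_g),
        )


@dataclass
class EffectiveAccel:
    """Per-axis acceleration in m/s² with gravity and offsets removed."""

    time_s: np.ndarray
    acc_ms2: np.ndarray
    provenance: dict = field(default_factory=dict)
    flags: tuple = ()


def _window_slice(trace: AccelTrace, t0: float, t1: float) -> slice:
    i0 = int(np.searchsorted(trace.time_s, t0, side="left"))
    i1 = int(np.searchsorted(trace.time_s, t1, side="right"))
    return slice(i0, i1)


def calibrate(
    trace: AccelTrace,
    rest_windows,
    mode: str = "reference",
    reference=(0.0, 0.0, 1.0),
    min_window_s: float = 0.5,
) -> tuple[AccelTrace, CalibrationReport]:
    """Estimate and remove per-axis offsets using rest windows.

    ``mode="reference"`` (default) assumes the resting posture places gravity
    along ``reference`` in the sensor frame (the task guarantees the hand is
    flat on the start sensor), so the bias is the rest mean minus that unit
    vector.  ``mode="radial"`` makes no directional assumption and removes
    only the radial excess, bias = mean − mean/|mean|, which cannot see bias
    components orthogonal to gravity.  A scalar scale maps the corrected rest
    magnitude to exactly 1 g.
    """
    usable = [(t0, t1) for t0, t1 in rest_windows if t1 - t0 >= min_window_s]
    if not usable:
        raise CalibrationError(
            f"no rest window of at least {min_window_s} s among {len(list(rest_windows))} candidates"
        )
    ref = np.asarray(reference, dtype=float)
    ref = ref / np.linalg.norm(ref)

    means, weights = [], []
    for t0, t1 in usable:
        sl = _window_slice(trace, t0, t1)
        if sl.stop - sl.start < 2:
            continue
        means.append(trace.acc_g[sl].mean(axis=0))
        weights.append(sl.stop - sl.start)
    if not means:
        raise CalibrationError("rest windows contain no samples")
    mean = np.average(means, axis=0, weights=weights)

    if mode == "reference":
        bias = mean - ref
    elif mode == "radial":
        bias = mean - mean / np.linalg.norm(mean)
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")

    corrected_mean = mean - bias
    scale = float(np.linalg.norm(corrected_mean))
    if scale <= 0:
        raise CalibrationError("degenerate rest vector")

    acc = (trace.acc_g - bias) / scale
    out = AccelTrace(trace.time_s, acc, trace.sample_rate_hz,
                     trace.range_g, trace.resolution_bits)
    resid = abs(np.linalg.norm(corrected_mean / scale) - 1.0)
    return out, CalibrationReport(bias_g=bias, scale=scale,
                                  rest_windows=usable, residual_g=resid)


def remove_gravity(
    trace: AccelTrace,
    trial_window: tuple,
    rest_window: tuple,
    min_rest_s: float = 0.2,
    rest_tolerance_g: float = 0.05,
    lowpass_hz: float | None = None,
    fallback_gravity_g: np.ndarray | None = None,
) -> EffectiveAccel:
    """Effective acceleration of one trial, in m/s².

    Subtracts the mean vector over the trial's rest window (hand still on the
    start sensor before the stimulus) from every sample in the trial window,
    then converts g → m/s².  The rest window must precede the movement; if it
    is too short or not still, the trial is flagged and, when available, a
    session-level gravity estimate is used instead.
    """
    flags = []
    t0, t1 = trial_window
    r0, r1 = rest_window

    rsl = _window_slice(trace, r0, r1)
    grav = None
    if r1 - r0 >= min_rest_s and rsl.stop - rsl.start >= 2:
        seg = trace.acc_g[rsl]
        grav = seg.mean(axis=0)
        if seg.std(axis=0).max() > rest_tolerance_g:
            flags.append("rest_window_not_still")
        if abs(np.linalg.norm(grav) - 1.0) > rest_tolerance_g:
            flags.append("rest_magnitude_off")
    else:
        flags.append("rest_window_too_short")

    if grav is None or "rest_window_not_still" in flags:
        if fallback_gravity_g is not None:
            grav = np.asarray(fallback_gravity_g, dtype=float)
            flags.append("used_fallback_gravity")
        elif grav is None:
            raise CalibrationError("no rest window and no fallback gravity vector")

    sl = _window_slice(trace, t0, t1)
    t = trace.time_s[sl]
    acc = (trace.acc_g[sl] - grav) * STANDARD_GRAVITY
    if lowpass_hz is not None:
        nyq = trace.sample_rate_hz / 2.0
        b, a = butter(2, lowpass_hz / nyq)
        acc = filtfilt(b, a, acc, axis=0)
    return EffectiveAccel(
        time_s=t,
        acc_ms2=acc,
        provenance=dict(gravity_g=[float(g) for g in grav],
                        rest_window=[float(r0), float(r1)],
                        lowpass_hz=lowpass_hz),
        flags=tuple(flags),
    )
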