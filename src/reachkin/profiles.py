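"""Ground-truth reaching kinematics.

Two analytic profile families are provided:

* a minimum-jerk reach, whose rest-to-rest speed profile is the classic
  symmetric bell with its peak at 50% of movement duration, and
* an asymmetric reach with an exactly controllable time-to-peak-velocity
  fraction, built from a beta-shaped speed bump.

Both return position, velocity and acceleration sampled on a uniform grid so
that downstream numerical integration can be checked against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, betaln

#: standard gravity, m/s^2 per g
STANDARD_GRAVITY = 9.80665


@dataclass(frozen=True)
class KinematicProfile:
    """Sampled ground-truth kinematics of a single straight reach.

    Attributes
    ----------
    t : seconds, uniform grid starting at 0.
    pos, vel, acc : (n, 3) arrays in m, m/s, m/s^2 (body frame).
    true_tpv_frac : fraction of the duration at which speed peaks, in (0, 1).
    duration_s, amplitude_m : nominal movement duration and straight-line
        amplitude of the reach.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    true_tpv_frac: float
    duration_s: float
    amplitude_m: float

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def speed(self) -> np.ndarray:
        """Euclidean norm of the velocity, m/s."""
        return np.linalg.norm(self.vel, axis=1)


def _time_grid(duration_s: float, sample_rate_hz: float) -> np.ndarray:
    n = int(round(duration_s * sample_rate_hz))
    if n < 2:
        raise ValueError(
            f"duration {duration_s} s at {sample_rate_hz} Hz yields fewer than "
            "3 samples"
        )
    return np.arange(n + 1) / sample_rate_hz


def _unit_axis(axis) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    if a.shape != (3,):
        raise ValueError("axis must be a 3-vector")
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    return a / norm


def gen_min_jerk_reach(
    duration_s: float,
    amplitude_m: float,
    sample_rate_hz: float = 100.0,
    axis=(1.0, 0.0, 0.0),
) -> KinematicProfile:
    """Minimum-jerk rest-to-rest reach along a straight line.

    Position follows x(tau) = A (10 tau^3 - 15 tau^4 + 6 tau^5) with
    tau = t/T; velocity and acceleration are its analytic derivatives.
    Speed peaks at tau = 1/2 with value 1.875 A/T.
    """
    if duration_s <= 0 or amplitude_m <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration, amplitude and sample rate must be positive")
    t = _time_grid(duration_s, sample_rate_hz)
    tau = np.clip(t / duration_s, 0.0, 1.0)
    x = amplitude_m * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    v = amplitude_m / duration_s * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    a = amplitude_m / duration_s**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    u = _unit_axis(axis)
    return KinematicProfile(
        t=t,
        pos=np.outer(x, u),
        vel=np.outer(v, u),
        acc=np.outer(a, u),
        true_tpv_frac=0.5,
        duration_s=duration_s,
        amplitude_m=amplitude_m,
    )


def gen_asymmetric_reach(
    duration_s: float,
    amplitude_m: float,
    tpv_frac: float,
    sample_rate_hz: float = 100.0,
    concentration: float = 6.0,
    axis=(1.0, 0.0, 0.0),
) -> KinematicProfile:
    """Straight reach whose speed bump peaks at an exact, chosen fraction.

    The speed profile is a rescaled beta-function bump,
    s(tau) ∝ tau^a (1-tau)^b with a = c·m, b = c·(1-m), whose mode sits at
    a/(a+b) = m = ``tpv_frac`` exactly, for any concentration c.  The
    concentration is raised automatically when needed so that min(a, b) > 1,
    keeping the acceleration finite and zero at both endpoints.  The integral
    of speed equals ``amplitude_m`` (closed form via the beta function), and
    position is the regularized incomplete beta function.
    """
    if not 0.0 < tpv_frac < 1.0:
        raise ValueError("tpv_frac must lie strictly between 0 and 1")
    if duration_s <= 0 or amplitude_m <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration, amplitude and sample rate must be positive")
    m = float(tpv_frac)
    c = max(concentration, 1.2 / min(m, 1.0 - m))
    a_sh = c * m
    b_sh = c * (1.0 - m)

    t = _time_grid(duration_s, sample_rate_hz)
    tau = np.clip(t / duration_s, 0.0, 1.0)
    lnB = betaln(a_sh + 1.0, b_sh + 1.0)

    interior = (tau > 0.0) & (tau < 1.0)
    ti = tau[interior]
    log_bump = a_sh * np.log(ti) + b_sh * np.log1p(-ti) - lnB

    v = np.zeros_like(tau)
    v[interior] = amplitude_m / duration_s * np.exp(log_bump)

    # dv/dt = v(tau) * (a/tau - b/(1-tau)) / T ; endpoints are zero because
    # min(a, b) > 1.
    a_arr = np.zeros_like(tau)
    a_arr[interior] = v[interior] * (a_sh / ti - b_sh / (1.0 - ti)) / duration_s

    x = amplitude_m * betainc(a_sh + 1.0, b_sh + 1.0, tau)

    u = _unit_axis(axis)
    return KinematicProfile(
        t=t,
        pos=np.outer(x, u),
        vel=np.outer(v, u),
        acc=np.outer(a_arr, u),
        true_tpv_frac=m,
        duration_s=duration_s,
        amplitude_m=amplitude_m,
    )
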