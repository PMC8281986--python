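"""Wrist-accelerometer forward model.

Turns ground-truth body acceleration into the record a MEMS wrist sensor
would log: rotation into the sensor frame, the 1 g gravity reaction, per-axis
bias, white noise, range clipping and ADC quantization.  Defaults mirror a
GENEActiv-class device: ±8 g range, 12-bit resolution (one LSB = 3.90625 mg),
100 Hz logging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import STANDARD_GRAVITY, KinematicProfile


@dataclass
class AccelTrace:
    """Timestamped 3-axis acceleration record, in g.

    ``acc_g`` has shape (n, 3) with columns x, y, z.
    """

    time_s: np.ndarray
    acc_g: np.ndarray
    sample_rate_hz: float
    range_g: float = 8.0
    resolution_bits: int = 12

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.acc_g = np.asarray(self.acc_g, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.acc_g.shape != (self.time_s.size, 3):
            raise ValueError("acc_g must have shape (n, 3)")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    def window(self, t0: float, t1: float) -> "AccelTrace":
        """Sub-trace with timestamps snapped to the nearest samples of [t0, t1]."""
        i0 = int(np.argmin(np.abs(self.time_s - t0)))
        i1 = int(np.argmin(np.abs(self.time_s - t1)))
        if i1 - i0 < 1:
            raise ValueError("window too short")
        return AccelTrace(
            self.time_s[i0 : i1 + 1],
            self.acc_g[i0 : i1 + 1],
            self.sample_rate_hz,
            self.range_g,
            self.resolution_bits,
        )


def _rotation_matrix(orientation) -> np.ndarray:
    R = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 rotation matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("orientation must be orthonormal")
    return R


def rotation_about(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_rad`` (Rodrigues formula)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass
class SensorParams:
    """MEMS accelerometer parameters.

    ``orientation`` maps the body/world frame to the sensor frame (identity
    by default, i.e. gravity shows up on the sensor +z axis at rest).
    ``orientation_drift_rad_s`` optionally applies a slow additional rotation
    about ``drift_axis`` over time, as an orientation-instability stress test.
    """

    sample_rate_hz: float = 100.0
    range_g: float = 8.0
    resolution_bits: int = 12
    bias_g: tuple = (0.0, 0.0, 0.0)
    noise_sd_g: float = 0.003
    orientation: np.ndarray | None = None
    gravity_axis: int = 2
    orientation_drift_rad_s: float = 0.0
    drift_axis: tuple = (0.0, 1.0, 0.0)

    def __post_init__(self):
        if self.sample_rate_hz <= 0 or self.range_g <= 0 or self.resolution_bits < 2:
            raise ValueError("invalid sensor parameters")
        if self.noise_sd_g < 0:
            raise ValueError("noise SD must be non-negative")
        self.orientation = _rotation_matrix(self.orientation)

    @property
    def quantization_step_g(self) -> float:
        """ADC step: full scale span divided by the code count."""
        return 2.0 * self.range_g / 2.0**self.resolution_bits

    @property
    def gravity_unit(self) -> np.ndarray:
        g = np.zeros(3)
        g[self.gravity_axis] = 1.0
        return g


def quantize(values_g: np.ndarray, step_g: float) -> np.ndarray:
    """Round to the nearest ADC code (round-half-even like a real converter)."""
    return np.round(values_g / step_g) * step_g


def sense_array(
    t: np.ndarray,
    acc_body_ms2: np.ndarray,
    sensor: SensorParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the full sensor chain to body acceleration; returns g units."""
    R = sensor.orientation
    a_g = acc_body_ms2 / STANDARD_GRAVITY
    if sensor.orientation_drift_rad_s != 0.0:
        out = np.empty_like(a_g)
        for i, (ti, ai) in enumerate(zip(t, a_g)):
            Rd = rotation_about(sensor.drift_axis, sensor.orientation_drift_rad_s * ti) @ R
            out[i] = Rd @ (ai + sensor.gravity_unit)
        a_sensor = out
    else:
        a_sensor = (a_g + sensor.gravity_unit) @ R.T
    a_sensor = a_sensor + np.asarray(sensor.bias_g, dtype=float)
    if sensor.noise_sd_g > 0:
        if rng is None:
            rng = np.random.default_rng()
        a_sensor = a_sensor + rng.normal(0.0, sensor.noise_sd_g, a_sensor.shape)
    a_sensor = np.clip(a_sensor, -sensor.range_g, sensor.range_g)
    return quantize(a_sensor, sensor.quantization_step_g)


def sense(
    profile: KinematicProfile,
    sensor: SensorParams,
    seed: int | np.random.Generator | None = None,
) -> AccelTrace:
    """Record a kinematic profile through the sensor model.

    The profile must be sampled at the sensor rate or an integer multiple of
    it; excess samples are decimated by striding.
    """
    ratio = profile.sample_rate_hz / sensor.sample_rate_hz
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-6:
        raise ValueError(
            "profile must be sampled at an integer multiple of the sensor rate"
        )
    t = profile.t[::stride]
    acc = profile.acc[::stride]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return AccelTrace(
        time_s=t,
        acc_g=sense_array(t, acc, sensor, rng),
        sample_rate_hz=sensor.sample_rate_hz,
        range_g=sensor.range_g,
        resolution_bits=sensor.resolution_bits,
    )
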