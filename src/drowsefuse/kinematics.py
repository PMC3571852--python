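"""Vehicle speed from accelerometer magnitude, plus temperature validation.

Speed is derived from the Euclidean magnitude of the three-axis
accelerometer reading: SP = (|a| - C) * 3.6, with C standard gravity
(9.80665 m/s^2).  The formula converts the magnitude's deviation from 1 g
into km/h; negative deviations (magnitude below gravity) clamp to zero.
An optional trapezoidal integrating estimator is provided as a clearly
separate alternative for users who want velocity from integrated
longitudinal acceleration instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "STANDARD_GRAVITY",
    "GRAVITY_KMH_PER_S",
    "AccelSample",
    "SpeedEstimate",
    "TemperatureReading",
    "speed_from_accel",
    "speed_series",
    "smooth_speed",
    "integrated_speed",
    "validate_temperature",
]

log = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665  # m/s^2
#: standard gravity expressed per second in km/h units: 9.80665 * 3.6
GRAVITY_KMH_PER_S = STANDARD_GRAVITY * 3.6


@dataclass(frozen=True)
class AccelSample:
    timestamp: float
    x_axis: float
    y_axis: float
    z_axis: float

    def __post_init__(self):
        if not all(np.isfinite([self.x_axis, self.y_axis, self.z_axis])):
            raise ConfigError("accelerometer components must be finite")


@dataclass(frozen=True)
class SpeedEstimate:
    raw_magnitude: float  # m/s^2, Euclidean norm of the reading
    speed_kmh: float
    gravity_constant: float = STANDARD_GRAVITY
    timestamp: float = 0.0


@dataclass(frozen=True)
class TemperatureReading:
    timestamp: float
    celsius: float
    in_band: bool = True


def speed_from_accel(sample: AccelSample, c: float = STANDARD_GRAVITY) -> SpeedEstimate:
    """Speed in km/h from one accelerometer sample.

    Magnitudes below ``c`` would give negative speed; these clamp to 0.
    """
    if c <= 0:
        raise ConfigError("gravity constant must be positive")
    mag = float(np.sqrt(sample.x_axis**2 + sample.y_axis**2 + sample.z_axis**2))
    kmh = (mag - c) * 3.6
    if kmh < 0:
        log.debug("accel magnitude %.3f below gravity; clamping speed to 0", mag)
        kmh = 0.0
    return SpeedEstimate(
        raw_magnitude=mag, speed_kmh=kmh, gravity_constant=c, timestamp=sample.timestamp
    )


def speed_series(
    timestamps: np.ndarray, xyz: np.ndarray, c: float = STANDARD_GRAVITY
) -> np.ndarray:
    """Vectorized speed (km/h) for an N x 3 accelerometer array."""
    if c <= 0:
        raise ConfigError("gravity constant must be positive")
    mag = np.linalg.norm(np.asarray(xyz, dtype=float), axis=1)
    return np.maximum((mag - c) * 3.6, 0.0)


def smooth_speed(timestamps: np.ndarray, speeds: np.ndarray, window: float = 2.0) -> np.ndarray:
    """Trailing moving-average over ``window`` seconds; preserves length."""
    if window <= 0:
        raise ConfigError("window must be positive")
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(speeds, dtype=float)
    out = np.empty_like(v)
    start = np.searchsorted(t, t - window, side="right")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(v.size):
        lo = min(start[i], i)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return np.maximum(out, 0.0)


def integrated_speed(
    timestamps: np.ndarray, xyz: np.ndarray, c: float = STANDARD_GRAVITY
) -> np.ndarray:
    """Alternative estimator: trapezoidal integral of the magnitude deviation.

    Treats (|a| - c) as a longitudinal acceleration and integrates it to a
    velocity (km/h).  Provided for comparison only; the primary estimator is
    :func:`speed_from_accel`.
    """
    t = np.asarray(timestamps, dtype=float)
    dev = np.linalg.norm(np.asarray(xyz, dtype=float), axis=1) - c
    vel = np.concatenate([[0.0], np.cumsum(0.5 * (dev[1:] + dev[:-1]) * np.diff(t))])
    return np.maximum(vel * 3.6, 0.0)


def validate_temperature(
    reading: TemperatureReading, band: tuple[float, float] = (-20.0, 60.0)
) -> TemperatureReading:
    """Flag readings outside the plausibility band (edges inclusive).

    In-band readings pass through unchanged; out-of-band readings come back
    with ``in_band=False`` and are excluded from fusion by the pipeline.
    """
    lo, hi = band
    ok = lo <= reading.celsius <= hi
    if not ok:
        log.warning("temperature %.1f C outside plausibility band [%s, %s]",
                    reading.celsius, lo, hi)
    return TemperatureReading(reading.timestamp, reading.celsius, in_band=ok)
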