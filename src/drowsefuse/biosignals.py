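"""ECG heart rate and PPG-derived blood pressure.

Heart rate comes from R-R intervals of the ECG, detected with a
Pan-Tompkins-style chain (bandpass, derivative, squaring, moving-window
integration, adaptive threshold with a refractory period).  Blood pressure
uses the linear surrogate BP = a*PP - b, where PP is the interval from a
PPG systolic peak to the following valley within one pulse cycle and (a, b)
are subject-calibration constants supplied by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, InsufficientBufferError, InsufficientDataError

__all__ = [
    "SignalTrace",
    "RPeakSeries",
    "HeartRate",
    "PulseCycle",
    "CalibrationConstants",
    "BloodPressure",
    "detect_r_peaks",
    "heart_rate",
    "sdnn",
    "detect_ppg_cycles",
    "blood_pressure",
]

MIN_PPG_BUFFER = 15  # below this, spurious extra peaks/valleys are likely


@dataclass
class SignalTrace:
    """A timestamped scalar stream (ECG in mV, PPG in a.u., temperature in C)."""

    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float | None = None

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ConfigError("trace needs >= 2 samples with matching timestamps")
        if np.any(np.diff(t) <= 0):
            raise ConfigError("timestamps must be strictly increasing")
        self.timestamps, self.values = t, v

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def rate(self) -> float:
        """Nominal sampling rate, estimated from median spacing if unset."""
        if self.nominal_rate:
            return float(self.nominal_rate)
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass(frozen=True)
class RPeakSeries:
    peak_times: np.ndarray
    rr_intervals: np.ndarray  # successive differences, seconds


@dataclass(frozen=True)
class HeartRate:
    bpm: float
    window_start: float
    window_end: float

    def __post_init__(self):
        if not self.bpm > 0:
            raise ConfigError("bpm must be positive")


@dataclass(frozen=True)
class PulseCycle:
    peak_time: float
    valley_time: float

    @property
    def pp(self) -> float:
        """Peak-to-valley interval, seconds."""
        return self.valley_time - self.peak_time


@dataclass(frozen=True)
class CalibrationConstants:
    """Slope/offset of the linear PP -> pressure map (mmHg/s, mmHg)."""

    a: float
    b: float

    def __post_init__(self):
        if self.a == 0:
            raise ConfigError("calibration slope a must be nonzero")


@dataclass(frozen=True)
class BloodPressure:
    mmHg: float
    cycle_time: float


# ---------------------------------------------------------------------------
# ECG


def _uniform(trace: SignalTrace) -> tuple[np.ndarray, float, float]:
    """Resample onto a uniform grid at the trace's nominal rate."""
    fs = trace.rate
    t0, t1 = trace.timestamps[0], trace.timestamps[-1]
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    return np.interp(grid, trace.timestamps, trace.values), fs, float(t0)


def detect_r_peaks(ecg: SignalTrace, min_rr: float = 0.25) -> RPeakSeries:
    """Detect ECG R peaks (Pan-Tompkins-style) and their R-R intervals.

    Chain: 5-15 Hz bandpass -> derivative -> squaring -> 150 ms
    moving-window integration -> adaptive signal/noise threshold with a
    ``min_rr`` refractory period.  Peak times are refined to the bandpassed
    maximum within +-80 ms of each integrator crest.
    """
    if ecg.duration < 2.0:
        raise InsufficientDataError("ECG trace shorter than 2 s")
    if ecg.rate < 50:
        raise ConfigError(f"ECG sampling rate {ecg.rate:.1f} Hz too low (need >= 50)")
    x, fs, t0 = _uniform(ecg)
    if np.ptp(x) == 0:
        raise InsufficientDataError("flatline ECG trace")

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq], btype="band")
    band = sps.filtfilt(b, a, x)
    deriv = np.gradient(band) * fs
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    crest_idx, _ = sps.find_peaks(integ, distance=max(int(round(min_rr * fs)), 1))
    if crest_idx.size < 2:
        raise InsufficientDataError("fewer than 2 candidate beats")

    # adaptive signal/noise levels, classic Pan-Tompkins running estimates
    spki = float(np.percentile(integ[crest_idx], 90))
    npki = float(np.percentile(integ, 50))
    accepted = []
    for i in crest_idx:
        thr = npki + 0.25 * (spki - npki)
        if integ[i] >= thr:
            if accepted and (i - accepted[-1]) < int(round(min_rr * fs)):
                if integ[i] > integ[accepted[-1]]:
                    accepted[-1] = i
                continue
            accepted.append(int(i))
            spki = 0.125 * integ[i] + 0.875 * spki
        else:
            npki = 0.125 * integ[i] + 0.875 * npki
    if len(accepted) < 2:
        raise InsufficientDataError("fewer than 2 accepted beats")

    # refine: the R wave is the bandpassed maximum near the integrator crest
    half = int(round(0.080 * fs))
    refined = []
    for i in accepted:
        lo, hi = max(i - half, 0), min(i + half + 1, band.size)
        refined.append(lo + int(np.argmax(band[lo:hi])))
    peaks = t0 + np.unique(refined) / fs
    rr = np.diff(peaks)
    keep = rr > 0
    return RPeakSeries(peak_times=peaks, rr_intervals=rr[keep])


def heart_rate(rpeaks: RPeakSeries) -> HeartRate:
    """Mean-RR heart rate in beats per minute."""
    if rpeaks.rr_intervals.size < 1:
        raise InsufficientDataError("no RR intervals")
    return HeartRate(
        bpm=60.0 / float(np.mean(rpeaks.rr_intervals)),
        window_start=float(rpeaks.peak_times[0]),
        window_end=float(rpeaks.peak_times[-1]),
    )


def sdnn(rpeaks: RPeakSeries) -> float:
    """Standard deviation of RR intervals (s) — optional HRV diagnostic."""
    if rpeaks.rr_intervals.size < 2:
        raise InsufficientDataError("need >= 2 RR intervals for SDNN")
    return float(np.std(rpeaks.rr_intervals, ddof=1))


# ---------------------------------------------------------------------------
# PPG


def detect_ppg_cycles(
    ppg: SignalTrace, min_cycle: float = 0.4, max_pp: float = 2.0
) -> list[PulseCycle]:
    """Pair each PPG systolic peak with the following valley.

    Peaks and valleys are prominence-gated local extrema separated by at
    least ``min_cycle`` seconds.  Buffers below 15 samples are rejected:
    with so few points spurious extra extrema are likely.  Pairs longer
    than ``max_pp`` are discarded — they arise from recording gaps, not
    pulse cycles.
    """
    if min_cycle <= 0:
        raise ConfigError("min_cycle must be positive")
    if ppg.timestamps.size < MIN_PPG_BUFFER:
        raise InsufficientBufferError(
            f"PPG buffer has {ppg.timestamps.size} samples, need >= {MIN_PPG_BUFFER}"
        )
    x, fs, t0 = _uniform(ppg)
    dist = max(int(round(min_cycle * fs)), 1)
    prom = 0.25 * np.ptp(x)
    if prom == 0:
        return []
    peaks, _ = sps.find_peaks(x, distance=dist, prominence=prom)
    valleys, _ = sps.find_peaks(-x, distance=dist, prominence=prom)
    cycles: list[PulseCycle] = []
    for i, p in enumerate(peaks):
        nxt = valleys[valleys > p]
        if nxt.size == 0:
            continue
        v = nxt[0]
        if i + 1 < peaks.size and v >= peaks[i + 1]:
            continue  # no valley before the next peak
        if (v - p) / fs > max_pp:
            continue
        cycles.append(PulseCycle(peak_time=t0 + p / fs, valley_time=t0 + v / fs))
    return cycles


def blood_pressure(pp: float, cal: CalibrationConstants, cycle_time: float = 0.0) -> BloodPressure:
    """Linear pulse-interval surrogate: pressure = a*PP - b (mmHg)."""
    if pp <= 0:
        raise ConfigError("PP interval must be positive")
    return BloodPressure(mmHg=cal.a * pp - cal.b, cycle_time=cycle_time)
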