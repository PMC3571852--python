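"""Synthetic five-modality session generator with ground truth.

Emulates a driving-simulator recording session: an ECG spike train with
state-dependent rate and variability, a PPG pulse waveform with a known
peak-to-valley interval, an eye-openness stream with fast blinks when awake
and slow droops when drowsy, an accelerometer stream whose Euclidean
magnitude encodes a target speed, and a temperature stream.  Every
generator also returns the ground truth needed to score its detector
(true beat times, true pulse peak/valley times, true openness, face/eye
geometry, per-segment state labels).

Waveform realism is deliberately minimal — templated pulses plus Gaussian
noise — because the downstream detectors are threshold/extremum based.
Default state parameters are chosen to be physiologically plausible and
well separated across the awake/drowsy boundary used by the default fusion
network: awake 75 bpm / PP 0.30 s / 22 degC / 30 km/h / rare 0.2 s blinks,
drowsy 52 bpm / PP 0.42 s / 29 degC / 85 km/h / droops covering 35 % of
the time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError
from .biosignals import SignalTrace
from .vision import EyeOpennessSeries, Frame

__all__ = [
    "StateParams",
    "Segment",
    "SessionSpec",
    "GroundTruth",
    "Session",
    "FaceGeometry",
    "AWAKE_PARAMS",
    "DROWSY_PARAMS",
    "synth_ecg",
    "synth_ppg",
    "synth_eye_stream",
    "synth_accel",
    "synth_temperature",
    "synth_session",
    "render_face_frame",
]


@dataclass(frozen=True)
class StateParams:
    """Per-state generator parameters (one set for awake, one for drowsy)."""

    hr_bpm: float = 75.0
    rr_jitter_s: float = 0.04
    pp_s: float = 0.30
    blink_rate_per_min: float = 15.0
    blink_duration_s: float = 0.2
    droop_fraction: float = 0.0
    droop_period_s: float = 4.0
    temperature_c: float = 22.0
    temperature_noise_c: float = 0.1
    speed_kmh: float = 30.0
    speed_noise_kmh: float = 0.0
    ecg_noise: float = 0.05
    ppg_noise: float = 0.02


AWAKE_PARAMS = StateParams()
DROWSY_PARAMS = StateParams(
    hr_bpm=52.0,
    rr_jitter_s=0.015,
    pp_s=0.42,
    blink_rate_per_min=4.0,
    blink_duration_s=0.3,
    droop_fraction=0.35,
    temperature_c=29.0,
    speed_kmh=85.0,
)


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    state: str  # 'awake' | 'drowsy'


@dataclass
class SessionSpec:
    duration: float = 240.0
    seed: int = 0
    segments: tuple[Segment, ...] = ()
    params: dict[str, StateParams] = field(default_factory=dict)
    frame_rate: float = 5.0
    ecg_rate: float = 250.0
    ppg_rate: float = 50.0
    accel_rate: float = 10.0
    temp_rate: float = 1.0

    def __post_init__(self):
        if not self.segments:
            half = self.duration / 2.0
            self.segments = (
                Segment(0.0, half, "awake"),
                Segment(half, self.duration, "drowsy"),
            )
        self.segments = tuple(self.segments)
        if not self.params:
            self.params = {"awake": AWAKE_PARAMS, "drowsy": DROWSY_PARAMS}
        t = 0.0
        for seg in self.segments:
            if abs(seg.start - t) > 1e-9 or seg.end <= seg.start:
                raise ConfigError("segments must tile [0, duration] without gaps/overlap")
            if seg.state not in self.params:
                raise ConfigError(f"no parameters for state {seg.state!r}")
            t = seg.end
        if abs(t - self.duration) > 1e-9:
            raise ConfigError("segments must end exactly at the session duration")
        for name, p in self.params.items():
            if not (30.0 <= p.hr_bpm <= 200.0):
                raise ConfigError(f"{name}: mean HR {p.hr_bpm} outside [30, 200] bpm")
            if not (0.0 < p.pp_s < 60.0 / p.hr_bpm):
                raise ConfigError(f"{name}: PP must be positive and shorter than the beat period")

    def state_at(self, t: float) -> str:
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg.state
        return self.segments[-1].state

    def params_at(self, t: float) -> StateParams:
        return self.params[self.state_at(t)]

    def labels(self, times: np.ndarray) -> np.ndarray:
        return np.array([self.state_at(float(t)) for t in np.asarray(times)])


def _rngs(spec: SessionSpec, n: int = 5) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(n)]


# ---------------------------------------------------------------------------
# ECG


def synth_ecg(spec: SessionSpec, rng: np.random.Generator | None = None):
    """ECG trace plus true beat times.

    R spikes (Gaussian, amplitude 1, sigma 12 ms) ride on a flat baseline
    with a small T-wave bump; RR intervals are 60/HR plus Gaussian jitter
    for the segment state; additive noise is ``ecg_noise`` of R amplitude.
    """
    rng = rng or _rngs(spec)[0]
    beats = []
    t = 0.3
    while t < spec.duration:
        beats.append(t)
        p = spec.params_at(t)
        rr = 60.0 / p.hr_bpm + (rng.normal(0.0, p.rr_jitter_s) if p.rr_jitter_s > 0 else 0.0)
        t += max(rr, 0.3)
    beats = np.array(beats)
    grid = np.arange(0.0, spec.duration, 1.0 / spec.ecg_rate)
    x = np.zeros_like(grid)
    for b in beats:
        sel = slice(
            np.searchsorted(grid, b - 0.1), np.searchsorted(grid, b + 0.35)
        )
        dt = grid[sel] - b
        x[sel] += np.exp(-0.5 * (dt / 0.012) ** 2)  # R
        x[sel] += 0.18 * np.exp(-0.5 * ((dt - 0.22) / 0.05) ** 2)  # T
    noise = spec.params_at(0.0).ecg_noise
    if noise > 0:
        x = x + rng.normal(0.0, noise, size=x.shape)
    return SignalTrace(grid, x, nominal_rate=spec.ecg_rate), beats


# ---------------------------------------------------------------------------
# PPG


def synth_ppg(spec: SessionSpec, rng: np.random.Generator | None = None):
    """PPG trace plus true peak times, valley times and per-cycle PP.

    Each cycle runs valley -> peak -> valley over one beat period T; the
    systolic peak sits PP seconds before the closing valley, so the
    peak-to-valley interval equals the state's PP exactly.
    """
    rng = rng or _rngs(spec)[1]
    valleys, peaks, pps = [0.0], [], []
    v = 0.0
    while True:
        p = spec.params_at(v)
        period = 60.0 / p.hr_bpm
        peak = v + (period - p.pp_s)
        nxt = v + period
        if nxt >= spec.duration:
            break
        peaks.append(peak)
        pps.append(p.pp_s)
        valleys.append(nxt)
        v = nxt
    grid = np.arange(0.0, spec.duration, 1.0 / spec.ppg_rate)
    x = np.zeros_like(grid)
    for v0, pk, v1 in zip(valleys[:-1], peaks, valleys[1:]):
        rise = (grid >= v0) & (grid < pk)
        fall = (grid >= pk) & (grid < v1)
        x[rise] = 0.5 - 0.5 * np.cos(np.pi * (grid[rise] - v0) / (pk - v0))
        x[fall] = 0.5 + 0.5 * np.cos(np.pi * (grid[fall] - pk) / (v1 - pk))
    noise = spec.params_at(0.0).ppg_noise
    if noise > 0:
        x = x + rng.normal(0.0, noise, size=x.shape)
    return (
        SignalTrace(grid, x, nominal_rate=spec.ppg_rate),
        np.array(peaks),
        np.array(valleys[1:]),
        np.array(pps),
    )


# ---------------------------------------------------------------------------
# eyes


def synth_eye_stream(spec: SessionSpec, rng: np.random.Generator | None = None) -> EyeOpennessSeries:
    """Eye-openness stream: fast blinks when awake, slow droops when drowsy.

    Awake segments place ``blink_duration_s`` blinks with exponential
    inter-blink gaps at the state blink rate.  Drowsy segments close the
    eyes for ``droop_fraction`` of every ``droop_period_s`` cycle
    (deterministic duty cycle, so windowed PERCLOS equals the droop
    fraction by construction), with residual blinks on top.
    """
    rng = rng or _rngs(spec)[2]
    times = np.arange(0.0, spec.duration, 1.0 / spec.frame_rate)
    openness = np.ones_like(times)
    for seg in spec.segments:
        p = spec.params[seg.state]
        in_seg = (times >= seg.start) & (times < seg.end)
        if p.droop_fraction > 0:
            phase = (times[in_seg] - seg.start) % p.droop_period_s
            # half-open closed interval [0, fraction*period); tolerance guards
            # against frame times like 1.1999999 landing just under the edge
            droop = phase < p.droop_fraction * p.droop_period_s - 1e-6
            vals = openness[in_seg]
            vals[droop] = 0.05
            openness[in_seg] = vals
        if p.blink_rate_per_min > 0:
            t = seg.start + rng.exponential(60.0 / p.blink_rate_per_min)
            while t < seg.end:
                blink = in_seg & (times >= t) & (times < t + p.blink_duration_s)
                openness[blink] = 0.0
                t += p.blink_duration_s + rng.exponential(60.0 / p.blink_rate_per_min)
    return EyeOpennessSeries(times, openness)


@dataclass(frozen=True)
class FaceGeometry:
    """Ground-truth layout of a rendered face frame."""

    width: int = 160
    height: int = 120
    face_center: tuple[int, int] = (60, 80)  # (row, col)
    face_radii: tuple[int, int] = (40, 32)  # (row, col) semi-axes
    eye_row: int = 52
    eye_cols: tuple[int, int] = (64, 96)
    eye_width: int = 16
    eye_open_height: int = 16
    eyebrow_row: int = 34
    eyebrow_height: int = 6
    eyebrow_width: int = 16
    skin_hue: float = 20.0
    background_hue: float = 220.0

    @property
    def face_bbox(self) -> tuple[int, int, int, int]:
        (r, c), (ry, rx) = self.face_center, self.face_radii
        return (r - ry, c - rx, r + ry + 1, c + rx + 1)


def _hsv_px(h: float, s: float, v: float) -> np.ndarray:
    from skimage.color import hsv2rgb

    rgb = hsv2rgb(np.array([[[h / 360.0, s, v]]]))[0, 0]
    return np.round(rgb * 255).astype(np.uint8)


def render_face_frame(
    openness: float,
    geometry: FaceGeometry = FaceGeometry(),
    timestamp: float = 0.0,
    draw_eyebrows: bool = True,
) -> Frame:
    """Render a skin-hue face ellipse with eye holes scaled by openness.

    Eyes are dark (non-skin) rectangles whose height scales with openness;
    below roughly 1/3 openness the slit becomes thinner than the default
    morphological kernel and is closed away, which reproduces the real
    failure mode of a hole-based eye detector on closed eyes (the frame
    then scores openness 0 via the eyes-not-found convention, provided
    eyebrows are not drawn).  Eyebrow bars sit above the eyes to exercise
    the lower/larger disambiguation rule.
    """
    g = geometry
    img = np.empty((g.height, g.width, 3), dtype=np.uint8)
    img[:] = _hsv_px(g.background_hue, 0.5, 0.5)
    rr, cc = np.mgrid[0 : g.height, 0 : g.width]
    (r0, c0), (ry, rx) = g.face_center, g.face_radii
    face = ((rr - r0) / ry) ** 2 + ((cc - c0) / rx) ** 2 <= 1.0
    img[face] = _hsv_px(g.skin_hue, 0.5, 0.8)
    dark = _hsv_px(0.0, 0.05, 0.15)
    if draw_eyebrows:
        for c in g.eye_cols:
            img[
                g.eyebrow_row : g.eyebrow_row + g.eyebrow_height,
                c - g.eyebrow_width // 2 : c + g.eyebrow_width // 2,
            ] = dark
    h = int(round(g.eye_open_height * float(np.clip(openness, 0.0, 1.0))))
    if h > 0:
        for c in g.eye_cols:
            img[
                g.eye_row - h // 2 : g.eye_row - h // 2 + h,
                c - g.eye_width // 2 : c + g.eye_width // 2,
            ] = dark
    return Frame(pixels=img, timestamp=timestamp)


# ---------------------------------------------------------------------------
# accelerometer + temperature


def synth_accel(spec: SessionSpec, rng: np.random.Generator | None = None):
    """Accelerometer samples whose magnitude encodes the state's speed.

    Inverts the speed formula: |a| = C + speed/3.6, pointed along a random
    (per-session) orientation; optional Gaussian magnitude noise.
    """
    from .kinematics import STANDARD_GRAVITY

    rng = rng or _rngs(spec)[3]
    times = np.arange(0.0, spec.duration, 1.0 / spec.accel_rate)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    speeds = np.array([spec.params_at(float(t)).speed_kmh for t in times])
    noises = np.array([spec.params_at(float(t)).speed_noise_kmh for t in times])
    if np.any(noises > 0):
        speeds = np.maximum(speeds + rng.normal(0.0, 1.0, size=speeds.shape) * noises, 0.0)
    mags = STANDARD_GRAVITY + speeds / 3.6
    xyz = mags[:, None] * direction[None, :]
    return times, xyz, speeds


def synth_temperature(spec: SessionSpec, rng: np.random.Generator | None = None) -> SignalTrace:
    rng = rng or _rngs(spec)[4]
    times = np.arange(0.0, spec.duration, 1.0 / spec.temp_rate)
    vals = np.array([spec.params_at(float(t)).temperature_c for t in times])
    sigmas = np.array([spec.params_at(float(t)).temperature_noise_c for t in times])
    vals = vals + rng.normal(0.0, 1.0, size=vals.shape) * sigmas
    return SignalTrace(times, vals, nominal_rate=spec.temp_rate)


# ---------------------------------------------------------------------------
# full session


@dataclass
class GroundTruth:
    segments: tuple[Segment, ...]
    beat_times: np.ndarray
    ppg_peak_times: np.ndarray
    ppg_valley_times: np.ndarray
    ppg_pp: np.ndarray
    openness: EyeOpennessSeries
    true_speeds: np.ndarray

    def labels(self, times: np.ndarray) -> np.ndarray:
        out = np.empty(len(times), dtype=object)
        for i, t in enumerate(np.asarray(times, dtype=float)):
            out[i] = self.segments[-1].state
            for seg in self.segments:
                if seg.start <= t < seg.end:
                    out[i] = seg.state
                    break
        return out

    def to_manifest(self) -> dict:
        return {
            "segments": [asdict(s) for s in self.segments],
            "beat_times": self.beat_times.tolist(),
            "ppg_peak_times": self.ppg_peak_times.tolist(),
            "ppg_valley_times": self.ppg_valley_times.tolist(),
            "ppg_pp": self.ppg_pp.tolist(),
            "openness": {
                "timestamps": self.openness.timestamps.tolist(),
                "values": self.openness.openness.tolist(),
            },
            "true_speeds": self.true_speeds.tolist(),
        }

    @classmethod
    def from_manifest(cls, d: dict) -> "GroundTruth":
        return cls(
            segments=tuple(Segment(**s) for s in d["segments"]),
            beat_times=np.array(d["beat_times"]),
            ppg_peak_times=np.array(d["ppg_peak_times"]),
            ppg_valley_times=np.array(d["ppg_valley_times"]),
            ppg_pp=np.array(d["ppg_pp"]),
            openness=EyeOpennessSeries(
                np.array(d["openness"]["timestamps"]), np.array(d["openness"]["values"])
            ),
            true_speeds=np.array(d["true_speeds"]),
        )


@dataclass
class Session:
    spec: SessionSpec
    ecg: SignalTrace
    ppg: SignalTrace
    accel_times: np.ndarray
    accel_xyz: np.ndarray
    temperature: SignalTrace
    eyes: EyeOpennessSeries
    truth: GroundTruth


def synth_session(spec: SessionSpec, out_dir=None) -> Session:
    """Generate all five mutually time-aligned streams plus ground truth.

    With ``out_dir`` set, writes the CSV streams and a ``manifest.json``
    in exactly the formats the pipeline readers consume.
    """
    r_ecg, r_ppg, r_eye, r_acc, r_tmp = _rngs(spec)
    ecg, beats = synth_ecg(spec, r_ecg)
    ppg, peaks, valls, pps = synth_ppg(spec, r_ppg)
    eyes = synth_eye_stream(spec, r_eye)
    acc_t, acc_xyz, speeds = synth_accel(spec, r_acc)
    temp = synth_temperature(spec, r_tmp)
    truth = GroundTruth(
        segments=spec.segments,
        beat_times=beats,
        ppg_peak_times=peaks,
        ppg_valley_times=valls,
        ppg_pp=pps,
        openness=eyes,
        true_speeds=speeds,
    )
    session = Session(spec, ecg, ppg, acc_t, acc_xyz, temp, eyes, truth)
    if out_dir is not None:
        from . import io as dio
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_signal_csv(out / "ecg.csv", ecg)
        dio.write_signal_csv(out / "ppg.csv", ppg)
        dio.write_accel_csv(out / "accel.csv", acc_t, acc_xyz)
        dio.write_temperature_csv(out / "temperature.csv", temp)
        dio.write_openness_csv(out / "eyes.csv", eyes)
        with open(out / "manifest.json", "w") as fh:
            json.dump(truth.to_manifest(), fh)
    return session
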