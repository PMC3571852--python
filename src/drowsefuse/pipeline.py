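"""Session orchestration: per-tick feature extraction, fusion and scoring.

``run_pipeline`` walks the common time span of the five streams on a fixed
tick (default 0.2 s), computes each indicator from the most recent window
of its modality, fuzzifies, runs the fuzzy-Bayesian inference and records
the vigilance assessment and alert flag per tick.  A modality with no new
data at a tick is held at its last value and the record flagged stale;
ticks before a feature's first availability are backfilled from its first
computed value (and likewise flagged).

``evaluate`` scores per-tick predictions against ground-truth segment
labels into an awake/drowsy confusion table with integer percentages under
round-half-up — the same arithmetic is exposed as :func:`percent` so
published count tables can be checked directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import yaml

from . import biosignals as bs
from . import kinematics as km
from .errors import ConfigError, DrowsefuseError, InsufficientDataError, OutOfSupportError
from .fbn import FusionNetwork, default_network
from .vision import EyeOpennessSeries, compute_perclos

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SessionStreams",
    "TickRecord",
    "ConfusionTable",
    "percent",
    "run_pipeline",
    "evaluate",
    "summarize",
]

#: p_true at or above this is scored as a drowsy prediction (the lower edge
#: of the partial-sleep band).
DROWSY_DECISION = 0.60


@dataclass
class PipelineConfig:
    tick: float = 0.2
    hr_window: float = 10.0
    bp_window: float = 10.0
    perclos_window: float = 60.0
    speed_smooth_window: float = 2.0
    stale_after: float = 2.0  # newest supporting datum older than this -> stale flag
    closure_threshold: float = 0.2
    min_rr: float = 0.25
    min_cycle: float = 0.4
    calibration_a: float = -250.0  # mmHg per second of PP
    calibration_b: float = -180.0  # mmHg offset
    temperature_band: tuple[float, float] = (-20.0, 60.0)
    gravity: float = km.STANDARD_GRAVITY

    def __post_init__(self):
        if self.tick <= 0:
            raise ConfigError("tick must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "temperature_band" in d:
            d["temperature_band"] = tuple(d["temperature_band"])
        return cls(**d)


@dataclass
class SessionStreams:
    """In-memory bundle of the five input streams."""

    ecg: bs.SignalTrace
    ppg: bs.SignalTrace
    accel_times: np.ndarray
    accel_xyz: np.ndarray
    temperature: bs.SignalTrace
    eyes: EyeOpennessSeries

    @classmethod
    def from_session(cls, session) -> "SessionStreams":
        return cls(
            ecg=session.ecg,
            ppg=session.ppg,
            accel_times=session.accel_times,
            accel_xyz=session.accel_xyz,
            temperature=session.temperature,
            eyes=session.eyes,
        )

    @classmethod
    def from_dir(cls, directory, nominal_ecg_rate=None, nominal_ppg_rate=None):
        from . import io as dio

        d = Path(directory)
        acc_t, acc_xyz = dio.read_accel_csv(d / "accel.csv")
        return cls(
            ecg=dio.read_signal_csv(d / "ecg.csv", nominal_rate=nominal_ecg_rate),
            ppg=dio.read_signal_csv(d / "ppg.csv", nominal_rate=nominal_ppg_rate),
            accel_times=acc_t,
            accel_xyz=acc_xyz,
            temperature=dio.read_temperature_csv(d / "temperature.csv"),
            eyes=dio.read_openness_csv(d / "eyes.csv"),
        )


@dataclass
class TickRecord:
    t: float
    features: dict[str, float]
    stale: tuple[str, ...]
    p_true: float
    p_false: float
    state_probs: dict[str, float]
    selected_state: str
    interval_label: str
    advisory: str | None
    alert: bool

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["stale"] = list(self.stale)
        return json.dumps(d)


def _feature_tracks(streams: SessionStreams, cfg: PipelineConfig, ticks: np.ndarray):
    """Per-tick raw feature values (None where not yet computable).

    A feature is flagged stale at a tick when its window holds no data or
    its newest supporting datum is older than ``cfg.stale_after``.
    """
    n = ticks.size
    tracks: dict[str, list] = {k: [None] * n for k in ("HR", "BP", "TP", "SP", "PR")}
    fresh: dict[str, list] = {k: [None] * n for k in tracks}  # newest datum time
    stale: dict[str, list] = {k: [False] * n for k in tracks}

    # heavy detectors run once over the whole trace
    try:
        rpeaks = bs.detect_r_peaks(streams.ecg, min_rr=cfg.min_rr)
        peak_t = rpeaks.peak_times
    except InsufficientDataError:
        peak_t = np.array([])
    try:
        cycles = bs.detect_ppg_cycles(streams.ppg, min_cycle=cfg.min_cycle)
    except InsufficientDataError:
        cycles = []
    cyc_end = np.array([c.valley_time for c in cycles])
    cyc_pp = np.array([c.pp for c in cycles])
    cal = bs.CalibrationConstants(cfg.calibration_a, cfg.calibration_b)

    raw_speed = km.speed_series(streams.accel_times, streams.accel_xyz, c=cfg.gravity)
    smooth = km.smooth_speed(streams.accel_times, raw_speed, window=cfg.speed_smooth_window)

    temp_t = streams.temperature.timestamps
    temp_ok = np.array(
        [
            km.validate_temperature(
                km.TemperatureReading(float(tt), float(v)), cfg.temperature_band
            ).in_band
            for tt, v in zip(temp_t, streams.temperature.values)
        ]
    )

    eye_t = streams.eyes.timestamps
    for i, t in enumerate(ticks):
        in_win = (peak_t > t - cfg.hr_window) & (peak_t <= t)
        if in_win.sum() >= 2:
            rr = np.diff(peak_t[in_win])
            tracks["HR"][i] = 60.0 / float(np.mean(rr))
            fresh["HR"][i] = float(peak_t[in_win][-1])

        in_bp = (cyc_end > t - cfg.bp_window) & (cyc_end <= t)
        if in_bp.any():
            tracks["BP"][i] = bs.blood_pressure(float(np.mean(cyc_pp[in_bp])), cal).mmHg
            fresh["BP"][i] = float(cyc_end[in_bp][-1])

        j = np.searchsorted(temp_t, t, side="right") - 1
        while j >= 0 and not temp_ok[j]:
            j -= 1
        if j >= 0:
            tracks["TP"][i] = float(streams.temperature.values[j])
            fresh["TP"][i] = float(temp_t[j])

        j = np.searchsorted(streams.accel_times, t, side="right") - 1
        if j >= 0:
            tracks["SP"][i] = float(smooth[j])
            fresh["SP"][i] = float(streams.accel_times[j])

        # PERCLOS only once a full window of frames exists; short partial
        # windows are dominated by single blinks
        if eye_t.size and eye_t[0] <= t - cfg.perclos_window + 1e-9:
            try:
                tracks["PR"][i] = compute_perclos(
                    streams.eyes, window=cfg.perclos_window,
                    closure_threshold=cfg.closure_threshold, t_end=float(t),
                ).pr
                newest = eye_t[(eye_t > t - cfg.perclos_window) & (eye_t <= t)]
                fresh["PR"][i] = float(newest[-1])
            except InsufficientDataError:
                pass

    # staleness flags, hold-last-value, then backfill the leading gap
    for name in tracks:
        vals, flags = tracks[name], stale[name]
        last = None
        for i in range(n):
            if vals[i] is None:
                flags[i] = True
                vals[i] = last
            else:
                if ticks[i] - fresh[name][i] > cfg.stale_after:
                    flags[i] = True
                last = vals[i]
        first = next((v for v in vals if v is not None), None)
        if first is None:
            raise InsufficientDataError(f"feature {name} never became available")
        for i in range(n):
            if vals[i] is None:
                vals[i] = first
    return tracks, stale


def run_pipeline(
    streams: SessionStreams,
    network: FusionNetwork | None = None,
    cfg: PipelineConfig | None = None,
    alert_log=None,
) -> list[TickRecord]:
    """One record per tick over the common time span of all streams."""
    from .fbn import alert_decision, classify_vigilance

    network = network or default_network()
    cfg = cfg or PipelineConfig()
    starts = [
        streams.ecg.timestamps[0],
        streams.ppg.timestamps[0],
        streams.accel_times[0],
        streams.temperature.timestamps[0],
        streams.eyes.timestamps[0],
    ]
    ends = [
        streams.ecg.timestamps[-1],
        streams.ppg.timestamps[-1],
        streams.accel_times[-1],
        streams.temperature.timestamps[-1],
        streams.eyes.timestamps[-1],
    ]
    t0, t1 = max(starts), min(ends)
    if t1 <= t0:
        raise ConfigError("streams share no temporal overlap")
    ticks = np.arange(t0 + cfg.tick, t1 + 1e-9, cfg.tick)
    tracks, stale = _feature_tracks(streams, cfg, ticks)

    from .fbn import fuzzify

    records: list[TickRecord] = []
    held_vectors: dict[str, object] = {}
    alerts = []
    for i, t in enumerate(ticks):
        values = {name: tracks[name][i] for name in tracks}
        flags = [f"{name.lower()}_stale" for name in tracks if stale[name][i]]
        vectors = []
        for name in network.cpt.parent_order:
            # hold the last valid state vector if the value leaves all supports
            try:
                vec = fuzzify(values[name], network.variables[name])
                held_vectors[name] = vec
            except OutOfSupportError:
                if name not in held_vectors:
                    raise
                vec = held_vectors[name]
                flags.append(f"{name.lower()}_out_of_support")
            vectors.append(vec)
        dist = network.infer(vectors)
        assess = classify_vigilance(dist, network.intervals)
        alert = alert_decision(dist, network.alert_threshold)
        rec = TickRecord(
            t=float(t),
            features={k: float(v) for k, v in values.items()},
            stale=tuple(flags),
            p_true=dist.p_true,
            p_false=dist.p_false,
            state_probs=dist.state_probs,
            selected_state=dist.selected_state,
            interval_label=assess.interval_label,
            advisory=assess.advisory,
            alert=alert.triggered,
        )
        records.append(rec)
        if alert.triggered:
            alerts.append({"t": float(t), "p_true": dist.p_true})
    if alert_log is not None:
        with open(alert_log, "a") as fh:
            for a in alerts:
                fh.write(json.dumps(a) + "\n")
    return records


# ---------------------------------------------------------------------------
# evaluation


def percent(true_count: int, total: int) -> int:
    """Integer percentage under round-half-up."""
    if total <= 0:
        raise ConfigError("total must be positive")
    return int(
        (Decimal(100) * Decimal(true_count) / Decimal(total)).quantize(
            Decimal(1), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class ConfusionTable:
    """Awake/drowsy per-class counts with integer-rounded percentages."""

    aw_total: int
    dw_total: int
    aw_true: int
    dw_true: int

    def __post_init__(self):
        if self.aw_true > self.aw_total or self.dw_true > self.dw_total:
            raise ConfigError("true counts cannot exceed totals")

    @property
    def aw_false(self) -> int:
        return self.aw_total - self.aw_true

    @property
    def dw_false(self) -> int:
        return self.dw_total - self.dw_true

    @property
    def aw_true_pct(self) -> int:
        return percent(self.aw_true, self.aw_total)

    @property
    def aw_false_pct(self) -> int:
        return percent(self.aw_false, self.aw_total)

    @property
    def dw_true_pct(self) -> int:
        return percent(self.dw_true, self.dw_total)

    @property
    def dw_false_pct(self) -> int:
        return percent(self.dw_false, self.dw_total)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.aw_true + self.dw_true) / (self.aw_total + self.dw_total)


def summarize(tables: list[ConfusionTable]) -> ConfusionTable:
    """Aggregate row: sum counts first, then compute percentages."""
    return ConfusionTable(
        aw_total=sum(t.aw_total for t in tables),
        dw_total=sum(t.dw_total for t in tables),
        aw_true=sum(t.aw_true for t in tables),
        dw_true=sum(t.dw_true for t in tables),
    )


def evaluate(
    records: list[TickRecord],
    truth_labels: np.ndarray,
    drowsy_threshold: float = DROWSY_DECISION,
) -> ConfusionTable:
    """Score per-tick predictions against ground-truth awake/drowsy labels.

    A tick is predicted drowsy when its fused p_true reaches the
    partial-sleep band (p_true >= ``drowsy_threshold``).
    """
    labels = np.asarray(truth_labels)
    if len(records) != labels.size:
        raise ConfigError(
            f"records ({len(records)}) and truth ({labels.size}) length mismatch"
        )
    aw_total = dw_total = aw_true = dw_true = 0
    for rec, lab in zip(records, labels):
        pred_drowsy = rec.p_true >= drowsy_threshold
        if lab == "awake":
            aw_total += 1
            aw_true += not pred_drowsy
        elif lab == "drowsy":
            dw_total += 1
            dw_true += pred_drowsy
        else:
            raise ConfigError(f"unknown truth label {lab!r}")
    if aw_total == 0 or dw_total == 0:
        raise ConfigError("need both awake and drowsy ticks to evaluate")
    return ConfusionTable(aw_total=aw_total, dw_total=dw_total,
                          aw_true=aw_true, dw_true=dw_true)
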