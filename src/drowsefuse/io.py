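"""CSV / PNG / JSON readers and writers for the sensor streams.

All CSV schemas have a mandatory exact header; rows must parse as floats
(standard decimal or exponent notation, locale-independent) and timestamps
must be strictly increasing.  Violations raise StreamFormatError with the
offending 1-based line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biosignals import SignalTrace
from .errors import StreamFormatError
from .vision import EyeOpennessSeries, Frame

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_accel_csv",
    "write_accel_csv",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_openness_csv",
    "write_openness_csv",
    "write_events_csv",
    "load_frames",
    "read_manifest",
]


def _read_table(path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise StreamFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if tuple(df.columns) != columns:
        raise StreamFormatError(
            f"{path}: expected header {','.join(columns)!r}, got "
            f"{','.join(map(str, df.columns))!r}",
            line=1,
        )
    out = pd.DataFrame(index=df.index)
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        missing = vals.index[df[col].isna()]
        if len(bad):
            raise StreamFormatError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column {col}",
                line=int(bad[0]) + 2,
            )
        if len(missing):
            raise StreamFormatError(f"{path}: missing value in column {col}",
                                    line=int(missing[0]) + 2)
        out[col] = vals.astype(float)
    t = out[columns[0]].to_numpy()
    if t.size and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise StreamFormatError(f"{path}: timestamps not strictly increasing", line=i + 3)
    return out


def read_signal_csv(path, nominal_rate: float | None = None) -> SignalTrace:
    df = _read_table(path, ("timestamp", "value"))
    return SignalTrace(df["timestamp"].to_numpy(), df["value"].to_numpy(),
                       nominal_rate=nominal_rate)


def write_signal_csv(path, trace: SignalTrace) -> None:
    pd.DataFrame({"timestamp": trace.timestamps, "value": trace.values}).to_csv(
        path, index=False
    )


def read_accel_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_table(path, ("timestamp", "x", "y", "z"))
    return df["timestamp"].to_numpy(), df[["x", "y", "z"]].to_numpy()


def write_accel_csv(path, timestamps: np.ndarray, xyz: np.ndarray) -> None:
    pd.DataFrame(
        {"timestamp": timestamps, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
    ).to_csv(path, index=False)


def read_temperature_csv(path) -> SignalTrace:
    df = _read_table(path, ("timestamp", "celsius"))
    return SignalTrace(df["timestamp"].to_numpy(), df["celsius"].to_numpy())


def write_temperature_csv(path, trace: SignalTrace) -> None:
    pd.DataFrame({"timestamp": trace.timestamps, "celsius": trace.values}).to_csv(
        path, index=False
    )


def read_openness_csv(path) -> EyeOpennessSeries:
    df = _read_table(path, ("timestamp", "openness"))
    return EyeOpennessSeries(df["timestamp"].to_numpy(), df["openness"].to_numpy())


def write_openness_csv(path, series: EyeOpennessSeries) -> None:
    pd.DataFrame({"timestamp": series.timestamps, "openness": series.openness}).to_csv(
        path, index=False
    )


def write_events_csv(path, times: np.ndarray, kinds: list[str]) -> None:
    """Beat / pulse-cycle annotations as ``time,type`` rows."""
    pd.DataFrame({"time": times, "type": kinds}).to_csv(path, index=False)


def load_frames(directory, frame_rate: float) -> list[Frame]:
    """PNG frames from a directory, lexicographic order = time order."""
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(directory.glob("*.png"))
    if not paths:
        raise StreamFormatError(f"{directory}: no PNG frames found")
    frames = []
    for i, p in enumerate(paths):
        img = iio.imread(p)
        if img.ndim == 3 and img.shape[2] == 4:
            img = img[..., :3]
        frames.append(Frame(pixels=img, timestamp=i / frame_rate))
    return frames


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
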