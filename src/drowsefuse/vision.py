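"""Face/eye detection from skin-color segmentation and PERCLOS.

The vision chain mirrors what a phone-camera drowsiness monitor does per
frame: convert the camera buffer to HSV, threshold on the skin hue band to a
binary mask, clean the mask morphologically, take the largest skin component
as the face, and look for hole pairs inside it (eyes appear as non-skin
holes).  Eye openness is the combined hole area normalized by the running
session maximum, and PERCLOS (P80 by default) is the fraction of frames in a
window whose openness falls below the closure threshold.

Coordinates are 0-based with the origin at the top-left; regions are
half-open on their bottom/right edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure, morphology

from .errors import ConfigError, EyesNotFoundError, InsufficientDataError, NoFaceError

__all__ = [
    "Frame",
    "Region",
    "EyePair",
    "EyeOpennessSeries",
    "PerclosResult",
    "OpennessTracker",
    "to_hsv",
    "nv21_to_rgb",
    "rgb_to_nv21",
    "skin_mask",
    "clean_mask",
    "extract_face_region",
    "locate_eyes",
    "eye_openness",
    "compute_perclos",
]


@dataclass(frozen=True)
class Frame:
    """One camera frame.

    ``pixels`` is an ``H x W x 3`` uint8 array in the declared
    ``color_space`` ('rgb'); NV21 camera buffers are decoded with
    :func:`nv21_to_rgb` before constructing a Frame.
    """

    pixels: np.ndarray
    timestamp: float = 0.0
    color_space: str = "rgb"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ConfigError(f"frame must be H x W x 3, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Region:
    """Axis-aligned pixel region, half-open on bottom/right."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self):
        if not (self.top < self.bottom and self.left < self.right):
            raise ConfigError(
                f"degenerate region ({self.top},{self.left},{self.bottom},{self.right})"
            )

    @property
    def area(self) -> int:
        return (self.bottom - self.top) * (self.right - self.left)

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) center."""
        return ((self.top + self.bottom - 1) / 2.0, (self.left + self.right - 1) / 2.0)

    def contains(self, row: float, col: float) -> bool:
        return self.top <= row < self.bottom and self.left <= col < self.right


@dataclass(frozen=True)
class EyePair:
    """Two eye regions plus their vertical center offset (rows)."""

    left_eye: Region
    right_eye: Region
    vertical_offset: float
    combined_area: int


@dataclass
class EyeOpennessSeries:
    """Per-frame eye openness as a fraction of the session maximum."""

    timestamps: np.ndarray
    openness: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        o = np.asarray(self.openness, dtype=float)
        if t.shape != o.shape or t.ndim != 1:
            raise ConfigError("timestamps and openness must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ConfigError("timestamps must be strictly increasing")
        if o.size and (o.min() < 0 or o.max() > 1):
            raise ConfigError("openness values must lie in [0, 1]")
        self.timestamps, self.openness = t, o

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class PerclosResult:
    window_start: float
    window_end: float
    pr: float
    n_frames: int


# ---------------------------------------------------------------------------
# color conversion


_BT601 = np.array(
    [[0.299, 0.587, 0.114], [-0.168736, -0.331264, 0.5], [0.5, -0.418688, -0.081312]]
)


def rgb_to_nv21(rgb: np.ndarray) -> bytes:
    """Encode an RGB uint8 image (even H and W) as an NV21 byte buffer.

    NV21 stores a full-resolution Y plane followed by a half-resolution
    interleaved V/U plane (BT.601, full range).  Used by the synthetic
    generator to emulate camera buffers.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    h, w = rgb.shape[:2]
    if h % 2 or w % 2:
        raise ConfigError("NV21 needs even frame dimensions")
    ycc = rgb @ _BT601.T
    y = np.clip(np.round(ycc[..., 0]), 0, 255).astype(np.uint8)
    # chroma subsample 2x2 by averaging
    cb = ycc[..., 1].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3)) + 128
    cr = ycc[..., 2].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3)) + 128
    vu = np.empty((h // 2, w), dtype=np.uint8)
    vu[:, 0::2] = np.clip(np.round(cr), 0, 255).astype(np.uint8)
    vu[:, 1::2] = np.clip(np.round(cb), 0, 255).astype(np.uint8)
    return y.tobytes() + vu.tobytes()


def nv21_to_rgb(buf: bytes, width: int, height: int) -> np.ndarray:
    """Decode an NV21 buffer to an RGB uint8 image."""
    expected = width * height * 3 // 2
    if len(buf) != expected:
        raise ConfigError(f"NV21 buffer length {len(buf)} != {expected} for {width}x{height}")
    raw = np.frombuffer(buf, dtype=np.uint8)
    y = raw[: width * height].reshape(height, width).astype(np.float64)
    vu = raw[width * height:].reshape(height // 2, width)
    cr = vu[:, 0::2].astype(np.float64) - 128
    cb = vu[:, 1::2].astype(np.float64) - 128
    cr = np.repeat(np.repeat(cr, 2, axis=0), 2, axis=1)[:height, :width]
    cb = np.repeat(np.repeat(cb, 2, axis=0), 2, axis=1)[:height, :width]
    r = y + 1.402 * cr
    g = y - 0.344136 * cb - 0.714136 * cr
    b = y + 1.772 * cb
    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def to_hsv(frame: Frame | np.ndarray, color_space: str | None = None) -> np.ndarray:
    """Convert a frame to HSV with H in degrees [0, 360) and S, V in [0, 1].

    Achromatic pixels get hue 0 by convention.
    """
    if isinstance(frame, Frame):
        pixels, space = frame.pixels, frame.color_space
    else:
        pixels, space = np.asarray(frame), color_space or "rgb"
    space = space.lower()
    if space not in ("rgb",):
        raise ConfigError(
            f"unknown source color space {space!r}; decode camera buffers "
            "(e.g. NV21) to RGB with nv21_to_rgb first"
        )
    if pixels.size == 0:
        raise ConfigError("empty image")
    hsv = skcolor.rgb2hsv(pixels)
    hsv[..., 0] *= 360.0
    return hsv


# ---------------------------------------------------------------------------
# segmentation


def skin_mask(
    hsv: np.ndarray, hue_range: tuple[float, float] = (0.0, 50.0), sat_min: float = 0.15
) -> np.ndarray:
    """Threshold an HSV image on the skin hue band.

    True exactly where hue lies in ``hue_range`` (degrees, treated modulo
    360 so a wrapping band like (340, 20) works) and saturation >= sat_min.
    """
    hsv = np.asarray(hsv)
    if hsv.size == 0:
        raise ConfigError("empty image")
    lo, hi = (x % 360.0 for x in hue_range)
    h, s = hsv[..., 0] % 360.0, hsv[..., 1]
    if lo <= hi:
        in_band = (h >= lo) & (h <= hi)
    else:  # wrapping band
        in_band = (h >= lo) | (h <= hi)
    return in_band & (s >= sat_min)


def clean_mask(mask: np.ndarray, kernel: int = 5, hole_frac: float = 0.01) -> np.ndarray:
    """Morphological close, then fill small interior holes.

    A hole is a false connected component that does not touch the image
    border; holes smaller than ``hole_frac`` of the largest true component
    are filled.  Larger holes (the eyes) survive.
    """
    if kernel < 1:
        raise ConfigError("kernel must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    closed = morphology.closing(mask, footprint=np.ones((kernel, kernel), bool))
    true_labels = measure.label(closed, connectivity=2)
    if true_labels.max() == 0:
        return closed
    largest = max(np.bincount(true_labels.ravel())[1:])
    cutoff = hole_frac * largest
    out = closed.copy()
    hole_labels = measure.label(~closed, connectivity=2)
    border = np.zeros_like(closed)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = np.unique(hole_labels[border & ~closed])
    for region in measure.regionprops(hole_labels):
        if region.label in border_ids:
            continue
        if region.area < cutoff:
            out[hole_labels == region.label] = True
    return out


def extract_face_region(mask: np.ndarray) -> Region:
    """Bounding box of the largest true connected component."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise NoFaceError("no skin component in mask")
    props = measure.regionprops(labels)
    best = max(props, key=lambda r: r.area)
    top, left, bottom, right = best.bbox
    return Region(top=top, left=left, bottom=bottom, right=right)


def _hole_candidates(mask: np.ndarray, face: Region):
    """False components strictly inside the face region (not touching its edge)."""
    sub = np.asarray(mask, dtype=bool)[face.top:face.bottom, face.left:face.right]
    labels = measure.label(~sub, connectivity=2)
    if labels.max() == 0:
        return []
    edge = np.zeros_like(sub)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    edge_ids = set(np.unique(labels[edge & ~sub]))
    out = []
    for region in measure.regionprops(labels):
        if region.label in edge_ids:
            continue
        top, left, bottom, right = region.bbox
        out.append(
            {
                "region": Region(
                    top=top + face.top,
                    left=left + face.left,
                    bottom=bottom + face.top,
                    right=right + face.left,
                ),
                "row": region.centroid[0] + face.top,
                "col": region.centroid[1] + face.left,
                "area": int(region.area),
            }
        )
    return out


def locate_eyes(mask: np.ndarray, face: Region, tolerance_px: float = 10.0) -> EyePair:
    """Pick the eye pair among hole candidates inside the face region.

    Candidate pairs must have vertical centers within ``tolerance_px`` rows
    of each other.  When several aligned pairs exist (the eyebrow/eye
    confound), pairs are grouped into vertical bands one tolerance tall; the
    lowest band wins, inside a band the larger combined area wins, and a
    final tie goes to the lower pair.  Selection is therefore invariant to
    the left/right ordering of the candidates.
    """
    cands = _hole_candidates(mask, face)
    pairs = []
    for a, b in itertools.combinations(cands, 2):
        if abs(a["row"] - b["row"]) > tolerance_px:
            continue
        if abs(a["col"] - b["col"]) < 1.0:  # vertically stacked, not a pair
            continue
        left, right = sorted((a, b), key=lambda c: c["col"])
        pairs.append((a, b, left, right))
    if not pairs:
        raise EyesNotFoundError("no vertically aligned hole pair inside face region")

    def key(p):
        a, b, _, _ = p
        mean_row = (a["row"] + b["row"]) / 2.0
        return (int(mean_row // max(tolerance_px, 1.0)), a["area"] + b["area"], mean_row)

    a, b, left, right = max(pairs, key=key)
    return EyePair(
        left_eye=left["region"],
        right_eye=right["region"],
        vertical_offset=abs(a["row"] - b["row"]),
        combined_area=a["area"] + b["area"],
    )


def eye_openness(eyes: EyePair, running_max_area: float) -> float:
    """Combined eye area over the session's running maximum, clamped to 1."""
    if running_max_area <= 0:
        raise ConfigError("running_max_area must be positive")
    return min(eyes.combined_area / running_max_area, 1.0)


class OpennessTracker:
    """Run the full per-frame chain and accumulate an EyeOpennessSeries.

    Frames with a face but no aligned eye pair score openness 0 (closed
    eyes leave no holes); frames with no face are skipped entirely.
    """

    def __init__(
        self,
        hue_range: tuple[float, float] = (0.0, 50.0),
        sat_min: float = 0.15,
        kernel: int = 5,
        hole_frac: float = 0.01,
        tolerance_px: float = 10.0,
    ):
        self.hue_range = hue_range
        self.sat_min = sat_min
        self.kernel = kernel
        self.hole_frac = hole_frac
        self.tolerance_px = tolerance_px
        self.running_max_area: float = 0.0
        self._times: list[float] = []
        self._openness: list[float] = []
        self.n_skipped = 0

    def process(self, frame: Frame) -> float | None:
        hsv = to_hsv(frame)
        mask = clean_mask(
            skin_mask(hsv, self.hue_range, self.sat_min), self.kernel, self.hole_frac
        )
        try:
            face = extract_face_region(mask)
        except NoFaceError:
            self.n_skipped += 1
            return None
        try:
            eyes = locate_eyes(mask, face, self.tolerance_px)
        except EyesNotFoundError:
            value = 0.0
        else:
            self.running_max_area = max(self.running_max_area, eyes.combined_area)
            value = eye_openness(eyes, self.running_max_area)
        self._times.append(frame.timestamp)
        self._openness.append(value)
        return value

    @property
    def series(self) -> EyeOpennessSeries:
        return EyeOpennessSeries(np.array(self._times), np.array(self._openness))


def compute_perclos(
    series: EyeOpennessSeries,
    window: float = 60.0,
    closure_threshold: float = 0.2,
    t_end: float | None = None,
) -> PerclosResult:
    """PERCLOS over the window ending at ``t_end`` (default: last frame).

    ``pr`` is the fraction of frames whose openness is below
    ``closure_threshold``; the 0.2 default realizes the P80 criterion (eye
    at least 80 % closed relative to the session maximum).
    """
    if window <= 0:
        raise ConfigError("window must be positive")
    if len(series) == 0:
        raise InsufficientDataError("empty openness series")
    t_end = float(series.timestamps[-1]) if t_end is None else float(t_end)
    t_start = t_end - window
    sel = (series.timestamps > t_start) & (series.timestamps <= t_end)
    n = int(sel.sum())
    if n == 0:
        raise InsufficientDataError("no frames in PERCLOS window")
    pr = float(np.count_nonzero(series.openness[sel] < closure_threshold)) / n
    return PerclosResult(window_start=t_start, window_end=t_end, pr=pr, n_frames=n)
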