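"""Footfall-cycle analytics for peristaltic crawling.

Each substrate-contacting protopodium cycles through four phases: swing
initiation (SI, movement begins), swing period (SwP, off the substrate), swing
termination (ST, movement ends) and stance period (StP, planted).  This module
segments those phases from tracked landmark speeds, measures anteroposterior
(AP) latencies between posterior and anterior denticle rows (positive =
posterior-led), regresses latencies against wave duration, and extracts
kymographs and contact-onset latencies from displacement map series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .erism import DisplacementMap

__all__ = [
    "TrackTable",
    "FootfallEvent",
    "WaveAnnotation",
    "ApLatency",
    "EventDelays",
    "point_velocities",
    "segment_footfalls",
    "ap_latency",
    "latency_duration_regression",
    "kymograph",
    "contact_onset_latency",
    "event_delay",
]


@dataclass(frozen=True)
class TrackTable:
    """Tracked landmark coordinates over time.

    ``data`` columns: time_s, point_id, x_um, y_um.  Rows are canonicalised
    (sorted by point then time) on construction.
    """

    data: pd.DataFrame
    frame_rate: float

    def __post_init__(self):
        required = {"time_s", "point_id", "x_um", "y_um"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"track table needs columns {sorted(required)}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        df = self.data.sort_values(["point_id", "time_s"], kind="stable").reset_index(drop=True)
        for pid, g in df.groupby("point_id"):
            if np.any(np.diff(g["time_s"].to_numpy()) <= 0):
                raise ValueError(f"point {pid!r}: duplicate or non-increasing timestamps")
        object.__setattr__(self, "data", df)

    @classmethod
    def from_csv(cls, path, frame_rate: float) -> "TrackTable":
        return cls(pd.read_csv(path), frame_rate)

    def point_ids(self) -> list:
        return list(self.data["point_id"].unique())


@dataclass(frozen=True)
class FootfallEvent:
    """One footfall cycle of a landmark: SwP = [si_time, st_time]."""

    point_id: object
    si_time: float
    st_time: float
    stp_end: float = float("nan")  # start of the next swing, when known

    def __post_init__(self):
        if not self.si_time < self.st_time:
            raise ValueError("si_time must precede st_time")

    @property
    def swp_interval(self) -> tuple[float, float]:
        return (self.si_time, self.st_time)

    @property
    def stp_interval(self) -> tuple[float, float]:
        return (self.st_time, self.stp_end)

    @property
    def swing_duration(self) -> float:
        return self.st_time - self.si_time


@dataclass(frozen=True)
class WaveAnnotation:
    """A single peristaltic wave; forward waves progress posterior -> anterior."""

    wave_id: object
    direction: str  # "forward" | "backward"
    duration: float  # s
    events: dict = field(default_factory=dict)  # segment/point id -> FootfallEvent

    def __post_init__(self):
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


# ---------------------------------------------------------------------------
# velocities and footfall segmentation


def point_velocities(tracks: TrackTable, smoothing_window: int = 1) -> pd.DataFrame:
    """Per-point speed series [um/s] by central differences.

    Endpoints use one-sided differences, so the series keeps its length.  A
    moving-average window > 1 smooths the speed.  Returns a data frame with
    columns time_s, point_id, speed_um_s.
    """
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    frames = []
    for pid, g in tracks.data.groupby("point_id"):
        t = g["time_s"].to_numpy()
        if t.size < 3:
            raise ValueError(f"point {pid!r}: need at least 3 samples")
        vx = np.gradient(g["x_um"].to_numpy(), t)
        vy = np.gradient(g["y_um"].to_numpy(), t)
        speed = np.hypot(vx, vy)
        if smoothing_window > 1:
            speed = ndimage.uniform_filter1d(speed, smoothing_window, mode="nearest")
        frames.append(pd.DataFrame({"time_s": t, "point_id": pid, "speed_um_s": speed}))
    return pd.concat(frames, ignore_index=True)


def _crossing_time(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def segment_footfalls(
    times: np.ndarray,
    speed: np.ndarray,
    v_on: float = 20.0,
    v_off: float = 10.0,
    min_swing: float = 0.0,
    point_id=None,
) -> list[FootfallEvent]:
    """Detect SI/ST events from a speed series with hysteresis thresholds.

    SI is the upward crossing of ``v_on`` and ST the subsequent downward
    crossing of ``v_off`` (v_on >= v_off > 0 prevents chatter); crossing times
    are refined by linear interpolation.  Swings shorter than ``min_swing``
    are discarded, as is a swing still open at the end of the series.
    """
    if not v_on >= v_off > 0:
        raise ValueError("need v_on >= v_off > 0")
    t = np.asarray(times, dtype=float)
    v = np.asarray(speed, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and speed must be matching 1-D arrays")
    events: list[FootfallEvent] = []
    moving = v[0] > v_on
    si = t[0] if moving else None
    for i in range(1, t.size):
        if not moving and v[i - 1] <= v_on < v[i]:
            moving = True
            si = _crossing_time(t[i - 1], t[i], v[i - 1], v[i], v_on)
        elif moving and v[i - 1] >= v_off > v[i]:
            moving = False
            st = _crossing_time(t[i - 1], t[i], v[i - 1], v[i], v_off)
            if si is not None and st > si and (st - si) >= min_swing:
                events.append(FootfallEvent(point_id, si, st))
            si = None
    # close stance intervals against the following swing
    closed = []
    for i, ev in enumerate(events):
        nxt = events[i + 1].si_time if i + 1 < len(events) else float("nan")
        closed.append(FootfallEvent(ev.point_id, ev.si_time, ev.st_time, nxt))
    return closed


class ApLatency(NamedTuple):
    si_latency: float  # s; positive = posterior row led
    st_latency: float
    si_pct: float  # % of wave duration
    st_pct: float


def ap_latency(
    posterior_events: Sequence[FootfallEvent],
    anterior_events: Sequence[FootfallEvent],
    wave: WaveAnnotation,
) -> ApLatency:
    """AP latencies between posterior- and anterior-row events of one wave.

    si_latency = anterior SI - posterior SI (positive = posterior-led; in a
    backward wave the anterior row leads and the SI latency flips sign).
    Events are paired in temporal order; unmatched ones are dropped with a
    warning.  Latencies are averaged over matched pairs and also expressed as
    a percentage of the wave duration.
    """
    post = sorted(posterior_events, key=lambda e: e.si_time)
    ant = sorted(anterior_events, key=lambda e: e.si_time)
    n = min(len(post), len(ant))
    if n == 0:
        raise ValueError("no events to match")
    if len(post) != len(ant):
        warnings.warn(
            f"{abs(len(post) - len(ant))} unmatched event(s) excluded", stacklevel=2
        )
    si = float(np.mean([a.si_time - p.si_time for p, a in zip(post[:n], ant[:n])]))
    st = float(np.mean([a.st_time - p.st_time for p, a in zip(post[:n], ant[:n])]))
    return ApLatency(si, st, 100.0 * si / wave.duration, 100.0 * st / wave.duration)


def latency_duration_regression(pairs) -> tuple[float, float, float]:
    """OLS regression of latency on wave duration: (slope, intercept, R^2)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (duration, latency) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in duration")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# displacement-series analytics


def _as_array_series(disp_series) -> tuple[np.ndarray, float]:
    if isinstance(disp_series, np.ndarray):
        return disp_series, 1.0
    maps = list(disp_series)
    px = maps[0].pixel_size if isinstance(maps[0], DisplacementMap) else 1.0
    arr = np.stack([m.values if isinstance(m, DisplacementMap) else m for m in maps])
    return arr, px


def kymograph(disp_series, polyline, width: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Displacement sampled along a polyline over time: (position x time) map.

    ``polyline`` is a sequence of (x, y) pixel coordinates (x = column).  The
    line is arc-length parameterised at unit-pixel spacing and width-averaged
    over ``width`` pixels perpendicular to the local direction, with bilinear
    interpolation.  Returns (kymo, positions_um).
    """
    arr, px = _as_array_series(disp_series)
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be >= 2 points of (x, y)")
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    if total <= 0:
        raise ValueError("degenerate (zero-length) polyline")
    s_knots = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.arange(0.0, total + 1e-9, 1.0)
    x = np.interp(s, s_knots, pts[:, 0])
    y = np.interp(s, s_knots, pts[:, 1])
    # unit normals from the local tangent
    tx = np.gradient(x)
    ty = np.gradient(y)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(width) - (width - 1) / 2.0
    kymo = np.empty((s.size, arr.shape[0]))
    for f in range(arr.shape[0]):
        acc = np.zeros(s.size)
        for o in offsets:
            coords = np.vstack([y + o * ny, x + o * nx])  # (row, col)
            acc += ndimage.map_coordinates(arr[f], coords, order=1, mode="nearest")
        kymo[:, f] = acc / offsets.size
    return kymo, s * px


def _first_crossing(times: np.ndarray, series: np.ndarray, threshold: float) -> float:
    below = series < threshold
    if not below.any():
        return float("nan")
    i = int(np.argmax(below))
    if i == 0:
        return float(times[0])
    return _crossing_time(times[i - 1], times[i], series[i - 1], series[i], threshold)


def contact_onset_latency(
    disp_series,
    positions,
    reference,
    threshold: float = 0.0,
    frame_rate: float = 60.0,
) -> np.ndarray:
    """Contact-onset latency [s] of probe points relative to a reference point.

    For each (x, y) probe the displacement series is sampled bilinearly and
    the first time it indents below ``threshold`` [nm] is found with sub-frame
    interpolation.  Latency = probe onset - reference onset.  Probes that
    never cross are reported as NaN; a non-crossing reference is an error.
    """
    arr, _ = _as_array_series(disp_series)
    times = np.arange(arr.shape[0]) / frame_rate
    pts = np.asarray(positions, dtype=float).reshape(-1, 2)
    ref = np.asarray(reference, dtype=float).reshape(2)
    all_pts = np.vstack([ref[None, :], pts])
    coords = np.vstack([all_pts[:, 1], all_pts[:, 0]])  # (row, col)
    series = np.stack(
        [ndimage.map_coordinates(arr[f], coords, order=1, mode="nearest") for f in range(arr.shape[0])]
    )  # (T, n_points)
    t_ref = _first_crossing(times, series[:, 0], threshold)
    if np.isnan(t_ref):
        raise ValueError("reference point never crosses the contact threshold")
    out = np.array([_first_crossing(times, series[:, i + 1], threshold) for i in range(pts.shape[0])])
    return out - t_ref


class EventDelays(NamedTuple):
    delays: np.ndarray  # s, one per matched a-event
    mean: float
    sd: float
    n_unmatched: int


def event_delay(events_a, events_b, max_gap: float = 2.0) -> EventDelays:
    """Delay from each a-event to the first subsequent b-event within ``max_gap``.

    Each b-event is consumed by at most one a-event.  Unmatched a-events are
    counted separately (an a-event need not trigger a b-event).
    """
    a = np.sort(np.asarray(events_a, dtype=float))
    b = np.sort(np.asarray(events_b, dtype=float))
    delays = []
    j = 0
    unmatched = 0
    for ta in a:
        while j < b.size and b[j] < ta:
            j += 1
        if j < b.size and b[j] - ta <= max_gap:
            delays.append(b[j] - ta)
            j += 1
        else:
            unmatched += 1
    d = np.asarray(delays)
    mean = float(d.mean()) if d.size else float("nan")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return EventDelays(d, mean, sd, unmatched)
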