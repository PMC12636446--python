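"""Developmental staging from locomotion tracks.

A centroid track is converted into a speed series (trailing-window
displacement speed, then a centered moving average), from which hatch time,
quiescence bouts and the three larval-stage transitions (bout midpoints)
are called.  All times inside :class:`DevelopmentalTimeline` are minutes
since recording start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocomotionTrack",
    "SpeedSeries",
    "QuiescenceBout",
    "DevelopmentalTimeline",
    "StagingError",
    "compute_speed",
    "smooth_speed",
    "default_threshold",
    "detect_hatch",
    "detect_quiescence_bouts",
    "call_transitions",
    "roaming_fraction",
    "stage_track",
]

#: time gap (s) above which a track is split and speed is never computed
#: across the split
MAX_FRAME_GAP_S = 2.0


class StagingError(RuntimeError):
    """Raised when a track cannot be staged."""


@dataclass
class LocomotionTrack:
    """Centroid trajectory of one individual.

    ``time`` is seconds since recording start and must be strictly
    increasing; ``x``/``y`` are arena units.
    """

    frame_index: np.ndarray
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 3.0
    individual_id: str = ""

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.time)
        if not (len(self.frame_index) == len(self.x) == len(self.y) == n):
            raise ValueError("track columns must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("track time must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.time)

    def gap_splits(self) -> np.ndarray:
        """Indices where a frame gap > MAX_FRAME_GAP_S starts a new segment."""
        if len(self) < 2:
            return np.array([], dtype=np.int64)
        return np.flatnonzero(np.diff(self.time) > MAX_FRAME_GAP_S) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame_index, "time_s": self.time, "x": self.x, "y": self.y}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, frame_rate: float = 3.0, individual_id: str | None = None
    ) -> "LocomotionTrack":
        df = pd.read_csv(path, sep="\t", comment="#")
        if individual_id is None:
            individual_id = Path(path).stem
        return cls(
            frame_index=df["frame"].to_numpy(),
            time=df["time_s"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            frame_rate=frame_rate,
            individual_id=individual_id,
        )


@dataclass
class SpeedSeries:
    """Speed (arena units / s) on a stated timescale, with smoothing record."""

    time: np.ndarray
    speed: np.ndarray
    timescale_s: float
    smoothing_window: int = 1
    individual_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if len(self.time) != len(self.speed):
            raise ValueError("time and speed must have equal length")
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")


@dataclass
class QuiescenceBout:
    """One behavioral quiescence interval, minutes since recording start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("bout start must precede end")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class DevelopmentalTimeline:
    """Hatch, three stage transitions and collection time (minutes)."""

    hatch_time: float
    transitions: tuple[float, float, float]
    collection_time: float
    individual_id: str = ""
    partial: bool = False
    n_transitions: int = field(default=3)

    def __post_init__(self) -> None:
        self.transitions = tuple(float(t) for t in self.transitions)
        self.n_transitions = sum(np.isfinite(self.transitions))
        finite = [t for t in self.transitions if np.isfinite(t)]
        seq = [self.hatch_time, *finite]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("timeline must be strictly ordered: hatch < t1 < t2 < t3")
        if finite and self.collection_time < finite[-1]:
            raise ValueError("collection precedes last transition")

    def age_since_hatch(self, t: float | np.ndarray) -> float | np.ndarray:
        return t - self.hatch_time

    def age_since_l4(self, t: float | np.ndarray) -> float | np.ndarray:
        return t - self.transitions[2]

    def to_row(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "hatch_min": self.hatch_time,
            "t1_min": self.transitions[0],
            "t2_min": self.transitions[1],
            "t3_min": self.transitions[2],
            "collection_min": self.collection_time,
            "age_since_hatch_min": self.age_since_hatch(self.collection_time),
            "age_since_l4_min": self.age_since_l4(self.collection_time),
        }


def timelines_to_tsv(timelines: list[DevelopmentalTimeline], path: str | Path) -> None:
    pd.DataFrame([tl.to_row() for tl in timelines]).to_csv(path, sep="\t", index=False)


def timelines_from_tsv(path: str | Path) -> list[DevelopmentalTimeline]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DevelopmentalTimeline(
            hatch_time=row.hatch_min,
            transitions=(row.t1_min, row.t2_min, row.t3_min),
            collection_time=row.collection_min,
            individual_id=str(row.individual_id),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# speed


def compute_speed(track: LocomotionTrack, timescale_s: float = 10.0) -> SpeedSeries:
    """Trailing-window displacement speed.

    ``speed[i]`` is the Euclidean displacement between the position at
    ``t[i]`` and the position ``timescale_s`` earlier, divided by
    ``timescale_s``.  Speed is never computed across frame gaps larger
    than :data:`MAX_FRAME_GAP_S`.
    """
    if timescale_s <= 0:
        raise ValueError("timescale must be positive")
    window = int(round(timescale_s * track.frame_rate))
    if len(track) <= window:
        raise StagingError(
            f"track {track.individual_id!r}: {len(track)} frames is shorter than "
            f"one {timescale_s:g}-s window ({window + 1} frames)"
        )
    splits = track.gap_splits()
    seg_id = np.zeros(len(track), dtype=np.int64)
    seg_id[splits] = 1
    seg_id = np.cumsum(seg_id)

    dx = track.x[window:] - track.x[:-window]
    dy = track.y[window:] - track.y[:-window]
    speed = np.hypot(dx, dy) / timescale_s
    valid = seg_id[window:] == seg_id[:-window]
    return SpeedSeries(
        time=track.time[window:][valid],
        speed=speed[valid],
        timescale_s=timescale_s,
        individual_id=track.individual_id,
    )


def smooth_speed(series: SpeedSeries, window_frames: int = 225) -> SpeedSeries:
    """Centered moving average; edges use shrinking windows."""
    if window_frames <= 0:
        raise ValueError("window must be positive")
    if window_frames % 2 == 0:
        window_frames += 1
    if len(series.speed) <= window_frames:
        raise StagingError("series shorter than smoothing window")
    smoothed = (
        pd.Series(series.speed)
        .rolling(window_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return SpeedSeries(
        time=series.time,
        speed=smoothed,
        timescale_s=series.timescale_s,
        smoothing_window=window_frames,
        individual_id=series.individual_id,
    )


def default_threshold(series: SpeedSeries, frac: float = 0.1) -> float:
    """Scale-free activity threshold: ``frac`` of the median smoothed speed.

    The median is dominated by active-period frames because quiescence
    occupies a small fraction of a developmental recording.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    return frac * float(np.median(series.speed))


# ---------------------------------------------------------------------------
# event detection


def detect_hatch(
    track: LocomotionTrack,
    activity_threshold: float | None = None,
    persistence_min: float = 2.0,
    timescale_s: float = 10.0,
    smooth_window: int = 225,
) -> float:
    """First time (min) the smoothed speed stays above threshold.

    The run must persist for at least ``persistence_min`` minutes so
    isolated jitter before hatching is not mistaken for activity onset.
    """
    series = smooth_speed(compute_speed(track, timescale_s), smooth_window)
    if activity_threshold is None:
        activity_threshold = default_threshold(series)
    above = series.speed > activity_threshold
    if not above.any():
        raise StagingError(f"no hatch detected for {track.individual_id!r}")
    run_frames = max(1, int(round(persistence_min * 60 * track.frame_rate)))
    starts, ends = _runs(above)
    for s, e in zip(starts, ends):
        if e - s >= run_frames:
            # the window extends timescale_s backwards; activity actually
            # started around the beginning of the displacement window
            return max(0.0, (series.time[s] - timescale_s) / 60.0)
    raise StagingError(f"no sustained activity found for {track.individual_id!r}")


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) / end (exclusive) indices of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(np.int8))
    return np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)


def detect_quiescence_bouts(
    series: SpeedSeries,
    threshold: float | None = None,
    min_duration_min: float = 10.0,
    merge_gap_min: float = 5.0,
) -> list[QuiescenceBout]:
    """Maximal sub-threshold runs, merged across short gaps, length-filtered."""
    if threshold is None:
        threshold = default_threshold(series)
    below = series.speed < threshold
    starts, ends = _runs(below)
    if len(starts) == 0:
        return []
    t = series.time / 60.0
    intervals = [(t[s], t[e - 1]) for s, e in zip(starts, ends)]
    merged: list[list[float]] = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo - merged[-1][1] < merge_gap_min:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    return [
        QuiescenceBout(lo, hi)
        for lo, hi in merged
        if hi - lo >= min_duration_min
    ]


def call_transitions(
    bouts: list[QuiescenceBout],
    hatch_time: float,
    collection_time: float | None = None,
    individual_id: str = "",
    allow_partial: bool = False,
) -> DevelopmentalTimeline:
    """Stage transitions = midpoints of the three longest post-hatch bouts.

    Ties on duration prefer the earlier bout.  With ``allow_partial`` a
    timeline with missing (NaN) transitions is returned instead of raising.
    """
    post = [b for b in bouts if b.midpoint > hatch_time]
    if len(post) < 3 and not allow_partial:
        raise StagingError(
            f"individual {individual_id!r}: only {len(post)} qualifying "
            "quiescence bouts; need 3 for a complete L1-L4 timeline"
        )
    ranked = sorted(post, key=lambda b: (-b.duration, b.start))[:3]
    chosen = sorted(b.midpoint for b in ranked)
    while len(chosen) < 3:
        chosen.append(np.nan)
    if collection_time is None:
        collection_time = max(
            [b.end for b in post], default=hatch_time + 1.0
        )
    return DevelopmentalTimeline(
        hatch_time=hatch_time,
        transitions=tuple(chosen),
        collection_time=collection_time,
        individual_id=individual_id,
        partial=len(post) < 3,
    )


def stage_track(
    track: LocomotionTrack,
    threshold_frac: float = 0.1,
    timescale_s: float = 10.0,
    smooth_window: int = 225,
    min_duration_min: float = 10.0,
    merge_gap_min: float = 5.0,
    allow_partial: bool = False,
) -> DevelopmentalTimeline:
    """Full staging of one track: hatch, bouts, transitions, collection."""
    series = smooth_speed(compute_speed(track, timescale_s), smooth_window)
    threshold = default_threshold(series, threshold_frac)
    hatch = detect_hatch(track, threshold, timescale_s=timescale_s, smooth_window=smooth_window)
    bouts = detect_quiescence_bouts(series, threshold, min_duration_min, merge_gap_min)
    return call_transitions(
        bouts,
        hatch,
        collection_time=track.time[-1] / 60.0,
        individual_id=track.individual_id,
        allow_partial=allow_partial,
    )


# ---------------------------------------------------------------------------
# roaming / dwelling


def roaming_fraction(
    track: LocomotionTrack,
    bin_min: float = 3.0,
    speed_threshold: float | None = None,
    turn_threshold_rad_s: float = 1.0,
    timescale_s: float = 10.0,
) -> pd.DataFrame:
    """Fraction of frames classified roaming per ``bin_min``-minute bin.

    A frame roams when its displacement speed is at or above
    ``speed_threshold`` (default: half the median positive speed) and its
    heading turn rate is at or below ``turn_threshold_rad_s``.  This is a
    two-threshold approximation of published roaming/dwelling criteria.
    """
    series = compute_speed(track, timescale_s)
    speed = series.speed
    if speed_threshold is None:
        pos = speed[speed > 0]
        speed_threshold = 0.5 * float(np.median(pos)) if len(pos) else np.inf

    window = int(round(timescale_s * track.frame_rate))
    dx = track.x[window:] - track.x[:-window]
    dy = track.y[window:] - track.y[:-window]
    heading = np.arctan2(dy, dx)
    dt = np.diff(series.time, prepend=series.time[0] - 1.0 / track.frame_rate)
    dh = np.abs(np.angle(np.exp(1j * np.diff(heading, prepend=heading[0]))))
    with np.errstate(divide="ignore", invalid="ignore"):
        turn_rate = np.where(dt > 0, dh / dt, 0.0)

    roaming = (speed >= speed_threshold) & (turn_rate <= turn_threshold_rad_s)
    bins = np.floor(series.time / 60.0 / bin_min).astype(np.int64)
    df = pd.DataFrame({"bin": bins, "roaming": roaming.astype(float)})
    out = df.groupby("bin")["roaming"].agg(["mean", "size"]).reset_index()
    out.columns = ["bin", "roaming_fraction", "n_frames"]
    out["bin_start_min"] = out["bin"] * bin_min
    return out[["bin", "bin_start_min", "roaming_fraction", "n_frames"]]
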