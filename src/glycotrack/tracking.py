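"""Trajectory analytics for 3D nucleus tracks.

Positions are in micrometres, times in seconds (uniform frame spacing;
the two-photon movies ran at one frame per 40 s).  Speeds are reported in
um/min.  Directionality is the classic persistence ratio: per fixed-length
segment, net start-to-end displacement over summed path length, averaged
over segments and then over tracks.  Germband entry time is the interval
between the first nucleus reaching the tissue edge (T0) and the first
nucleus being inside (T1), with the boundary supplied as predicates rather
than inferred from images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Track",
    "SpeedSummary",
    "NoEntryError",
    "instantaneous_speeds",
    "condition_mean_speed",
    "directionality",
    "condition_mean_directionality",
    "germband_entry_time",
    "axis_threshold",
    "percent_reduction",
]


class NoEntryError(RuntimeError):
    """No track satisfied the requested boundary crossing."""


@dataclass(frozen=True)
class Track:
    """One nucleus trajectory: ordered times (s) and 3D positions (um)."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        p = np.asarray(self.positions, float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if t.ndim != 1 or t.size != p.shape[0]:
            raise ValueError("times and positions lengths must match")
        if t.size < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(p)):
            raise ValueError("times and positions must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpeedSummary:
    """Track-weighted condition speed: mean over per-track means, SE over
    tracks (NaN when only one track)."""

    mean: float
    se: float
    n_tracks: int


def _check_uniform(times: np.ndarray) -> None:
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("track times must be uniformly spaced")


def instantaneous_speeds(track: Track) -> np.ndarray:
    """Per-step speeds |p_{i+1}-p_i| / (t_{i+1}-t_i) in um/min."""
    _check_uniform(track.times)
    disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    return disp / np.diff(track.times) * 60.0


def condition_mean_speed(tracks: Sequence[Track]) -> SpeedSummary:
    """Mean instantaneous speed per track, then unweighted mean over tracks
    (each trajectory one vote); SE across tracks."""
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    means = np.array([instantaneous_speeds(t).mean() for t in tracks])
    se = float(means.std(ddof=1) / math.sqrt(means.size)) if means.size > 1 else float("nan")
    return SpeedSummary(mean=float(means.mean()), se=se, n_tracks=means.size)


def directionality(
    track: Track, window: int = 10, overlapping: bool = False
) -> float:
    """Mean per-segment persistence ratio in [0, 1].

    The trajectory is split into segments of ``window`` frames
    (non-overlapping consecutive chunks by default; ``overlapping=True``
    slides the window one frame at a time).  Each segment scores net
    start-to-end distance over summed step path length; a zero-path
    (stationary) segment scores 0.  Trailing frames short of a full window
    are dropped.  1 means straight motion.
    """
    if window < 2:
        raise ValueError("window must be >= 2 frames")
    n = len(track)
    if n < window:
        raise ValueError(
            f"track {track.track_id} has {n} frames, shorter than window {window}"
        )
    starts = range(0, n - window + 1) if overlapping else range(0, n - window + 1, window)
    vals = []
    for s in starts:
        seg = track.positions[s : s + window]
        path = float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum())
        net = float(np.linalg.norm(seg[-1] - seg[0]))
        vals.append(net / path if path > 0 else 0.0)
    return float(np.mean(vals))


def condition_mean_directionality(
    tracks: Sequence[Track], window: int = 10, overlapping: bool = False
) -> tuple[float, int]:
    """Mean directionality over tracks long enough for one full window;
    returns (mean, n_tracks_used).  Short tracks are excluded, not errors."""
    vals = [
        directionality(t, window=window, overlapping=overlapping)
        for t in tracks
        if len(t) >= window
    ]
    if not vals:
        raise ValueError("no track is at least one window long")
    return float(np.mean(vals)), len(vals)


def axis_threshold(
    axis: int, value: float, side: str = "ge"
) -> Callable[[np.ndarray], np.ndarray]:
    """Planar boundary predicate: positions[:, axis] >= value ('ge') or
    <= value ('le')."""
    if side not in ("ge", "le"):
        raise ValueError("side must be 'ge' or 'le'")
    if side == "ge":
        return lambda pos: np.asarray(pos)[..., axis] >= value
    return lambda pos: np.asarray(pos)[..., axis] <= value


def germband_entry_time(
    tracks: Sequence[Track],
    at_edge: Callable[[np.ndarray], np.ndarray],
    inside: Callable[[np.ndarray], np.ndarray],
) -> float:
    """T1 - T0 in minutes: T0 is the earliest time any nucleus satisfies
    the edge predicate, T1 the earliest time any nucleus (possibly a
    different track) satisfies the interior predicate.

    Raises NoEntryError when no track reaches the edge or the interior.
    """
    t_edge = math.inf
    t_inside = math.inf
    for tr in tracks:
        e = np.asarray(at_edge(tr.positions), bool)
        i = np.asarray(inside(tr.positions), bool)
        if e.any():
            t_edge = min(t_edge, float(tr.times[e.argmax()]))
        if i.any():
            t_inside = min(t_inside, float(tr.times[i.argmax()]))
    if not math.isfinite(t_edge):
        raise NoEntryError("no track reached the germband edge")
    if not math.isfinite(t_inside):
        raise NoEntryError("no track entered the germband")
    if t_inside < t_edge:
        raise ValueError("interior reached before the edge: inconsistent boundary")
    return (t_inside - t_edge) / 60.0


def percent_reduction(control_mean: float, test_mean: float) -> int:
    """Integer percent reduction of the test condition relative to control,
    rounded half away from zero: round((control - test) / control * 100)."""
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValueError("control mean must be positive")
    if not np.isfinite(test_mean):
        raise ValueError("test mean must be finite")
    x = (control_mean - test_mean) / control_mean * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
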