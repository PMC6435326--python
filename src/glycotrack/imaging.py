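"""Image-derived quantifications.

Four measurements used on fixed and live fluorescence micrographs:
Pearson colocalization of two channels, arbitrary-unit (AU) normalization
of background-subtracted ROI intensities against same-day controls,
multichannel line profiles with bilinear interpolation, and the
percent-of-expected migration of ovary border cells.  Pixel coordinates
are 0-based with the origin at the top-left pixel centre; physical
coordinates are micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImagePair",
    "RoiPair",
    "MigrationPercent",
    "ConstantChannelError",
    "MissingReferenceError",
    "pearson_coloc",
    "t_antigen_au",
    "line_profile",
    "border_cell_migration_pct",
]


class ConstantChannelError(ValueError):
    """A channel is constant over the mask: Pearson r is undefined."""


class MissingReferenceError(ValueError):
    """An imaging day has no control ROIs and no reference divisor."""


@dataclass(frozen=True)
class ImagePair:
    """Two equal-shape grayscale channels, optionally masked."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.channel_a, float)
        b = np.asarray(self.channel_b, float)
        if a.shape != b.shape:
            raise ValueError("channels must have equal shapes")
        m = self.mask
        if m is not None:
            m = np.asarray(m, bool)
            if m.shape != a.shape:
                raise ValueError("mask shape must match the channels")
            if m.sum() < 2:
                raise ValueError("mask must keep at least 2 pixels")
        elif a.size < 2:
            raise ValueError("need at least 2 pixels")
        object.__setattr__(self, "channel_a", a)
        object.__setattr__(self, "channel_b", b)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class RoiPair:
    """Mean intensity of a signal ROI (over a macrophage) and of an
    adjacent macrophage-free background ROI, with the imaging-day label."""

    signal_mean: float
    background_mean: float
    day_id: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.signal_mean < 0 or self.background_mean < 0:
            raise ValueError("ROI means must be >= 0")


@dataclass(frozen=True)
class MigrationPercent:
    """Raw percent of expected migration, plus the 0-clamped value and a
    flag marking that clamping occurred (movement opposite the target)."""

    raw: float
    value: float
    clamped: bool


def pearson_coloc(pair: ImagePair) -> float:
    """Sample Pearson correlation of the two channels over unmasked pixels.

    Plain Pearson over the mask — no Costes-style auto-thresholding.
    """
    a = pair.channel_a
    b = pair.channel_b
    if pair.mask is not None:
        a = a[pair.mask]
        b = b[pair.mask]
    a = a.ravel()
    b = b.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantChannelError("constant channel: correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r)


def t_antigen_au(
    measurements: Sequence[RoiPair] | pd.DataFrame,
    reference_day_control_mean: float | None = None,
) -> pd.DataFrame:
    """Arbitrary-unit normalization of background-subtracted ROI signal.

    For each ROI pair, background is subtracted from signal individually;
    each value is then divided by the mean background-subtracted signal of
    the *control* ROIs from the same imaging day (so the control-group mean
    is 1 per day by construction, and per-day laser-gain differences cancel).
    A day with no controls uses ``reference_day_control_mean`` if given,
    otherwise raises MissingReferenceError.

    Accepts RoiPair sequences or a DataFrame with columns signal_mean,
    background_mean, day_id, is_control; returns that table with
    ``net`` and ``au`` columns added.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
        required = {"signal_mean", "background_mean", "day_id", "is_control"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [
                {
                    "signal_mean": m.signal_mean,
                    "background_mean": m.background_mean,
                    "day_id": m.day_id,
                    "is_control": m.is_control,
                }
            for m in measurements
            ]
        )
    if df.empty:
        raise ValueError("no measurements")
    df["net"] = df["signal_mean"] - df["background_mean"]
    divisors: dict = {}
    for day, g in df.groupby("day_id"):
        ctrl = g.loc[g["is_control"].astype(bool), "net"]
        if len(ctrl):
            divisors[day] = float(ctrl.mean())
        elif reference_day_control_mean is not None:
            divisors[day] = float(reference_day_control_mean)
        else:
            raise MissingReferenceError(
                f"imaging day {day!r} has no control ROIs and no reference"
            )
    bad = [d for d, v in divisors.items() if v == 0]
    if bad:
        raise ValueError(f"zero control mean on day(s) {bad}: AU undefined")
    df["au"] = df["net"] / df["day_id"].map(divisors)
    return df


def line_profile(
    image: np.ndarray,
    p0: Sequence[float],
    p1: Sequence[float],
    pixel_size: float,
    n_samples: int = 50,
) -> pd.DataFrame:
    """Per-channel intensity along a line, bilinearly interpolated.

    ``image`` is (H, W) or (C, H, W); ``p0``/``p1`` are (x, y) endpoints in
    micrometres, with x along columns and y along rows and the origin at
    the centre of the top-left pixel (so pixel (r, c) sits at physical
    (c*pixel_size, r*pixel_size)).  Returns a DataFrame with distance_um
    (from p0) and one column per channel, sampled at ``n_samples``
    equidistant points including both endpoints.
    """
    img = np.asarray(image, float)
    if img.ndim == 2:
        img = img[None, ...]
    if img.ndim != 3:
        raise ValueError("image must be (H, W) or (C, H, W)")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if p0.shape != (2,) or p1.shape != (2,):
        raise ValueError("endpoints must be 2D (x, y) in um")
    if np.allclose(p0, p1):
        raise ValueError("endpoints must differ")
    _, h, w = img.shape
    for pt in (p0, p1):
        col, row = pt / pixel_size
        if not (0 <= col <= w - 1 and 0 <= row <= h - 1):
            raise ValueError(f"endpoint {tuple(pt)} um lies outside the raster")
    frac = np.linspace(0.0, 1.0, n_samples)
    xs = (p0[0] + frac * (p1[0] - p0[0])) / pixel_size  # columns
    ys = (p0[1] + frac * (p1[1] - p0[1])) / pixel_size  # rows
    out = {"distance_um": frac * float(np.linalg.norm(p1 - p0))}
    for c in range(img.shape[0]):
        out[f"ch{c}"] = ndimage.map_coordinates(
            img[c], np.vstack([ys, xs]), order=1, mode="nearest"
        )
    return pd.DataFrame(out)


def border_cell_migration_pct(
    current_position: Sequence[float],
    origin: Sequence[float],
    target: Sequence[float],
) -> MigrationPercent:
    """Percent of expected migration along the origin-to-target axis.

    100 * projection of (current - origin) onto the unit origin-to-target
    direction, divided by the full origin-to-target distance; 0 at the
    origin, 100 at the target (values > 100 mean overshoot and are
    reported as-is).  Negative raw values (movement away) are clamped to 0
    with the flag set.
    """
    cur = np.asarray(current_position, float)
    o = np.asarray(origin, float)
    t = np.asarray(target, float)
    axis = t - o
    d2 = float(axis @ axis)
    if d2 == 0 or not np.all(np.isfinite(np.concatenate([cur, o, t]))):
        raise ValueError("origin and target must be distinct and finite")
    raw = 100.0 * float((cur - o) @ axis) / d2
    clamped = raw < 0
    return MigrationPercent(raw=raw, value=max(raw, 0.0), clamped=clamped)
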