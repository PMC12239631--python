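"""Bout segmentation and kinematic profiling of larval zebrafish tracking.

A larva in a square well of a 96-well plate is tracked as a centroid
``(x, y)`` plus a per-frame pixel-change scalar ``dpx`` (how many camera
pixels changed between consecutive frames; here a displacement-coupled
proxy, see :mod:`zfbattery.synthetic`).  Zebrafish larvae swim in discrete
bouts: short bursts of movement separated by rest.  This module

* segments bouts as supra-threshold runs of ``dpx`` (short gaps merged,
  runt runs discarded),
* computes the per-bout kinematic battery: start-to-end displacement,
  path distance, duration, mean speed, cumulative revolutions, fraction of
  frames spent in the central zone of the well,
* applies the rule-based classifier for seizure-like movements (high-speed
  circling): more than 4 full revolutions, path distance over 70 px, mean
  speed between 0.3 and 1.3 px/ms,
* bins bouts into labeled epochs and fixed-width time bins for the
  downstream statistics.

Frame indices are 0-based and intervals half-open throughout; times are
milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "FrameSeries",
    "WellGeometry",
    "BoutParams",
    "KinematicMeasures",
    "SEIZURE_MIN_REVOLUTIONS",
    "SEIZURE_MIN_DISTANCE_PX",
    "SEIZURE_SPEED_RANGE_PX_MS",
    "segment_bouts",
    "bout_kinematics",
    "classify_seizure",
    "bout_table",
    "bin_measures",
    "BASELINE_MEASURES",
]

# Seizure-like movement rule: strictly more than 4 full revolutions, path
# distance strictly over 70 px, mean speed inside the inclusive band
# 0.3-1.3 px/ms.
SEIZURE_MIN_REVOLUTIONS = 4.0
SEIZURE_MIN_DISTANCE_PX = 70.0
SEIZURE_SPEED_RANGE_PX_MS = (0.3, 1.3)


@dataclass
class FrameSeries:
    """One well's tracking record: timestamps (ms), centroid, pixel change."""

    fps: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dpx: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.dpx = np.asarray(self.dpx, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.dpx) == n):
            raise ValidationError("FrameSeries arrays must have equal length")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if n and (np.nanmin(self.dpx) < 0):
            raise ValidationError("dpx must be nonnegative")
        if n and (np.isnan(self.x).any() or np.isnan(self.y).any()):
            raise ValidationError("centroid contains NaN")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class WellGeometry:
    """Square well; the center zone is a concentric square whose side is
    ``center_fraction_linear`` times the well side (default 0.5, i.e. 25%
    of the well area)."""

    side_px: float
    center_fraction_linear: float = 0.5

    def __post_init__(self) -> None:
        if self.side_px <= 0:
            raise ValidationError("side_px must be positive")
        if not 0.0 < self.center_fraction_linear < 1.0:
            raise ValidationError("center_fraction_linear must be in (0, 1)")


@dataclass
class BoutParams:
    """Segmentation constants.

    dpx_threshold
        activity threshold on the pixel-change channel.
    min_bout_frames
        merged runs shorter than this are discarded (2 frames ~ 66 ms at
        30 fps).
    min_gap_frames
        supra-threshold runs separated by fewer sub-threshold frames than
        this are merged into one bout.
    heading_min_step_px
        steps smaller than this do not update the heading, so tracking
        jitter cannot accumulate spurious revolutions.
    """

    dpx_threshold: float = 2.0
    min_bout_frames: int = 2
    min_gap_frames: int = 3
    heading_min_step_px: float = 1.0

    def __post_init__(self) -> None:
        if self.dpx_threshold <= 0 or self.heading_min_step_px <= 0:
            raise ValidationError("thresholds must be positive")
        if self.min_bout_frames < 1 or self.min_gap_frames < 1:
            raise ValidationError("frame counts must be >= 1")


@dataclass
class KinematicMeasures:
    displacement_px: float
    distance_px: float
    duration_ms: float
    velocity_px_ms: float
    revolutions: float
    center_fraction: float
    is_seizure: bool = False


def segment_bouts(series: FrameSeries, params: BoutParams) -> list[tuple[int, int]]:
    """Detect movement bouts as maximal supra-threshold runs of ``dpx``.

    Runs separated by fewer than ``min_gap_frames`` sub-threshold frames
    are merged; merged runs shorter than ``min_bout_frames`` are dropped.
    Returns disjoint, ordered half-open frame-index intervals.
    """
    if len(series) == 0:
        return []
    active = series.dpx > params.dpx_threshold
    if not active.any():
        return []
    edges = np.diff(active.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if active[0]:
        starts = np.concatenate(([0], starts))
    if active[-1]:
        ends = np.concatenate((ends, [len(active)]))
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < params.min_gap_frames:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged if e - s >= params.min_bout_frames]


def _revolutions(dx: np.ndarray, dy: np.ndarray, step: np.ndarray,
                 min_step: float) -> float:
    keep = step >= min_step
    if keep.sum() < 2:
        return 0.0
    headings = np.degrees(np.arctan2(dy[keep], dx[keep]))
    dh = np.diff(headings)
    dh = (dh + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    return float(np.abs(dh).sum() / 360.0)


def bout_kinematics(series: FrameSeries, interval: tuple[int, int],
                    geometry: WellGeometry, params: BoutParams) -> KinematicMeasures:
    """Kinematic battery for one bout (half-open frame interval).

    Speed is path distance divided by duration in ms; revolutions is the
    cumulative absolute wrapped heading change over steps of at least
    ``heading_min_step_px``, in units of full turns.
    """
    i0, i1 = interval
    if not (0 <= i0 <= i1 <= len(series)):
        raise ValidationError(f"interval {interval} outside series of length {len(series)}")
    if i1 - i0 < 2:
        dur = float(series.t[i1 - 1] - series.t[i0]) if i1 > i0 else 0.0
        return KinematicMeasures(0.0, 0.0, dur, 0.0, 0.0, 0.0)
    x = series.x[i0:i1]
    y = series.y[i0:i1]
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    distance = float(step.sum())
    displacement = float(math.hypot(x[-1] - x[0], y[-1] - y[0]))
    duration = float(series.t[i1 - 1] - series.t[i0])
    velocity = distance / duration if duration > 0 else 0.0
    revs = _revolutions(dx, dy, step, params.heading_min_step_px)
    half = geometry.side_px * geometry.center_fraction_linear / 2.0
    c = geometry.side_px / 2.0
    inside = (np.abs(x - c) <= half) & (np.abs(y - c) <= half)
    measures = KinematicMeasures(
        displacement_px=displacement,
        distance_px=distance,
        duration_ms=duration,
        velocity_px_ms=velocity,
        revolutions=revs,
        center_fraction=float(inside.mean()),
    )
    measures.is_seizure = classify_seizure(measures)
    return measures


def classify_seizure(k: KinematicMeasures) -> bool:
    """Seizure-like movement rule: > 4 full revolutions (strict), path
    distance > 70 px (strict), mean speed in [0.3, 1.3] px/ms (inclusive)."""
    lo, hi = SEIZURE_SPEED_RANGE_PX_MS
    return (
        k.revolutions > SEIZURE_MIN_REVOLUTIONS
        and k.distance_px > SEIZURE_MIN_DISTANCE_PX
        and lo <= k.velocity_px_ms <= hi
    )


_MEASURE_COLS = [
    "displacement_px",
    "distance_px",
    "duration_ms",
    "velocity_px_ms",
    "revolutions",
    "center_fraction",
]

#: Baseline (non-stimulus) measures produced by :func:`bin_measures`.
BASELINE_MEASURES = ["bout_count", "seizure_count"] + [f"mean_{c}" for c in _MEASURE_COLS]


def bout_table(series_map: dict[str, FrameSeries], geometry: WellGeometry,
               params: BoutParams) -> pd.DataFrame:
    """Segment and score every well; one row per bout with its absolute
    start time (``t_start_ms``) and kinematic measures."""
    rows = []
    for well in sorted(series_map):
        series = series_map[well]
        for i0, i1 in segment_bouts(series, params):
            k = bout_kinematics(series, (i0, i1), geometry, params)
            rows.append({
                "well": well,
                "t_start_ms": float(series.t[i0]),
                "displacement_px": k.displacement_px,
                "distance_px": k.distance_px,
                "duration_ms": k.duration_ms,
                "velocity_px_ms": k.velocity_px_ms,
                "revolutions": k.revolutions,
                "center_fraction": k.center_fraction,
                "is_seizure": k.is_seizure,
            })
    cols = ["well", "t_start_ms"] + _MEASURE_COLS + ["is_seizure"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def bin_measures(bouts: pd.DataFrame, bin_width_ms: float,
                 epochs: list[tuple[str, float, float]],
                 wells: list[str]) -> pd.DataFrame:
    """Bin bouts per well into labeled epochs and fixed-width bins.

    Each row is one (well, epoch, bin): ``bout_count`` and
    ``seizure_count`` (zeros where no bouts) plus per-bin means of every
    kinematic measure (NaN where no bouts).  A bout belongs to the bin its
    start time falls in; epochs are half-open ``[start_ms, end_ms)`` spans
    and may overlap (e.g. "all" plus day/night segments).
    """
    if bin_width_ms <= 0:
        raise ValidationError("bin_width_ms must be positive")
    out = []
    for label, t0, t1 in epochs:
        if t1 <= t0:
            raise ValidationError(f"epoch {label!r} has nonpositive span")
        n_bins = int(math.ceil((t1 - t0) / bin_width_ms))
        if len(bouts):
            sel = bouts[(bouts["t_start_ms"] >= t0) & (bouts["t_start_ms"] < t1)].copy()
        else:
            sel = bouts.copy()
        if len(sel):
            sel["bin"] = ((sel["t_start_ms"] - t0) // bin_width_ms).astype(int)
            grouped = sel.groupby(["well", "bin"])
            counts = grouped.size()
            seiz = grouped["is_seizure"].sum()
            means = grouped[_MEASURE_COLS].mean()
        else:
            counts = seiz = means = None
        index = pd.MultiIndex.from_product([wells, range(n_bins)], names=["well", "bin"])
        frame = pd.DataFrame(index=index)
        if counts is not None:
            frame["bout_count"] = counts.reindex(index).fillna(0).astype(int)
            frame["seizure_count"] = seiz.reindex(index).fillna(0).astype(int)
            for c in _MEASURE_COLS:
                frame[f"mean_{c}"] = means[c].reindex(index)
        else:
            frame["bout_count"] = 0
            frame["seizure_count"] = 0
            for c in _MEASURE_COLS:
                frame[f"mean_{c}"] = np.nan
        frame = frame.reset_index()
        frame.insert(0, "epoch", label)
        frame["bin_start_ms"] = t0 + frame["bin"] * bin_width_ms
        out.append(frame)
    result = pd.concat(out, ignore_index=True)
    cols = ["epoch", "well", "bin", "bin_start_ms"] + BASELINE_MEASURES
    return result[cols]
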