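"""Scoring of stimulus responses from 1-s high-speed tracking windows.

The behavioral battery interleaves visual stimuli (dark flashes, light
flashes) and acoustic-vibrational stimuli (strong taps, weak taps,
prepulses) with repeated habituation blocks.  Responses are scored from
high-speed (285 fps) windows of 1 s around each stimulus: a larva
responded if its pixel-change trace crosses the activity threshold after
onset; latency is the time of the first supra-threshold frame and the
response magnitude is measured over the contiguous movement that starts
there.  Habituation is the decline of response frequency across a block
of identical stimuli, expressed relative to a pre-habituation block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError, logger
from .features import FrameSeries

__all__ = [
    "STIM_TYPES",
    "StimulusEvent",
    "ResponseParams",
    "ResponseScore",
    "detect_response",
    "response_frequency",
    "average_responder_trace",
    "habituation_index",
    "score_dataset",
]

STIM_TYPES = ("dark_flash", "light_flash", "tap_strong", "tap_weak", "prepulse")


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus: type, absolute onset time (ms), block label."""

    type: str
    time_ms: float
    block: str

    def __post_init__(self) -> None:
        if self.type not in STIM_TYPES:
            raise ValidationError(f"unknown stimulus type {self.type!r}")


@dataclass
class ResponseParams:
    """Response threshold on dpx (defaults to the segmentation threshold)
    and the length of the causal scoring window after onset."""

    dpx_threshold: float = 2.0
    window_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.dpx_threshold <= 0 or self.window_ms <= 0:
            raise ValidationError("response params must be positive")


@dataclass
class ResponseScore:
    responded: bool
    latency_ms: float  # NaN when no response
    magnitude_displacement_px: float
    magnitude_dpx_sum: float


def detect_response(window: FrameSeries, onset_ms: float,
                    params: ResponseParams | None = None) -> ResponseScore:
    """Score one high-speed window against one stimulus onset.

    The window must cover ``[onset, onset + window_ms]`` (to within one
    frame interval).  Frames before onset are ignored, so the score is
    invariant to any pre-onset activity.
    """
    params = params or ResponseParams()
    if len(window) < 2:
        raise ValidationError("window too short")
    dt = 1000.0 / window.fps
    if window.t[0] > onset_ms + 0.5 * dt or window.t[-1] < onset_ms + params.window_ms - 1.5 * dt:
        raise ValidationError(
            f"window [{window.t[0]:.1f}, {window.t[-1]:.1f}] ms does not cover "
            f"[{onset_ms:.1f}, {onset_ms + params.window_ms:.1f}] ms"
        )
    mask = (window.t >= onset_ms) & (window.t <= onset_ms + params.window_ms)
    idx = np.flatnonzero(mask & (window.dpx > params.dpx_threshold))
    if idx.size == 0:
        return ResponseScore(False, float("nan"), 0.0, 0.0)
    first = int(idx[0])
    # contiguous supra-threshold movement beginning at the first crossing
    last = first
    stop = int(np.flatnonzero(mask)[-1])
    while last + 1 <= stop and window.dpx[last + 1] > params.dpx_threshold:
        last += 1
    latency = float(window.t[first] - onset_ms)
    disp = float(np.hypot(window.x[last] - window.x[first], window.y[last] - window.y[first]))
    return ResponseScore(True, latency, disp, float(window.dpx[first:last + 1].sum()))


def response_frequency(scores: list[ResponseScore]) -> float:
    """Fraction of events with a response."""
    if not scores:
        raise ValidationError("response frequency undefined for zero events")
    return sum(s.responded for s in scores) / len(scores)


def average_responder_trace(windows: list[FrameSeries]) -> np.ndarray:
    """Pointwise mean dpx trace over responder windows, frame-aligned to
    onset (windows are truncated to the shortest length)."""
    if not windows:
        raise ValidationError("no responder windows")
    n = min(len(w) for w in windows)
    return np.mean([w.dpx[:n] for w in windows], axis=0)


def habituation_index(pre_freq: float, block_freqs: list[float]) -> list[float]:
    """Per-block response frequency relative to the pre-habituation block;
    values below 1 indicate habituation."""
    if pre_freq <= 0:
        raise ValidationError("habituation index undefined when pre-block frequency is 0")
    return [b / pre_freq for b in block_freqs]


def score_dataset(highspeed_windows: dict[tuple[str, int], FrameSeries],
                  stim_log: list[StimulusEvent],
                  params: ResponseParams | None = None) -> pd.DataFrame:
    """Score every (well, event) high-speed window.

    Returns one row per window: well, event index, stimulus type, block,
    responded, latency_ms, magnitude_displacement_px, magnitude_dpx_sum.
    """
    params = params or ResponseParams()
    rows = []
    for (well, event_idx) in sorted(highspeed_windows):
        if event_idx >= len(stim_log):
            logger.warning("window (%s, %d) has no stimulus event; skipped", well, event_idx)
            continue
        ev = stim_log[event_idx]
        s = detect_response(highspeed_windows[(well, event_idx)], ev.time_ms, params)
        rows.append({
            "well": well,
            "event": event_idx,
            "type": ev.type,
            "block": ev.block,
            "responded": s.responded,
            "latency_ms": s.latency_ms,
            "magnitude_displacement_px": s.magnitude_displacement_px,
            "magnitude_dpx_sum": s.magnitude_dpx_sum,
        })
    cols = ["well", "event", "type", "block", "responded", "latency_ms",
            "magnitude_displacement_px", "magnitude_dpx_sum"]
    return pd.DataFrame(rows, columns=cols)
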