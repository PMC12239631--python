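"""Synthetic plates of larval zebrafish tracking data with known effects.

The generator emulates the behavioral rig at desk scale: each well holds
one larva whose locomotion is a two-state renewal process (exponential
rest dwells alternating with gamma-distributed movement bouts rendered as
smooth centroid arcs), with optional seizure-like circling bouts inserted
as a Poisson process, and 1-s high-speed windows around each stimulus in
which the larva responds with probability ``p_respond`` attenuated by a
habituation decay within each block.  Genotype effects enter as named
multipliers on these parameters, so every downstream stage can be tested
against planted ground truth.

The pixel-change channel ``dpx`` is synthesized as the per-frame centroid
displacement plus small positive noise — a displacement-coupled proxy for
the camera's between-frame changed-pixel count that preserves the
structure bout segmentation needs.

The module also plants structure for the transcriptomic stage: DE tables
with shifted gene sets (:func:`simulate_deg_table`) and negative-binomial
cluster-expression matrices with up-shifted marker genes
(:func:`simulate_cluster_matrix`).

Determinism: one RNG stream per well is derived from ``(seed, well
index)``, so the same seed and config reproduce a byte-identical dataset
and adding wells never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError, logger
from .features import FrameSeries
from .stimulus import STIM_TYPES, StimulusEvent

__all__ = [
    "SimConfig",
    "PlateDataset",
    "default_stim_schedule",
    "simulate_plate",
    "simulate_seizure_bout",
    "simulate_deg_table",
    "simulate_cluster_matrix",
]

# sd of the positive noise added to the displacement-coupled dpx proxy (px)
DPX_NOISE_SD = 0.3
# margin kept between the centroid and the well walls (px)
WALL_MARGIN_PX = 6.0
# guard band around an inserted seizure bout within which ordinary bouts
# are dropped, so segmentation cannot merge them into the seizure (ms)
SEIZURE_BUFFER_MS = 200.0
# startle-like speed range for stimulus-response bursts (px/ms); fast
# enough that the high-speed per-frame displacement clears the response
# threshold
RESPONSE_PEAK_SPEED_RANGE = (0.8, 1.5)

_MULTIPLIER_KEYS = {
    "bout_rate", "bout_duration", "bout_peak_speed", "turn_sd",
    "center_bias", "seizure_rate", "p_respond", "habituation_decay",
}


def _default_p_respond() -> dict[str, float]:
    return {
        "dark_flash": 0.8,
        "light_flash": 0.5,
        "tap_strong": 0.9,
        "tap_weak": 0.4,
        "prepulse": 0.6,
    }


@dataclass
class SimConfig:
    """Generator parameters.

    Plate composition defaults to the scale of a real run (23 homozygous
    mutants, 18 wild types, 36 heterozygotes in a 96-well plate); timing
    is compressed to a 10-minute desk-scale experiment with the stimulus
    block structure preserved in miniature.
    """

    seed: int = 0
    n_per_genotype: dict[str, int] = field(
        default_factory=lambda: {"wt": 18, "hom": 23, "het": 36})
    well_size_px: float = 200.0
    baseline_fps: float = 30.0
    highspeed_fps: float = 285.0
    duration_s: float = 600.0
    rest_mean_s: float = 1.5
    bout_duration_ms: float = 200.0
    bout_peak_speed_px_ms: float = 0.25
    turn_sd_deg: float = 25.0
    center_bias: float = 0.3
    seizure_rate_per_h: float = 1.0
    stim_schedule: list[StimulusEvent] | None = None
    p_respond: dict[str, float] = field(default_factory=_default_p_respond)
    habituation_decay: float = 0.85
    effect_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("well_size_px", "baseline_fps", "highspeed_fps",
                     "duration_s", "rest_mean_s", "bout_duration_ms",
                     "bout_peak_speed_px_ms", "turn_sd_deg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.seizure_rate_per_h < 0:
            raise ValidationError("seizure_rate_per_h must be nonnegative")
        if not 0.0 <= self.center_bias <= 1.0:
            raise ValidationError("center_bias must be in [0, 1]")
        if not 0.0 < self.habituation_decay <= 1.0:
            raise ValidationError("habituation_decay must be in (0, 1]")
        for k, v in self.p_respond.items():
            if k not in STIM_TYPES:
                raise ValidationError(f"unknown stimulus type in p_respond: {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"p_respond[{k!r}] must be in [0, 1]")
        for n in self.n_per_genotype.values():
            if n < 0 or n != int(n):
                raise ValidationError("n_per_genotype counts must be nonnegative integers")
        for geno, mults in self.effect_multipliers.items():
            unknown = set(mults) - _MULTIPLIER_KEYS
            if unknown:
                raise ValidationError(
                    f"unknown effect multiplier(s) for {geno!r}: {sorted(unknown)}")
            for k, m in mults.items():
                if m < 0:
                    raise ValidationError("effect multipliers must be nonnegative")
        if self.seizure_rate_per_h > 0:
            _seizure_radius_bounds(self)  # raises if the well is too small


@dataclass
class PlateDataset:
    """Simulated plate: per-well baseline tracking, the stimulus log, the
    genotype map, and one 1-s high-speed window per (well, event).

    ``truth`` holds the generator's planted ground truth per well (bout
    and seizure event start times) so tests can separate generative
    properties from detection losses; it is empty for datasets read from
    disk."""

    frame_series: dict[str, FrameSeries]
    stim_log: list[StimulusEvent]
    genotypes: dict[str, str]
    highspeed_windows: dict[tuple[str, int], FrameSeries]
    truth: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def wells(self) -> list[str]:
        return sorted(self.frame_series)


def default_stim_schedule(duration_s: float) -> list[StimulusEvent]:
    """Compressed default battery: a light-flash block, a mixed acoustic
    pre-habituation block (strong/weak taps and prepulses), three acoustic
    habituation blocks of strong taps, three dark-flash blocks."""
    blocks: list[tuple[str, list[str]]] = [
        ("light", ["light_flash"] * 5),
        ("pre", ["tap_strong", "tap_weak", "prepulse"] * 4),
        ("hab1", ["tap_strong"] * 8),
        ("hab2", ["tap_strong"] * 8),
        ("hab3", ["tap_strong"] * 8),
        ("df1", ["dark_flash"] * 5),
        ("df2", ["dark_flash"] * 5),
        ("df3", ["dark_flash"] * 5),
    ]
    n = sum(len(types) for _, types in blocks)
    spacing = duration_s * 1000.0 / (n + 1)
    if spacing < 1100.0:
        raise ValidationError(
            f"duration_s={duration_s} too short for the default schedule of {n} events")
    events = []
    i = 0
    for block, types in blocks:
        for typ in types:
            events.append(StimulusEvent(typ, (i + 1) * spacing, block))
            i += 1
    return events


# ---------------------------------------------------------------------------
# per-genotype effective parameters

def _resolve_params(config: SimConfig, genotype: str) -> dict:
    p = {
        "rest_mean_ms": config.rest_mean_s * 1000.0,
        "bout_duration_ms": config.bout_duration_ms,
        "bout_peak_speed": config.bout_peak_speed_px_ms,
        "turn_sd_deg": config.turn_sd_deg,
        "center_bias": config.center_bias,
        "seizure_rate_per_h": config.seizure_rate_per_h,
        "p_respond": dict(config.p_respond),
        "habituation_decay": config.habituation_decay,
    }
    mults = config.effect_multipliers.get(genotype, {})
    if "bout_duration" in mults:
        p["bout_duration_ms"] *= mults["bout_duration"]
    if "bout_rate" in mults:
        # scale the renewal rate 1/(rest + bout) exactly by m
        m = mults["bout_rate"]
        if m <= 0:
            raise ValidationError("bout_rate multiplier must be positive")
        cycle = p["rest_mean_ms"] + p["bout_duration_ms"]
        rest = cycle / m - p["bout_duration_ms"]
        if rest <= 0:
            raise ValidationError(
                f"bout_rate multiplier {m} infeasible: implied rest dwell <= 0")
        p["rest_mean_ms"] = rest
    if "bout_peak_speed" in mults:
        p["bout_peak_speed"] *= mults["bout_peak_speed"]
    if "turn_sd" in mults:
        p["turn_sd_deg"] *= mults["turn_sd"]
    if "center_bias" in mults:
        p["center_bias"] = min(1.0, p["center_bias"] * mults["center_bias"])
    if "seizure_rate" in mults:
        p["seizure_rate_per_h"] *= mults["seizure_rate"]
    if "p_respond" in mults:
        p["p_respond"] = {k: min(1.0, v * mults["p_respond"])
                          for k, v in p["p_respond"].items()}
    if "habituation_decay" in mults:
        p["habituation_decay"] = min(1.0, p["habituation_decay"] * mults["habituation_decay"])
    return p


# ---------------------------------------------------------------------------
# trajectory primitives

def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    period = 2.0 * (hi - lo)
    w = np.mod(v - lo, period)
    return lo + np.minimum(w, period - w)


def _bout_path(rng: np.random.Generator, pos: np.ndarray, n_points: int,
               dt_ms: float, peak_speed: float, turn_sd_deg: float,
               center_bias: float, side: float) -> np.ndarray:
    """Smooth arc of ``n_points`` centroid positions starting at ``pos``,
    with a half-sine speed profile and a random-walk heading; the initial
    heading points toward the well center with probability ``center_bias``."""
    n_steps = n_points - 1
    j = np.arange(n_steps)
    speeds = peak_speed * np.sin(math.pi * (j + 0.5) / n_steps)
    center = np.array([side / 2.0, side / 2.0])
    if rng.random() < center_bias and not np.allclose(pos, center):
        h0 = math.atan2(center[1] - pos[1], center[0] - pos[0])
        h0 += rng.normal(0.0, math.radians(30.0))
    else:
        h0 = rng.uniform(0.0, 2.0 * math.pi)
    turns = rng.normal(0.0, math.radians(turn_sd_deg), n_steps)
    turns[0] = 0.0
    headings = h0 + np.cumsum(turns)
    steps = speeds[:, None] * dt_ms * np.column_stack(
        [np.cos(headings), np.sin(headings)])
    path = np.vstack([pos, pos + np.cumsum(steps, axis=0)])
    lo, hi = WALL_MARGIN_PX, side - WALL_MARGIN_PX
    return np.column_stack([_reflect(path[:, 0], lo, hi),
                            _reflect(path[:, 1], lo, hi)])


def _seizure_radius_bounds(config: SimConfig) -> tuple[float, float, int]:
    """Feasible circle radius range and steps-per-revolution for seizure
    bouts at the baseline frame rate; raises if the well is too small."""
    dt = 1000.0 / config.baseline_fps
    spr = max(8, int(round(config.baseline_fps / 3.0)))
    chord_per_speed = dt / (2.0 * math.sin(math.pi / spr))
    r_min = 0.35 * chord_per_speed  # radius at the slowest admissible speed
    r_max = 0.95 * (config.well_size_px / 2.0 - WALL_MARGIN_PX)
    if r_min > r_max:
        raise ValidationError(
            f"well_size_px={config.well_size_px} too small to contain a "
            "seizure-like circling bout at this frame rate")
    return r_min, r_max, spr


def _draw_seizure_spec(config: SimConfig, rng: np.random.Generator
                       ) -> tuple[float, float]:
    """(revolutions, chord speed) for one seizure bout: 4.6-5.6 turns at
    0.5-1.05 px/ms, capped so the circle fits the well; keeps measured
    revolutions > 4.4, path distance > 70 px and measured speed inside
    [0.3, 1.3] px/ms by construction."""
    dt = 1000.0 / config.baseline_fps
    _, r_max, spr = _seizure_radius_bounds(config)
    chord_per_speed = dt / (2.0 * math.sin(math.pi / spr))
    revs = rng.uniform(4.6, 5.6)
    speed = min(rng.uniform(0.5, 1.05), r_max / chord_per_speed)
    return revs, speed


def _seizure_path(config: SimConfig, rng: np.random.Generator,
                  pos: np.ndarray, revs: float | None = None,
                  speed: float | None = None) -> np.ndarray:
    """Circular centroid path implementing one seizure-like bout, anchored
    at the nearest circle point to ``pos`` and kept inside the well."""
    dt = 1000.0 / config.baseline_fps
    _, _, spr = _seizure_radius_bounds(config)
    if revs is None or speed is None:
        revs, speed = _draw_seizure_spec(config, rng)
    chord_per_speed = dt / (2.0 * math.sin(math.pi / spr))
    r = speed * chord_per_speed
    side = config.well_size_px
    center = np.clip(pos, WALL_MARGIN_PX + r, side - WALL_MARGIN_PX - r)
    offset = pos - center
    phi0 = math.atan2(offset[1], offset[0]) if np.hypot(*offset) > 1e-9 \
        else rng.uniform(0.0, 2.0 * math.pi)
    direction = 1.0 if rng.random() < 0.5 else -1.0
    n_steps = int(round(revs * spr))
    phi = phi0 + direction * 2.0 * math.pi * np.arange(n_steps + 1) / spr
    return center + r * np.column_stack([np.cos(phi), np.sin(phi)])


def simulate_seizure_bout(config: SimConfig, rng_state) -> FrameSeries:
    """A standalone seizure-like bout at the baseline frame rate, placed
    at the well center, with ``dpx`` equal to the per-step displacement
    (first frame included so the whole segment is one supra-threshold run)."""
    rng = rng_state if isinstance(rng_state, np.random.Generator) \
        else np.random.default_rng(rng_state)
    center = np.array([config.well_size_px / 2.0] * 2)
    path = _seizure_path(config, rng, center)
    dt = 1000.0 / config.baseline_fps
    t = np.arange(len(path)) * dt
    step = np.hypot(*np.diff(path, axis=0).T)
    dpx = np.concatenate([[step[0]], step])
    return FrameSeries(config.baseline_fps, t, path[:, 0], path[:, 1], dpx)


# ---------------------------------------------------------------------------
# plate simulation

def _simulate_well_frames(config: SimConfig, params: dict,
                          rng: np.random.Generator
                          ) -> tuple[FrameSeries, dict[str, np.ndarray]]:
    fps = config.baseline_fps
    dt = 1000.0 / fps
    duration_ms = config.duration_s * 1000.0
    n = int(round(config.duration_s * fps))
    side = config.well_size_px
    lo, hi = WALL_MARGIN_PX, side - WALL_MARGIN_PX

    # renewal process of ordinary bouts: (start_ms, duration_ms)
    bouts: list[tuple[float, float]] = []
    tcur = 0.0
    while True:
        rest = rng.exponential(params["rest_mean_ms"])
        bstart = tcur + rest
        bdur = rng.gamma(3.0, params["bout_duration_ms"] / 3.0)
        if bstart + bdur >= duration_ms:
            break
        bouts.append((bstart, bdur))
        tcur = bstart + bdur

    # Poisson seizure insertions; overlapping ordinary bouts are dropped
    # spec entries: (start_ms, duration_ms, revolutions, chord speed)
    seizures: list[tuple[float, float, float, float]] = []
    rate = params["seizure_rate_per_h"] * config.duration_s / 3600.0
    n_seiz = rng.poisson(rate) if rate > 0 else 0
    _, _, spr = _seizure_radius_bounds(config) if n_seiz else (0, 0, 0)
    for _ in range(n_seiz):
        revs, speed = _draw_seizure_spec(config, rng)
        sdur = int(round(revs * spr)) * dt
        if sdur + 2 * SEIZURE_BUFFER_MS >= duration_ms:
            logger.warning("experiment too short for a seizure bout; skipped")
            continue
        for _attempt in range(20):
            s0 = rng.uniform(SEIZURE_BUFFER_MS, duration_ms - sdur - SEIZURE_BUFFER_MS)
            if all(s0 + sdur + SEIZURE_BUFFER_MS < o0 or o0 + od + SEIZURE_BUFFER_MS < s0
                   for o0, od, _, _ in seizures):
                seizures.append((s0, sdur, revs, speed))
                break
    keep = [
        (b0, bd) for b0, bd in bouts
        if all(b0 + bd + SEIZURE_BUFFER_MS < s0 or s0 + sd + SEIZURE_BUFFER_MS < b0
               for s0, sd, _, _ in seizures)
    ]

    events = sorted(
        [(b0, bd, None) for b0, bd in keep]
        + [(s0, sd, (revs, speed)) for s0, sd, revs, speed in seizures],
        key=lambda e: e[0])

    x = np.empty(n)
    y = np.empty(n)
    pos = rng.uniform(lo + 0.2 * side, hi - 0.2 * side, 2)
    cursor = 0
    for b0, bd, sspec in events:
        i0 = int(math.ceil(b0 / dt))
        if sspec is not None:
            i1 = i0 + int(round(bd / dt)) + 1
        else:
            i1 = int(math.ceil((b0 + bd) / dt))
        i1 = min(i1, n)
        if i1 - i0 < 2 or i0 < cursor:
            continue
        x[cursor:i0] = pos[0]
        y[cursor:i0] = pos[1]
        if sspec is not None:
            # circle anchored at the actual current position
            path = _seizure_path(config, rng, pos, *sspec)[: i1 - i0]
        else:
            path = _bout_path(rng, pos, i1 - i0, dt, params["bout_peak_speed"],
                              params["turn_sd_deg"], params["center_bias"], side)
        x[i0:i1] = path[:, 0]
        y[i0:i1] = path[:, 1]
        pos = path[-1].copy()
        cursor = i1
    x[cursor:] = pos[0]
    y[cursor:] = pos[1]

    disp = np.hypot(np.diff(x), np.diff(y))
    noise = np.abs(rng.normal(0.0, DPX_NOISE_SD, n))
    dpx = noise
    dpx[1:] += disp
    t = np.arange(n) * dt
    truth = {
        "bout_start_ms": np.array([b0 for b0, _ in keep]),
        "seizure_start_ms": np.array([s0 for s0, _, _, _ in seizures]),
    }
    return FrameSeries(fps, t, x, y, dpx), truth


def _within_block_indices(schedule: list[StimulusEvent]) -> list[int]:
    """1-based index of each event among same-(block, type) events, in
    time order — the exponent base for habituation decay."""
    order = sorted(range(len(schedule)), key=lambda i: schedule[i].time_ms)
    counters: dict[tuple[str, str], int] = {}
    k = [0] * len(schedule)
    for i in order:
        key = (schedule[i].block, schedule[i].type)
        counters[key] = counters.get(key, 0) + 1
        k[i] = counters[key]
    return k


def _simulate_windows(config: SimConfig, params: dict, rng: np.random.Generator,
                      schedule: list[StimulusEvent], within_block: list[int],
                      frames: FrameSeries) -> dict[int, FrameSeries]:
    fps = config.highspeed_fps
    dt = 1000.0 / fps
    n = int(round(fps)) + 1  # exactly 1 s inclusive of both endpoints
    side = config.well_size_px
    windows: dict[int, FrameSeries] = {}
    base_dt = 1000.0 / config.baseline_fps
    for idx, ev in enumerate(schedule):
        fi = min(int(ev.time_ms / base_dt), len(frames) - 1)
        pos = np.array([frames.x[fi], frames.y[fi]])
        t = ev.time_ms + np.arange(n) * dt
        x = np.full(n, pos[0])
        y = np.full(n, pos[1])
        noise = np.abs(rng.normal(0.0, DPX_NOISE_SD, n))
        p_eff = params["p_respond"].get(ev.type, 0.0) \
            * params["habituation_decay"] ** (within_block[idx] - 1)
        if rng.random() < p_eff:
            latency = rng.uniform(15.0, 60.0)
            burst_ms = rng.uniform(80.0, 200.0)
            j0 = int(np.searchsorted(t, ev.time_ms + latency))
            n_burst = max(3, int(round(burst_ms / dt)))
            j1 = min(j0 + n_burst, n)
            peak = rng.uniform(*RESPONSE_PEAK_SPEED_RANGE)
            if ev.type == "dark_flash":
                peak *= 1.3  # O-bend responses are large
            path = _bout_path(rng, pos, j1 - j0, dt, peak,
                              params["turn_sd_deg"], params["center_bias"], side)
            x[j0:j1] = path[:, 0]
            y[j0:j1] = path[:, 1]
            x[j1:] = path[-1, 0]
            y[j1:] = path[-1, 1]
        dpx = noise
        dpx[1:] += np.hypot(np.diff(x), np.diff(y))
        windows[idx] = FrameSeries(fps, t, x, y, dpx)
    return windows


def simulate_plate(config: SimConfig) -> PlateDataset:
    """Simulate a full plate under ``config``; deterministic given the
    seed, with an independent RNG stream per well."""
    config.validate()
    schedule = config.stim_schedule
    if schedule is None:
        schedule = default_stim_schedule(config.duration_s)
    duration_ms = config.duration_s * 1000.0
    for ev in schedule:
        if not 0.0 <= ev.time_ms <= duration_ms - 1000.0:
            raise ValidationError(
                f"stimulus at {ev.time_ms} ms does not fit a 1-s window "
                f"inside the {duration_ms:.0f}-ms experiment")
    within_block = _within_block_indices(schedule)

    labels = [g for g in sorted(config.n_per_genotype)
              for _ in range(int(config.n_per_genotype[g]))]
    wells = [f"w{i:03d}" for i in range(len(labels))]
    assign_rng = np.random.default_rng([config.seed, 999_999_999])
    labels = list(np.array(labels)[assign_rng.permutation(len(labels))]) if labels else []

    frame_series: dict[str, FrameSeries] = {}
    genotypes: dict[str, str] = {}
    highspeed: dict[tuple[str, int], FrameSeries] = {}
    truth: dict[str, dict[str, np.ndarray]] = {}
    for i, well in enumerate(wells):
        geno = str(labels[i])
        genotypes[well] = geno
        params = _resolve_params(config, geno)
        rng = np.random.default_rng([config.seed, i])
        frames, well_truth = _simulate_well_frames(config, params, rng)
        frame_series[well] = frames
        truth[well] = well_truth
        for idx, win in _simulate_windows(config, params, rng, schedule,
                                          within_block, frames).items():
            highspeed[(well, idx)] = win
    return PlateDataset(frame_series, list(schedule), genotypes, highspeed, truth)


# ---------------------------------------------------------------------------
# transcriptomic inputs

def gene_universe(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def simulate_deg_table(n_genes: int,
                       planted: Mapping[str, tuple[Sequence[str], float]] | None = None,
                       null_sd: float = 0.3,
                       seed: int = 0) -> pd.DataFrame:
    """Differential-expression table with planted shifts.

    Null genes draw ``log2FoldChange ~ Normal(0, null_sd)``; each planted
    set named in ``planted`` maps to ``(members, delta)`` and its members
    are shifted by ``delta``.  Two-sided p-values are exact under the null
    model, so they are uniform for unshifted genes; ``padj`` is BH.
    """
    if n_genes < 0:
        raise ValidationError("n_genes must be nonnegative")
    if null_sd <= 0:
        raise ValidationError("null_sd must be positive")
    genes = gene_universe(n_genes)
    cols = ["gene", "log2FoldChange", "pvalue", "padj", "baseMean"]
    if n_genes == 0:
        return pd.DataFrame(columns=cols)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng([seed, 7])
    lfc = rng.normal(0.0, null_sd, n_genes)
    if planted:
        assigned: dict[str, float] = {}
        for name, (members, delta) in planted.items():
            for g in members:
                if g not in index:
                    raise ValidationError(f"planted gene {g!r} outside the universe")
                if g in assigned and assigned[g] != delta:
                    raise ValidationError(
                        f"gene {g!r} planted with conflicting shifts "
                        f"{assigned[g]} and {delta}")
                assigned[g] = delta
        for g, delta in assigned.items():
            lfc[index[g]] += delta
    p = 2.0 * stats.norm.sf(np.abs(lfc) / null_sd)
    p = np.maximum(p, 1e-300)
    padj = stats.false_discovery_control(p)
    base = rng.lognormal(5.0, 1.5, n_genes)
    return pd.DataFrame({
        "gene": genes,
        "log2FoldChange": lfc,
        "pvalue": p,
        "padj": padj,
        "baseMean": base,
    })


def simulate_cluster_matrix(n_genes: int,
                            clusters: Mapping[str, tuple[int, Sequence[str], float]],
                            seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial cells-by-genes count matrix with planted markers.

    ``clusters`` maps a cluster label to ``(n_cells, marker_genes,
    fold_up)``; marker genes have their mean multiplied by ``fold_up`` in
    that cluster only.  Returns ``(counts, labels)`` with one row per cell.
    """
    genes = gene_universe(n_genes)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng([seed, 11])
    base_mu = rng.lognormal(0.0, 1.0, n_genes)
    theta = 5.0  # NB dispersion (size)
    blocks = []
    labels = []
    cells = []
    for label in sorted(clusters):
        n_cells, markers, fold_up = clusters[label]
        if n_cells <= 0:
            raise ValidationError(f"cluster {label!r} has no cells")
        if fold_up <= 0:
            raise ValidationError("fold-up must be positive")
        mu = base_mu.copy()
        for g in markers:
            if g not in index:
                raise ValidationError(f"marker gene {g!r} outside the universe")
            mu[index[g]] *= fold_up
        p_nb = theta / (theta + mu)
        blocks.append(rng.negative_binomial(theta, p_nb, size=(n_cells, n_genes)))
        labels.extend([label] * n_cells)
        cells.extend(f"{label}_{j}" for j in range(n_cells))
    counts = pd.DataFrame(np.vstack(blocks) if blocks else
                          np.empty((0, n_genes), dtype=int),
                          index=cells, columns=genes)
    return counts, pd.Series(labels, index=cells, name="cluster")
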