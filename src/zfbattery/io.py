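"""File formats and run configuration.

All formats are tab-separated UTF-8 text with a header row, '.' decimal
and 6-significant-digit floats, written in a deterministic row order so
fixed-seed runs are byte-identical.  Pixel coordinates are 0-based,
origin top-left, y increasing downward (image convention); times are
milliseconds everywhere, never frame counts, so 30 fps baseline data and
285 fps high-speed windows interoperate.

Formats
-------
frame table        well, t_ms, x_px, y_px, dpx
high-speed table   well, event, t_ms, x_px, y_px, dpx  (event = stimulus index)
stimulus log       type, time_ms, block
genotype map       well, genotype
DE table           gene, log2FoldChange, pvalue, padj (DESeq2 dialect;
                   padj recomputed by BH when absent)
gene sets          GMT: name, description, members (tab-separated)
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import ValidationError, logger
from .features import BoutParams, FrameSeries, WellGeometry
from .stimulus import ResponseParams, StimulusEvent
from .synthetic import PlateDataset, SimConfig

__all__ = [
    "FLOAT_FORMAT",
    "read_frame_table", "write_frame_table",
    "read_highspeed_table", "write_highspeed_table",
    "read_stim_log", "write_stim_log",
    "read_genotype_map", "write_genotype_map",
    "read_deg_table", "write_deg_table",
    "read_gmt", "write_gmt",
    "write_table", "read_table",
    "write_plate", "read_plate",
    "RunConfig", "load_run_config",
]

FLOAT_FORMAT = "%.6g"

FRAME_COLUMNS = ["well", "t_ms", "x_px", "y_px", "dpx"]
HS_COLUMNS = ["well", "event", "t_ms", "x_px", "y_px", "dpx"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df


def _to_float(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        try:
            out[c] = pd.to_numeric(out[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-numeric value in column {c!r}: {exc}")
    return out


# ---------------------------------------------------------------------------
# tracking formats

def _frames_from_table(df: pd.DataFrame, fps: float, path, group_cols):
    for key, sub in df.groupby(group_cols, sort=True):
        t = sub["t_ms"].to_numpy(dtype=float)
        if np.isnan(sub[["x_px", "y_px"]].to_numpy(dtype=float)).any():
            bad = int(sub.index[sub[["x_px", "y_px"]].isna().any(axis=1)][0]) + 2
            raise ValidationError(f"{path}: NaN centroid at row {bad}")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(sub.index[1:][np.diff(t) <= 0][0]) + 2
            raise ValidationError(
                f"{path}: non-monotone t_ms for {key!r} at row {bad}")
        yield key, FrameSeries(fps, t, sub["x_px"].to_numpy(dtype=float),
                               sub["y_px"].to_numpy(dtype=float),
                               sub["dpx"].to_numpy(dtype=float))


def read_frame_table(path, fps: float = 30.0) -> dict[str, FrameSeries]:
    """One FrameSeries per well; strict per-well time monotonicity."""
    df = _read_tsv(path, FRAME_COLUMNS)
    if not len(df):
        return {}
    df = _to_float(df, ["t_ms", "x_px", "y_px", "dpx"], path)
    return {key: series for key, series
            in _frames_from_table(df, fps, path, "well")}


def write_frame_table(series_map: dict[str, FrameSeries], path) -> None:
    frames = []
    for well in sorted(series_map):
        s = series_map[well]
        frames.append(pd.DataFrame({
            "well": well, "t_ms": s.t, "x_px": s.x, "y_px": s.y, "dpx": s.dpx}))
    df = pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame(columns=FRAME_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_highspeed_table(path, fps: float = 285.0
                         ) -> dict[tuple[str, int], FrameSeries]:
    df = _read_tsv(path, HS_COLUMNS)
    if not len(df):
        return {}
    df = _to_float(df, ["event", "t_ms", "x_px", "y_px", "dpx"], path)
    return {(well, int(event)): series for (well, event), series
            in _frames_from_table(df, fps, path, ["well", "event"])}


def write_highspeed_table(windows: dict[tuple[str, int], FrameSeries], path) -> None:
    frames = []
    for well, event in sorted(windows):
        s = windows[(well, event)]
        frames.append(pd.DataFrame({
            "well": well, "event": event, "t_ms": s.t,
            "x_px": s.x, "y_px": s.y, "dpx": s.dpx}))
    df = pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame(columns=HS_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_stim_log(path) -> list[StimulusEvent]:
    df = _read_tsv(path, ["type", "time_ms", "block"])
    df = _to_float(df, ["time_ms"], path)
    return [StimulusEvent(r.type, float(r.time_ms), r.block)
            for r in df.itertuples()]


def write_stim_log(events: list[StimulusEvent], path) -> None:
    pd.DataFrame({
        "type": [e.type for e in events],
        "time_ms": [e.time_ms for e in events],
        "block": [e.block for e in events],
    }).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_genotype_map(path) -> dict[str, str]:
    df = _read_tsv(path, ["well", "genotype"])
    if df["well"].duplicated().any():
        dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
        raise ValidationError(f"{path}: duplicate well {dup!r}")
    return dict(zip(df["well"], df["genotype"]))


def write_genotype_map(genotypes: dict[str, str], path) -> None:
    pd.DataFrame({"well": sorted(genotypes),
                  "genotype": [genotypes[w] for w in sorted(genotypes)]}
                 ).to_csv(path, sep="\t", index=False)


def write_plate(dataset: PlateDataset, out_dir) -> None:
    """Write a plate as frames.tsv, highspeed.tsv, stim_log.tsv,
    genotypes.tsv inside ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_frame_table(dataset.frame_series, out / "frames.tsv")
    write_highspeed_table(dataset.highspeed_windows, out / "highspeed.tsv")
    write_stim_log(dataset.stim_log, out / "stim_log.tsv")
    write_genotype_map(dataset.genotypes, out / "genotypes.tsv")


def read_plate(in_dir, baseline_fps: float = 30.0,
               highspeed_fps: float = 285.0) -> PlateDataset:
    p = Path(in_dir)
    return PlateDataset(
        frame_series=read_frame_table(p / "frames.tsv", baseline_fps),
        stim_log=read_stim_log(p / "stim_log.tsv"),
        genotypes=read_genotype_map(p / "genotypes.tsv"),
        highspeed_windows=read_highspeed_table(p / "highspeed.tsv", highspeed_fps),
    )


# ---------------------------------------------------------------------------
# transcriptomic formats

def read_deg_table(path) -> pd.DataFrame:
    """DESeq2-dialect DE table; drops unparseable rows with a warning and
    recomputes padj by BH when the column is absent."""
    df = _read_tsv(path, ["gene", "log2FoldChange", "pvalue"])
    numeric = ["log2FoldChange", "pvalue"] + (["padj"] if "padj" in df else [])
    coerced = df.copy()
    for c in numeric:
        coerced[c] = pd.to_numeric(coerced[c], errors="coerce")
    parse_bad = coerced["log2FoldChange"].isna() | coerced["pvalue"].isna()
    if parse_bad.any():
        logger.warning("%s: dropped %d row(s) with unparseable numerics",
                       path, int(parse_bad.sum()))
        coerced = coerced[~parse_bad]
    if coerced["gene"].duplicated().any():
        dup = coerced.loc[coerced["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    if "padj" not in coerced.columns:
        coerced["padj"] = sps.false_discovery_control(
            coerced["pvalue"].to_numpy(dtype=float)) if len(coerced) else []
        logger.info("%s: padj column absent; computed by Benjamini-Hochberg", path)
    cols = ["gene", "log2FoldChange", "pvalue", "padj"]
    extra = [c for c in coerced.columns if c not in cols]
    return coerced[cols + extra].reset_index(drop=True)


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gmt(path) -> list:
    """GMT gene sets: name <tab> description <tab> member..."""
    from .enrichment import GeneSet
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} field(s))")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# generic result tables ------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration

@dataclasses.dataclass
class RunConfig:
    """Every tunable of the pipeline in one place; unknown keys in a
    config file are rejected."""

    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 999
    bin_width_ms: float = 60_000.0
    epochs: list | None = None        # [[label, start_ms, end_ms], ...]
    control_genotype: str = "wt"
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    bout: BoutParams = dataclasses.field(default_factory=BoutParams)
    response: ResponseParams = dataclasses.field(default_factory=ResponseParams)
    center_fraction_linear: float = 0.5
    category_map: dict | None = None  # measure -> category overrides
    deg_p_max: float = 0.05
    deg_lfc_min: float = 0.2
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000

    def geometry(self) -> WellGeometry:
        return WellGeometry(self.sim.well_size_px, self.center_fraction_linear)

    def epoch_spans(self) -> list[tuple[str, float, float]]:
        if self.epochs is not None:
            return [(str(label), float(t0), float(t1))
                    for label, t0, t1 in self.epochs]
        t_end = self.sim.duration_s * 1000.0
        q = t_end / 4.0
        return [("all", 0.0, t_end)] + [(f"q{k + 1}", k * q, (k + 1) * q)
                                        for k in range(4)]


def _build_dataclass(cls, data: dict[str, Any], context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValidationError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if key == "sim":
            value = _build_dataclass(SimConfig, dict(value), "sim")
        elif key == "bout":
            value = _build_dataclass(BoutParams, dict(value), "bout")
        elif key == "response":
            value = _build_dataclass(ResponseParams, dict(value), "response")
        elif key == "stim_schedule" and value is not None:
            value = [StimulusEvent(e["type"], float(e["time_ms"]), e["block"])
                     for e in value]
        kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    """Parse a YAML run config; key names match the dataclass fields
    exactly and unknown keys raise."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    cfg = _build_dataclass(RunConfig, data, "run config")
    cfg.sim.validate()
    return cfg
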