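"""Two-tier statistics for the behavioral battery.

Baseline measures (bout counts and kinematics binned over long epochs)
are tested with a linear mixed model — measure ~ genotype with a
per-animal random intercept across time bins — whose inference is by
permutation of genotype labels at the animal level, making the test
distribution-free.  Stimulus-response measures (one value per animal) use
the Kruskal–Wallis rank test.  Every result carries the strictly
standardized mean difference

    SSMD  β = (μ_mutant − μ_control) / sqrt(σ²_mutant + σ²_control),

a variance-normalized effect size from high-throughput screening; a
negative β means the measure is reduced in mutants.

The mixed model is fit by profiled REML: for a grid of variance ratios
λ = τ²/σ² (random-intercept over residual variance) the GLS estimate of
the genotype coefficient reduces to a weighted regression on per-animal
means with weights n_i/(1 + n_i λ); the REML criterion selects λ and the
observed statistic is |β̂|/SE.  Because inference is by animal-level
label permutation, the fitting method affects power only, never validity:
the permutation p-value (1 + #{|t*| ≥ |t|}) / (1 + n_perm) is exact under
exchangeability, with attainable floor 1/(1 + n_perm) — 0.001 at the
default n_perm = 999.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError, logger
from .features import BASELINE_MEASURES, BoutParams, WellGeometry, bin_measures, bout_table
from .stimulus import ResponseParams, score_dataset
from .synthetic import PlateDataset

__all__ = [
    "StatResult",
    "ssmd",
    "kruskal_wallis",
    "lmm_baseline_test",
    "run_measure_battery",
    "results_frame",
]

_LAMBDA_GRID = np.concatenate(([0.0], np.logspace(-3.0, 3.0, 40)))


@dataclass
class StatResult:
    """One behavioral measure in one epoch for one mutant-vs-control
    contrast."""

    measure: str
    epoch: str
    contrast: tuple[str, str]  # (mutant, control)
    test: str                  # "lmm_permutation" | "kruskal_wallis" | fallback
    p_value: float
    ssmd: float
    group_means: dict[str, float] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)
    note: str = ""


def ssmd(group_a, group_b) -> float:
    """Strictly standardized mean difference β with sample (n−1)
    variances; ``group_a`` is the mutant group, so β < 0 means reduced in
    mutants.  Degenerate zero-variance input yields 0 for equal means and
    signed infinity otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("ssmd needs at least 2 values per group")
    diff = a.mean() - b.mean()
    denom = math.sqrt(a.var(ddof=1) + b.var(ddof=1))
    if denom == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return float(diff / denom)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H (mid-rank ties, tie-corrected) and its chi-square
    p-value; all-equal data is defined as (H, p) = (0, 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("empty group")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValidationError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _reml_stat(n_i: np.ndarray, ybar: np.ndarray, ssw: float,
               g_matrix: np.ndarray) -> np.ndarray:
    """|t| statistic of the genotype coefficient for each label row.

    ``g_matrix`` is (P, A) of 0/1 mutant indicators; per-animal bin counts
    ``n_i``, per-animal means ``ybar`` and the pooled within-animal sum of
    squares ``ssw`` are sufficient for the profiled REML fit.
    """
    n_total = float(n_i.sum())
    dof = n_total - 2.0
    t_best = np.zeros(g_matrix.shape[0])
    crit_best = np.full(g_matrix.shape[0], np.inf)
    for lam in _LAMBDA_GRID:
        u = n_i / (1.0 + n_i * lam)
        s0 = u.sum()
        sy = float(u @ ybar)
        syy = float(u @ ybar**2)
        sg = g_matrix @ u
        sgy = g_matrix @ (u * ybar)
        det = sg * (s0 - sg)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (s0 * sgy - sg * sy) / det
            alpha = (sy - beta * sg) / s0
            rss_b = syy - alpha * sy - beta * sgy
            rss_b = np.maximum(rss_b, 0.0)
            sigma2 = (ssw + rss_b) / dof
            crit = (dof * np.log(np.maximum(sigma2, 1e-300))
                    + np.log(1.0 + n_i * lam).sum()
                    + np.log(np.maximum(det, 1e-300)))
            se = np.sqrt(sigma2 * s0 / det)
            t = np.abs(beta) / np.maximum(se, 1e-300)
        better = crit < crit_best
        crit_best = np.where(better, crit, crit_best)
        t_best = np.where(better, t, t_best)
    return t_best


def _perm_pvalue(stat_obs: float, stat_perm: np.ndarray, n_perm: int) -> float:
    return float((1 + np.sum(stat_perm >= stat_obs - 1e-12)) / (1 + n_perm))


def lmm_baseline_test(values: pd.DataFrame, genotype_map: dict[str, str],
                      contrast: tuple[str, str], n_perm: int = 999,
                      seed: int = 0, measure: str = "", epoch: str = "") -> StatResult:
    """Permutation mixed-model test of one binned baseline measure.

    ``values`` has columns ``well`` and ``value`` (one row per time bin,
    NaN rows dropped).  If the design has no within-animal replication the
    fit is singular and the test falls back to a two-sample permutation
    test of per-animal means (recorded in ``note``).
    """
    mutant, control = contrast
    df = values.dropna(subset=["value"]).copy()
    df["genotype"] = df["well"].map(genotype_map)
    df = df[df["genotype"].isin([mutant, control])]
    per_animal = df.groupby("well")["value"].agg(["mean", "count"])
    genos = pd.Series({w: genotype_map[w] for w in per_animal.index})
    n_mut = int((genos == mutant).sum())
    n_ctl = int((genos == control).sum())
    if n_mut < 2 or n_ctl < 2:
        raise ValidationError(
            f"need >= 2 animals per group, got {n_mut} {mutant!r} / {n_ctl} {control!r}")

    ybar = per_animal["mean"].to_numpy()
    n_i = per_animal["count"].to_numpy(dtype=float)
    is_mut = (genos == mutant).to_numpy()
    a_vals = ybar[is_mut]
    c_vals = ybar[~is_mut]
    beta = ssmd(a_vals, c_vals)
    means = {mutant: float(a_vals.mean()), control: float(c_vals.mean())}
    ns = {mutant: n_mut, control: n_ctl}

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, len(ybar)), dtype=bool)
    for r in range(n_perm):
        perms[r] = rng.permutation(is_mut)

    within = df.groupby("well")["value"]
    ssw = float(((df["value"] - within.transform("mean")) ** 2).sum())
    replicated = bool((n_i > 1).any()) and ssw > 0
    if replicated:
        g_all = np.vstack([is_mut[None, :], perms])
        t_all = _reml_stat(n_i, ybar, ssw, g_all.astype(float))
        p = _perm_pvalue(t_all[0], t_all[1:], n_perm)
        test, note = "lmm_permutation", ""
    else:
        # singular fit: two-sample permutation of per-animal means
        def stat(mask: np.ndarray) -> np.ndarray:
            mask = np.atleast_2d(mask)
            m1 = (mask * ybar).sum(axis=1) / mask.sum(axis=1)
            m0 = ((~mask) * ybar).sum(axis=1) / (~mask).sum(axis=1)
            return np.abs(m1 - m0)

        p = _perm_pvalue(stat(is_mut)[0], stat(perms), n_perm)
        test, note = "lmm_permutation", "fallback_two_sample"
    return StatResult(measure, epoch, contrast, test, p, beta, means, ns, note)


# ---------------------------------------------------------------------------
# battery orchestration

_STIM_VALUE_COLS = {
    "resp_freq": "responded",
    "resp_mag": "magnitude_displacement_px",
    "resp_latency": "latency_ms",
}


def _per_animal_stimulus_measures(scores: pd.DataFrame,
                                  pre_block: str = "pre") -> pd.DataFrame:
    """Per-animal stimulus measures in long form (well, measure, value).

    For every (block, type): response frequency across events, mean
    magnitude and mean latency over responder events.  For each
    habituation block of strong taps, the habituation index relative to
    the strong taps of ``pre_block`` (animals with a zero pre-block
    frequency are dropped for that measure)."""
    rows = []
    if not len(scores):
        return pd.DataFrame(columns=["well", "measure", "value"])
    for (block, typ), sub in scores.groupby(["block", "type"]):
        freq = sub.groupby("well")["responded"].mean()
        for well, v in freq.items():
            rows.append((well, f"resp_freq[{block}:{typ}]", float(v)))
        responders = sub[sub["responded"]]
        for col, name in (("magnitude_displacement_px", "resp_mag"),
                          ("latency_ms", "resp_latency")):
            for well, v in responders.groupby("well")[col].mean().items():
                rows.append((well, f"{name}[{block}:{typ}]", float(v)))
    strong = scores[scores["type"] == "tap_strong"]
    pre = strong[strong["block"] == pre_block]
    if len(pre):
        pre_freq = pre.groupby("well")["responded"].mean()
        hab_blocks = sorted(b for b in strong["block"].unique()
                            if b.startswith("hab"))
        for block in hab_blocks:
            bf = strong[strong["block"] == block].groupby("well")["responded"].mean()
            for well in bf.index:
                pf = pre_freq.get(well, 0.0)
                if pf > 0:
                    rows.append((well, f"habituation_index[{block}]",
                                 float(bf[well] / pf)))
    return pd.DataFrame(rows, columns=["well", "measure", "value"])


def run_measure_battery(dataset: PlateDataset,
                        bout_params: BoutParams | None = None,
                        geometry: WellGeometry | None = None,
                        response_params: ResponseParams | None = None,
                        epochs: list[tuple[str, float, float]] | None = None,
                        bin_width_ms: float = 60_000.0,
                        control: str = "wt",
                        contrasts: list[tuple[str, str]] | None = None,
                        n_perm: int = 999,
                        seed: int = 0,
                        pre_block: str = "pre") -> list[StatResult]:
    """Run the full two-tier battery on a plate.

    Baseline measures per epoch go through the permutation LMM; per-animal
    stimulus measures through Kruskal–Wallis.  Each non-control genotype
    is contrasted pairwise against ``control`` unless explicit contrasts
    are given.  Wells without a genotype are excluded with a warning.
    """
    bout_params = bout_params or BoutParams()
    response_params = response_params or ResponseParams()
    wells = dataset.wells()
    missing = [w for w in wells if w not in dataset.genotypes]
    if missing:
        logger.warning("excluding %d well(s) without genotype: %s",
                       len(missing), missing)
        wells = [w for w in wells if w not in missing]
    genotype_map = {w: dataset.genotypes[w] for w in wells}
    if geometry is None:
        side = max((float(np.max(s.x)) for s in dataset.frame_series.values()
                    if len(s)), default=100.0)
        geometry = WellGeometry(side_px=math.ceil(side))
    if epochs is None:
        t_end = max((float(s.t[-1]) for s in dataset.frame_series.values()
                     if len(s)), default=0.0) + 1.0
        q = t_end / 4.0
        epochs = [("all", 0.0, t_end)] + [
            (f"q{k + 1}", k * q, (k + 1) * q) for k in range(4)]

    genos = sorted(set(genotype_map.values()))
    if contrasts is None:
        if control not in genos:
            raise ValidationError(f"control genotype {control!r} not on the plate")
        contrasts = [(g, control) for g in genos if g != control]

    bouts = bout_table({w: dataset.frame_series[w] for w in wells},
                       geometry, bout_params)
    binned = bin_measures(bouts, bin_width_ms, epochs, wells)
    scores = score_dataset({k: v for k, v in dataset.highspeed_windows.items()
                            if k[0] in genotype_map},
                           dataset.stim_log, response_params)
    stim_long = _per_animal_stimulus_measures(scores, pre_block)

    results: list[StatResult] = []
    test_idx = 0
    for contrast in contrasts:
        mutant, ctl = contrast
        for epoch_label, _, _ in epochs:
            esub = binned[binned["epoch"] == epoch_label]
            for measure in BASELINE_MEASURES:
                vals = esub[["well", measure]].rename(columns={measure: "value"})
                res = lmm_baseline_test(
                    vals, genotype_map, contrast, n_perm=n_perm,
                    seed=(seed * 1_000_003 + test_idx) % (2**31 - 1),
                    measure=measure, epoch=epoch_label)
                results.append(res)
                test_idx += 1
        for measure, sub in stim_long.groupby("measure"):
            sub = sub.dropna(subset=["value"])
            sub_geno = sub["well"].map(genotype_map)
            a = sub.loc[sub_geno == mutant, "value"].to_numpy()
            c = sub.loc[sub_geno == ctl, "value"].to_numpy()
            if len(a) < 2 or len(c) < 2:
                logger.warning("skipping %s (%s vs %s): too few animals",
                               measure, mutant, ctl)
                continue
            h, p = kruskal_wallis([a, c])
            results.append(StatResult(
                measure, "stimulus", contrast, "kruskal_wallis", p,
                ssmd(a, c),
                {mutant: float(a.mean()), ctl: float(c.mean())},
                {mutant: len(a), ctl: len(c)}))
    return results


def results_frame(results: list[StatResult]) -> pd.DataFrame:
    """Flatten StatResults into a table (one row per result)."""
    rows = []
    for r in results:
        mutant, ctl = r.contrast
        rows.append({
            "measure": r.measure,
            "epoch": r.epoch,
            "mutant": mutant,
            "control": ctl,
            "test": r.test,
            "p_value": r.p_value,
            "ssmd": r.ssmd,
            "mean_mutant": r.group_means.get(mutant, float("nan")),
            "mean_control": r.group_means.get(ctl, float("nan")),
            "n_mutant": r.n_per_group.get(mutant, 0),
            "n_control": r.n_per_group.get(ctl, 0),
            "note": r.note,
        })
    cols = ["measure", "epoch", "mutant", "control", "test", "p_value", "ssmd",
            "mean_mutant", "mean_control", "n_mutant", "n_control", "note"]
    return pd.DataFrame(rows, columns=cols)
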