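"""Generator properties: determinism, renewal rates, planted effects."""

import numpy as np
import pytest

import zfbattery as z
from zfbattery.errors import ValidationError
from zfbattery.synthetic import WALL_MARGIN_PX


def test_zero_wells_gives_empty_dataset():
    cfg = z.SimConfig(seed=0, n_per_genotype={}, duration_s=120.0)
    ds = z.simulate_plate(cfg)
    assert ds.frame_series == {} and ds.genotypes == {}
    assert ds.highspeed_windows == {}


def test_negative_rate_rejected():
    with pytest.raises(ValidationError):
        z.SimConfig(rest_mean_s=-1.0).validate()
    with pytest.raises(ValidationError):
        z.SimConfig(p_respond={"tap_strong": 1.5}).validate()
    with pytest.raises(ValidationError):
        z.SimConfig(effect_multipliers={"hom": {"nonsense": 2.0}}).validate()


def test_same_seed_identical_datasets():
    cfg = dict(seed=11, n_per_genotype={"wt": 2, "hom": 1}, duration_s=90.0)
    a = z.simulate_plate(z.SimConfig(**cfg))
    b = z.simulate_plate(z.SimConfig(**cfg))
    assert a.genotypes == b.genotypes
    for w in a.frame_series:
        assert np.array_equal(a.frame_series[w].x, b.frame_series[w].x)
        assert np.array_equal(a.frame_series[w].dpx, b.frame_series[w].dpx)
    for key in a.highspeed_windows:
        assert np.array_equal(a.highspeed_windows[key].dpx,
                              b.highspeed_windows[key].dpx)


def test_adding_wells_preserves_existing_streams():
    small = z.simulate_plate(z.SimConfig(seed=3, n_per_genotype={"wt": 2},
                                         duration_s=60.0, stim_schedule=[]))
    big = z.simulate_plate(z.SimConfig(seed=3, n_per_genotype={"wt": 5},
                                       duration_s=60.0, stim_schedule=[]))
    for w in small.frame_series:
        assert np.array_equal(small.frame_series[w].x, big.frame_series[w].x)


def test_centroids_stay_inside_well(small_plate):
    cfg_side = 200.0
    for s in small_plate.frame_series.values():
        assert s.x.min() >= WALL_MARGIN_PX - 1e-9
        assert s.x.max() <= cfg_side - WALL_MARGIN_PX + 1e-9
        assert s.y.min() >= WALL_MARGIN_PX - 1e-9
        assert s.y.max() <= cfg_side - WALL_MARGIN_PX + 1e-9


def test_renewal_rate_matches_expectation():
    """Mean generated bout count over 50 wells equals
    duration / (rest_mean + bout_duration) within 5%."""
    cfg = z.SimConfig(seed=21, n_per_genotype={"wt": 50}, duration_s=600.0,
                      seizure_rate_per_h=0.0, stim_schedule=[])
    ds = z.simulate_plate(cfg)
    counts = [len(t["bout_start_ms"]) for t in ds.truth.values()]
    expected = 600.0 / (1.5 + 0.2)
    assert np.mean(counts) == pytest.approx(expected, rel=0.05)


def test_bout_rate_multiplier_scales_rate():
    cfg = z.SimConfig(seed=22, n_per_genotype={"wt": 30, "hom": 30},
                      duration_s=600.0, seizure_rate_per_h=0.0, stim_schedule=[],
                      effect_multipliers={"hom": {"bout_rate": 0.5}})
    ds = z.simulate_plate(cfg)
    by_geno = {"wt": [], "hom": []}
    for w, t in ds.truth.items():
        by_geno[ds.genotypes[w]].append(len(t["bout_start_ms"]))
    ratio = np.mean(by_geno["hom"]) / np.mean(by_geno["wt"])
    assert ratio == pytest.approx(0.5, rel=0.10)


def test_seizure_rate_poisson_expectation(geometry, bout_params):
    """At 6 events/h over 1 h, the scored seizure-bout count per well
    averages inside the 95% Monte-Carlo band around 6 (50 wells)."""
    cfg = z.SimConfig(seed=23, n_per_genotype={"wt": 50}, duration_s=3600.0,
                      rest_mean_s=10.0, seizure_rate_per_h=6.0, stim_schedule=[])
    ds = z.simulate_plate(cfg)
    bouts = z.bout_table(ds.frame_series, geometry, bout_params)
    scored = bouts.groupby("well")["is_seizure"].sum()
    assert 4.5 <= scored.reindex(ds.wells(), fill_value=0).mean() <= 7.5
    truth = np.mean([len(t["seizure_start_ms"]) for t in ds.truth.values()])
    assert scored.sum() == pytest.approx(truth * 50, rel=0.02)


def test_seizure_bout_constructive_guarantee(geometry, bout_params):
    cfg = z.SimConfig()
    for seed in range(50):
        fs = z.simulate_seizure_bout(cfg, seed)
        assert len(fs) > 1 and fs.t[-1] > 0
        assert fs.x.min() >= WALL_MARGIN_PX - 1e-9
        assert fs.x.max() <= cfg.well_size_px - WALL_MARGIN_PX + 1e-9
        k = z.bout_kinematics(fs, (0, len(fs)), geometry, bout_params)
        assert z.classify_seizure(k), (k.revolutions, k.distance_px, k.velocity_px_ms)


def _hab_schedule(n_taps: int, spacing_ms: float = 6000.0):
    return [z.StimulusEvent("tap_strong", 5000.0 + i * spacing_ms, "hab1")
            for i in range(n_taps)]


def test_habituation_decay_recovered_by_regression():
    """Response frequency to the k-th tap decays as p * decay^(k-1);
    weighted log-linear regression over 200 wells recovers log(decay)
    within 10%."""
    n_taps, decay = 12, 0.85
    cfg = z.SimConfig(seed=24, n_per_genotype={"wt": 200}, duration_s=80.0,
                      seizure_rate_per_h=0.0, habituation_decay=decay,
                      stim_schedule=_hab_schedule(n_taps))
    ds = z.simulate_plate(cfg)
    scores = z.score_dataset(ds.highspeed_windows, ds.stim_log)
    freq = scores.groupby("event")["responded"].mean().to_numpy()
    n = 200
    w = n * freq / np.maximum(1.0 - freq, 1e-9)  # inverse binomial variance
    k = np.arange(n_taps)
    X = np.column_stack([np.ones(n_taps), k])
    coef = np.linalg.solve(X.T * w @ X, X.T * w @ np.log(freq))
    assert coef[1] == pytest.approx(np.log(decay), rel=0.10)


def test_response_frequency_converges_to_p_respond():
    cfg = z.SimConfig(seed=25, n_per_genotype={"wt": 100}, duration_s=80.0,
                      seizure_rate_per_h=0.0, habituation_decay=1.0,
                      p_respond={"tap_strong": 0.9},
                      stim_schedule=_hab_schedule(12))
    ds = z.simulate_plate(cfg)
    scores = z.score_dataset(ds.highspeed_windows, ds.stim_log)
    freq = scores["responded"].mean()
    se = np.sqrt(0.9 * 0.1 / len(scores))
    assert abs(freq - 0.9) <= 3 * se + 1e-9


def test_highspeed_windows_cover_one_second(small_plate):
    for (well, idx), win in list(small_plate.highspeed_windows.items())[:20]:
        onset = small_plate.stim_log[idx].time_ms
        assert win.t[0] == pytest.approx(onset)
        assert win.t[-1] - win.t[0] == pytest.approx(1000.0, abs=1e-6)
        assert win.fps == 285.0


class TestDegTable:
    def test_empty(self):
        assert len(z.simulate_deg_table(0)) == 0

    def test_deterministic(self):
        a = z.simulate_deg_table(200, seed=5)
        b = z.simulate_deg_table(200, seed=5)
        assert a.equals(b)

    def test_planted_shift_moves_lfc(self):
        members = [f"g{i:05d}" for i in range(30)]
        tab = z.simulate_deg_table(500, {"s": (members, -1.0)}, 0.3, seed=6)
        planted = tab[tab.gene.isin(members)]
        rest = tab[~tab.gene.isin(members)]
        assert planted.log2FoldChange.mean() < -0.7
        assert abs(rest.log2FoldChange.mean()) < 0.1

    def test_conflicting_shifts_rejected(self):
        g = [f"g{i:05d}" for i in range(5)]
        with pytest.raises(ValidationError):
            z.simulate_deg_table(100, {"a": (g, 1.0), "b": (g[:2], -1.0)})

    def test_null_pvalues_uniform(self):
        tab = z.simulate_deg_table(3000, seed=7)
        from scipy import stats as sps
        assert sps.kstest(tab.pvalue, "uniform").pvalue > 0.01


class TestClusterMatrix:
    def test_deterministic(self):
        a, la = z.simulate_cluster_matrix(100, {"A": (10, [], 1.0)}, seed=1)
        b, lb = z.simulate_cluster_matrix(100, {"A": (10, [], 1.0)}, seed=1)
        assert a.equals(b) and la.equals(lb)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValidationError):
            z.simulate_cluster_matrix(100, {"A": (0, [], 1.0)})

    def test_markers_upshifted_in_cluster_only(self):
        mk = [f"g{i:05d}" for i in range(10)]
        counts, labels = z.simulate_cluster_matrix(
            200, {"A": (50, mk, 8.0), "B": (50, [], 1.0)}, seed=2)
        in_a = counts.loc[labels == "A", mk].to_numpy().mean()
        in_b = counts.loc[labels == "B", mk].to_numpy().mean()
        assert in_a > 3 * in_b
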