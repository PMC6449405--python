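"""Compartment calling, switch classification, saddle, and decay-curve behaviour."""

import numpy as np
import pandas as pd
import pytest

from hicdyn import pipeline, simulate
from hicdyn.compartments import (
    CompartmentTrack,
    classify_switches,
    compartment_fraction,
    compute_pc1,
    decay_curves,
    delta_saddle,
    saddle,
    _category_from_means,
)
from hicdyn.contacts import BinTable, ContactMap, ice_balance, oe_normalize


def _block_oe_map(n=30, strength=3.0, seed=0):
    """O/E-like map with alternating 5-bin A/B blocks."""
    rng = np.random.default_rng(seed)
    bins = BinTable.from_chrom_sizes({"chr1": n * 1_000}, 1_000)
    lab = np.array([1 if (i // 5) % 2 == 0 else -1 for i in range(n)])
    m = np.where(lab[:, None] == lab[None, :], strength, 1.0) + rng.normal(0, 0.01, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return ContactMap(bins, np.abs(m), balanced=True), lab


def _pearson_oracle(x):
    """Brute-force pairwise Pearson correlation between rows, diagonal excluded."""
    from scipy import stats as sps

    x = x.astype(float).copy()
    np.fill_diagonal(x, np.nan)
    n = x.shape[0]
    corr = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            ok = np.isfinite(x[i]) & np.isfinite(x[j])
            corr[i, j] = sps.pearsonr(x[i][ok], x[j][ok])[0]
    return (corr + corr.T) / 2


def _power_iteration(mat, n_iter=5_000, seed=1):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=mat.shape[0])
    # shift to make the dominant eigenvalue of the PSD-shifted matrix the leading one
    shifted = mat + mat.shape[0] * np.eye(mat.shape[0])
    for _ in range(n_iter):
        v = shifted @ v
        v /= np.linalg.norm(v)
    return v


class TestPC1:
    def test_two_block_structure_partitions_blocks(self):
        oe, lab = _block_oe_map()
        track = compute_pc1(oe, orientation=(lab == 1).astype(float))
        called = np.sign(track.score)
        assert np.array_equal(called, lab)

    def test_matches_brute_force_eigendecomposition(self):
        oe, lab = _block_oe_map(seed=5)
        track = compute_pc1(oe, orientation=(lab == 1).astype(float))
        corr = _pearson_oracle(oe.matrix)
        lead = _power_iteration(corr)
        cos = abs(np.dot(track.score / np.linalg.norm(track.score), lead))
        assert cos > 1 - 1e-8

    def test_global_scaling_invariance(self, small_config):
        maps, truth = simulate.gen_hic(small_config)
        tracks = simulate.gen_tracks(small_config, truth)
        key = ("t0", "r1")
        oe1 = oe_normalize(ice_balance(maps[key]))
        doubled = ContactMap(maps[key].bins, maps[key].matrix * 7.0)
        oe2 = oe_normalize(ice_balance(doubled))
        t1 = compute_pc1(oe1, tracks["gene_density"])
        t2 = compute_pc1(oe2, tracks["gene_density"])
        ok = np.isfinite(t1.score) & np.isfinite(t2.score)
        assert np.allclose(t1.score[ok], t2.score[ok], atol=1e-8)


def _make_tracks(values_by_sample, bins):
    """values_by_sample: {(tp, rep): per-bin array}."""
    return {k: CompartmentTrack(bins, np.asarray(v, dtype=float)) for k, v in values_by_sample.items()}


class TestSwitchClassification:
    @pytest.fixture
    def bins4(self):
        return BinTable.from_chrom_sizes({"chr1": 4_000}, 1_000)

    def test_constant_positive_is_stable_A_with_p_one(self, bins4):
        vals = {(f"t{t}", f"r{r}"): [0.5, 0.5, 0.5, 0.5] for t in range(2) for r in (1, 2)}
        calls = classify_switches(_make_tracks(vals, bins4), ["t0", "t1"])
        assert (calls["category"] == "stable-A").all()
        assert (calls["anova_p"] == 1.0).all()

    def test_sign_sequence_rule_a_to_b(self, bins4):
        rng = np.random.default_rng(0)
        vals = {}
        for t, mean in enumerate([0.5, 0.5, -0.5, -0.5]):
            for r in (1, 2):
                vals[(f"t{t}", f"r{r}")] = mean + rng.normal(0, 0.01, 4)
        calls = classify_switches(_make_tracks(vals, bins4), [f"t{t}" for t in range(4)])
        assert (calls["category"] == "A-B").all()
        assert (calls["anova_p"] < 0.01).all()

    @pytest.mark.parametrize(
        "means, expected",
        [
            ((1, 1, 1, 1), "stable-A"),
            ((-1, -1, -1, -1), "stable-B"),
            ((1, 1, -1, -1), "A-B"),
            ((-1, 1, 1, 1), "B-A"),
            ((1, -1, -1, 1), "A-B-A"),
            ((-1, 1, -1, 1), "B-A"),  # 4-segment merged by first/last sign
            ((1, -1, 1, -1), "A-B"),
            ((1, 0, -1, -1), "A-B"),  # zero inherits previous sign
        ],
    )
    def test_category_from_sign_sequence(self, means, expected):
        assert _category_from_means(np.array(means, dtype=float)) == expected

    def test_alpha_zero_calls_nothing_alpha_one_calls_all_sign_changers(self, small_config):
        res = pipeline.switch_recovery(small_config, alpha=0.0)
        from hicdyn.compartments import STABLE_CATEGORIES

        assert res["calls"]["category"].isin(STABLE_CATEGORIES).all()
        res1 = pipeline.switch_recovery(small_config, alpha=1.0)
        calls = res1["calls"]
        mcols = [c for c in calls.columns if c.startswith("mean_")]
        sign_change = (calls[mcols].min(axis=1) < 0) & (calls[mcols].max(axis=1) > 0)
        switching = ~calls["category"].isin(STABLE_CATEGORIES)
        assert (switching == sign_change).all()

    def test_planted_switches_recovered(self, small_config):
        res = pipeline.switch_recovery(small_config)
        assert res["called_switching_fraction"] == pytest.approx(
            res["true_switching_fraction"], abs=0.05
        )


class TestSaddleDecay:
    def test_unit_oe_gives_zero_saddle(self):
        bins = BinTable.from_chrom_sizes({"chr1": 40_000}, 1_000)
        n = bins.n_bins
        m = np.ones((n, n))
        cmap = ContactMap(bins, m, balanced=True)
        rng = np.random.default_rng(1)
        track = CompartmentTrack(bins, rng.normal(size=n))
        s = saddle(cmap, track)
        assert np.allclose(s.grid[np.isfinite(s.grid)], 0.0)

    def test_delta_saddle_identity_is_zero(self):
        bins = BinTable.from_chrom_sizes({"chr1": 40_000}, 1_000)
        n = bins.n_bins
        rng = np.random.default_rng(2)
        m = rng.uniform(0.5, 2, (n, n))
        m = (m + m.T) / 2
        cmap = ContactMap(bins, m, balanced=True)
        track = CompartmentTrack(bins, rng.normal(size=n))
        s = saddle(cmap, track)
        d = delta_saddle(s, s)
        assert np.allclose(d[np.isfinite(d)], 0.0)

    def test_planted_strength_corners_exceed_center(self, small_config):
        res = pipeline.switch_recovery(small_config)
        key = ("t0", "r1")
        s = saddle(res["oe_maps"][key], res["tracks"][key])
        corner = np.nanmean([s.grid[0, 0], s.grid[9, 9]])
        center = np.nanmean(s.grid[4:6, 4:6])
        assert corner > center

    def test_decay_single_class_is_unity(self):
        bins = BinTable.from_chrom_sizes({"chr1": 40_000}, 1_000)
        n = bins.n_bins
        rng = np.random.default_rng(3)
        m = rng.uniform(1, 3, (n, n))
        m = (m + m.T) / 2
        cmap = ContactMap(bins, m, balanced=True)
        track = CompartmentTrack(bins, np.ones(n))
        curves = decay_curves(cmap, track)
        assert np.allclose(curves["A-A"].dropna(), 1.0)

    def test_decay_weighted_mean_is_one(self, small_config):
        res = pipeline.switch_recovery(small_config)
        key = ("t0", "r1")
        bal = ice_balance(res["raw_maps"][key])
        curves = decay_curves(bal, res["tracks"][key])
        for _, row in curves.iterrows():
            total_n = row[["n_A-A", "n_B-B", "n_A-B"]].sum()
            weighted = sum(
                row[c] * row[f"n_{c}"] for c in ["A-A", "B-B", "A-B"] if row[f"n_{c}"] > 0
            )
            assert weighted / total_n == pytest.approx(1.0, abs=1e-9)

    def test_late_stage_gains_longrange_bb(self):
        cfg = simulate.HiCSimConfig(
            bins_per_chrom=60, seed=11, switch_fraction=0.0, bb_longrange_gain_per_stage=0.4
        )
        res = pipeline.switch_recovery(cfg)
        early, late = ("t0", "r1"), ("t3", "r1")
        bal_e = ice_balance(res["raw_maps"][early])
        bal_l = ice_balance(res["raw_maps"][late])
        c_e = decay_curves(bal_e, res["tracks"][early])
        c_l = decay_curves(bal_l, res["tracks"][late])
        sel = c_e.index > 10_000_000
        assert c_l.loc[sel, "B-B"].mean() > c_e.loc[sel, "B-B"].mean()


class TestCompartmentFraction:
    def test_all_positive(self, toy_bins):
        track = CompartmentTrack(toy_bins, np.ones(toy_bins.n_bins))
        assert compartment_fraction(track) == {"A": 1.0, "B": 0.0}

    def test_sign_flip_swaps_exactly(self, toy_bins):
        rng = np.random.default_rng(4)
        s = rng.normal(size=toy_bins.n_bins)
        s[s == 0] = 0.1
        f1 = compartment_fraction(CompartmentTrack(toy_bins, s))
        f2 = compartment_fraction(CompartmentTrack(toy_bins, -s))
        assert f1["A"] == f2["B"] and f1["B"] == f2["A"]

    def test_planted_even_split_recovered(self, small_config):
        res = pipeline.switch_recovery(small_config)
        stacked = np.stack([res["tracks"][("t0", f"r{r}")].score for r in (1, 2)])
        mean_score = np.where(
            np.isfinite(stacked).all(axis=0), stacked.mean(axis=0), np.nan
        )
        track = CompartmentTrack(res["tracks"][("t0", "r1")].bins, mean_score)
        frac = compartment_fraction(track)
        assert frac["A"] == pytest.approx(0.5, abs=0.05)
        assert frac["A"] + frac["B"] == pytest.approx(1.0)
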