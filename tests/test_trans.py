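"""Trans-contact Z-scores, gene-set association, permutation null, network edges."""

import numpy as np
import pandas as pd
import pytest

from hicdyn import simulate
from hicdyn.contacts import BinTable, ContactMap, ice_balance
from hicdyn.trans import (
    build_network,
    geneset_trans_score,
    locus_trans_zscores,
    median_trans_count,
    permutation_null,
)


@pytest.fixture
def four_chrom_map():
    """Balanced-like map over 4 chromosomes x 5 bins with distinct trans values."""
    bins = BinTable.from_chrom_sizes({f"chr{c}": 5_000 for c in range(1, 5)}, 1_000)
    rng = np.random.default_rng(0)
    n = bins.n_bins
    m = rng.uniform(1, 3, (n, n))
    m = (m + m.T) / 2
    return ContactMap(bins, m, balanced=True)


class TestLocusZ:
    def test_equal_trans_values_give_zero_z(self):
        bins = BinTable.from_chrom_sizes({"chr1": 5_000, "chr2": 5_000}, 1_000)
        n = bins.n_bins
        cmap = ContactMap(bins, np.full((n, n), 4.0), balanced=True)
        prof = locus_trans_zscores(cmap, anchor_bin=0, trim=0.0)
        assert np.allclose(prof["z"], 0.0)

    def test_hand_computed_trim_and_z(self):
        # anchor on chr1; 10 trans partners with one extreme outlier
        bins = BinTable.from_chrom_sizes({"chr1": 1_000, "chr2": 10_000}, 1_000)
        vals = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 100.0])
        n = bins.n_bins
        m = np.zeros((n, n))
        m[0, 1:] = vals
        m[1:, 0] = vals
        cmap = ContactMap(bins, m, balanced=True)
        prof = locus_trans_zscores(cmap, anchor_bin=0, trim=0.005)
        # floor(10 * 0.995) = 9 retained values; the outlier is dropped
        kept = vals[:9]
        assert len(prof) == 9
        assert 100.0 not in prof["value"].values
        expect = (kept - kept.mean()) / kept.std()
        assert np.allclose(np.sort(prof["z"]), np.sort(expect))

    def test_masked_anchor_raises(self, four_chrom_map):
        four_chrom_map.mask[2] = True
        with pytest.raises(ValueError, match="masked"):
            locus_trans_zscores(four_chrom_map, anchor_bin=2)

    def test_trim_monotone_in_retained_bins(self, four_chrom_map):
        n_prev = None
        for trim in [0.0, 0.05, 0.2, 0.5]:
            prof = locus_trans_zscores(four_chrom_map, 0, trim=trim)
            if n_prev is not None:
                assert len(prof) <= n_prev
            n_prev = len(prof)


class TestGenesetScore:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])

    def test_same_chromosome_pair_scores_zero(self, four_chrom_map):
        genes = self._genes([("g1", "chr1", 500), ("g2", "chr1", 3_500)])
        score, edges = geneset_trans_score(four_chrom_map, genes)
        assert score == 0.0
        assert edges.empty

    def test_hand_summed_three_genes(self):
        bins = BinTable.from_chrom_sizes({f"chr{c}": 2_000 for c in (1, 2, 3)}, 1_000)
        n = bins.n_bins
        m = np.zeros((n, n))
        # gene bins: chr1 bin0, chr2 bin2, chr3 bin4
        m[0, 2] = m[2, 0] = 12.0
        m[0, 4] = m[4, 0] = 5.0
        m[2, 4] = m[4, 2] = 7.0
        cmap = ContactMap(bins, m, balanced=True)
        genes = self._genes([("a", "chr1", 100), ("b", "chr2", 100), ("c", "chr3", 100)])
        score, edges = geneset_trans_score(cmap, genes)
        assert score == pytest.approx(24.0)
        assert len(edges) == 3

    def test_gene_order_invariance(self, four_chrom_map):
        genes = self._genes(
            [("a", "chr1", 500), ("b", "chr2", 1_500), ("c", "chr3", 2_500), ("d", "chr4", 500)]
        )
        s1, _ = geneset_trans_score(four_chrom_map, genes)
        s2, _ = geneset_trans_score(four_chrom_map, genes.iloc[::-1])
        assert s1 == pytest.approx(s2)

    def test_off_assembly_gene_raises(self, four_chrom_map):
        genes = self._genes([("a", "chr1", 500), ("zz", "chr9", 100)])
        with pytest.raises(KeyError, match="zz"):
            geneset_trans_score(four_chrom_map, genes)

    def test_score_linear_in_counts(self, four_chrom_map):
        genes = self._genes([("a", "chr1", 500), ("b", "chr2", 1_500), ("c", "chr3", 500)])
        s1, _ = geneset_trans_score(four_chrom_map, genes)
        doubled = ContactMap(four_chrom_map.bins, four_chrom_map.matrix * 2, balanced=True)
        s2, _ = geneset_trans_score(doubled, genes)
        assert s2 == pytest.approx(2 * s1)


def _hub_setup(hub_gain, seed=0, n_hub=16):
    cfg = simulate.HiCSimConfig(
        bins_per_chrom=25,
        n_timepoints=2,
        n_replicates=1,
        seed=seed,
        switch_fraction=0.0,
        hub_gain=hub_gain,
        n_hub_genes=n_hub,
    )
    maps, truth = simulate.gen_hic(cfg)
    tracks = simulate.gen_tracks(cfg, truth, n_genes_per_chrom=30)
    genes = tracks["genes"][["gene_id", "chrom", "tss"]]
    hub = genes[genes["gene_id"].isin(truth.hub_genes)]
    late = ice_balance(maps[("t1", "r1")])
    return late, hub, genes


class TestPermutationNull:
    def test_fixed_seed_reproduces_null_vector(self):
        late, hub, genes = _hub_setup(hub_gain=1.0)
        r1 = permutation_null(late, hub, genes, n=50, seed=9)
        r2 = permutation_null(late, hub, genes, n=50, seed=9)
        assert np.array_equal(r1["null"], r2["null"])
        assert r1["p"] == r2["p"]

    def test_planted_hub_detected(self):
        late, hub, genes = _hub_setup(hub_gain=5.0, seed=1)
        res = permutation_null(late, hub, genes, n=1000, seed=2)
        assert res["p"] <= 0.01

    def test_null_p_centered_under_no_hub(self):
        # random seed sets from the universe: p should hover around 0.5
        late, _, genes = _hub_setup(hub_gain=1.0, seed=4)
        rng = np.random.default_rng(5)
        ps = []
        for k in range(20):
            seed_set = genes.sample(n=12, random_state=int(rng.integers(2**31)))
            res = permutation_null(late, seed_set, genes, n=99, seed=int(rng.integers(2**31)))
            ps.append(res["p"])
        assert 0.25 < np.median(ps) < 0.75

    def test_small_universe_raises(self, four_chrom_map):
        genes = pd.DataFrame(
            [("a", "chr1", 500), ("b", "chr2", 500)], columns=["gene_id", "chrom", "tss"]
        )
        with pytest.raises(ValueError, match="universe too small"):
            permutation_null(four_chrom_map, genes, genes, n=10, seed=0)

    def test_p_invariant_under_count_scaling(self):
        late, hub, genes = _hub_setup(hub_gain=3.0, seed=6)
        r1 = permutation_null(late, hub, genes, n=200, seed=3)
        doubled = ContactMap(late.bins, late.matrix * 2, mask=late.mask, balanced=True)
        r2 = permutation_null(doubled, hub, genes, n=200, seed=3)
        assert r2["observed"] == pytest.approx(2 * r1["observed"])
        assert np.allclose(r2["null"], 2 * r1["null"])
        assert r1["p"] == r2["p"]


class TestNetwork:
    def test_counts_at_median_are_not_displayed(self):
        bins = BinTable.from_chrom_sizes({f"chr{c}": 2_000 for c in (1, 2, 3)}, 1_000)
        n = bins.n_bins
        m = np.full((n, n), 2.0)
        cmap = ContactMap(bins, m, balanced=True)
        genes = pd.DataFrame(
            [("a", "chr1", 100), ("b", "chr2", 100), ("c", "chr3", 100)],
            columns=["gene_id", "chrom", "tss"],
        )
        net = build_network({"e": cmap, "l": cmap}, genes, early="e", late="l")
        assert not net["display"].any()  # strict inequality vs the median

    def test_hub_edge_displayed_with_positive_foldchange(self):
        early, hub, genes = _hub_setup(hub_gain=1.0, seed=7)
        late, hub, genes = _hub_setup(hub_gain=6.0, seed=7)
        net = build_network({"e": early, "l": late}, hub, early="e", late="l")
        assert net["display"].any()
        assert net.loc[net["display"], "log2fc"].median() > 0

    def test_swapping_timepoints_negates_foldchange(self, four_chrom_map):
        genes = pd.DataFrame(
            [("a", "chr1", 500), ("b", "chr2", 500), ("c", "chr3", 500)],
            columns=["gene_id", "chrom", "tss"],
        )
        other = ContactMap(four_chrom_map.bins, four_chrom_map.matrix * 1.7, balanced=True)
        n1 = build_network({"e": four_chrom_map, "l": other}, genes, early="e", late="l")
        n2 = build_network({"e": other, "l": four_chrom_map}, genes, early="l", late="e")
        merged = n1.merge(n2, on=["gene_a", "gene_b"], suffixes=("_fwd", "_rev"))
        assert np.allclose(merged["log2fc_fwd"], -merged["log2fc_rev"])

    def test_median_trans_count_ignores_cis(self):
        bins = BinTable.from_chrom_sizes({"chr1": 3_000, "chr2": 3_000}, 1_000)
        n = bins.n_bins
        m = np.zeros((n, n))
        code = np.repeat([0, 1], 3)
        trans = code[:, None] != code[None, :]
        m[trans] = 5.0
        m[~trans] = 1000.0
        m = (m + m.T) / 2
        cmap = ContactMap(bins, m, balanced=True)
        assert median_trans_count(cmap) == 5.0
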