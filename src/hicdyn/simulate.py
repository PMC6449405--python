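"""Synthetic multi-stage Hi-C, expression, peak, and FISH data with known ground truth.

The generator emulates the structure of a differentiation time-course Hi-C
study on a toy genome (by default 4 chromosomes of 10 Mb at 500 kb):

* block A/B compartment structure with power-law distance decay
  (cis expectation ``depth * d^-alpha``, multiplied by a homotypic boost when
  both bins share the true compartment label at that time point);
* a configurable fraction of bins planted to switch compartment between time
  points, with a configurable mix over the A-B / B-A / A-B-A / B-A-B
  categories;
* a stage-ramped gain in long-range B-B cis contacts (heterochromatin
  compaction) and a constitutive A-A boost in trans;
* a planted trans-contact hub among a chosen set of gene bins whose gain
  ramps up over the time course;
* separate 40 kb matrices with planted TAD blocks for boundary-caller tests;
* gene annotations with stage-peaked expression and differential-expression
  flags, stage-specific peak sets, and boundary-proximal peak sets;
* FISH spot tables from ellipsoidal nuclei with a configurable true
  proximity fraction and aneuploid-cell fraction.

Counts are negative-binomial around the multiplicative expectation
(``var = mu + dispersion * mu^2``); ``dispersion = 0`` returns the rounded
expectation itself.  All randomness flows from the config seed, so a fixed
seed reproduces every output byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import BinTable, ContactMap

__all__ = [
    "HiCSimConfig",
    "GroundTruth",
    "gen_hic",
    "gen_tad_hic",
    "gen_tracks",
    "gen_boundary_peaks",
    "gen_spots",
]

CATEGORIES = ("A-B", "B-A", "A-B-A", "B-A-B")


@dataclass
class HiCSimConfig:
    """Study conditions for the synthetic time course.

    Defaults mirror the real study's shape: 4 time points x 2 replicates,
    a ~50/50 A/B genome with 19% of bins switching in the mix
    (0.33, 0.49, 0.08, 0.10) over A-B / B-A / A-B-A / B-A-B.
    """

    n_chromosomes: int = 4
    bins_per_chrom: int = 50
    resolution: int = 500_000
    n_timepoints: int = 4
    n_replicates: int = 2
    switch_fraction: float = 0.19
    switch_category_mix: tuple = (0.33, 0.49, 0.08, 0.10)
    decay_exponent: float = 1.0
    compartment_strength: float = 1.8
    bb_longrange_gain_per_stage: float = 0.2
    longrange_cutoff: int = 10_000_000
    trans_aa_boost: float = 1.5
    hub_gain: float = 1.0  # multiplicative trans gain between hub bins at the final stage
    n_hub_genes: int = 0
    cis_depth: float = 100.0
    trans_depth: float = 5.0
    compartment_block_bins: int = 5
    tad_block_sizes: tuple = (1_000_000,)
    noise_dispersion: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.switch_category_mix) - 1.0) > 1e-9:
            raise ValueError("switch_category_mix must sum to 1")
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise ValueError("switch_fraction must be in [0, 1]")
        for name in ("compartment_strength", "trans_aa_boost", "hub_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bb_longrange_gain_per_stage < 0:
            raise ValueError("bb_longrange_gain_per_stage must be >= 0")
        if self.n_timepoints < 2 or self.n_replicates < 1:
            raise ValueError("need >= 2 time points and >= 1 replicate")


@dataclass
class GroundTruth:
    """Planted truth serialized next to the generated files.

    ``labels`` is (n_timepoints, n_bins) of +1 (A) / -1 (B);
    ``switch_category`` holds the planted category per bin ('' = stable).
    """

    labels: np.ndarray
    switch_category: np.ndarray
    hub_bins: list = field(default_factory=list)
    hub_genes: list = field(default_factory=list)
    tad_boundaries: list = field(default_factory=list)

    @property
    def switching_fraction(self) -> float:
        return float((self.switch_category != "").mean())

    def category_shares(self) -> dict[str, float]:
        switching = self.switch_category[self.switch_category != ""]
        return {c: float((switching == c).mean()) if len(switching) else 0.0 for c in CATEGORIES}

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.tolist(),
            "switch_category": self.switch_category.tolist(),
            "hub_bins": [int(b) for b in self.hub_bins],
            "hub_genes": list(self.hub_genes),
            "tad_boundaries": [int(b) for b in self.tad_boundaries],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            labels=np.asarray(d["labels"]),
            switch_category=np.asarray(d["switch_category"], dtype=object),
            hub_bins=d["hub_bins"],
            hub_genes=d["hub_genes"],
            tad_boundaries=d["tad_boundaries"],
        )


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2 (0 => round(mu))."""
    if dispersion <= 0:
        return np.round(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * np.maximum(mu, 1e-12))
    return rng.poisson(lam).astype(float)


def _plant_labels(config: HiCSimConfig, rng: np.random.Generator) -> GroundTruth:
    n = config.n_chromosomes * config.bins_per_chrom
    T = config.n_timepoints
    # alternating A/B blocks with geometric lengths (mean compartment_block_bins):
    # irregular block sizes keep the label composition mixed at every distance,
    # as in real genomes
    base = np.empty(n, dtype=int)
    blk = config.compartment_block_bins
    for c in range(config.n_chromosomes):
        lab = 1 if rng.random() < 0.5 else -1
        b = 0
        while b < config.bins_per_chrom:
            length = int(rng.geometric(1.0 / blk))
            end = min(b + length, config.bins_per_chrom)
            base[c * config.bins_per_chrom + b : c * config.bins_per_chrom + end] = lab
            lab = -lab
            b = end
    labels = np.tile(base, (T, 1))
    switch_category = np.full(n, "", dtype=object)
    n_switch = int(round(config.switch_fraction * n))
    if n_switch:
        chosen = rng.choice(n, size=n_switch, replace=False)
        cats = rng.choice(len(CATEGORIES), size=n_switch, p=np.asarray(config.switch_category_mix))
        for bin_id, ci in zip(chosen, cats):
            cat = CATEGORIES[ci]
            switch_category[bin_id] = cat
            first = 1 if cat[0] == "A" else -1
            if cat in ("A-B", "B-A"):
                change = rng.integers(1, T)  # change point in [1, T-1]
                seq = [first] * change + [-first] * (T - change)
            else:  # transient: away and back, interior stretch
                a = rng.integers(1, T - 1)
                b = rng.integers(a + 1, T)
                seq = [first] * a + [-first] * (b - a) + [first] * (T - b)
            labels[:, bin_id] = seq
    return GroundTruth(labels=labels, switch_category=switch_category)


def _pick_hub_bins(config: HiCSimConfig, truth: GroundTruth, rng: np.random.Generator) -> None:
    """Spread hub bins over chromosomes, preferring constitutively-A stable bins."""
    if config.n_hub_genes <= 0:
        return
    n = truth.labels.shape[1]
    always_a = (truth.labels == 1).all(axis=0) & (truth.switch_category == "")
    per_chrom = np.array_split(np.arange(n), config.n_chromosomes)
    hubs: list[int] = []
    k = 0
    while len(hubs) < config.n_hub_genes:
        pool = per_chrom[k % config.n_chromosomes]
        cand = [b for b in pool if always_a[b] and b not in hubs]
        if not cand:
            cand = [b for b in pool if b not in hubs]
        hubs.append(int(rng.choice(cand)))
        k += 1
    truth.hub_bins = sorted(hubs)


def _expected_matrix(config: HiCSimConfig, truth: GroundTruth, tp: int) -> np.ndarray:
    n = truth.labels.shape[1]
    lab = truth.labels[tp]
    bpc = config.bins_per_chrom
    chrom_of = np.repeat(np.arange(config.n_chromosomes), bpc)
    pos = np.tile(np.arange(bpc), config.n_chromosomes)
    same_chrom = chrom_of[:, None] == chrom_of[None, :]
    d = np.abs(pos[:, None] - pos[None, :]).astype(float)
    same_lab = lab[:, None] == lab[None, :]
    both_a = (lab[:, None] == 1) & (lab[None, :] == 1)
    both_b = (lab[:, None] == -1) & (lab[None, :] == -1)

    mu = np.zeros((n, n))
    with np.errstate(divide="ignore"):
        decay = np.where(d > 0, d**-config.decay_exponent, 2.0)
    cis = config.cis_depth * decay
    cis = np.where(same_lab, cis * config.compartment_strength, cis)
    stage_frac = tp / (config.n_timepoints - 1)
    longrange = d * config.resolution > config.longrange_cutoff
    gain = 1.0 + config.bb_longrange_gain_per_stage * tp
    cis = np.where(both_b & longrange, cis * gain, cis)
    mu[same_chrom] = cis[same_chrom]

    trans = np.full((n, n), config.trans_depth)
    trans = np.where(both_a, trans * config.trans_aa_boost, trans)
    if truth.hub_bins and config.hub_gain > 1.0:
        hub = np.zeros(n, dtype=bool)
        hub[truth.hub_bins] = True
        hub_pair = hub[:, None] & hub[None, :]
        hub_factor = 1.0 + (config.hub_gain - 1.0) * stage_frac
        trans = np.where(hub_pair, trans * hub_factor, trans)
    mu[~same_chrom] = trans[~same_chrom]
    return mu


def gen_hic(config: HiCSimConfig) -> tuple[dict[tuple[str, str], ContactMap], GroundTruth]:
    """Raw contact maps for every (time point, replicate) plus the planted truth.

    Time points are named ``t0..t{T-1}``, replicates ``r1..rR``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _plant_labels(config, rng)
    _pick_hub_bins(config, truth, rng)
    chrom_sizes = {
        f"chr{c + 1}": config.bins_per_chrom * config.resolution
        for c in range(config.n_chromosomes)
    }
    bins = BinTable.from_chrom_sizes(chrom_sizes, config.resolution)
    maps = {}
    n = bins.n_bins
    iu, ju = np.triu_indices(n)
    for tp in range(config.n_timepoints):
        mu = _expected_matrix(config, truth, tp)
        for rep in range(config.n_replicates):
            counts_u = _sample_counts(rng, mu[iu, ju], config.noise_dispersion)
            m = np.zeros((n, n))
            m[iu, ju] = counts_u
            m[ju, iu] = counts_u
            maps[(f"t{tp}", f"r{rep + 1}")] = ContactMap(bins, m)
    return maps, truth


def gen_tad_hic(
    n_blocks: int = 8,
    block_bins: int = 25,
    resolution: int = 40_000,
    depth: float = 80.0,
    decay_exponent: float = 1.0,
    tad_boost: float = 3.0,
    noise_dispersion: float = 0.05,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[ContactMap, list[int]]:
    """Single-chromosome 40 kb matrix with planted TAD blocks.

    Contacts within a block are boosted ``tad_boost``-fold over the power-law
    background.  Returns the raw map and the internal block-junction positions
    (bp), which are the true boundaries.
    """
    rng = np.random.default_rng(seed)
    n = n_blocks * block_bins
    bins = BinTable.from_chrom_sizes({chrom: n * resolution}, resolution)
    block = np.repeat(np.arange(n_blocks), block_bins)
    pos = np.arange(n)
    d = np.abs(pos[:, None] - pos[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        mu = depth * np.where(d > 0, d**-decay_exponent, 2.0)
    mu = np.where(block[:, None] == block[None, :], mu * tad_boost, mu)
    iu, ju = np.triu_indices(n)
    counts = _sample_counts(rng, mu[iu, ju], noise_dispersion)
    m = np.zeros((n, n))
    m[iu, ju] = counts
    m[ju, iu] = counts
    boundaries = [int(b * block_bins * resolution) for b in range(1, n_blocks)]
    return ContactMap(bins, m), boundaries


def gen_tracks(
    config: HiCSimConfig,
    truth: GroundTruth,
    n_genes_per_chrom: int | None = None,
    late_stage_odds: float = 4.0,
    regulated_fraction: float = 0.7,
    peak_height: float = 30.0,
    baseline_fpkm: float = 1.0,
    fpkm_noise_sd: float = 0.1,
    n_peaks_per_stage: int = 200,
    peak_switch_odds: float = 1.0,
    seed: int | None = None,
) -> dict:
    """Gene annotation, FPKM table, DE flags, and per-stage peak BED sets.

    Genes are placed preferentially in constitutively-A bins (2:1 density),
    giving the orientation track its sign.  Each regulated gene peaks at one
    stage; genes in planted B-A bins peak at the final stage with odds
    ``late_stage_odds`` relative to background.  Hub bins (if any) each get a
    dedicated hub gene.  Stage-specific peaks land in switching bins with odds
    ``peak_switch_odds``.

    Returns dict with ``genes`` (gene_id, chrom, tss, start, end, bin),
    ``fpkm`` (genes x stages), ``de_flags``, ``peak_sets`` (stage -> BED
    frame), ``gene_density`` (per-bin counts), ``true_peak_stage``.
    """
    if n_genes_per_chrom is None:
        # roughly two genes per bin, matching genome-wide gene density at 500 kb
        n_genes_per_chrom = 2 * config.bins_per_chrom
    if n_genes_per_chrom < 10:
        raise ValueError("need >= 10 genes per chromosome")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    T = config.n_timepoints
    stages = [f"t{t}" for t in range(T)]
    n = truth.labels.shape[1]
    bpc = config.bins_per_chrom
    res = config.resolution
    chrom_of = np.repeat(np.arange(config.n_chromosomes), bpc)

    always_a = (truth.labels == 1).all(axis=0)
    weight = np.where(always_a, 2.0, 1.0)
    rows = []
    gid = 0
    hub_assigned = set()
    for c in range(config.n_chromosomes):
        bins_c = np.flatnonzero(chrom_of == c)
        w = weight[bins_c] / weight[bins_c].sum()
        chosen = rng.choice(bins_c, size=n_genes_per_chrom, p=w)
        for b in chosen:
            offset = int(rng.integers(0, res - 10_000))
            tss = int((b % bpc) * res + offset)
            rows.append((f"G{gid:05d}", f"chr{c + 1}", tss, tss, tss + int(rng.integers(5_000, 200_000)), int(b)))
            gid += 1
    # dedicated hub genes, one per hub bin
    for k, b in enumerate(truth.hub_bins):
        c = int(chrom_of[b])
        tss = int((b % bpc) * res + res // 2)
        name = f"HUB{k:03d}"
        rows.append((name, f"chr{c + 1}", tss, tss, tss + 100_000, int(b)))
        hub_assigned.add(name)
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "start", "end", "bin"])
    truth.hub_genes = sorted(hub_assigned)

    # true peak stage: uniform background, late-stage odds boost in B->A bins
    b_to_a = truth.switch_category == "B-A"
    probs = np.ones(T)
    peak_stage = []
    for _, g in genes.iterrows():
        p = probs.copy()
        if b_to_a[g["bin"]]:
            p[-1] *= late_stage_odds
        p /= p.sum()
        peak_stage.append(int(rng.choice(T, p=p)))
    peak_stage = np.asarray(peak_stage)
    regulated = rng.random(len(genes)) < regulated_fraction
    regulated |= genes["gene_id"].isin(hub_assigned).values  # hub genes are upregulated

    fpkm = np.full((len(genes), T), baseline_fpkm)
    for i, (stg, reg) in enumerate(zip(peak_stage, regulated)):
        if reg:
            fpkm[i, stg] += peak_height
    fpkm *= np.exp(rng.normal(0.0, fpkm_noise_sd, size=fpkm.shape))
    fpkm_df = pd.DataFrame(fpkm, index=genes["gene_id"], columns=stages)
    de_flags = pd.Series(regulated, index=genes["gene_id"], name="de_flag")

    # per-stage peak sets: stage-specific peaks enriched in switching bins
    switching = truth.switch_category != ""
    peak_sets = {}
    w_base = np.ones(n)
    w_switch = np.where(switching, peak_switch_odds, 1.0)
    for t, stage in enumerate(stages):
        w = w_base * w_switch
        w = w / w.sum()
        chosen = rng.choice(n, size=n_peaks_per_stage, p=w)
        starts = (chosen % bpc) * res + rng.integers(0, res - 600, size=n_peaks_per_stage)
        df = pd.DataFrame(
            {
                "chrom": [f"chr{chrom_of[b] + 1}" for b in chosen],
                "start": starts,
                "end": starts + 500,
            }
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
        peak_sets[stage] = df

    gene_density = np.bincount(genes["bin"], minlength=n).astype(float)
    return {
        "genes": genes,
        "fpkm": fpkm_df,
        "de_flags": de_flags,
        "peak_sets": peak_sets,
        "gene_density": gene_density,
        "true_peak_stage": pd.Series([f"t{s}" for s in peak_stage], index=genes["gene_id"]),
    }


def gen_boundary_peaks(
    boundaries: pd.DataFrame,
    fraction_near: float = 0.7,
    max_dist: int = 1_000,
    n_background: int = 100,
    genome_size: int = 10_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Peak set placed within ``max_dist`` of a ``fraction_near`` share of boundaries.

    The rest of the peaks are background placed uniformly (at least 10 kb from
    any boundary so the planted fraction is exact up to Bernoulli sampling).
    """
    rng = np.random.default_rng(seed)
    rows = []
    bpos = {c: sub["pos"].values for c, sub in boundaries.groupby("chrom")}
    for _, b in boundaries.iterrows():
        if rng.random() < fraction_near:
            start = int(b["pos"] + rng.integers(-max_dist, max_dist - 200))
            rows.append((b["chrom"], max(start, 0), max(start, 0) + 200))
    chroms = list(bpos)
    placed = 0
    while placed < n_background:
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, genome_size - 200))
        if np.abs(bpos[c] - s).min() > 10_000:
            rows.append((c, s, s + 200))
            placed += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


def _uniform_in_ellipsoid(rng: np.random.Generator, axes: np.ndarray, size: int) -> np.ndarray:
    pts = np.empty((size, 3))
    k = 0
    while k < size:
        cand = rng.uniform(-1, 1, size=(size * 2, 3))
        inside = (cand**2).sum(axis=1) <= 1.0
        take = cand[inside][: size - k]
        pts[k : k + len(take)] = take
        k += len(take)
    return pts * axes


def _periphery_distance(p: np.ndarray, axes: np.ndarray) -> float:
    """Radial distance from point to the ellipsoid surface along its own direction."""
    r = np.linalg.norm(p)
    if r == 0:
        return float(axes.min())
    u = p / r
    r_dir = 1.0 / np.sqrt(((u / axes) ** 2).sum())
    return float(max(r_dir - r, 0.0))


def gen_spots(
    n_cells: int,
    p_true: float,
    seed: int = 0,
    mean_volume: float = 600.0,
    volume_cv: float = 0.15,
    aneuploid_fraction: float = 0.0,
    axis_ratio: tuple = (1.2, 1.0, 0.8),
    n_foci: int = 0,
    focus_overlap_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FISH spot table for one condition with a planted true proximity fraction.

    A ``p_true`` Bernoulli fraction of diploid cells gets one green-orange
    pair placed so its volume-normalized distance (against ``mean_volume`` as
    reference) is below 2 µm; all other pairs are rejection-sampled to stay
    above it.  Aneuploid cells carry a third spot in one locus channel.  With
    ``n_foci > 0`` a focus channel is added, overlapping (< 1 µm raw) the
    first green spot in a ``focus_overlap_fraction`` of cells.

    Returns the spot table and a per-cell truth frame
    (``cell_id, is_aneuploid, is_proximal``).
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    ref = mean_volume
    for ci in range(n_cells):
        cell_id = f"cell{ci:04d}"
        volume = float(mean_volume * np.exp(rng.normal(0.0, volume_cv)))
        # ellipsoid with fixed axis ratios and the drawn volume
        base = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        ratios = np.asarray(axis_ratio, dtype=float)
        axes = base * ratios / np.prod(ratios) ** (1.0 / 3.0)
        aneuploid = rng.random() < aneuploid_fraction
        proximal = (not aneuploid) and (rng.random() < p_true)
        norm_factor = (ref / volume) ** (1.0 / 3.0)  # raw -> normalized multiplier

        def sample_spots():
            g = _uniform_in_ellipsoid(rng, axes, 2)
            o = _uniform_in_ellipsoid(rng, axes, 2)
            return g, o

        for _ in range(1000):
            g, o = sample_spots()
            d = np.linalg.norm(g[:, None, :] - o[None, :, :], axis=2) * norm_factor
            if d.min() >= 2.2:
                break
        if proximal:
            # place one orange spot near the first green spot at a normalized
            # distance drawn well inside the 2 um proximity threshold
            target_norm = rng.uniform(0.3, 1.8)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            o[0] = g[0] + direction * (target_norm / norm_factor)

        spots = [("green", g[0]), ("green", g[1]), ("orange", o[0]), ("orange", o[1])]
        if aneuploid:
            extra_channel = "green" if rng.random() < 0.5 else "orange"
            spots.append((extra_channel, _uniform_in_ellipsoid(rng, axes, 1)[0]))
        if n_foci > 0:
            foci = _uniform_in_ellipsoid(rng, axes, n_foci)
            if rng.random() < focus_overlap_fraction:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                foci[0] = g[0] + direction * rng.uniform(0.1, 0.9)
            for f in foci:
                spots.append(("focus", f))
        for channel, p in spots:
            rows.append(
                (
                    cell_id,
                    channel,
                    float(p[0]),
                    float(p[1]),
                    float(p[2]),
                    volume,
                    _periphery_distance(np.asarray(p), axes),
                )
            )
        truth_rows.append((cell_id, aneuploid, proximal))
    table = pd.DataFrame(
        rows,
        columns=["cell_id", "channel", "x", "y", "z", "nucleus_volume", "periphery_distance"],
    )
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "is_aneuploid", "is_proximal"])
    return table, truth
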