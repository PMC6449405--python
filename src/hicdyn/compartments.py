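"""A/B compartment calling and dynamics over a differentiation time course.

The compartment score of a 500 kb bin is the leading eigenvector (PC1) of the
Pearson correlation matrix of the per-chromosome observed/expected map, with
the sign oriented per chromosome so that positive scores correlate with an
activity proxy (gene density by default).  Bins with positive replicate-mean
score are called A, negative B.

Compartment switching across the time course is called per bin by a one-way
ANOVA of replicate scores across time points (p < alpha) combined with a sign
change of the time-point means; the dynamics category is the sequence of
time-point signs with consecutive duplicates collapsed, and four-segment
sequences are merged into the two-segment category given by their first and
last sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import BinTable, ContactMap, expected_by_distance, oe_normalize

__all__ = [
    "CompartmentTrack",
    "SaddleMatrix",
    "compute_pc1",
    "classify_switches",
    "saddle",
    "delta_saddle",
    "decay_curves",
    "compartment_fraction",
]

SWITCH_CATEGORIES = ("A-B", "B-A", "A-B-A", "B-A-B")
STABLE_CATEGORIES = ("stable-A", "stable-B")


@dataclass
class CompartmentTrack:
    """Per-bin PC1 scores for one sample (time point x replicate).

    ``score`` is NaN for masked bins.  Within each chromosome the stored vector
    is the unit-norm leading eigenvector of the O/E correlation matrix scaled
    by the square root of its eigenvalue, oriented A-positive.
    """

    bins: BinTable
    score: np.ndarray
    sample: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.to_frame()
        df["score"] = self.score
        return df


def _leading_eigvec(corr: np.ndarray) -> tuple[np.ndarray, float]:
    vals, vecs = np.linalg.eigh(corr)
    return vecs[:, -1], float(vals[-1])


def compute_pc1(
    oe_map: ContactMap,
    orientation: np.ndarray,
    min_bins: int = 10,
    sample: str = "",
) -> CompartmentTrack:
    """Leading eigenvector of the per-chromosome O/E Pearson correlation matrix.

    Parameters
    ----------
    oe_map
        Observed/expected-normalized cis map (see :func:`~hicdyn.contacts.oe_normalize`).
    orientation
        Per-bin reference track (e.g. gene density); the eigenvector sign on
        each chromosome is flipped so its correlation with this track is
        positive, making A-compartment scores positive.
    min_bins
        Chromosomes with fewer unmasked bins are skipped (scores stay NaN).
    """
    import warnings

    bins = oe_map.bins
    score = np.full(bins.n_bins, np.nan)
    orientation = np.asarray(orientation, dtype=float)
    for chrom in bins.chrom_names():
        idx = bins.chrom_bins(chrom)
        live = idx[~oe_map.mask[idx]]
        sub = oe_map.matrix[np.ix_(live, live)].astype(float)
        np.fill_diagonal(sub, np.nan)  # diagonal excluded from the correlation
        # additionally drop zero-variance bins (constant rows break Pearson r)
        var_ok = np.nanstd(sub, axis=1) > 0
        live = live[var_ok]
        if live.size < min_bins:
            warnings.warn(f"chromosome {chrom}: {live.size} unmasked bins, skipped", stacklevel=2)
            continue
        sub = oe_map.matrix[np.ix_(live, live)].astype(float)
        np.fill_diagonal(sub, np.nan)
        # pairwise-complete Pearson correlation between bin contact profiles
        corr = pd.DataFrame(sub.T).corr().values
        vec, val = _leading_eigvec(corr)
        vec = vec * np.sqrt(max(val, 0.0))
        ref = orientation[live]
        if ref.std() > 0 and np.corrcoef(vec, ref)[0, 1] < 0:
            vec = -vec
        score[live] = vec
    return CompartmentTrack(bins, score, sample=sample)


def _collapse_signs(signs: list[int]) -> list[int]:
    out: list[int] = []
    for s in signs:
        if not out or s != out[-1]:
            out.append(s)
    return out


def _category_from_means(means: np.ndarray) -> str:
    """Dynamics category from the signs of time-point mean scores.

    Exact zeros inherit the previous sign (ties broken toward no transition);
    a leading zero takes the first nonzero sign.  Four-segment sequences are
    merged into the two-segment category of their first and last sign.
    """
    signs = np.sign(means).astype(int).tolist()
    nonzero = [s for s in signs if s != 0]
    if not nonzero:
        return "stable-A"  # degenerate all-zero track; arbitrary but deterministic
    # fill zeros with previous sign (or first nonzero for a leading zero)
    filled = []
    prev = nonzero[0]
    for s in signs:
        if s == 0:
            s = prev
        filled.append(s)
        prev = s
    seq = _collapse_signs(filled)
    label = {1: "A", -1: "B"}
    if len(seq) == 1:
        return f"stable-{label[seq[0]]}"
    if len(seq) >= 4:  # A-B-A-B / B-A-B-A merge into first-last
        seq = [seq[0], seq[-1]]
    return "-".join(label[s] for s in seq)


def classify_switches(
    tracks: dict[tuple[str, str], CompartmentTrack],
    timepoints: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin compartment-dynamics category from replicate PC1 scores.

    Parameters
    ----------
    tracks
        Mapping ``(timepoint, replicate) -> CompartmentTrack`` on a shared bin
        table; at least two time points and two replicates per time point.
    timepoints
        Time points in temporal order.
    alpha
        ANOVA significance level for calling a bin switching.

    Returns
    -------
    DataFrame with columns ``chrom, start, end, bin_id, category, anova_p``
    plus one ``mean_<tp>`` column per time point.  Bins with any missing
    replicate score are excluded (reported via the ``n_excluded`` attr).

    Notes
    -----
    Switching requires both p < alpha and at least one positive and one
    negative time-point mean.  Bins whose replicate values are identical
    across all samples get p = 1 (no variance, stable).
    """
    keys = sorted(tracks)
    reps_by_tp = {tp: [k for k in keys if k[0] == tp] for tp in timepoints}
    if len(timepoints) < 2 or any(len(v) < 2 for v in reps_by_tp.values()):
        raise ValueError("need >=2 time points with >=2 replicates each")
    bins = tracks[keys[0]].bins
    n = bins.n_bins
    data = {tp: np.stack([tracks[k].score for k in reps_by_tp[tp]]) for tp in timepoints}

    complete = np.ones(n, dtype=bool)
    for tp in timepoints:
        complete &= np.isfinite(data[tp]).all(axis=0)

    means = {tp: data[tp].mean(axis=0) for tp in timepoints}
    pvals = np.full(n, np.nan)
    cats = np.full(n, "", dtype=object)
    for b in np.flatnonzero(complete):
        groups = [data[tp][:, b] for tp in timepoints]
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:
            p = 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.f_oneway(*groups)
            if not np.isfinite(p):
                p = 1.0
        m = np.array([means[tp][b] for tp in timepoints])
        cat = _category_from_means(m)
        if cat not in STABLE_CATEGORIES and p >= alpha:
            # sign change without significance: stable by grand-mean sign
            cat = "stable-A" if m.mean() >= 0 else "stable-B"
        pvals[b] = p
        cats[b] = cat

    df = bins.to_frame().loc[complete].copy()
    df["category"] = cats[complete]
    df["anova_p"] = pvals[complete]
    for tp in timepoints:
        df[f"mean_{tp}"] = means[tp][complete]
    df.attrs["n_excluded"] = int(n - complete.sum())
    return df


@dataclass
class SaddleMatrix:
    """Grid of log2 mean O/E per PC1-quantile pair (NaN where a cell is empty)."""

    grid: np.ndarray
    edges: np.ndarray
    domain: str  # "cis" or "trans"


def saddle(
    oe_map: ContactMap,
    track: CompartmentTrack,
    n_quantiles: int = 10,
    domain: str = "cis",
) -> SaddleMatrix:
    """Compartmentalization saddle: log2 mean O/E between PC1 quantile pairs.

    Bins are assigned to ``n_quantiles`` quantile groups of the PC1 track
    (deciles by default, edges computed on this track's own unmasked scores);
    cell (q1, q2) averages O/E over all unmasked cis (or trans) pairs whose
    bins fall in those groups.  Empty cells are NaN, never zero.
    """
    score = track.score
    ok = np.isfinite(score) & ~oe_map.mask
    edges = np.quantile(score[ok], np.linspace(0, 1, n_quantiles + 1))
    q = np.full(len(score), -1)
    q[ok] = np.clip(np.searchsorted(edges, score[ok], side="right") - 1, 0, n_quantiles - 1)

    cis = oe_map.cis_pairs_mask()
    pair_ok = oe_map.valid_pairs_mask() & (cis if domain == "cis" else ~cis)
    if domain == "cis":
        np.fill_diagonal(pair_ok, False)
    grid = np.full((n_quantiles, n_quantiles), np.nan)
    pair_ok &= (q[:, None] >= 0) & (q[None, :] >= 0)
    qa = np.minimum(q[:, None], q[None, :])[pair_ok]
    qb = np.maximum(q[:, None], q[None, :])[pair_ok]
    key = qa * n_quantiles + qb
    sums = np.bincount(key, weights=oe_map.matrix[pair_ok], minlength=n_quantiles**2)
    counts = np.bincount(key, minlength=n_quantiles**2)
    for a in range(n_quantiles):
        for b in range(a, n_quantiles):
            c = counts[a * n_quantiles + b]
            if c > 0:
                mean = sums[a * n_quantiles + b] / c
                if mean > 0:
                    grid[a, b] = grid[b, a] = np.log2(mean)
    return SaddleMatrix(grid, edges, domain)


def delta_saddle(late: SaddleMatrix, early: SaddleMatrix) -> np.ndarray:
    """Change in compartmentalization: difference of the two log2 grids."""
    return late.grid - early.grid


def decay_curves(
    balanced_map: ContactMap,
    track: CompartmentTrack,
    min_pairs: int = 20,
) -> pd.DataFrame:
    """Distance-decay of cis contacts by compartment-pair class (A-A, B-B, A-B).

    At each bin distance the mean contact of each class is divided by the mean
    contact of all pairs at that distance, so the pair-count-weighted mean of
    the three class values is 1 at every distance.  Distances with fewer than
    ``min_pairs`` total pairs are dropped.

    Returns a frame indexed by distance (bp) with columns ``A-A, B-B, A-B``.
    """
    bins = balanced_map.bins
    label = np.where(track.score > 0, 1, -1)
    ok = np.isfinite(track.score) & ~balanced_map.mask
    res = bins.resolution
    max_d = max(len(bins.chrom_bins(c)) for c in bins.chrom_names())
    sums = np.zeros((max_d, 3))
    counts = np.zeros((max_d, 3), dtype=np.int64)
    for chrom in bins.chrom_names():
        idx = bins.chrom_bins(chrom)
        live = idx[ok[idx]]
        if live.size < 2:
            continue
        sub = balanced_map.matrix[np.ix_(live, live)]
        pos = np.searchsorted(idx, live)
        dmat = np.abs(pos[:, None] - pos[None, :])
        lab = label[live]
        same = lab[:, None] == lab[None, :]
        is_a = (lab[:, None] == 1) & (lab[None, :] == 1)
        cls = np.where(same & is_a, 0, np.where(same, 1, 2))  # 0=AA 1=BB 2=AB
        iu, ju = np.triu_indices(len(live), k=1)
        key = dmat[iu, ju] * 3 + cls[iu, ju]
        s = np.bincount(key, weights=sub[iu, ju], minlength=max_d * 3)
        c = np.bincount(key, minlength=max_d * 3)
        sums += s.reshape(max_d, 3)
        counts += c.reshape(max_d, 3)
    names = ["A-A", "B-B", "A-B"]
    rows = {}
    for d in range(1, max_d):
        ntot = counts[d].sum()
        if ntot < min_pairs:
            continue
        overall = sums[d].sum() / ntot
        if overall == 0:
            continue
        row = {}
        for ci, name in enumerate(names):
            nc = counts[d, ci]
            row[name] = (sums[d, ci] / nc) / overall if nc else np.nan
            row[f"n_{name}"] = nc
        rows[d * res] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("distance")


def compartment_fraction(track: CompartmentTrack) -> dict[str, float]:
    """Fraction of unmasked bins in A (score > 0) and B (score < 0); sums to 1."""
    score = track.score[np.isfinite(track.score)]
    if score.size == 0:
        raise ValueError("no scored bins")
    a = float((score > 0).sum())
    b = float((score < 0).sum())
    zero = float((score == 0).sum())
    # exact zeros split toward A by the A-if->0-else-B convention applied to >=
    a += zero
    tot = a + b
    return {"A": a / tot, "B": b / tot}
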