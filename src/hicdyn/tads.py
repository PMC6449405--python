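"""TAD boundary detection and boundary dynamics at 40 kb resolution.

Two complementary boundary callers are provided:

* directionality index (DI): for each bin, contrast the summed contacts to
  bins within a window upstream (A) vs downstream (B) as
  ``DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)`` with ``E = (A + B)/2``;
  domains are segmented by deterministic run-length thresholds on the DI track
  (the original pipeline's HMM is deliberately not reimplemented).
* insulation score: log2 of the mean contact in a square sliding along the
  diagonal, normalized to the chromosome mean of that statistic; boundaries at
  sufficiently strong local minima.

Boundary sets are compared across replicates/time points by greedy one-to-one
nearest matching within a tolerance (±80 kb replicates, ±200 kb time points)
and summarized by the Jaccard index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import BinTable, ContactMap

__all__ = [
    "directionality_index",
    "di_domains",
    "insulation_score",
    "insulation_boundaries",
    "compare_boundaries",
    "tad_compartment_assignment",
    "boundary_category_enrichment",
    "nearest_gene_expression_change",
]


def di_statistic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """DI from upstream sums ``a`` and downstream sums ``b`` (vectorized)."""
    e = (a + b) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        di = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    di[~np.isfinite(di)] = 0.0
    return di


def directionality_index(cmap: ContactMap, window: int = 2_000_000) -> pd.DataFrame:
    """Per-bin DI track; bins whose window spills off the chromosome are flagged.

    Returns columns ``chrom, start, end, bin_id, up, down, di, at_edge``.
    """
    bins = cmap.bins
    w = max(1, window // bins.resolution)
    frames = []
    for chrom in bins.chrom_names():
        idx = bins.chrom_bins(chrom)
        nb = len(idx)
        if w >= nb:
            import warnings

            warnings.warn(f"window {window} bp exceeds chromosome {chrom}, skipped", stacklevel=2)
            continue
        sub = cmap.matrix[np.ix_(idx, idx)]
        up = np.zeros(nb)
        down = np.zeros(nb)
        for k in range(nb):
            up[k] = sub[k, max(0, k - w) : k].sum()
            down[k] = sub[k, k + 1 : min(nb, k + w + 1)].sum()
        di = di_statistic(up, down)
        df = bins.to_frame().iloc[idx].copy()
        df["up"] = up
        df["down"] = down
        df["di"] = di
        df["at_edge"] = (np.arange(nb) < w) | (np.arange(nb) >= nb - w)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def di_domains(
    di_track: pd.DataFrame,
    pos_thresh: float | None = None,
    neg_thresh: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment TADs from a DI track by run-length thresholds.

    A domain opens at the start of a downstream-biased stretch
    (DI >= pos_thresh) and closes at the end of the next upstream-biased
    stretch (DI <= neg_thresh).  Default thresholds are the 0.9 / 0.1
    quantiles of the DI distribution.

    Returns ``(tads, boundaries)`` as BED-like frames; boundaries are the
    domain edges, unique per (chrom, position).
    """
    if pos_thresh is None:
        pos_thresh = float(np.quantile(di_track["di"], 0.9))
    if neg_thresh is None:
        neg_thresh = float(np.quantile(di_track["di"], 0.1))
    tad_rows, bound_rows = [], []
    for chrom, sub in di_track.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        di = sub["di"].values
        state = 0  # 0 idle, 1 inside domain (seen opening stretch)
        open_start = None
        k = 0
        n = len(sub)
        while k < n:
            if state == 0 and di[k] >= pos_thresh:
                open_start = sub.loc[k, "start"]
                state = 1
            elif state == 1 and di[k] <= neg_thresh:
                # consume the whole upstream-biased stretch, close at its end
                while k + 1 < n and di[k + 1] <= neg_thresh:
                    k += 1
                end = sub.loc[k, "end"]
                tad_rows.append((chrom, int(open_start), int(end)))
                state = 0
                open_start = None
            k += 1
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    for chrom, s, e in tad_rows:
        bound_rows.append((chrom, s))
        bound_rows.append((chrom, e))
    boundaries = (
        pd.DataFrame(bound_rows, columns=["chrom", "pos"])
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return tads, boundaries


def insulation_score(cmap: ContactMap, square: int = 500_000) -> pd.DataFrame:
    """Sliding-square insulation track: log2(square mean / chromosome mean).

    The square of side ``square`` bp slides along the diagonal; the score is
    defined only where the full square fits (NaN near chromosome ends and at
    masked bins).
    """
    bins = cmap.bins
    w = max(1, square // bins.resolution)
    frames = []
    for chrom in bins.chrom_names():
        idx = bins.chrom_bins(chrom)
        nb = len(idx)
        sub = cmap.matrix[np.ix_(idx, idx)]
        ok = ~cmap.mask[idx]
        valid = np.outer(ok, ok)
        raw = np.full(nb, np.nan)
        for k in range(w, nb - w):
            win = sub[k - w : k, k + 1 : k + w + 1]
            vw = valid[k - w : k, k + 1 : k + w + 1]
            if vw.any():
                # masked rows/columns are excluded from the square mean; the
                # center bin itself is never part of the square
                raw[k] = win[vw].mean()
        live = np.isfinite(raw) & (raw > 0)
        score = np.full(nb, np.nan)
        if live.any():
            mean = raw[live].mean()
            score[live] = np.log2(raw[live] / mean)
        df = bins.to_frame().iloc[idx].copy()
        df["insulation"] = score
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def insulation_boundaries(track: pd.DataFrame, min_strength: float = 0.1) -> pd.DataFrame:
    """Boundaries at local minima of the insulation track.

    Boundary strength is the smaller of the rises from the minimum to the
    nearest flanking local maxima; minima with strength < ``min_strength``
    are discarded (raising the threshold can only remove boundaries).
    """
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        s = sub["insulation"].values
        n = len(s)
        finite = np.isfinite(s)
        if not finite.any():
            continue
        for k in range(1, n - 1):
            if not (finite[k] and finite[k - 1] and finite[k + 1]):
                continue
            if not (s[k] <= s[k - 1] and s[k] <= s[k + 1] and (s[k] < s[k - 1] or s[k] < s[k + 1])):
                continue
            # walk to flanking local maxima
            left = k
            while left > 0 and finite[left - 1] and s[left - 1] >= s[left]:
                left -= 1
            right = k
            while right < n - 1 and finite[right + 1] and s[right + 1] >= s[right]:
                right += 1
            strength = min(s[left] - s[k], s[right] - s[k])
            if strength >= min_strength:
                rows.append((chrom, int(sub.loc[k, "start"]), float(strength)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strength"])


def compare_boundaries(
    set_a: pd.DataFrame, set_b: pd.DataFrame, tolerance: int
) -> dict:
    """Greedy one-to-one matching of two boundary sets within a tolerance (bp).

    Each boundary is used at most once; matches are made nearest-first.
    Returns shared count, the A-/B-specific frames, and the Jaccard index
    ``shared / (|A| + |B| - shared)``.
    """
    shared = 0
    a_used = np.zeros(len(set_a), dtype=bool)
    b_used = np.zeros(len(set_b), dtype=bool)
    a_idx = set_a.reset_index(drop=True)
    b_idx = set_b.reset_index(drop=True)
    cands = []
    for ia, ra in a_idx.iterrows():
        for ib, rb in b_idx.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            d = abs(int(ra["pos"]) - int(rb["pos"]))
            if d <= tolerance:
                cands.append((d, ia, ib))
    for d, ia, ib in sorted(cands):
        if not a_used[ia] and not b_used[ib]:
            a_used[ia] = b_used[ib] = True
            shared += 1
    union = len(a_idx) + len(b_idx) - shared
    return {
        "shared": shared,
        "a_specific": a_idx[~a_used],
        "b_specific": b_idx[~b_used],
        "union": union,
        "jaccard": shared / union if union else 1.0,
    }


def tad_compartment_assignment(tads: pd.DataFrame, switch_calls: pd.DataFrame) -> pd.DataFrame:
    """Assign each TAD the compartment-dynamics category covering most of its span.

    Requires a majority (>= 51% of the TAD's covered span); TADs overlapping
    only masked/unclassified bins are left unassigned (category NaN).
    """
    out = tads.copy()
    cats = []
    for _, tad in tads.iterrows():
        sel = switch_calls[
            (switch_calls["chrom"] == tad["chrom"])
            & (switch_calls["end"] > tad["start"])
            & (switch_calls["start"] < tad["end"])
        ]
        if sel.empty:
            cats.append(np.nan)
            continue
        cover = (
            np.minimum(sel["end"], tad["end"]) - np.maximum(sel["start"], tad["start"])
        ).groupby(sel["category"].values).sum()
        cats.append(cover.idxmax())  # majority category over the covered span
    out["category"] = cats
    return out


def _category_of_positions(positions: pd.DataFrame, switch_calls: pd.DataFrame) -> pd.Series:
    """Compartment-dynamics category of the bin covering each boundary position."""
    cats = []
    for _, row in positions.iterrows():
        sel = switch_calls[
            (switch_calls["chrom"] == row["chrom"])
            & (switch_calls["start"] <= row["pos"])
            & (row["pos"] < switch_calls["end"])
        ]
        if sel.empty:
            # boundary on a bin edge: fall back to the bin ending here
            sel = switch_calls[
                (switch_calls["chrom"] == row["chrom"]) & (switch_calls["end"] == row["pos"])
            ]
        cats.append(sel["category"].iloc[0] if not sel.empty else np.nan)
    return pd.Series(cats, index=positions.index)


def boundary_category_enrichment(
    boundary_class: pd.DataFrame,
    switch_calls: pd.DataFrame,
    union_set: pd.DataFrame,
) -> pd.DataFrame:
    """Enrichment of a boundary class across compartment-dynamics categories.

    Compares the category distribution of ``boundary_class`` against that of
    the union boundary set: per category ``log2(observed share / union share)``
    with a chi-squared test of the observed counts against expectations
    proportional to the union distribution.
    """
    obs_cat = _category_of_positions(boundary_class, switch_calls).dropna()
    uni_cat = _category_of_positions(union_set, switch_calls).dropna()
    cats = sorted(uni_cat.unique())
    obs = np.array([(obs_cat == c).sum() for c in cats], dtype=float)
    uni = np.array([(uni_cat == c).sum() for c in cats], dtype=float)
    expected = uni / uni.sum() * obs.sum()
    keep = expected > 0
    chi2, p = stats.chisquare(obs[keep], expected[keep])
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2((obs / obs.sum()) / (uni / uni.sum()))
    return pd.DataFrame(
        {
            "category": cats,
            "observed": obs,
            "expected": expected,
            "log2_ratio": log2,
            "chi2": chi2,
            "p": p,
        }
    )


def nearest_gene_expression_change(
    boundaries: pd.DataFrame,
    genes: pd.DataFrame,
    fpkm: pd.DataFrame,
    early: str,
    late: str,
    pseudocount: float = 0.1,
) -> dict:
    """log2 FPKM fold change (late/early) of the gene with the nearest TSS to each boundary.

    ``genes`` needs columns ``gene_id, chrom, tss``; ``fpkm`` is indexed by
    gene_id with one column per time point.  Boundaries on chromosomes without
    genes are dropped.  Returns the per-boundary log2 fold changes and a
    one-sample two-sided t-test against mean 0.
    """
    lfc = []
    for _, row in boundaries.iterrows():
        sub = genes[genes["chrom"] == row["chrom"]]
        if sub.empty:
            continue
        nearest = sub.iloc[(sub["tss"] - row["pos"]).abs().values.argmin()]
        g = nearest["gene_id"]
        lfc.append(
            np.log2((fpkm.loc[g, late] + pseudocount) / (fpkm.loc[g, early] + pseudocount))
        )
    lfc = np.asarray(lfc)
    if lfc.size >= 2 and np.ptp(lfc) > 0:
        t, p = stats.ttest_1samp(lfc, 0.0)
    else:
        t, p = 0.0, 1.0
    return {"log2fc": lfc, "mean": float(lfc.mean()) if lfc.size else np.nan, "t": float(t), "p": float(p)}
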