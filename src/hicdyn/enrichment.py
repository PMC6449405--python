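"""Category enrichment of gene sets and interval sets in compartment dynamics.

Features (gene TSSs or interval midpoints) are assigned to the covering
compartment bin and their distribution over dynamics categories is compared
to a background set: per category ``log2(observed share / background share)``
with a chi-squared test of observed counts against expectations proportional
to the background distribution.  Also covers stage-specific peak-set
construction by interval overlap, peak-stage classification of differentially
expressed genes, and nearest-feature proximity fractions (e.g. the fraction of
TAD boundaries with a CTCF peak within 1 kb).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_gene_stage",
    "category_enrichment",
    "stage_specific_features",
    "feature_proximity_fraction",
]


def classify_gene_stage(
    fpkm: pd.DataFrame,
    de_flags: pd.Series,
    min_fpkm: float = 5.0,
) -> pd.DataFrame:
    """Peak-expression stage for differentially expressed genes.

    The DE set is the flagged genes (externally supplied q < 0.05 calls) whose
    maximum FPKM across time points is at least ``min_fpkm``.  The peak stage
    is the argmax time point (ties resolve to the earliest; ``tie`` column
    marks them).  All-zero genes are excluded.
    """
    fpkm = fpkm.loc[fpkm.max(axis=1) > 0]
    flagged = fpkm.index.intersection(de_flags[de_flags].index)
    de = fpkm.loc[flagged]
    de = de[de.max(axis=1) >= min_fpkm]
    peak = de.idxmax(axis=1)  # first max = earliest time point on ties
    tie = (de.eq(de.max(axis=1), axis=0).sum(axis=1) > 1)
    return pd.DataFrame({"peak_stage": peak, "tie": tie})


def _assign_category(points: pd.DataFrame, switch_calls: pd.DataFrame) -> pd.Series:
    """Dynamics category of the compartment bin covering each (chrom, pos) point."""
    cats = pd.Series(np.nan, index=points.index, dtype=object)
    for chrom, sub in points.groupby("chrom"):
        calls = switch_calls[switch_calls["chrom"] == chrom].sort_values("start")
        if calls.empty:
            continue
        starts = calls["start"].values
        ends = calls["end"].values
        pos = sub["pos"].values
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        vals = np.where(ok, calls["category"].values[np.clip(k, 0, len(ends) - 1)], None)
        cats.loc[sub.index] = vals
    return cats


def _points_from_features(features: pd.DataFrame) -> pd.DataFrame:
    """Interval midpoints or gene TSSs as (chrom, pos) points."""
    if "tss" in features.columns:
        return pd.DataFrame({"chrom": features["chrom"], "pos": features["tss"]})
    if "pos" in features.columns:
        return features[["chrom", "pos"]]
    mid = (features["start"] + features["end"]) // 2
    return pd.DataFrame({"chrom": features["chrom"], "pos": mid})


def category_enrichment(
    features: pd.DataFrame,
    switch_calls: pd.DataFrame,
    background: pd.DataFrame,
    min_expected: float = 1.0,
) -> pd.DataFrame:
    """Enrichment of a feature set over compartment-dynamics categories.

    Expected counts are proportional to the background's category
    distribution (e.g. all genes, normalizing for gene density; or the union
    peak set).  Categories whose expected count falls below ``min_expected``
    are merged into ``other`` before the chi-squared test.
    """
    f_cat = _assign_category(_points_from_features(features), switch_calls).dropna()
    b_cat = _assign_category(_points_from_features(background), switch_calls).dropna()
    cats = sorted(b_cat.unique())
    obs = np.array([(f_cat == c).sum() for c in cats], dtype=float)
    bkg = np.array([(b_cat == c).sum() for c in cats], dtype=float)
    expected = bkg / bkg.sum() * obs.sum()
    small = expected < min_expected
    if small.any() and small.sum() < len(cats):
        keep = ~small
        cats = [c for c, k in zip(cats, keep) if k] + ["other"]
        obs = np.append(obs[keep], obs[~keep].sum())
        bkg = np.append(bkg[keep], bkg[~keep].sum())
        expected = bkg / bkg.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, expected)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2((obs / obs.sum()) / (bkg / bkg.sum()))
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


def _overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Per-interval flag: does interval in ``a`` overlap (>=1 bp) any interval in ``b``."""
    out = np.zeros(len(a), dtype=bool)
    for chrom, sub in a.groupby("chrom"):
        bb = b[b["chrom"] == chrom].sort_values("start")
        if bb.empty:
            continue
        starts = bb["start"].values
        ends = bb["end"].values
        # max end seen up to each sorted interval, for interval stabbing
        cummax_end = np.maximum.accumulate(ends)
        for i, (s, e) in zip(sub.index, sub[["start", "end"]].values):
            k = np.searchsorted(starts, e)  # candidates with start < e
            if k == 0:
                continue
            out[a.index.get_loc(i)] = cummax_end[k - 1] > s
    return out


def stage_specific_features(peak_sets: dict[str, pd.DataFrame]) -> dict[str, dict]:
    """Split per-stage peak sets into stage-specific, shared, and constitutive.

    Stage-specific peaks overlap (>= 1 bp) no peak of any other stage;
    constitutive peaks overlap a peak in every stage (any-overlap rule).
    """
    stages = list(peak_sets)
    result = {}
    for stage in stages:
        peaks = peak_sets[stage].sort_values(["chrom", "start"]).reset_index(drop=True)
        others = [s for s in stages if s != stage]
        overlap_counts = np.zeros(len(peaks), dtype=int)
        for other in others:
            overlap_counts += _overlaps_any(peaks, peak_sets[other]).astype(int)
        specific = peaks[overlap_counts == 0]
        constitutive = peaks[overlap_counts == len(others)]
        shared = peaks[(overlap_counts > 0) & (overlap_counts < len(others))]
        result[stage] = {"specific": specific, "shared": shared, "constitutive": constitutive}
    return result


def feature_proximity_fraction(
    set_a: pd.DataFrame, set_b: pd.DataFrame, max_dist: int
) -> float:
    """Fraction of A features whose nearest B feature is within ``max_dist`` bp.

    Overlapping intervals have distance 0.  Point sets may be given with a
    ``pos`` column.  An empty B set yields 0 with a warning.
    """
    import warnings

    if len(set_b) == 0:
        warnings.warn("empty reference set; proximity fraction is 0", stacklevel=2)
        return 0.0

    def intervals(df):
        if "pos" in df.columns and "start" not in df.columns:
            return pd.DataFrame({"chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1})
        return df[["chrom", "start", "end"]]

    a = intervals(set_a)
    b = intervals(set_b)
    n_close = 0
    for chrom, sub in a.groupby("chrom"):
        bb = b[b["chrom"] == chrom]
        if bb.empty:
            continue
        bs = bb["start"].values[None, :]
        be = bb["end"].values[None, :]
        s = sub["start"].values[:, None]
        e = sub["end"].values[:, None]
        # gap between half-open intervals: 0 when they overlap or abut
        gap = np.maximum(0, np.maximum(bs - e, s - be))
        n_close += (gap.min(axis=1) <= max_dist).sum()
    return float(n_close) / len(a)
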