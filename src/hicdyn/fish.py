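"""Statistics on exported 3D DNA FISH / immunoFISH spot tables.

Input is one CSV row per detected spot: ``cell_id, channel, x, y, z`` (µm),
``nucleus_volume`` (µm³) and ``periphery_distance`` (µm, from the image
distance transform).  Spots follow the 1-µm-wide convention (radius 0.5 µm).

Analyses: diploid filtering (exactly two spots per locus channel),
volume-normalized minimum pair distances
(``X_norm = X_raw * ref_volume^(1/3) * volume^(-1/3)``), proximity calls
(normalized minimum distance < 2 µm, twice the spot diameter), locus/focus
overlap calls (raw center-to-center distance < 1 µm, one spot diameter), and
rank-based group comparisons (rank-sum for two groups, Kruskal-Wallis with
Dunn's pairwise post-hoc for more).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_diploid",
    "min_pair_distance",
    "cell_distances",
    "proximity_fraction",
    "focus_overlap",
    "group_compare",
]

LOCUS_CHANNELS = ("green", "orange")
PROXIMITY_THRESHOLD = 2.0  # µm, on normalized distances
OVERLAP_THRESHOLD = 1.0  # µm, on raw distances


def filter_diploid(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain cells with exactly two spots in each locus channel.

    Focus-channel spot counts are unconstrained.  Returns the diploid subset
    and a per-cell exclusion report with the offending spot counts.
    """
    counts = (
        table[table["channel"].isin(LOCUS_CHANNELS)]
        .groupby(["cell_id", "channel"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(LOCUS_CHANNELS), fill_value=0)
    )
    all_cells = pd.Index(table["cell_id"].unique())
    counts = counts.reindex(all_cells, fill_value=0)
    diploid = counts.index[(counts["green"] == 2) & (counts["orange"] == 2)]
    report = counts.loc[~counts.index.isin(diploid)].reset_index()
    return table[table["cell_id"].isin(diploid)].copy(), report


def _spot_coords(cell: pd.DataFrame, channel: str) -> np.ndarray:
    sub = cell[cell["channel"] == channel]
    return sub[["x", "y", "z"]].values.astype(float)


def min_pair_distance(cell: pd.DataFrame, ref_volume: float) -> dict:
    """Minimum green-orange center distance for one diploid cell, volume-normalized.

    Normalization multiplies the raw distance by
    ``ref_volume^(1/3) * volume^(-1/3)`` (cube-root rescaling to a reference
    nuclear volume); proximity is a normalized distance below 2 µm.
    Cells with any non-finite coordinate are rejected (ValueError).
    """
    g = _spot_coords(cell, "green")
    o = _spot_coords(cell, "orange")
    if not (np.isfinite(g).all() and np.isfinite(o).all()):
        raise ValueError("non-finite spot coordinate")
    d = np.linalg.norm(g[:, None, :] - o[None, :, :], axis=2)
    raw = float(d.min())
    volume = float(cell["nucleus_volume"].iloc[0])
    norm = raw * ref_volume ** (1.0 / 3.0) * volume ** (-1.0 / 3.0)
    return {
        "cell_id": cell["cell_id"].iloc[0],
        "raw_min_distance": raw,
        "normalized_min_distance": norm,
        "proximity": norm < PROXIMITY_THRESHOLD,
        "nucleus_volume": volume,
    }


def cell_distances(
    table: pd.DataFrame,
    ref_volume: float,
    normalize_periphery: bool = True,
) -> pd.DataFrame:
    """Per-diploid-cell distance results for a spot table (see :func:`min_pair_distance`).

    Also reports the volume-normalized (optionally raw) per-cell mean locus
    periphery distance per channel.  Cells with missing coordinates are
    dropped and counted in the ``n_dropped`` attr.
    """
    diploid, _ = filter_diploid(table)
    rows = []
    dropped = 0
    for _, cell in diploid.groupby("cell_id", sort=False):
        try:
            rec = min_pair_distance(cell, ref_volume)
        except ValueError:
            dropped += 1
            continue
        factor = (ref_volume / rec["nucleus_volume"]) ** (1.0 / 3.0) if normalize_periphery else 1.0
        for channel in LOCUS_CHANNELS:
            sub = cell[cell["channel"] == channel]
            if "periphery_distance" in sub.columns:
                rec[f"periphery_{channel}"] = float(sub["periphery_distance"].mean()) * factor
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = dropped
    return out


def proximity_fraction(results: pd.DataFrame) -> dict:
    """Fraction of diploid cells with a proximity call, with a 95% binomial CI."""
    if len(results) == 0:
        raise ValueError("no cells")
    k = int(results["proximity"].sum())
    n = len(results)
    frac = k / n
    lo, hi = stats.binomtest(k, n).proportion_ci(confidence_level=0.95)
    return {"fraction": frac, "n": n, "ci_low": float(lo), "ci_high": float(hi)}


def focus_overlap(
    table: pd.DataFrame,
    locus_channel: str = "green",
    focus_channel: str = "focus",
    overlap_thresh: float = OVERLAP_THRESHOLD,
) -> pd.DataFrame:
    """Per-locus overlap with the nearest focus (raw center distance < threshold).

    Overlap is evaluated on raw distances since the threshold encodes the
    physical spot size.  All cells are included (polyploid too); cells without
    foci get overlap False and ``n_foci`` 0.
    """
    rows = []
    for cell_id, cell in table.groupby("cell_id", sort=False):
        loci = _spot_coords(cell, locus_channel)
        foci = _spot_coords(cell, focus_channel)
        for k, locus in enumerate(loci):
            if len(foci) == 0:
                rows.append((cell_id, k, np.nan, False, 0))
                continue
            d = np.linalg.norm(foci - locus, axis=1).min()
            rows.append((cell_id, k, float(d), bool(d < overlap_thresh), len(foci)))
    return pd.DataFrame(
        rows, columns=["cell_id", "locus_index", "min_focus_distance", "overlap", "n_foci"]
    )


def _dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with tie correction and Holm adjustment."""
    names = list(groups)
    data = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    ranks = stats.rankdata(data)
    n = len(data)
    # tie correction term
    _, tie_counts = np.unique(data, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    sizes = {g: (labels == g).sum() for g in names}
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    df["p_adj"] = multipletests(df["p"], method="holm")[1]
    return df


def group_compare(results_by_condition: dict[str, pd.DataFrame], column: str = "normalized_min_distance") -> dict:
    """Rank-based comparison of a distance column across conditions.

    Two conditions: two-sided Wilcoxon rank-sum.  More: Kruskal-Wallis
    followed by Dunn's pairwise post-hoc with Holm adjustment.  Groups of
    size < 3 trigger a warning.
    """
    import warnings

    groups = {c: df[column].dropna().values for c, df in results_by_condition.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions")
    for c, v in groups.items():
        if len(v) < 3:
            warnings.warn(f"condition {c!r} has {len(v)} observations", stacklevel=2)
    if len(groups) == 2:
        (a, b) = groups.values()
        if np.ptp(np.concatenate([a, b])) == 0:
            return {"test": "ranksum", "stat": 0.0, "p": 1.0}
        stat, p = stats.ranksums(a, b)
        return {"test": "ranksum", "stat": float(stat), "p": float(p)}
    flat = np.concatenate(list(groups.values()))
    if np.ptp(flat) == 0:
        return {"test": "kruskal", "stat": 0.0, "p": 1.0, "pairwise": None}
    stat, p = stats.kruskal(*groups.values())
    return {
        "test": "kruskal",
        "stat": float(stat),
        "p": float(p),
        "pairwise": _dunn_test(groups),
    }
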