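"""Inter-chromosomal (trans) contact statistics and the trans-interacting-domain test.

Implements three layers:

* per-locus trans profiles: all inter-chromosomal balanced counts for an
  anchor bin, trimmed of the top 0.5% values and Z-scored, then stratified by
  the A/B compartment of the partner bins;
* gene-set trans association: the summed balanced counts between the bins of
  all unordered gene pairs on different chromosomes, tested against a null of
  random gene sets with the same per-chromosome composition (chromosome-matched
  permutations, empirical p with add-one correction);
* network edge tables with the display filter (edge count above the late
  time point's genome-wide median trans count) and log2 fold-change annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMap
from .compartments import CompartmentTrack

__all__ = [
    "locus_trans_zscores",
    "geneset_trans_score",
    "permutation_null",
    "build_network",
    "median_trans_count",
]


def locus_trans_zscores(
    cmap: ContactMap,
    anchor_bin: int,
    track: CompartmentTrack | None = None,
    trim: float = 0.005,
) -> pd.DataFrame:
    """Z-scored trans contacts of one anchor bin, optionally labelled by compartment.

    The top ``trim`` fraction of raw trans values is removed before Z-scoring
    (and is absent from the output); over the retained partner bins the
    Z-scores have mean 0 and (population) SD 1.  Partner compartments come
    from the sign of ``track`` scores.
    """
    import warnings

    if cmap.mask[anchor_bin]:
        raise ValueError(f"anchor bin {anchor_bin} is masked")
    bins = cmap.bins
    code = pd.factorize(bins.chroms)[0]
    partners = np.flatnonzero((code != code[anchor_bin]) & ~cmap.mask)
    values = cmap.matrix[anchor_bin, partners]
    if trim > 0 and len(values):
        # retain the lowest floor((1 - trim) * n) values; ties broken by stable order
        n_target = max(int(np.floor(len(values) * (1.0 - trim))), 1)
        order = np.argsort(values, kind="stable")
        keep = np.zeros(len(values), dtype=bool)
        keep[order[:n_target]] = True
        partners, values = partners[keep], values[keep]
    if len(partners) < 100:
        warnings.warn(f"only {len(partners)} retained partner bins", stacklevel=2)
    sd = values.std()
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    df = bins.to_frame().iloc[partners].copy()
    df["value"] = values
    df["z"] = z
    if track is not None:
        df["compartment"] = np.where(track.score[partners] > 0, "A", "B")
        df.loc[~np.isfinite(track.score[partners]), "compartment"] = np.nan
    return df.reset_index(drop=True)


def compare_z_by_group(profile: pd.DataFrame, group_col: str = "compartment") -> dict:
    """Median Z per group plus a two-sided rank-sum test between the two groups."""
    groups = profile.dropna(subset=[group_col]).groupby(group_col)["z"]
    medians = groups.median().to_dict()
    keys = sorted(medians)
    result = {"median_z": medians}
    if len(keys) == 2:
        a, b = (profile.loc[profile[group_col] == k, "z"] for k in keys)
        stat, p = stats.ranksums(a, b)
        result.update({"ranksum_stat": float(stat), "p": float(p)})
    return result


def _gene_bins(cmap: ContactMap, genes: pd.DataFrame) -> pd.DataFrame:
    """Map each gene's promoter (TSS) to its covering bin; errors list offenders."""
    bad = []
    bins = []
    for _, g in genes.iterrows():
        try:
            bins.append(cmap.bins.locate(g["chrom"], int(g["tss"])))
        except KeyError:
            bad.append(g["gene_id"])
            bins.append(-1)
    if bad:
        raise KeyError(f"genes off assembly: {bad}")
    out = genes.copy()
    out["bin"] = bins
    return out


def geneset_trans_score(cmap: ContactMap, genes: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Summed balanced counts over all unordered trans gene pairs, plus the edge table.

    ``genes`` needs ``gene_id, chrom, tss``.  Pairs on the same chromosome
    contribute zero and are omitted from the edge table.  Genes sharing a bin
    each count in their own pairs.
    """
    gb = _gene_bins(cmap, genes)
    rows = []
    total = 0.0
    recs = gb.to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a["chrom"] == b["chrom"]:
                continue
            v = float(cmap.matrix[a["bin"], b["bin"]])
            total += v
            rows.append((a["gene_id"], b["gene_id"], v))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "count"])
    return total, edges


def permutation_null(
    cmap: ContactMap,
    genes: pd.DataFrame,
    universe: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    exclude_seed: bool = True,
) -> dict:
    """Chromosome-matched permutation null for the gene-set trans score.

    Each permutation draws, per chromosome, the same number of genes as the
    seed set from ``universe`` (without replacement, excluding the seed genes
    by default) and scores the drawn set identically.  The empirical p-value
    uses the add-one correction ``(1 + #{null >= observed}) / (n + 1)`` so it
    is never zero.
    """
    rng = np.random.default_rng(seed)
    observed, edges = geneset_trans_score(cmap, genes)
    pool = universe
    if exclude_seed:
        pool = universe[~universe["gene_id"].isin(genes["gene_id"])]
    pool_bins = _gene_bins(cmap, pool)
    need = genes.groupby("chrom").size()
    by_chrom = {c: sub["bin"].values for c, sub in pool_bins.groupby("chrom")}
    for chrom, k in need.items():
        avail = len(by_chrom.get(chrom, ()))
        if avail < k:
            raise ValueError(f"universe too small on {chrom}: need {k}, have {avail}")
    chrom_list = []
    for chrom, k in need.items():
        chrom_list.append((chrom, int(k)))
    null = np.empty(n)
    for it in range(n):
        bins_drawn, chrom_of = [], []
        for chrom, k in chrom_list:
            picks = rng.choice(by_chrom[chrom], size=k, replace=False)
            bins_drawn.extend(picks)
            chrom_of.extend([chrom] * k)
        bins_drawn = np.asarray(bins_drawn)
        codes = pd.factorize(np.asarray(chrom_of))[0]
        sub = cmap.matrix[np.ix_(bins_drawn, bins_drawn)]
        diff = codes[:, None] != codes[None, :]
        iu, ju = np.triu_indices(len(bins_drawn), k=1)
        null[it] = sub[iu, ju][diff[iu, ju]].sum()
    p = (1.0 + float((null >= observed).sum())) / (n + 1.0)
    return {"observed": observed, "null": null, "p": p, "edges": edges}


def median_trans_count(cmap: ContactMap) -> float:
    """Genome-wide median balanced trans count over unmasked bin pairs."""
    cis = cmap.cis_pairs_mask()
    sel = (~cis) & cmap.valid_pairs_mask()
    iu = np.triu_indices(cmap.bins.n_bins, k=1)
    pick = sel[iu]
    return float(np.median(cmap.matrix[iu][pick]))


def build_network(
    maps: dict[str, ContactMap],
    genes: pd.DataFrame,
    early: str,
    late: str,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Edge table across time points with display filter and fold-change annotation.

    An edge is flagged for display iff its late-time-point count exceeds the
    genome-wide median trans count of the late map (strict inequality).  The
    annotation is ``log2((count_late/median_late) / (count_early/median_early))``;
    zero early counts fall back to ``pseudocount`` and are flagged.
    """
    per_tp = {}
    medians = {}
    for tp, cmap in maps.items():
        _, edges = geneset_trans_score(cmap, genes)
        per_tp[tp] = edges.set_index(["gene_a", "gene_b"])["count"]
        medians[tp] = median_trans_count(cmap)
    out = per_tp[late].rename("count_late").to_frame()
    out["count_early"] = per_tp[early]
    out["display"] = out["count_late"] > medians[late]
    e = out["count_early"].where(out["count_early"] > 0, pseudocount)
    out["early_zero"] = out["count_early"] <= 0
    out["log2fc"] = np.log2(
        (out["count_late"] / medians[late]).where(out["count_late"] > 0, pseudocount)
        / (e / medians[early])
    )
    return out.reset_index()
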