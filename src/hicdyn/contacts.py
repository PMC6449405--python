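"""Binned Hi-C contact matrices: I/O, ICE balancing, expected-by-distance, O/E, virtual 4C.

A :class:`ContactMap` couples a genome-wide :class:`BinTable` with a dense
symmetric matrix of contact values plus a per-bin validity mask.  Matrices are
exchanged on disk as upper-triangle triplet text (``bin_i  bin_j  value``) with
a companion BED file describing the bins — the plain-text dialect written by
HiC-Pro style pipelines.  All intervals are 0-based half-open.

Balancing follows the iterative-correction (ICE) scheme: multiplicative per-bin
weights are found so that every unmasked row of the corrected matrix has the
same marginal.  Observed/expected normalization divides each cis entry by the
mean balanced value at its bin distance on the same chromosome, and each trans
entry by the global trans mean.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "ContactMap",
    "ExpectedProfile",
    "FormatError",
    "ice_balance",
    "expected_by_distance",
    "oe_normalize",
    "virtual_4c",
]


class FormatError(ValueError):
    """Raised for malformed matrix / bin-table input, naming the offending line."""


@dataclass(frozen=True)
class BinTable:
    """Uniform genomic bins with dense 0..N-1 ids.

    Parameters
    ----------
    chroms
        Per-bin chromosome names (length N).
    starts, ends
        Per-bin coordinates in bp, 0-based half-open.
    resolution
        Nominal bin width in bp (the last bin of a chromosome may be shorter).
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    resolution: int

    def __post_init__(self):
        object.__setattr__(self, "chroms", np.asarray(self.chroms, dtype=object))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends length mismatch")

    @classmethod
    def from_chrom_sizes(cls, chrom_sizes: dict[str, int], resolution: int) -> "BinTable":
        chroms, starts, ends = [], [], []
        for chrom, size in chrom_sizes.items():
            edges = np.arange(0, size, resolution, dtype=np.int64)
            chroms.extend([chrom] * len(edges))
            starts.extend(edges)
            ends.extend(np.minimum(edges + resolution, size))
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends), resolution)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "bin_id": np.arange(self.n_bins),
            }
        )

    def chrom_index(self) -> np.ndarray:
        """Integer chromosome code per bin, in order of first appearance."""
        return pd.factorize(self.chroms)[0]

    def chrom_bins(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)

    def chrom_names(self) -> list[str]:
        return list(pd.unique(self.chroms))

    def locate(self, chrom: str, pos: int) -> int:
        """Bin id covering ``chrom:pos``; raises ``KeyError`` off-assembly."""
        idx = self.chrom_bins(chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in bin table")
        hit = idx[(self.starts[idx] <= pos) & (pos < self.ends[idx])]
        if hit.size == 0:
            raise KeyError(f"position {chrom}:{pos} outside assembly")
        return int(hit[0])

    def write_bed(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path, resolution: int | None = None) -> "BinTable":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "bin_id"],
            dtype={"chrom": str},
        )
        if not (df["bin_id"].values == np.arange(len(df))).all():
            raise FormatError(f"{path}: bin ids are not dense 0..N-1")
        if resolution is None:
            resolution = int((df["end"] - df["start"]).max())
        return cls(df["chrom"].values.astype(object), df["start"].values, df["end"].values, resolution)


@dataclass
class ContactMap:
    """Symmetric binned contact matrix with mask and optional balancing weights.

    ``matrix`` holds the full dense symmetric matrix (raw counts or balanced
    values).  ``mask`` marks bins excluded from every statistic.  When
    ``balanced`` is true, ``weights`` satisfies
    ``balanced(i, j) = w_i * w_j * raw(i, j)``.
    """

    bins: BinTable
    matrix: np.ndarray
    mask: np.ndarray = field(default=None)  # True = masked out
    weights: np.ndarray | None = None
    balanced: bool = False
    converged: bool | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.bins.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    # -- indexing helpers ---------------------------------------------------
    def cis_pairs_mask(self) -> np.ndarray:
        code = pd.factorize(self.bins.chroms)[0]
        return code[:, None] == code[None, :]

    def valid_pairs_mask(self) -> np.ndarray:
        ok = ~self.mask
        return ok[:, None] & ok[None, :]

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_triplets(cls, bins: BinTable, i, j, values) -> "ContactMap":
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        n = bins.n_bins
        m = np.zeros((n, n))
        m[i, j] = values
        m[j, i] = values
        return cls(bins, m)

    def to_triplets(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.bins.n_bins)
        v = self.matrix[iu, ju]
        keep = v != 0
        return pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "value": v[keep]})

    def write(self, matrix_path, bins_path=None) -> None:
        trip = self.to_triplets()
        with open(matrix_path, "w") as fh:
            for i, j, v in trip.itertuples(index=False):
                # integers as integers, floats at shortest round-trip precision
                text = str(int(v)) if v == int(v) else repr(float(v))
                fh.write(f"{int(i)}\t{int(j)}\t{text}\n")
        if bins_path is not None:
            self.bins.write_bed(bins_path)

    @classmethod
    def read(cls, matrix_path, bins_path=None, bins: BinTable | None = None) -> "ContactMap":
        if bins is None:
            if bins_path is None:
                raise ValueError("need bins_path or bins")
            bins = BinTable.read_bed(bins_path)
        n = bins.n_bins
        m = np.zeros((n, n))
        seen = set()
        with open(matrix_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{matrix_path}:{lineno}: expected 3 fields, got {len(parts)}")
                try:
                    i, j = int(parts[0]), int(parts[1])
                    v = float(parts[2])
                except ValueError as e:
                    raise FormatError(f"{matrix_path}:{lineno}: {e}") from None
                if not (0 <= i < n and 0 <= j < n):
                    raise FormatError(f"{matrix_path}:{lineno}: bin index out of range ({i}, {j})")
                if v < 0:
                    raise FormatError(f"{matrix_path}:{lineno}: negative value {v}")
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise FormatError(f"{matrix_path}:{lineno}: duplicate entry ({i}, {j})")
                seen.add(key)
                m[i, j] = v
                m[j, i] = v
        return cls(bins, m)


@dataclass
class ExpectedProfile:
    """Mean balanced contact by bin distance per chromosome, plus the trans mean.

    ``cis[chrom][d]`` is the mean over unmasked pairs at bin distance ``d``
    (``d = 0``, the diagonal, is excluded and stored as NaN).
    """

    cis: dict[str, np.ndarray]
    trans_mean: float


def _marginal_mask(matrix: np.ndarray, mask_quantile: float) -> np.ndarray:
    """Mask bins with zero marginal plus the lowest ``mask_quantile`` fraction."""
    marg = matrix.sum(axis=0)
    masked = marg == 0
    if mask_quantile > 0 and (~masked).any():
        cutoff = np.quantile(marg[~masked], mask_quantile)
        masked |= marg < cutoff
    return masked


def ice_balance(
    cmap: ContactMap,
    tol: float = 1e-5,
    max_iter: int = 200,
    mask_quantile: float = 0.02,
) -> ContactMap:
    """Iterative correction: equalize unmasked row marginals with multiplicative weights.

    Bins with a zero marginal, plus the lowest ``mask_quantile`` fraction of
    marginals, are masked before iterating.  Returns a new balanced map whose
    ``weights`` satisfy ``balanced = w_i * w_j * raw`` with unmasked row sums
    equal within ``tol`` (relative).  Non-convergence sets ``converged=False``
    (with a warning) rather than raising.
    """
    import warnings

    raw = cmap.matrix.copy()
    masked = cmap.mask | _marginal_mask(raw, mask_quantile)
    work = raw.copy()
    work[masked, :] = 0.0
    work[:, masked] = 0.0
    n = cmap.bins.n_bins
    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        marg = work.sum(axis=0)
        live = ~masked
        scale = np.ones(n)
        mean_marg = marg[live].mean()
        if mean_marg == 0:
            break
        scale[live] = marg[live] / mean_marg
        scale[scale == 0] = 1.0
        work /= scale[:, None]
        work /= scale[None, :]
        bias *= scale
        if np.abs(scale[live] - 1.0).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"ICE did not converge in {max_iter} iterations", stacklevel=2)
    weights = np.where(masked, np.nan, 1.0 / bias)
    # rebuild from weights so balanced = w_i w_j raw holds exactly
    w = np.where(masked, 0.0, 1.0 / bias)
    bal = raw * w[:, None] * w[None, :]
    return ContactMap(
        cmap.bins, bal, mask=masked, weights=weights, balanced=True, converged=converged
    )


def expected_by_distance(cmap: ContactMap) -> ExpectedProfile:
    """Per-chromosome mean contact at each bin distance (diagonal excluded) and the trans mean."""
    if not cmap.balanced:
        raise ValueError("expected_by_distance requires a balanced map")
    bins = cmap.bins
    ok = ~cmap.mask
    cis_exp: dict[str, np.ndarray] = {}
    for chrom in bins.chrom_names():
        idx = bins.chrom_bins(chrom)
        sub = cmap.matrix[np.ix_(idx, idx)]
        live = ok[idx]
        nb = len(idx)
        pos = np.arange(nb)
        dmat = np.abs(pos[:, None] - pos[None, :])
        valid = live[:, None] & live[None, :]
        np.fill_diagonal(valid, False)
        dv = dmat[valid]
        sums = np.bincount(dv, weights=sub[valid], minlength=nb)
        counts = np.bincount(dv, minlength=nb)
        with np.errstate(invalid="ignore"):
            exp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        exp[0] = np.nan
        cis_exp[chrom] = exp
    cis_mask = cmap.cis_pairs_mask()
    tsel = (~cis_mask) & cmap.valid_pairs_mask()
    trans_mean = float(cmap.matrix[tsel].mean()) if tsel.any() else float("nan")
    return ExpectedProfile(cis_exp, trans_mean)


def oe_normalize(cmap: ContactMap, profile: ExpectedProfile | None = None) -> ContactMap:
    """Observed/expected map: cis entries by distance-expected, trans by the trans mean.

    The diagonal is set to zero (it is excluded from the expected profile and
    from every downstream statistic).  Pairs whose expected value is zero or
    undefined are set to NaN-free zero and excluded via the mask semantics.
    """
    if profile is None:
        profile = expected_by_distance(cmap)
    bins = cmap.bins
    oe = np.zeros_like(cmap.matrix)
    for chrom in bins.chrom_names():
        idx = bins.chrom_bins(chrom)
        sub = cmap.matrix[np.ix_(idx, idx)]
        nb = len(idx)
        pos = np.arange(nb)
        dmat = np.abs(pos[:, None] - pos[None, :])
        exp = profile.cis[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            evals = np.where(dmat > 0, exp[dmat], np.nan)
            res = sub / evals
        res[~np.isfinite(res)] = 0.0
        oe[np.ix_(idx, idx)] = res
    cis_mask = cmap.cis_pairs_mask()
    if np.isfinite(profile.trans_mean) and profile.trans_mean > 0:
        oe[~cis_mask] = cmap.matrix[~cis_mask] / profile.trans_mean
    out = ContactMap(cmap.bins, oe, mask=cmap.mask.copy(), balanced=True)
    out.converged = cmap.converged
    return out


def virtual_4c(cmap: ContactMap, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Mean balanced contact between anchor bin(s) and every other bin.

    Returns a bedGraph-style frame (chrom, start, end, value) with an extra
    ``is_anchor`` column flagging the anchor bins themselves.
    """
    if not cmap.balanced:
        raise ValueError("virtual_4c requires a balanced map")
    bins = cmap.bins
    idx = bins.chrom_bins(chrom)
    if idx.size == 0:
        raise KeyError(f"chromosome {chrom!r} not in assembly")
    anchor = idx[(bins.ends[idx] > start) & (bins.starts[idx] < end)]
    if anchor.size == 0:
        raise KeyError(f"anchor {chrom}:{start}-{end} maps to no bin")
    track = cmap.matrix[anchor, :].mean(axis=0)
    df = bins.to_frame()
    df["value"] = track
    df["is_anchor"] = np.isin(np.arange(bins.n_bins), anchor)
    df.loc[cmap.mask, "value"] = np.nan
    return df[["chrom", "start", "end", "value", "is_anchor"]]


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "value") -> None:
    """Write a (chrom, start, end, value) frame as bedGraph, dropping NaN rows."""
    out = df[["chrom", "start", "end", value_col]].dropna(subset=[value_col])
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
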