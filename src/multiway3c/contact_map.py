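"""Binned contact matrices, distance-scaling curves and chromosome-pair
mean matrices.

The raw contact map is the symmetric matrix of read-pair counts between
fixed-width loci; each pairwise contact increments exactly one unordered
bin pair (loci assigned by their 5'-mapped coordinate).  The scaling curve
is the classic polymer-physics diagnostic: contact probability versus
genomic distance, which decays roughly as a power law for crosslinked
chromatin and is flat for non-crosslinked controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import MultiContact
from .genome import BinTable

__all__ = [
    "RawContactMatrix",
    "bin_contacts",
    "scaling_curve",
    "fit_powerlaw_slope",
    "chrom_pair_means",
]


@dataclass
class RawContactMatrix:
    """Symmetric binned contact counts over a :class:`BinTable`."""

    bins: BinTable
    counts: sp.csr_matrix  # (m, m), symmetric, counts >= 0

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)

    def mass(self) -> float:
        """Total contact count (upper triangle plus diagonal)."""
        return float(sp.triu(self.counts).sum())

    # ---------------------------------------------------------------- I/O
    def to_triplets(self, path: str) -> None:
        coo = sp.triu(self.counts).tocoo()
        pd.DataFrame(
            {"bin1": coo.row, "bin2": coo.col, "count": coo.data}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_triplets(cls, path: str, bins: BinTable) -> "RawContactMatrix":
        df = pd.read_csv(path, sep="\t")
        m = bins.n_bins
        mat = sp.coo_matrix(
            (df["count"], (df["bin1"], df["bin2"])), shape=(m, m)
        ).tocsr()
        upper = sp.triu(mat)
        full = upper + sp.triu(upper, k=1).T
        return cls(bins, full.tocsr())


def bin_contacts(doubles: Iterable[MultiContact], bins: BinTable) -> RawContactMatrix:
    """Accumulate arity-2 contacts into a symmetric binned matrix.

    Every double counts once; the total matrix mass equals the number of
    binnable doubles.
    """
    m = bins.n_bins
    rows, cols = [], []
    for c in doubles:
        if c.arity != 2:
            continue
        a, b = c.loci
        i = bins.bin_index(a.chrom, a.pos)
        j = bins.bin_index(b.chrom, b.pos)
        i, j = min(i, j), max(i, j)
        rows.append(i)
        cols.append(j)
    upper = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m)
    ).tocsr()
    full = upper + sp.triu(upper, k=1).T
    return RawContactMatrix(bins, full.tocsr())


def scaling_curve(
    doubles: Iterable[MultiContact],
    chrom_lengths: dict[str, int],
    min_dist: float = 1000.0,
    factor: float = math.sqrt(2.0),
) -> pd.DataFrame:
    """Contact probability versus genomic distance for intra doubles.

    Distances are histogrammed into multiplicative bins (ratio ``factor``,
    i.e. 2^0.5 spacing) starting at ``min_dist``; the count in each bin is
    normalized by the number of genomic position pairs at that distance
    (``sum over chromosomes of max(0, L - d)`` integrated over the bin), so
    a uniform random contact process gives a flat curve.
    """
    dists = []
    for c in doubles:
        if c.arity != 2 or c.span != "intra":
            continue
        a, b = c.loci
        d = abs(a.pos - b.pos)
        if d >= min_dist:
            dists.append(float(d))
    max_len = max(chrom_lengths.values())
    edges = [min_dist]
    while edges[-1] < max_len:
        edges.append(edges[-1] * factor)
    edges_arr = np.array(edges)
    counts, _ = np.histogram(dists, bins=edges_arr)
    lo, hi = edges_arr[:-1], edges_arr[1:]
    mid = np.sqrt(lo * hi)
    possible = np.zeros_like(mid)
    for L in chrom_lengths.values():
        # integral of (L - s) ds over [lo, min(hi, L))
        hi_c = np.minimum(hi, L)
        w = np.maximum(hi_c - lo, 0.0)
        possible += np.maximum(L - (lo + hi_c) / 2.0, 0.0) * w
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(possible > 0, counts / possible, np.nan)
    total = np.nansum(prob)
    return pd.DataFrame(
        {
            "d_lo": lo, "d_hi": hi, "mid": mid,
            "count": counts, "possible": possible,
            "prob": prob / total if total > 0 else prob,
        }
    )


def fit_powerlaw_slope(
    curve: pd.DataFrame, d_range: tuple[float, float] | None = None
) -> float:
    """Log-log slope of the scaling curve (optionally over a distance range)."""
    sel = (curve["count"] > 0) & np.isfinite(curve["prob"]) & (curve["prob"] > 0)
    if d_range is not None:
        sel &= (curve["mid"] >= d_range[0]) & (curve["mid"] <= d_range[1])
    x = np.log(curve.loc[sel, "mid"])
    y = np.log(curve.loc[sel, "prob"])
    if len(x) < 2:
        raise ValueError("not enough populated distance bins to fit a slope")
    return float(np.polyfit(x, y, 1)[0])


def chrom_pair_means(
    matrix: RawContactMatrix, min_mappable: float = 0.5
) -> pd.DataFrame:
    """Mean contact count per chromosome pair over mappable window pairs.

    A window participates when its ``mappable_fraction`` annotation is at
    least ``min_mappable``.  The diagonal (same-chromosome) entries average
    the whole intrachromosomal block.  Copy-number-2 chromosomes show up as
    rows/columns with roughly doubled means.
    """
    bins = matrix.bins
    dense = matrix.dense()
    ok = bins.df["mappable_fraction"].to_numpy() >= min_mappable
    chroms = bins.chroms
    out = pd.DataFrame(index=chroms, columns=chroms, dtype=float)
    for ca in chroms:
        alo, ahi = bins.chrom_range(ca)
        amask = ok[alo:ahi]
        for cb in chroms:
            blo, bhi = bins.chrom_range(cb)
            bmask = ok[blo:bhi]
            block = dense[alo:ahi, blo:bhi][amask][:, bmask]
            out.loc[ca, cb] = block.mean() if block.size else np.nan
    return out
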