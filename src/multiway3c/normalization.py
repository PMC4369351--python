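"""Copy-number-aware iterative correction for a nearly haploid genome.

Standard iterative correction (ICE) assumes every locus is present in the
same number of copies; in a near-haploid karyotype with a diploid
chromosome (and a partially diploid one) this assumption fails: diploid
loci legitimately accumulate twice the coverage.  The procedure here:

1.  *Deduplicate*: expand the m x m locus matrix to an n x n bead matrix in
    which each diploid locus contributes two homolog beads.  Counts
    involving diploid loci are split into two equal parts across the
    same-configuration bead pairs; counts between different homolog copies
    are set to zero (homologs are modeled as interacting identically and
    not with each other).
2.  *Sparsity filter*: rank loci by their fraction of zero intrachromosomal
    entries and drop the worst 10% (low-mappability regions).
3.  *ICE* on the bead matrix: multiplicative per-bead bias ``beta`` under
    the equal-visibility hypothesis; normalized = raw / (beta (x) beta).
4.  *Re-sum homologs* back to an m x m matrix, in which diploid loci end up
    with exactly twice the coverage of haploid loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contact_map import RawContactMatrix
from .genome import BeadMap, BinTable

__all__ = [
    "IceResult",
    "NormalizedMatrix",
    "deduplicate",
    "sparsity_filter",
    "ice",
    "resum_homologs",
    "normalize_near_haploid",
]

log = logging.getLogger(__name__)


def deduplicate(counts: np.ndarray, beadmap: BeadMap) -> np.ndarray:
    """Expand locus-level counts to an n x n bead-level matrix.

    Haploid-haploid entries pass through unchanged; entries with a diploid
    locus are divided into two equal parts over the allowed (same-copy)
    bead-pair configurations; inter-homolog entries are zero.  Total mass is
    conserved.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (beadmap.m, beadmap.m):
        raise ValueError("counts shape inconsistent with bead map")
    cn = beadmap.copy_number()
    phi = beadmap.phi
    # number of allowed configurations for each locus pair = max(cn_k, cn_l)
    nconf = np.maximum.outer(cn, cn).astype(float)
    B = counts[np.ix_(phi, phi)] / nconf[np.ix_(phi, phi)]
    both_dip = (cn[phi][:, None] == 2) & (cn[phi][None, :] == 2)
    same_copy = beadmap.copy_label[:, None] == beadmap.copy_label[None, :]
    B[both_dip & ~same_copy] = 0.0
    return B


def sparsity_filter(
    counts: np.ndarray, bins: BinTable, fraction: float = 0.10
) -> np.ndarray:
    """Boolean mask of retained loci after the zero-fraction prefilter.

    Loci are ranked by their percentage of intrachromosomal entries with
    zero counts; the top ``floor(fraction * m_eligible)`` are removed (ties
    broken by locus index, lower index removed first).  Chromosomes with
    fewer than 2 bins are exempt.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    counts = np.asarray(counts, dtype=float)
    m = bins.n_bins
    zero_frac = np.zeros(m)
    eligible = np.zeros(m, dtype=bool)
    for chrom in bins.chroms:
        lo, hi = bins.chrom_range(chrom)
        if hi - lo < 2:
            continue
        block = counts[lo:hi, lo:hi]
        zero_frac[lo:hi] = (block == 0).mean(axis=1)
        eligible[lo:hi] = True
    n_remove = int(np.floor(fraction * eligible.sum()))
    mask = np.ones(m, dtype=bool)
    if n_remove > 0:
        idx = np.flatnonzero(eligible)
        order = idx[np.lexsort((idx, -zero_frac[idx]))]
        mask[order[:n_remove]] = False
    return mask


@dataclass
class IceResult:
    bias: np.ndarray          # per-bead beta; NaN for filtered beads
    normalized: np.ndarray    # raw / (beta (x) beta); zero rows for filtered
    iterations: int
    converged: bool


def ice(
    counts: np.ndarray,
    mask: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> IceResult:
    """Iterative correction to equal per-locus visibility.

    Repeatedly divides the matrix by the outer product of its (normalized)
    coverage vector until the maximum relative coverage deviation among
    retained loci falls below ``tol``.  The returned bias has unit geometric
    mean over retained loci.  Non-convergence returns with a warning flag
    rather than raising.
    """
    W = np.asarray(counts, dtype=float).copy()
    n = W.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    W[~mask, :] = 0.0
    W[:, ~mask] = 0.0
    bias = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cov = W.sum(axis=1)[mask]
        if cov.max() == 0:
            break
        s = cov / cov.mean()
        dev = np.abs(s - 1.0).max()
        if dev < tol:
            converged = True
            break
        s = np.where(s == 0, 1.0, s)
        f = np.ones(n)
        f[mask] = s
        W /= np.outer(f, f)
        bias *= f
    # unit geometric mean over retained loci with positive bias
    pos = mask & (bias > 0)
    g = np.exp(np.log(bias[pos]).mean()) if pos.any() else 1.0
    bias = bias / g
    normalized = np.zeros_like(W)
    denom = np.outer(bias[mask], bias[mask])
    raw = np.asarray(counts, dtype=float)
    normalized[np.ix_(mask, mask)] = raw[np.ix_(mask, mask)] / denom
    bias_out = np.where(mask, bias, np.nan)
    if not converged:
        log.warning("ICE did not converge in %d iterations", max_iter)
    return IceResult(bias=bias_out, normalized=normalized, iterations=it,
                     converged=converged)


def resum_homologs(bead_counts: np.ndarray, beadmap: BeadMap) -> np.ndarray:
    """Sum bead-level entries back to the m x m locus matrix."""
    P = beadmap.incidence()
    return P.T @ np.asarray(bead_counts, dtype=float) @ P


@dataclass
class NormalizedMatrix:
    """ICE-normalized locus-level matrix with the retained-locus mask."""

    bins: BinTable
    counts: np.ndarray       # (m, m) normalized, filtered rows zeroed
    mask: np.ndarray         # (m,) retained loci
    bead_bias: np.ndarray    # (n,) per-bead beta (NaN where filtered)
    converged: bool

    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def normalize_near_haploid(
    matrix: RawContactMatrix,
    beadmap: BeadMap,
    fraction: float = 0.10,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> NormalizedMatrix:
    """Full dedup -> filter -> ICE -> resum procedure.

    After convergence the mean coverage of diploid loci is twice that of
    haploid loci (each homolog bead reaches equal visibility, and a diploid
    locus sums two beads).
    """
    C = matrix.dense()
    locus_mask = sparsity_filter(C, matrix.bins, fraction=fraction)
    B = deduplicate(C, beadmap)
    bead_mask = locus_mask[beadmap.phi]
    res = ice(B, mask=bead_mask, tol=tol, max_iter=max_iter)
    M = resum_homologs(res.normalized, beadmap)
    return NormalizedMatrix(
        bins=matrix.bins, counts=M, mask=locus_mask,
        bead_bias=res.bias, converged=res.converged,
    )
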