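"""Open/closed compartment calling by eigendecomposition.

Per chromosome, the Pearson correlation matrix of the intrachromosomal
normalized contact map is eigendecomposed; the sign pattern of the leading
eigenvector partitions bins into two megabase-scale compartments.  When the
leading eigenvector is single-signed (it then tracks overall coverage, not
the plaid pattern) the second eigenvector is used instead.  Signs are
oriented by GC content: the sign group with higher mean GC is labelled
"open" chromatin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CompartmentTrack",
    "correlation_compartments",
    "orient_by_gc",
    "agreement",
]

log = logging.getLogger(__name__)

OPEN, CLOSED = "open", "closed"


@dataclass(frozen=True)
class CompartmentTrack:
    """Per-bin compartment labels for one chromosome.

    ``labels`` holds 'open' / 'closed' / None (NA); ``eigvec`` carries the
    chosen eigenvector values (NaN on NA bins); ``eig_index`` is 0 if the
    first eigenvector was used, 1 if the second.
    """

    chrom: str
    labels: np.ndarray
    eigvec: np.ndarray
    eig_index: int
    oriented: bool = False

    def n_labeled(self) -> int:
        return int(sum(l is not None for l in self.labels))


def _single_signed(v: np.ndarray) -> bool:
    nz = v[np.abs(v) > 0]
    if nz.size == 0:
        return True
    return bool((nz > 0).all() or (nz < 0).all())


def correlation_compartments(
    counts: np.ndarray,
    chrom: str = "",
    mask: np.ndarray | None = None,
) -> CompartmentTrack:
    """Compartment track from an intrachromosomal matrix.

    ``mask`` marks retained bins (filtered bins become NA).  Bins whose row
    has zero variance are also dropped.  The eigenvector is scaled so its
    largest-magnitude entry is positive, removing solver-dependent sign
    flips; labels are provisional ('+' group = open) until
    :func:`orient_by_gc`.  Fewer than 4 usable bins yields an all-NA track.
    """
    counts = np.asarray(counts, dtype=float)
    m = counts.shape[0]
    if mask is None:
        mask = np.ones(m, dtype=bool)
    valid = mask.copy()
    valid &= np.isfinite(counts).all(axis=1)
    sub = counts[np.ix_(valid, valid)]
    if valid.sum() >= 2:
        keep = sub.std(axis=1) > 0
        idx = np.flatnonzero(valid)
        valid[:] = False
        valid[idx[keep]] = True
        sub = counts[np.ix_(valid, valid)]

    labels = np.full(m, None, dtype=object)
    eigvec = np.full(m, np.nan)
    if valid.sum() < 4:
        return CompartmentTrack(chrom, labels, eigvec, eig_index=0)

    corr = np.corrcoef(sub)
    corr = (corr + corr.T) / 2.0
    w, V = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    v = V[:, order[0]]
    eig_index = 0
    if _single_signed(v):
        v = V[:, order[1]]
        eig_index = 1
    # deterministic sign: largest-magnitude entry positive
    v = v * np.sign(v[np.argmax(np.abs(v))] or 1.0)
    eigvec[valid] = v
    labels[valid] = np.where(v >= 0, OPEN, CLOSED)
    return CompartmentTrack(chrom, labels, eigvec, eig_index)


def orient_by_gc(track: CompartmentTrack, gc: np.ndarray) -> CompartmentTrack:
    """Assign the sign group with higher mean GC content as open chromatin.

    Flipping all eigenvector signs leaves the oriented labels unchanged.  A
    GC tie keeps the positive group open (deterministic fallback, warned).
    """
    gc = np.asarray(gc, dtype=float)
    lab = track.labels
    pos = np.array([l == OPEN for l in lab])
    neg = np.array([l == CLOSED for l in lab])
    if not pos.any() or not neg.any():
        return replace(track, oriented=True)
    gc_pos, gc_neg = np.nanmean(gc[pos]), np.nanmean(gc[neg])
    if gc_pos == gc_neg:
        log.warning("GC tie on %s; keeping '+' group as open", track.chrom)
        flip = False
    else:
        flip = gc_neg > gc_pos
    if flip:
        new = np.full(len(lab), None, dtype=object)
        new[pos] = CLOSED
        new[neg] = OPEN
        return replace(track, labels=new, oriented=True)
    return replace(track, oriented=True)


def agreement(track_a: CompartmentTrack, track_b: CompartmentTrack) -> float:
    """Percentage of commonly labeled bins with equal compartment labels."""
    la, lb = track_a.labels, track_b.labels
    if len(la) != len(lb):
        raise ValueError("tracks cover different numbers of bins")
    both = [(a, b) for a, b in zip(la, lb) if a is not None and b is not None]
    if not both:
        return float("nan")
    same = sum(a == b for a, b in both)
    return 100.0 * same / len(both)
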