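"""Contact calling: end classification, multi-way enumeration, filters.

A paired-end read contributes up to four mapped loci: each end is either
fully mapped (F, one locus), partially mapped after splitting at a cleavage
site (P2: two loci, P1: one locus) or unmapped.  With ``L`` the union of
mapped loci across both ends, the read yields all C(|L|, 2) pairwise
contacts ("doubles"), C(|L|, 3) triples and C(|L|, 4) quadruples.  A
P2 + P2 read therefore yields 6 doubles, 4 triples and 1 quadruple.

Contacts carry the read-pair class (F-F, P-F or P-P), a span class (intra /
inter / mixed) and per-locus provenance (end, fragment, strand) so that
intrachromosomal orientation signatures can be tabulated: for unligated
sonication products the end orientations are constrained (inward facing),
whereas genuine religation junctions give a uniform distribution over the
sign combinations, which is why a 1 kb genomic-distance threshold that
removes sonication-scale products leaves a uniform signature table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentRecord

__all__ = [
    "Locus",
    "EndStatus",
    "MultiContact",
    "classify_end",
    "enumerate_contacts",
    "orientation_signature",
    "apply_distance_filter",
    "write_doubles",
    "read_doubles",
    "write_multiway",
    "read_multiway",
]

_FRAG_ORDER = {"whole": 0, "left": 0, "right": 1}


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int
    strand: str
    end: int          # which read end produced it (1 or 2)
    fragment: str     # "whole", "left" or "right"


@dataclass(frozen=True)
class EndStatus:
    """Mapping outcome of a single read end.

    status: 'F' (whole read mapped), 'P2' / 'P1' (two / one split fragments
    mapped), or 'none'.
    """

    status: str
    loci: tuple[Locus, ...]

    def __post_init__(self) -> None:
        expected = {"F": 1, "P1": 1, "P2": 2, "none": 0}[self.status]
        if len(self.loci) != expected:
            raise ValueError(f"{self.status} end must carry {expected} loci")


def classify_end(
    end: int,
    phase1_records: Sequence[AlignmentRecord],
    phase2_records: Sequence[AlignmentRecord],
    n_sites: int,
) -> EndStatus:
    """Classify one read end from its *filter-passing* records.

    ``phase1_records`` / ``phase2_records`` must already have been filtered
    with the phase-specific policies.  A whole-read record wins (F); reads
    with exactly one cleavage site are classified by how many split
    fragments mapped; anything else is uninformative.
    """
    whole = [r for r in phase1_records if r.fragment == "whole" and r.end == end]
    if len(whole) > 1:
        raise ValueError(f"conflicting whole-read records for end {end}")
    if whole:
        r = whole[0]
        return EndStatus("F", (Locus(r.chrom, r.pos, r.strand, end, "whole"),))
    if n_sites != 1:
        return EndStatus("none", ())
    frags: dict[str, AlignmentRecord] = {}
    for r in phase2_records:
        if r.end != end or r.fragment not in ("left", "right"):
            continue
        if r.fragment in frags:
            raise ValueError(f"conflicting records for end {end} fragment {r.fragment}")
        frags[r.fragment] = r
    loci = tuple(
        Locus(r.chrom, r.pos, r.strand, end, r.fragment)
        for r in sorted(frags.values(), key=lambda r: _FRAG_ORDER[r.fragment])
    )
    status = {2: "P2", 1: "P1", 0: "none"}[len(loci)]
    return EndStatus(status, loci)


@dataclass(frozen=True)
class MultiContact:
    """A contact linking 2, 3 or 4 loci, derived from one read pair.

    ``loci`` are stored sorted by (chrom, pos) for deterministic
    deduplication; each locus retains its end/fragment provenance.
    """

    arity: int
    loci: tuple[Locus, ...]
    cls: str          # 'F-F', 'P-F' or 'P-P'
    span: str         # 'intra', 'inter' or 'mixed'
    read_id: str

    def __post_init__(self) -> None:
        if self.arity != len(self.loci):
            raise ValueError("arity must equal the number of loci")


def _span_class(loci: Sequence[Locus]) -> str:
    chroms = [l.chrom for l in loci]
    distinct = len(set(chroms))
    if distinct == 1:
        return "intra"
    if distinct == len(chroms):
        return "inter"
    return "mixed"


def _pair_class(end1: EndStatus, end2: EndStatus) -> str:
    kinds = {("F" if s.status == "F" else "P") for s in (end1, end2)
             if s.status != "none"}
    if kinds == {"F"}:
        return "F-F"
    if kinds == {"P"}:
        return "P-P"
    return "P-F"


def enumerate_contacts(
    read_id: str, end1: EndStatus, end2: EndStatus
) -> list[MultiContact]:
    """All doubles, triples and quadruples supported by one read pair."""
    loci = end1.loci + end2.loci
    if len(loci) < 2:
        return []
    cls = _pair_class(end1, end2)
    out = []
    for k in (2, 3, 4):
        for combo in combinations(loci, k):
            ordered = tuple(sorted(combo, key=lambda l: (l.chrom, l.pos, l.end)))
            out.append(
                MultiContact(k, ordered, cls, _span_class(ordered), read_id)
            )
    return out


def orientation_signature(contact: MultiContact) -> str:
    """Strand-sign signature "<end1 signs>/<end2 signs>" (e.g. "++/-").

    Defined for intrachromosomal doubles and triples; fragment signs within
    an end appear in read order (left before right).
    """
    if contact.span != "intra" or contact.arity not in (2, 3):
        raise ValueError("signature defined for intrachromosomal doubles/triples")
    parts = []
    for end in (1, 2):
        frags = sorted(
            (l for l in contact.loci if l.end == end),
            key=lambda l: _FRAG_ORDER[l.fragment],
        )
        parts.append("".join(l.strand for l in frags))
    return "/".join(parts)


def _min_intra_distance(contact: MultiContact) -> int | None:
    dists = [
        abs(a.pos - b.pos)
        for a, b in combinations(contact.loci, 2)
        if a.chrom == b.chrom
    ]
    return min(dists) if dists else None


def apply_distance_filter(
    contacts: Iterable[MultiContact], min_dist: int
) -> list[MultiContact]:
    """Drop contacts with two same-chromosome loci closer than ``min_dist``.

    Purely interchromosomal contacts always pass.  The 1 kb threshold used
    after contact calling eliminates sonication products (size-selected at
    ~250 bp); 20 kb is the short-range threshold used in domain analyses.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    out = []
    for c in contacts:
        d = _min_intra_distance(c)
        if d is None or d >= min_dist:
            out.append(c)
    return out


# ----------------------------------------------------------------- TSV I/O
#
# Doubles: one row per pairwise contact
#   readID chr1 pos1 strand1 end1 frag1 chr2 pos2 strand2 end2 frag2 class span
# Multiway (arity 3-4): readID arity then chrom/pos/strand/end/frag per locus
# (padded with '.') followed by class and span.

_DOUBLE_COLS = [
    "read_id",
    "chrom1", "pos1", "strand1", "end1", "frag1",
    "chrom2", "pos2", "strand2", "end2", "frag2",
    "cls", "span",
]


def write_doubles(path: str, contacts: Iterable[MultiContact]) -> None:
    rows = []
    for c in contacts:
        if c.arity != 2:
            continue
        a, b = c.loci
        rows.append(
            (c.read_id, a.chrom, a.pos, a.strand, a.end, a.fragment,
             b.chrom, b.pos, b.strand, b.end, b.fragment, c.cls, c.span)
        )
    pd.DataFrame(rows, columns=_DOUBLE_COLS).to_csv(path, sep="\t", index=False)


def read_doubles(path: str) -> list[MultiContact]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    out = []
    for row in df.itertuples(index=False):
        loci = (
            Locus(row.chrom1, int(row.pos1), row.strand1, int(row.end1), row.frag1),
            Locus(row.chrom2, int(row.pos2), row.strand2, int(row.end2), row.frag2),
        )
        out.append(MultiContact(2, loci, row.cls, row.span, str(row.read_id)))
    return out


def write_multiway(path: str, contacts: Iterable[MultiContact]) -> None:
    cols = ["read_id", "arity"]
    for i in range(1, 5):
        cols += [f"chrom{i}", f"pos{i}", f"strand{i}", f"end{i}", f"frag{i}"]
    cols += ["cls", "span"]
    rows = []
    for c in contacts:
        if c.arity < 3:
            continue
        row: list = [c.read_id, c.arity]
        for i in range(4):
            if i < c.arity:
                l = c.loci[i]
                row += [l.chrom, l.pos, l.strand, l.end, l.fragment]
            else:
                row += [".", ".", ".", ".", "."]
        row += [c.cls, c.span]
        rows.append(tuple(row))
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_multiway(path: str) -> list[MultiContact]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        arity = int(row.arity)
        loci = tuple(
            Locus(
                getattr(row, f"chrom{i}"),
                int(getattr(row, f"pos{i}")),
                getattr(row, f"strand{i}"),
                int(getattr(row, f"end{i}")),
                getattr(row, f"frag{i}"),
            )
            for i in range(1, arity + 1)
        )
        out.append(MultiContact(arity, loci, row.cls, row.span, str(row.read_id)))
    return out
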