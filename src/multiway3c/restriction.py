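"""Restriction-site scanning and chimeric-read splitting.

Multi-way 3C libraries are digested with one or more 4-cutter enzymes; a
sequencing read that spans a ligation junction contains the reconstituted
recognition site of the enzyme that produced the junction.  Reads that fail
whole-read alignment but contain exactly one cleavage site are split at that
site into two fragments -- the entire recognition sequence is preserved on
both fragments, so each fragment remains alignable across the junction.

Reads with zero sites cannot be chimeric and are discarded from the second
mapping phase; reads with two or more sites are discarded as ambiguous (the
fate of exactly-two-site reads is ambiguous in the protocol description; we
discard them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Enzyme",
    "CutSiteHit",
    "ENZYMES",
    "ENZYME_SETS",
    "get_enzymes",
    "revcomp",
    "scan_sites",
    "count_read_sites",
    "split_read",
    "split_for_alignment",
    "MIN_FRAGMENT_LEN",
]

#: Fragments shorter than this are not emitted for alignment: they cannot be
#: placed uniquely in a mammalian-scale genome.
MIN_FRAGMENT_LEN = 16

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition sequence and cut offset within it."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.site or set(self.site) - set("ACGT"):
            raise ValueError(f"invalid recognition sequence {self.site!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut_offset outside recognition sequence")


#: The four 4-cutters used in multi-way 3C libraries.  '|' marks the cut:
#: AluI AG|CT, MboI/DpnII |GATC, MspI C|CGG, NlaIII CATG|.
ENZYMES: dict[str, Enzyme] = {
    "AluI": Enzyme("AluI", "AGCT", 2),
    "DpnII": Enzyme("DpnII", "GATC", 0),
    "MboI": Enzyme("MboI", "GATC", 0),
    "MspI": Enzyme("MspI", "CCGG", 1),
    "NlaIII": Enzyme("NlaIII", "CATG", 4),
}

#: Named enzyme sets matching the standard library designs: a single-enzyme
#: digest (DpnII only) and the four-enzyme cocktail.
ENZYME_SETS: dict[str, tuple[str, ...]] = {
    "TM3C-1": ("DpnII",),
    "TM3C-4": ("AluI", "DpnII", "MspI", "NlaIII"),
}


def get_enzymes(spec: str | Iterable[str | Enzyme]) -> tuple[Enzyme, ...]:
    """Resolve an enzyme-set name, enzyme names, or Enzyme objects."""
    if isinstance(spec, str):
        if spec in ENZYME_SETS:
            return tuple(ENZYMES[n] for n in ENZYME_SETS[spec])
        if spec in ENZYMES:
            return (ENZYMES[spec],)
        raise KeyError(f"unknown enzyme or enzyme set: {spec!r}")
    out = []
    for e in spec:
        out.append(e if isinstance(e, Enzyme) else ENZYMES[e])
    if not out:
        raise ValueError("empty enzyme set")
    return tuple(out)


@dataclass(frozen=True)
class CutSiteHit:
    """An occurrence of a recognition sequence within a scanned read."""

    start: int
    enzyme: str

    def site(self) -> str:
        return ENZYMES[self.enzyme].site if self.enzyme in ENZYMES else ""


def _find_all(seq: str, motif: str) -> list[int]:
    # overlapping occurrences
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def scan_sites(seq: str, enzymes: Sequence[Enzyme]) -> list[CutSiteHit]:
    """All recognition-site occurrences of every enzyme, sorted by start.

    The read strand and the reverse complement of each motif are both
    scanned (all standard 4-cutter motifs here are palindromic, so this is a
    no-op for them, but custom enzymes may be asymmetric); identical
    intervals are reported once.  Overlapping occurrences are counted.
    Ambiguous bases (N) never match.
    """
    if not enzymes:
        raise ValueError("empty enzyme set")
    seq = seq.upper()
    seen: set[tuple[int, int, str]] = set()
    hits: list[CutSiteHit] = []
    for enz in enzymes:
        for motif in {enz.site, revcomp(enz.site)}:
            for start in _find_all(seq, motif):
                key = (start, start + len(motif), enz.name)
                if key not in seen:
                    seen.add(key)
                    hits.append(CutSiteHit(start, enz.name))
    hits.sort(key=lambda h: (h.start, h.enzyme))
    return hits


def count_read_sites(read: str, enzymes: Sequence[Enzyme]) -> int:
    """Number of cleavage sites in a read across the whole enzyme set."""
    return len(scan_sites(read, enzymes))


def split_read(read: str, hit: CutSiteHit) -> tuple[str, str]:
    """Split a read at a cleavage site, keeping the full site on both parts.

    ``left = read[:start + len(site)]`` and ``right = read[start:]``; the
    duplicated recognition sequence means
    ``len(left) + len(right) == len(read) + len(site)`` and collapsing the
    duplicate reconstructs the read exactly.
    """
    site_len = len(ENZYMES[hit.enzyme].site)
    if hit.start < 0 or hit.start + site_len > len(read):
        raise ValueError("cut-site hit outside read")
    return read[: hit.start + site_len], read[hit.start :]


def split_for_alignment(
    read: str,
    enzymes: Sequence[Enzyme],
    min_len: int = MIN_FRAGMENT_LEN,
) -> dict[str, str]:
    """Second-phase splitting of a non-mapped read.

    Returns ``{"left": ..., "right": ...}`` restricted to fragments of at
    least ``min_len`` bp when the read contains exactly one cleavage site;
    an empty dict otherwise (0 sites: surely not chimeric; >= 2 sites:
    discarded as ambiguous).
    """
    hits = scan_sites(read, enzymes)
    if len(hits) != 1:
        return {}
    left, right = split_read(read, hits[0])
    out = {}
    if len(left) >= min_len:
        out["left"] = left
    if len(right) >= min_len:
        out["right"] = right
    return out
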