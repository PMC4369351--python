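"""Alignment records, phase-specific filters and a naive exact aligner.

Real libraries are mapped with an external short-read aligner (e.g. bwa);
this module consumes its SAM/BAM output.  Phase-specific filters follow the
two-phase mapping design: a record is retained iff it is (i) unique, (ii)
MAPQ >= 30 and (iii) within the phase's edit-distance budget (NM <= 3 for
whole reads, NM <= 1 for split fragments).

``naive_align`` is a test-only substitute for the external aligner: exact
string matching on both strands of an in-memory genome, with uniqueness
decided by occurrence count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import pysam

from .restriction import revcomp

__all__ = [
    "AlignmentRecord",
    "FilterPolicy",
    "PHASE1",
    "PHASE2",
    "pass_filter",
    "naive_align",
    "parse_sam",
    "encode_read_name",
    "decode_read_name",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of a whole read end or a split fragment.

    ``pos`` is the 5'-mapped coordinate of the read (0-based): the leftmost
    aligned base for '+' alignments, the rightmost for '-' alignments.
    """

    read_id: str
    end: int                  # 1 or 2
    fragment: str             # "whole", "left" or "right"
    chrom: str
    pos: int
    strand: str               # '+' or '-'
    mapq: int
    edit_distance: int | None
    unique: bool


@dataclass(frozen=True)
class FilterPolicy:
    min_mapq: int
    max_edit_distance: int
    require_unique: bool = True


PHASE1 = FilterPolicy(min_mapq=30, max_edit_distance=3)
PHASE2 = FilterPolicy(min_mapq=30, max_edit_distance=1)


def pass_filter(rec: AlignmentRecord, policy: FilterPolicy) -> bool:
    """True iff the record is unique, high quality and within the edit budget.

    A missing edit-distance annotation fails the filter (logged).
    """
    if rec.edit_distance is None:
        log.warning("record %s has no edit-distance annotation; failing", rec.read_id)
        return False
    if policy.require_unique and not rec.unique:
        return False
    return rec.mapq >= policy.min_mapq and rec.edit_distance <= policy.max_edit_distance


def naive_align(
    fragment: str,
    genome: Mapping[str, str],
    read_id: str = "",
    end: int = 1,
    fragment_label: str = "whole",
) -> list[AlignmentRecord]:
    """Exact-match alignment of ``fragment`` against both strands.

    Every exact occurrence is reported; ``unique`` is set iff there is
    exactly one occurrence genome-wide.  Exact hits get MAPQ 60 and edit
    distance 0.  An empty list means the fragment is non-mapped.
    """
    fragment = fragment.upper()
    rc = revcomp(fragment)
    occ: list[tuple[str, int, str]] = []
    for chrom, seq in genome.items():
        i = seq.find(fragment)
        while i != -1:
            occ.append((chrom, i, "+"))
            i = seq.find(fragment, i + 1)
        i = seq.find(rc)
        while i != -1:
            occ.append((chrom, i + len(fragment) - 1, "-"))
            i = seq.find(rc, i + 1)
    unique = len(occ) == 1
    return [
        AlignmentRecord(
            read_id=read_id, end=end, fragment=fragment_label,
            chrom=chrom, pos=pos, strand=strand,
            mapq=60, edit_distance=0, unique=unique,
        )
        for chrom, pos, strand in occ
    ]


# ---------------------------------------------------------------- SAM input

#: Read-name suffix convention carrying end / fragment provenance, so that
#: output from an external aligner can be re-joined: "<id>/1", "<id>/2" for
#: whole ends, "<id>/1:L", "<id>/1:R" (etc.) for split fragments.
_FRAG_CODE = {"L": "left", "R": "right"}
_CODE_FRAG = {"left": "L", "right": "R"}


def encode_read_name(read_id: str, end: int, fragment: str = "whole") -> str:
    name = f"{read_id}/{end}"
    if fragment != "whole":
        name += f":{_CODE_FRAG[fragment]}"
    return name


def decode_read_name(name: str) -> tuple[str, int, str]:
    """Inverse of :func:`encode_read_name`."""
    fragment = "whole"
    if name.endswith((":L", ":R")):
        fragment = _FRAG_CODE[name[-1]]
        name = name[:-2]
    if name.endswith(("/1", "/2")):
        end = int(name[-1])
        name = name[:-2]
    else:
        end = 1
    return name, end, fragment


def _is_unique(aln: pysam.AlignedSegment) -> bool:
    # bwa-style annotations when present; otherwise NH; otherwise assume the
    # aligner reported a single best placement.
    if aln.has_tag("XT"):
        return aln.get_tag("XT") == "U"
    if aln.has_tag("XA"):
        return False
    if aln.has_tag("NH"):
        return aln.get_tag("NH") == 1
    return not (aln.is_secondary or aln.is_supplementary)


def parse_sam(path: str) -> Iterator[AlignmentRecord]:
    """Yield :class:`AlignmentRecord` for every mapped primary alignment."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            read_id, end, fragment = decode_read_name(aln.query_name)
            if aln.is_reverse:
                strand, pos = "-", aln.reference_end - 1
            else:
                strand, pos = "+", aln.reference_start
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            yield AlignmentRecord(
                read_id=read_id, end=end, fragment=fragment,
                chrom=aln.reference_name, pos=pos, strand=strand,
                mapq=aln.mapping_quality, edit_distance=nm,
                unique=_is_unique(aln),
            )
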