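"""Two-phase mapping pipeline: whole-read alignment, cut-site splitting,
re-alignment of fragments, contact enumeration and distance filtering.

The pipeline can run fully in-memory against the naive exact aligner (for
simulated libraries) or consume SAM files produced by an external aligner
for both phases.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import (
    PHASE1,
    PHASE2,
    AlignmentRecord,
    FilterPolicy,
    naive_align,
    pass_filter,
)
from .contacts import EndStatus, MultiContact, classify_end, enumerate_contacts, \
    apply_distance_filter
from .restriction import Enzyme, count_read_sites, split_for_alignment

__all__ = [
    "ReadPair",
    "PipelineStats",
    "classify_pair_naive",
    "call_contacts_naive",
    "call_contacts_from_sam",
    "contacts_summary",
]


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str


@dataclass
class PipelineStats:
    """Stage-boundary attrition counts, in the style of a library summary
    table (doubles/triples/quadruples split by inter/intra/mixed)."""

    n_pairs: int = 0
    n_ff: int = 0
    n_rescued_ends: int = 0
    contacts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "read_pairs": self.n_pairs,
            "ff_pairs": self.n_ff,
            "rescued_ends": self.n_rescued_ends,
            "contacts": self.contacts,
        }


def _classify_one_end(
    read_id: str,
    end: int,
    seq: str,
    genome: Mapping[str, str],
    enzymes: Sequence[Enzyme],
    policy1: FilterPolicy,
    policy2: FilterPolicy,
) -> EndStatus:
    recs1 = [
        r
        for r in naive_align(seq, genome, read_id=read_id, end=end)
        if pass_filter(r, policy1)
    ]
    if recs1:
        return classify_end(end, recs1[:1], [], n_sites=0)
    n_sites = count_read_sites(seq, enzymes)
    recs2: list[AlignmentRecord] = []
    for label, frag in split_for_alignment(seq, enzymes).items():
        hits = [
            r
            for r in naive_align(frag, genome, read_id=read_id, end=end,
                                 fragment_label=label)
            if pass_filter(r, policy2)
        ]
        recs2.extend(hits[:1])
    return classify_end(end, [], recs2, n_sites=n_sites)


def classify_pair_naive(
    pair: ReadPair,
    genome: Mapping[str, str],
    enzymes: Sequence[Enzyme],
    policy1: FilterPolicy = PHASE1,
    policy2: FilterPolicy = PHASE2,
) -> tuple[EndStatus, EndStatus]:
    e1 = _classify_one_end(pair.read_id, 1, pair.seq1, genome, enzymes, policy1, policy2)
    e2 = _classify_one_end(pair.read_id, 2, pair.seq2, genome, enzymes, policy1, policy2)
    return e1, e2


def call_contacts_naive(
    pairs: Iterable[ReadPair],
    genome: Mapping[str, str],
    enzymes: Sequence[Enzyme],
    min_dist: int = 1000,
) -> tuple[list[MultiContact], PipelineStats]:
    """Run the full two-phase pipeline with the naive exact aligner."""
    stats = PipelineStats()
    contacts: list[MultiContact] = []
    for pair in pairs:
        stats.n_pairs += 1
        e1, e2 = classify_pair_naive(pair, genome, enzymes)
        if e1.status == "F" and e2.status == "F":
            stats.n_ff += 1
        stats.n_rescued_ends += sum(s.status in ("P1", "P2") for s in (e1, e2))
        contacts.extend(enumerate_contacts(pair.read_id, e1, e2))
    contacts = apply_distance_filter(contacts, min_dist)
    stats.contacts = contacts_summary(contacts)
    return contacts, stats


def call_contacts_from_sam(
    phase1_records: Iterable[AlignmentRecord],
    phase2_records: Iterable[AlignmentRecord],
    min_dist: int = 1000,
    policy1: FilterPolicy = PHASE1,
    policy2: FilterPolicy = PHASE2,
) -> tuple[list[MultiContact], PipelineStats]:
    """Call contacts from externally produced alignments.

    Phase-2 records must follow the read-name provenance convention
    (``:L`` / ``:R`` suffixes, see :mod:`multiway3c.align`); their presence
    implies the read had exactly one cleavage site (the split stage only
    emits such reads).
    """
    p1: dict[str, dict[int, list[AlignmentRecord]]] = defaultdict(lambda: defaultdict(list))
    p2: dict[str, dict[int, list[AlignmentRecord]]] = defaultdict(lambda: defaultdict(list))
    for r in phase1_records:
        if pass_filter(r, policy1):
            p1[r.read_id][r.end].append(r)
    for r in phase2_records:
        if pass_filter(r, policy2):
            p2[r.read_id][r.end].append(r)

    stats = PipelineStats()
    contacts: list[MultiContact] = []
    for read_id in sorted(set(p1) | set(p2)):
        stats.n_pairs += 1
        ends = []
        for end in (1, 2):
            whole = [r for r in p1[read_id][end] if r.fragment == "whole"]
            frags = p2[read_id][end]
            n_sites = 1 if frags else 0
            ends.append(classify_end(end, whole, frags, n_sites=n_sites))
        e1, e2 = ends
        if e1.status == "F" and e2.status == "F":
            stats.n_ff += 1
        stats.n_rescued_ends += sum(s.status in ("P1", "P2") for s in (e1, e2))
        contacts.extend(enumerate_contacts(read_id, e1, e2))
    contacts = apply_distance_filter(contacts, min_dist)
    stats.contacts = contacts_summary(contacts)
    return contacts, stats


def contacts_summary(contacts: Iterable[MultiContact]) -> dict:
    """Counts of doubles/triples/quadruples split by inter/intra/mixed."""
    names = {2: "doubles", 3: "triples", 4: "quadruples"}
    out: dict[str, dict[str, int]] = {
        v: {"inter": 0, "intra": 0, "mixed": 0} for v in names.values()
    }
    for c in contacts:
        out[names[c.arity]][c.span] += 1
    return out
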