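"""Genome layout, fixed-width bins and the bead-to-locus map.

A chromosome-conformation experiment on a near-haploid cell line (one copy
of most chromosomes, two copies of some chromosomes or chromosome segments)
observes contact counts at the level of *loci* -- fixed-width genomic bins
that cannot distinguish homologs.  Downstream normalization and 3D modeling
instead work with *beads*, one structural unit per homolog copy of each
locus.  This module holds the three bookkeeping objects:

``GenomeLayout``
    chromosome names/lengths plus copy-number-2 segments.
``BinTable``
    fixed-resolution tiling of the genome into loci, with per-bin GC,
    mappability and DNase-hypersensitive-site annotations.
``BeadMap``
    the surjection ``phi`` from beads onto loci, with a homolog label per
    bead.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HG19_CHROM_SIZES",
    "PloidySegment",
    "GenomeLayout",
    "BinTable",
    "BeadMap",
    "make_bins",
    "build_bead_map",
]

#: hg19 (GRCh37) chromosome lengths for chr1-22, X, Y.  Bundled so that the
#: whole-genome 1 Mb bin count (3113) can be checked without any download.
HG19_CHROM_SIZES: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}


@dataclass(frozen=True)
class PloidySegment:
    """A genomic interval with an explicit copy number (1 or 2)."""

    chrom: str
    start: int
    end: int
    copy_number: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment interval [{self.start}, {self.end})")
        if self.copy_number not in (1, 2):
            raise ValueError("copy_number must be 1 or 2")


@dataclass
class GenomeLayout:
    """Ordered chromosomes and their copy-number-2 segments.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; lengths in bp, > 0.
    ploidy_segments
        Copy-number segments.  Segments must lie within their chromosome and
        segments on the same chromosome must not overlap.  Regions not
        covered by any segment are haploid.
    """

    chromosomes: list[tuple[str, int]]
    ploidy_segments: list[PloidySegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout must contain at least one chromosome")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        for name, ln in self.chromosomes:
            if ln <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        by_chrom: dict[str, list[PloidySegment]] = {}
        for seg in self.ploidy_segments:
            if seg.chrom not in lengths:
                raise ValueError(f"ploidy segment on unknown chromosome {seg.chrom}")
            if seg.end > lengths[seg.chrom]:
                raise ValueError(f"ploidy segment {seg} exceeds chromosome length")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping ploidy segments on {chrom}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, ln in self.chromosomes:
            if name == chrom:
                return ln
        raise KeyError(chrom)

    def copy_number_at(self, chrom: str, pos: int) -> int:
        """Copy number of a single base-pair position (default 1)."""
        for seg in self.ploidy_segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.copy_number
        return 1

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_chromsizes(
        cls, path: str, ploidy_segments: list[PloidySegment] | None = None
    ) -> "GenomeLayout":
        """Read a two-column (name, length) chrom.sizes TSV."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(
            chromosomes=list(zip(df["chrom"], df["length"].astype(int))),
            ploidy_segments=list(ploidy_segments or []),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "GenomeLayout":
        """Read a layout config: ``chromosomes`` and ``ploidy_segments`` keys."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        chroms = [(str(c["name"]), int(c["length"])) for c in doc["chromosomes"]]
        segs = [
            PloidySegment(
                str(s["chrom"]), int(s["start"]), int(s["end"]),
                int(s.get("copy_number", 2)),
            )
            for s in doc.get("ploidy_segments", []) or []
        ]
        return cls(chromosomes=chroms, ploidy_segments=segs)

    def to_yaml(self, path: str) -> None:
        doc = {
            "chromosomes": [{"name": n, "length": ln} for n, ln in self.chromosomes],
            "ploidy_segments": [
                {"chrom": s.chrom, "start": s.start, "end": s.end,
                 "copy_number": s.copy_number}
                for s in self.ploidy_segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


class BinTable:
    """Fixed-resolution tiling of a genome into indexed bins (loci).

    Bins tile each chromosome contiguously from 0; every bin except possibly
    the last per chromosome has length equal to the resolution.  Per-bin
    annotations (``gc_fraction``, ``mappable_fraction``, ``dhs_count``) are
    stored as columns of :attr:`df` and default to NaN / 1.0 / 0.
    """

    def __init__(self, df: pd.DataFrame, resolution: int):
        self.df = df.reset_index(drop=True)
        self.resolution = int(resolution)
        self._ranges: dict[str, tuple[int, int]] = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            self._ranges[chrom] = (int(grp.index[0]), int(grp.index[-1]) + 1)

    # ------------------------------------------------------------ properties
    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._ranges)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global index range of a chromosome's bins."""
        return self._ranges[chrom]

    def chrom_of(self) -> np.ndarray:
        """Per-bin chromosome name array."""
        return self.df["chrom"].to_numpy()

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing ``pos`` (assigned by 5' coordinate)."""
        lo, hi = self._ranges[chrom]
        idx = lo + pos // self.resolution
        if not lo <= idx < hi:
            raise ValueError(f"position {chrom}:{pos} outside binned genome")
        return idx

    # ------------------------------------------------------------------- I/O
    def to_bed(self, path: str) -> None:
        out = self.df[["chrom", "start", "end"]].copy()
        out["name"] = np.arange(len(out))
        out.to_csv(path, sep="\t", header=False, index=False)

    def set_annotation(self, name: str, values: np.ndarray) -> None:
        if len(values) != self.n_bins:
            raise ValueError("annotation length mismatch")
        self.df[name] = np.asarray(values)


def make_bins(layout: GenomeLayout, resolution: int) -> BinTable:
    """Tile every chromosome of ``layout`` into fixed-width bins.

    Per chromosome there are ``ceil(length / resolution)`` bins; the last one
    may be shorter.  Global indices are consecutive and follow layout order.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rows = []
    for chrom, length in layout.chromosomes:
        n = math.ceil(length / resolution)
        for i in range(n):
            rows.append(
                (chrom, i * resolution, min((i + 1) * resolution, length))
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["gc_fraction"] = np.nan
    df["mappable_fraction"] = 1.0
    df["dhs_count"] = 0
    return BinTable(df, resolution)


@dataclass
class BeadMap:
    """Mapping ``phi`` from structural beads onto observed loci.

    Every locus has one bead per copy; diploid loci have two beads labelled
    ``'A'`` and ``'B'``.  ``n`` (bead count) exceeds ``m`` (locus count)
    exactly by the number of copy-number-2 bins.
    """

    phi: np.ndarray          # (n,) bead -> locus index
    copy_label: np.ndarray   # (n,) 'A' or 'B'
    m: int                   # number of loci

    @property
    def n(self) -> int:
        return len(self.phi)

    def copy_number(self) -> np.ndarray:
        """Per-locus copy number ``|phi^-1(k)|``."""
        return np.bincount(self.phi, minlength=self.m)

    def beads_for_locus(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.phi == k)

    def incidence(self) -> np.ndarray:
        """(n, m) 0/1 matrix ``P`` with ``P[i, phi(i)] = 1``."""
        P = np.zeros((self.n, self.m))
        P[np.arange(self.n), self.phi] = 1.0
        return P


def bin_copy_number(bins: BinTable, layout: GenomeLayout) -> np.ndarray:
    """Per-bin copy number; ploidy segment edges snap outward to the
    containing bins (a segment overlapping any part of a bin covers it)."""
    cn = np.ones(bins.n_bins, dtype=int)
    res = bins.resolution
    for seg in layout.ploidy_segments:
        lo, hi = bins.chrom_range(seg.chrom)
        first = lo + seg.start // res
        last = lo + math.ceil(seg.end / res)  # exclusive
        cn[first:min(last, hi)] = seg.copy_number
    return cn


def build_bead_map(bins: BinTable, layout: GenomeLayout) -> BeadMap:
    """Enumerate one bead per bin per copy.

    Beads are ordered: all first copies in bin order ('A'), then the second
    copies of diploid bins in bin order ('B'), mirroring a genome in which
    the duplicated chromosomes/segments are appended as extra homologs.
    """
    cn = bin_copy_number(bins, layout)
    phi = list(range(bins.n_bins))
    labels = ["A"] * bins.n_bins
    for k in np.flatnonzero(cn == 2):
        phi.append(int(k))
        labels.append("B")
    return BeadMap(
        phi=np.asarray(phi, dtype=int),
        copy_label=np.asarray(labels, dtype=object),
        m=bins.n_bins,
    )
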