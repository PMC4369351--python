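"""Synthetic genomes, proximity-ligation libraries and structure-driven
contact matrices with planted ground truth.

The library generator emulates the molecule types of a multi-enzyme in-gel
ligation protocol sequenced as 100 bp paired ends of ~250 bp size-selected
fragments:

* *sonication products* -- unligated genomic spans; both reads map fully at
  short genomic distance (eliminated downstream by the 1 kb filter);
* *two-fragment chimeras* with the ligation junction between the two read
  ends (an F-F double);
* *three-fragment molecules* with one junction inside read 1 and one
  between the reads (P2 + F: three loci, one triple);
* *four-fragment molecules* with junctions inside both reads (P2 + P2:
  four loci, one quadruple).

Ligation junctions coincide with restriction-fragment boundaries, so the
enzyme's full recognition site is reconstituted across every junction --
exactly the signal the second mapping phase splits on.  Each emitted read
is an exact substring of its molecule (error-free mode; an optional uniform
substitution mode exercises the edit-distance filters), and a truth table
records the mapped loci each read pair should produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import BeadMap, BinTable, GenomeLayout, PloidySegment
from .pipeline import ReadPair
from .restriction import Enzyme, count_read_sites, get_enzymes, revcomp

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_library",
    "simulate_counts_from_structure",
    "simulate_compartment_matrix",
    "write_fasta",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Stated world of the simulator.

    Defaults mirror the assay design: 100 bp paired-end reads from ~250 bp
    size-selected molecules.  Class fractions (sonication, double, triple,
    quadruple) are a design choice: sonication products dominate real
    libraries and multi-way molecules are rare, but at desk scale we keep
    enough multi-way molecules to exercise every code path.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 120_000), ("chr2", 120_000))
    ploidy_segments: tuple[PloidySegment, ...] = ()
    enzymes: str | tuple = "TM3C-1"
    read_length: int = 100
    fragment_size: int = 250
    n_read_pairs: int = 200
    class_fractions: tuple[float, float, float, float] = (0.40, 0.40, 0.15, 0.05)
    intra_fraction: float = 0.3
    min_partner_distance: int = 2_000
    error_rate: float = 0.0
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.read_length > self.fragment_size:
            raise ValueError("read length must not exceed fragment size")
        if self.fragment_size < 2 * self.read_length + 10:
            raise ValueError(
                "fragment size must exceed twice the read length (the "
                "junction-placement scheme needs a gap between the ends)"
            )


@dataclass
class SimulatedGenome:
    seqs: dict[str, str]
    layout: GenomeLayout


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Random genome with the configured chromosomes and GC content.

    Uniform base composition gives a 4-cutter site density of ~4^-4 per bp,
    ample cut sites for fragment selection.
    """
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {
        name: "".join(rng.choice(_BASES, size=length, p=p))
        for name, length in config.chromosomes
    }
    layout = GenomeLayout(
        chromosomes=list(config.chromosomes),
        ploidy_segments=list(config.ploidy_segments),
    )
    return SimulatedGenome(seqs=seqs, layout=layout)


# ------------------------------------------------------------------ library


@dataclass
class _Fragment:
    chrom: str
    start: int  # cut position (5' end of the digest fragment)
    end: int


class _Digest:
    """Per-chromosome digest fragments for one enzyme."""

    def __init__(self, genome: SimulatedGenome, enzyme: Enzyme,
                 min_partner_distance: int = 0):
        self.enzyme = enzyme
        self.min_partner_distance = min_partner_distance
        self.fragments: list[_Fragment] = []
        site, off = enzyme.site, enzyme.cut_offset
        total_sites = 0
        for chrom, seq in genome.seqs.items():
            cuts = []
            i = seq.find(site)
            while i != -1:
                cuts.append(i + off)
                i = seq.find(site, i + 1)
            total_sites += len(cuts)
            for a, b in zip(cuts, cuts[1:]):
                self.fragments.append(_Fragment(chrom, a, b))
        if total_sites == 0:
            raise ValueError(f"enzyme {enzyme.name} has no sites in the genome")
        self._len = np.array([f.end - f.start for f in self.fragments])
        self._chrom = np.array([f.chrom for f in self.fragments])
        self._start = np.array([f.start for f in self.fragments])

    def pick(
        self,
        rng: np.random.Generator,
        min_len: int,
        max_len: int | None = None,
        chrom: str | None = None,
        not_chrom: str | None = None,
        min_dist_from: tuple[str, int] | None = None,
    ) -> _Fragment | None:
        sel = self._len >= min_len
        if max_len is not None:
            sel &= self._len <= max_len
        if chrom is not None:
            sel &= self._chrom == chrom
        if not_chrom is not None:
            sel &= self._chrom != not_chrom
        if min_dist_from is not None:
            c, p = min_dist_from
            sel &= (self._chrom != c) | (
                np.abs(self._start - p) >= self.min_partner_distance
            )
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            return None
        return self.fragments[int(rng.choice(idx))]


def _partner_kwargs(cfg: SimConfig, rng: np.random.Generator, prev: _Fragment, n_chroms: int):
    if n_chroms > 1 and rng.random() >= cfg.intra_fraction:
        return {"not_chrom": prev.chrom}
    return {"chrom": prev.chrom, "min_dist_from": (prev.chrom, prev.start)}


@dataclass
class _Molecule:
    cls: str
    fragments: list[_Fragment]
    junctions: list[int]       # window offsets of the junctions
    window: str                # the sequenced molecule (length = fragment_size)
    enzyme: Enzyme


def _assemble(genome: SimulatedGenome, cls: str, frags: list[_Fragment],
              junctions: list[int], W: int, enzyme: Enzyme) -> _Molecule:
    seqs = genome.seqs
    bounds = [0] + junctions + [W]
    parts = []
    for q, f in enumerate(frags):
        span = bounds[q + 1] - bounds[q]
        if q == 0:
            parts.append(seqs[f.chrom][f.end - span : f.end])
        else:
            parts.append(seqs[f.chrom][f.start : f.start + span])
    return _Molecule(cls, frags, junctions, "".join(parts), enzyme)


def _truth_loci(mol: _Molecule, read_length: int, W: int):
    """Expected mapped loci (chrom, pos, strand, end) per read end.

    A read end covering q fragments produces q loci; 5' coordinates are
    exact for leading pieces and within the enzyme's cut offset (< 5 bp)
    for pieces that start at a junction.
    """
    bounds = [0] + mol.junctions + [W]
    gstarts = []
    for q, f in enumerate(mol.fragments):
        span = bounds[q + 1] - bounds[q]
        gstarts.append(f.end - span if q == 0 else f.start)
    loci = []
    for end, (w_lo, w_hi) in ((1, (0, read_length)), (2, (W - read_length, W))):
        for q, f in enumerate(mol.fragments):
            a, b = max(bounds[q], w_lo), min(bounds[q + 1], w_hi)
            if a >= b:
                continue
            if end == 1:
                pos = gstarts[q] + (a - bounds[q])
                loci.append((f.chrom, pos, "+", end))
            else:
                pos = gstarts[q] + (b - 1 - bounds[q])
                loci.append((f.chrom, pos, "-", end))
    return loci


def _expected_junctions_in_span(mol, w_lo, w_hi):
    sl, off = len(mol.enzyme.site), mol.enzyme.cut_offset
    n = 0
    for j in mol.junctions:
        if w_lo <= j - off and j - off + sl <= w_hi:
            n += 1
    return n


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
    return "".join(arr)


def simulate_library(
    config: SimConfig,
    genome: SimulatedGenome,
    rng: np.random.Generator | None = None,
    structure: tuple[np.ndarray, BeadMap, BinTable] | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired-end reads plus a truth table of plantable contacts.

    Junction placement is drawn uniformly within the offsets compatible
    with each molecule class, so junctions fall both within read ends
    (producing P ends) and between them (producing F-F chimeras).  Each
    candidate molecule is validated: a read end must contain exactly the
    intended cleavage sites of the full enzyme set -- otherwise the read
    would be discarded (>1 site) or mis-split, and the molecule is redrawn.

    When ``structure`` is given, the partner locus of two-fragment
    molecules is sampled with probability proportional to ``d ** -3`` of
    the planted structure.
    """
    rng = rng or np.random.default_rng(config.seed)
    enzymes = get_enzymes(config.enzymes)
    digests = [_Digest(genome, e, config.min_partner_distance) for e in enzymes]
    RL, W = config.read_length, config.fragment_size
    gap_lo, gap_hi = RL + 10, W - RL - 5   # junction offsets "between" reads
    n_chroms = len(genome.seqs)
    classes = ["sonication", "double", "triple", "quadruple"]
    probs = np.asarray(config.class_fractions)

    pair_sampler = None
    if structure is not None:
        pair_sampler = _StructurePairSampler(*structure, rng=rng)

    reads: list[ReadPair] = []
    truth_rows = []
    for ridx in range(config.n_read_pairs):
        cls = classes[int(rng.choice(4, p=probs))]
        mol = None
        for _ in range(100):
            mol = _draw_molecule(cls, config, genome, digests, rng, pair_sampler)
            if mol is None:
                continue
            r1 = mol.window[:RL]
            r2_span = (W - RL, W)
            if cls != "sonication":
                ok1 = count_read_sites(r1, enzymes) == _expected_junctions_in_span(mol, 0, RL)
                ok2 = (
                    count_read_sites(mol.window[r2_span[0]:], enzymes)
                    == _expected_junctions_in_span(mol, *r2_span)
                )
                if not (ok1 and ok2):
                    mol = None
                    continue
            break
        if mol is None:
            raise RuntimeError(f"could not assemble a {cls} molecule; too few "
                               "candidate restriction fragments")
        read_id = f"sim{ridx:06d}"
        seq1 = _apply_errors(mol.window[:RL], config.error_rate, rng)
        seq2 = _apply_errors(revcomp(mol.window[W - RL:]), config.error_rate, rng)
        reads.append(ReadPair(read_id, seq1, seq2))
        loci = _truth_loci(mol, RL, W)
        truth_rows.append(
            {
                "read_id": read_id,
                "cls": mol.cls,
                "n_loci": len(loci),
                "loci": ";".join(f"{c}:{p}:{s}:{e}" for c, p, s, e in loci),
                "junctions": ";".join(map(str, mol.junctions)),
            }
        )
    return reads, pd.DataFrame(truth_rows)


def _draw_molecule(cls, config, genome, digests, rng, pair_sampler):
    RL, W = config.read_length, config.fragment_size
    if cls == "sonication":
        chrom = list(genome.seqs)[int(rng.integers(len(genome.seqs)))]
        seq = genome.seqs[chrom]
        if len(seq) <= W:
            return None
        s = int(rng.integers(0, len(seq) - W))
        frag = _Fragment(chrom, s, s + W)
        # a single "fragment", no junctions; enzyme irrelevant
        return _Molecule(cls, [frag], [], seq[s : s + W],
                         digests[0].enzyme)
    dig = digests[int(rng.integers(len(digests)))]
    sl = len(dig.enzyme.site)
    n_chroms = len(genome.seqs)
    j_between = (RL + 10, W - RL - 5)

    if cls == "double":
        j1 = int(rng.integers(j_between[0], j_between[1] + 1))
        f1 = dig.pick(rng, min_len=j1 + sl)
        if f1 is None:
            return None
        if pair_sampler is not None:
            f2 = pair_sampler.pick_partner(dig, f1, rng, min_len=W - j1 + sl)
        else:
            f2 = dig.pick(rng, min_len=W - j1 + sl,
                          **_partner_kwargs(config, rng, f1, n_chroms))
        if f2 is None or f2 is f1:
            return None
        return _assemble(genome, cls, [f1, f2], [j1], W, dig.enzyme)

    if cls == "triple":
        f2 = dig.pick(rng, min_len=j_between[0] - (RL - 30), max_len=j_between[1] - 30)
        if f2 is None:
            return None
        len2 = f2.end - f2.start
        lo = max(30, j_between[0] - len2)
        hi = min(RL - 30, j_between[1] - len2)
        if lo > hi:
            return None
        j1 = int(rng.integers(lo, hi + 1))
        j2 = j1 + len2
        f1 = dig.pick(rng, min_len=j1 + sl,
                      **_partner_kwargs(config, rng, f2, n_chroms))
        f3 = dig.pick(rng, min_len=W - j2 + sl,
                      **_partner_kwargs(config, rng, f2, n_chroms))
        if f1 is None or f3 is None or len({id(f1), id(f2), id(f3)}) < 3:
            return None
        return _assemble(genome, cls, [f1, f2, f3], [j1, j2], W, dig.enzyme)

    # quadruple: junctions inside both reads plus one between them
    f2 = dig.pick(rng, min_len=40, max_len=j_between[1] - 30)
    if f2 is None:
        return None
    len2 = f2.end - f2.start
    lo = max(30, j_between[0] - len2)
    hi = min(RL - 30, j_between[1] - len2)
    if lo > hi:
        return None
    j1 = int(rng.integers(lo, hi + 1))
    j2 = j1 + len2
    lo3, hi3 = (W - RL + 30) - j2, (W - 30) - j2
    f3 = dig.pick(rng, min_len=max(40, lo3), max_len=hi3,
                  **_partner_kwargs(config, rng, f2, n_chroms))
    if f3 is None:
        return None
    j3 = j2 + (f3.end - f3.start)
    f1 = dig.pick(rng, min_len=j1 + sl,
                  **_partner_kwargs(config, rng, f2, n_chroms))
    f4 = dig.pick(rng, min_len=(W - j3) + sl,
                  **_partner_kwargs(config, rng, f3, n_chroms))
    if f1 is None or f4 is None or len({id(f1), id(f2), id(f3), id(f4)}) < 4:
        return None
    return _assemble(genome, "quadruple", [f1, f2, f3, f4], [j1, j2, j3], W, dig.enzyme)


class _StructurePairSampler:
    """Samples partner loci with probability proportional to d**-3."""

    def __init__(self, X: np.ndarray, beadmap: BeadMap, bins: BinTable,
                 rng: np.random.Generator):
        self.bins = bins
        self.beadmap = beadmap
        d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        P = beadmap.incidence()
        w = P.T @ (d ** -3.0) @ P  # locus-level weights
        np.fill_diagonal(w, 0.0)
        self.weights = w

    def pick_partner(self, dig, f1, rng, min_len):
        k = self.bins.bin_index(f1.chrom, f1.start)
        p = self.weights[k]
        if p.sum() == 0:
            return None
        l = int(rng.choice(len(p), p=p / p.sum()))
        row = self.bins.df.iloc[l]
        sel = (dig._chrom == row["chrom"]) & (dig._start >= row["start"]) \
            & (dig._start < row["end"]) & (dig._len >= min_len)
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            return None
        return dig.fragments[int(rng.choice(idx))]


# ------------------------------------------------- structure-driven counts


def simulate_counts_from_structure(
    X: np.ndarray,
    beadmap: BeadMap,
    alpha: float = -3.0,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Locus-level counts drawn as Poisson(scale * d**alpha) per bead pair.

    Same-copy bead pairs only (homologs do not interact); draws are summed
    over the bead pairs of each locus pair.  The diagonal is zero.
    """
    rng = rng or np.random.default_rng(0)
    n, m = beadmap.n, beadmap.m
    labels = beadmap.copy_label
    phi = beadmap.phi
    cn = beadmap.copy_number()
    C = np.zeros((m, m))
    for i in range(n):
        for j in range(i + 1, n):
            k, l = phi[i], phi[j]
            if k == l:
                continue
            if cn[k] == 2 and cn[l] == 2 and labels[i] != labels[j]:
                continue
            d = np.linalg.norm(X[i] - X[j])
            cnt = rng.poisson(scale * d ** alpha)
            C[k, l] += cnt
            C[l, k] += cnt
    return C


def simulate_compartment_matrix(
    labels: Sequence[str],
    base: float = 20.0,
    contrast: float = 0.4,
    noise: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plaid contact matrix with a planted two-compartment structure.

    Same-label bin pairs get mean ``base * (1 + contrast)``, cross-label
    pairs ``base * (1 - contrast)``, perturbed by multiplicative lognormal
    noise.  Returns the (symmetric) matrix and a GC track correlated with
    the open compartment (open 0.55, closed 0.40).
    """
    rng = rng or np.random.default_rng(0)
    lab = np.asarray(labels, dtype=object)
    m = len(lab)
    same = lab[:, None] == lab[None, :]
    mean = base * np.where(same, 1 + contrast, 1 - contrast)
    noise_mat = rng.lognormal(mean=0.0, sigma=noise, size=(m, m))
    M = mean * noise_mat
    M = (M + M.T) / 2.0
    gc = np.where(lab == "open", 0.55, 0.40) + rng.normal(0, 0.01, size=m)
    return M, gc


# ----------------------------------------------------------------- writers


def write_fasta(genome: SimulatedGenome, path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.seqs.items()
    ]
    SeqIO.write(records, path, "fasta")


def write_fastq(reads: Sequence[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}/1\n{r.seq1}\n+\n{'I' * len(r.seq1)}\n")
            f2.write(f"@{r.read_id}/2\n{r.seq2}\n+\n{'I' * len(r.seq2)}\n")
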