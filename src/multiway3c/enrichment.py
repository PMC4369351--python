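"""Observed/expected enrichment of contacts over bin annotations.

Two families of analyses:

*   Group fractions: interchromosomal doubles (and triples linking three
    distinct chromosomes) are segregated by the compartment labels -- or
    DNase-hypersensitivity classes -- of the windows they link into
    all-open / all-closed / mixed groups.  Expected fractions come from
    exact enumeration of all eligible window tuples; a ratio observed over
    expected above 1 is an enrichment.  With exactly equal numbers of open
    and closed windows per chromosome the expected percentages are
    25/25/50 for pairs and 12.5/12.5/75 for triples.

*   Topological-domain analyses: the fraction of intrachromosomal triples
    whose three loci fall within one domain, compared against a null in
    which domain (and gap) lengths are reshuffled within each chromosome
    arm, preserving the per-arm length multisets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contacts import MultiContact
from .genome import BinTable

__all__ = [
    "GroupFractions",
    "DomainShuffleNull",
    "expected_fractions",
    "observed_fractions",
    "dhs_classes",
    "within_domain_fraction",
    "shuffle_domains",
    "shuffle_null",
    "boundary_overlap",
]


@dataclass(frozen=True)
class GroupFractions:
    """Fractions of tuples/contacts per label group; they sum to 1."""

    fractions: dict[str, float]
    n: int
    observed: bool

    def __post_init__(self) -> None:
        if self.n > 0 and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")

    def percent(self, group: str) -> float:
        return 100.0 * self.fractions[group]


def _label_counts_per_chrom(
    chroms: Sequence[str], labels: Sequence, label_pair: tuple[str, str]
) -> pd.DataFrame:
    a, b = label_pair
    rows = {}
    for chrom, lab in zip(chroms, labels):
        if lab not in (a, b):
            continue  # NA / filtered bins are excluded from the universe
        rows.setdefault(chrom, [0, 0])
        rows[chrom][0 if lab == a else 1] += 1
    return pd.DataFrame.from_dict(rows, orient="index", columns=[a, b])


def expected_fractions(
    chroms: Sequence[str],
    labels: Sequence,
    arity: int,
    label_pair: tuple[str, str] = ("open", "closed"),
) -> GroupFractions:
    """Exact-enumeration expected group fractions.

    For ``arity == 2`` the universe is all interchromosomal bin pairs; for
    ``arity == 3`` all bin triples on three distinct chromosomes.  Counting
    uses products of per-chromosome label counts, not sampling.
    """
    if arity not in (2, 3):
        raise ValueError("arity must be 2 or 3")
    a, b = label_pair
    cnt = _label_counts_per_chrom(chroms, labels, label_pair)
    na = cnt[a].to_numpy(dtype=float)
    nb = cnt[b].to_numpy(dtype=float)
    tot = na + nb
    all_a = all_b = total = 0.0
    idx = range(len(cnt))
    for combo in combinations(idx, arity):
        all_a += np.prod(na[list(combo)])
        all_b += np.prod(nb[list(combo)])
        total += np.prod(tot[list(combo)])
    if total == 0:
        return GroupFractions({f"all_{a}": 0.0, f"all_{b}": 0.0, "mixed": 0.0},
                              n=0, observed=False)
    mixed = total - all_a - all_b
    return GroupFractions(
        {f"all_{a}": all_a / total, f"all_{b}": all_b / total,
         "mixed": mixed / total},
        n=int(total),
        observed=False,
    )


def observed_fractions(
    contacts: Iterable[MultiContact],
    bins: BinTable,
    labels: Sequence,
    arity: int,
    label_pair: tuple[str, str] = ("open", "closed"),
) -> GroupFractions:
    """Contact-weighted group fractions over the same filtered universe.

    Only interchromosomal doubles / three-chromosome triples count;
    contacts touching an unlabeled (NA or filtered) window are skipped.
    """
    if arity not in (2, 3):
        raise ValueError("arity must be 2 or 3")
    a, b = label_pair
    n_a = n_b = n_mixed = 0
    for c in contacts:
        if c.arity != arity or c.span != "inter":
            continue
        labs = []
        ok = True
        for l in c.loci:
            lab = labels[bins.bin_index(l.chrom, l.pos)]
            if lab not in (a, b):
                ok = False
                break
            labs.append(lab)
        if not ok:
            continue
        if all(x == a for x in labs):
            n_a += 1
        elif all(x == b for x in labs):
            n_b += 1
        else:
            n_mixed += 1
    n = n_a + n_b + n_mixed
    if n == 0:
        return GroupFractions({f"all_{a}": 0.0, f"all_{b}": 0.0, "mixed": 0.0},
                              n=0, observed=True)
    return GroupFractions(
        {f"all_{a}": n_a / n, f"all_{b}": n_b / n, "mixed": n_mixed / n},
        n=n,
        observed=True,
    )


def dhs_classes(
    dhs_count: Sequence[float], mask: np.ndarray | None = None
) -> np.ndarray:
    """Median split of windows by DNase-hypersensitive-site count.

    Windows are sorted by decreasing count; the top 50% are 'high', the
    bottom 50% 'low' (odd counts: the extra window goes to 'low'; ties are
    broken by bin index).  Masked-out windows get None.
    """
    counts = np.asarray(dhs_count, dtype=float)
    m = len(counts)
    if mask is None:
        mask = np.ones(m, dtype=bool)
    labels = np.full(m, None, dtype=object)
    idx = np.flatnonzero(mask)
    order = idx[np.lexsort((idx, -counts[idx]))]
    n_high = len(order) // 2
    labels[order[:n_high]] = "high"
    labels[order[n_high:]] = "low"
    return labels


# ------------------------------------------------------- topological domains


def _domain_arrays(domains: Sequence[tuple[str, int, int]]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in domains:
        by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    out = {}
    for chrom, iv in by_chrom.items():
        iv.sort()
        out[chrom] = (np.array([s for s, _ in iv]), np.array([e for _, e in iv]))
    return out


def _domain_index(arrays, chrom: str, pos: int) -> int:
    """Index of the domain containing pos, or -1."""
    if chrom not in arrays:
        return -1
    starts, ends = arrays[chrom]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i >= 0 and pos < ends[i]:
        return i
    return -1


def within_domain_fraction(
    triples: Iterable[MultiContact],
    domains: Sequence[tuple[str, int, int]],
    min_span: int = 20_000,
    window: int = 40_000,
) -> tuple[float, int]:
    """Fraction of eligible intrachromosomal triples inside one domain.

    Excluded from numerator and denominator: triples with total span below
    ``min_span`` and triples linking at least two loci within the same
    ``window``-sized bin (both would trivially inflate the fraction).
    Returns ``(fraction, n_eligible)``.
    """
    arrays = _domain_arrays(domains)
    n_in = n_elig = 0
    for c in triples:
        if c.arity != 3 or c.span != "intra":
            continue
        pos = sorted(l.pos for l in c.loci)
        if pos[-1] - pos[0] < min_span:
            continue
        wins = [p // window for p in pos]
        if len(set(wins)) < 3:
            continue
        n_elig += 1
        ids = {_domain_index(arrays, c.loci[0].chrom, p) for p in pos}
        if len(ids) == 1 and -1 not in ids:
            n_in += 1
    return (n_in / n_elig if n_elig else float("nan")), n_elig


def shuffle_domains(
    domains: Sequence[tuple[str, int, int]],
    arms: Sequence[tuple[str, int, int]],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Reshuffle domains within each chromosome arm.

    Domain lengths and inter-domain gap lengths (including the flanks to the
    arm ends) are independently permuted and re-laid alternately from the
    arm start, preserving both per-arm length multisets exactly and hence
    the covered fraction of each arm.
    """
    out: list[tuple[str, int, int]] = []
    for chrom, a_start, a_end in arms:
        doms = sorted(
            (s, e) for c, s, e in domains if c == chrom and s >= a_start and e <= a_end
        )
        if not doms:
            continue
        dlens = np.array([e - s for s, e in doms])
        edges = [a_start] + [x for s, e in doms for x in (s, e)] + [a_end]
        glens = np.array(
            [edges[2 * i + 1] - edges[2 * i] for i in range(len(doms) + 1)]
        )
        dlens = rng.permutation(dlens)
        glens = rng.permutation(glens)
        pos = a_start
        for i, dl in enumerate(dlens):
            pos += int(glens[i])
            out.append((chrom, pos, pos + int(dl)))
            pos += int(dl)
    return out


@dataclass(frozen=True)
class DomainShuffleNull:
    observed: float
    replicates: np.ndarray
    mean: float
    sd: float
    z: float


def shuffle_null(
    domains: Sequence[tuple[str, int, int]],
    arms: Sequence[tuple[str, int, int]],
    triples: Sequence[MultiContact],
    replicates: int = 100,
    seed: int = 0,
    min_span: int = 20_000,
    window: int = 40_000,
) -> DomainShuffleNull:
    """Shuffled-domain null for the within-domain triple fraction.

    ``z = (observed - mean) / sd`` over ``replicates`` reshufflings; when
    the null is degenerate (sd == 0) the z-score is 0 if the observed value
    equals the null mean and signed infinity otherwise.
    """
    if replicates < 2:
        raise ValueError("need more than one replicate")
    rng = np.random.default_rng(seed)
    triples = list(triples)
    obs, _ = within_domain_fraction(triples, domains, min_span, window)
    reps = np.empty(replicates)
    for r in range(replicates):
        shuffled = shuffle_domains(domains, arms, rng)
        reps[r], _ = within_domain_fraction(triples, shuffled, min_span, window)
    mean, sd = float(np.mean(reps)), float(np.std(reps))
    eps = 1e-12
    if sd <= eps:  # degenerate null (e.g. shuffle-invariant domain cover)
        sd = 0.0
        z = 0.0 if abs(obs - mean) <= eps else \
            float(np.sign(obs - mean)) * float("inf")
    else:
        z = (obs - mean) / sd
    return DomainShuffleNull(observed=obs, replicates=reps, mean=mean, sd=sd, z=z)


def boundary_overlap(
    domains_a: Sequence[tuple[str, int, int]],
    domains_b: Sequence[tuple[str, int, int]],
    adjacency: int = 0,
) -> float:
    """Percentage of A domain boundaries matched by a B boundary.

    Each domain contributes its two edge positions as boundaries.  Two
    boundaries match when they coincide or lie within ``adjacency`` bp of
    each other -- pass the calling resolution (bin width) to treat
    boundaries in adjacent bins as overlapping.
    """
    def edges(domains):
        out: dict[str, list[int]] = {}
        for chrom, s, e in domains:
            out.setdefault(chrom, []).extend((int(s), int(e)))
        return {c: np.array(sorted(set(v))) for c, v in out.items()}

    ea, eb = edges(domains_a), edges(domains_b)
    total = matched = 0
    for chrom, pos_a in ea.items():
        total += len(pos_a)
        if chrom not in eb:
            continue
        pos_b = eb[chrom]
        for p in pos_a:
            i = np.searchsorted(pos_b, p)
            near = []
            if i < len(pos_b):
                near.append(abs(int(pos_b[i]) - p))
            if i > 0:
                near.append(abs(int(pos_b[i - 1]) - p))
            if near and min(near) <= adjacency:
                matched += 1
    return 100.0 * matched / total if total else float("nan")
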