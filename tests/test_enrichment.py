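from itertools import combinations

import numpy as np
import pytest

from multiway3c.contacts import EndStatus, Locus, MultiContact
from multiway3c.enrichment import (
    boundary_overlap,
    dhs_classes,
    expected_fractions,
    observed_fractions,
    shuffle_domains,
    shuffle_null,
    within_domain_fraction,
)
from multiway3c.genome import GenomeLayout, make_bins


def _toy_labels(n_chrom=4, n_bins=10, n_open=5):
    chroms = np.repeat([f"c{i}" for i in range(n_chrom)], n_bins)
    labels = np.array((["open"] * n_open + ["closed"] * (n_bins - n_open)) * n_chrom,
                      dtype=object)
    return chroms, labels


def _contact(loci_spec, rid="r"):
    loci = tuple(
        Locus(c, p, "+", 1 + (i % 2), "whole") for i, (c, p) in enumerate(loci_spec)
    )
    chroms = [c for c, _ in loci_spec]
    span = ("intra" if len(set(chroms)) == 1
            else "inter" if len(set(chroms)) == len(chroms) else "mixed")
    return MultiContact(len(loci), loci, "F-F", span, rid)


class TestExpectedFractions:
    def test_equal_split_triples(self):
        chroms, labels = _toy_labels()
        gf = expected_fractions(chroms, labels, arity=3)
        assert gf.percent("mixed") == pytest.approx(75.0)
        assert gf.percent("all_open") == pytest.approx(12.5)
        assert gf.percent("all_closed") == pytest.approx(12.5)

    def test_equal_split_pairs(self):
        chroms, labels = _toy_labels()
        gf = expected_fractions(chroms, labels, arity=2)
        assert gf.percent("mixed") == pytest.approx(50.0)
        assert gf.percent("all_open") == pytest.approx(25.0)

    def test_all_open_genome(self):
        chroms, labels = _toy_labels(n_open=10)
        gf = expected_fractions(chroms, labels, arity=3)
        assert gf.percent("all_open") == 100.0

    @pytest.mark.parametrize("arity", [2, 3])
    def test_matches_bruteforce_tuple_oracle(self, arity):
        """Exact counting equals explicit enumeration on small genomes."""
        rng = np.random.default_rng(0)
        for _ in range(3):
            n_chrom = int(rng.integers(arity, 5))
            sizes = rng.integers(2, 16, size=n_chrom)  # <= 60 bins total
            chroms = np.repeat([f"c{i}" for i in range(n_chrom)], sizes)
            labels = rng.choice(["open", "closed"], size=sizes.sum())
            gf = expected_fractions(chroms, labels, arity)
            groups = {"all_open": 0, "all_closed": 0, "mixed": 0}
            for combo in combinations(range(len(chroms)), arity):
                if len({chroms[i] for i in combo}) < arity:
                    continue
                labs = {labels[i] for i in combo}
                if labs == {"open"}:
                    groups["all_open"] += 1
                elif labs == {"closed"}:
                    groups["all_closed"] += 1
                else:
                    groups["mixed"] += 1
            total = sum(groups.values())
            for g, cnt in groups.items():
                assert gf.fractions[g] == pytest.approx(cnt / total)
            assert gf.n == total

    def test_fractions_sum_to_one(self):
        chroms, labels = _toy_labels(3, 7, 2)
        for arity in (2, 3):
            gf = expected_fractions(chroms, labels, arity)
            assert sum(gf.fractions.values()) == pytest.approx(1.0)


class TestObservedFractions:
    @pytest.fixture
    def bins(self):
        return make_bins(
            GenomeLayout([(f"c{i}", 10_000) for i in range(4)]), 1000
        )

    def test_uniform_sampling_matches_expected(self, bins):
        """Contacts drawn uniformly over eligible tuples: observed ~=
        expected, so every enrichment ratio ~= 1."""
        rng = np.random.default_rng(1)
        chroms, labels = _toy_labels()
        gf_exp = expected_fractions(chroms, labels, arity=2)
        eligible = [
            (i, j)
            for i in range(40)
            for j in range(i + 1, 40)
            if chroms[i] != chroms[j]
        ]
        picks = rng.choice(len(eligible), size=4000)
        contacts = []
        for t, pick in enumerate(picks):
            i, j = eligible[pick]
            contacts.append(
                _contact([(chroms[i], (i % 10) * 1000), (chroms[j], (j % 10) * 1000)],
                         rid=f"r{t}")
            )
        gf_obs = observed_fractions(contacts, bins, labels, arity=2)
        for g in gf_exp.fractions:
            assert gf_obs.percent(g) == pytest.approx(gf_exp.percent(g), abs=2.5)
            ratio = gf_obs.fractions[g] / gf_exp.fractions[g]
            assert ratio == pytest.approx(1.0, abs=0.11)

    def test_contacts_only_among_open(self, bins):
        chroms, labels = _toy_labels()
        contacts = [
            _contact([("c0", 0), ("c1", 1000), ("c2", 2000)]),
            _contact([("c0", 2000), ("c2", 0), ("c3", 4000)]),
        ]
        gf = observed_fractions(contacts, bins, labels, arity=3)
        assert gf.percent("all_open") == 100.0

    def test_intra_and_mixed_span_skipped(self, bins):
        chroms, labels = _toy_labels()
        contacts = [
            _contact([("c0", 0), ("c0", 5000)]),              # intra pair
            _contact([("c0", 0), ("c0", 5000), ("c1", 0)]),   # mixed triple
        ]
        assert observed_fractions(contacts, bins, labels, 2).n == 0
        assert observed_fractions(contacts, bins, labels, 3).n == 0


class TestDhsClasses:
    def test_median_split(self):
        rng = np.random.default_rng(2)
        labels = dhs_classes(rng.integers(0, 100, size=100))
        assert (labels == "high").sum() == 50
        assert (labels == "low").sum() == 50

    def test_all_equal_counts_deterministic(self):
        labels = dhs_classes(np.full(10, 7))
        assert list(labels[:5]) == ["high"] * 5
        assert list(labels[5:]) == ["low"] * 5

    def test_scaling_counts_leaves_labels_unchanged(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=30)
        assert (dhs_classes(counts) == dhs_classes(counts * 2)).all()

    def test_high_windows_have_higher_counts(self):
        rng = np.random.default_rng(4)
        counts = rng.permutation(np.arange(20))
        labels = dhs_classes(counts)
        assert counts[labels == "high"].min() > counts[labels == "low"].max()


DOMAINS = [("c1", 0, 100_000), ("c1", 150_000, 300_000)]


def _triple(chrom, p1, p2, p3, rid="t"):
    return _contact([(chrom, p1), (chrom, p2), (chrom, p3)], rid=rid)


class TestWithinDomain:
    def test_all_in_one_domain_counts(self):
        frac, n = within_domain_fraction(
            [_triple("c1", 1000, 45_000, 95_000)], DOMAINS
        )
        assert (frac, n) == (1.0, 1)

    def test_two_loci_in_same_window_excluded(self):
        frac, n = within_domain_fraction(
            [_triple("c1", 1000, 30_000, 95_000)], DOMAINS, window=40_000
        )
        assert n == 0  # 1000 and 30000 share the first 40 kb window

    def test_short_span_excluded(self):
        frac, n = within_domain_fraction(
            [_triple("c1", 160_000, 165_000, 175_000)], DOMAINS, window=4_000
        )
        assert n == 0  # span 15 kb < 20 kb

    def test_boundary_spanning_in_denominator_only(self):
        frac, n = within_domain_fraction(
            [_triple("c1", 1000, 95_000, 200_000)], DOMAINS
        )
        assert (frac, n) == (0.0, 1)


ARMS = [("c1", 0, 600_000)]


class TestShuffle:
    def test_length_multisets_preserved(self):
        rng = np.random.default_rng(5)
        domains = [("c1", 10_000, 60_000), ("c1", 100_000, 250_000),
                   ("c1", 300_000, 390_000)]
        shuffled = shuffle_domains(domains, ARMS, rng)
        assert sorted(e - s for _, s, e in shuffled) == \
            sorted(e - s for _, s, e in domains)
        # total gap length preserved too
        assert sum(e - s for _, s, e in shuffled) == \
            sum(e - s for _, s, e in domains)
        for _, s, e in shuffled:
            assert 0 <= s < e <= 600_000

    def test_full_cover_equal_lengths_invariant_z_zero(self):
        """Equal-length domains tiling the arm: shuffling reproduces the
        same cover, so the observed fraction equals the null and z = 0."""
        domains = [("c1", i * 150_000, (i + 1) * 150_000) for i in range(4)]
        triples = [
            _triple("c1", 5_000, 50_000, 145_000),
            _triple("c1", 155_000, 200_000, 295_000),
            _triple("c1", 140_000, 200_000, 290_000),  # spans a boundary
        ]
        null = shuffle_null(domains, ARMS, triples, replicates=20, seed=0)
        assert null.sd == 0.0
        assert null.z == 0.0

    def test_planted_intra_domain_triples_give_large_z(self):
        rng = np.random.default_rng(6)
        domains = [("c1", 20_000, 150_000), ("c1", 200_000, 340_000),
                   ("c1", 400_000, 560_000)]
        triples = []
        for t in range(60):
            _, s, e = domains[t % 3]
            a = int(rng.integers(s, e - 100_000))
            triples.append(_triple("c1", a, a + 45_000, e - 1, rid=f"t{t}"))
        null = shuffle_null(domains, ARMS, triples, replicates=50, seed=1)
        assert null.observed > null.mean
        assert null.z > 3.0

    def test_seed_determinism(self):
        domains = [("c1", 20_000, 170_000), ("c1", 300_000, 420_000)]
        triples = [_triple("c1", 25_000, 85_000, 165_000)]
        a = shuffle_null(domains, ARMS, triples, replicates=10, seed=7)
        b = shuffle_null(domains, ARMS, triples, replicates=10, seed=7)
        assert np.array_equal(a.replicates, b.replicates)
        assert (a.mean, a.sd, a.z) == (b.mean, b.sd, b.z)


class TestBoundaryOverlap:
    def test_identical_sets(self):
        assert boundary_overlap(DOMAINS, DOMAINS) == 100.0

    def test_disjoint_non_adjacent(self):
        other = [("c1", 500_000, 600_000)]
        assert boundary_overlap(DOMAINS, other) == 0.0

    def test_adjacent_bin_edges_overlap(self):
        a = [("c1", 0, 80_000)]
        b = [("c1", 120_000, 200_000)]
        assert boundary_overlap(a, b, adjacency=40_000) == 50.0
        assert boundary_overlap(a, b, adjacency=0) == 0.0
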