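# Methods

This note records the models, parameter choices and numerical decisions in
`multiway3c`, and what the synthetic-data tests do and do not establish.

## Two-phase mapping and contact enumeration

A read end is *fully mapped* (F) when the whole 100 bp read aligns
uniquely with MAPQ ≥ 30 and edit distance ≤ 3.  Ends failing phase 1 are
scanned for restriction recognition sites of the library's enzyme set;
only reads with **exactly one** site are split (the full site is kept on
both fragments, so `len(left) + len(right) = len(read) + len(site)`), and
fragments realign under a tighter edit-distance budget (≤ 1) because they
are shorter.  Reads with zero sites cannot span a ligation junction; reads
with two or more sites are discarded as ambiguous — the protocol
description is internally inconsistent about two-site reads, and we take
the conservative reading (split nothing that is not unambiguous).
Fragments shorter than 16 bp are never sent to alignment: they cannot be
placed uniquely in a mammalian-scale genome.

Motifs are searched on the read together with their reverse complements,
with identical intervals deduplicated (all four standard 4-cutter motifs
are palindromic, so this matters only for custom enzymes), and
overlapping occurrences are counted.

Contacts are enumerated as all subsets of size 2–4 of the mapped loci of a
read pair.  The contact coordinate of a fragment is its 5'-mapped base;
loci within a contact are sorted by (chromosome, position) with end and
fragment provenance retained, which keeps output deterministic and lets
intrachromosomal orientation signatures (the strand-sign table used to
diagnose sonication products) be reconstructed.  The default 1 kb
intrachromosomal distance filter reflects the ~250 bp size selection: no
unligated molecule can span 1 kb.

## Copy-number-aware normalization

Iterative correction assumes equal locus visibility, which a near-haploid
karyotype breaks.  The procedure is: (1) *deduplicate* — expand the m×m
locus matrix to n×n homolog beads, splitting each count involving a
diploid locus equally over its same-copy bead-pair configurations and
zeroing inter-homolog entries (homologs are modeled as interacting
identically and not with each other); (2) filter the top 10% of loci by
intrachromosomal zero fraction (ties broken by locus index; chromosomes
with fewer than two bins are exempt because their zero fraction is
meaningless); (3) ICE on the bead matrix; (4) re-sum homolog beads.
Without ICE, steps 1+4 are the identity; with ICE, diploid loci end with
exactly twice the haploid coverage — the test asserts the ratio to 1e-6
after running ICE to a 1e-9 coverage tolerance, since the convergence
tolerance must sit well below the measured one.  Defaults: tolerance 1e-5
on the maximum relative coverage deviation, 300 iterations, bias
normalized to unit geometric mean over retained loci.

## Compartments

The correlation matrix of the normalized intrachromosomal map is
eigendecomposed; the eigenvector with the largest eigenvalue is used
unless it is single-signed (ignoring exact zeros), in which case the
second is taken.  Before labeling, the eigenvector is scaled so its
largest-magnitude entry is positive, removing solver-dependent sign flips;
GC orientation then assigns "open" to the sign group with higher mean GC
(ties fall back deterministically to the positive group, with a warning).
Bins that are filtered, non-finite or have zero row variance are NA, and
chromosomes with fewer than four usable bins produce all-NA tracks.

## Enrichment statistics

Expected group fractions are exact counts — products of per-chromosome
label counts over chromosome pairs/triples — never sampled.  The universe
is interchromosomal window pairs and window triples on three distinct
chromosomes, restricted to windows with ≥ 50% uniquely mappable bases.
DNase-hypersensitivity classes are a median split (windows sorted by
decreasing count; odd leftovers go to "low"; ties broken by index).

Within-domain triple fractions exclude triples spanning < 20 kb and
triples with two loci in one 40 kb window, both of which would inflate the
fraction trivially.  The shuffle null permutes domain lengths *and*
inter-domain gap lengths within each chromosome arm and re-lays them
alternately from the arm start — preserving the per-arm length multisets
and covered fraction exactly.  A degenerate null (all replicates equal,
e.g. an arm tiled by equal-length domains) reports z = 0 when the observed
value equals the null.  Domain-boundary overlap treats each domain edge as
a boundary; pass the calling resolution as the adjacency tolerance to
count boundaries in adjacent bins as overlapping.

## 3D inference

The Poisson mean of the count assigned to bead pair (i, j) is d_ij^α with
α = −3 and **no multiplicative scale coefficient**: coordinate units are
therefore fixed by the counts (the maximum-likelihood distance of an
isolated pair with assigned count c is c^(1/α)).  The likelihood runs over
bead pairs of locus pairs with nonzero counts; the matrix diagonal is
excluded (a locus' self-contacts carry no distance information).

Constraints and defaults:

* `d_max`: 97% quantile (linear interpolation) of c^(−1/3) over adjacent
  haploid bead pairs.  The distance cap is enforced on **adjacent same-copy
  bead pairs**, via a smooth hinge penalty (weight 100) inside L-BFGS: its
  purpose is to keep chains connected where normalization produced outlier
  adjacent counts.  Capping *all* pairwise distances at an adjacent-scale
  quantile would be infeasible under the d^−3 law and is not intended.
* `μ`: per locus pair, an exact grid search with step 0.01 under the
  sum-to-one constraint; multi-configuration groups (any pair involving a
  diploid locus) are boxed into [0.3, 0.7].  The box is the device that
  keeps the homolog count split identifiable: with free proportions the
  optimizer reaches higher-likelihood structures far from any planted
  truth.
* Alternation: μ-step (exactly optimal given X) then structure step
  (L-BFGS with analytic gradient, ≤ 300 inner iterations); a structure
  step that lowers the penalized objective is rejected, making the
  alternation monotone.  Outer loop: ≤ 50 alternations or relative change
  < 1e-6.  Initialization: X isotropic Gaussian at d_max/2 scale, μ
  uniform per group.  Restarts: 10 by default with the top 10% returned
  (mirroring a 1000-restart / top-100 production setting); all randomness
  flows from one seed, so runs are bit-reproducible.
* Coincident beads are clamped to distance 1e-9 with a warning rather
  than raising mid-optimization.

## Synthetic data: what it emulates, what it does not

The library generator assembles molecules from restriction digest
fragments, so every ligation junction reconstitutes the enzyme's full
recognition site — exactly the signal phase 2 splits on — and takes a
250 bp window with junction offsets drawn uniformly within the ranges
that realize each molecule class: junction between the read ends
(two-fragment, an F-F chimera), inside end 1 (three-fragment: P2+F) or
inside both ends (four-fragment: P2+P2).  Sonication products are plain
genomic spans.  Reads are exact substrings of their molecules; an optional
uniform substitution mode exists to exercise the edit-distance filters.
Candidate molecules whose read spans contain unintended cleavage sites of
the enzyme set are redrawn, and same-chromosome ligation partners are kept
≥ 2 kb apart — in-nucleus ligation partners at sonication scale are
indistinguishable from unligated molecules by construction, and the 1 kb
filter would (correctly) remove them.

Defaults mirror the stated assay design: 100 bp ends, 250 bp molecules,
DpnII-only ("TM3C-1") or the four-enzyme set ("TM3C-4").  Class fractions
(0.40 sonication, 0.40 double, 0.15 triple, 0.05 quadruple) are a desk-
scale choice: real libraries are dominated by sonication products with far
rarer multi-way molecules, but tests need every class populated.  The
generator does not model crosslinking biology, fragment-length/GC bias,
PCR duplication or base-quality error profiles; a green end-to-end test
establishes the bookkeeping (splitting, filtering, enumeration) is exact
on clean reads, not that the pipeline is robust to real sequencing noise.

The planted 30-bead structure used for recovery testing places the two
homolog copies of the diploid chromosome congruently and nearly
coincident.  This is deliberate: inter-homolog contact counts are
structurally zero, so the data contain no information about inter-homolog
geometry, and the deduplication model itself assumes homologs interact
identically.  A planted truth violating that assumption is not recoverable
by any method consuming these counts; the green test therefore establishes
recovery of model-consistent structures only.

## Known limitations

* The built-in aligner is exact-match and for tests; real data should be
  aligned externally and consumed as SAM (read-name suffixes `/1`, `/2`,
  `:L`, `:R` carry end/fragment provenance).
* Uniqueness semantics follow the external aligner's annotations (XT/XA/
  NH when present); they are not guaranteed to reproduce any specific
  aligner version.
* Topological domains are consumed as BED intervals from an external
  caller; no domain caller is included.
* Whole-genome (3000+ bead, 1000-restart) inference is cluster-scale and
  outside the test envelope; the implementation is the same code path at
  larger n.
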