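# Methods

## The problem

A SINE-derived satellite (sSat) is a tandem array whose repeat unit is a
sub-region of a SINE retrotransposon — shorter than the full SINE, with
terminal monomers that often extend further along the SINE consensus
toward one or both termini. Detecting them requires (a) finding all
SINE-related fragments in an assembly, (b) deciding which clusters of
fragments are tandem arrays rather than interspersed copies, (c)
segmenting each array into monomers anchored on the SINE consensus, and
(d) characterizing variation within and between arrays. Every stage here
is validated against synthetic genomes with exact planted truth, because
real assemblies provide no ground truth for any of these calls.

## Hit search

The consensus is aligned to the genome with affine-gap Smith–Waterman
(match +5, mismatch −4, gap open 12, gap extend 2 — a gap of length *k*
costs 12 + 2(*k*−1); numba-compiled, deterministic tie-break: smallest
target end, then smallest query end). The genome-scale search is
restricted to windows seeded by exact 11-mers shared with either strand
of the consensus; within a window the best alignment is extracted,
masked, and the alignment repeated, so each monomer of a tandem cluster
surfaces as its own hit.

Two numerical consequences of the permissive +5/−4 scoring are handled
explicitly:

- Optimal local alignments of *unrelated* DNA plateau near 50–57 %
  identity (a 55 %-identity column still scores positive on average), so
  hits below an identity floor of 58 % are discarded. Genuinely
  homologous copies stay above ~65 % local identity even at 35 %
  substitution divergence, so the floor costs essentially no recall.
- A junk-bridged alignment can span genuine short fragments. Before a
  rejected span is masked, it is re-aligned iteratively under stringent
  scoring (+2/−5) that only extends through ≥ ~70 % identity, recovering
  every embedded high-identity core.

A hit is kept when its span on the consensus covers ≥ 20 % of the
consensus length (the fragment regime used to find candidate loci). The
separate near-full-length filter used for subfamily work is strict on
both axes: coverage > 90 % of the consensus *and* identity > 65 %, so a
copy at exactly 90 % coverage or exactly 65 % identity is excluded.

Identity is defined throughout as matching columns / alignment columns
(gap columns count against identity). Global identities are computed
with edlib minimum-edit-distance alignment; because equally optimal
paths depend on argument order, the sequence pair is canonicalized
before aligning, making the measure exactly symmetric.

## Subfamily refinement

Copies passing the full-length filter are star-aligned to a provisional
reference (the longest copy), a majority consensus is called
(per column: most frequent non-gap symbol when non-gap symbols are the
majority, ties broken A<C<G<T, gap-majority columns dropped), and one
refinement round re-anchors the star alignment on that consensus. Copies
are then ordered by identity to the overall consensus (descending,
stable) and chunked into consecutive groups of 100 (the last group may be
smaller); each group is star-aligned and majority-called, and the group
consensuses are aligned to each other. Ordering by identity to the
overall consensus is a deterministic, MSA-tool-independent surrogate for
similarity presorting: when two subfamilies are present, the chimeric
overall consensus is closer to one source at more sites than the other,
which is enough to bias the two chunks toward the two sources; the
per-group majority call then converges on each source. The
parameter-recovery test (two sources 15 % apart, 100 copies each at 2 %
copy noise) requires ≥ 98 % consensus-to-source identity for at least
9 of 10 random seeds — the ordering is statistical, not guaranteed, and
one seed in ten is allowed to split the sources imperfectly.

## Locus assembly and tandem calling

Hits fewer than 100 bp apart are merged transitively (a gap of exactly
100 bp is *not* merged), and merged regions longer than 500 bp (strict)
become candidate loci.

Within a candidate, the tandem structure is derived in three steps:

1. **Period.** Spacings between repeated 12-mers inside the locus are
   histogrammed (smoothed ±2 nt); the fundamental period is the smallest
   spacing whose count is within 50 % of the maximum. Periods below 20 nt
   are ignored so microsatellite runs inside a monomer cannot masquerade
   as the unit. No repeated 12-mer → no tandem (a solo SINE copy returns
   an empty tiling).
2. **Canonical unit.** A period-length probe is cut from the middle of
   the repeated region (its phase is arbitrary), doubled so one
   contiguous copy of the canonical unit crosses the junction, and
   aligned against the consensus under stringent scoring. The aligned
   consensus interval defines the repeat unit. Deriving the unit this way
   rather than from the hit endpoints is deliberate: iterated-masking hit
   boundaries on a tandem array are phase-shifted and widened by
   junk-bridging, whereas the period is a property of the sequence
   itself. A probe spanning the entire consensus is rejected (a tandem of
   full SINEs is not a shorter-unit satellite).
3. **Tiling.** The unit is placed repeatedly (best infix placement,
   masked, repeated) accepting monomers at ≥ 60 % identity; the longest
   run of placements whose inter-monomer gaps stay under 100 bp is kept.
   N runs of ≥ 20 nt are not counted toward gaps, so poorly sequenced
   loci are not fragmented. Terminal monomers are extended into the
   flanking sequence wherever the consensus continues to match under
   stringent scoring (≥ 8 nt, junction-anchored within 3 nt), recording
   how far the leading/trailing monomers run toward the SINE termini.

A locus becomes an sSat when it has at least 4 middle monomers (the two
terminal monomers are excluded from the count) and all adjacent gaps are
under 100 bp. The reported unit interval is the component-wise mode of
the middle monomers' consensus placements, with the interval length
snapped to the modal monomer length: a single chance-matching base at a
unit boundary would otherwise stretch the aligned interval by one
position. Mixed-strand candidates are resolved toward the strand with
more member hits.

The "at least four middle monomers" default reconciles two stated
conventions for the same threshold; it is configurable
(`min_middle_monomers`), as is whether orthology-grade loci (≥ 2 repeat
units) are included.

Note an interaction of the thresholds with short units: with a 67-nt
unit, a tandem array needs ≥ 6 monomers plus terminal extensions before
its merged span clears the 500-bp candidate minimum, so arrays of 4–5
total monomers are not callable by construction. End-to-end recovery is
therefore scored against the *callable* truth set: planted arrays with
≥ 4 middle monomers and a span over 500 bp.

## Profiling

- **Homogeneity**: mean pairwise global-alignment identity over all
  unordered monomer pairs; permutation-invariant and 100 % iff all
  monomers are identical.
- **Variants** (genome-wide): single-linkage clustering of locus unit
  consensuses; two loci join when unit identity ≥ 80 % *and* unit
  endpoints agree within 10 nt (both configurable; nested 5′-truncation
  variants of one unit stay > 80 % identical, so the boundary rule is
  what separates them — tighter tolerances are needed when truncation
  offsets are below 10 nt). Variants are labelled V1, V2, … by
  descending membership.
- **Subvariants** (within a locus): single linkage on pairwise monomer
  distance (100 − identity), cut at the largest merge-distance gap with
  k ≤ 3 and a minimum separation of 5 identity points (below that a
  locus is called homogeneous).
- **Alternation**: the statistic is the number of adjacent monomer pairs
  with different subvariant labels; the null permutes the label multiset
  (seeded generator); the one-sided p-value carries the add-one
  correction (b+1)/(n_perm+1). With all-equal labels no alternation
  excess is possible and p = 1 by definition.
- **Census**: loci binned by middle-monomer count into 4–5, 6–8, ≥ 9.
- **Microsatellites**: the (TC)n region inside the SINE body is measured
  per copy as the maximal uninterrupted motif run at/after the anchor
  position mapped through the copy-to-consensus alignment (anchor
  default: consensus position 110, configurable — the anchor is a
  convention, not a property the code derives). Motif classes are
  canonicalized to the lexicographically smallest rotation of the
  primitive root or its reverse complement, so (ATGGA)n, (TGGAA)n and
  (GGAAT)n collapse to one class.

## Orthology

For each locus with ≥ 2 repeat units in genome A, both 500-nt flanks are
located in genome B (14-mer seeded; windows backed by fewer than two
seeds are noise and skipped; placements require ≥ 80 % identity over
≥ half the flank). A pairing needs a co-linear placement: same contig,
same orientation, left flank before right, span ≤ 100 kb. Equal combined
identities that remain tied yield no call rather than an arbitrary one.
The enclosed interval in B is re-tiled with locus A's own unit — the
comparison is unit-anchored, not an independent variant call — and the
monomer-count difference is reported. Flank length, identity threshold
and span bound are declared defaults, exposed as flags.

## Chromosomal profiling

- Telomere tracts: maximal chains of exact motif occurrences (either
  orientation) with occurrence gaps ≤ 3 motif lengths, accepted at
  ≥ 1000 units and ≤ 5 % interrupted positions.
- Motif scans (e.g. the CENP-B box) run under IUPAC degeneracy with a
  mismatch budget on both strands; the shipped CENP-B 17-mer is an
  external constant from the centromere literature, configurable.
- Centromeric-satellite blocks reuse the hit-merge-tile machinery with
  the satellite consensus as its own unit; at high divergence an array
  fragments into sub-blocks wherever a unit dips below threshold, so
  detection is judged collectively over a region.
- Subtelomeric enrichment: each feature's distance to the nearer
  chromosome end is normalized by half the chromosome length; the
  statistic is the median normalized distance of the control class minus
  that of the sSat class, with a label-permutation null and add-one
  correction. A median-based statistic keeps the test robust to the
  heavy-tailed positions of real repeat tracks.

## Synthetic genomes

The simulator composes an i.i.d. background (default GC 0.42,
squamate-like) and overwrites it with planted features at uniform
non-overlapping positions (bounded rejection sampling, 1000 retries), so
truth intervals slice the emitted FASTA byte-for-byte. Divergence is
per-site: substitutions pick uniformly among the three alternative bases
(so expected identity after rate *r* is exactly 1 − *r*; the
Jukes–Cantor-like choice is the simplest defensible model given no
empirical divergence spectrum for these elements), and indels are
geometric with configurable mean. Arrays are planted monomer-by-monomer
(independent or serial divergence) with exact breakpoint truth; terminal
monomers carry configurable extensions toward the SINE termini, matching
the canonical sSat architecture. The packaged 300-nt "Squam3-like"
consensus is synthetic — sampled background with structural landmarks
(tRNA-like head, body with a (TC)8 tract at position 110, LDR, A-rich
tail) — and contains no real SINE sequence.

Ortholog pairs share a base layout of arrays separated by unique
spacers; genome B's array counts are jittered (floored at one monomer,
grown by replicating an interior monomer, shrunk from the 3′ side so
terminal extensions stay terminal) and both genomes are then mutated
per segment, keeping truth coordinates exact. The default test regime
places 74 % of pairs at equal counts and 14 % at |Δ| = 1, with the
remaining 12 % spread over |Δ| = 2–15 — the same-count-dominated regime
expected between two closely related assemblies.

What the simulator does *not* model: real base composition and CpG
decay, lineage-specific SINE subfamily histories, assembly artifacts
other than N runs, and segmental duplications of flanks. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on any particular real assembly.

## Statistical checks and problem sizes

Permutation tests are validated for type-I error over 500 null
simulations at α = 0.05 (199 permutations each): the subtelomeric test
uses a continuous statistic and is required to sit inside the two-sided
binomial band; the alternation statistic is integer-valued, so its test
is allowed to be conservative (rate ≤ α + 3 SD) and its null p-values
are additionally checked for uniformity by a KS test.

End-to-end recovery runs on a 5-Mbp two-contig genome with 30 planted
arrays (4–50 monomers, ≤ 10 % divergence) and 200 solo SINE copies;
orthology-regime recovery uses 500 array pairs at 2 % genome divergence;
subfamily recovery uses 10 seeds of 200 copies. These sizes give the
recovery statistics enough resolution for the stated bounds
(sensitivity/precision ≥ 0.95, multinomial CIs at n ≈ 500) while keeping
the whole suite runnable on a laptop in a few minutes.

## Known limitations

- The unit-boundary phase of a perfect tandem array is intrinsically
  ambiguous; the caller reports the phase anchored by the stringent
  consensus alignment, snapped to the array period, which can differ
  from the planted phase by a base or two (the unit *length* is exact).
- Arrays more diverged than ~25 % per monomer fragment into sub-blocks
  at the 60 % tiling threshold; the caller reports the longest coherent
  run rather than attempting to bridge.
- Hit detection requires one intact seed 11-mer; at ≥ 30 % substitution
  divergence a measurable fraction of solo copies carries none and is
  invisible to the search (the retention tests model this explicitly).
- Subfamily refinement assumes roughly balanced subfamilies at the
  group-size scale; heavily skewed mixtures land in one group and are
  averaged into its consensus.
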