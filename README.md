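# sinesat

Discovery and characterization of **SINE-derived satellites (sSats)** in
genome assemblies.

Satellite DNA usually arises without any obvious relationship to other
repeat classes, but in squamate reptiles tandem arrays have been found
whose repeat unit is a sub-region of a SINE retrotransposon. `sinesat`
implements the full computational workflow needed to find and analyse such
elements in an assembly, for researchers studying satellite evolution,
repeat annotation, or the interplay between transposable elements and
tandem repeats:

1. **SINE search** — affine-gap Smith–Waterman of a family consensus
   against the genome (k-mer seeded, both strands), keeping every fragment
   whose span covers ≥ 20 % of the consensus; a strict near-full-length
   filter (> 90 % length, > 65 % identity) feeds subfamily consensus
   refinement (grouping copies ordered by identity into blocks of 100 and
   majority-calling each block).
2. **Locus assembly & tandem calling** — fragments < 100 bp apart are
   merged; merged regions > 500 bp become candidates; the tandem period is
   estimated from repeated k-mers, anchored onto the consensus, and the
   locus is tiled into monomers. A locus with ≥ 4 middle monomers (the
   terminal *leading*/*trailing* monomers may extend further toward the
   SINE termini) is called an sSat.
3. **Profiling** — within-locus monomer identity, genome-wide variant
   clustering by shared repeat unit, locus-level subvariant labelling with
   a permutation test for alternation along the array, per-genome census
   tables, and (TC)n-style microsatellite variation inside SINE bodies
   (with rotation/reverse-complement canonicalization of motifs, e.g.
   ATGGA ≡ TGGAA ≡ (GGAAT)n).
4. **Orthology** — flank-anchored matching of sSat loci between two
   assemblies and the distribution of tandem-count differences.
5. **Chromosomal localization** — telomere tract detection ((TTAGGG)n runs
   of ≥ 1000 units), CENP-B box and degenerate motif scans, centromeric
   satellite block finding, and a label-permutation test for subtelomeric
   enrichment of sSats against a control repeat class.
6. **Synthetic genomes** — a first-class simulator that plants diverged
   SINE copies, tandem arrays with exact monomer breakpoints, telomere
   tracts, satellite blocks, and orthologous genome pairs with jittered
   tandem counts, emitting byte-exact ground truth for every feature.

All genomic coordinates are 0-based half-open (BED convention); positions
on a SINE consensus are reported 1-based inclusive, as in "the unit spans
consensus positions 42–108".

## Worked example

Plant a snake-style satellite (12 tandem copies of the 67-nt consensus
sub-interval 42–108, 5 % per-monomer divergence, terminal monomers
extending toward the SINE termini) and call it back:

```python
from sinesat import (MutationModel, PlantedArraySpec, call_loci,
                     mean_pairwise_identity, label_subvariants)
from sinesat.simulate import (generate_background, plant_ssat_array,
                              squam3_like_consensus)

consensus = squam3_like_consensus()          # 300-nt Squam3-like SINE consensus
genome = generate_background(50_000, gc_fraction=0.42, seed=11)
spec = PlantedArraySpec(
    unit_interval=(42, 108),                 # 67-nt repeat unit
    n_monomers=12,
    per_monomer_model=MutationModel(substitution_rate=0.05, seed=1),
    leading_extension=41, trailing_extension=100,
)
genome, truth = plant_ssat_array(genome, consensus, spec, seed=12)

loci = call_loci(genome, consensus)
locus = loci[0]
print(f"called {len(loci)} sSat locus at {locus.contig}:{locus.start}-{locus.end}")
print(f"unit interval on consensus: {locus.unit_interval}  "
      f"(length {locus.unit_length} nt)")
print(f"monomers: {locus.n_monomers} ({locus.n_middle} middle), "
      f"roles {''.join(m.role[0].upper() for m in locus.monomers)}")
middles = [m.sequence for m in locus.monomers if m.role == "middle"]
print(f"mean pairwise monomer identity: {mean_pairwise_identity(middles):.1f}%")
ann = label_subvariants(locus, seed=0)
print(f"subvariants: {ann.n_subvariants}, alternation p = {ann.alternation_pvalue:.3f}")
```

Output:

```
called 1 sSat locus at chr1:46678-47625
unit interval on consensus: (42, 108)  (length 67 nt)
monomers: 12 (10 middle), roles LMMMMMMMMMMT
mean pairwise monomer identity: 91.1%
subvariants: 1, alternation p = 1.000
```

The caller recovers the planted unit exactly (positions 42–108, 67 nt),
classifies the terminal monomers as leading/trailing, and the measured
monomer homogeneity (91.1 %) reflects the planted 5 % per-monomer
divergence. The single subvariant and alternation p-value of 1 say the
array is homogeneous rather than built from alternating monomer classes.

## Command line

```sh
sinesat simulate  --config sim.yaml --out-fasta g.fa --out-truth truth.bed
sinesat search    --genome g.fa --consensus squam3.fa --out-prefix run
sinesat call      --genome g.fa --consensus squam3.fa --out-prefix run
sinesat run       --config pipeline.yaml          # search + call + profile
sinesat ortho     --genome-a a.fa --genome-b b.fa --consensus squam3.fa --out-prefix rx
sinesat chromprof --genome g.fa --ssat-bed run.ssat.bed12 --sine-bed run.hits.bed --out-prefix cp
```

`sinesat run` writes a report bundle (hits BED6/TSV, sSat BED12 with one
block per monomer, per-locus/variant/subvariant/census TSVs) plus a
manifest with the config hash and seed; the whole pipeline is a pure
function of (inputs, config, seed).

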