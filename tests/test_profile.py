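"""sSat characterization: homogeneity, variants, subvariants, alternation,
census, and SINE-internal microsatellites."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sinesat._align import revcomp
from sinesat.profile import (
    alternation_test,
    canonical_motif,
    cluster_variants,
    label_subvariants,
    mean_pairwise_identity,
    scan_internal_microsat,
    summarize_genome,
)
from sinesat.simulate import generate_background, mutate
from sinesat.tandem import classify_monomers
from sinesat.types import Monomer, MutationModel, SineConsensus, SsatLocus


def make_locus(middle_seqs, unit_interval=(42, 108), locus_id="L1", contig="chr1"):
    """Assemble an SsatLocus from given middle-monomer sequences (plus
    terminal monomers copying the first/last)."""
    seqs = [middle_seqs[0]] + list(middle_seqs) + [middle_seqs[-1]]
    monomers = []
    pos = 0
    for s in seqs:
        monomers.append(Monomer(pos, pos + len(s), "middle", unit_interval, s))
        pos += len(s)
    classify_monomers(monomers)
    return SsatLocus(contig=contig, start=0, end=pos, monomers=monomers,
                     unit_interval=unit_interval, locus_id=locus_id)


class TestMeanPairwiseIdentity:
    def test_identical_is_100(self):
        assert mean_pairwise_identity(["ACGTAC"] * 5) == 100.0

    def test_single_mismatch_67nt(self):
        a = generate_background(67, 0.5, seed=1)
        b = a[:10] + ("A" if a[10] != "A" else "G") + a[11:]
        assert mean_pairwise_identity([a, b]) == pytest.approx(100 * 66 / 67)

    def test_permutation_invariant(self):
        seqs = [generate_background(67, 0.5, seed=s) for s in range(4)]
        v1 = mean_pairwise_identity(seqs)
        v2 = mean_pairwise_identity(list(reversed(seqs)))
        assert v1 == pytest.approx(v2)
        assert v1 < 100.0

    def test_requires_two(self):
        with pytest.raises(ValueError):
            mean_pairwise_identity(["ACGT"])

    def test_matches_closed_form_expectation(self):
        # independent copies at rate r differ per site with probability
        # 2r(1-r) + (2/3)r^2 (substitutions never preserve the base)
        r = 0.05
        unit = generate_background(67, 0.5, seed=2)
        monomers = [mutate(unit, MutationModel(substitution_rate=r, seed=100 + i))
                    for i in range(20)]
        expected = 100 * (1 - (2 * r * (1 - r) + r * r * 2 / 3))
        got = mean_pairwise_identity(monomers)
        sd = 100 * math.sqrt(0.1 * 0.9 / 67) / math.sqrt(190 / 10)
        assert abs(got - expected) < max(3 * sd, 1.5)

    def test_longer_loci_more_homogeneous_under_enforced_homogenization(self):
        # the generator couples divergence to array length (serial
        # homogenization proxy); stratified similarity must be monotone
        unit = generate_background(67, 0.5, seed=3)
        strata = []
        for n, r in ((4, 0.10), (8, 0.05), (16, 0.02)):
            vals = []
            for rep in range(5):
                monomers = [mutate(unit, MutationModel(substitution_rate=r,
                                                       seed=rep * 100 + i))
                            for i in range(n)]
                vals.append(mean_pairwise_identity(monomers))
            strata.append(np.mean(vals))
        assert strata[0] < strata[1] < strata[2]


class TestClusterVariants:
    def test_single_planted_unit_single_variant(self):
        unit = generate_background(67, 0.5, seed=4)
        loci = [make_locus([unit] * 6, locus_id=f"L{i}") for i in range(5)]
        variants = cluster_variants(loci)
        assert len(variants) == 1
        assert variants[0].fraction_of_loci == 1.0
        assert len(variants[0].member_loci) == 5

    def test_disjoint_units_two_variants(self, consensus):
        unit1 = consensus.sequence[41:108]
        unit2 = consensus.sequence[150:260]
        loci = [make_locus([unit1] * 6, (42, 108), f"A{i}") for i in range(4)]
        loci += [make_locus([unit2] * 6, (151, 260), f"B{i}") for i in range(3)]
        variants = cluster_variants(loci)
        assert len(variants) == 2
        assert sorted(len(v.member_loci) for v in variants) == [3, 4]
        big = max(variants, key=lambda v: len(v.member_loci))
        assert all(m.startswith("A") for m in big.member_loci)

    def test_5prime_truncation_variants_recovered(self, consensus):
        # three variants split by 16- and 23-nt truncations at the unit 5'
        # end, in 27/20/19-style proportions
        base = consensus.sequence
        specs = [((42, 108), 12), ((58, 108), 9), ((65, 108), 8)]
        loci = []
        for vi, ((lo, hi), count) in enumerate(specs):
            unit = base[lo - 1:hi]
            for i in range(count):
                loci.append(make_locus([unit] * 6, (lo, hi), f"V{vi}_{i}"))
        # nested truncations stay >80% identical globally, so the unit
        # boundary rule is the discriminator; the smallest offset between
        # variants is 7 nt, hence a tolerance below that
        variants = cluster_variants(loci, boundary_tolerance=5)
        assert len(variants) == 3
        starts = sorted(v.unit_interval[0] for v in variants)
        assert starts[1] - starts[0] == 16
        assert starts[2] - starts[0] == 23


class TestLabelSubvariants:
    def test_homogeneous_locus_one_subvariant(self):
        unit = generate_background(67, 0.5, seed=5)
        ann = label_subvariants(make_locus([unit] * 10))
        assert ann.n_subvariants == 1
        assert ann.labels == [1] * 10
        assert not ann.is_alternating

    def test_alternating_two_subvariants(self):
        unit = generate_background(67, 0.5, seed=6)
        sub2 = mutate(unit, MutationModel(substitution_rate=0.05, seed=7))
        middles = [unit if i % 2 == 0 else sub2 for i in range(20)]
        ann = label_subvariants(make_locus(middles), seed=1)
        assert ann.n_subvariants == 2
        assert ann.labels == [1 if i % 2 == 0 else 2 for i in range(20)]
        assert ann.is_alternating
        assert ann.alternation_pvalue <= 0.001

    def test_three_interleaved_subvariants(self):
        unit = generate_background(67, 0.5, seed=8)
        subs = [unit,
                mutate(unit, MutationModel(substitution_rate=0.06, seed=11)),
                mutate(unit, MutationModel(substitution_rate=0.06, seed=17))]
        truth = [i % 3 for i in range(21)]
        middles = [subs[t] for t in truth]
        ann = label_subvariants(make_locus(middles), seed=2)
        assert ann.n_subvariants <= 3
        best = max(
            sum(int(perm[t] == l) for t, l in zip(truth, ann.labels))
            for perm in permutations(sorted(set(ann.labels)), 3)
        ) / len(truth) if ann.n_subvariants == 3 else 0
        assert ann.n_subvariants == 3 and best >= 0.9


class TestAlternationTest:
    def test_constant_labels_p_one(self):
        assert alternation_test([1] * 10) == 1.0

    def test_strict_alternation_small_p(self):
        labels = [1, 2] * 10
        p = alternation_test(labels, n_perm=10_000, seed=3)
        assert p <= 0.001

    def test_null_pvalues_uniform(self):
        # KS test vs uniform over 200 random-label runs at alpha 0.01
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            labels = rng.integers(1, 3, size=20).tolist()
            if len(set(labels)) < 2:
                continue
            pvals.append(alternation_test(labels, n_perm=999,
                                          seed=int(rng.integers(0, 2**31 - 1))))
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01


class TestSummarizeGenome:
    def test_binning(self):
        loci = [make_locus([("ACGT" * 17)[:67]] * n, locus_id=f"L{n}")
                for n in (4, 5, 6, 8, 9, 20)]
        s = summarize_genome(loci, sine_hits=[], genome={"chr1": "ACGT" * 100})
        assert (s.loci_4_5, s.loci_6_8, s.loci_9_plus) == (2, 2, 2)
        assert s.total_loci == 6
        assert s.genome_size == 400

    def test_empty(self):
        s = summarize_genome([], [], {"chr1": "ACGT"})
        assert s.total_loci == 0
        assert (s.loci_4_5, s.loci_6_8, s.loci_9_plus) == (0, 0, 0)


class TestScanInternalMicrosat:
    def _copy_with_run(self, consensus, k):
        # replace the consensus's entire (TC)n tract (anchor 110, 16 nt)
        # with (TC)k terminated by GG so the run cannot extend
        seq = consensus.sequence
        return seq[:109] + "TC" * k + "GG" + seq[125:]

    def test_planted_run_measured_exactly(self, consensus):
        copy = self._copy_with_run(consensus, 12)
        assert scan_internal_microsat([copy], consensus)[0] == 12

    def test_copy_without_motif_scores_zero(self, consensus):
        # entire anchor neighborhood replaced by TC-free sequence
        seq = consensus.sequence
        copy = seq[:100] + "AAGG" * 8 + seq[132:]
        assert scan_internal_microsat([copy], consensus)[0] == 0

    def test_geometric_run_lengths_recovered(self, consensus):
        # planted geometric run lengths; measured distribution passes a
        # chi-square goodness-of-fit against the planted law at alpha 0.01
        rng = np.random.default_rng(11)
        p = 0.25
        planted = [int(rng.geometric(p)) for _ in range(200)]
        copies = [self._copy_with_run(consensus, min(k, 40)) for k in planted]
        measured = scan_internal_microsat(copies, consensus)
        assert measured == [min(k, 40) for k in planted]
        # GoF of the planted sample itself vs the geometric pmf
        kmax = 8
        obs = np.bincount(np.minimum(planted, kmax), minlength=kmax + 1)[1:]
        exp = np.array([200 * p * (1 - p) ** (k - 1) for k in range(1, kmax)]
                       + [200 * (1 - p) ** (kmax - 1)])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=kmax - 1)


class TestCanonicalMotif:
    def brute(self, motif):
        # independent brute-force oracle over all rotations of the
        # primitive root and its reverse complement
        n = len(motif)
        for d in range(1, n + 1):
            if n % d == 0 and motif == motif[:d] * (n // d):
                root = motif[:d]
                break
        forms = []
        for s in (root, revcomp(root)):
            forms += [s[i:] + s[:i] for i in range(len(s))]
        return min(forms)

    def test_overlapping_pentamers_collapse(self):
        assert canonical_motif("ATGGA") == canonical_motif("TGGAA") \
            == canonical_motif("GGAAT") == self.brute("GGAAT")

    def test_tc_class(self):
        forms = {canonical_motif(m) for m in ("TC", "CT", "GA", "AG")}
        assert len(forms) == 1

    def test_homopolymer_reduces(self):
        assert canonical_motif("AAAAA") == "A"

    @given(st.text(alphabet="ACGT", min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_class_invariance_and_brute_force_agreement(self, motif):
        c = canonical_motif(motif)
        assert c == self.brute(motif)
        assert canonical_motif(c) == c
        assert canonical_motif(revcomp(motif)) == c
        for i in range(len(motif)):
            assert canonical_motif(motif[i:] + motif[:i]) == c
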