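"""Synthetic-genome generator: determinism, truth conservation, divergence
expectations."""

import math

import numpy as np
import pytest

from sinesat.simulate import (
    categorical,
    generate_background,
    generate_ortholog_pair,
    make_ortholog_base,
    mutate,
    plant_motif_tract,
    plant_sine_copies,
    plant_ssat_array,
)
from sinesat.types import MutationModel, PlantedArraySpec, TruthRecord


class TestBackground:
    def test_deterministic_under_seed(self):
        a = generate_background(1000, 0.5, seed=7)
        b = generate_background(1000, 0.5, seed=7)
        assert a == b and len(a) == 1000

    def test_gc_fraction_within_binomial_bound(self):
        # 3 SD of binomial(100000, 0.40): sd = sqrt(p q / n)
        seq = generate_background(100_000, 0.40, seed=1)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        sd = math.sqrt(0.40 * 0.60 / 100_000)
        assert abs(gc - 0.40) < 3 * sd

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            generate_background(0, 0.5, seed=1)


class TestMutate:
    def test_zero_rates_identity(self):
        seq = generate_background(500, 0.5, seed=3)
        assert mutate(seq, MutationModel()) == seq

    def test_substitution_only_identity_matches_expectation(self):
        # substitutions always change the base, so expected position-wise
        # identity is exactly 1 - rate (verified by brute force below)
        seq = generate_background(10_000, 0.5, seed=4)
        out = mutate(seq, MutationModel(substitution_rate=0.10, seed=9))
        assert len(out) == len(seq)
        ident = sum(a == b for a, b in zip(seq, out)) / len(seq)
        sd = math.sqrt(0.10 * 0.90 / 10_000)
        assert abs(ident - 0.90) < 3 * sd

    def test_near_total_deletion_leaves_near_empty(self):
        seq = "ACGT" * 50
        out = mutate(seq, MutationModel(deletion_rate=0.99, seed=5))
        assert len(out) < 10

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            MutationModel(substitution_rate=1.0)
        with pytest.raises(ValueError):
            MutationModel(substitution_rate=0.6, deletion_rate=0.5)

    def test_deterministic_under_seed(self):
        seq = generate_background(2000, 0.5, seed=6)
        m = MutationModel(substitution_rate=0.1, insertion_rate=0.02,
                          deletion_rate=0.02, indel_length_mean=2.0, seed=11)
        assert mutate(seq, m) == mutate(seq, m)


class TestPlantSineCopies:
    def test_exact_copy_without_mutation(self, consensus):
        g = generate_background(5000, 0.42, seed=1)
        g, truth = plant_sine_copies(g, consensus, 1, MutationModel(),
                                     tail_motif="", seed=2)
        t = truth[0]
        planted = g[t.start:t.end]
        if t.strand == "-":
            from sinesat import revcomp
            planted = revcomp(planted)
        assert planted == consensus.sequence

    def test_count_conservation_and_non_overlap(self, consensus):
        g = generate_background(500_000, 0.42, seed=2)
        g, truth = plant_sine_copies(g, consensus, 50,
                                     MutationModel(substitution_rate=0.1), seed=3)
        assert len(truth) == 50
        ivs = sorted((t.start, t.end) for t in truth)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_truth_slices_reproduce_planted_sequences(self, consensus):
        # truth conservation: re-planting with the same seed reproduces the
        # same genome, and intervals are in-bounds
        g0 = generate_background(100_000, 0.42, seed=4)
        g1, truth1 = plant_sine_copies(g0, consensus, 10,
                                       MutationModel(substitution_rate=0.05), seed=5)
        g2, truth2 = plant_sine_copies(g0, consensus, 10,
                                       MutationModel(substitution_rate=0.05), seed=5)
        assert g1 == g2
        assert [(t.start, t.end) for t in truth1] == [(t.start, t.end) for t in truth2]
        assert all(0 <= t.start < t.end <= len(g1) for t in truth1)


class TestPlantArray:
    def test_snake_unit_array_length(self, consensus, snake_unit_interval):
        # 10 x 67-nt unit, no extensions, zero divergence -> 670 nt
        g = generate_background(5000, 0.42, seed=1)
        spec = PlantedArraySpec(unit_interval=snake_unit_interval, n_monomers=10)
        g, truth = plant_ssat_array(g, consensus, spec, seed=2)
        assert truth.end - truth.start == 670
        unit = consensus.sequence[41:108]
        assert g[truth.start:truth.end] == unit * 10
        assert truth.n_monomers == 10
        assert len(truth.monomer_breakpoints) == 11

    def test_two_monomer_boundary(self, consensus, snake_unit_interval):
        g = generate_background(5000, 0.42, seed=3)
        spec = PlantedArraySpec(unit_interval=snake_unit_interval, n_monomers=2,
                                leading_extension=10, trailing_extension=10)
        g, truth = plant_ssat_array(g, consensus, spec, seed=4)
        assert truth.n_monomers == 2
        assert truth.end - truth.start == 2 * 67 + 20

    def test_unit_must_be_shorter_than_sine(self, consensus):
        spec = PlantedArraySpec(unit_interval=(1, 300), n_monomers=5)
        g = generate_background(5000, 0.42, seed=5)
        with pytest.raises(ValueError):
            plant_ssat_array(g, consensus, spec, seed=6)

    def test_mean_monomer_identity_matches_oracle(self, consensus, snake_unit_interval):
        # independent divergence at rate r: two copies differ per site with
        # prob 2r(1-r) + r^2 * 2/3 (both substituted, 1/3 chance same base)
        r = 0.05
        spec = PlantedArraySpec(
            unit_interval=snake_unit_interval, n_monomers=20,
            per_monomer_model=MutationModel(substitution_rate=r, seed=0))
        g = generate_background(10_000, 0.42, seed=7)
        g, truth = plant_ssat_array(g, consensus, spec, seed=8)
        bp = truth.monomer_breakpoints
        monomers = [g[a:b] for a, b in zip(bp, bp[1:])]
        idents = []
        for i in range(len(monomers)):
            for j in range(i + 1, len(monomers)):
                a, b = monomers[i], monomers[j]
                idents.append(sum(x == y for x, y in zip(a, b)) / len(a))
        expected = 1 - (2 * r * (1 - r) + r * r * 2 / 3)
        n_pairs = len(idents)
        sd = math.sqrt(expected * (1 - expected) / (67 * n_pairs)) * 3  # loose bound
        assert abs(np.mean(idents) - expected) < max(3 * sd, 0.01)


class TestMotifTract:
    def test_telomere_at_contig_end(self):
        g = generate_background(20_000, 0.42, seed=1)
        g, truth = plant_motif_tract(g, "TTAGGG", 1000, location="end")
        assert truth.end - truth.start == 6000
        assert truth.end == len(g)
        assert g[truth.start:truth.end] == "TTAGGG" * 1000
        assert truth.kind == "telomere_tract"

    def test_internal_microsat(self):
        g = generate_background(5000, 0.42, seed=2)
        g, truth = plant_motif_tract(g, "GGAAT", 200, location=1000)
        assert truth.end - truth.start == 1000
        assert truth.kind == "microsat_tract"

    def test_zero_repeats_rejected(self):
        g = generate_background(1000, 0.42, seed=3)
        with pytest.raises(ValueError):
            plant_motif_tract(g, "TTAGGG", 0)


class TestOrthologPair:
    def test_degenerate_jitter_identical_genomes(self, consensus, snake_unit_interval):
        base = make_ortholog_base(consensus, 5, snake_unit_interval, seed=1)
        ga, ta, gb, tb, pairs = generate_ortholog_pair(
            base, jitter=lambda rng: 0, model=MutationModel(), seed_a=1, seed_b=2)
        assert ga == gb
        assert all(p.delta == 0 for p in pairs)

    def test_floor_rule(self, consensus, snake_unit_interval):
        from sinesat.simulate import constant, uniform_int
        base = make_ortholog_base(consensus, 5, snake_unit_interval,
                                  count_dist=constant(4), seed=2)
        ga, ta, gb, tb, pairs = generate_ortholog_pair(
            base, jitter=constant(-5), model=MutationModel(), seed_a=1, seed_b=2)
        assert all(p.count_b == 1 for p in pairs)

    def test_jitter_distribution_recovered_in_truth(self, consensus, snake_unit_interval):
        # planted regime: P(0)=0.74, P(+/-1)=0.07 each, rest over +/-2..15
        pmf = {0: 0.74, 1: 0.07, -1: 0.07}
        rest = 0.12 / 28
        for d in range(2, 16):
            pmf[d] = rest
            pmf[-d] = rest
        base = make_ortholog_base(consensus, 300, snake_unit_interval,
                                  count_dist=lambda rng: int(rng.integers(4, 9)),
                                  seed=3, spacer_len=300)
        ga, ta, gb, tb, pairs = generate_ortholog_pair(
            base, jitter=categorical(pmf), model=MutationModel(), seed_a=4, seed_b=5)
        frac0 = sum(p.delta == 0 for p in pairs) / len(pairs)
        frac1 = sum(abs(p.delta) == 1 for p in pairs) / len(pairs)
        n = len(pairs)
        assert abs(frac0 - 0.74) < 3 * math.sqrt(0.74 * 0.26 / n)
        # floor can only shrink large negative jitters, not |delta|=1 draws
        assert abs(frac1 - 0.14) < 3 * math.sqrt(0.14 * 0.86 / n) + 0.02

    def test_truth_intervals_slice_back(self, consensus, snake_unit_interval):
        base = make_ortholog_base(consensus, 10, snake_unit_interval, seed=6)
        ga, ta, gb, tb, pairs = generate_ortholog_pair(
            base, jitter=categorical({0: 0.5, 1: 0.25, -1: 0.25}),
            model=MutationModel(substitution_rate=0.02), seed_a=7, seed_b=8)
        for truth, genome in ((ta, ga), (tb, gb)):
            for t in truth:
                assert 0 <= t.start < t.end <= len(genome)
                bp = t.monomer_breakpoints
                assert bp[0] == t.start and bp[-1] == t.end
                assert all(a < b for a, b in zip(bp, bp[1:]))


class TestTruthRecord:
    def test_breakpoints_must_increase(self):
        with pytest.raises(ValueError):
            TruthRecord("chr1", 0, 100, "ssat_array",
                        monomer_breakpoints=[0, 50, 40, 100])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            TruthRecord("chr1", 0, 100, "mystery")
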