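"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from sinesat.simulate import generate_background, plant_ssat_array, squam3_like_consensus
from sinesat.types import MutationModel, PlantedArraySpec


@pytest.fixture(scope="session")
def consensus():
    """The synthetic Squam3-like 300-nt SINE consensus used throughout."""
    return squam3_like_consensus()


@pytest.fixture(scope="session")
def snake_unit_interval():
    """The snake-style repeat unit: consensus positions 42-108 (67 nt)."""
    return (42, 108)


@pytest.fixture(scope="session")
def perfect_array_genome(consensus, snake_unit_interval):
    """20-kb genome with one zero-divergence 10-monomer array with terminal
    extensions, plus its truth record."""
    g = generate_background(20_000, 0.42, seed=2)
    spec = PlantedArraySpec(unit_interval=snake_unit_interval, n_monomers=10,
                            leading_extension=41, trailing_extension=100)
    g, truth = plant_ssat_array(g, consensus, spec, seed=5)
    return g, truth, spec


def pairwise_identity_ungapped(a: str, b: str) -> float:
    """Position-wise identity for equal-length sequences (test oracle)."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def loci_from_truth(truth, unit_interval=(42, 108)):
    """Build SsatLocus objects from planted array truth records."""
    from sinesat.tandem import classify_monomers
    from sinesat.types import Monomer, SsatLocus

    loci = []
    for t in truth:
        if t.kind != "ssat_array":
            continue
        bp = t.monomer_breakpoints
        monomers = [Monomer(a, b, "middle", unit_interval, "")
                    for a, b in zip(bp, bp[1:])]
        classify_monomers(monomers)
        loci.append(SsatLocus(contig=t.contig, start=t.start, end=t.end,
                              monomers=monomers, unit_interval=unit_interval,
                              locus_id=f"{t.contig}:{t.start}-{t.end}"))
    return loci
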