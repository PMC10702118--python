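"""Synthetic squamate-like genomes with planted repeat structures.

Provides ground truth for every downstream stage: interspersed diverged
SINE copies (5'-truncated, simple-repeat tailed, both strands), tandem
arrays of a SINE sub-region with longer terminal monomers, telomeric
(TTAGGG)n tracts, pericentromeric satellite blocks, and pairs of genomes
sharing orthologous arrays with jittered tandem counts.

Placement is uniform with bounded rejection retries so planted features
never overlap; planted features overwrite the i.i.d. background in place,
so every truth interval slices the emitted sequence back out
byte-for-byte.  All randomness flows through ``numpy.random.default_rng``
seeded explicitly: identical seeds give identical genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import encode, revcomp
from .types import MutationModel, PlantedArraySpec, SineConsensus, TruthRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Raised when a feature cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# distributions: callables rng -> int


def constant(value: int):
    return lambda rng: value


def uniform_int(lo: int, hi: int):
    """Uniform integer on [lo, hi] inclusive."""
    return lambda rng: int(rng.integers(lo, hi + 1))


def geometric(mean: float):
    """Geometric on {1, 2, ...} with the given mean (>= 1)."""
    p = 1.0 / max(mean, 1.0)
    return lambda rng: int(rng.geometric(p))


def categorical(pmf: dict[int, float]):
    """Discrete distribution over integer outcomes with given probabilities."""
    keys = np.array(sorted(pmf), dtype=np.int64)
    probs = np.array([pmf[k] for k in sorted(pmf)], dtype=float)
    probs = probs / probs.sum()
    return lambda rng: int(rng.choice(keys, p=probs))


def _draw(dist, rng) -> int:
    if dist is None:
        return 0
    if isinstance(dist, (int, np.integer)):
        return int(dist)
    return int(dist(rng))


# ---------------------------------------------------------------------------
# background and mutation


def generate_background(length: int, gc_fraction: float = 0.42, seed: int = 0) -> str:
    """I.i.d. random sequence with the given expected GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def mutate(seq: str, model: MutationModel, rng: np.random.Generator | None = None) -> str:
    """Apply per-site substitutions and geometric-length indels.

    Each site independently: substituted with ``substitution_rate`` (to one
    of the three alternative bases, uniformly), starts a deletion run with
    ``deletion_rate``, or receives an insertion of random bases before it
    with ``insertion_rate``.  Non-ACGT sites (N runs) are never substituted.
    Deterministic given ``model.seed`` (or an explicit generator).
    """
    if not seq:
        raise ValueError("mutate requires a non-empty sequence")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = len(seq)
    ps, pd, pi = model.substitution_rate, model.deletion_rate, model.insertion_rate
    codes = encode(seq).copy()
    u = rng.random(n)
    # substitutions (vectorized; skip non-ACGT)
    sub_mask = (u < ps) & (codes < 4)
    n_sub = int(sub_mask.sum())
    if n_sub:
        offsets = rng.integers(1, 4, size=n_sub)
        codes[sub_mask] = (codes[sub_mask] + offsets) % 4
    out = np.where(codes < 4, _BASES[np.minimum(codes, 3)],
                   np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
    if pd == 0.0 and pi == 0.0:
        return out.tobytes().decode("ascii")
    del_mask = (u >= ps) & (u < ps + pd)
    ins_mask = (u >= ps + pd) & (u < ps + pd + pi)
    p_geo = 1.0 / max(model.indel_length_mean, 1.0)
    keep = np.ones(n, dtype=bool)
    for i in np.nonzero(del_mask)[0]:
        run = int(rng.geometric(p_geo))
        keep[i:i + run] = False
    pieces: list[bytes] = []
    prev = 0
    seq_bytes = out.tobytes()
    for i in np.nonzero(ins_mask)[0]:
        run = int(rng.geometric(p_geo))
        ins = _BASES[rng.integers(0, 4, size=run)].tobytes()
        pieces.append(bytes(b for j, b in enumerate(seq_bytes[prev:i], prev) if keep[j]))
        pieces.append(ins)
        prev = int(i)
    pieces.append(bytes(b for j, b in enumerate(seq_bytes[prev:], prev) if keep[j]))
    return b"".join(pieces).decode("ascii")


# ---------------------------------------------------------------------------
# planting


def _place(
    rng: np.random.Generator,
    genome_len: int,
    feat_len: int,
    occupied: list[tuple[int, int]],
    max_retries: int = 1000,
) -> int:
    """Uniform non-overlapping start position, bounded rejection sampling."""
    if feat_len > genome_len:
        raise PlacementError("feature longer than genome")
    for _ in range(max_retries):
        pos = int(rng.integers(0, genome_len - feat_len + 1))
        if all(pos + feat_len <= s or pos >= e for s, e in occupied):
            return pos
    raise PlacementError(f"could not place feature of length {feat_len} after {max_retries} tries")


def _splice(genome: str, pos: int, insert: str) -> str:
    """Overwrite genome[pos : pos+len(insert)] with the planted sequence."""
    return genome[:pos] + insert + genome[pos + len(insert):]


def build_sine_copy(
    consensus: SineConsensus,
    model: MutationModel,
    rng: np.random.Generator,
    truncation_5p: int = 0,
    tail_motif: str = "",
    tail_len: int = 0,
) -> str:
    """One diverged SINE copy: 5'-truncated, mutated, simple-repeat tailed."""
    body = consensus.sequence[truncation_5p:]
    if not body:
        body = consensus.sequence[-1]
    copy = mutate(body, model, rng)
    if tail_motif and tail_len > 0:
        tail = (tail_motif * (tail_len // len(tail_motif) + 1))[:tail_len]
        copy += tail
    return copy


def plant_sine_copies(
    genome: str,
    consensus: SineConsensus,
    n: int,
    model: MutationModel,
    truncation_5p_dist=None,
    tail_motif: str = "A",
    tail_len_dist=None,
    seed: int = 0,
    contig: str = "chr1",
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, list[TruthRecord]]:
    """Plant ``n`` non-overlapping diverged SINE copies on random strands."""
    rng = np.random.default_rng(seed)
    occupied = list(occupied) if occupied else []
    truth: list[TruthRecord] = []
    for i in range(n):
        trunc = max(0, _draw(truncation_5p_dist, rng))
        tail_len = max(0, _draw(tail_len_dist, rng))
        sub = MutationModel(
            model.substitution_rate, model.insertion_rate, model.deletion_rate,
            model.indel_length_mean, seed=int(rng.integers(0, 2**31 - 1)),
        )
        copy = build_sine_copy(consensus, sub, np.random.default_rng(sub.seed),
                               trunc, tail_motif, tail_len)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = copy if strand == "+" else revcomp(copy)
        pos = _place(rng, len(genome), len(planted), occupied)
        genome = _splice(genome, pos, planted)
        occupied.append((pos, pos + len(planted)))
        truth.append(TruthRecord(
            contig=contig, start=pos, end=pos + len(planted), kind="sine_copy",
            strand=strand,
            params={"truncation_5p": trunc, "tail_len": tail_len,
                    "substitution_rate": model.substitution_rate, "index": i},
        ))
    truth.sort(key=lambda t: t.start)
    return genome, truth


def build_array_monomers(
    consensus: SineConsensus, spec: PlantedArraySpec, rng: np.random.Generator
) -> list[str]:
    """Monomer sequences of one tandem array (leading, middles, trailing).

    The leading monomer carries ``leading_extension`` extra consensus
    nucleotides toward the 5' terminus; the trailing monomer extends toward
    the 3' terminus.  Divergence is per-monomer, either independent of the
    unit or serial (each middle monomer derived from the previous one).
    """
    lo, hi = spec.unit_interval
    L = len(consensus)
    if hi > L:
        raise ValueError(f"unit_interval {spec.unit_interval} outside consensus 1..{L}")
    if spec.unit_length >= L:
        raise ValueError("repeat unit must be shorter than the SINE consensus")
    if lo - spec.leading_extension < 1:
        raise ValueError("leading_extension exceeds the remaining 5' consensus span")
    if hi + spec.trailing_extension > L:
        raise ValueError("trailing_extension exceeds the remaining 3' consensus span")
    unit = consensus.sequence[lo - 1:hi]
    lead_ext = consensus.sequence[lo - 1 - spec.leading_extension:lo - 1]
    trail_ext = consensus.sequence[hi:hi + spec.trailing_extension]
    model = spec.per_monomer_model
    monomers: list[str] = []
    source = unit
    for i in range(spec.n_monomers):
        sub_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        mut = source if _model_is_null(model) else mutate(source, model, sub_rng)
        monomers.append(mut)
        if spec.homogeneity_mode == "serial":
            source = mut
    monomers[0] = lead_ext + monomers[0]
    monomers[-1] = monomers[-1] + trail_ext
    return monomers


def _model_is_null(m: MutationModel) -> bool:
    return m.substitution_rate == 0 and m.insertion_rate == 0 and m.deletion_rate == 0


def plant_ssat_array(
    genome: str,
    consensus: SineConsensus,
    spec: PlantedArraySpec,
    seed: int = 0,
    contig: str = "chr1",
    at: int | None = None,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, TruthRecord]:
    """Plant one tandem array; truth carries exact monomer breakpoints."""
    rng = np.random.default_rng(seed)
    monomers = build_array_monomers(consensus, spec, rng)
    array = "".join(monomers)
    occupied = list(occupied) if occupied else []
    pos = at if at is not None else _place(rng, len(genome), len(array), occupied)
    genome = _splice(genome, pos, array)
    breakpoints = [pos]
    for m in monomers:
        breakpoints.append(breakpoints[-1] + len(m))
    truth = TruthRecord(
        contig=contig, start=pos, end=pos + len(array), kind="ssat_array",
        params={"unit_interval": spec.unit_interval, "n_monomers": spec.n_monomers,
                "substitution_rate": spec.per_monomer_model.substitution_rate,
                "leading_extension": spec.leading_extension,
                "trailing_extension": spec.trailing_extension},
        monomer_breakpoints=breakpoints,
    )
    return genome, truth


def plant_motif_tract(
    genome: str,
    motif: str,
    n_repeats: int,
    location: int | str = "end",
    kind: str | None = None,
    contig: str = "chr1",
) -> tuple[str, TruthRecord]:
    """Plant an exact tandem tract of ``motif`` x ``n_repeats``.

    ``location`` is a 0-based start, or "start"/"end" for contig termini
    (the telomere case).
    """
    if n_repeats <= 0:
        raise ValueError("n_repeats must be positive")
    tract = motif * n_repeats
    if len(tract) > len(genome):
        raise PlacementError("tract longer than contig")
    if location == "start":
        pos = 0
    elif location == "end":
        pos = len(genome) - len(tract)
    else:
        pos = int(location)
    if kind is None:
        kind = "telomere_tract" if location in ("start", "end") else "microsat_tract"
    genome = _splice(genome, pos, tract)
    truth = TruthRecord(contig=contig, start=pos, end=pos + len(tract), kind=kind,
                        params={"motif": motif, "n_repeats": n_repeats})
    return genome, truth


def plant_satellite_block(
    genome: str,
    satellite_consensus: str,
    n_tandems: int,
    model: MutationModel = MutationModel(),
    seed: int = 0,
    contig: str = "chr1",
    at: int | None = None,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, TruthRecord]:
    """Plant a (peri)centromeric-style block of tandem satellite units."""
    if n_tandems <= 0:
        raise ValueError("n_tandems must be positive")
    rng = np.random.default_rng(seed)
    units = []
    for _ in range(n_tandems):
        if _model_is_null(model):
            units.append(satellite_consensus)
        else:
            sub_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
            units.append(mutate(satellite_consensus, model, sub_rng))
    block = "".join(units)
    occupied = list(occupied) if occupied else []
    pos = at if at is not None else _place(rng, len(genome), len(block), occupied)
    genome = _splice(genome, pos, block)
    breakpoints = [pos]
    for u in units:
        breakpoints.append(breakpoints[-1] + len(u))
    truth = TruthRecord(contig=contig, start=pos, end=pos + len(block),
                        kind="centromeric_block",
                        params={"n_tandems": n_tandems,
                                "substitution_rate": model.substitution_rate},
                        monomer_breakpoints=breakpoints)
    return genome, truth


# ---------------------------------------------------------------------------
# reference consensus used across tests and examples


def squam3_like_consensus(length: int = 300, seed: int = 20230, tc_anchor: int = 110,
                          tc_repeats: int = 8) -> SineConsensus:
    """A synthetic stand-in for a snake Squam3-like SINE consensus.

    300 nt: tRNA-like head (1-100), body (101-250) carrying a (TC)n
    microsatellite region at ``tc_anchor``, LINE-derived region (251-290)
    and an A-rich tail (291-300).  Purely synthetic — sampled background
    with the structural landmarks planted, no real SINE sequence.
    """
    seq = list(generate_background(length, gc_fraction=0.45, seed=seed))
    tc = "TC" * tc_repeats
    seq[tc_anchor - 1:tc_anchor - 1 + len(tc)] = tc
    seq[length - 10:] = "A" * 10
    return SineConsensus(
        name="Squam3-like", family="Squam3", sequence="".join(seq),
        segments={"head": (1, 100), "box_b": (70, 80), "body": (101, 250),
                  "ldr": (251, 290), "tail": (291, 300)},
    )


# ---------------------------------------------------------------------------
# whole-genome scenario and ortholog pairs


@dataclass
class SimulatedGenome:
    """A simulated multi-contig genome plus its truth set."""

    contigs: dict[str, str]
    truth: list[TruthRecord] = field(default_factory=list)

    def occupied(self, contig: str) -> list[tuple[int, int]]:
        return [(t.start, t.end) for t in self.truth if t.contig == contig]


def simulate_genome(
    consensus: SineConsensus,
    contig_lengths: dict[str, int],
    n_sine_copies: int = 0,
    array_specs: list[PlantedArraySpec] | None = None,
    sine_model: MutationModel = MutationModel(substitution_rate=0.10),
    telomeres: bool = False,
    telomere_repeats: int = 1000,
    gc_fraction: float = 0.42,
    seed: int = 0,
) -> SimulatedGenome:
    """Compose a study-condition genome: background + SINEs + arrays (+ telomeres).

    SINE copies and arrays are spread across contigs proportionally to
    contig length; all features are mutually non-overlapping.
    """
    rng = np.random.default_rng(seed)
    names = list(contig_lengths)
    lengths = np.array([contig_lengths[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    sim = SimulatedGenome(contigs={}, truth=[])
    for i, name in enumerate(names):
        sim.contigs[name] = generate_background(
            contig_lengths[name], gc_fraction, seed=int(rng.integers(0, 2**31 - 1)))
    if telomeres:
        for name in names:
            for loc in ("start", "end"):
                g, t = plant_motif_tract(sim.contigs[name], "TTAGGG", telomere_repeats,
                                         location=loc, contig=name)
                sim.contigs[name] = g
                sim.truth.append(t)
    for spec in array_specs or []:
        name = names[int(rng.choice(len(names), p=weights))]
        g, t = plant_ssat_array(sim.contigs[name], consensus, spec,
                                seed=int(rng.integers(0, 2**31 - 1)), contig=name,
                                occupied=sim.occupied(name))
        sim.contigs[name] = g
        sim.truth.append(t)
    if n_sine_copies:
        counts = rng.multinomial(n_sine_copies, weights)
        for name, k in zip(names, counts):
            if k == 0:
                continue
            g, t = plant_sine_copies(
                sim.contigs[name], consensus, int(k), sine_model,
                truncation_5p_dist=uniform_int(0, len(consensus) // 3),
                tail_motif="A", tail_len_dist=uniform_int(0, 20),
                seed=int(rng.integers(0, 2**31 - 1)), contig=name,
                occupied=sim.occupied(name))
            sim.contigs[name] = g
            sim.truth.extend(t)
    sim.truth.sort(key=lambda t: (t.contig, t.start))
    return sim


@dataclass
class OrthologTruth:
    """Planted ortholog-pair truth: per-array counts in both genomes."""

    pair_id: int
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    count_a: int
    count_b: int

    @property
    def delta(self) -> int:
        return self.count_b - self.count_a


@dataclass
class _BaseLayout:
    segments: list[tuple[str, object]]  # ("bg", seq) or ("array", list of monomer seqs)


def make_ortholog_base(
    consensus: SineConsensus,
    n_arrays: int,
    unit_interval: tuple[int, int],
    count_dist=None,
    monomer_model: MutationModel = MutationModel(),
    spacer_len: int = 2000,
    seed: int = 0,
) -> _BaseLayout:
    """Ancestral layout: arrays separated by unique background spacers."""
    rng = np.random.default_rng(seed)
    count_dist = count_dist or uniform_int(2, 6)
    segments: list[tuple[str, object]] = []
    for i in range(n_arrays):
        bg = generate_background(spacer_len, 0.42, seed=int(rng.integers(0, 2**31 - 1)))
        segments.append(("bg", bg))
        n = max(2, _draw(count_dist, rng))
        spec = PlantedArraySpec(unit_interval=unit_interval, n_monomers=n,
                                per_monomer_model=monomer_model)
        monomers = build_array_monomers(consensus, spec, rng)
        segments.append(("array", monomers))
    segments.append(("bg", generate_background(spacer_len, 0.42,
                                               seed=int(rng.integers(0, 2**31 - 1)))))
    return _BaseLayout(segments=segments)


def _realize(layout_segments, model: MutationModel, rng: np.random.Generator,
             contig: str) -> tuple[str, list[TruthRecord]]:
    parts: list[str] = []
    truth: list[TruthRecord] = []
    pos = 0
    pair_id = 0
    for kind, payload in layout_segments:
        if kind == "bg":
            seg = payload if _model_is_null(model) else mutate(
                payload, model, np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
            parts.append(seg)
            pos += len(seg)
        else:
            breakpoints = [pos]
            mono_out = []
            for m in payload:
                mm = m if _model_is_null(model) else mutate(
                    m, model, np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
                mono_out.append(mm)
                breakpoints.append(breakpoints[-1] + len(mm))
            seg = "".join(mono_out)
            truth.append(TruthRecord(contig=contig, start=pos, end=pos + len(seg),
                                     kind="ssat_array",
                                     params={"pair_id": pair_id, "n_monomers": len(payload)},
                                     monomer_breakpoints=breakpoints))
            pair_id += 1
            parts.append(seg)
            pos += len(seg)
    return "".join(parts), truth


def generate_ortholog_pair(
    base: _BaseLayout,
    jitter,
    model: MutationModel = MutationModel(),
    seed_a: int = 1,
    seed_b: int = 2,
    contig: str = "chr1",
) -> tuple[str, list[TruthRecord], str, list[TruthRecord], list[OrthologTruth]]:
    """Two genomes sharing the base layout with jittered array counts.

    Genome A realizes the base directly; in genome B each array's monomer
    count is ``count_A + jitter`` floored at 1 (grown by repeating the last
    middle monomer before the trailing one, shrunk by dropping middles from
    the 3' side).  Both genomes are then independently mutated per segment
    so truth coordinates stay exact.
    """
    rng_b_layout = np.random.default_rng(seed_b)
    genome_a, truth_a = _realize(base.segments, model, np.random.default_rng(seed_a), contig)
    segments_b: list[tuple[str, object]] = []
    counts: list[tuple[int, int]] = []
    for kind, payload in base.segments:
        if kind == "bg":
            segments_b.append((kind, payload))
            continue
        monomers = list(payload)
        n_a = len(monomers)
        n_b = max(1, n_a + _draw(jitter, rng_b_layout))
        if n_b > n_a:
            # replicate an interior monomer so terminal extensions stay terminal
            src = monomers[-2] if n_a >= 2 else monomers[-1]
            insert_at = max(1, len(monomers) - 1)
            monomers[insert_at:insert_at] = [src] * (n_b - n_a)
        elif n_b < n_a:
            # drop middles from the 3' side, keeping the trailing monomer
            while len(monomers) > n_b:
                if len(monomers) > 1:
                    del monomers[max(1, len(monomers) - 2)]
                else:
                    monomers.pop()
        segments_b.append(("array", monomers))
        counts.append((n_a, n_b))
    genome_b, truth_b = _realize(segments_b, model, np.random.default_rng(seed_b + 1), contig)
    pairs = []
    arrays_a = [t for t in truth_a if t.kind == "ssat_array"]
    arrays_b = [t for t in truth_b if t.kind == "ssat_array"]
    for i, (ta, tb) in enumerate(zip(arrays_a, arrays_b)):
        n_a, n_b = counts[i]
        pairs.append(OrthologTruth(pair_id=i, interval_a=(ta.start, ta.end),
                                   interval_b=(tb.start, tb.end),
                                   count_a=n_a, count_b=n_b))
    return genome_a, truth_a, genome_b, truth_b, pairs
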