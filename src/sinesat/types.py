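"""Domain types shared across the sinesat pipeline.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open ``[start, end)`` throughout, the
BED convention.  Positions on a SINE consensus are reported 1-based
inclusive, the convention used in the satellite-DNA literature when a
repeat unit is said to span, e.g., positions 42-108 of a consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MutationModel:
    """Per-site stochastic divergence model applied to planted sequences.

    Substitutions pick uniformly among the three alternative bases
    (Jukes-Cantor-like).  Indel lengths are geometric with mean
    ``indel_length_mean``; inserted bases are uniform random.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    indel_length_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        total = self.substitution_rate + self.insertion_rate + self.deletion_rate
        if total >= 1.0:
            raise ValueError(f"sum of event rates must be < 1, got {total}")
        if self.indel_length_mean < 1.0:
            raise ValueError("indel_length_mean must be >= 1")


@dataclass(frozen=True)
class SineConsensus:
    """A named SINE family consensus with optional structural segments.

    ``segments`` maps labels such as ``head``, ``box_a``, ``box_b``,
    ``body``, ``ldr``, ``tail`` to 1-based inclusive intervals on the
    consensus.
    """

    name: str
    sequence: str
    family: str = "other"
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("consensus sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        n = len(self.sequence)
        for label, (lo, hi) in self.segments.items():
            if not (1 <= lo <= hi <= n):
                raise ValueError(f"segment {label} ({lo},{hi}) outside consensus 1..{n}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantedArraySpec:
    """Blueprint for one planted SINE-derived tandem array.

    ``unit_interval`` is the consensus sub-region (1-based inclusive) that
    forms the repeat unit; terminal monomers may carry ``leading_extension``
    / ``trailing_extension`` extra consensus nucleotides toward the 5'/3'
    SINE terminus.  ``homogeneity_mode`` selects whether monomers diverge
    independently from the unit ("independent") or serially from the
    previous monomer ("serial").
    """

    unit_interval: tuple[int, int]
    n_monomers: int
    per_monomer_model: MutationModel = MutationModel()
    leading_extension: int = 0
    trailing_extension: int = 0
    homogeneity_mode: str = "independent"

    def __post_init__(self) -> None:
        lo, hi = self.unit_interval
        if lo < 1 or hi < lo:
            raise ValueError(f"bad unit_interval {self.unit_interval}")
        if self.n_monomers < 2:
            raise ValueError("n_monomers must be >= 2")
        if self.leading_extension < 0 or self.trailing_extension < 0:
            raise ValueError("extensions must be >= 0")
        if self.homogeneity_mode not in ("independent", "serial"):
            raise ValueError("homogeneity_mode must be 'independent' or 'serial'")

    @property
    def unit_length(self) -> int:
        return self.unit_interval[1] - self.unit_interval[0] + 1


@dataclass
class TruthRecord:
    """Ground truth for one planted feature (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    kind: str  # sine_copy | ssat_array | telomere_tract | microsat_tract | centromeric_block
    strand: str = "+"
    params: dict = field(default_factory=dict)
    monomer_breakpoints: list[int] = field(default_factory=list)

    KINDS = ("sine_copy", "ssat_array", "telomere_tract", "microsat_tract", "centromeric_block")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown truth kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("empty truth interval")
        bp = self.monomer_breakpoints
        if bp and any(b >= c for b, c in zip(bp, bp[1:])):
            raise ValueError("monomer_breakpoints must be strictly increasing")

    @property
    def n_monomers(self) -> int:
        return max(0, len(self.monomer_breakpoints) - 1)


@dataclass
class SineHit:
    """One local-alignment match of a SINE consensus against the genome.

    ``consensus_interval`` is 1-based inclusive on the consensus (forward
    consensus coordinates regardless of hit strand); ``identity`` is percent
    matching columns over alignment columns.
    """

    contig: str
    start: int
    end: int
    strand: str
    consensus_interval: tuple[int, int]
    identity: float
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hit interval must be non-empty")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def consensus_coverage(self) -> int:
        lo, hi = self.consensus_interval
        return hi - lo + 1


@dataclass
class SubfamilySet:
    """Result of grouping SINE copies into subfamily consensuses."""

    group_consensuses: list[tuple[str, str, int]]  # (group id, consensus, member count)
    alignment_of_consensuses: list[str]  # equal-length rows, one per group

    @property
    def n_members(self) -> int:
        return sum(n for _, _, n in self.group_consensuses)


@dataclass
class CandidateLocus:
    """A merged cluster of SINE hits that may contain a tandem array."""

    contig: str
    start: int
    end: int
    member_hits: list[SineHit]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Monomer:
    """One repeat-unit instance in a tandem array.

    ``start``/``end`` are genome coordinates (0-based half-open);
    ``consensus_interval`` is 1-based inclusive on the source consensus.
    Roles: ``leading`` (5'-terminal), ``middle``, ``trailing`` (3'-terminal).
    """

    start: int
    end: int
    role: str
    consensus_interval: tuple[int, int]
    sequence: str
    identity: float = 100.0


@dataclass
class SsatLocus:
    """A called SINE-derived satellite locus."""

    contig: str
    start: int
    end: int
    monomers: list[Monomer]
    unit_interval: tuple[int, int]
    family: str = "other"
    locus_id: str = ""

    @property
    def unit_length(self) -> int:
        return self.unit_interval[1] - self.unit_interval[0] + 1

    @property
    def n_middle(self) -> int:
        return sum(1 for m in self.monomers if m.role == "middle")

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)


@dataclass
class SsatVariant:
    """A genome-wide class of sSat loci sharing a repeat unit."""

    label: str
    unit_consensus: str
    unit_interval: tuple[int, int]
    member_loci: list[str]
    fraction_of_loci: float


@dataclass
class SubvariantAnnotation:
    """Within-locus monomer classes and the alternation permutation test."""

    locus_id: str
    labels: list[int]  # one label per middle monomer, in array order
    n_subvariants: int
    alternation_pvalue: float
    is_alternating: bool


@dataclass
class GenomeSummary:
    """Per-family satellite census of one genome."""

    family: str
    total_loci: int
    loci_4_5: int
    loci_6_8: int
    loci_9_plus: int
    total_sine_copies: int
    genome_size: int


@dataclass
class OrthologPair:
    """Matched sSat loci in two assemblies, anchored by flanking sequence."""

    locus_a: SsatLocus
    contig_b: str
    start_b: int
    end_b: int
    left_flank_identity: float
    right_flank_identity: float
    inter_flank_span_b: int
    count_a: int
    count_b: int

    @property
    def delta_monomers(self) -> int:
        return self.count_b - self.count_a


@dataclass
class ChromProfile:
    """Feature tracks and subtelomeric-enrichment statistics for one chromosome."""

    chrom: str
    length: int
    tracks: dict[str, list[tuple[int, int, str]]]  # class -> [(start, end, size_fraction)]
    distance_to_end: dict[str, list[int]]
    enrichment_statistic: float | None = None
    enrichment_pvalue: float | None = None
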