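"""Orthologous sSat locus identification between two assemblies.

The three-step flank-matching pipeline: (1) take sSat loci with at least
two repeat units in genome A; (2) locate both flanking sequences of each
locus in genome B, requiring a co-linear placement (same contig, same
orientation, left flank before right, bounded span); (3) compare the
tandem content between the flanks in B against locus A, counting monomers
in B with the same repeat unit as locus A.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._align import KmerIndex, local_align, revcomp, seed_windows
from .tandem import _tile_unit
from .types import OrthologPair, SineConsensus, SsatLocus


@dataclass
class Flanks:
    """Flanking sequences of a locus; truncated flags mark contig-end clipping."""

    left: str
    right: str
    left_truncated: bool = False
    right_truncated: bool = False


def extract_flanks(locus: SsatLocus, genome, flank_len: int = 500) -> Flanks:
    """Sequences immediately outside the locus interval (clipped and
    flagged at contig ends)."""
    contigs = {"chr1": genome} if isinstance(genome, str) else genome
    seq = contigs[locus.contig]
    ls = max(0, locus.start - flank_len)
    left = seq[ls:locus.start]
    right = seq[locus.end:locus.end + flank_len]
    return Flanks(left=left, right=right,
                  left_truncated=len(left) < flank_len,
                  right_truncated=len(right) < flank_len)


@dataclass
class _Placement:
    contig: str
    start: int
    end: int
    strand: str
    identity: float
    score: int


def _best_placements(
    flank: str, index: KmerIndex, min_identity: float, top_n: int = 5,
    min_seeds: int = 2
) -> list[_Placement]:
    """Best local placements of a flank in the indexed genome.

    Windows backed by fewer than ``min_seeds`` exact k-mer seeds are
    skipped: an isolated seed in an unrelated region is noise, while a
    genuinely homologous flank carries many intact k-mers.
    """
    import numpy as np

    placements: list[_Placement] = []
    fl_rev = revcomp(flank)
    for contig, positions in index.query(flank).items():
        seq = index.contigs[contig]
        for ws, we in seed_windows(positions, len(seq), pad=len(flank) + 50,
                                   merge_gap=len(flank)):
            n_seeds = int(np.searchsorted(positions, we) - np.searchsorted(positions, ws))
            if n_seeds < min_seeds:
                continue
            window = seq[ws:we]
            for strand, q in (("+", flank), ("-", fl_rev)):
                aln = local_align(q, window)
                if aln.columns == 0 or aln.identity < min_identity:
                    continue
                qb, qe = aln.query_interval
                if qe - qb < 0.5 * len(flank):
                    continue
                tb, te = aln.target_interval
                placements.append(_Placement(contig, ws + tb, ws + te, strand,
                                             aln.identity, aln.score))
    placements.sort(key=lambda p: (-p.score, p.contig, p.start))
    return placements[:top_n]


def find_ortholog(
    locus_a: SsatLocus,
    genome_a,
    genome_b,
    consensus: SineConsensus,
    flank_len: int = 500,
    min_flank_identity: float = 80.0,
    max_span: int = 100_000,
    min_unit_identity: float = 60.0,
    index_b: KmerIndex | None = None,
    seed_k: int = 14,
) -> OrthologPair | None:
    """Best co-linear placement of both flanks of ``locus_a`` in genome B.

    Returns None when no placement qualifies or when equally scoring
    placements remain tied after the combined-identity tie-break.  The
    enclosed B interval is re-tiled with locus A's repeat unit to obtain
    the monomer-count difference.
    """
    if locus_a.n_monomers < 2:
        raise ValueError("orthology search starts from loci with >= 2 repeat units")
    contigs_b = {"chr1": genome_b} if isinstance(genome_b, str) else genome_b
    if index_b is None:
        index_b = KmerIndex(contigs_b, k=seed_k)
    flanks = extract_flanks(locus_a, genome_a, flank_len)
    if not flanks.left or not flanks.right:
        return None
    lefts = _best_placements(flanks.left, index_b, min_flank_identity)
    rights = _best_placements(flanks.right, index_b, min_flank_identity)
    candidates = []
    for lp in lefts:
        for rp in rights:
            if lp.contig != rp.contig or lp.strand != rp.strand:
                continue
            if lp.strand == "+":
                if rp.start < lp.end:
                    continue
                span = rp.start - lp.end
                interval = (lp.end, rp.start)
            else:
                if lp.start < rp.end:
                    continue
                span = lp.start - rp.end
                interval = (rp.end, lp.start)
            if span > max_span:
                continue
            candidates.append((lp.identity + rp.identity, lp, rp, interval))
    if not candidates:
        return None
    candidates.sort(key=lambda c: -c[0])
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        return None  # ambiguous placement
    combined, lp, rp, (bs, be) = candidates[0]
    ulo, uhi = locus_a.unit_interval
    unit = consensus.sequence[ulo - 1:uhi]
    region = contigs_b[lp.contig][bs:be]
    if lp.strand == "-":
        region = revcomp(region)
    count_b = len(_tile_unit(region, unit, min_unit_identity)) if region else 0
    return OrthologPair(
        locus_a=locus_a, contig_b=lp.contig, start_b=bs, end_b=be,
        left_flank_identity=round(lp.identity, 2),
        right_flank_identity=round(rp.identity, 2),
        inter_flank_span_b=be - bs,
        count_a=locus_a.n_monomers, count_b=count_b,
    )


def match_orthologs(
    loci_a: list[SsatLocus],
    genome_a,
    genome_b,
    consensus: SineConsensus,
    flank_len: int = 500,
    min_flank_identity: float = 80.0,
    max_span: int = 100_000,
    min_unit_identity: float = 60.0,
    seed_k: int = 14,
) -> list[OrthologPair]:
    """Pair every eligible locus of genome A against genome B."""
    contigs_b = {"chr1": genome_b} if isinstance(genome_b, str) else genome_b
    index_b = KmerIndex(contigs_b, k=seed_k)
    pairs = []
    for locus in loci_a:
        if locus.n_monomers < 2:
            continue
        pair = find_ortholog(locus, genome_a, genome_b, consensus,
                             flank_len=flank_len,
                             min_flank_identity=min_flank_identity,
                             max_span=max_span,
                             min_unit_identity=min_unit_identity,
                             index_b=index_b)
        if pair is not None:
            pairs.append(pair)
    return pairs


def delta_distribution(pairs: list[OrthologPair]) -> dict:
    """Histogram of |delta_monomers| plus the fractions with delta 0 and
    |delta| 1."""
    counts = Counter(abs(p.delta_monomers) for p in pairs)
    n = len(pairs)
    return {
        "bins": dict(sorted(counts.items())),
        "fraction_same": counts.get(0, 0) / n if n else 0.0,
        "fraction_delta1": counts.get(1, 0) / n if n else 0.0,
        "n_pairs": n,
    }
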