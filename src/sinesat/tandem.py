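"""Candidate locus assembly, tandem-unit detection, and sSat calling.

Pipeline stages after the SINE hit search:

1. ``merge_hits`` — hits less than ``max_gap`` (default 100 bp) apart are
   merged (transitive, strand-agnostic) into candidate regions.
2. ``select_candidates`` — regions longer than ``min_len`` (default
   500 bp, strict) are candidate satellite loci.
3. ``detect_tandem_units`` — the candidate repeat unit is derived from the
   member hits' consensus intervals (the most frequently overlapped
   consensus sub-interval); the locus is then tiled by iterated glocal
   placement of the unit, and terminal monomers are extended toward the
   SINE termini where the flanking sequence keeps matching the consensus.
4. ``classify_monomers`` / ``call_ssat`` — roles (leading/middle/trailing)
   and the final sSat call with at least ``min_middle_monomers`` middle
   monomers, all adjacent gaps under ``max_gap``.

N runs of at least 20 nt inside a locus are not counted toward inter-
monomer gaps (poorly sequenced loci stay intact).
"""

from __future__ import annotations

import math
import re
from collections import Counter

import numpy as np

from ._align import glocal_best, local_align, revcomp
from .types import CandidateLocus, Monomer, SineConsensus, SineHit, SsatLocus

_N_RUN = re.compile("N{20,}")


def merge_hits(hits: list[SineHit], max_gap: int = 100) -> list[CandidateLocus]:
    """Transitive closure of the "gap < max_gap" relation, per contig.

    The gap between [0,100) and [200,300) is exactly 100 and is *not*
    merged ("less than 100 bp apart").
    """
    by_contig: dict[str, list[SineHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    out: list[CandidateLocus] = []
    for contig in sorted(by_contig):
        chunk = sorted(by_contig[contig], key=lambda h: (h.start, h.end))
        cur = [chunk[0]]
        cur_end = chunk[0].end
        for h in chunk[1:]:
            if h.start - cur_end < max_gap:
                cur.append(h)
                cur_end = max(cur_end, h.end)
            else:
                out.append(CandidateLocus(contig, cur[0].start, cur_end, cur))
                cur = [h]
                cur_end = h.end
        out.append(CandidateLocus(contig, cur[0].start, cur_end, cur))
    return out


def select_candidates(regions: list[CandidateLocus], min_len: int = 500) -> list[CandidateLocus]:
    """Regions strictly longer than ``min_len`` ("longer than 500 bp")."""
    return [r for r in regions if r.length > min_len]


def kmer_period(
    seq: str, k: int = 12, min_period: int = 20, max_period: int | None = None
) -> tuple[int, list[int]] | None:
    """Tandem period of ``seq`` from spacings of repeated k-mers.

    Returns ``(period, repeat_positions)`` where ``repeat_positions`` are
    the start positions of k-mers occurring more than once (they localize
    the repeated region), or None when no periodicity is found.  The
    period is the smallest spacing whose smoothed (+/-2 nt) count is close
    to maximal, which favors the fundamental period over its multiples.
    """
    last: dict[str, int] = {}
    diffs: Counter = Counter()
    repeat_positions: list[int] = []
    max_period = max_period or len(seq)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer or "#" in kmer:
            continue
        if kmer in last:
            d = i - last[kmer]
            if min_period <= d <= max_period:
                diffs[d] += 1
                repeat_positions.append(i)
        last[kmer] = i
    if not diffs:
        return None
    candidates = sorted(diffs)
    best_score = 0
    for d in candidates:
        s = sum(diffs.get(d + o, 0) for o in range(-2, 3))
        if s > best_score:
            best_score = s
    if best_score < 2:
        return None
    for d in candidates:
        s = sum(diffs.get(d + o, 0) for o in range(-2, 3))
        if s >= 0.5 * best_score:
            return d, repeat_positions
    return None  # pragma: no cover


# stringent scoring for unit-boundary refinement: extension requires
# local identity above ~70%, so alignments do not creep through the
# medium-similarity shoulders that permissive hit scoring tolerates
_STRICT_SCORING = {"match": 2, "mismatch": -5, "gap_open": 7, "gap_extend": 3}


def _canonical_unit(
    probe: str, consensus: SineConsensus
) -> tuple[str, tuple[int, int]] | None:
    """Map an arbitrary-phase monomer probe onto the consensus.

    The probe is doubled so that one contiguous copy of the canonical unit
    crosses the junction regardless of the probe's rotation; the best
    strict-scoring local alignment of the consensus against the doubled
    probe delimits the unit interval on the consensus (1-based inclusive).
    """
    tt = probe + probe
    aln = local_align(consensus.sequence, tt, **_STRICT_SCORING)
    qb, qe = aln.query_interval
    span = qe - qb
    if span < 10 or span < 0.5 * len(probe):
        return None
    if span >= len(consensus):
        return None  # tandem of the full SINE, not a shorter-unit satellite
    return consensus.sequence[qb:qe], (qb + 1, qe)


def _tile_unit(seq: str, unit: str, min_identity: float) -> list[tuple[int, int, float]]:
    """Non-overlapping glocal placements of ``unit`` in ``seq``, found by
    iterated best placement with masking; sorted by position."""
    max_dist = max(2, int(len(unit) * 0.45))
    work = list(seq)
    placements: list[tuple[int, int, float]] = []
    cap = len(seq) // max(len(unit) // 2, 1) + 8
    for _ in range(cap):
        res = glocal_best(unit, "".join(work), max_dist=max_dist)
        if res is None:
            break
        s, e, ident = res
        if ident < min_identity:
            break
        placements.append((s, e, ident))
        for i in range(s, e):
            work[i] = "#"
    placements.sort()
    # clip the rare 1-2 nt overlap from alignment slop
    clipped: list[tuple[int, int, float]] = []
    for s, e, ident in placements:
        if clipped and s < clipped[-1][1]:
            s = clipped[-1][1]
            if e - s < len(unit) // 2:
                continue
        clipped.append((s, e, ident))
    return clipped


def _effective_gap(seq: str, lo: int, hi: int) -> int:
    """Gap length between positions lo..hi, discounting N runs >= 20 nt."""
    gap = seq[lo:hi]
    n_len = sum(m.end() - m.start() for m in _N_RUN.finditer(gap))
    return len(gap) - n_len


def _extend_terminal(
    flank: str, cons_part: str, min_identity: float, anchor_tol: int = 3, min_len: int = 8
) -> int:
    """Length of the terminal-monomer extension into ``flank``.

    ``flank`` is the genomic sequence adjacent to the terminal monomer and
    ``cons_part`` the consensus continuation toward the SINE terminus, both
    oriented so the junction is at the *right* end of each.  Returns the
    number of flank nucleotides the extension covers (0 if none).
    """
    if not flank or not cons_part:
        return 0
    aln = local_align(cons_part, flank, **_STRICT_SCORING)
    if aln.columns == 0 or aln.identity < min_identity:
        return 0
    qb, qe = aln.query_interval
    tb, te = aln.target_interval
    # extension must abut the junction on both sequences
    if len(flank) - te > anchor_tol or len(cons_part) - qe > anchor_tol:
        return 0
    if te - tb < min_len:
        return 0
    return len(flank) - tb


def detect_tandem_units(
    locus: CandidateLocus,
    consensus: SineConsensus,
    genome,
    min_unit_identity: float = 60.0,
    max_gap: int = 100,
) -> list[Monomer]:
    """Ordered, non-overlapping monomer tiling of a candidate locus.

    Returns an empty list when the locus has no SINE-anchored periodic
    structure (e.g., a single full-length SINE copy).  Monomer roles are
    set by :func:`classify_monomers`.
    """
    contigs = {"chr1": genome} if isinstance(genome, str) else genome
    seq = contigs[locus.contig][locus.start:locus.end].upper()
    minus = sum(1 for h in locus.member_hits if h.strand == "-") > len(locus.member_hits) / 2
    work_seq = revcomp(seq) if minus else seq
    period = kmer_period(work_seq)
    if period is None:
        return []
    p, repeat_positions = period
    # probe: one period-length window centred on the repeated region
    mid = int(np.median(repeat_positions))
    b = min(max(0, mid - p // 2), max(0, len(work_seq) - p))
    probe = work_seq[b:b + p]
    canon = _canonical_unit(probe, consensus)
    if canon is None:
        return []
    unit, (ulo, uhi) = canon
    placements = _tile_unit(work_seq, unit, min_unit_identity)
    if len(placements) < 2:
        return []
    # keep the longest run of placements whose effective gaps stay < max_gap
    runs: list[list[tuple[int, int, float]]] = [[placements[0]]]
    for p in placements[1:]:
        if _effective_gap(work_seq, runs[-1][-1][1], p[0]) < max_gap:
            runs[-1].append(p)
        else:
            runs.append([p])
    run = max(runs, key=len)
    if len(run) < 2:
        return []
    # terminal extensions toward the SINE termini
    first_s = run[0][0]
    last_e = run[-1][1]
    lead_cons = consensus.sequence[:ulo - 1]
    up_len = min(first_s, len(lead_cons) + 20)
    lead_ext = _extend_terminal(work_seq[first_s - up_len:first_s], lead_cons,
                                min_unit_identity) if up_len > 0 else 0
    trail_cons = consensus.sequence[uhi:]
    down_len = min(len(work_seq) - last_e, len(trail_cons) + 20)
    trail_ext = 0
    if down_len > 0 and trail_cons:
        # mirror so the junction sits at the right end of both sequences
        trail_ext = _extend_terminal(work_seq[last_e:last_e + down_len][::-1],
                                     trail_cons[::-1], min_unit_identity)
    monomers: list[Monomer] = []
    for idx, (s, e, ident) in enumerate(run):
        ms, me = s, e
        if idx == 0:
            ms = s - lead_ext
        if idx == len(run) - 1:
            me = e + trail_ext
        mseq = work_seq[ms:me]
        placed = glocal_best(mseq, consensus.sequence, max_dist=max(2, int(len(mseq) * 0.45)))
        if placed is not None:
            cs, ce, _ = placed
            cons_iv = (cs + 1, ce)
        else:
            cons_iv = (ulo, uhi)
        monomers.append(Monomer(start=ms, end=me, role="middle",
                                consensus_interval=cons_iv, sequence=mseq,
                                identity=round(ident, 2)))
    if minus:
        n = len(work_seq)
        flipped = [Monomer(start=n - m.end, end=n - m.start, role="middle",
                           consensus_interval=m.consensus_interval,
                           sequence=revcomp(m.sequence), identity=m.identity)
                   for m in monomers]
        monomers = sorted(flipped, key=lambda m: m.start)
    for m in monomers:
        m.start += locus.start
        m.end += locus.start
    return classify_monomers(monomers)


def classify_monomers(monomers: list[Monomer]) -> list[Monomer]:
    """Assign roles: first monomer leading, last trailing, rest middle."""
    if not monomers:
        return monomers
    for m in monomers:
        m.role = "middle"
    monomers[0].role = "leading"
    monomers[-1].role = "trailing"
    return monomers


def _mode(values: list[int], prefer) -> int:
    counts = Counter(values)
    top = max(counts.values())
    candidates = [v for v, c in counts.items() if c == top]
    return prefer(candidates)


def call_ssat(
    locus: CandidateLocus,
    monomers: list[Monomer],
    min_middle_monomers: int = 4,
    max_gap: int = 100,
    genome=None,
    family: str = "other",
) -> SsatLocus | None:
    """Emit an sSat locus when there are at least ``min_middle_monomers``
    middle monomers and all adjacent monomer gaps are under ``max_gap``.

    The locus unit interval is the component-wise mode of the middle
    monomers' consensus intervals (ties resolved toward the longer unit).
    """
    if not monomers:
        return None
    middles = [m for m in monomers if m.role == "middle"]
    if len(middles) < min_middle_monomers:
        return None
    seq = None
    if genome is not None:
        contigs = {"chr1": genome} if isinstance(genome, str) else genome
        seq = contigs[locus.contig]
    ordered = sorted(monomers, key=lambda m: m.start)
    for a, b in zip(ordered, ordered[1:]):
        gap = b.start - a.end
        if seq is not None:
            gap = _effective_gap(seq, a.end, b.start)
        if gap >= max_gap:
            return None
    ustart = _mode([m.consensus_interval[0] for m in middles], prefer=min)
    uend = _mode([m.consensus_interval[1] for m in middles], prefer=max)
    # snap the unit length to the array period (the modal middle-monomer
    # length): a single chance-matching base at a unit boundary can
    # otherwise stretch the aligned interval by one position
    period = int(np.median([m.end - m.start for m in middles]))
    if 0 < abs((uend - ustart + 1) - period) <= 5:
        uend = ustart + period - 1
    start = ordered[0].start
    end = ordered[-1].end
    return SsatLocus(
        contig=locus.contig, start=start, end=end, monomers=ordered,
        unit_interval=(ustart, uend), family=family,
        locus_id=f"{locus.contig}:{start}-{end}",
    )


def call_loci(
    genome,
    consensus: SineConsensus,
    hits: list[SineHit] | None = None,
    min_cov_frac: float = 0.20,
    max_gap: int = 100,
    min_candidate_len: int = 500,
    min_middle_monomers: int = 4,
    min_unit_identity: float = 60.0,
) -> list[SsatLocus]:
    """Full chain: hit search -> merge -> candidates -> tiling -> sSat calls."""
    from .search import find_sine_hits

    if hits is None:
        hits = find_sine_hits(genome, consensus, min_cov_frac=min_cov_frac)
    if not hits:
        return []
    regions = merge_hits(hits, max_gap=max_gap)
    candidates = select_candidates(regions, min_len=min_candidate_len)
    loci = []
    for cand in candidates:
        monomers = detect_tandem_units(cand, consensus, genome,
                                       min_unit_identity=min_unit_identity,
                                       max_gap=max_gap)
        locus = call_ssat(cand, monomers, min_middle_monomers=min_middle_monomers,
                          max_gap=max_gap, genome=genome, family=consensus.family)
        if locus is not None:
            loci.append(locus)
    return loci
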