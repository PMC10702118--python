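"""SINE copy search and subfamily consensus refinement.

Hits are found by exact k-mer seeding followed by exhaustive affine-gap
local alignment within each candidate window, on both strands, with
iterated best-hit masking so every fragment of a tandem cluster is
reported separately.  A hit is kept when its span on the consensus covers
at least ``min_cov_frac`` of the consensus length (the fragment-search
regime); ``filter_full_length`` then applies the strict near-full-length
criteria (coverage > 90% of the consensus and identity > 65%) used when
refining family consensuses.

Subfamily refinement partitions copies, ordered by identity to the overall
majority consensus, into consecutive groups and calls a majority consensus
per group (the SubFam grouping procedure).
"""

from __future__ import annotations

import math

import edlib
import numpy as np

from ._align import (
    LocalAlignment,
    encode,
    global_identity,
    local_align,
    revcomp,
    seed_positions,
    seed_windows,
)
from .types import SineConsensus, SineHit, SubfamilySet

DEFAULT_SCORING = {"match": 5, "mismatch": -4, "gap_open": 12, "gap_extend": 2}


def _as_contigs(genome) -> dict[str, str]:
    if isinstance(genome, str):
        return {"chr1": genome}
    return dict(genome)


def _window_hits(
    consensus: SineConsensus,
    contig: str,
    wstart: int,
    wseq: str,
    min_cov_len: int,
    scoring: dict,
    identity_floor: float,
) -> list[SineHit]:
    """Iterated best-local-hit extraction with masking within one window."""
    L = len(consensus)
    cons_fwd = consensus.sequence
    cons_rev = revcomp(cons_fwd)
    stop_score = max(scoring["match"], int(min_cov_len * scoring["match"] * 0.3))
    work = list(wseq)
    hits: list[SineHit] = []
    cap = len(wseq) // max(min_cov_len, 1) + 8
    for _ in range(cap):
        target = "".join(work)
        aln_f = local_align(cons_fwd, target, **scoring)
        aln_r = local_align(cons_rev, target, **scoring)
        if aln_f.score >= aln_r.score:
            aln, strand = aln_f, "+"
        else:
            aln, strand = aln_r, "-"
        if aln.score < stop_score or aln.columns == 0:
            break
        qb, qe = aln.query_interval
        tb, te = aln.target_interval
        if strand == "+":
            cons_iv = (qb + 1, qe)
        else:
            cons_iv = (L - qe + 1, L - qb)
        if qe - qb >= min_cov_len and aln.identity >= identity_floor:
            hits.append(SineHit(
                contig=contig, start=wstart + tb, end=wstart + te, strand=strand,
                consensus_interval=cons_iv, identity=round(aln.identity, 2),
                score=float(aln.score),
            ))
        elif aln.identity < identity_floor:
            # permissive scoring can bridge noise across genuine short
            # fragments; re-align the span under stringent scoring to pull
            # out every high-identity core before the span is masked away
            query = cons_fwd if strand == "+" else cons_rev
            span = list(target[tb:te])
            for _ in range((te - tb) // max(min_cov_len, 1) + 2):
                core = local_align(query, "".join(span), match=2, mismatch=-5,
                                   gap_open=7, gap_extend=3)
                if core.columns == 0 or core.score < min_cov_len:
                    break
                cqb, cqe = core.query_interval
                ctb, cte = core.target_interval
                if cqe - cqb >= min_cov_len and core.identity >= identity_floor:
                    if strand == "+":
                        core_iv = (cqb + 1, cqe)
                    else:
                        core_iv = (L - cqe + 1, L - cqb)
                    hits.append(SineHit(
                        contig=contig, start=wstart + tb + ctb,
                        end=wstart + tb + cte, strand=strand,
                        consensus_interval=core_iv,
                        identity=round(core.identity, 2), score=float(core.score),
                    ))
                for i in range(ctb, cte):
                    span[i] = "#"
        for i in range(tb, te):
            work[i] = "#"
    return hits


def _suppress_redundant(hits: list[SineHit], min_reciprocal_overlap: float = 0.5) -> list[SineHit]:
    """Greedy best-score-first suppression of same-strand redundant hits."""
    kept: list[SineHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.contig, h.start)):
        redundant = False
        for k in kept:
            if k.contig != h.contig or k.strand != h.strand:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            if ov <= 0:
                continue
            if (ov / (h.end - h.start) >= min_reciprocal_overlap
                    and ov / (k.end - k.start) >= min_reciprocal_overlap):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start, h.end))
    return kept


def find_sine_hits(
    genome,
    consensus: SineConsensus,
    min_cov_frac: float = 0.20,
    seed_k: int = 11,
    identity_floor: float = 58.0,
    scoring: dict | None = None,
) -> list[SineHit]:
    """All non-redundant local hits of ``consensus`` on both strands whose
    consensus span covers at least ``min_cov_frac`` of the consensus.

    ``genome`` is a contig-name -> sequence mapping (or a bare sequence,
    taken as contig "chr1").  Hits are sorted by contig then start.

    ``identity_floor`` discards alignments in the junk regime: with
    permissive DNA scoring, optimal local alignments of unrelated
    sequences plateau around 50-57% identity, so the floor sits just
    above that while staying well below the identity of genuinely
    homologous copies (>= ~65% even at 35% substitution divergence).
    """
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    contigs = _as_contigs(genome)
    L = len(consensus)
    min_cov_len = max(1, math.ceil(min_cov_frac * L))
    all_hits: list[SineHit] = []
    for name, seq in contigs.items():
        seq = seq.upper()
        codes = encode(seq)
        pos = seed_positions(codes, consensus.sequence, seed_k)
        for ws, we in seed_windows(pos, len(seq), pad=L + 50, merge_gap=L):
            all_hits.extend(_window_hits(consensus, name, ws, seq[ws:we],
                                         min_cov_len, scoring, identity_floor))
    return _suppress_redundant(all_hits)


def filter_full_length(
    hits: list[SineHit],
    consensus: SineConsensus,
    min_len_frac: float = 0.90,
    min_identity: float = 65.0,
) -> list[SineHit]:
    """Retain near-full-length copies: consensus coverage strictly greater
    than ``min_len_frac`` and identity strictly greater than ``min_identity``."""
    L = len(consensus)
    return [h for h in hits
            if h.consensus_coverage / L > min_len_frac and h.identity > min_identity]


# ---------------------------------------------------------------------------
# subfamily refinement


def column_consensus(msa: list[str]) -> str:
    """Majority-rule consensus of equal-length alignment rows.

    Per column: the most frequent non-gap symbol if non-gap symbols
    outnumber gaps, else the column is dropped.  Ties break by fixed base
    order A < C < G < T (then alphabetic for other symbols).
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows must have equal length")
    out = []
    for col in range(width):
        counts: dict[str, int] = {}
        for row in msa:
            c = row[col]
            counts[c] = counts.get(c, 0) + 1
        gaps = counts.get("-", 0)
        non_gap = len(msa) - gaps
        if non_gap <= gaps:
            continue
        best = min((c for c in counts if c != "-"),
                   key=lambda c: (-counts[c], c))
        out.append(best)
    return "".join(out)


def star_align(copies: list[str], reference: str) -> list[str]:
    """Project each copy onto reference columns (star alignment).

    Each copy is globally aligned to the reference with edlib; per
    reference position the row records the aligned copy base or '-';
    copy insertions relative to the reference are dropped.
    """
    rows = []
    for copy in copies:
        res = edlib.align(copy, reference, mode="NW", task="path")
        row = []
        qi = 0
        num = 0
        for ch in res["cigar"]:
            if ch.isdigit():
                num = num * 10 + ord(ch) - 48
                continue
            if ch in "=XM":
                row.extend(copy[qi:qi + num])
                qi += num
            elif ch == "I":  # copy-only bases: insertion, dropped
                qi += num
            elif ch == "D":  # reference-only: gap in copy
                row.extend("-" * num)
            num = 0
        rows.append("".join(row))
    return rows


def refine_consensus(copies: list[str], group_size: int = 100) -> SubfamilySet:
    """Group SINE copies into subfamilies and call per-group consensuses.

    Copies are ordered by identity to the overall majority consensus
    (descending, stable), chunked into consecutive groups of
    ``group_size`` (the last group may be smaller), each group is star-
    aligned and majority-consensus called, and the group consensuses are
    aligned to each other.
    """
    if not copies:
        raise ValueError("refine_consensus requires at least one copy")
    copies = [c.upper() for c in copies]
    reference = max(copies, key=len)
    overall = column_consensus(star_align(copies, reference))
    # one refinement round stabilizes the reference choice
    overall = column_consensus(star_align(copies, overall))
    idents = [global_identity(c, overall) for c in copies]
    order = sorted(range(len(copies)), key=lambda i: (-idents[i], i))
    ordered = [copies[i] for i in order]
    groups = [ordered[i:i + group_size] for i in range(0, len(ordered), group_size)]
    group_consensuses = []
    for gi, group in enumerate(groups, 1):
        cons = column_consensus(star_align(group, overall))
        group_consensuses.append((f"G{gi}", cons, len(group)))
    alignment = star_align([c for _, c, _ in group_consensuses], overall)
    return SubfamilySet(group_consensuses=group_consensuses,
                        alignment_of_consensuses=alignment)
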