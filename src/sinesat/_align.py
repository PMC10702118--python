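"""Shared sequence/alignment primitives.

The local aligner is an affine-gap Smith-Waterman (numba-compiled) with a
deterministic tie-break: among equal-scoring cells the smallest target end
wins, then the smallest query end; traceback prefers diagonal over vertical
over horizontal moves.  Gap scoring convention: a gap of length ``k`` costs
``gap_open + gap_extend * (k - 1)``.

Genome-scale search uses exact k-mer seeding to restrict the dynamic
programming to candidate windows; the DP itself is exhaustive within each
window.  Glocal (infix) placement of short units and global identity use
edlib's banded edit-distance alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3, anything else (N, IUPAC) as 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class LocalAlignment:
    """Result of a local alignment.

    ``query_interval`` / ``target_interval`` are 0-based half-open on the
    input sequences; ``identity`` is percent matches over alignment columns.
    """

    score: int
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.zeros((n + 1, m + 1), dtype=np.int32)  # gap in target (vertical)
    F = np.zeros((n + 1, m + 1), dtype=np.int32)  # gap in query (horizontal)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    # ptr bits: 0-1 H source (0 stop, 1 diag, 2 vert, 3 horiz); bit 2 E from E; bit 3 F from F
    best = np.int32(0)
    bi = 0
    bj = 0
    neg = np.int32(-1_000_000_000)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - gap_open
            e_ext = E[i - 1, j] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptr[i, j] |= 4
            else:
                E[i, j] = e_open
            f_open = H[i, j - 1] - gap_open
            f_ext = F[i, j - 1] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptr[i, j] |= 8
            else:
                F[i, j] = f_open
            tj = t[j - 1]
            if qi < 4 and qi == tj:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, j - 1] + sub
            h = diag
            src = 1
            if E[i, j] > h:
                h = E[i, j]
                src = 2
            if F[i, j] > h:
                h = F[i, j]
                src = 3
            if h <= 0:
                h = 0
                src = 0
            H[i, j] = h
            ptr[i, j] |= src
            # tie-break: strictly greater, so the earliest (smallest j outer?
            # loops run i outer) — prefer smallest target end then query end:
            if h > best or (h == best and (j < bj or (j == bj and i < bi))):
                if h > 0:
                    best = h
                    bi = i
                    bj = j
    # traceback
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0 = in H, 1 = in E, 2 = in F
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                columns += 1
                if q[i - 1] < 4 and q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            from_e = p & 4
            i -= 1
            if not from_e:
                state = 0
        else:
            columns += 1
            from_f = p & 8
            j -= 1
            if not from_f:
                state = 0
    return best, i, bi, j, bj, matches, columns


def local_align(
    query: str,
    target: str,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = 12,
    gap_extend: int = 2,
) -> LocalAlignment:
    """Optimal affine-gap local alignment of ``query`` against ``target``.

    Raises ``ValueError`` on empty input.  Ties are broken deterministically
    (smallest target end, then smallest query end; diagonal-preferring
    traceback, which yields the shortest alignment at that endpoint).
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    q = encode(query)
    t = encode(target)
    score, qb, qe, tb, te, matches, columns = _sw_kernel(
        q, t, np.int32(match), np.int32(mismatch), np.int32(gap_open), np.int32(gap_extend)
    )
    return LocalAlignment(
        score=int(score),
        query_interval=(int(qb), int(qe)),
        target_interval=(int(tb), int(te)),
        matches=int(matches),
        columns=int(columns),
    )


# ---------------------------------------------------------------------------
# k-mer seeding


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes and a validity mask (no non-ACGT base)."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    c = codes.astype(np.int64)
    for j in range(k):
        vals = vals * 4 + np.where(c[j:j + n] < 4, c[j:j + n], 0)
        valid &= c[j:j + n] < 4
    return vals, valid


def seed_positions(target_codes: np.ndarray, query: str, k: int) -> np.ndarray:
    """Start positions in the target sharing an exact k-mer with the query
    (either strand of the query)."""
    qset = set()
    for s in (query, revcomp(query)):
        vals, valid = kmer_codes(encode(s), k)
        qset.update(vals[valid].tolist())
    if not qset:
        return np.empty(0, dtype=np.int64)
    tvals, tvalid = kmer_codes(target_codes, k)
    qarr = np.fromiter(qset, dtype=np.int64)
    qarr.sort()
    idx = np.searchsorted(qarr, tvals)
    idx[idx == qarr.shape[0]] = 0
    hit = tvalid & (qarr[idx] == tvals)
    return np.nonzero(hit)[0].astype(np.int64)


def seed_windows(
    positions: np.ndarray, target_len: int, pad: int, merge_gap: int
) -> list[tuple[int, int]]:
    """Cluster seed positions into padded candidate windows."""
    if positions.size == 0:
        return []
    windows: list[tuple[int, int]] = []
    run_start = run_end = int(positions[0])
    for p in positions[1:]:
        p = int(p)
        if p - run_end > merge_gap:
            windows.append((max(0, run_start - pad), min(target_len, run_end + pad)))
            run_start = p
        run_end = p
    windows.append((max(0, run_start - pad), min(target_len, run_end + pad)))
    # merge overlapping padded windows
    merged = [windows[0]]
    for s, e in windows[1:]:
        ps, pe = merged[-1]
        if s <= pe:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


class KmerIndex:
    """Sorted k-mer index over a set of contigs for repeated seed queries."""

    def __init__(self, contigs: dict[str, str], k: int = 12):
        self.k = k
        self.contigs = contigs
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in contigs.items():
            codes = encode(seq)
            vals, valid = kmer_codes(codes, k)
            pos = np.nonzero(valid)[0]
            v = vals[pos]
            order = np.argsort(v, kind="stable")
            self._index[name] = (v[order], pos[order])

    def query(self, query_seq: str) -> dict[str, np.ndarray]:
        """Per-contig sorted positions sharing a k-mer with either strand
        of the query."""
        qset = set()
        for s in (query_seq, revcomp(query_seq)):
            vals, valid = kmer_codes(encode(s), self.k)
            qset.update(vals[valid].tolist())
        out: dict[str, np.ndarray] = {}
        if not qset:
            return out
        qarr = np.fromiter(qset, dtype=np.int64)
        for name, (svals, spos) in self._index.items():
            lo = np.searchsorted(svals, qarr, side="left")
            hi = np.searchsorted(svals, qarr, side="right")
            hits = [spos[a:b] for a, b in zip(lo, hi) if b > a]
            if hits:
                pos = np.concatenate(hits)
                pos.sort()
                out[name] = pos
        return out


# ---------------------------------------------------------------------------
# edlib wrappers


def _path_stats(query: str, target_infix: str, cigar: str) -> tuple[int, int]:
    """(matches, columns) from an edlib cigar over query vs target infix."""
    matches = 0
    columns = 0
    qi = ti = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
            continue
        if ch == "=":
            matches += num
            columns += num
            qi += num
            ti += num
        elif ch == "X":
            columns += num
            qi += num
            ti += num
        elif ch == "M":
            for _ in range(num):
                if query[qi] == target_infix[ti]:
                    matches += 1
                qi += 1
                ti += 1
            columns += num
        elif ch == "I":  # insertion to target (consumes query)
            columns += num
            qi += num
        elif ch == "D":
            columns += num
            ti += num
        num = 0
    return matches, columns


def global_identity(a: str, b: str) -> float:
    """Percent identity (matches / alignment columns) of a global
    minimum-edit-distance alignment.

    Symmetric by construction: among equally optimal alignments the path
    depends on argument order, so the pair is canonicalized first.
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    a, b = sorted((a, b))
    res = edlib.align(a, b, mode="NW", task="path")
    matches, columns = _path_stats(a, b, res["cigar"])
    return 100.0 * matches / columns


def glocal_best(query: str, target: str, max_dist: int = -1):
    """Best infix placement of ``query`` inside ``target`` (edlib HW mode).

    Returns ``(start, end, identity_percent)`` with a 0-based half-open
    target interval, or ``None`` when no alignment within ``max_dist``.
    Ambiguity is resolved toward the leftmost location.
    """
    res = edlib.align(query, target, mode="HW", task="path", k=max_dist)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    e += 1
    matches, columns = _path_stats(query, target[s:e], res["cigar"])
    return s, e, 100.0 * matches / columns
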