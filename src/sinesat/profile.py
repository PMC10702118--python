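"""Characterization of called sSat loci.

Covers within-locus homogeneity (mean pairwise monomer identity),
genome-wide variant clustering by shared repeat unit, locus-level
subvariant structure with a permutation test for alternation of
subvariants along the array, the per-genome census table, and the
(TC)n-style microsatellite variation inside SINE bodies.
"""

from __future__ import annotations

from itertools import combinations

import edlib
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._align import global_identity, revcomp
from .search import column_consensus, star_align
from .types import (
    GenomeSummary,
    SineConsensus,
    SsatLocus,
    SsatVariant,
    SubvariantAnnotation,
)


def mean_pairwise_identity(monomers: list[str]) -> float:
    """Mean percent identity over all unordered pairs (global alignment,
    matches / alignment columns)."""
    if len(monomers) < 2:
        raise ValueError("mean_pairwise_identity requires at least 2 sequences")
    idents = [global_identity(a, b) for a, b in combinations(monomers, 2)]
    return float(np.mean(idents))


def locus_unit_consensus(locus: SsatLocus) -> str:
    """Majority consensus of the locus's middle monomers."""
    middles = [m.sequence for m in locus.monomers if m.role == "middle"]
    if not middles:
        middles = [m.sequence for m in locus.monomers]
    reference = max(middles, key=len)
    return column_consensus(star_align(middles, reference))


def cluster_variants(
    loci: list[SsatLocus],
    identity_threshold: float = 80.0,
    boundary_tolerance: int = 10,
) -> list[SsatVariant]:
    """Single-linkage clustering of loci into genome-wide sSat variants.

    Two loci join when their unit consensuses align at >= the identity
    threshold AND their unit-interval endpoints agree within the boundary
    tolerance.  Variants are ordered by member count (descending) and
    labeled V1, V2, ...
    """
    if not loci:
        return []
    units = [locus_unit_consensus(l) for l in loci]
    n = len(loci)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        si, ei = loci[i].unit_interval
        sj, ej = loci[j].unit_interval
        if abs(si - sj) > boundary_tolerance or abs(ei - ej) > boundary_tolerance:
            continue
        if global_identity(units[i], units[j]) >= identity_threshold:
            pi, pj = find(i), find(j)
            if pi != pj:
                parent[max(pi, pj)] = min(pi, pj)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), c[0]))
    variants = []
    for vi, members in enumerate(ordered, 1):
        member_units = [units[i] for i in members]
        cons = column_consensus(star_align(member_units, member_units[0]))
        starts = [loci[i].unit_interval[0] for i in members]
        ends = [loci[i].unit_interval[1] for i in members]
        variants.append(SsatVariant(
            label=f"V{vi}", unit_consensus=cons,
            unit_interval=(int(np.median(starts)), int(np.median(ends))),
            member_loci=[loci[i].locus_id for i in members],
            fraction_of_loci=len(members) / n,
        ))
    return variants


def _subvariant_k(heights: np.ndarray, k_max: int, min_gap: float) -> int:
    """Number of clusters from the largest merge-distance gap, capped at
    ``k_max``; 1 when no gap exceeds ``min_gap`` identity points."""
    m = len(heights)
    hs = np.sort(heights)[::-1]  # descending: hs[0] = final merge
    best_k, best_gap = 1, min_gap
    for k in range(2, min(k_max, m + 1) + 1):
        upper = hs[k - 2]
        lower = hs[k - 1] if k - 1 < m else 0.0
        gap = upper - lower
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def label_subvariants(
    locus: SsatLocus,
    k_max: int = 3,
    min_gap: float = 5.0,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SubvariantAnnotation:
    """Cluster middle monomers into <= ``k_max`` locus-specific subvariants
    and test whether subvariants alternate along the array.

    Clustering is single linkage on pairwise distance (100 - identity);
    the cut is the largest merge-distance gap, requiring at least
    ``min_gap`` identity points of separation to split at all.
    """
    middles = [m.sequence for m in locus.monomers if m.role == "middle"]
    n = len(middles)
    if n < 2:
        return SubvariantAnnotation(locus.locus_id, [1] * n, 1, 1.0, False)
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = 100.0 - global_identity(middles[i], middles[j])
        dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="single")
    k = _subvariant_k(Z[:, 2], k_max, min_gap)
    if k == 1:
        labels = [1] * n
    else:
        raw = fcluster(Z, t=k, criterion="maxclust")
        # canonical relabeling by first occurrence along the array
        remap: dict[int, int] = {}
        labels = []
        for r in raw:
            if r not in remap:
                remap[r] = len(remap) + 1
            labels.append(remap[r])
    p = alternation_test(labels, n_perm=n_perm, seed=seed)
    n_sub = len(set(labels))
    return SubvariantAnnotation(locus.locus_id, labels, n_sub, p,
                                bool(n_sub >= 2 and p <= alpha))


def alternation_test(labels: list[int], n_perm: int = 10000, seed: int = 0) -> float:
    """One-sided permutation test for alternation excess.

    Statistic: number of adjacent pairs with different labels.  Null:
    uniformly random permutations of the observed label multiset.  Returns
    the add-one-corrected p-value (b + 1) / (n_perm + 1) where b counts
    permutations with a statistic >= the observed one.
    """
    arr = np.asarray(labels)
    n = arr.size
    if n < 2 or len(set(labels)) < 2:
        return 1.0
    observed = int(np.sum(arr[1:] != arr[:-1]))
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    order = np.argsort(keys, axis=1)
    perms = arr[order]
    stats = np.sum(perms[:, 1:] != perms[:, :-1], axis=1)
    b = int(np.sum(stats >= observed))
    return (b + 1) / (n_perm + 1)


def summarize_genome(
    loci: list[SsatLocus],
    sine_hits: list,
    genome,
    family: str = "other",
) -> GenomeSummary:
    """Census of one genome: total sSat loci, binned by middle-monomer
    count (4-5, 6-8, >= 9), total SINE copy count, and genome size."""
    contigs = {"chr1": genome} if isinstance(genome, str) else dict(genome)
    b45 = sum(1 for l in loci if 4 <= l.n_middle <= 5)
    b68 = sum(1 for l in loci if 6 <= l.n_middle <= 8)
    b9 = sum(1 for l in loci if l.n_middle >= 9)
    return GenomeSummary(
        family=family, total_loci=len(loci), loci_4_5=b45, loci_6_8=b68,
        loci_9_plus=b9, total_sine_copies=len(sine_hits),
        genome_size=sum(len(s) for s in contigs.values()),
    )


def scan_internal_microsat(
    sine_copies: list[str],
    consensus: SineConsensus,
    motif: str = "TC",
    anchor: int = 110,
    slack: int = 10,
) -> list[int]:
    """Per-copy length (in repeat units) of the maximal uninterrupted motif
    run at/after the anchored consensus position.

    The anchor (1-based consensus coordinate) is mapped into each copy via
    alignment; the run must start within ``slack`` nt of the mapped
    position.  Copies lacking the motif there score 0.
    """
    m = len(motif)
    out = []
    for copy in sine_copies:
        copy = copy.upper()
        res = edlib.align(copy, consensus.sequence, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            out.append(0)
            continue
        loc_start = res["locations"][0][0]
        cons_pos = loc_start + 1  # 1-based
        copy_pos = 0
        mapped = None
        if anchor <= cons_pos:
            mapped = 0
        num = 0
        for ch in res["cigar"]:
            if ch.isdigit():
                num = num * 10 + ord(ch) - 48
                continue
            if mapped is not None:
                break
            if ch in "=XM":
                if cons_pos + num > anchor:
                    mapped = copy_pos + (anchor - cons_pos)
                cons_pos += num
                copy_pos += num
            elif ch == "I":
                copy_pos += num
            elif ch == "D":
                if cons_pos + num > anchor:
                    mapped = copy_pos
                cons_pos += num
            num = 0
        if mapped is None:
            out.append(0)
            continue
        best = 0
        for start in range(max(0, mapped - slack), min(len(copy), mapped + slack + 1)):
            if copy[start:start + m] != motif:
                continue
            run = 0
            while copy[start + run * m:start + (run + 1) * m] == motif:
                run += 1
            best = max(best, run)
        out.append(best)
    return out


def canonical_motif(motif: str) -> str:
    """Canonical representative of a microsatellite motif class.

    The class is closed under rotation and reverse complement; the
    canonical form is the lexicographically smallest rotation of the
    primitive root of the motif or of its reverse complement (so e.g.
    (ATGGA)n, (TGGAA)n and (TCCAT)n all share one canonical form, and
    homopolymer runs reduce to a single base).
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    n = len(motif)
    root = motif
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            root = motif[:d]
            break
    candidates = []
    for s in (root, revcomp(root)):
        candidates.extend(s[i:] + s[:i] for i in range(len(s)))
    return min(candidates)
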