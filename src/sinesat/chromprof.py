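"""Chromosomal localization of satellites vs control repeats.

Telomere tract detection ((TTAGGG)n runs of >= 1000 units on either
strand), degenerate-motif scans (e.g. the CENP-B box), centromeric-
satellite block finding, distance-to-end statistics, size-fraction
tracks, and a label-permutation test for subtelomeric enrichment of sSat
loci relative to a control feature class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._align import encode, revcomp
from .types import ChromProfile, SineConsensus

# canonical CENP-B box 17-mer from the centromere literature; an external
# constant (configurable), not derived from any satellite analysed here
CENP_B_BOX = "NTTCGNNNNANNCGGGN"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class TelomereTract:
    start: int
    end: int
    strand: str
    n_units: int


def find_telomere_tracts(
    chrom: str,
    motif: str = "TTAGGG",
    min_repeats: int = 1000,
    max_interrupt_frac: float = 0.05,
) -> list[TelomereTract]:
    """Maximal tandem runs of ``motif`` (either orientation) with at least
    ``min_repeats`` units, tolerating up to ``max_interrupt_frac``
    interrupted positions within the run."""
    chrom = chrom.upper()
    m = len(motif)
    tracts: list[TelomereTract] = []
    for strand, probe in (("+", motif), ("-", revcomp(motif))):
        starts = [match.start() for match in re.finditer(f"(?={re.escape(probe)})", chrom)]
        if not starts:
            continue
        # greedy non-overlapping occurrence chain with small gaps allowed
        runs: list[list[int]] = []
        cur = [starts[0]]
        occ_end = starts[0] + m
        for s in starts[1:]:
            if s < occ_end:
                continue  # overlapping occurrence, skip
            if s - occ_end <= 3 * m:
                cur.append(s)
            else:
                runs.append(cur)
                cur = [s]
            occ_end = s + m
        runs.append(cur)
        for run in runs:
            n_units = len(run)
            span = run[-1] + m - run[0]
            interrupted = span - n_units * m
            if n_units >= min_repeats and interrupted <= max_interrupt_frac * span:
                tracts.append(TelomereTract(run[0], run[-1] + m, strand, n_units))
    tracts.sort(key=lambda t: t.start)
    return tracts


def scan_motif(
    chrom: str, motif: str, max_mismatches: int = 0
) -> list[tuple[int, str]]:
    """All matches of a degenerate IUPAC motif on both strands with at most
    ``max_mismatches`` mismatching positions.

    Returns sorted (0-based start on the forward strand, strand) tuples.
    """
    chrom = chrom.upper()
    codes = encode(chrom)
    out: list[tuple[int, str]] = []
    for strand, probe in (("+", motif.upper()), ("-", revcomp(motif.upper()))):
        k = len(probe)
        n = codes.shape[0] - k + 1
        if n <= 0:
            continue
        mism = np.zeros(n, dtype=np.int32)
        for j, sym in enumerate(probe):
            allowed = _IUPAC.get(sym)
            if allowed is None:
                raise ValueError(f"unknown IUPAC symbol {sym!r} in motif")
            codeset = np.array([encode(c)[0] for c in allowed])
            window = codes[j:j + n]
            mism += (~np.isin(window, codeset)).astype(np.int32)
        for pos in np.nonzero(mism <= max_mismatches)[0]:
            out.append((int(pos), strand))
    out.sort()
    return out


def find_satellite_blocks(
    chrom: str,
    satellite_consensus: str,
    min_identity: float = 65.0,
    min_tandems: int = 2,
    max_gap: int = 100,
) -> list[tuple[int, int, int]]:
    """Tandem blocks of a satellite consensus: local-alignment hits merged
    into regions, each re-tiled with the consensus to count tandems.

    Returns (start, end, n_tandems) per block with >= ``min_tandems``.
    """
    from .search import find_sine_hits
    from .tandem import _tile_unit, merge_hits

    cons = SineConsensus(name="satellite", sequence=satellite_consensus)
    hits = find_sine_hits({"chr1": chrom}, cons, min_cov_frac=0.5,
                          identity_floor=min_identity)
    if not hits:
        return []
    blocks = []
    for region in merge_hits(hits, max_gap=max_gap):
        seq = chrom[region.start:region.end]
        minus = sum(1 for h in region.member_hits if h.strand == "-") \
            > len(region.member_hits) / 2
        if minus:
            seq = revcomp(seq)
        tiles = _tile_unit(seq, satellite_consensus, min_identity)
        if len(tiles) >= min_tandems:
            blocks.append((region.start, region.end, len(tiles)))
    return blocks


def distance_to_end(
    features: list[tuple[int, int]], chrom_length: int
) -> list[int]:
    """min(start, length - end) per feature (0 at a chromosome terminus)."""
    out = []
    for start, end in features:
        if not (0 <= start < end <= chrom_length):
            raise ValueError(f"feature ({start},{end}) outside chromosome 0..{chrom_length}")
        out.append(min(start, chrom_length - end))
    return out


def subtelomeric_enrichment(
    ssat_features: list[tuple[str, int, int]],
    control_features: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Label-permutation test for subtelomeric preference of sSat loci.

    Each feature's distance to the nearer chromosome end is normalized by
    half the chromosome length (so 0 = at a terminus, 1 = at the middle).
    Statistic: median normalized distance of the control class minus that
    of the sSat class (positive when sSats sit closer to the ends).  The
    null permutes class labels over the pooled feature set; the one-sided
    p-value carries the add-one correction.
    """

    def norm_dist(features):
        vals = []
        for chrom, start, end in features:
            L = chrom_lengths[chrom]
            d = min(start, L - end)
            vals.append(d / (L / 2))
        return np.array(vals)

    a = norm_dist(ssat_features)
    b = norm_dist(control_features)
    if a.size == 0 or b.size == 0:
        raise ValueError("both feature sets must be non-empty")
    observed = float(np.median(b) - np.median(a))
    pooled = np.concatenate([a, b])
    na = a.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = float(np.median(perm[na:]) - np.median(perm[:na]))
        if stat >= observed:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return observed, p


def size_fraction_track(
    tandem_counts: list[int], split: int = 6
) -> list[str]:
    """Class each locus by tandem count: "low" below ``split``, "high" at
    or above it (the 1-5 vs >= 6 tandem fractions)."""
    return ["high" if c >= split else "low" for c in tandem_counts]


def build_chrom_profile(
    chrom: str,
    length: int,
    ssat_loci: list[tuple[int, int, int]],
    sine_hits: list[tuple[int, int]],
    telomere_tracts: list[TelomereTract] | None = None,
    satellite_blocks: list[tuple[int, int, int]] | None = None,
    split: int = 6,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ChromProfile:
    """Assemble the per-chromosome profile: classed tracks, distances, and
    the sSat-vs-SINE subtelomeric-enrichment test (when both are present).

    ``ssat_loci`` / ``satellite_blocks`` carry (start, end, n_tandems).
    """
    ssat_frac = size_fraction_track([c for _, _, c in ssat_loci], split=split)
    tracks = {
        "ssat": [(s, e, f) for (s, e, _), f in zip(ssat_loci, ssat_frac)],
        "sine": [(s, e, "na") for s, e in sine_hits],
        "telomere": [(t.start, t.end, "na") for t in (telomere_tracts or [])],
        "censat": [(s, e, "na") for s, e, _ in (satellite_blocks or [])],
    }
    dte = {
        name: distance_to_end([(s, e) for s, e, _ in feats], length)
        for name, feats in tracks.items() if feats
    }
    stat = pval = None
    if ssat_loci and sine_hits:
        stat, pval = subtelomeric_enrichment(
            [(chrom, s, e) for s, e, _ in ssat_loci],
            [(chrom, s, e) for s, e in sine_hits],
            {chrom: length}, n_perm=n_perm, seed=seed)
    return ChromProfile(chrom=chrom, length=length, tracks=tracks,
                        distance_to_end=dte,
                        enrichment_statistic=stat, enrichment_pvalue=pval)
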