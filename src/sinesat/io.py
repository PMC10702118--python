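"""FASTA/BED/TSV input-output shared by the pipeline stages.

Genomic intervals are written 0-based half-open (BED); consensus
positions appear in TSV reports 1-based inclusive.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .types import SineHit, SsatLocus, TruthRecord


class FastaParseError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    """Named sequences, uppercase-normalized, order preserved.

    Raises :class:`FastaParseError` naming the offending line for
    malformed input (content before the first header, or a header with no
    sequence).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    seen_header = False
    last_header_line = None
    has_seq = False
    for i, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if line.startswith(">"):
            if seen_header and not has_seq:
                raise FastaParseError(
                    f"{path}: record at line {last_header_line} has no sequence")
            seen_header = True
            last_header_line = i
            has_seq = False
        else:
            if not seen_header:
                raise FastaParseError(f"{path}: sequence before first header at line {i}")
            has_seq = True
    if not seen_header:
        raise FastaParseError(f"{path}: no FASTA records found")
    if not has_seq:
        raise FastaParseError(f"{path}: record at line {last_header_line} has no sequence")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(contigs: dict[str, str], path, width: int = 60) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# BED


def hit_to_bed6(hit: SineHit, name: str = "sine_hit") -> tuple:
    return (hit.contig, hit.start, hit.end, name, int(round(hit.identity * 10)), hit.strand)


def truth_to_bed6(t: TruthRecord) -> tuple:
    return (t.contig, t.start, t.end, t.kind, 0, t.strand)


def locus_to_bed12(locus: SsatLocus) -> tuple:
    """BED12 row with one block per monomer."""
    block_starts = [m.start - locus.start for m in locus.monomers]
    block_sizes = [m.end - m.start for m in locus.monomers]
    return (
        locus.contig, locus.start, locus.end,
        locus.locus_id or "ssat", locus.n_middle, "+",
        locus.start, locus.end, "0,0,0", len(locus.monomers),
        ",".join(map(str, block_sizes)) + ",",
        ",".join(map(str, block_starts)) + ",",
    )


def write_bed(rows: list[tuple], path, dialect: str = "bed6") -> None:
    """Write BED6 or BED12 rows, sorted by contig then start, atomically."""
    ncol = {"bed6": 6, "bed12": 12}[dialect]
    rows = sorted(rows, key=lambda r: (r[0], int(r[1]), int(r[2])))
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for row in rows:
            if len(row) != ncol:
                raise ValueError(f"{dialect} row needs {ncol} columns, got {len(row)}")
            fh.write("\t".join(map(str, row)) + "\n")
    os.replace(tmp, path)


def read_bed(path) -> list[tuple]:
    """Rows with numeric coordinate columns restored to int."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row = []
            for i, f in enumerate(fields):
                row.append(int(f) if i in (1, 2, 4, 6, 7, 9) and f.lstrip("-").isdigit() else f)
            out.append(tuple(row))
    return out


def bed12_blocks(row: tuple) -> list[tuple[int, int]]:
    """Absolute (start, end) monomer intervals from a BED12 row."""
    start = int(row[1])
    sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
    starts = [int(x) for x in str(row[11]).rstrip(",").split(",")]
    return [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def hits_to_frame(hits: list[SineHit]) -> pd.DataFrame:
    return pd.DataFrame({
        "contig": [h.contig for h in hits],
        "start": [h.start for h in hits],
        "end": [h.end for h in hits],
        "strand": [h.strand for h in hits],
        "consensus_start": [h.consensus_interval[0] for h in hits],
        "consensus_end": [h.consensus_interval[1] for h in hits],
        "identity": [h.identity for h in hits],
        "score": [h.score for h in hits],
    })


def loci_to_frame(loci: list[SsatLocus]) -> pd.DataFrame:
    return pd.DataFrame({
        "locus_id": [l.locus_id for l in loci],
        "contig": [l.contig for l in loci],
        "start": [l.start for l in loci],
        "end": [l.end for l in loci],
        "family": [l.family for l in loci],
        "n_monomers": [l.n_monomers for l in loci],
        "n_middle": [l.n_middle for l in loci],
        "unit_start": [l.unit_interval[0] for l in loci],
        "unit_end": [l.unit_interval[1] for l in loci],
        "unit_length": [l.unit_length for l in loci],
        "roles": ["".join(m.role[0].upper() for m in l.monomers) for l in loci],
    })


def truth_params_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        row = {"contig": t.contig, "start": t.start, "end": t.end,
               "kind": t.kind, "strand": t.strand,
               "n_monomers": t.n_monomers if t.monomer_breakpoints else ""}
        row.update({f"param_{k}": v for k, v in sorted(t.params.items())})
        rows.append(row)
    return pd.DataFrame(rows)
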