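"""Configuration and the end-to-end pipeline driver.

Every threshold of every stage lives in one :class:`PipelineConfig` so a
run is auditable and reproducible: the pipeline is a pure function of
(inputs, config, seed), and the run manifest records the config hash.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as sio
from .profile import cluster_variants, label_subvariants, summarize_genome
from .search import find_sine_hits
from .tandem import call_ssat, detect_tandem_units, merge_hits, select_candidates
from .types import SineConsensus


@dataclass
class PipelineConfig:
    """All thresholds, paths, and the global seed for one pipeline run."""

    genome_fasta: str = ""
    consensus_fasta: str = ""
    genome_b_fasta: str = ""  # optional second assembly for orthology
    out_dir: str = "sinesat_out"
    seed: int = 0
    # hit search ("at least 20% of the consensus sequence length")
    min_cov_frac: float = 0.20
    # full-length filter ("more than 90% length and more than 65% similarity")
    min_len_frac: float = 0.90
    min_identity: float = 65.0
    # locus assembly ("less than 100 bp apart" / "longer than 500 bp")
    max_gap: int = 100
    min_candidate_len: int = 500
    # sSat calling ("at least four middle monomers")
    min_middle_monomers: int = 4
    min_unit_identity: float = 60.0
    # orthology
    flank_len: int = 500
    min_flank_identity: float = 80.0
    max_span: int = 100_000
    # chromosome profiling ("stretches of at least 1000 repeats")
    telomere_min_repeats: int = 1000
    # permutation tests
    n_perm: int = 10_000

    def validate(self) -> None:
        if self.min_middle_monomers < 1:
            raise ValueError("min_middle_monomers must be >= 1")
        if not 0 < self.min_cov_frac <= 1:
            raise ValueError("min_cov_frac must be in (0, 1]")
        if self.max_gap < 1 or self.min_candidate_len < 1:
            raise ValueError("gap/length thresholds must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific configuration (thresholds and seed);
        input/output paths do not change the run identity."""
        payload = {k: v for k, v in asdict(self).items()
                   if not k.endswith(("fasta", "dir"))}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    hits: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    subvariants: list = field(default_factory=list)
    summary: object = None
    out_dir: str = ""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """search -> merge -> call -> profile, writing the report bundle.

    Output files are written atomically; any stage failure removes the
    partial bundle and raises :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(writer, payload, name):
        path = out / name
        writer(payload, path)
        written.append(path)

    stage = "load"
    try:
        genome = sio.read_fasta(config.genome_fasta)
        cons_seqs = sio.read_fasta(config.consensus_fasta)
        name, seq = next(iter(cons_seqs.items()))
        consensus = SineConsensus(name=name, sequence=seq)

        stage = "search"
        hits = find_sine_hits(genome, consensus, min_cov_frac=config.min_cov_frac)
        emit(lambda h, p: sio.write_bed([sio.hit_to_bed6(x) for x in h], p), hits,
             "hits.bed")
        emit(lambda h, p: sio.write_tsv(sio.hits_to_frame(h), p), hits, "hits.tsv")

        stage = "call"
        regions = merge_hits(hits, max_gap=config.max_gap)
        candidates = select_candidates(regions, min_len=config.min_candidate_len)
        loci = []
        for cand in candidates:
            monomers = detect_tandem_units(cand, consensus, genome,
                                           min_unit_identity=config.min_unit_identity,
                                           max_gap=config.max_gap)
            locus = call_ssat(cand, monomers,
                              min_middle_monomers=config.min_middle_monomers,
                              max_gap=config.max_gap, genome=genome,
                              family=consensus.family)
            if locus is not None:
                loci.append(locus)
        emit(lambda l, p: sio.write_bed([sio.locus_to_bed12(x) for x in l], p,
                                        dialect="bed12"), loci, "ssat.bed12")
        emit(lambda l, p: sio.write_tsv(sio.loci_to_frame(l), p), loci, "loci.tsv")

        stage = "profile"
        variants = cluster_variants(loci)
        import pandas as pd
        vf = pd.DataFrame({
            "label": [v.label for v in variants],
            "n_members": [len(v.member_loci) for v in variants],
            "fraction_of_loci": [round(v.fraction_of_loci, 4) for v in variants],
            "unit_start": [v.unit_interval[0] for v in variants],
            "unit_end": [v.unit_interval[1] for v in variants],
            "unit_consensus": [v.unit_consensus for v in variants],
        })
        emit(lambda df, p: sio.write_tsv(df, p), vf, "variants.tsv")
        subvariants = [label_subvariants(l, n_perm=config.n_perm, seed=config.seed)
                       for l in loci]
        sf = pd.DataFrame({
            "locus_id": [s.locus_id for s in subvariants],
            "n_subvariants": [s.n_subvariants for s in subvariants],
            "labels": ["".join(map(str, s.labels)) for s in subvariants],
            "alternation_pvalue": [s.alternation_pvalue for s in subvariants],
            "is_alternating": [s.is_alternating for s in subvariants],
        })
        emit(lambda df, p: sio.write_tsv(df, p), sf, "subvariants.tsv")
        summary = summarize_genome(loci, hits, genome, family=consensus.family)
        emit(lambda s, p: sio.write_tsv(pd.DataFrame([asdict(s)]), p), summary,
             "summary.tsv")

        stage = "manifest"
        manifest = {"config_hash": config.digest(), "seed": config.seed,
                    "thresholds": {k: v for k, v in asdict(config).items()
                                   if not k.endswith(("fasta", "dir"))},
                    "n_hits": len(hits), "n_candidates": len(candidates),
                    "n_loci": len(loci)}
        mpath = out / "manifest.json"
        tmp = mpath.with_suffix(".json.tmp")
        with open(tmp, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        os.replace(tmp, mpath)
        written.append(mpath)
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise StageError(stage, exc) from exc
    return PipelineResult(hits=hits, loci=loci, variants=variants,
                          subvariants=subvariants, summary=summary,
                          out_dir=str(out))
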