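"""End-to-end orchestration: graph → coordinates → coverage → correction →
abundance → output bundle.

Outputs written to the run directory:

* ``coordinates.tsv`` — per-contig global scaffold coordinates
* ``coverage_per_base.tsv`` — run-length-encoded per-base scaffold coverage
* ``coverage_summary.tsv`` — mean and standard deviation per scaffold
* ``scaffolds.fasta`` — linearized final scaffolds
* ``changepoints.tsv`` — change-point call log (pre-correction ids)
* ``abundance_metabat2.tsv`` (and optional MaxBin 2.0 / CONCOCT tables)

Linearization of a non-linear scaffold is necessarily lossy: contigs are
painted onto the span at their coordinates; where intervals conflict
(bubbles, overlaps) the contig whose interval extends furthest right wins
the conflicting bases, gap positions are filled with ``N``, and the record
length always equals the span. The coordinate table retains the full graph
layout alongside.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from . import coverage as cov
from .changepoint import (
    ChangePointCall,
    ChangePointParams,
    CorrectionResult,
    correct_all,
    layout_scaffolds,
    write_calls,
)
from .coordinates import CoordinateMap, write_coordinates
from .graph import load_scaffold_graph

logger = logging.getLogger("scafcov")

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    graph_path: PathLike
    fasta_path: PathLike
    bedgraph_paths: Sequence[PathLike]
    outdir: PathLike
    sample_names: Sequence[str] | None = None
    params: ChangePointParams = field(default_factory=ChangePointParams)
    correction: bool = True
    primary_sample: int = 0  # index of the sample the scaffolds derive from
    binner_formats: Sequence[str] = ("metabat2",)

    def validate(self) -> None:
        for p in [self.graph_path, self.fasta_path, *self.bedgraph_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not self.bedgraph_paths:
            raise ValueError("at least one bedGraph is required")
        if not 0 <= self.primary_sample < len(self.bedgraph_paths):
            raise ValueError("primary_sample out of range")
        known = {"metabat2", "maxbin2", "concoct"}
        bad = set(self.binner_formats) - known
        if bad:
            raise ValueError(f"unknown binner format(s): {sorted(bad)}")


@dataclass
class PipelineResult:
    cmaps: list[CoordinateMap]
    tracks: list[cov.CoverageTrack]
    calls: list[ChangePointCall]
    abundance: "object"  # pandas DataFrame
    paths: dict[str, Path]
    correction: CorrectionResult | None = None


def write_scaffold_fasta(
    cmaps: Sequence[CoordinateMap],
    sequences: Mapping[str, str],
    path: PathLike,
) -> None:
    """Linearize scaffolds into FASTA records (see module docstring).

    Reverse-oriented contigs are written reverse-complemented, so the
    record reads along the scaffold axis.
    """
    with open(path, "w") as fh:
        for cmap in cmaps:
            span = cmap.span
            buf = bytearray(b"N" * span)
            order = sorted(cmap.placements.items(), key=lambda kv: (kv[1].end, kv[0]))
            for cid, pl in order:
                if cid not in sequences:
                    raise KeyError(f"no sequence for placed contig {cid!r}")
                seq = sequences[cid]
                if len(seq) != pl.length:
                    raise ValueError(
                        f"contig {cid!r}: sequence length {len(seq)} != placed length {pl.length}"
                    )
                if pl.orientation == "-":
                    seq = str(Seq(seq).reverse_complement())
                buf[pl.start : pl.end] = seq.encode()
            fh.write(f">{cmap.scaffold_id} contigs={len(cmap.placements)} span={span}\n")
            text = buf.decode()
            for i in range(0, span, 80):
                fh.write(text[i : i + 80] + "\n")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full flow and write the output bundle.

    Stages: load graph and sequences → break cycles → coordinates →
    primary-sample coverage → change-point correction (unless disabled) →
    recompute layout → multi-sample abundance → writers.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name: str) -> None:
        logger.info("[%6.2fs] %s", time.time() - t0, name)

    stage("loading sequences and scaffold graph")
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(config.fasta_path), "fasta")}
    lengths = {cid: len(s) for cid, s in sequences.items()}
    graph = load_scaffold_graph(config.graph_path, lengths)

    stage("loading per-base contig depth")
    samples = [cov.read_bedgraph(p, lengths) for p in config.bedgraph_paths]
    primary = samples[config.primary_sample]

    calls: list[ChangePointCall] = []
    correction: CorrectionResult | None = None
    if config.correction:
        stage("change-point detection and delinking")
        correction = correct_all(graph, primary, config.params)
        cmaps, tracks, calls = correction.cmaps, correction.tracks, correction.calls
    else:
        stage("coordinate assignment (correction disabled)")
        _, _, cmaps, tracks, _ = layout_scaffolds(graph, primary)

    stage("multi-sample abundance")
    names = list(config.sample_names) if config.sample_names else [
        Path(p).stem for p in config.bedgraph_paths
    ]
    abundance = cov.multi_sample_abundance(cmaps, samples, names)

    stage("writing outputs")
    paths: dict[str, Path] = {}
    paths["coordinates"] = outdir / "coordinates.tsv"
    write_coordinates(cmaps, paths["coordinates"])
    paths["coverage_per_base"] = outdir / "coverage_per_base.tsv"
    cov.write_coverage_tracks(tracks, paths["coverage_per_base"])
    paths["coverage_summary"] = outdir / "coverage_summary.tsv"
    cov.write_coverage_summary(tracks, paths["coverage_summary"])
    paths["scaffolds_fasta"] = outdir / "scaffolds.fasta"
    write_scaffold_fasta(cmaps, sequences, paths["scaffolds_fasta"])
    paths["changepoints"] = outdir / "changepoints.tsv"
    write_calls(calls, paths["changepoints"])
    if "metabat2" in config.binner_formats:
        paths["abundance_metabat2"] = outdir / "abundance_metabat2.tsv"
        cov.write_metabat2(abundance, paths["abundance_metabat2"])
    if "maxbin2" in config.binner_formats:
        for p in cov.write_maxbin2(abundance, outdir / "abundance_maxbin2"):
            paths[p.name] = p
    if "concoct" in config.binner_formats:
        paths["abundance_concoct"] = outdir / "abundance_concoct.tsv"
        cov.write_concoct(abundance, paths["abundance_concoct"])
    stage("done")
    return PipelineResult(cmaps, tracks, calls, abundance, paths, correction)
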