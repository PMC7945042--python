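"""Reference-based scoring of bins (completeness / contamination).

A bin — a set of contigs a binning tool grouped together — is assigned to
the reference genome to which the majority of its base pairs align.
Completeness is the percentage of the assigned genome represented in the
bin; contamination is the percentage of base pairs in the bin that did not
align to the assigned genome. Completeness is a genome-coordinate notion,
so alignment intervals on the genome are merged before counting (a genome
base covered twice counts once); contamination is a bin-side notion and
uses raw aligned base pairs.

Alignments enter either as minimap2 PAF or as an in-memory mapping
contig → [(genome, target_start, target_end), ...]; "aligned bp" is the
target-interval length of each record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

PathLike = Union[str, Path]

Alignments = Mapping[str, Sequence[tuple[str, int, int]]]


@dataclass
class BinAssignment:
    """A bin's majority-rule genome assignment and its supporting counts."""

    bin_id: str
    genome: str | None  # None = unassigned (no aligned bp)
    aligned_bp: dict[str, int]  # genome -> total aligned bp (bin side)
    bin_total_bp: int
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict, repr=False)


def read_paf(path: PathLike) -> dict[str, list[tuple[str, int, int]]]:
    """Collect (target genome, target start, target end) per query contig."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns")
            qname, tname = fields[0], fields[5]
            tstart, tend = int(fields[7]), int(fields[8])
            out.setdefault(qname, []).append((tname, tstart, tend))
    return out


def read_bin_table(path: PathLike) -> dict[str, list[str]]:
    """Bin membership TSV: ``bin_id<TAB>contig_id`` per line."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'bin_id<TAB>contig_id'")
            out.setdefault(fields[0], []).append(fields[1])
    return out


def _merged_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    end_prev = None
    start_prev = None
    for s, e in sorted(intervals):
        if end_prev is None or s > end_prev:
            if end_prev is not None:
                total += end_prev - start_prev
            start_prev, end_prev = s, e
        else:
            end_prev = max(end_prev, e)
    if end_prev is not None:
        total += end_prev - start_prev
    return total


def assign_bins(
    bin_membership: Mapping[str, Sequence[str]],
    alignments: Alignments,
    contig_lengths: Mapping[str, int],
) -> list[BinAssignment]:
    """Majority-bp genome assignment for every bin.

    Ties go to the lexicographically first genome with a warning; a bin
    whose contigs align nowhere is returned unassigned.
    """
    out = []
    for bin_id in sorted(bin_membership):
        members = bin_membership[bin_id]
        aligned: dict[str, int] = {}
        intervals: dict[str, list[tuple[int, int]]] = {}
        total_bp = 0
        for cid in members:
            if cid not in contig_lengths:
                raise ValueError(f"bin {bin_id!r}: unknown contig {cid!r}")
            total_bp += contig_lengths[cid]
            for genome, ts, te in alignments.get(cid, ()):
                aligned[genome] = aligned.get(genome, 0) + (te - ts)
                intervals.setdefault(genome, []).append((ts, te))
        if not aligned:
            out.append(BinAssignment(bin_id, None, {}, total_bp))
            continue
        best_bp = max(aligned.values())
        winners = sorted(g for g, bp in aligned.items() if bp == best_bp)
        if len(winners) > 1:
            warnings.warn(
                f"bin {bin_id!r}: majority tie between {winners}; "
                f"assigning lexicographically first ({winners[0]})"
            )
        out.append(BinAssignment(bin_id, winners[0], aligned, total_bp, intervals))
    return out


def completeness_contamination(
    assignment: BinAssignment,
    genome_length: int,
) -> tuple[float, float]:
    """Score one assigned bin against its genome.

    completeness = 100 * (distinct genome bases covered by the bin's
    alignments to the assigned genome) / genome_length;
    contamination = 100 * (bin bp not aligned to the assigned genome) /
    bin bp. Both are clipped to [0, 100].
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if assignment.genome is None:
        return 0.0, 100.0 if assignment.bin_total_bp else 0.0
    covered = _merged_length(assignment.intervals.get(assignment.genome, []))
    completeness = 100.0 * covered / genome_length
    if assignment.bin_total_bp == 0:
        raise ValueError(f"bin {assignment.bin_id!r} is empty")
    aligned_to_assigned = assignment.aligned_bp.get(assignment.genome, 0)
    contamination = 100.0 * (assignment.bin_total_bp - aligned_to_assigned) / assignment.bin_total_bp
    return (
        float(min(max(completeness, 0.0), 100.0)),
        float(min(max(contamination, 0.0), 100.0)),
    )


def evaluate_bins(
    bin_membership: Mapping[str, Sequence[str]],
    alignments: Alignments,
    contig_lengths: Mapping[str, int],
    genome_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-bin metrics table: assignment, completeness %, contamination %."""
    rows = []
    for a in assign_bins(bin_membership, alignments, contig_lengths):
        if a.genome is None:
            rows.append(
                {"bin_id": a.bin_id, "genome": "unassigned", "bin_bp": a.bin_total_bp,
                 "completeness": 0.0, "contamination": 100.0 if a.bin_total_bp else 0.0}
            )
            continue
        comp, cont = completeness_contamination(a, genome_lengths[a.genome])
        rows.append(
            {"bin_id": a.bin_id, "genome": a.genome, "bin_bp": a.bin_total_bp,
             "completeness": comp, "contamination": cont}
        )
    return pd.DataFrame(rows, columns=["bin_id", "genome", "bin_bp", "completeness", "contamination"])


def write_metrics(metrics: pd.DataFrame, path: PathLike) -> None:
    metrics.to_csv(path, sep="\t", index=False, float_format="%.4f")
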