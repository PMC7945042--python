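"""Synthetic communities with known ground truth.

Generates the exact inputs the pipeline consumes — contig FASTA, an
oriented edge table, and per-base depth in bedGraph — from simulated
genomes, keeping a truth table (contig → genome and true coordinates) and
a list of planted chimeric junctions.

Each genome is a random nucleotide sequence with a planted abundance; its
per-base depth is drawn i.i.d. Poisson(abundance), the coverage model the
change-point detector assumes. Genomes are fragmented into ordered contigs
whose consecutive pairs overlap (edge gap = -overlap), so a clean genome
reassembles into a single path scaffold whose span equals the genome
length. Bubbles — two variant contigs spanning the same interval, the
graph signature of strain variation — are planted at a configurable rate;
each variant draws Poisson depth at half the genome rate so the summed
track over the bubble stays comparable to the backbone. Depth is simulated
directly per base rather than via reads: the pipeline only ever sees
bedGraph, so read-level simulation would add nothing testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .graph import Contig, ScaffoldEdge, build_graph

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimContig:
    """A simulated contig with its true origin."""

    id: str
    genome: str
    start: int  # true genome coordinates, 0-based half-open
    end: int
    orientation: str
    sequence: str = field(repr=False)
    depth: np.ndarray = field(repr=False)  # in contig orientation

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Junction:
    """A planted chimeric edge between two genomes."""

    source: str  # contig id in genome_a
    target: str  # contig id in genome_b
    genome_a: str
    genome_b: str
    gap: int


@dataclass
class SimulatedCommunity:
    genomes: dict[str, str]  # genome id -> sequence
    genome_depths: dict[str, float]  # genome id -> planted Poisson rate
    contigs: dict[str, SimContig]
    edges: list[ScaffoldEdge]
    truth: dict[str, str]  # contig id -> genome id
    junctions: list[Junction]

    def graph(self):
        """The scaffold graph of the community (validated networkx DiGraph)."""
        contigs = [
            Contig(c.id, c.length, c.orientation) for c in self.contigs.values()
        ]
        return build_graph(contigs, self.edges)

    def depths(self) -> dict[str, np.ndarray]:
        """Planted per-contig depth vectors (the 'primary sample')."""
        return {cid: c.depth for cid, c in self.contigs.items()}

    def contig_lengths(self) -> dict[str, int]:
        return {cid: c.length for cid, c in self.contigs.items()}

    def genome_lengths(self) -> dict[str, int]:
        return {gid: len(seq) for gid, seq in self.genomes.items()}


def _fragment(genome_len: int, frag_range: tuple[int, int], overlap_range: tuple[int, int], rng) -> list[tuple[int, int]]:
    """Cut [0, genome_len) into overlapping intervals."""
    lo, hi = frag_range
    omin, omax = overlap_range
    if lo > genome_len:
        raise ValueError(f"fragment length {lo} exceeds genome length {genome_len}")
    cuts: list[tuple[int, int]] = []
    start = 0
    while True:
        length = int(rng.integers(lo, hi + 1))
        end = start + length
        if end >= genome_len:
            cuts.append((start, genome_len))
            break
        cuts.append((start, end))
        overlap = int(rng.integers(omin, omax + 1))
        start = end - overlap
    # a runt last fragment (shorter than any allowed overlap) merges backwards
    if len(cuts) > 1 and cuts[-1][1] - cuts[-1][0] <= omax + 1:
        last = cuts.pop()
        prev = cuts.pop()
        cuts.append((prev[0], last[1]))
    return cuts


def simulate_community(
    n_genomes: int = 10,
    genome_length: int = 15_000,
    depth_range: tuple[int, int] = (10, 60),
    fragment_length_range: tuple[int, int] = (1_500, 3_000),
    overlap_range: tuple[int, int] = (20, 100),
    bubble_rate: float = 0.1,
    seed: int = 0,
    depths: Sequence[float] | None = None,
    reverse_rate: float = 0.25,
) -> SimulatedCommunity:
    """Build a reproducible community with fully recorded ground truth.

    Parameters
    ----------
    depths
        Optional explicit per-genome Poisson rates, overriding random draws
        from ``depth_range`` (one value per genome). Useful when an
        experiment needs controlled abundance contrasts.
    reverse_rate
        Probability that a non-first fragment is recorded reverse-oriented
        (its sequence and depth vector are stored in contig orientation).
    """
    if n_genomes < 1 or genome_length < 1:
        raise ValueError("n_genomes and genome_length must be positive")
    if depths is not None and len(depths) != n_genomes:
        raise ValueError("depths must list one rate per genome")
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    genome_depths: dict[str, float] = {}
    contigs: dict[str, SimContig] = {}
    edges: list[ScaffoldEdge] = []
    truth: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for gi in range(n_genomes):
        gid = f"genome_{gi + 1:03d}"
        seq = "".join(rng.choice(bases, size=genome_length))
        rate = float(depths[gi]) if depths is not None else float(
            rng.integers(depth_range[0], depth_range[1] + 1)
        )
        genomes[gid] = seq
        genome_depths[gid] = rate
        cuts = _fragment(genome_length, fragment_length_range, overlap_range, rng)
        frag_ids: list[list[str]] = []  # per slot: backbone contig [+ variant]
        for fi, (s, e) in enumerate(cuts):
            cid = f"{gid}_c{fi + 1:03d}"
            orient = "+"
            if fi > 0 and rng.random() < reverse_rate:
                orient = "-"
            sub = seq[s:e]
            cseq = sub if orient == "+" else _revcomp(sub)
            slot = [cid]
            is_bubble = 0 < fi < len(cuts) - 1 and rng.random() < bubble_rate
            slot_rate = rate / 2 if is_bubble else rate
            contigs[cid] = SimContig(
                cid, gid, s, e, orient, cseq,
                rng.poisson(slot_rate, size=e - s).astype(float),
            )
            truth[cid] = gid
            if is_bubble:
                vid = f"{gid}_c{fi + 1:03d}v"
                vseq = list(sub)
                n_mut = max(1, len(vseq) // 50)
                for p in rng.choice(len(vseq), size=n_mut, replace=False):
                    vseq[p] = str(rng.choice(bases))
                contigs[vid] = SimContig(
                    vid, gid, s, e, "+", "".join(vseq),
                    rng.poisson(slot_rate, size=e - s).astype(float),
                )
                truth[vid] = gid
                slot.append(vid)
            frag_ids.append(slot)
        for fi in range(len(cuts) - 1):
            gap = cuts[fi][1] - cuts[fi + 1][0]  # always >= overlap, stored negative
            for u in frag_ids[fi]:
                for v in frag_ids[fi + 1]:
                    edges.append(ScaffoldEdge(u, v, -gap, support=int(rng.integers(3, 12))))
    return SimulatedCommunity(genomes, genome_depths, contigs, edges, truth, [])


def plant_chimera(
    community: SimulatedCommunity,
    genome_a: str,
    genome_b: str,
    seed: int = 0,
    gap: int = 0,
) -> SimulatedCommunity:
    """Append a false edge joining the end of genome_a to the start of genome_b.

    The junction — the scaffold coordinate where the two genomes meet — is
    recorded as truth. A warning is emitted when the two genomes share the
    same planted depth: such a junction produces no coverage discontinuity
    and is undetectable by design.
    """
    for gid in (genome_a, genome_b):
        if gid not in community.genomes:
            raise ValueError(f"unknown genome {gid!r}")
    if community.genome_depths[genome_a] == community.genome_depths[genome_b]:
        warnings.warn(
            f"chimera {genome_a}->{genome_b}: identical planted depths "
            f"({community.genome_depths[genome_a]}); junction will be undetectable"
        )
    def _last_contig(gid: str) -> SimContig:
        cands = [c for c in community.contigs.values() if c.genome == gid and not c.id.endswith("v")]
        return max(cands, key=lambda c: c.end)

    def _first_contig(gid: str) -> SimContig:
        cands = [c for c in community.contigs.values() if c.genome == gid and not c.id.endswith("v")]
        return min(cands, key=lambda c: c.start)

    src = _last_contig(genome_a)
    tgt = _first_contig(genome_b)
    community.edges.append(ScaffoldEdge(src.id, tgt.id, gap, support=2))
    community.junctions.append(Junction(src.id, tgt.id, genome_a, genome_b, gap))
    return community


def sample_depths(
    community: SimulatedCommunity,
    seed: int,
    scale_range: tuple[float, float] = (0.2, 2.0),
    absent_rate: float = 0.0,
) -> dict[str, np.ndarray]:
    """Draw a fresh sample's per-contig depth vectors.

    Each genome's rate is rescaled by a uniform factor (its abundance in
    this sample); with probability ``absent_rate`` a genome is absent and
    all its contigs get zero depth.
    """
    rng = np.random.default_rng(seed)
    factors = {}
    for gid, rate in community.genome_depths.items():
        if rng.random() < absent_rate:
            factors[gid] = 0.0
        else:
            factors[gid] = rate * rng.uniform(*scale_range)
    out = {}
    for cid, c in community.contigs.items():
        slot_rate = factors[c.genome]
        if cid.endswith("v") or (cid + "v") in community.contigs:
            slot_rate /= 2  # bubble arms split the genome's coverage
        out[cid] = rng.poisson(slot_rate, size=c.length).astype(float) if slot_rate > 0 else np.zeros(c.length)
    return out


def write_fasta(community: SimulatedCommunity, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for cid in sorted(community.contigs):
            c = community.contigs[cid]
            fh.write(f">{cid}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")


def write_edges(community: SimulatedCommunity, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("# source\tsource_orientation\ttarget\ttarget_orientation\tgap\tsupport\n")
        for e in community.edges:
            so = community.contigs[e.source].orientation
            to = community.contigs[e.target].orientation
            fh.write(f"{e.source}\t{so}\t{e.target}\t{to}\t{e.gap}\t{e.support}\n")


def write_truth(community: SimulatedCommunity, path: Union[str, Path]) -> None:
    """Truth table: contig, genome, true genome interval, orientation."""
    with open(path, "w") as fh:
        fh.write("contig_id\tgenome_id\tstart\tend\torientation\n")
        for cid in sorted(community.contigs):
            c = community.contigs[cid]
            fh.write(f"{cid}\t{c.genome}\t{c.start}\t{c.end}\t{c.orientation}\n")


def truth_alignments(community: SimulatedCommunity) -> dict[str, list[tuple[str, int, int]]]:
    """Perfect contig-to-genome alignments implied by the truth table."""
    return {
        cid: [(c.genome, c.start, c.end)] for cid, c in community.contigs.items()
    }
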