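"""Scaffold graphs: oriented contigs linked by paired-end evidence.

A scaffold graph is a directed graph whose nodes are contigs (with a length
and an orientation already resolved by the upstream scaffolder) and whose
edges carry a gap estimate in bases — negative gaps mean the two contigs
overlap. Each weakly connected component of the graph is one scaffold,
possibly non-linear: bubbles and branches are preserved rather than forced
into a single path.

The graph is stored as a :class:`networkx.DiGraph` with node attributes
``length`` and ``orientation`` ('+'/'-') and edge attributes ``gap`` and
``support``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import networkx as nx
from Bio import SeqIO

FORWARD = "+"
REVERSE = "-"

PathLike = Union[str, Path]


class GraphInputError(ValueError):
    """Raised when edge or contig input fails validation."""


@dataclass(frozen=True)
class Contig:
    """An assembled contig as a scaffold-graph node."""

    id: str
    length: int
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GraphInputError(f"contig {self.id!r}: length must be >= 1, got {self.length}")
        if self.orientation not in (FORWARD, REVERSE):
            raise GraphInputError(
                f"contig {self.id!r}: orientation must be '+' or '-', got {self.orientation!r}"
            )


@dataclass(frozen=True)
class ScaffoldEdge:
    """A directed linkage edge between two oriented contigs.

    ``gap`` is the estimated distance in bases between the end of the source
    and the start of the target; a negative gap of -k means the contigs
    overlap by k bases.
    """

    source: str
    target: str
    gap: int
    support: int = 1

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise GraphInputError(f"self-edge on contig {self.source!r} is not allowed")
        if self.support < 1:
            raise GraphInputError(
                f"edge {self.source}->{self.target}: support must be positive"
            )


def build_graph(contigs: Iterable[Contig], edges: Iterable[ScaffoldEdge]) -> nx.DiGraph:
    """Assemble and validate a scaffold graph from contigs and edges.

    Raises
    ------
    GraphInputError
        If an edge references an unknown contig, duplicates another edge on
        the same (source, target) pair, or has a gap so negative that the
        projected intervals would degenerate.
    """
    g = nx.DiGraph()
    for c in contigs:
        if c.id in g:
            raise GraphInputError(f"duplicate contig id {c.id!r}")
        g.add_node(c.id, length=c.length, orientation=c.orientation)
    for e in edges:
        for cid in (e.source, e.target):
            if cid not in g:
                raise GraphInputError(f"edge {e.source}->{e.target} references unknown contig {cid!r}")
        if g.has_edge(e.source, e.target):
            raise GraphInputError(f"duplicate edge {e.source}->{e.target}")
        min_len = min(g.nodes[e.source]["length"], g.nodes[e.target]["length"])
        if e.gap <= -min_len:
            raise GraphInputError(
                f"edge {e.source}->{e.target}: gap {e.gap} collapses the shorter contig "
                f"(must be > -{min_len})"
            )
        g.add_edge(e.source, e.target, gap=e.gap, support=e.support)
    return g


def read_edge_table(path: PathLike) -> tuple[list[ScaffoldEdge], dict[str, str]]:
    """Parse the tab-separated oriented-links dialect.

    One edge per line: ``source_id  source_orientation  target_id
    target_orientation  gap  support``; ``#`` starts a comment. Returns the
    edges and the per-contig orientations seen on them (first mention wins;
    conflicting later mentions trigger a warning).
    """
    edges: list[ScaffoldEdge] = []
    orientations: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise GraphInputError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            src, sor, tgt, tor, gap_s, sup_s = fields
            try:
                gap = int(gap_s)
            except ValueError:
                raise GraphInputError(f"{path}:{lineno}: non-integer gap {gap_s!r}") from None
            try:
                support = int(sup_s)
            except ValueError:
                raise GraphInputError(f"{path}:{lineno}: non-integer support {sup_s!r}") from None
            edges.append(ScaffoldEdge(src, tgt, gap, support))
            for cid, orient in ((src, sor), (tgt, tor)):
                if orient not in (FORWARD, REVERSE):
                    raise GraphInputError(
                        f"{path}:{lineno}: orientation must be '+' or '-', got {orient!r}"
                    )
                if cid in orientations:
                    if orientations[cid] != orient:
                        warnings.warn(
                            f"contig {cid!r}: conflicting orientations in edge file; "
                            f"keeping first seen ({orientations[cid]!r})"
                        )
                else:
                    orientations[cid] = orient
    return edges, orientations


def read_contig_lengths(path: PathLike) -> dict[str, int]:
    """Read contig lengths from FASTA or a 2-column ``id<TAB>length`` TSV.

    The format is sniffed from the first non-blank character ('>' = FASTA).
    """
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GraphInputError(f"{path}:{lineno}: expected 'id<TAB>length'")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise GraphInputError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
    return lengths


def load_scaffold_graph(edge_path: PathLike, contig_source: Union[PathLike, Mapping[str, int]]) -> nx.DiGraph:
    """Load a scaffold graph from an edge table plus contig lengths.

    ``contig_source`` may be a FASTA path, a 2-column TSV path, or an
    in-memory id→length mapping. Contigs absent from the edge file become
    singleton scaffolds; contigs referenced by an edge but missing from the
    table raise :class:`GraphInputError`.
    """
    if isinstance(contig_source, (str, Path)):
        lengths = read_contig_lengths(contig_source)
    else:
        lengths = dict(contig_source)
    edges, orientations = read_edge_table(edge_path)
    contigs = [
        Contig(cid, length, orientations.get(cid, FORWARD))
        for cid, length in lengths.items()
    ]
    return build_graph(contigs, edges)


def load_scaffold_graph_gml(path: PathLike) -> nx.DiGraph:
    """Convenience GML reader; expects the same node/edge attributes."""
    g = nx.read_gml(str(path))
    h = nx.DiGraph()
    for n, d in g.nodes(data=True):
        h.add_node(str(n), length=int(d["length"]), orientation=d.get("orientation", FORWARD))
    for u, v, d in g.edges(data=True):
        h.add_edge(str(u), str(v), gap=int(d["gap"]), support=int(d.get("support", 1)))
    return h


def scaffold_components(g: nx.DiGraph) -> list[nx.DiGraph]:
    """Split the graph into scaffolds = weakly connected components.

    Components are returned as independent subgraph copies, ordered by their
    lexicographically smallest contig id so the partition is deterministic.
    """
    comps = sorted(nx.weakly_connected_components(g), key=min)
    return [g.subgraph(c).copy() for c in comps]


def break_cycles(component: nx.DiGraph) -> tuple[nx.DiGraph, list[ScaffoldEdge]]:
    """Make a scaffold component acyclic so coordinates can be assigned.

    A directed cycle leaves the scaffold without an in-degree-0 entry point.
    Finding the fewest edges to cut (minimum feedback arc set) is NP-hard,
    so the heuristic repeatedly picks, among the vertices still involved in
    a cycle, the one with the lowest in-degree (ties to the lexicographically
    smallest id) and removes all of its incoming edges, until the component
    is a DAG. Graphs that are already acyclic are returned untouched.

    Returns the acyclic graph and the list of removed edges.
    """
    h = component.copy()
    removed: list[ScaffoldEdge] = []
    while True:
        cyclic = set()
        for scc in nx.strongly_connected_components(h):
            if len(scc) > 1:
                cyclic |= scc
        if not cyclic:
            break
        victim = min(cyclic, key=lambda n: (h.in_degree(n), n))
        for u in sorted(h.predecessors(victim)):
            d = h.edges[u, victim]
            removed.append(ScaffoldEdge(u, victim, d["gap"], d["support"]))
        h.remove_edges_from([(u, victim) for u in list(h.predecessors(victim))])
    return h, removed
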