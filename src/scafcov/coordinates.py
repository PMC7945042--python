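"""Global coordinate assignment for acyclic scaffold components.

Every in-degree-0 contig is seeded at provisional offset 0 and the rest are
relaxed in topological (breadth-first) order: each edge u→v with gap g
proposes ``end(u) + g`` as the start of v, and v keeps the MAXIMUM proposal
over all its predecessors. With the maximum rule a breadth-first sweep over
a DAG is exactly a longest-path relaxation, which is what keeps bubble arms
aligned on their reconvergence point instead of piling coverage onto an
artificially shortened layout. Negative gaps (overlaps) can push starts
below zero, so the finished frame is shifted so the smallest start is 0;
the scaffold span is then the largest end.

Intervals are 0-based half-open throughout, matching bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import networkx as nx


@dataclass(frozen=True)
class Placement:
    start: int
    end: int
    orientation: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoordinateMap:
    """Global (start, end, orientation) per contig within one scaffold."""

    scaffold_id: str
    placements: dict[str, Placement]

    @property
    def span(self) -> int:
        return scaffold_span(self)

    def boundaries(self) -> list[tuple[int, str, str]]:
        """All contig boundaries as (coordinate, kind, contig_id), sorted."""
        out = []
        for cid, pl in self.placements.items():
            out.append((pl.start, "start", cid))
            out.append((pl.end, "end", cid))
        return sorted(out)


def assign_coordinates(component: nx.DiGraph, scaffold_id: str = "scaffold") -> CoordinateMap:
    """Place every contig of an acyclic component on a global axis.

    Raises
    ------
    ValueError
        If the component still contains a directed cycle (break cycles
        first) or is empty.
    """
    if component.number_of_nodes() == 0:
        raise ValueError("cannot assign coordinates to an empty component")
    try:
        order = list(nx.lexicographical_topological_sort(component))
    except nx.NetworkXUnfeasible:
        raise ValueError(
            f"component for {scaffold_id!r} contains a directed cycle; run break_cycles first"
        ) from None

    start: dict[str, int] = {}
    for v in order:
        proposals = [
            start[u] + component.nodes[u]["length"] + component.edges[u, v]["gap"]
            for u in component.predecessors(v)
        ]
        start[v] = max(proposals, default=0)

    shift = min(start.values())
    placements = {
        v: Placement(
            start[v] - shift,
            start[v] - shift + component.nodes[v]["length"],
            component.nodes[v].get("orientation", "+"),
        )
        for v in component.nodes
    }
    return CoordinateMap(scaffold_id, placements)


def scaffold_span(cmap: CoordinateMap) -> int:
    """Total effective length: distance from leftmost start to rightmost end."""
    if not cmap.placements:
        raise ValueError(f"scaffold {cmap.scaffold_id!r} has no placements")
    starts = [p.start for p in cmap.placements.values()]
    ends = [p.end for p in cmap.placements.values()]
    return max(ends) - min(starts)


def write_coordinates(cmaps: Iterable[CoordinateMap], path: Union[str, Path]) -> None:
    """Write per-contig global coordinates as a TSV."""
    with open(path, "w") as fh:
        fh.write("scaffold_id\tcontig_id\tstart\tend\torientation\n")
        for cmap in cmaps:
            for cid in sorted(cmap.placements):
                pl = cmap.placements[cid]
                fh.write(f"{cmap.scaffold_id}\t{cid}\t{pl.start}\t{pl.end}\t{pl.orientation}\n")
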