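from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from scafcov import Contig, ScaffoldEdge, build_graph


@pytest.fixture
def bubble_graph() -> nx.DiGraph:
    """A(500) forks into B(300) (gap 0) and C(200) (gap 50); both rejoin D(100).

    Longest-path layout: B at (500, 800), C at (550, 750), D starts at
    max(800 + 0, 750 + 0) = 800; span 900.
    """
    contigs = [
        Contig("A", 500),
        Contig("B", 300),
        Contig("C", 200),
        Contig("D", 100),
    ]
    edges = [
        ScaffoldEdge("A", "B", 0),
        ScaffoldEdge("A", "C", 50),
        ScaffoldEdge("B", "D", 0),
        ScaffoldEdge("C", "D", 0),
    ]
    return build_graph(contigs, edges)


@pytest.fixture
def bubble_depths() -> dict[str, np.ndarray]:
    """Uniform depth 10 on every contig of the bubble graph."""
    return {cid: np.full(n, 10.0) for cid, n in
            {"A": 500, "B": 300, "C": 200, "D": 100}.items()}


def bins_by_truth(components, truth, contig_lengths) -> dict[str, list[str]]:
    """Group scaffolds into per-genome bins by majority-bp of their contigs."""
    bins: dict[str, list[str]] = {}
    for comp in components:
        bp: dict[str, int] = {}
        for n in comp.nodes:
            bp[truth[n]] = bp.get(truth[n], 0) + contig_lengths[n]
        winner = max(sorted(bp), key=lambda g: bp[g])
        bins.setdefault(winner, []).extend(comp.nodes)
    return bins
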