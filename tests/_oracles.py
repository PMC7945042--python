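"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own algorithms: path enumeration
instead of topological relaxation, subset search instead of the feedback
heuristic, plain per-window loops instead of cumulative sums.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_force_starts(g: nx.DiGraph) -> dict[str, int]:
    """Normalized start coordinates by exhaustive source-to-node path enumeration."""
    sources = [n for n in g.nodes if g.in_degree(n) == 0]
    starts: dict[str, float] = {}
    for v in g.nodes:
        best = 0.0 if g.in_degree(v) == 0 else -math.inf
        for s in sources:
            if s == v:
                continue
            for path in nx.all_simple_paths(g, s, v):
                w = sum(
                    g.nodes[u]["length"] + g.edges[u, x]["gap"]
                    for u, x in zip(path, path[1:])
                )
                best = max(best, w)
        starts[v] = best
    shift = min(starts.values())
    return {v: int(s - shift) for v, s in starts.items()}


def min_feedback_arc_size(g: nx.DiGraph) -> int:
    """Size of a minimum feedback arc set by exhaustive subset search."""
    edges = list(g.edges)
    for k in range(len(edges) + 1):
        for combo in itertools.combinations(edges, k):
            h = g.copy()
            h.remove_edges_from(combo)
            if nx.is_directed_acyclic_graph(h):
                return k
    raise AssertionError("unreachable")


def naive_z(track: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position Z by direct window slicing (positions, z)."""
    span = track.size
    positions = np.arange(w, span - w + 1)
    z = np.empty(positions.size)
    for k, i in enumerate(positions):
        pred = track[i - w : i]
        succ = track[i : i + w]
        denom = math.sqrt(pred.var() + succ.var())
        z[k] = (pred.mean() - succ.mean()) / denom if denom > 0 else 0.0
    return positions, z


def random_digraph(rng: np.random.Generator, max_nodes: int, p: float = 0.25) -> nx.DiGraph:
    """Random directed graph with contig-like node attributes (no self-loops)."""
    n = int(rng.integers(2, max_nodes + 1))
    g = nx.DiGraph()
    names = [f"c{i:02d}" for i in range(n)]
    for name in names:
        g.add_node(name, length=int(rng.integers(100, 1001)), orientation="+")
    for u in names:
        for v in names:
            if u != v and rng.random() < p:
                g.add_edge(u, v, gap=int(rng.integers(-50, 201)), support=1)
    return g


def random_dag(rng: np.random.Generator, max_nodes: int) -> nx.DiGraph:
    """Random DAG with lengths 100-1000 and gaps -200..500, intervals kept valid."""
    n = int(rng.integers(1, max_nodes + 1))
    g = nx.DiGraph()
    names = [f"c{i:02d}" for i in range(n)]
    for name in names:
        g.add_node(name, length=int(rng.integers(100, 1001)), orientation="+")
    for i in range(n):
        for j in range(i + 1, n):  # edges only forward in index order => acyclic
            if rng.random() < 0.3:
                u, v = names[i], names[j]
                min_len = min(g.nodes[u]["length"], g.nodes[v]["length"])
                gap = int(rng.integers(-200, 501))
                gap = max(gap, -(min_len - 1))
                g.add_edge(u, v, gap=gap, support=1)
    return g
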