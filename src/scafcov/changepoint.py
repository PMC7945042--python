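"""Coverage change-point detection and mis-join correction.

Paired-end linkage occasionally joins contigs from different organisms into
one scaffold. Because each organism's per-base coverage is modelled as
Poisson (approximately Gaussian with mean mu and variance sigma^2), a
chimeric junction shows up as a discontinuity in the scaffold's coverage
track. The detector slides two adjacent windows of |w| bases along the
track and compares their empirical distributions with the two-sample
Z-statistic

    Z(i) = (mu_{i-1} - mu_i) / sqrt(sigma2_{i-1} + sigma2_i)

where window w_{i-1} covers [i-w, i) and window w_i covers [i, i+w).
Positions in the alpha-percentile tails of the scaffold's own empirical Z
distribution become change-point candidates; a candidate that falls within
beta bases of a contig's start (end) triggers delinking of that contig from
its predecessors (successors), splitting the scaffold. Candidates away from
every boundary are reported but never acted on — they may be mid-contig
assembly errors, which are out of scope here.

Candidate selection details (the published description leaves the selection
loop open; these choices are documented in the methods note):

* Selection is two-tailed: Z <= alpha-th percentile or Z >= (100-alpha)-th.
* Because percentile tails are relative, they flag ~2*alpha% of positions
  of every scaffold, including perfectly homogeneous ones. Each candidate
  must therefore also reject the null of equal window means under the
  Poisson/Gaussian coverage model: Var(Z) ~= 1/|w| when both windows sample
  one organism. The scan compares ~span/|w| effectively independent window
  pairs per scaffold, so the two-sided level-(alpha/100) test is Bonferroni
  corrected for that count: |Z| >= z_{1 - alpha/(200*n_eff)} / sqrt(|w|),
  n_eff = span/|w|.
* Candidates within w of one another are merged, keeping the position of
  maximal |Z|.
* If both window variances are 0 the statistic is undefined; equal means
  give Z = 0, unequal means flag the position as a degenerate candidate (a
  certain discontinuity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np
from scipy.stats import norm

from .coordinates import CoordinateMap, assign_coordinates
from .coverage import CoverageTrack, project_coverage
from .graph import break_cycles, scaffold_components

_VAR_EPS = 1e-9
_MEAN_EPS = 1e-9


@dataclass(frozen=True)
class ChangePointParams:
    """Tunables of the detection/correction routine.

    window
        Sliding window size |w| in bp (default 1500). For scaffolds shorter
        than 2*|w| the window is recursively divided by 5 until it fits;
        below ``window_floor`` the scaffold is skipped.
    alpha
        Tail percentile for candidate selection (default 1, i.e. the 1st
        and 99th percentiles).
    beta
        Boundary-match tolerance in bp; conventionally the read length
        (default 150).
    """

    window: int = 1500
    alpha: float = 1.0
    beta: int = 150
    window_floor: int = 10
    iterate: bool = False

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 < self.alpha < 50:
            raise ValueError("alpha must be in (0, 50)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class ZSeries:
    """Windowed two-sample Z-statistic along one scaffold track."""

    positions: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    mu_pred: np.ndarray = field(repr=False)
    var_pred: np.ndarray = field(repr=False)
    mu_succ: np.ndarray = field(repr=False)
    var_succ: np.ndarray = field(repr=False)
    degenerate: np.ndarray = field(repr=False)  # bool: both variances 0, means differ
    window: int = 0

    def z_at(self, position: int) -> float:
        idx = int(position) - int(self.positions[0])
        return float(self.z[idx])


@dataclass(frozen=True)
class ChangePointCall:
    """One candidate change point and the action (if any) it triggered."""

    scaffold_id: str
    position: int
    z: float
    matched_contig: str | None
    boundary: str  # 'start' | 'end' | 'none'
    action: str  # 'delink_predecessors' | 'delink_successors' | 'unresolved'


@dataclass
class CorrectionResult:
    """Full output of one detect-and-delink pass over a scaffold graph."""

    graph: nx.DiGraph
    scaffolds: list[nx.DiGraph]
    cmaps: list[CoordinateMap]
    tracks: list[CoverageTrack]
    calls: list[ChangePointCall]
    removed_edges: list[tuple[str, str]]
    cycle_edges: list[tuple[str, str]]


def effective_window(span: int, w0: int, floor: int = 10) -> int | None:
    """Window size usable on a scaffold of the given span.

    Returns ``w0`` when the span holds two windows; otherwise divides by 5
    (floor division) until it fits, and returns None once the window drops
    below ``floor`` — such scaffolds are too short to scan.
    """
    if span < 1 or w0 < 1:
        raise ValueError("span and window must be positive")
    w = w0
    while span < 2 * w:
        w //= 5
        if w < floor:
            return None
    return w


def z_series(track: CoverageTrack, w: int) -> ZSeries:
    """Compute Z at every position i in [w, span - w].

    Means and population variances come from cumulative sums of the
    mean-centred signal (centring avoids catastrophic cancellation in the
    variance at high depth).
    """
    x = np.asarray(track.depth, dtype=float)
    span = x.size
    if span < 2 * w:
        raise ValueError(f"track span {span} < 2*window ({2 * w})")
    offset = x.mean()
    xc = x - offset
    s1 = np.concatenate([[0.0], np.cumsum(xc)])
    s2 = np.concatenate([[0.0], np.cumsum(xc * xc)])
    pos = np.arange(w, span - w + 1)
    mu_pred_c = (s1[pos] - s1[pos - w]) / w
    mu_succ_c = (s1[pos + w] - s1[pos]) / w
    var_pred = np.maximum((s2[pos] - s2[pos - w]) / w - mu_pred_c**2, 0.0)
    var_succ = np.maximum((s2[pos + w] - s2[pos]) / w - mu_succ_c**2, 0.0)
    diff = mu_pred_c - mu_succ_c
    vsum = var_pred + var_succ
    degenerate = (vsum <= _VAR_EPS) & (np.abs(diff) > _MEAN_EPS)
    z = np.zeros_like(diff)
    ok = vsum > _VAR_EPS
    z[ok] = diff[ok] / np.sqrt(vsum[ok])
    z[degenerate] = np.sign(diff[degenerate]) * np.inf
    return ZSeries(
        positions=pos,
        z=z,
        mu_pred=mu_pred_c + offset,
        var_pred=var_pred,
        mu_succ=mu_succ_c + offset,
        var_succ=var_succ,
        degenerate=degenerate,
        window=w,
    )


def detect_candidates(zs: ZSeries, alpha: float, merge_radius: int | None = None) -> list[int]:
    """Select and merge candidate change-point positions.

    A position qualifies when its Z lies in the alpha-percentile tails of
    the scaffold's empirical Z distribution AND passes the equal-means
    significance gate (see module docstring), or when it is flagged
    degenerate. Qualifying positions closer than the merge radius
    (default: the window size) collapse onto the position of maximal |Z|.
    """
    w = zs.window
    if merge_radius is None:
        merge_radius = w
    z = zs.z
    deg = zs.degenerate
    mask = deg.copy()
    finite = z[~deg]
    if finite.size:
        q_lo, q_hi = np.percentile(finite, [alpha, 100.0 - alpha])
        if q_hi > q_lo:  # a flat Z distribution has no tails
            tails = (~deg) & ((z <= q_lo) | (z >= q_hi))
            span = int(zs.positions[-1]) + w
            n_eff = max(1, round(span / w))
            z_crit = norm.ppf(1.0 - alpha / (200.0 * n_eff)) / math.sqrt(w)
            tails &= np.abs(z) >= z_crit
            mask |= tails
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    # non-maximum suppression within the merge radius, largest |Z| first
    scores = np.where(deg[idx], np.inf, np.abs(z[idx]))
    order = sorted(range(idx.size), key=lambda k: (-scores[k], zs.positions[idx[k]]))
    kept: list[int] = []
    for k in order:
        p = int(zs.positions[idx[k]])
        if all(abs(p - q) > merge_radius for q in kept):
            kept.append(p)
    return sorted(kept)


def match_and_delink(
    candidates: Sequence[int],
    cmap: CoordinateMap,
    graph: nx.DiGraph,
    beta: int,
    zs: ZSeries | None = None,
) -> tuple[nx.DiGraph, list[ChangePointCall]]:
    """Match candidates to contig boundaries and delink mis-joined contigs.

    A candidate at position p matches the nearest boundary b with
    |p - b| <= beta (ties: lexicographically smaller contig id, then start
    before end). A start match removes the contig's incoming edges, an end
    match its outgoing edges. Unmatched candidates are reported with
    action='unresolved' and the graph is left alone.
    """
    edited = graph.copy()
    calls: list[ChangePointCall] = []
    boundaries = cmap.boundaries()
    for p in sorted(int(c) for c in candidates):
        zval = zs.z_at(p) if zs is not None else float("nan")
        best = min(
            boundaries,
            key=lambda b: (abs(p - b[0]), b[2], 0 if b[1] == "start" else 1),
        )
        coord, kind, cid = best
        if abs(p - coord) > beta:
            calls.append(ChangePointCall(cmap.scaffold_id, p, zval, None, "none", "unresolved"))
            continue
        if kind == "start":
            edited.remove_edges_from(list(edited.in_edges(cid)))
            action = "delink_predecessors"
        else:
            edited.remove_edges_from(list(edited.out_edges(cid)))
            action = "delink_successors"
        calls.append(ChangePointCall(cmap.scaffold_id, p, zval, cid, kind, action))
    return edited, calls


def _scaffold_name(index: int) -> str:
    return f"scaffold_{index + 1}"


def layout_scaffolds(
    graph: nx.DiGraph,
    depths: Mapping[str, np.ndarray] | None = None,
) -> tuple[nx.DiGraph, list[nx.DiGraph], list[CoordinateMap], list[CoverageTrack], list[tuple[str, str]]]:
    """Break cycles, extract scaffolds, assign coordinates (and tracks).

    Returns (acyclic working graph, components, coordinate maps, tracks,
    cycle-removed edges); tracks are empty when no depths are given.
    """
    work = graph.copy()
    cycle_edges: list[tuple[str, str]] = []
    for comp in scaffold_components(graph):
        _, removed = break_cycles(comp)
        cycle_edges += [(e.source, e.target) for e in removed]
    work.remove_edges_from(cycle_edges)
    comps = scaffold_components(work)
    cmaps = [assign_coordinates(c, _scaffold_name(i)) for i, c in enumerate(comps)]
    tracks = [project_coverage(m, depths) for m in cmaps] if depths is not None else []
    return work, comps, cmaps, tracks, cycle_edges


def correct_all(
    graph: nx.DiGraph,
    depths: Mapping[str, np.ndarray],
    params: ChangePointParams = ChangePointParams(),
) -> CorrectionResult:
    """One full detect-and-delink pass over every scaffold.

    For each scaffold: break cycles, assign coordinates, project coverage,
    scan for change points, delink boundary-matched candidates. The edited
    graph is then re-componentized and coordinates/tracks are recomputed
    once. Contigs are never removed — only edges — so the contig set is
    conserved. With ``params.iterate`` the pass repeats until no further
    edge is removed.
    """
    work, comps, cmaps, tracks, cycle_edges = layout_scaffolds(graph, depths)
    all_calls: list[ChangePointCall] = []
    removed_edges: list[tuple[str, str]] = []
    while True:
        pass_removed: list[tuple[str, str]] = []
        for comp, cmap, track in zip(comps, cmaps, tracks):
            w = effective_window(track.span, params.window, params.window_floor)
            if w is None:
                continue
            zs = z_series(track, w)
            cands = detect_candidates(zs, params.alpha)
            if not cands:
                continue
            edited, calls = match_and_delink(cands, cmap, comp, params.beta, zs)
            pass_removed += [e for e in comp.edges if not edited.has_edge(*e)]
            all_calls += calls
        work.remove_edges_from(pass_removed)
        removed_edges += pass_removed
        if not pass_removed or not params.iterate:
            break
        comps = scaffold_components(work)
        cmaps = [assign_coordinates(c, _scaffold_name(i)) for i, c in enumerate(comps)]
        tracks = [project_coverage(m, depths) for m in cmaps]
    final_comps = scaffold_components(work)
    final_cmaps = [assign_coordinates(c, _scaffold_name(i)) for i, c in enumerate(final_comps)]
    final_tracks = [project_coverage(m, depths) for m in final_cmaps]
    return CorrectionResult(
        graph=work,
        scaffolds=final_comps,
        cmaps=final_cmaps,
        tracks=final_tracks,
        calls=all_calls,
        removed_edges=removed_edges,
        cycle_edges=cycle_edges,
    )


def write_calls(calls: Iterable[ChangePointCall], path: Union[str, Path]) -> None:
    """Change-point call log as TSV (scaffold ids are pre-correction)."""
    with open(path, "w") as fh:
        fh.write("scaffold\tposition\tz\tmatched_contig\tboundary\taction\n")
        for c in calls:
            contig = c.matched_contig if c.matched_contig is not None else "."
            fh.write(f"{c.scaffold_id}\t{c.position}\t{c.z:.6g}\t{contig}\t{c.boundary}\t{c.action}\n")
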