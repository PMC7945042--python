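from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pytest

from scafcov import (
    ChangePointParams,
    Contig,
    ScaffoldEdge,
    assign_coordinates,
    build_graph,
    correct_all,
    detect_candidates,
    effective_window,
    match_and_delink,
    simulate_community,
    plant_chimera,
    z_series,
)
from scafcov.coverage import CoverageTrack

from _oracles import naive_z


def _step_track(levels, lengths, rng=None):
    parts = []
    for lvl, ln in zip(levels, lengths):
        if rng is None:
            parts.append(np.full(ln, float(lvl)))
        else:
            parts.append(rng.poisson(lvl, ln).astype(float))
    return CoverageTrack("s", np.concatenate(parts))


class TestEffectiveWindow:
    @pytest.mark.parametrize(
        "span,w0,expected",
        [
            (10_000, 1500, 1500),
            (2_800, 1500, 300),  # 1500 -> 300; 2800 >= 600
            (15, 1500, None),  # window collapses below the 10 bp floor
            (3_000, 1500, 1500),  # boundary: span == 2w exactly
        ],
    )
    def test_window_recursion(self, span, w0, expected):
        assert effective_window(span, w0) == expected


class TestZSeries:
    def test_constant_track_all_zero(self):
        zs = z_series(CoverageTrack("s", np.full(5000, 10.0)), 1500)
        assert not zs.degenerate.any()
        assert (zs.z == 0).all()
        assert zs.positions[0] == 1500
        assert zs.positions[-1] == 5000 - 1500

    def test_noiseless_step_is_degenerate_at_junction(self):
        track = _step_track([10, 50], [2000, 2000])
        zs = z_series(track, 1500)
        at = np.flatnonzero(zs.positions == 2000)[0]
        assert zs.degenerate[at]
        assert np.isinf(zs.z[at]) and zs.z[at] < 0

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(8)
        track = _step_track([10, 50], [2500, 2500], rng)
        zs = z_series(track, 1500)
        positions, expected = naive_z(track.depth, 1500)
        np.testing.assert_array_equal(zs.positions, positions)
        np.testing.assert_allclose(zs.z, expected, rtol=1e-9)

    def test_reversed_track_negates_z(self):
        rng = np.random.default_rng(9)
        track = _step_track([10, 50], [2000, 2200], rng)
        zs = z_series(track, 500)
        rev = z_series(CoverageTrack("s", track.depth[::-1]), 500)
        np.testing.assert_allclose(rev.z, -zs.z[::-1], atol=1e-9)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="span"):
            z_series(CoverageTrack("s", np.ones(100)), 100)


class TestDetectCandidates:
    def test_flat_z_gives_no_candidates(self):
        zs = z_series(CoverageTrack("s", np.full(6000, 7.0)), 1500)
        assert detect_candidates(zs, alpha=1.0) == []

    def test_single_step_one_candidate_near_junction(self):
        hits = 0
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            track = _step_track([10, 50], [4000, 4000], rng)
            zs = z_series(track, 1500)
            cands = detect_candidates(zs, alpha=1.0)
            if len(cands) >= 1 and any(abs(c - 4000) <= 1500 for c in cands):
                hits += 1
        assert hits >= 19

    def test_two_distant_steps_two_candidates(self):
        rng = np.random.default_rng(5)
        w = 500
        track = _step_track([10, 50, 10], [3000, 3000, 3000], rng)
        zs = z_series(track, w)
        cands = detect_candidates(zs, alpha=1.0)
        assert len(cands) == 2
        assert any(abs(c - 3000) <= w for c in cands)
        assert any(abs(c - 6000) <= w for c in cands)

    def test_merging_keeps_strongest_within_radius(self):
        rng = np.random.default_rng(6)
        track = _step_track([10, 50], [4000, 4000], rng)
        zs = z_series(track, 1500)
        cands = detect_candidates(zs, alpha=5.0)
        assert len(cands) == len(set(cands))
        for i, p in enumerate(cands):
            for q in cands[i + 1:]:
                assert abs(p - q) > 1500


class TestMatchAndDelink:
    def _two_contig_scaffold(self):
        g = build_graph(
            [Contig("A", 2000), Contig("B", 2000)], [ScaffoldEdge("A", "B", 0)]
        )
        return g, assign_coordinates(g)

    def test_candidate_at_contig_start_delinks_predecessors(self):
        g, cmap = self._two_contig_scaffold()
        edited, calls = match_and_delink([2000], cmap, g, beta=150)
        assert edited.number_of_edges() == 0
        (call,) = calls
        assert call.boundary in ("start", "end")
        assert call.action.startswith("delink")

    def test_far_candidate_is_unresolved(self):
        g, cmap = self._two_contig_scaffold()
        edited, calls = match_and_delink([1000], cmap, g, beta=150)
        assert set(edited.edges) == set(g.edges)
        (call,) = calls
        assert call.action == "unresolved"
        assert call.matched_contig is None

    def test_chimeric_scaffold_splits_into_planted_species(self):
        c = simulate_community(
            n_genomes=2, genome_length=8000, depths=[10, 50],
            overlap_range=(0, 0), bubble_rate=0.0, seed=13,
        )
        plant_chimera(c, "genome_001", "genome_002", seed=13)
        res = correct_all(c.graph(), c.depths())
        parts = [frozenset(s.nodes) for s in res.scaffolds]
        by_genome = {
            g: frozenset(cid for cid, t in c.truth.items() if t == g)
            for g in ("genome_001", "genome_002")
        }
        assert set(parts) == set(by_genome.values())


class TestCorrectAll:
    def test_clean_scaffolding_is_fixed_point(self):
        c = simulate_community(
            n_genomes=3, genome_length=12000, depths=[15, 30, 45],
            overlap_range=(0, 0), bubble_rate=0.0, seed=2,
        )
        g = c.graph()
        res = correct_all(g, c.depths())
        assert res.removed_edges == []
        assert set(res.graph.edges) == set(g.edges)

    def test_contig_conservation_and_edge_subset(self):
        c = simulate_community(n_genomes=4, genome_length=9000, seed=5, bubble_rate=0.3)
        gids = sorted(c.genomes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plant_chimera(c, gids[0], gids[1], seed=5)
        g = c.graph()
        res = correct_all(g, c.depths())
        assert sorted(n for s in res.scaffolds for n in s.nodes) == sorted(g.nodes)
        assert set(res.graph.edges) <= set(g.edges)

    def test_all_singletons_pass_through(self):
        g = build_graph([Contig(f"c{i}", 200) for i in range(5)], [])
        depths = {f"c{i}": np.full(200, 5.0) for i in range(5)}
        res = correct_all(g, depths)
        assert len(res.scaffolds) == 5
        assert res.calls == []

    def test_one_chimera_among_clean_scaffolds(self):
        depths = [10, 50, 20, 30, 40, 15, 60, 25, 35, 55]
        c = simulate_community(
            n_genomes=10, genome_length=10000, depths=depths,
            overlap_range=(0, 0), bubble_rate=0.0, seed=17,
        )
        plant_chimera(c, "genome_001", "genome_002", seed=17)
        res = correct_all(c.graph(), c.depths())
        assert [tuple(e) for e in res.removed_edges] == [
            (c.junctions[0].source, c.junctions[0].target)
        ]
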