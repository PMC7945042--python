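from __future__ import annotations

import io

import numpy as np
import pytest

from scafcov import (
    Contig,
    ScaffoldEdge,
    assign_coordinates,
    build_graph,
    multi_sample_abundance,
    project_coverage,
    read_bedgraph,
    summarize_coverage,
)
from scafcov.coverage import CoverageInputError, CoverageTrack, write_bedgraph


class TestReadBedgraph:
    def test_uniform_interval(self):
        depths = read_bedgraph(io.StringIO("A\t0\t500\t7\n"), {"A": 500})
        assert depths["A"].shape == (500,)
        assert (depths["A"] == 7).all()

    def test_two_intervals_mean(self):
        depths = read_bedgraph(io.StringIO("A\t0\t250\t4\nA\t250\t500\t8\n"), {"A": 500})
        assert depths["A"].mean() == 6.0

    def test_interval_past_contig_end_rejected(self):
        with pytest.raises(CoverageInputError, match=r"A"):
            read_bedgraph(io.StringIO("A\t480\t520\t3\n"), {"A": 500})

    def test_uncovered_positions_default_zero_with_warning(self):
        with pytest.warns(UserWarning, match="-bga"):
            depths = read_bedgraph(io.StringIO("A\t0\t100\t5\n"), {"A": 200})
        assert (depths["A"][100:] == 0).all()

    def test_roundtrip_through_writer(self, tmp_path):
        rng = np.random.default_rng(0)
        original = {"A": rng.poisson(9, 300).astype(float), "B": rng.poisson(2, 150).astype(float)}
        p = tmp_path / "d.bedgraph"
        write_bedgraph(original, p)
        back = read_bedgraph(p, {"A": 300, "B": 150})
        for cid in original:
            np.testing.assert_array_equal(back[cid], original[cid])


class TestProjectCoverage:
    def test_overlap_adds_depth(self):
        g = build_graph(
            [Contig("A", 500), Contig("B", 400)], [ScaffoldEdge("A", "B", -100)]
        )
        cmap = assign_coordinates(g)
        track = project_coverage(cmap, {"A": np.full(500, 5.0), "B": np.full(400, 5.0)})
        assert track.span == 800
        assert (track.depth[:400] == 5).all()
        assert (track.depth[400:500] == 10).all()
        assert (track.depth[500:] == 5).all()

    def test_singleton_identity(self):
        g = build_graph([Contig("A", 50)], [])
        vec = np.arange(50, dtype=float)
        track = project_coverage(assign_coordinates(g), {"A": vec})
        np.testing.assert_array_equal(track.depth, vec)

    def test_bubble_mass_conservation(self, bubble_graph, bubble_depths):
        track = project_coverage(assign_coordinates(bubble_graph), bubble_depths)
        assert track.depth.sum() == 10 * (500 + 300 + 200 + 100)

    def test_missing_depth_names_contig(self, bubble_graph, bubble_depths):
        del bubble_depths["C"]
        with pytest.raises(CoverageInputError, match="'C'"):
            project_coverage(assign_coordinates(bubble_graph), bubble_depths)

    def test_conservation_on_random_fixtures(self):
        from _oracles import random_dag

        rng = np.random.default_rng(21)
        for _ in range(25):
            g = random_dag(rng, 8)
            cmap = assign_coordinates(g)
            depths = {
                n: rng.integers(0, 30, size=g.nodes[n]["length"]).astype(float)
                for n in g.nodes
            }
            track = project_coverage(cmap, depths)
            assert track.depth.sum() == sum(v.sum() for v in depths.values())

    def test_reversing_contig_and_vector_leaves_track_unchanged(self, bubble_graph, bubble_depths):
        rng = np.random.default_rng(1)
        bubble_depths["B"] = rng.poisson(8, 300).astype(float)
        base = project_coverage(assign_coordinates(bubble_graph), bubble_depths)
        flipped_graph = bubble_graph.copy()
        flipped_graph.nodes["B"]["orientation"] = "-"
        flipped_depths = dict(bubble_depths, B=bubble_depths["B"][::-1])
        flipped = project_coverage(assign_coordinates(flipped_graph), flipped_depths)
        np.testing.assert_array_equal(base.depth, flipped.depth)

    def test_adding_contig_never_decreases_track(self, bubble_graph, bubble_depths):
        without = bubble_graph.copy()
        without.remove_node("C")
        t0 = project_coverage(assign_coordinates(without), bubble_depths)
        t1 = project_coverage(assign_coordinates(bubble_graph), bubble_depths)
        assert t0.span == t1.span  # C is interior to the bubble
        assert (t1.depth >= t0.depth).all()


class TestSummaries:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            (np.full(1000, 10.0), (10.0, 0.0)),
            (np.concatenate([np.full(500, 4.0), np.full(500, 8.0)]), (6.0, 2.0)),
        ],
    )
    def test_known_summaries(self, vec, expected):
        assert summarize_coverage(CoverageTrack("s", vec)) == expected

    def test_matches_naive_two_pass(self):
        rng = np.random.default_rng(2)
        vec = rng.poisson(14, 5000).astype(float)
        mean, std = summarize_coverage(CoverageTrack("s", vec))
        naive_mean = sum(vec) / len(vec)
        naive_std = (sum((x - naive_mean) ** 2 for x in vec) / len(vec)) ** 0.5
        assert mean == pytest.approx(naive_mean, rel=1e-12)
        assert std == pytest.approx(naive_std, rel=1e-12)


class TestMultiSample:
    def _single_scaffold(self):
        g = build_graph([Contig("A", 200)], [])
        return [assign_coordinates(g, "s1")]

    def test_single_cell(self):
        table = multi_sample_abundance(self._single_scaffold(), [{"A": np.full(200, 12.0)}])
        row = table.iloc[0]
        assert row["sample_1.mean"] == 12.0
        assert row["sample_1.var"] == 0.0
        assert row["totalAvgDepth"] == 12.0

    def test_two_samples_keep_column_order(self):
        table = multi_sample_abundance(
            self._single_scaffold(),
            [{"A": np.full(200, 5.0)}, {"A": np.full(200, 20.0)}],
            ["t0", "t1"],
        )
        assert list(table.columns) == [
            "contigName", "contigLen", "totalAvgDepth", "t0.mean", "t0.var", "t1.mean", "t1.var",
        ]
        assert table.iloc[0]["t0.mean"] == 5.0
        assert table.iloc[0]["t1.mean"] == 20.0

    def test_absent_sample_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            table = multi_sample_abundance(
                self._single_scaffold(), [{"A": np.full(200, 7.0)}, {}], ["t0", "t1"]
            )
        assert table.iloc[0]["t1.mean"] == 0.0
        assert table.iloc[0]["t1.var"] == 0.0
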