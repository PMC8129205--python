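"""Matrix preprocessing, Louvain consensus, and visual summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tracemap import connectivity as cn
from tracemap import synth


def make_matrix(vals, kinds=None, index=None, columns=None, colors=None):
    df = pd.DataFrame(np.asarray(vals, dtype=float))
    df.index = index or [f"i{k}" for k in range(len(df))]
    df.columns = columns if columns is not None else [f"t{k}" for k in range(df.shape[1])]
    kinds = kinds or {i: cn.ANTEROGRADE for i in df.index}
    return cn.AnnotationMatrix(df, kinds, colors or {})


@pytest.fixture(scope="module")
def planted_3block():
    blocks = [
        (list(range(0, 6)), list(range(0, 40)), 1.0),
        (list(range(6, 12)), list(range(40, 80)), 1.2),
        (list(range(12, 18)), list(range(80, 120)), 0.9),
    ]
    spec = synth.PlantedMatrixSpec(18, 120, blocks, noise_rate=0.02, seed=4)
    return synth.gen_annotation_matrix(spec)


class TestAggregate:
    def test_single_case_identity(self):
        m = make_matrix([[1.0, 2.0]])
        out = cn.aggregate([m])
        assert out.values.equals(m.values)

    def test_disjoint_targets_concatenate(self):
        a = make_matrix([[1.0]], index=["a"], columns=["t1"])
        b = make_matrix([[2.0]], index=["b"], columns=["t2"])
        out = cn.aggregate([a, b])
        assert out.values.shape == (2, 2)
        assert out.values.loc["a", "t2"] == 0.0

    def test_shared_target_columns_summed(self):
        a = make_matrix([[1.0]], index=["a"], columns=["t1"])
        b = make_matrix([[2.5]], index=["a"], columns=["t1"])
        out = cn.aggregate([a, b])
        assert out.values.loc["a", "t1"] == pytest.approx(3.5)

    def test_conflicting_tracer_kind_rejected(self):
        a = make_matrix([[1.0]], index=["a"], kinds={"a": cn.ANTEROGRADE})
        b = make_matrix([[1.0]], index=["a"], kinds={"a": cn.RETROGRADE})
        with pytest.raises(ValueError, match="conflicting"):
            cn.aggregate([a, b])


class TestThresholds:
    def test_anterograde_keeps_at_threshold(self):
        m = make_matrix([[0.0045, 0.0044]])
        out = cn.apply_thresholds(m)
        assert list(out.values.iloc[0]) == [0.0045, 0.0]

    def test_retrograde_keeps_at_threshold(self):
        m = make_matrix([[8.0, 7.0]], kinds={"i0": cn.RETROGRADE})
        out = cn.apply_thresholds(m)
        assert list(out.values.iloc[0]) == [8.0, 0.0]

    def test_zero_matrix_unchanged(self):
        m = make_matrix(np.zeros((2, 3)))
        assert cn.apply_thresholds(m).values.equals(m.values)

    def test_never_increases_entries(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.random((4, 10)) * 0.01)
        out = cn.apply_thresholds(m)
        assert np.all(out.values.to_numpy() <= m.values.to_numpy())


class TestNormalization:
    def test_row_totals_equalized(self):
        m = make_matrix([[5.0, 0.0], [4.0, 6.0], [12.0, 8.0]])
        out = cn.normalize_rows(m)
        assert np.allclose(out.values.sum(axis=1), 20.0)

    def test_proportions_preserved(self):
        m = make_matrix([[1.0, 3.0], [10.0, 30.0]])
        out = cn.normalize_rows(m)
        props = out.values.div(out.values.sum(axis=1), axis=0)
        assert np.allclose(props.iloc[0], props.iloc[1])

    def test_max_row_bit_identical(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        out = cn.normalize_rows(m)
        assert np.array_equal(
            out.values.iloc[1].to_numpy(), m.values.iloc[1].to_numpy()
        )

    def test_single_row_unchanged(self):
        m = make_matrix([[1.0, 2.0]])
        assert cn.normalize_rows(m).values.equals(m.values)

    def test_zero_row_warns_all_zero_errors(self):
        m = make_matrix([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="no labeling"):
            out = cn.normalize_rows(m)
        assert out.values.iloc[0].sum() == 0
        with pytest.raises(ValueError):
            cn.normalize_rows(make_matrix(np.zeros((2, 2))))


class TestLouvain:
    def test_disconnected_blocks_always_split(self):
        m = make_matrix([[1.0, 1.0, 0, 0], [0, 0, 1.0, 1.0]])
        runs = cn.louvain_runs(m, n_runs=10, seed=1)
        for p in runs:
            assert p.n_communities == 2
            assert (
                p.assignment[cn.inj_node("i0")] != p.assignment[cn.inj_node("i1")]
            )

    def test_single_run_reproducible(self, planted_3block):
        m, _ = planted_3block
        m = cn.normalize_rows(cn.apply_thresholds(m))
        a = cn.louvain_runs(m, n_runs=1, seed=7)[0]
        b = cn.louvain_runs(m, n_runs=1, seed=7)[0]
        assert a.assignment == b.assignment

    def test_modal_run_recovers_planted_partition(self, planted_3block):
        m, planted = planted_3block
        m = cn.normalize_rows(cn.apply_thresholds(m))
        runs = cn.louvain_runs(m, n_runs=20, seed=3)
        nodes = sorted(planted, key=str)
        true = [planted[n] for n in nodes]
        aris = [
            adjusted_rand_score(true, [p.assignment[n] for n in nodes])
            for p in runs
        ]
        assert np.median(aris) >= 0.95

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            cn.louvain_runs(make_matrix(np.zeros((2, 2))), n_runs=1, seed=0)

    def test_partition_beats_trivial_modularity(self, planted_3block):
        import networkx as nx

        m, _ = planted_3block
        m = cn.normalize_rows(cn.apply_thresholds(m))
        g = cn.to_bipartite_graph(m)
        p = cn.louvain_runs(m, n_runs=1, seed=5)[0]
        comms = {}
        for n, c in p.assignment.items():
            comms.setdefault(c, set()).add(n)
        mod = nx.community.modularity(g, comms.values(), weight="weight")
        trivial = nx.community.modularity(g, [set(g.nodes)], weight="weight")
        assert mod >= trivial


class TestConsensus:
    def test_identical_partitions_fixed_point(self):
        assignment = {cn.inj_node("a"): 0, cn.tgt_node("x"): 0, cn.tgt_node("y"): 1}
        parts = [cn.CommunityPartition(dict(assignment), 1.0) for _ in range(10)]
        out = cn.consensus(parts, seed=0)
        assert out.assignment == parts[0].assignment
        assert out.provenance == "consensus-of-10"

    def test_idempotence(self, planted_3block):
        m, _ = planted_3block
        m = cn.normalize_rows(cn.apply_thresholds(m))
        runs = cn.louvain_runs(m, n_runs=12, seed=2)
        once = cn.consensus(runs, seed=1)
        twice = cn.consensus([once], seed=1)
        assert once.assignment == twice.assignment

    def test_split_node_joins_higher_coassignment_tie_lower_id(self):
        a1, a2 = cn.inj_node("a1"), cn.inj_node("a2")
        b1, b2 = cn.inj_node("b1"), cn.inj_node("b2")
        x = cn.tgt_node("x")
        base = {a1: 0, a2: 0, b1: 1, b2: 1}
        with_a = cn.CommunityPartition({**base, x: 0}, 1.0)
        with_b = cn.CommunityPartition({**base, x: 1}, 1.0)
        out = cn.consensus([with_a] * 5 + [with_b] * 5, seed=0)
        # blocks stay intact; the 50/50 node ties and takes the lower id
        assert out.assignment[a1] == out.assignment[a2]
        assert out.assignment[b1] == out.assignment[b2]
        assert out.assignment[a1] != out.assignment[b1]
        assert out.assignment[x] == out.assignment[a1]
        out2 = cn.consensus([with_a] * 7 + [with_b] * 3, seed=0)
        assert out2.assignment[x] == out2.assignment[a1]
        out3 = cn.consensus([with_a] * 3 + [with_b] * 7, seed=0)
        assert out3.assignment[x] == out3.assignment[b1]

    def test_node_set_mismatch_rejected(self):
        p1 = cn.CommunityPartition({cn.inj_node("a"): 0}, 1.0)
        p2 = cn.CommunityPartition({cn.inj_node("b"): 0}, 1.0)
        with pytest.raises(ValueError, match="node sets"):
            cn.consensus([p1, p2])


class TestReorder:
    def test_block_diagonal_made_contiguous(self, planted_3block):
        m, planted = planted_3block
        # shuffle rows/columns then recover block contiguity
        rng = np.random.default_rng(0)
        rows = list(m.values.index)
        cols = list(m.values.columns)
        rng.shuffle(rows)
        rng.shuffle(cols)
        shuffled = cn.AnnotationMatrix(
            m.values.loc[rows, cols], m.tracer_kind, m.colors
        )
        p = cn.CommunityPartition(dict(planted), 1.0)
        row_order, col_order = cn.reorder_for_matrix(shuffled, p)
        row_comms = [planted[cn.inj_node(r)] for r in row_order]
        col_comms = [planted[cn.tgt_node(c)] for c in col_order]
        assert row_comms == sorted(row_comms)
        assert col_comms == sorted(col_comms)

    def test_single_community_sorts_by_strength(self):
        m = make_matrix([[1.0, 5.0], [3.0, 4.0]])
        nodes = {cn.inj_node(i): 0 for i in m.injections}
        nodes.update({cn.tgt_node(t): 0 for t in m.targets})
        rows, cols = cn.reorder_for_matrix(m, cn.CommunityPartition(nodes, 1.0))
        assert rows == ["i1", "i0"]  # totals 7 > 6
        assert cols == ["t1", "t0"]  # totals 9 > 4


class TestColorCoding:
    def grid_matrix(self, vals, levels=(0,)):
        cols = [(lvl, 0, c) for lvl in levels for c in range(len(vals[0]) // len(levels))]
        return make_matrix(vals, columns=cols, colors={"i0": (1.0, 0, 0), "i1": (0, 0, 1.0)})

    def test_single_injection_single_color(self):
        m = self.grid_matrix([[1.0, 1.0]])
        p = cn.CommunityPartition(
            {cn.inj_node("i0"): 0, cn.tgt_node((0, 0, 0)): 0, cn.tgt_node((0, 0, 1)): 0},
            1.0,
        )
        seg = np.zeros((10, 400), dtype=bool)
        seg[2, 5] = seg[3, 200] = True
        maps = cn.color_code(p, m, {0: seg})
        assert np.allclose(maps[0].raster[2, 5], (1.0, 0, 0))
        assert np.allclose(maps[0].raster[3, 200], (1.0, 0, 0))

    def test_shared_community_pixel_goes_to_max_value_injection(self):
        m = self.grid_matrix([[0.9], [0.1]])
        p = cn.CommunityPartition(
            {cn.inj_node("i0"): 0, cn.inj_node("i1"): 0, cn.tgt_node((0, 0, 0)): 0},
            1.0,
        )
        seg = np.zeros((8, 8), dtype=bool)
        seg[1, 1] = True
        maps = cn.color_code(p, m, {0: seg})
        assert np.allclose(maps[0].raster[1, 1], (1.0, 0, 0))

    def test_community_without_injection_flagged(self):
        m = self.grid_matrix([[1.0, 0.0]])
        p = cn.CommunityPartition(
            {cn.inj_node("i0"): 0, cn.tgt_node((0, 0, 0)): 0, cn.tgt_node((0, 0, 1)): 1},
            1.0,
        )
        seg = np.zeros((8, 400), dtype=bool)
        seg[1, 200] = True  # grid (0,0,1): community 1 has no injection
        maps = cn.color_code(p, m, {0: seg})
        assert (0, 0, 1) in maps[0].uncolored_grids
        assert np.allclose(maps[0].raster[1, 200], 0.0)

    def test_distinct_colors_bounded_by_injections(self, planted_3block):
        m, planted = planted_3block
        colors = {i: tuple(np.random.default_rng(k).random(3)) for k, i in enumerate(m.injections)}
        m = cn.AnnotationMatrix(m.values, m.tracer_kind, colors)
        # no segmented pixels needed to check the legend bound
        maps = cn.color_code(
            cn.CommunityPartition(dict(planted), 1.0), m,
            {0: np.zeros((4, 4), dtype=bool)},
        )
        assert len(maps[0].legend) <= len(m.injections)


class TestStackedBars:
    def test_single_level_concentration(self):
        cols = [(3, 0, 0), (3, 0, 1)]
        m = make_matrix([[2.0, 3.0]], columns=cols)
        out = cn.stacked_bar_data(m, {c: "ACB" for c in cols})
        assert out.loc[0, "fraction"] == pytest.approx(1.0)

    def test_uniform_across_levels(self):
        cols = [(lvl, 0, 0) for lvl in range(4)]
        m = make_matrix([[1.0, 1.0, 1.0, 1.0]], columns=cols)
        out = cn.stacked_bar_data(m, {c: "X" for c in cols})
        assert np.allclose(out["fraction"], 0.25)

    def test_top_two_rois_match_brute_force(self):
        rng = np.random.default_rng(5)
        cols = [(0, 0, c) for c in range(12)]
        rois = ["ACB", "OT", "PL", "ILA"]
        lookup = {c: rois[k % 4] for k, c in enumerate(cols)}
        m = make_matrix(rng.random((3, 12)), columns=cols)
        out = cn.stacked_bar_data(m, lookup)
        sums = {}
        for c in cols:
            sums[lookup[c]] = sums.get(lookup[c], 0.0) + m.values[c].sum()
        expect = tuple(sorted(sums, key=lambda r: (-sums[r], r))[:2])
        assert out.loc[0, "top_rois"] == expect


class TestClustering:
    def test_identical_vectors_merge_first(self):
        vec = pd.DataFrame(
            [[1.0, 2.0, 0.0], [2.0, 4.0, 0.0], [0.0, 0.0, 5.0]],
            index=["a", "b", "c"],
        )
        out = cn.cluster_projection_vectors(vec)
        assert out.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(out.cut(2)[x] for x in ("a", "b")) == {out.cut(2)["a"]}

    def test_orthogonal_vectors_distance_one(self):
        vec = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        out = cn.cluster_projection_vectors(vec)
        assert out.linkage_matrix[0, 2] == pytest.approx(1.0)

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(0)
        rows, truth = {}, []
        for g in range(3):
            proto = np.full(30, 0.1)
            proto[g * 10:(g + 1) * 10] = 5.0
            for i in range(5):
                rows[f"g{g}c{i}"] = proto * (1 + 0.08 * rng.standard_normal(30))
                truth.append(g)
        cut = cn.cluster_projection_vectors(pd.DataFrame(rows).T).cut(3)
        labels = [cut[f"g{g}c{i}"] for g in range(3) for i in range(5)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_zero_vector_named_in_error(self):
        vec = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            cn.cluster_projection_vectors(vec)


class TestTertiles:
    def test_one_to_nine(self):
        out = cn.tertile_bins(np.arange(1, 10))
        assert list(out[:3]) == ["weak"] * 3
        assert list(out[3:6]) == ["moderate"] * 3
        assert list(out[6:]) == ["strong"] * 3

    def test_all_equal_all_strong(self):
        assert list(cn.tertile_bins([2.0, 2.0, 2.0])) == ["strong"] * 3

    def test_uniform_draw_bin_sizes(self):
        vals = np.random.default_rng(1).random(100)
        out = cn.tertile_bins(vals)
        counts = {b: int(np.sum(out == b)) for b in ("weak", "moderate", "strong")}
        assert all(abs(c - 100 / 3) <= 1.5 for c in counts.values())

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            cn.tertile_bins([1.0, 2.0])
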