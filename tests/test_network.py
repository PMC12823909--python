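import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microgat.data_io import AbundanceTable, normalize_to_percent
from microgat.network import (
    build_network,
    clr_transform,
    coat_correlation,
    default_pseudocount,
    induce_sample_graph,
    read_network,
    shuffle_edges,
    write_network,
)
from microgat.synthetic_data import SimulationConfig, generate_dataset


def brute_force_coat(values, pseudocount):
    """Independent oracle: explicit-loop CLR + textbook Pearson per pair."""
    n, g = values.shape
    clr = np.zeros((n, g))
    for i in range(n):
        x = np.array(
            [values[i, j] if values[i, j] > 0 else pseudocount for j in range(g)]
        )
        logs = np.log(x)
        gm = logs.mean()
        clr[i] = logs - gm
    corr = np.eye(g)
    for a in range(g):
        for b in range(a + 1, g):
            xa, xb = clr[:, a], clr[:, b]
            da, db = xa - xa.mean(), xb - xb.mean()
            denom = np.sqrt((da**2).sum() * (db**2).sum())
            c = (da * db).sum() / denom if denom > 0 else 0.0
            corr[a, b] = corr[b, a] = c
    return corr


class TestClr:
    def test_uniform_composition_is_zero(self):
        np.testing.assert_allclose(clr_transform(np.array([5.0, 5.0, 5.0])), 0.0)

    def test_hand_computed_example(self):
        out = clr_transform(np.array([1.0, 2.0, 4.0]))
        np.testing.assert_allclose(out, [-np.log(2), 0.0, np.log(2)], atol=1e-12)

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_components_sum_to_zero(self, xs):
        x = np.asarray(xs)
        if np.all(x == 0):
            with pytest.raises(ValueError):
                clr_transform(x, pseudocount=0.01)
        else:
            assert abs(clr_transform(x, pseudocount=0.01).sum()) < 1e-9

    def test_zero_without_pseudocount_errors(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([0.0, 1.0, 2.0]))


class TestCoat:
    def test_identical_columns_correlate_fully(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(1, 10, size=12)
        other = rng.uniform(1, 10, size=(12, 2))
        values = np.column_stack([col, col, other])
        corr = coat_correlation(values)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.1, 20.0, size=(10, 5))
        pc = default_pseudocount(values)
        ours = coat_correlation(values, pc)
        oracle = brute_force_coat(values, pc)
        assert np.abs(ours - oracle).max() < 1e-10

    def test_constant_composition_gets_zero_correlations(self):
        rng = np.random.default_rng(1)
        # every sample is the same composition rescaled: CLR variance is zero
        # for every genus, so all off-diagonal correlations are defined as 0
        base = np.array([4.0, 3.0, 2.0, 1.0])
        scales = rng.uniform(0.5, 2.0, size=10)
        values = np.outer(scales, base)
        corr = coat_correlation(values)
        off = corr - np.diag(np.diag(corr))
        assert np.all(off == 0)
        assert np.all(np.diag(corr) == 1.0)


def brute_force_network(table, tau, n_subsamples, fraction, pseudocount, seed):
    """Independent re-implementation of the subsample retention rule."""
    rng = np.random.default_rng(seed)
    n = table.n_samples
    m = int(np.floor(fraction * n))
    mats = []
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        mats.append(brute_force_coat(table.values[idx], pseudocount))
    g = table.n_genera
    edges = {}
    for i in range(g):
        for j in range(i + 1, g):
            cs = [mat[i, j] for mat in mats]
            if all(abs(c) >= tau for c in cs) and (
                all(c > 0 for c in cs) or all(c < 0 for c in cs)
            ):
                a, b = sorted((table.genus_ids[i], table.genus_ids[j]))
                edges[(a, b)] = np.mean(cs)
    return edges


class TestBuildNetwork:
    def test_matches_independent_retention_oracle(self):
        cfg = SimulationConfig(seed=21, n_samples=40, n_genera=10, n_blocks=1,
                               block_size=5, n_discriminative=0, embedding_dim=4)
        table, _, _, _ = generate_dataset(cfg)
        pc = default_pseudocount(table.values)
        net = build_network(table, tau=0.1, n_subsamples=5, subsample_fraction=0.8,
                            pseudocount=pc, seed=13)
        oracle = brute_force_network(table, 0.1, 5, 0.8, pc, 13)
        assert set(net.edges) == set(oracle)
        for e, w in net.edges.items():
            assert w == pytest.approx(oracle[e], abs=1e-10)

    def test_single_full_subsample_tau_zero_keeps_nonzero_pairs(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.5, 10, size=(12, 5))
        table = AbundanceTable([f"s{i}" for i in range(12)],
                               [f"g{j}" for j in range(5)], values)
        table = normalize_to_percent(table)
        net = build_network(table, tau=0.0, n_subsamples=1, subsample_fraction=1.0,
                            seed=0)
        corr = coat_correlation(table.values)
        expected = sum(
            1
            for i in range(5)
            for j in range(i + 1, 5)
            if corr[i, j] != 0
        )
        assert net.n_edges == expected

    def test_impossible_threshold_gives_empty_network(self, small_dataset):
        table = small_dataset[0]
        net = build_network(table, tau=1.01, seed=0)
        assert net.n_edges == 0

    def test_monotone_in_tau(self, small_dataset):
        table = small_dataset[0]
        loose = build_network(table, tau=0.1, seed=5)
        tight = build_network(table, tau=0.2, seed=5)
        assert set(tight.edges) <= set(loose.edges)

    def test_deterministic_given_seed(self, small_dataset):
        table = small_dataset[0]
        n1 = build_network(table, seed=2)
        n2 = build_network(table, seed=2)
        assert n1.edges == n2.edges

    def test_planted_block_recovery(self):
        # one 8-genus block among 60 genera: enough passive genera that the
        # compositional closure term does not spill the block factor into
        # every CLR coordinate
        cfg = SimulationConfig(seed=31, n_samples=300, n_genera=150, n_blocks=1,
                               block_size=8, n_discriminative=0, effect_size=0.0,
                               zero_inflation=0.0, embedding_dim=4,
                               latent_strength=1.3, noise_sd=1.0)
        table, _, _, truth = generate_dataset(cfg)
        net = build_network(table, seed=17)
        in_block = {g for g, b in truth.block_memberships.items() if b is not None}
        within = [
            (a, b)
            for a in sorted(in_block)
            for b in sorted(in_block)
            if a < b
        ]
        found_within = sum(1 for e in within if e in net.edges)
        between = [e for e in net.edges if not (e[0] in in_block and e[1] in in_block)]
        n_between_pairs = (150 * 149) // 2 - len(within)
        assert found_within / len(within) >= 0.8
        assert len(between) / n_between_pairs <= 0.05

    def test_small_subsample_errors(self, toy):
        table, _, _ = toy
        with pytest.raises(ValueError):
            build_network(table, subsample_fraction=0.25, seed=0)


class TestSampleGraphs:
    def test_toy_fixture_induction_matches_hand_enumeration(self, toy):
        table, embeddings, _ = toy
        # hand-built network over the 6 toy genera
        edges = {
            ("gA", "gB"): 0.5,
            ("gA", "gD"): -0.3,
            ("gB", "gC"): 0.4,
            ("gC", "gF"): 0.2,
            ("gD", "gE"): 0.6,
        }
        from microgat.network import CoexpressionNetwork

        net = CoexpressionNetwork(list(table.genus_ids), edges)
        # sample T1 has gF = 0: active gA..gE, edges not involving gF
        g = induce_sample_graph(net, table, embeddings, "T1")
        assert g.genus_ids == ["gA", "gB", "gC", "gD", "gE"]
        named = {
            tuple(sorted((g.genus_ids[i], g.genus_ids[j]))) for i, j in g.edges
        }
        assert named == {("gA", "gB"), ("gA", "gD"), ("gB", "gC"), ("gD", "gE")}
        # sample T2 has gC = 0
        g2 = induce_sample_graph(net, table, embeddings, "T2")
        assert "gC" not in g2.genus_ids
        named2 = {
            tuple(sorted((g2.genus_ids[i], g2.genus_ids[j]))) for i, j in g2.edges
        }
        assert named2 == {("gA", "gB"), ("gA", "gD"), ("gD", "gE")}

    def test_no_edge_touches_inactive_genus(self, small_dataset, small_graphs):
        table = small_dataset[0]
        net, graphs = small_graphs
        for g in graphs:
            assert (g.abundance > 0).all()
            for i, j in g.edges:
                assert 0 <= i < g.n_nodes and 0 <= j < g.n_nodes

    def test_all_nonzero_sample_recovers_global_network(self, toy):
        table, embeddings, _ = toy
        from microgat.network import CoexpressionNetwork

        net = CoexpressionNetwork(
            list(table.genus_ids), {("gA", "gB"): 0.5, ("gE", "gF"): -0.2}
        )
        g = induce_sample_graph(net, table, embeddings, "T5")  # fully dense sample
        assert g.n_nodes == 6
        assert g.n_edges == 2

    def test_single_active_genus_gives_one_node_no_edges(self, toy):
        _, embeddings, _ = toy
        from microgat.network import CoexpressionNetwork

        table = AbundanceTable(
            ["only"], ["gA", "gB", "gC", "gD", "gE", "gF"],
            np.array([[100.0, 0, 0, 0, 0, 0]]),
        )
        net = CoexpressionNetwork(list(table.genus_ids), {("gA", "gB"): 0.9})
        g = induce_sample_graph(net, table, embeddings, "only")
        assert g.n_nodes == 1 and g.n_edges == 0


class TestShuffleEdges:
    def test_preserves_node_and_edge_counts(self, small_graphs):
        _, graphs = small_graphs
        g = max(graphs, key=lambda x: x.n_edges)
        sh = shuffle_edges(g, seed=0)
        assert sh.n_nodes == g.n_nodes and sh.n_edges == g.n_edges
        assert (sh.edges[:, 0] != sh.edges[:, 1]).all()
        assert len({tuple(e) for e in sh.edges}) == sh.n_edges

    def test_two_node_single_edge_unchanged(self):
        from microgat.network import SampleGraph

        g = SampleGraph("x", ["a", "b"], np.array([1.0, 2.0]),
                        np.zeros((2, 3)), np.array([[0, 1]]))
        sh = shuffle_edges(g, seed=99)
        np.testing.assert_array_equal(sh.edges, [[0, 1]])

    def test_deterministic(self, small_graphs):
        _, graphs = small_graphs
        g = max(graphs, key=lambda x: x.n_edges)
        a = shuffle_edges(g, seed=5)
        b = shuffle_edges(g, seed=5)
        np.testing.assert_array_equal(a.edges, b.edges)


def test_network_roundtrip(tmp_path, small_dataset):
    table = small_dataset[0]
    net = build_network(table, seed=1)
    write_network(net, tmp_path / "edges.tsv", tmp_path / "meta.json")
    back = read_network(tmp_path / "edges.tsv", tmp_path / "meta.json")
    assert back.genus_ids == net.genus_ids
    assert set(back.edges) == set(net.edges)
    for e in net.edges:
        assert back.edges[e] == pytest.approx(net.edges[e], rel=1e-10)
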