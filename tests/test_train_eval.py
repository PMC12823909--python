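import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from microgat.model import ModelConfig, predict_proba
from microgat.train_eval import (
    TrainConfig,
    compute_metrics,
    ensemble_predict,
    graph_embedding_silhouette,
    mann_whitney_u,
    run_ablation,
    split_dataset,
    summarize_runs,
    train_model,
    variant_graphs,
)

QUICK_TRAIN = TrainConfig(
    learning_rate=2e-3, max_epochs=8, early_stop_patience=8, weight_decay=0.0
)
QUICK_MODEL = ModelConfig(
    n_layers=2, n_heads=2, node_dim=8, abundance_dim=8, genomic_dim=8,
    mlp_hidden=(8, 4),
)


class TestSplit:
    def test_paper_cohort_sizes(self, small_dataset):
        # 99 samples at 60/20/20 split as 59/20/20
        table = small_dataset[0].subset_samples(small_dataset[0].sample_ids[:59])
        # construct a 99-sample table by reusing the generator instead
        from microgat.synthetic_data import SimulationConfig, generate_dataset

        cfg = SimulationConfig(seed=4, n_samples=99, n_genera=10, n_blocks=1,
                               block_size=4, n_discriminative=2, embedding_dim=4,
                               class_balance=70 / 99)
        t99 = generate_dataset(cfg)[0]
        train, val, test = split_dataset(t99, (0.6, 0.2, 0.2), seed=1)
        assert (len(train), len(val), len(test)) == (59, 20, 20)

    def test_partition_contract_and_determinism(self, small_dataset):
        table = small_dataset[0]
        a = split_dataset(table, seed=9)
        b = split_dataset(table, seed=9)
        assert a == b
        train, val, test = a
        ids = set(train) | set(val) | set(test)
        assert ids == set(table.sample_ids)
        assert not (set(train) & set(val)) and not (set(val) & set(test))

    def test_stratification_keeps_both_classes(self, small_dataset):
        table = small_dataset[0]
        labels = table.labels
        for part in split_dataset(table, seed=3):
            assert {labels[s] for s in part} == {0, 1}


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert m.auroc == 1.0 and m.f1 == 1.0

    def test_hand_enumerated_auroc(self):
        m = compute_metrics(np.array([0.9, 0.8, 0.3]), np.array([1, 0, 1]))
        assert m.auroc == pytest.approx(0.5)

    def test_null_predictions_near_half(self):
        rng = np.random.default_rng(0)
        p = rng.random(2000)
        y = rng.integers(0, 2, 2000)
        m = compute_metrics(p, y)
        assert abs(m.auroc - 0.5) < 0.03

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_auroc_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        p = np.round(rng.random(n), 2)  # ties likely
        m = compute_metrics(p, y)
        pos, neg = p[y == 1], p[y == 0]
        diff = pos[:, None] - neg[None, :]
        conc = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg))
        assert m.auroc == pytest.approx(conc, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_summary_report(self):
        per_seed = [
            compute_metrics(np.array([0.9, 0.1 * k, 0.2]), np.array([1, 0, 0]))
            for k in range(1, 6)
        ]
        rep = summarize_runs(per_seed)
        for k in ("auroc", "auprc", "f1"):
            lo, hi = rep.ci95[k]
            assert lo <= rep.mean[k] <= hi


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        a, b = [1.0, 5.0, 2.5], [2.0, 7.0]
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(b, a)
        assert p1 == pytest.approx(p2)

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 25)
        u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSilhouette:
    def test_separated_clouds_score_high(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(20, 3))
        b = rng.normal(5, 0.1, size=(20, 3)) + np.array([5.0, 0, 0])
        x = np.vstack([a, b])
        y = np.array([0] * 20 + [1] * 20)
        score, p = graph_embedding_silhouette(x, y, n_permutations=199, seed=0)
        assert score > 0.8
        assert p < 0.05

    def test_shuffled_labels_score_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=(40, 3))
        y = rng.integers(0, 2, 40)
        while min((y == 0).sum(), (y == 1).sum()) < 2:
            y = rng.integers(0, 2, 40)
        score, p = graph_embedding_silhouette(x, y, n_permutations=99, seed=1)
        assert abs(score) < 0.1

    def test_scale_free_property(self):
        # rescaling coordinates leaves the score exactly unchanged;
        # duplicating every point changes it only by O(1/n) edge effects
        # (the intra-cluster mean gains a zero distance per point)
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(12, 2))
        x[:6] += 4
        y = np.array([0] * 6 + [1] * 6)
        s1, _ = graph_embedding_silhouette(x, y, n_permutations=9, seed=0)
        s_scaled, _ = graph_embedding_silhouette(x * 37.0, y, n_permutations=9, seed=0)
        assert s1 == pytest.approx(s_scaled, abs=1e-9)
        s_dup, _ = graph_embedding_silhouette(
            np.vstack([x, x]), np.concatenate([y, y]), n_permutations=9, seed=0
        )
        assert s_dup == pytest.approx(s1, abs=0.08)

    def test_singleton_class_errors(self):
        with pytest.raises(ValueError):
            graph_embedding_silhouette(np.zeros((3, 2)), np.array([0, 1, 1]))


class TestTraining:
    def _parts(self, small_dataset, small_graphs):
        table = small_dataset[0]
        labels = table.labels
        net, graphs = small_graphs
        gmap = dict(zip(table.sample_ids, graphs))
        train, val, test = split_dataset(table, seed=0)

        def part(ids):
            return [gmap[s] for s in ids], np.array([labels[s] for s in ids], float)

        return part(train), part(val), part(test)

    def test_loss_decreases_and_is_reproducible(self, small_dataset, small_graphs):
        (gt, yt), (gv, yv), _ = self._parts(small_dataset, small_graphs)
        st1, log1 = train_model(gt, yt, gv, yv, QUICK_MODEL, QUICK_TRAIN, seed=0)
        st2, log2 = train_model(gt, yt, gv, yv, QUICK_MODEL, QUICK_TRAIN, seed=0)
        assert log1.train_loss[-1] < log1.train_loss[0]
        assert log1.val_loss == log2.val_loss
        for k in st1.params:
            np.testing.assert_array_equal(st1.params[k].data, st2.params[k].data)

    def test_best_checkpoint_matches_logged_val_loss(self, small_dataset, small_graphs):
        (gt, yt), (gv, yv), _ = self._parts(small_dataset, small_graphs)
        st, log = train_model(gt, yt, gv, yv, QUICK_MODEL, QUICK_TRAIN, seed=1)
        from microgat.train_eval import _eval_loss

        assert _eval_loss(st, gv, yv) == pytest.approx(log.best_val_loss, abs=1e-6)
        assert log.best_val_loss == pytest.approx(min(log.val_loss), abs=1e-12)

    def test_ensemble_mean_and_validation(self, small_dataset, small_graphs):
        (gt, yt), (gv, yv), (gs, ys) = self._parts(small_dataset, small_graphs)
        states = [
            train_model(gt, yt, gv, yv, QUICK_MODEL, QUICK_TRAIN, seed=s)[0]
            for s in (0, 1)
        ]
        per_model = np.vstack([predict_proba(s, gs) for s in states])
        ens = ensemble_predict(states, gs)
        np.testing.assert_allclose(ens, per_model.mean(axis=0), atol=1e-12)
        single = ensemble_predict([states[0]], gs)
        np.testing.assert_allclose(single, per_model[0], atol=1e-12)
        from dataclasses import replace

        bad = states[1].astype(np.float32)
        bad.config = replace(bad.config, n_heads=4)
        with pytest.raises(ValueError):
            ensemble_predict([states[0], bad], gs)


def test_run_ablation_deterministic_and_variant_aware(small_dataset):
    """run_ablation reproduces identical metrics under identical seeds and
    switches the model input width for the genomic-free variants."""
    table, embeddings, _, _ = small_dataset
    from microgat.network import build_network

    net = build_network(table, seed=3)
    rep1, states1 = run_ablation(table, embeddings, net, "full", QUICK_MODEL,
                                 QUICK_TRAIN, seeds=[0, 1], split_seed=2)
    rep2, _ = run_ablation(table, embeddings, net, "full", QUICK_MODEL,
                           QUICK_TRAIN, seeds=[0, 1], split_seed=2)
    assert rep1.ensemble.as_dict() == rep2.ensemble.as_dict()
    rep3, states3 = run_ablation(table, embeddings, net, "no_genomic",
                                 QUICK_MODEL, QUICK_TRAIN, seeds=[0],
                                 split_seed=2)
    assert states1[0].config.genomic_dim == embeddings.dim
    assert states3[0].config.genomic_dim == 0
    with pytest.raises(ValueError):
        run_ablation(table, embeddings, net, "bogus", QUICK_MODEL, QUICK_TRAIN,
                     seeds=[0])


class TestAblationVariants:
    def test_no_genomic_strips_features_keeps_topology(self, small_graphs):
        _, graphs = small_graphs
        out, stripped = variant_graphs(graphs, "no_genomic", seed=0)
        assert stripped
        for g0, g1 in zip(graphs, out):
            assert g1.genomic.shape == (g0.n_nodes, 0)
            np.testing.assert_array_equal(g0.edges, g1.edges)
            np.testing.assert_array_equal(g0.abundance, g1.abundance)

    def test_shuffled_edges_preserves_counts(self, small_graphs):
        _, graphs = small_graphs
        out, _ = variant_graphs(graphs, "shuffled_edges", seed=0)
        for g0, g1 in zip(graphs, out):
            assert g0.n_edges == g1.n_edges
            assert g1.genomic.shape[1] == 0

    def test_full_identity_and_unknown_variant(self, small_graphs):
        _, graphs = small_graphs
        out, stripped = variant_graphs(graphs, "full")
        assert out is graphs and not stripped
        with pytest.raises(ValueError):
            variant_graphs(graphs, "bogus")
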