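"""Canonical synthetic-study pipelines.

These functions wire the full method together — simulate, build the
co-expression network, split, train the seed ensemble, evaluate, interpret
and intervene — under one fixed set of desk-scale study conditions:
300 samples, 60 genera, four 8-genus co-abundance blocks, ten
disease-enriched genera shifted by 1.5 natural-log units, 20% zero
inflation, data seed 11.  Training uses the model's architecture defaults
with a schedule sized for a single CPU core (learning rate 2e-3, at most
120 epochs, early stopping with patience 40, no weight decay); five seeds
are trained and ensembled by probability averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import AbundanceTable, EmbeddingTable
from .interpret import (
    TaxaRanking,
    attention_profile,
    rank_taxa,
    run_intervention,
    stratify_groups,
)
from .model import ModelConfig, ModelState, predict_proba
from .network import CoexpressionNetwork, SampleGraph, build_network, induce_all
from .synthetic_data import GroundTruth, SimulationConfig, generate_dataset
from .train_eval import (
    Metrics,
    MetricsReport,
    TrainConfig,
    compute_metrics,
    ensemble_predict,
    graph_embedding_silhouette,
    split_dataset,
    summarize_runs,
    train_model,
    variant_graphs,
)

__all__ = [
    "study_simulation_config",
    "study_model_config",
    "study_train_config",
    "derive_seeds",
    "StudyRun",
    "run_classification_study",
    "interpretation_ranking",
    "matched_control_group",
]

STUDY_DATA_SEED = 11
STUDY_NETWORK_SEED = 7
STUDY_SPLIT_SEED = 0


def study_simulation_config(**overrides) -> SimulationConfig:
    return replace(SimulationConfig(seed=STUDY_DATA_SEED), **overrides)


def study_model_config(embedding_dim: int) -> ModelConfig:
    return ModelConfig(genomic_dim=embedding_dim)


def study_train_config() -> TrainConfig:
    return TrainConfig(
        learning_rate=2e-3,
        max_epochs=120,
        early_stop_patience=40,
        weight_decay=0.0,
    )


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-model seeds derived from one base seed."""
    return [(base_seed * 100003 + 7919 * k + 1) % (2**31 - 1) for k in range(n)]


@dataclass
class StudyRun:
    """Everything one trained study produces."""

    variant: str
    table: AbundanceTable
    embeddings: EmbeddingTable
    truth: GroundTruth
    network: CoexpressionNetwork
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    graphs: dict[str, SampleGraph]  # variant-applied graphs per sample
    states: list[ModelState]
    test_probs: np.ndarray  # ensemble probabilities on the test split
    test_labels: np.ndarray
    report: MetricsReport

    @property
    def ensemble_metrics(self) -> Metrics:
        return self.report.ensemble

    def test_graphs(self) -> list[SampleGraph]:
        return [self.graphs[s] for s in self.test_ids]

    def disease_test_ids(self) -> list[str]:
        labels = self.table.labels
        return [s for s in self.test_ids if labels[s] == 1]

    def qualifying_disease_ids(self, threshold: float = 0.5) -> list[str]:
        """Disease test samples the ensemble classifies correctly."""
        labels = self.table.labels
        return [
            s
            for s, p in zip(self.test_ids, self.test_probs)
            if labels[s] == 1 and p >= threshold
        ]


def run_classification_study(
    train_seeds: list[int],
    sim_config: SimulationConfig | None = None,
    variant: str = "full",
    network_seed: int = STUDY_NETWORK_SEED,
    split_seed: int = STUDY_SPLIT_SEED,
    train_config: TrainConfig | None = None,
) -> StudyRun:
    """Simulate, build the network, train the seed ensemble and evaluate.

    ``variant`` is ``full``, ``no_genomic`` or ``shuffled_edges`` (the two
    ablations strip genomic vectors; the latter also rewires each sample's
    subgraph at random).
    """
    sim = sim_config if sim_config is not None else study_simulation_config()
    table, embeddings, labels, truth = generate_dataset(sim)
    net = build_network(table, seed=network_seed)
    tcfg = train_config if train_config is not None else study_train_config()

    train_ids, val_ids, test_ids = split_dataset(
        table, tcfg.split_ratios, seed=split_seed
    )
    base_graphs = induce_all(net, table, embeddings)
    varied, stripped = variant_graphs(base_graphs, variant, seed=split_seed * 7919 + 1)
    graphs = dict(zip(table.sample_ids, varied))
    mcfg = study_model_config(0 if stripped else embeddings.dim)

    def part(ids):
        return [graphs[s] for s in ids], np.array([labels[s] for s in ids], float)

    g_train, y_train = part(train_ids)
    g_val, y_val = part(val_ids)
    g_test, y_test = part(test_ids)

    states, per_seed = [], []
    for s in train_seeds:
        state, _ = train_model(g_train, y_train, g_val, y_val, mcfg, tcfg, seed=s)
        states.append(state)
        per_seed.append(compute_metrics(predict_proba(state, g_test), y_test))
    probs = ensemble_predict(states, g_test)
    report = summarize_runs(per_seed, compute_metrics(probs, y_test))
    return StudyRun(
        variant=variant,
        table=table,
        embeddings=embeddings,
        truth=truth,
        network=net,
        train_ids=train_ids,
        val_ids=val_ids,
        test_ids=test_ids,
        graphs=graphs,
        states=states,
        test_probs=probs,
        test_labels=y_test,
        report=report,
    )


def interpretation_ranking(run: StudyRun) -> tuple[TaxaRanking, set[str], set[str]]:
    """Rank taxa by mean CLR attention over correctly classified disease test
    samples, then stratify into Groups A (mean CLR > 0) and B."""
    qualifying = run.qualifying_disease_ids()
    profiles = [attention_profile(run.states, run.graphs[s]) for s in qualifying]
    ranking = rank_taxa(profiles)
    group_a, group_b = stratify_groups(ranking)
    return ranking, group_a, group_b


def matched_control_group(run: StudyRun, seed: int) -> set[str]:
    """Random non-discriminative genus set matching the planted group size."""
    disc = run.truth.discriminative_genus_ids
    pool = [g for g in run.table.genus_ids if g not in disc]
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=len(disc), replace=False))


def knockout_comparison(
    run: StudyRun,
    removal_fraction: float = 0.5,
    n_repetitions: int = 100,
    seeds: list[int] | None = None,
) -> list[dict]:
    """Planted-group vs matched-control knockouts on disease test samples.

    Per seed, both groups are removed at the same fraction with the same
    repetition count; the planted group's mean probability drop should be
    the larger (more negative) one when the model has learned the signal.
    """
    seeds = seeds if seeds is not None else list(range(5))
    samples = run.disease_test_ids()
    out = []
    for s in seeds:
        planted = run_intervention(
            run.states, run.table, samples, run.network, run.embeddings,
            run.truth.discriminative_genus_ids, "planted",
            removal_fraction, n_repetitions, seed=s,
        )
        control = run_intervention(
            run.states, run.table, samples, run.network, run.embeddings,
            matched_control_group(run, seed=s), "control",
            removal_fraction, n_repetitions, seed=s,
        )
        out.append(
            {
                "seed": s,
                "planted": planted,
                "control": control,
                "planted_more_negative": planted.mean_delta < control.mean_delta,
            }
        )
    return out


def embedding_silhouette(run: StudyRun, n_permutations: int = 999, seed: int = 0):
    """Silhouette of the class labeling on mean-ensemble graph embeddings of
    the test split."""
    from .model import embed_graphs

    pooled = np.mean(
        [embed_graphs(st, run.test_graphs())[1] for st in run.states], axis=0
    )
    return graph_embedding_silhouette(
        pooled, run.test_labels.astype(int), n_permutations=n_permutations, seed=seed
    )
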