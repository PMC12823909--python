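"""Splitting, training, seed ensembling, metrics, significance and ablations.

Training minimizes unweighted binary cross-entropy with AdamW at an
initial learning rate of 1e-4, batch size 16 and a 1% learning-rate decay
every 10 epochs; the checkpoint with the best validation loss is returned
and early stopping monitors validation loss.  Ensembling averages the
output probabilities of models trained under different random seeds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    roc_auc_score,
    silhouette_score,
)

from .data_io import AbundanceTable, EmbeddingTable
from .model import (
    ModelConfig,
    ModelState,
    bce_with_logits,
    build_batch,
    forward,
    init_state,
    predict_proba,
)
from .network import CoexpressionNetwork, SampleGraph, induce_all, shuffle_edges

logger = logging.getLogger("microgat")

__all__ = [
    "TrainConfig",
    "Metrics",
    "MetricsReport",
    "TrainingLog",
    "split_dataset",
    "AdamW",
    "train_model",
    "ensemble_predict",
    "compute_metrics",
    "summarize_runs",
    "mann_whitney_u",
    "graph_embedding_silhouette",
    "run_ablation",
    "variant_graphs",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    lr_decay_factor: float = 0.99
    lr_decay_every: int = 10
    warmup_epochs: int = 0
    clip_norm: float | None = None
    adam_betas: tuple[float, float] = (0.9, 0.999)
    max_epochs: int = 300
    early_stop_patience: int = 30
    weight_decay: float = 0.01
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_ensemble_seeds: int = 5

    def validate(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if abs(sum(self.split_ratios) - 1.0) > 1e-6:
            raise ValueError("split ratios must sum to 1")
        if self.n_ensemble_seeds <= 0 or self.early_stop_patience <= 0:
            raise ValueError("counts must be positive")


# ---------------------------------------------------------------------------
# dataset splitting


def _allocate(counts: dict[int, int], total: int) -> dict[int, int]:
    """Largest-remainder apportionment of ``total`` across classes."""
    n = sum(counts.values())
    quotas = {c: total * k / n for c, k in counts.items()}
    alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
    rem = total - sum(alloc.values())
    order = sorted(counts, key=lambda c: (quotas[c] - alloc[c], c), reverse=True)
    for c in order[:rem]:
        alloc[c] += 1
    return alloc


def split_dataset(
    table: AbundanceTable,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list[str], list[str], list[str]]:
    """Class-stratified train/validation/test partition of the sample ids.

    Sizes follow rounded ratios (99 samples at 60/20/20 give 59/20/20);
    the partition is disjoint, exhaustive and reproducible from the seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError("ratios must sum to 1")
    labels = table.labels
    if labels is None:
        raise ValueError("table carries no labels to stratify on")
    ids = list(table.sample_ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_test = int(round(ratios[2] * n))
    n_val = int(round(ratios[1] * n))

    rng = np.random.default_rng(seed)
    if stratify:
        by_class: dict[int, list[str]] = {0: [], 1: []}
        for s in ids:
            by_class[labels[s]].append(s)
        for c in by_class:
            by_class[c] = [by_class[c][i] for i in rng.permutation(len(by_class[c]))]
        counts = {c: len(v) for c, v in by_class.items()}
        test_alloc = _allocate(counts, n_test)
        remaining = {c: counts[c] - test_alloc[c] for c in counts}
        val_alloc = _allocate(remaining, n_val)
        test, val, train = [], [], []
        for c, members in by_class.items():
            t, v = test_alloc[c], val_alloc[c]
            test.extend(members[:t])
            val.extend(members[t : t + v])
            train.extend(members[t + v :])
    else:
        perm = [ids[i] for i in rng.permutation(n)]
        test, val, train = perm[:n_test], perm[n_test : n_test + n_val], perm[n_test + n_val :]

    for name, part in (("train", train), ("validation", val), ("test", test)):
        classes = {labels[s] for s in part}
        if classes != {0, 1}:
            raise ValueError(f"{name} split lacks one of the classes")
    return train, val, test


# ---------------------------------------------------------------------------
# optimizer & training loop


class AdamW:
    """AdamW with decoupled weight decay (applied to every parameter)."""

    def __init__(
        self,
        params: dict,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(t.data, dtype=np.float64) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data, dtype=np.float64) for k, t in params.items()}

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, t in self.params.items():
            if t.grad is None:
                continue
            g = t.grad.astype(np.float64)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            update = mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * t.data
            t.data = (t.data - lr * update).astype(t.data.dtype)


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = math.inf
    stopped_epoch: int = -1


def _eval_loss(state: ModelState, graphs, y) -> float:
    loss_total = 0.0
    i = 0
    while i < len(graphs):
        j = i
        nodes = 0
        while j < len(graphs) and (nodes == 0 or nodes + graphs[j].n_nodes <= 8192):
            nodes += graphs[j].n_nodes
            j += 1
        batch = build_batch(graphs[i:j], dtype=state.dtype)
        logits = forward(state, batch, training=False)
        loss = bce_with_logits(logits, y[i:j])
        loss_total += float(loss.data) * (j - i)
        i = j
    return loss_total / len(graphs)


def train_model(
    train_graphs: list[SampleGraph],
    train_labels: np.ndarray,
    val_graphs: list[SampleGraph],
    val_labels: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int,
    dtype=np.float32,
) -> tuple[ModelState, TrainingLog]:
    """Train one model; returns the best-validation-loss checkpoint and the log."""
    train_config.validate()
    y_train = np.asarray(train_labels, dtype=np.float64)
    y_val = np.asarray(val_labels, dtype=np.float64)
    rng = np.random.default_rng(seed)
    state = init_state(model_config, seed=seed, dtype=dtype)
    opt = AdamW(
        state.params,
        betas=train_config.adam_betas,
        weight_decay=train_config.weight_decay,
    )
    log = TrainingLog()
    best_arrays = state.copy_arrays()
    bs = train_config.batch_size

    for epoch in range(train_config.max_epochs):
        lr = train_config.learning_rate * (
            train_config.lr_decay_factor ** (epoch // train_config.lr_decay_every)
        )
        if train_config.warmup_epochs and epoch < train_config.warmup_epochs:
            lr *= (epoch + 1) / train_config.warmup_epochs
        order = rng.permutation(len(train_graphs))
        epoch_loss = 0.0
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            batch = build_batch(
                [train_graphs[i] for i in idx],
                dtype=dtype,
                training=True,
                edge_dropout=model_config.edge_dropout,
                rng=rng,
            )
            state.zero_grad()
            logits = forward(state, batch, training=True, rng=rng)
            loss = bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            loss.backward()
            if train_config.clip_norm is not None:
                total = math.sqrt(
                    sum(
                        float(np.sum(t.grad.astype(np.float64) ** 2))
                        for t in state.params.values()
                        if t.grad is not None
                    )
                )
                if total > train_config.clip_norm:
                    scale = train_config.clip_norm / total
                    for t in state.params.values():
                        if t.grad is not None:
                            t.grad = t.grad * np.float32(scale)
            opt.step(lr)
            epoch_loss += float(loss.data) * len(idx)
        log.train_loss.append(epoch_loss / len(order))

        val_loss = _eval_loss(state, val_graphs, y_val)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"validation loss diverged at epoch {epoch}")
        log.val_loss.append(val_loss)
        if val_loss < log.best_val_loss - 1e-9:
            log.best_val_loss = val_loss
            log.best_epoch = epoch
            best_arrays = state.copy_arrays()
        elif epoch - log.best_epoch >= train_config.early_stop_patience:
            break
    log.stopped_epoch = len(log.val_loss) - 1
    state.load_arrays(best_arrays)
    return state, log


def ensemble_predict(
    states: list[ModelState], graphs: SampleGraph | list[SampleGraph]
) -> np.ndarray | float:
    """Arithmetic mean of per-model probabilities."""
    if not states:
        raise ValueError("need at least one model state")
    cfg0 = states[0].config
    for s in states[1:]:
        if s.config != cfg0:
            raise ValueError("ensemble members have mismatched configurations")
    single = isinstance(graphs, SampleGraph)
    glist = [graphs] if single else list(graphs)
    probs = np.mean([predict_proba(s, glist) for s in states], axis=0)
    return float(probs[0]) if single else probs


# ---------------------------------------------------------------------------
# metrics


@dataclass
class Metrics:
    auroc: float
    auprc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"auroc": self.auroc, "auprc": self.auprc, "f1": self.f1}


def compute_metrics(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """AUROC (rank statistic, ties count 1/2), AUPRC (precision-recall step
    integration) and F1 at the given probability threshold."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be equal-length vectors")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; metrics undefined")
    return Metrics(
        auroc=float(roc_auc_score(y, p)),
        auprc=float(average_precision_score(y, p)),
        f1=float(f1_score(y, (p >= threshold).astype(int))),
    )


@dataclass
class MetricsReport:
    per_seed: list[Metrics]
    mean: dict[str, float]
    std: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    ensemble: Metrics | None = None

    def as_dict(self) -> dict:
        return {
            "per_seed": [m.as_dict() for m in self.per_seed],
            "mean": self.mean,
            "std": self.std,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "ensemble": self.ensemble.as_dict() if self.ensemble else None,
        }


def summarize_runs(
    per_seed: list[Metrics], ensemble: Metrics | None = None
) -> MetricsReport:
    """Mean, standard deviation and normal-theory 95% CI over per-seed runs."""
    names = ("auroc", "auprc", "f1")
    arr = {k: np.array([getattr(m, k) for m in per_seed]) for k in names}
    mean = {k: float(v.mean()) for k, v in arr.items()}
    std = {k: float(v.std(ddof=1)) if len(per_seed) > 1 else 0.0 for k, v in arr.items()}
    half = {k: 1.96 * std[k] / math.sqrt(len(per_seed)) for k in names}
    ci = {k: (mean[k] - half[k], mean[k] + half[k]) for k in names}
    return MetricsReport(per_seed, mean, std, ci, ensemble)


# ---------------------------------------------------------------------------
# significance


def mann_whitney_u(
    group_a, group_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test.

    For pooled sizes up to 12 the null distribution of U is enumerated
    exhaustively over all group assignments of the pooled values (ties are
    handled naturally); otherwise the normal approximation with tie
    correction is used.  Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size

    def u_stat(x, y):
        diff = x[:, None] - y[None, :]
        return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))

    u_obs = u_stat(a, b)
    if n1 + n2 <= 12:
        pooled = np.concatenate([a, b])
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(comb)] = True
            u = u_stat(pooled[sel], pooled[~sel])
            total += 1
            if alternative == "two-sided":
                hits += abs(u - mu) >= dev_obs - 1e-12
            elif alternative == "greater":
                hits += u >= u_obs - 1e-12
            elif alternative == "less":
                hits += u <= u_obs + 1e-12
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        return u_obs, hits / total
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def graph_embedding_silhouette(
    embeddings: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean silhouette of the class labeling on graph embeddings (Euclidean)
    with a seeded label-permutation p-value."""
    x = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("need at least 2 samples in each of 2 classes")
    score = float(silhouette_score(x, y, metric="euclidean"))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        if float(silhouette_score(x, y[perm], metric="euclidean")) >= score:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return score, p


# ---------------------------------------------------------------------------
# ablations


def variant_graphs(
    graphs: list[SampleGraph], variant: str, seed: int = 0
) -> tuple[list[SampleGraph], bool]:
    """Apply an ablation variant to sample graphs.

    ``full`` returns the graphs unchanged; ``no_genomic`` strips genomic
    vectors (the model then runs on abundance features alone);
    ``shuffled_edges`` additionally rewires each sample's edges uniformly
    at random with per-sample seeds.  Returns (graphs, genomic_removed).
    """
    if variant == "full":
        return graphs, False
    if variant not in ("no_genomic", "shuffled_edges"):
        raise ValueError(f"unknown ablation variant {variant!r}")
    out = []
    for i, g in enumerate(graphs):
        gg = SampleGraph(
            g.sample_id,
            list(g.genus_ids),
            g.abundance.copy(),
            np.zeros((g.n_nodes, 0)),
            g.edges.copy(),
        )
        if variant == "shuffled_edges" and gg.n_nodes >= 2 and gg.n_edges:
            gg = shuffle_edges(gg, seed=seed + i)
        out.append(gg)
    return out, True


def run_ablation(
    table: AbundanceTable,
    embeddings: EmbeddingTable,
    net: CoexpressionNetwork,
    variant: str,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seeds: list[int],
    split_seed: int = 0,
) -> tuple[MetricsReport, list[ModelState]]:
    """Train ``len(seeds)`` models of one ablation variant and evaluate on
    the held-out test split."""
    train_ids, val_ids, test_ids = split_dataset(
        table, train_config.split_ratios, seed=split_seed
    )
    labels = table.labels
    graphs = {s: g for s, g in zip(table.sample_ids, induce_all(net, table, embeddings))}

    def part(ids):
        return [graphs[s] for s in ids], np.array([labels[s] for s in ids])

    g_train, y_train = part(train_ids)
    g_val, y_val = part(val_ids)
    g_test, y_test = part(test_ids)

    g_train, stripped = variant_graphs(g_train, variant, seed=split_seed * 7919 + 1)
    g_val, _ = variant_graphs(g_val, variant, seed=split_seed * 7919 + 2)
    g_test, _ = variant_graphs(g_test, variant, seed=split_seed * 7919 + 3)
    cfg = replace(model_config, genomic_dim=0) if stripped else model_config

    states, per_seed = [], []
    for s in seeds:
        st, _ = train_model(g_train, y_train, g_val, y_val, cfg, train_config, seed=s)
        states.append(st)
        per_seed.append(compute_metrics(predict_proba(st, g_test), y_test))
    ens = compute_metrics(ensemble_predict(states, g_test), y_test)
    return summarize_runs(per_seed, ens), states
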