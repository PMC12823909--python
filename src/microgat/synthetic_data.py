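"""Two-class zero-inflated compositional data with planted structure.

The generator emulates the statistical features the pipeline depends on:

* compositional genus abundances (each sample sums to 100) arising from a
  logistic-normal scheme — Gaussian log-abundances closed under the
  centered log-ratio analysis used downstream;
* planted co-abundance blocks: genera in a block share a per-sample latent
  factor, inducing positive within-block log-scale correlation that the
  network-inference stage should recover;
* planted class signal: a chosen set of discriminative genera receives a
  log-scale mean shift in the disease class (all shifts positive by
  default, i.e. disease-enriched taxa, so an in-silico knockout has a
  well-defined expected direction; signs are configurable);
* zero inflation applied before renormalization, mimicking zero counts in
  16S tables and exercising the sample-specific subgraph path;
* fixed random unit-norm genomic vectors per genus.  These carry no class
  signal by default; besides emulating opaque genome-language-model
  embeddings they act as node identities for the attention model.
  ``embedding_signal`` optionally adds a shared direction to the
  discriminative genera's vectors for ablation experiments.

Identical config and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AbundanceTable, EmbeddingTable, normalize_to_percent

__all__ = ["SimulationConfig", "GroundTruth", "generate_dataset", "make_toy_fixture"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 300 samples, 60 genera, four co-abundance blocks of eight genera,
    ten disease-enriched genera shifted by 1.5 natural-log units, 20%
    zero inflation, balanced classes.
    """

    seed: int
    n_samples: int = 300
    n_genera: int = 60
    n_blocks: int = 4
    block_size: int = 8
    n_discriminative: int = 10
    effect_size: float = 1.5
    zero_inflation: float = 0.2
    class_balance: float = 0.5
    embedding_dim: int = 32
    latent_strength: float = 1.0  # loading of the shared block factor
    noise_sd: float = 0.8  # idiosyncratic log-abundance noise
    baseline_sd: float = 1.0  # spread of per-genus baseline log-abundance
    discriminative_in_blocks: bool = True
    effect_signs: tuple[int, ...] | None = None  # per-genus, default all +1
    embedding_signal: float = 0.0

    def validate(self):
        if self.n_samples <= 0 or self.n_genera <= 0 or self.embedding_dim <= 0:
            raise ValueError("counts must be positive")
        if self.n_blocks < 0 or self.block_size < 0:
            raise ValueError("block counts must be non-negative")
        if self.n_blocks * self.block_size > self.n_genera:
            raise ValueError("n_blocks * block_size exceeds n_genera")
        if self.n_discriminative < 0 or self.n_discriminative > self.n_genera:
            raise ValueError("n_discriminative out of range")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be in [0, 1]")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        if self.effect_signs is not None and len(self.effect_signs) != self.n_discriminative:
            raise ValueError("effect_signs length must equal n_discriminative")


@dataclass
class GroundTruth:
    discriminative_genus_ids: set[str]
    effect_signs: dict[str, int]
    block_memberships: dict[str, int | None]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[AbundanceTable, EmbeddingTable, dict[str, int], GroundTruth]:
    """Draw one synthetic dataset under ``config``.

    Returns the percent-normalized abundance table (with labels attached),
    the genomic-vector table, the label map and the planted ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, G = config.n_samples, config.n_genera

    sample_ids = [f"S{i + 1:04d}" for i in range(S)]
    genus_ids = [f"g{j + 1:03d}" for j in range(G)]

    # block memberships: contiguous blocks at the head of the genus list
    block_of = np.full(G, -1, dtype=np.int64)
    for b in range(config.n_blocks):
        block_of[b * config.block_size : (b + 1) * config.block_size] = b

    # labels: balanced assignment, shuffled
    n_disease = int(round(config.class_balance * S))
    y = np.zeros(S, dtype=np.int64)
    y[:n_disease] = 1
    y = y[rng.permutation(S)]

    # discriminative genera
    if config.n_discriminative:
        if config.discriminative_in_blocks and config.n_blocks * config.block_size >= config.n_discriminative:
            pool = np.flatnonzero(block_of >= 0)
        else:
            pool = np.arange(G)
        disc = np.sort(rng.choice(pool, size=config.n_discriminative, replace=False))
    else:
        disc = np.zeros(0, dtype=np.int64)
    signs = (
        np.asarray(config.effect_signs, dtype=np.float64)
        if config.effect_signs is not None
        else np.ones(len(disc))
    )

    # logistic-normal log-abundances
    base = rng.normal(0.0, config.baseline_sd, size=G)
    z = rng.normal(0.0, 1.0, size=(S, max(config.n_blocks, 1)))
    eps = rng.normal(0.0, config.noise_sd, size=(S, G))
    logx = base[None, :] + eps
    in_block = block_of >= 0
    if config.n_blocks:
        logx[:, in_block] += config.latent_strength * z[:, block_of[in_block]]
    for d, s in zip(disc, signs):
        logx[:, d] += config.effect_size * s * y

    x = np.exp(logx)

    # independent zeroing, applied before renormalization
    if config.zero_inflation > 0:
        mask = rng.random((S, G)) < config.zero_inflation
        # keep at least one genus alive per sample
        all_zero = mask.all(axis=1)
        if all_zero.any():
            mask[all_zero, np.argmax(x[all_zero], axis=1)] = False
        x[mask] = 0.0

    labels = {s: int(v) for s, v in zip(sample_ids, y)}
    table = AbundanceTable(sample_ids, genus_ids, x, labels)
    table = normalize_to_percent(table)

    # fixed unit-norm genomic vectors
    vecs = rng.standard_normal((G, config.embedding_dim))
    if config.embedding_signal and len(disc):
        direction = rng.standard_normal(config.embedding_dim)
        direction /= np.linalg.norm(direction)
        vecs[disc] += config.embedding_signal * direction[None, :]
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    embeddings = EmbeddingTable(list(genus_ids), vecs)

    truth = GroundTruth(
        discriminative_genus_ids={genus_ids[d] for d in disc},
        effect_signs={genus_ids[d]: int(s) for d, s in zip(disc, signs)},
        block_memberships={
            g: (int(block_of[j]) if block_of[j] >= 0 else None)
            for j, g in enumerate(genus_ids)
        },
    )
    return table, embeddings, labels, truth


# ---------------------------------------------------------------------------
# committed toy fixture

_TOY_VALUES = [
    # gA    gB    gC    gD    gE    gF
    [40.0, 25.0, 15.0, 10.0, 10.0, 0.0],
    [35.0, 30.0, 0.0, 20.0, 5.0, 10.0],
    [50.0, 20.0, 10.0, 0.0, 12.0, 8.0],
    [45.0, 15.0, 20.0, 10.0, 0.0, 10.0],
    [10.0, 30.0, 25.0, 15.0, 12.0, 8.0],
    [15.0, 35.0, 20.0, 0.0, 18.0, 12.0],
    [20.0, 25.0, 30.0, 10.0, 15.0, 0.0],
    [12.0, 28.0, 22.0, 18.0, 0.0, 20.0],
]

_TOY_EMBEDDINGS = [
    [1.0, 0.0, 0.0, 0.0],
    [0.0, 1.0, 0.0, 0.0],
    [0.0, 0.0, 1.0, 0.0],
    [0.0, 0.0, 0.0, 1.0],
    [0.5, 0.5, 0.5, 0.5],
    [0.5, -0.5, 0.5, -0.5],
]


def make_toy_fixture() -> tuple[AbundanceTable, EmbeddingTable, dict[str, int]]:
    """A hard-coded 8-sample x 6-genus dataset with 4-dim genomic vectors.

    Rows sum to 100 and a few entries are zero so the induced-subgraph path
    is exercised; labels are 4 disease / 4 control.  Used in documentation
    and unit tests.
    """
    sample_ids = [f"T{i + 1}" for i in range(8)]
    genus_ids = ["gA", "gB", "gC", "gD", "gE", "gF"]
    labels = {s: (1 if i < 4 else 0) for i, s in enumerate(sample_ids)}
    table = AbundanceTable(
        sample_ids, genus_ids, np.array(_TOY_VALUES, dtype=np.float64), labels
    )
    embeddings = EmbeddingTable(
        list(genus_ids), np.array(_TOY_EMBEDDINGS, dtype=np.float64)
    )
    return table, embeddings, labels
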