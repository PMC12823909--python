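"""Attention-based interpretation and in-silico taxon knockout.

The readout's node attention scores A_i (a simplex over a sample's active
genera) are the model's per-microbe importance.  Because every sample
carries a different subset of genera, raw scores are not comparable across
samples; each profile is therefore centered log-ratio (CLR) transformed —
ln of the score over the within-sample geometric mean — before averaging.
Genera are ranked by their mean CLR attention over test samples whose true
label is disease and whose ensemble prediction agrees, then stratified
into Group A (mean CLR > 0, the model's positive contributors) and
Group B (the rest).

The in-silico intervention randomly zeroes a fraction of a group's genera
in each disease test sample, re-induces the subgraph, re-predicts with the
ensemble, and summarizes the mean change in predicted disease probability
over repetitions; significance is a two-sided Mann-Whitney U test of the
baseline per-sample probabilities against the pooled perturbed ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AbundanceTable, EmbeddingTable
from .model import ModelState, embed_graphs
from .network import (
    CoexpressionNetwork,
    SampleGraph,
    clr_transform,
    induce_sample_graph,
    remove_nodes,
)
from .train_eval import ensemble_predict, mann_whitney_u

logger = logging.getLogger("microgat")

__all__ = [
    "AttentionProfile",
    "TaxaRanking",
    "InterventionResult",
    "attention_profile",
    "rank_taxa",
    "stratify_groups",
    "run_intervention",
    "write_reports",
]


@dataclass
class AttentionProfile:
    """Per-sample node attention (simplex) and its CLR values."""

    sample_id: str
    genus_ids: list[str]
    raw: np.ndarray  # positive, sums to 1
    clr: np.ndarray  # sums to 0

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.clr = np.asarray(self.clr, dtype=np.float64)
        if np.any(self.raw <= 0) or abs(self.raw.sum() - 1.0) > 1e-6:
            raise ValueError("raw attention must be a strictly positive simplex")
        if abs(self.clr.sum()) > 1e-6:
            raise ValueError("CLR attention must sum to zero")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.genus_ids, self.clr))


@dataclass
class TaxaRanking:
    """Genera ordered by mean CLR attention (descending, ties lexicographic)."""

    entries: list[tuple[str, float, int]]  # (genus, mean CLR, supporting samples)

    def top(self, k: int) -> list[str]:
        return [g for g, _, _ in self.entries[:k]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rank": r + 1, "genus": g, "mean_clr_attention": v, "n_samples": n}
                for r, (g, v, n) in enumerate(self.entries)
            ]
        )


@dataclass
class InterventionResult:
    group_label: str
    removal_fraction: float
    mean_delta: float  # perturbed - baseline predicted probability
    p_value: float
    n_repetitions: int
    seed: int
    n_samples: int


def attention_profile(
    states: list[ModelState], graph: SampleGraph
) -> AttentionProfile:
    """Ensemble attention for one sample: the member simplexes are averaged
    and renormalized; CLR needs no pseudocount since softmax outputs are
    strictly positive."""
    if not states:
        raise ValueError("need at least one trained model")
    raws = []
    for s in states:
        _, _, attn = embed_graphs(s, [graph])
        raws.append(attn[0])
    raw = np.mean(raws, axis=0)
    raw = raw / raw.sum()
    clr = clr_transform(raw) if raw.size >= 2 else np.zeros_like(raw)
    return AttentionProfile(graph.sample_id, list(graph.genus_ids), raw, clr)


def rank_taxa(profiles: list[AttentionProfile]) -> TaxaRanking:
    """Mean CLR attention per genus over the given (qualifying) profiles.

    A genus contributes only where it is active; genera absent from every
    profile are excluded.  Invariant to sample and genus ordering.
    """
    if not profiles:
        raise ValueError(
            "no qualifying samples: need at least one correctly classified "
            "disease test sample to rank taxa"
        )
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for prof in profiles:
        for g, v in zip(prof.genus_ids, prof.clr):
            sums[g] = sums.get(g, 0.0) + float(v)
            counts[g] = counts.get(g, 0) + 1
    entries = sorted(
        ((g, sums[g] / counts[g], counts[g]) for g in sums),
        key=lambda e: (-e[1], e[0]),
    )
    return TaxaRanking(entries)


def stratify_groups(ranking: TaxaRanking) -> tuple[set[str], set[str]]:
    """Group A: mean CLR attention strictly above zero; Group B: the rest."""
    if not ranking.entries:
        raise ValueError("empty ranking")
    group_a = {g for g, v, _ in ranking.entries if v > 0}
    group_b = {g for g, v, _ in ranking.entries if v <= 0}
    return group_a, group_b


def _perturb_once(
    graph: SampleGraph,
    group: set[str],
    removal_fraction: float,
    rng: np.random.Generator,
) -> SampleGraph | None:
    """One random removal draw; returns None when no genus is removed.

    Zeroing a genus removes its node, so the perturbed graph is the induced
    subgraph of the sample graph on the surviving genera (remaining
    abundances are left unchanged).
    """
    candidates = [g for g in graph.genus_ids if g in group]
    k = int(np.floor(removal_fraction * len(candidates) + 0.5))
    if k == 0:
        return None
    for _ in range(20):
        removed = rng.choice(len(candidates), size=k, replace=False)
        removed_set = {candidates[i] for i in removed}
        if len(removed_set) < graph.n_nodes:
            return remove_nodes(graph, removed_set)
        logger.debug("redrawing removal set that emptied sample %s", graph.sample_id)
    raise RuntimeError(
        f"could not draw a non-emptying removal for {graph.sample_id!r}"
    )


def run_intervention(
    states: list[ModelState],
    table: AbundanceTable,
    sample_ids: list[str],
    net: CoexpressionNetwork,
    embeddings: EmbeddingTable,
    group: set[str],
    group_label: str,
    removal_fraction: float,
    n_repetitions: int = 100,
    seed: int = 0,
) -> InterventionResult:
    """Randomized in-silico removal of a genus group from disease samples.

    Per repetition and sample, ``round(fraction * |group ∩ active|)`` genera
    are zeroed (rounding half up), the subgraph re-induced and the ensemble
    re-applied.  ``mean_delta`` averages (perturbed − baseline) probability
    over all repetitions and samples; draws removing nothing contribute a
    delta of exactly zero.
    """
    if not group:
        raise ValueError("group is empty")
    if not (0.0 < removal_fraction < 1.0):
        raise ValueError("removal_fraction must be in (0, 1)")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    base_graphs = [
        induce_sample_graph(net, table, embeddings, s) for s in sample_ids
    ]
    baseline = np.asarray(ensemble_predict(states, base_graphs), dtype=np.float64)

    perturbed_graphs: list[SampleGraph] = []
    slots: list[tuple[int, int]] = []  # (repetition, sample index) per graph
    noop = 0
    deltas_fixed: list[tuple[int, int]] = []  # no-op draws contribute 0
    for rep in range(n_repetitions):
        for si, s in enumerate(sample_ids):
            g = _perturb_once(base_graphs[si], group, removal_fraction, rng)
            if g is None:
                noop += 1
                deltas_fixed.append((rep, si))
                continue
            perturbed_graphs.append(g)
            slots.append((rep, si))
    if noop:
        logger.info(
            "%d removal draws rounded to zero genera and contribute delta=0", noop
        )

    if perturbed_graphs:
        pert = np.asarray(ensemble_predict(states, perturbed_graphs), dtype=np.float64)
    else:
        pert = np.zeros(0)
    all_pert = np.empty(len(slots) + len(deltas_fixed))
    deltas = np.empty_like(all_pert)
    for i, ((rep, si), p) in enumerate(zip(slots, pert)):
        all_pert[i] = p
        deltas[i] = p - baseline[si]
    off = len(slots)
    for i, (rep, si) in enumerate(deltas_fixed):
        all_pert[off + i] = baseline[si]
        deltas[off + i] = 0.0

    _, p_value = mann_whitney_u(baseline, all_pert, alternative="two-sided")
    return InterventionResult(
        group_label=group_label,
        removal_fraction=removal_fraction,
        mean_delta=float(deltas.mean()),
        p_value=float(p_value),
        n_repetitions=n_repetitions,
        seed=seed,
        n_samples=len(sample_ids),
    )


def write_reports(
    ranking: TaxaRanking,
    interventions: list[InterventionResult],
    output_dir,
    provenance: dict | None = None,
):
    """Ranking TSV (rank, genus, mean CLR attention), intervention TSV
    (group x fraction grid) and a JSON provenance record; byte-identical
    across re-runs with identical inputs."""
    from pathlib import Path

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ranking.to_dataframe().to_csv(
        out / "taxa_ranking.tsv", sep="\t", index=False, float_format="%.10g"
    )
    rows = [
        {
            "group": r.group_label,
            "removal_fraction": r.removal_fraction,
            "mean_delta": r.mean_delta,
            "p_value": r.p_value,
            "n_repetitions": r.n_repetitions,
        }
        for r in interventions
    ]
    pd.DataFrame(
        rows,
        columns=["group", "removal_fraction", "mean_delta", "p_value", "n_repetitions"],
    ).to_csv(out / "interventions.tsv", sep="\t", index=False, float_format="%.10g")
    record = dict(provenance or {})
    record["n_ranked_taxa"] = len(ranking.entries)
    record["intervention_seeds"] = sorted({r.seed for r in interventions})
    with open(out / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
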