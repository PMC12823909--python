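"""Compositional co-expression network inference and per-sample subgraphs.

Edges of the global genus network are composition-adjusted (COAT-style)
correlations: Pearson correlation of centered log-ratio (CLR) transformed
samples.  Robustness comes from stability selection — the dataset is
subsampled five times at 80% and an edge is retained only if its
correlation magnitude clears the threshold with a consistent sign in every
draw; the stored weight is the mean per-draw correlation.

Per sample, the global network is induced on the genera with nonzero
abundance, carrying the abundance scalar and the genomic vector of each
active genus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AbundanceTable, EmbeddingTable

logger = logging.getLogger("microgat")

__all__ = [
    "CoexpressionNetwork",
    "SampleGraph",
    "clr_transform",
    "default_pseudocount",
    "coat_correlation",
    "build_network",
    "induce_sample_graph",
    "induce_all",
    "shuffle_edges",
    "write_network",
    "read_network",
]


@dataclass
class CoexpressionNetwork:
    """Global undirected genus graph with stability-selected edges.

    ``edges`` maps unordered genus-id pairs (stored sorted) to the mean
    COAT correlation across subsample draws.
    """

    genus_ids: list[str]
    edges: dict[tuple[str, str], float]
    tau: float = 0.1
    n_subsamples: int = 5
    subsample_fraction: float = 0.8
    pseudocount: float | None = None
    seed: int = 0

    def __post_init__(self):
        genus_set = set(self.genus_ids)
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-loop on genus {a!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"edge {(a, b)} not stored in sorted order")
            if a not in genus_set or b not in genus_set:
                raise ValueError(f"edge {(a, b)} references unknown genus")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genus_ids)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class SampleGraph:
    """The global network induced on one sample's nonzero genera."""

    sample_id: str
    genus_ids: list[str]  # active genera
    abundance: np.ndarray  # (n_active,) percent scalars, all > 0
    genomic: np.ndarray  # (n_active, d_g)
    edges: np.ndarray  # (n_edges, 2) local indices, i < j

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=np.float64)
        self.genomic = np.asarray(self.genomic, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n = len(self.genus_ids)
        if self.abundance.shape != (n,):
            raise ValueError("abundance length mismatch")
        if np.any(self.abundance <= 0):
            raise ValueError("active genera must have positive abundance")
        if self.genomic.shape[0] != n:
            raise ValueError("genomic matrix row mismatch")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge endpoint outside active node set")

    @property
    def n_nodes(self) -> int:
        return len(self.genus_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


# ---------------------------------------------------------------------------
# CLR and COAT correlation


def clr_transform(composition: np.ndarray, pseudocount: float | None = None) -> np.ndarray:
    """Centered log-ratio transform of one composition.

    ``pseudocount`` replaces zero entries only; positive entries are used
    as given.  The output is ln(x / geometric mean) and sums to zero.
    """
    x = np.asarray(composition, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("composition must be a vector of length >= 2")
    if np.any(x < 0):
        raise ValueError("composition entries must be non-negative")
    if np.all(x == 0):
        raise ValueError("composition is all zeros")
    if np.any(x == 0):
        if pseudocount is None or pseudocount <= 0:
            raise ValueError(
                "composition contains zeros; a positive pseudocount is required"
            )
        x = np.where(x == 0, pseudocount, x)
    logx = np.log(x)
    return logx - logx.mean()


def default_pseudocount(values: np.ndarray) -> float:
    """Half the smallest nonzero value in the table (multiplicative-replacement
    style zero handling)."""
    nz = values[values > 0]
    if nz.size == 0:
        raise ValueError("table has no positive values")
    return 0.5 * float(nz.min())


def coat_correlation(
    values: np.ndarray, pseudocount: float | None = None
) -> np.ndarray:
    """COAT correlation matrix: Pearson correlation of CLR-transformed rows.

    ``values`` is samples x genera.  Genera with zero variance after CLR get
    zero correlations (logged) rather than NaN.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 3 or values.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 genera")
    if pseudocount is None:
        pseudocount = default_pseudocount(values)
    clr = np.vstack([clr_transform(row, pseudocount) for row in values])
    sd = clr.std(axis=0)
    # tolerance absorbs float noise from log/geometric-mean cancellation
    degenerate = np.flatnonzero(sd <= 1e-12)
    if degenerate.size:
        logger.warning(
            "%d genera have zero CLR variance; their correlations are set to 0",
            degenerate.size,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(clr, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


# ---------------------------------------------------------------------------
# network construction


def build_network(
    table: AbundanceTable,
    tau: float = 0.1,
    n_subsamples: int = 5,
    subsample_fraction: float = 0.8,
    pseudocount: float | None = None,
    seed: int = 0,
) -> CoexpressionNetwork:
    """Stability-selected co-expression network.

    For each of ``n_subsamples`` seeded draws of ``floor(fraction * n)``
    samples without replacement, the COAT correlation matrix is computed;
    an edge (i, j) is retained iff |c_ij| >= tau with the same sign in every
    draw.  The stored weight is the mean per-draw correlation.  The
    pseudocount (by default half the smallest nonzero value of the full
    table) is shared across draws so zero replacement is consistent.
    """
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    n = table.n_samples
    m = int(np.floor(subsample_fraction * n))
    if m < 3:
        raise ValueError(f"subsample of {m} samples is too small (need >= 3)")
    if pseudocount is None:
        pseudocount = default_pseudocount(table.values)

    rng = np.random.default_rng(seed)
    corrs = np.empty((n_subsamples, table.n_genera, table.n_genera))
    for it in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        corrs[it] = coat_correlation(table.values[idx], pseudocount)

    strong = np.all(np.abs(corrs) >= tau, axis=0)
    consistent = np.all(corrs > 0, axis=0) | np.all(corrs < 0, axis=0)
    keep = strong & consistent
    np.fill_diagonal(keep, False)
    weights = corrs.mean(axis=0)

    edges: dict[tuple[str, str], float] = {}
    ii, jj = np.nonzero(np.triu(keep, k=1))
    for i, j in zip(ii, jj):
        a, b = sorted((table.genus_ids[i], table.genus_ids[j]))
        edges[(a, b)] = float(weights[i, j])
    return CoexpressionNetwork(
        list(table.genus_ids),
        edges,
        tau=tau,
        n_subsamples=n_subsamples,
        subsample_fraction=subsample_fraction,
        pseudocount=pseudocount,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-sample subgraphs


def induce_sample_graph(
    network: CoexpressionNetwork,
    table: AbundanceTable,
    embeddings: EmbeddingTable,
    sample_id: str,
) -> SampleGraph:
    """Induce the network on one sample's nonzero genera."""
    row = table.row(sample_id)
    net_set = set(network.genus_ids)
    active: list[str] = []
    abund: list[float] = []
    for g, v in zip(table.genus_ids, row):
        if v > 0 and g in net_set:
            active.append(g)
            abund.append(float(v))
    if not active:
        raise ValueError(f"sample {sample_id!r} has no active network genus")
    local = {g: i for i, g in enumerate(active)}
    pairs = [
        (local[a], local[b])
        for (a, b) in network.edges
        if a in local and b in local
    ]
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    if edges.shape[0] == 0:
        logger.debug("sample %s induces an edgeless graph", sample_id)
    emb_pos = {g: i for i, g in enumerate(embeddings.genus_ids)}
    missing = [g for g in active if g not in emb_pos]
    if missing:
        raise ValueError(f"genomic vector missing for genus {missing[0]!r}")
    genomic = embeddings.vectors[[emb_pos[g] for g in active]]
    return SampleGraph(sample_id, active, np.array(abund), genomic, edges)


def induce_all(
    network: CoexpressionNetwork,
    table: AbundanceTable,
    embeddings: EmbeddingTable,
    sample_ids: list[str] | None = None,
) -> list[SampleGraph]:
    ids = sample_ids if sample_ids is not None else table.sample_ids
    return [induce_sample_graph(network, table, embeddings, s) for s in ids]


def remove_nodes(graph: SampleGraph, names: set[str]) -> SampleGraph:
    """Induced subgraph after deleting the named genera.

    Equivalent to zeroing those genera in the sample row and re-inducing
    from the global network; remaining abundances are unchanged.
    """
    keep = [i for i, g in enumerate(graph.genus_ids) if g not in names]
    if not keep:
        raise ValueError(f"removing {len(names)} genera empties {graph.sample_id!r}")
    remap = {old: new for new, old in enumerate(keep)}
    kept = set(keep)
    edges = [
        (remap[i], remap[j])
        for i, j in graph.edges
        if i in kept and j in kept
    ]
    return SampleGraph(
        graph.sample_id,
        [graph.genus_ids[i] for i in keep],
        graph.abundance[keep],
        graph.genomic[keep],
        np.array(sorted(edges), dtype=np.int64).reshape(-1, 2),
    )


def shuffle_edges(graph: SampleGraph, seed: int) -> SampleGraph:
    """Resample the graph's edges uniformly among unordered node pairs.

    Node set, node features and edge count are preserved; no self-loops or
    duplicate edges are produced.  Seeded and reproducible.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes to shuffle edges")
    m = graph.n_edges
    total = n * (n - 1) // 2
    if m > total:
        raise ValueError(f"cannot place {m} edges among {total} possible pairs")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    edges = np.stack([iu[flat], ju[flat]], axis=1)
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
    return SampleGraph(
        graph.sample_id,
        list(graph.genus_ids),
        graph.abundance.copy(),
        graph.genomic.copy(),
        edges,
    )


# ---------------------------------------------------------------------------
# persistence


def write_network(network: CoexpressionNetwork, edges_path, meta_path=None):
    """Write the edge list as TSV (genus_a, genus_b, weight) plus an optional
    JSON provenance record."""
    rows = [
        {"genus_a": a, "genus_b": b, "weight": w}
        for (a, b), w in sorted(network.edges.items())
    ]
    pd.DataFrame(rows, columns=["genus_a", "genus_b", "weight"]).to_csv(
        edges_path, sep="\t", index=False, float_format="%.12g"
    )
    if meta_path is not None:
        meta = {
            "genus_ids": network.genus_ids,
            "tau": network.tau,
            "n_subsamples": network.n_subsamples,
            "subsample_fraction": network.subsample_fraction,
            "pseudocount": network.pseudocount,
            "seed": network.seed,
            "n_edges": network.n_edges,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_network(edges_path, meta_path=None) -> CoexpressionNetwork:
    df = pd.read_csv(edges_path, sep="\t", dtype={"genus_a": str, "genus_b": str})
    edges = {
        tuple(sorted((a, b))): float(w)
        for a, b, w in zip(df["genus_a"], df["genus_b"], df["weight"])
    }
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        return CoexpressionNetwork(
            meta["genus_ids"],
            edges,
            tau=meta["tau"],
            n_subsamples=meta["n_subsamples"],
            subsample_fraction=meta["subsample_fraction"],
            pseudocount=meta["pseudocount"],
            seed=meta["seed"],
        )
    genus_ids = sorted({g for e in edges for g in e})
    return CoexpressionNetwork(genus_ids, edges)
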