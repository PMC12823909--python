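"""GATv2 encoder with attention readout for sample-graph classification.

Architecture
------------
Node i of a sample graph enters the network as the concatenation of an
abundance vector — the scalar percent abundance times a single shared
64-dimensional learnable basis — and the genus's fixed genomic vector
(832 dimensions at the real-data defaults).

Three stacked GATv2 layers follow.  Per layer l and head k the attention
logit for directed neighbor pair (j -> i) is

    e_ij = a(l,k) . LeakyReLU(W_t(l,k) h_i + W_s(l,k) h_j),

i.e. the dynamic-attention form with the transformation applied before the
attention vector; W(l,k) = [W_t | W_s] acts on the concatenation
[h_i || h_j].  Coefficients are softmax-normalized over N_i (graph
neighbors plus a self-loop, which keeps the update defined for isolated
nodes), and the message aggregated for node i is sum_j alpha_ij W_s h_j.
Intermediate layers concatenate the K = 8 head outputs (width 256 at
defaults) and apply Mish; the final layer averages heads to width F = 32
with no activation, keeping the readout on an unsquashed representation.

The readout projects each final node embedding to a scalar importance
score via W_p, softmax-normalizes the scores over the graph's nodes into
attention A_i (a simplex), and pools P = sum_i A_i h_i.  A two-hidden-layer
MLP with sigmoid output maps P to the disease probability.

During training, edge dropout removes each undirected edge independently
(self-loops kept) and node dropout zeroes whole feature vectors once on
the layer-0 input, both with inverted-dropout scaling; evaluation is
deterministic.

Setting the module flag ``CHECK_INVARIANTS = True`` asserts on every
forward pass that each attention softmax sums to one (a test hook).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import SegmentPlan, Tensor
from .network import SampleGraph

__all__ = [
    "ModelConfig",
    "ModelState",
    "GraphBatch",
    "init_state",
    "init_node_features",
    "build_batch",
    "forward",
    "attention_coefficients",
    "predict",
    "predict_proba",
    "embed_graphs",
    "bce_with_logits",
    "save_checkpoint",
    "load_checkpoint",
]

# test hook: when True every segmented softmax asserts normalization
CHECK_INVARIANTS = False


@dataclass
class ModelConfig:
    n_layers: int = 3
    n_heads: int = 8
    node_dim: int = 32
    abundance_dim: int = 64
    genomic_dim: int = 768
    edge_dropout: float = 0.3
    node_dropout: float = 0.3
    mlp_hidden: tuple[int, int] = (32, 16)
    leaky_slope: float = 0.2
    # "per_head": every head outputs node_dim and intermediate layers
    #   concatenate to n_heads*node_dim (the default);
    # "node": every layer's output node representation has width node_dim
    #   (intermediate heads are node_dim/n_heads wide before concatenation),
    #   a cheaper reading of the same head-count/width constants.
    width_mode: str = "per_head"
    # half-range of the uniform init of the shared abundance basis; chosen so
    # percent-scale abundances (O(10)) map to O(0.1) features at init
    basis_init_range: float = 0.02

    def validate(self):
        if min(self.n_layers, self.n_heads, self.node_dim, self.abundance_dim) <= 0:
            raise ValueError("model dimensions must be positive")
        if self.genomic_dim < 0:
            raise ValueError("genomic_dim must be >= 0")
        if not all(0.0 <= p < 1.0 for p in (self.edge_dropout, self.node_dropout)):
            raise ValueError("dropout probabilities must be in [0, 1)")
        if len(self.mlp_hidden) != 2 or min(self.mlp_hidden) <= 0:
            raise ValueError("mlp_hidden must hold two positive widths")
        if self.width_mode not in ("node", "per_head"):
            raise ValueError(f"unknown width_mode {self.width_mode!r}")
        if self.width_mode == "node" and self.node_dim % self.n_heads:
            raise ValueError("node_dim must be divisible by n_heads in node mode")

    @property
    def input_dim(self) -> int:
        return self.abundance_dim + self.genomic_dim

    def layer_dims(self) -> list[tuple[int, int]]:
        """(input, per-head output) width of each GAT layer."""
        inter_head = (
            self.node_dim // self.n_heads
            if self.width_mode == "node"
            else self.node_dim
        )
        dims = []
        d = self.input_dim
        for l in range(1, self.n_layers + 1):
            per_head = self.node_dim if l == self.n_layers else inter_head
            dims.append((d, per_head))
            d = per_head * self.n_heads if l < self.n_layers else per_head
        return dims


@dataclass
class ModelState:
    """Learnable parameters plus their configuration."""

    config: ModelConfig
    params: dict[str, Tensor]
    seed: int
    dtype: np.dtype = np.dtype(np.float32)

    def param_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.params.items()}

    def copy_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]):
        for k, t in self.params.items():
            t.data = arrays[k].astype(self.dtype, copy=True)

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None

    def astype(self, dtype) -> "ModelState":
        dtype = np.dtype(dtype)
        params = {
            k: ag.parameter(t.data.astype(dtype)) for k, t in self.params.items()
        }
        return ModelState(self.config, params, self.seed, dtype)


def _glorot(rng, fan_in, fan_out, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_state(config: ModelConfig, seed: int, dtype=np.float32) -> ModelState:
    """Glorot-uniform weights; the shared abundance basis is initialized
    uniformly on a small symmetric range so that percent-scale abundance
    scalars produce well-conditioned features."""
    config.validate()
    dtype = np.dtype(dtype)
    rng = np.random.default_rng(seed)
    r = config.basis_init_range
    params: dict[str, Tensor] = {}
    params["abundance_basis"] = ag.parameter(
        rng.uniform(-r, r, size=config.abundance_dim).astype(dtype)
    )
    K, F = config.n_heads, config.node_dim
    for l, (d_in, f_out) in enumerate(config.layer_dims(), start=1):
        params[f"gat{l}.w_dst"] = ag.parameter(
            _glorot(rng, d_in, f_out, (K * f_out, d_in), dtype)
        )
        params[f"gat{l}.w_src"] = ag.parameter(
            _glorot(rng, d_in, f_out, (K * f_out, d_in), dtype)
        )
        params[f"gat{l}.att"] = ag.parameter(
            _glorot(rng, f_out, 1, (K, f_out), dtype)
        )
    params["readout.w"] = ag.parameter(_glorot(rng, F, 1, (1, F), dtype))
    widths = [F, *config.mlp_hidden, 1]
    for i, (a, b) in enumerate(zip(widths[:-1], widths[1:]), start=1):
        params[f"mlp{i}.w"] = ag.parameter(_glorot(rng, a, b, (b, a), dtype))
        params[f"mlp{i}.b"] = ag.parameter(np.zeros(b, dtype=dtype))
    return ModelState(config, params, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# batching


@dataclass
class GraphBatch:
    """Disjoint union of sample graphs prepared for one forward pass."""

    abundance: np.ndarray  # (N,)
    genomic: np.ndarray  # (N, d_g)
    graph_ids: np.ndarray  # (N,) node -> graph index
    src: np.ndarray  # (E,) directed edges incl. self-loops
    dst: np.ndarray  # (E,)
    n_nodes: int
    n_graphs: int
    plan_src: SegmentPlan
    plan_dst: SegmentPlan
    plan_graph: SegmentPlan
    node_slices: list[slice]


def build_batch(
    graphs: list[SampleGraph],
    dtype=np.float32,
    training: bool = False,
    edge_dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GraphBatch:
    if not graphs:
        raise ValueError("empty graph batch")
    dtype = np.dtype(dtype)
    abund, genomic, gids, srcs, dsts, slices = [], [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        if g.n_nodes == 0:
            raise ValueError(f"sample {g.sample_id!r} has an empty graph")
        n = g.n_nodes
        abund.append(g.abundance)
        genomic.append(g.genomic)
        gids.append(np.full(n, gi, dtype=np.int64))
        edges = g.edges
        if training and edge_dropout > 0 and edges.shape[0]:
            keep = rng.random(edges.shape[0]) >= edge_dropout
            edges = edges[keep]
        if edges.shape[0]:
            u = edges[:, 0] + offset
            v = edges[:, 1] + offset
            srcs.append(np.concatenate([u, v]))
            dsts.append(np.concatenate([v, u]))
        loop = np.arange(offset, offset + n, dtype=np.int64)
        srcs.append(loop)
        dsts.append(loop)
        slices.append(slice(offset, offset + n))
        offset += n
    src = np.concatenate(srcs)
    dst = np.concatenate(dsts)
    graph_ids = np.concatenate(gids)
    return GraphBatch(
        abundance=np.concatenate(abund).astype(dtype),
        genomic=np.vstack(genomic).astype(dtype),
        graph_ids=graph_ids,
        src=src,
        dst=dst,
        n_nodes=offset,
        n_graphs=len(graphs),
        plan_src=SegmentPlan(src, offset),
        plan_dst=SegmentPlan(dst, offset),
        plan_graph=SegmentPlan(graph_ids, len(graphs)),
        node_slices=slices,
    )


# ---------------------------------------------------------------------------
# forward pass


def init_node_features(graph: SampleGraph, state: ModelState) -> np.ndarray:
    """Layer-0 features of one graph: concat(abundance * shared basis, s_i)."""
    cfg = state.config
    basis = state.params["abundance_basis"].data
    feats = graph.abundance[:, None].astype(state.dtype) * basis[None, :]
    if cfg.genomic_dim:
        if graph.genomic.shape[1] != cfg.genomic_dim:
            raise ValueError(
                f"genomic vectors have dim {graph.genomic.shape[1]}, "
                f"model expects {cfg.genomic_dim}"
            )
        feats = np.concatenate(
            [feats, graph.genomic.astype(state.dtype)], axis=1
        )
    return feats


def forward(
    state: ModelState,
    batch: GraphBatch,
    training: bool = False,
    rng: np.random.Generator | None = None,
    collect: dict | None = None,
) -> Tensor:
    """Run the full network on a batch; returns per-graph logits (Tensor).

    With ``collect`` a dict, evaluation internals are stored in it:
    ``attention`` (N,), ``pooled`` (B, F), ``alphas`` (per layer, (E, K)).
    """
    cfg = state.config
    cfg.validate()
    if training and (cfg.node_dropout > 0 or cfg.edge_dropout > 0) and rng is None:
        raise ValueError("training-mode forward needs an rng for dropout")
    p = state.params
    dtype = state.dtype
    K = cfg.n_heads

    if cfg.genomic_dim and batch.genomic.shape[1] != cfg.genomic_dim:
        raise ValueError(
            f"genomic vectors have dim {batch.genomic.shape[1]}, "
            f"model expects {cfg.genomic_dim}"
        )

    abund = ag.constant(batch.abundance.astype(dtype)[:, None])
    basis = ag.reshape(p["abundance_basis"], (1, cfg.abundance_dim))
    h = abund * basis
    if cfg.genomic_dim:
        h = ag.concat([h, ag.constant(batch.genomic.astype(dtype))], axis=1)

    if training and cfg.node_dropout > 0:
        # node dropout: whole feature vectors zeroed once, on the input
        keep = (rng.random(batch.n_nodes) >= cfg.node_dropout).astype(dtype)
        mask = keep[:, None] / dtype.type(1.0 - cfg.node_dropout)
        h = h * ag.constant(mask)

    alphas = [] if collect is not None else None
    for l, (d_in, f_out) in enumerate(cfg.layer_dims(), start=1):
        xq = h @ p[f"gat{l}.w_dst"].T  # (N, K*F) query-side transform
        xk = h @ p[f"gat{l}.w_src"].T  # (N, K*F) key/message transform
        scores = ag.gatv2_scores(
            xq, xk, p[f"gat{l}.att"], batch.src, batch.dst, cfg.leaky_slope
        )  # (E, K)
        alpha = ag.segment_softmax(
            scores, batch.plan_dst, check=CHECK_INVARIANTS
        )
        if alphas is not None:
            alphas.append(alpha.data.astype(np.float64))
        agg = ag.attention_aggregate(
            alpha, xk, batch.src, batch.dst, batch.n_nodes
        )  # (N, K*F)
        if l < cfg.n_layers:
            h = ag.mish(agg)
        else:
            h = ag.reshape(agg, (-1, K, f_out)).sum(axis=1) * (1.0 / K)

    # attention readout
    hhat = h @ p["readout.w"].T  # (N, 1)
    attn = ag.segment_softmax(hhat, batch.plan_graph, check=CHECK_INVARIANTS)
    pooled = ag.segment_sum(h * attn, batch.plan_graph)  # (B, F)

    z = ag.mish(pooled @ p["mlp1.w"].T + ag.reshape(p["mlp1.b"], (1, -1)))
    z = ag.mish(z @ p["mlp2.w"].T + ag.reshape(p["mlp2.b"], (1, -1)))
    logits = z @ p["mlp3.w"].T + ag.reshape(p["mlp3.b"], (1, -1))
    logits = ag.reshape(logits, (-1,))

    if collect is not None:
        collect["attention"] = attn.data.astype(np.float64).ravel()
        collect["pooled"] = pooled.data.astype(np.float64)
        collect["alphas"] = alphas
        collect["node_slices"] = batch.node_slices
    return logits


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logits."""
    y = ag.constant(np.asarray(labels, dtype=logits.dtype))
    per = ag.softplus(logits) - y * logits
    return per.sum() * (1.0 / logits.shape[0])


# ---------------------------------------------------------------------------
# inference helpers


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return ag._sigmoid_data(np.asarray(x, dtype=np.float64))


def predict_proba(
    state: ModelState,
    graphs: list[SampleGraph],
    max_batch_nodes: int = 16384,
) -> np.ndarray:
    """Deterministic (evaluation-mode) disease probabilities for many graphs."""
    probs = np.empty(len(graphs), dtype=np.float64)
    i = 0
    while i < len(graphs):
        j = i
        nodes = 0
        while j < len(graphs) and (nodes == 0 or nodes + graphs[j].n_nodes <= max_batch_nodes):
            nodes += graphs[j].n_nodes
            j += 1
        batch = build_batch(graphs[i:j], dtype=state.dtype)
        logits = forward(state, batch, training=False)
        probs[i:j] = _sigmoid(logits.data)
        i = j
    return probs


def predict(graph: SampleGraph, state: ModelState) -> float:
    """Disease probability for a single sample graph (strictly inside (0, 1))."""
    return float(predict_proba(state, [graph])[0])


def embed_graphs(
    state: ModelState, graphs: list[SampleGraph], max_batch_nodes: int = 16384
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Probabilities, pooled graph embeddings and per-graph node attention."""
    probs = np.empty(len(graphs), dtype=np.float64)
    pooled = np.empty((len(graphs), state.config.node_dim), dtype=np.float64)
    attention: list[np.ndarray] = []
    i = 0
    while i < len(graphs):
        j = i
        nodes = 0
        while j < len(graphs) and (nodes == 0 or nodes + graphs[j].n_nodes <= max_batch_nodes):
            nodes += graphs[j].n_nodes
            j += 1
        batch = build_batch(graphs[i:j], dtype=state.dtype)
        collect: dict = {}
        logits = forward(state, batch, training=False, collect=collect)
        probs[i:j] = _sigmoid(logits.data)
        pooled[i:j] = collect["pooled"]
        for sl in collect["node_slices"]:
            attention.append(collect["attention"][sl])
        i = j
    return probs, pooled, attention


def attention_coefficients(
    state: ModelState, graph: SampleGraph, layer: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluation-mode attention coefficients of one GAT layer.

    Returns (alpha, src, dst) where ``alpha`` is (E, K) over the directed
    edge list including self-loops; for every node i and head k the
    coefficients over incoming edges sum to one.
    """
    if not (1 <= layer <= state.config.n_layers):
        raise ValueError(f"layer must be in 1..{state.config.n_layers}")
    batch = build_batch([graph], dtype=state.dtype)
    collect: dict = {}
    forward(state, batch, training=False, collect=collect)
    return collect["alphas"][layer - 1], batch.src, batch.dst


# ---------------------------------------------------------------------------
# checkpoints


def config_hash(config: ModelConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_checkpoint(state: ModelState, path):
    """Serialized parameter map (.npz) with a JSON config sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(path, **state.param_arrays())
    sidecar = path.with_suffix(".json")
    meta = {
        "config": asdict(config := state.config),
        "config_hash": config_hash(config),
        "seed": state.seed,
        "dtype": state.dtype.name,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_checkpoint(path) -> ModelState:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    cfg_d = dict(meta["config"])
    cfg_d["mlp_hidden"] = tuple(cfg_d["mlp_hidden"])
    config = ModelConfig(**cfg_d)
    dtype = np.dtype(meta["dtype"])
    arrays = np.load(path)
    params = {k: ag.parameter(arrays[k].astype(dtype)) for k in arrays.files}
    return ModelState(config, params, seed=meta["seed"], dtype=dtype)
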