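"""The multi-representation attention-readout graph network.

Architecture, per graph representation in a scheme:

1. *Encoding* — a linear layer maps node (and, for the atom graph, edge)
   feature vectors to ``embedding_dim``.
2. *Node embedding* — rounds of edge-aware GIN message passing: messages
   are ``relu(h_src + e)`` summed over neighbours, and each round's
   aggregate updates the node state through a GRU cell.
3. *Molecule readout* — a virtual super node linked to every real node
   attends over them (single-head GAT-style scoring, softmax per graph);
   the attention-weighted context updates the super-node state through a
   GRU.  The final round's attention coefficients are the per-node
   importance weights used for interpretation.

Molecule embeddings from all representations are concatenated and a small
fully connected head produces the prediction (a probability for
classification).  Each representation has its own encoder and backbone —
graphs are learned independently and only fused at the embedding level.

When the scheme combines the atom graph with reduced graphs, reduced node
features are first extended by sum-pooling the raw atom features over each
node's ``atom_map`` (*initial pooling*), so atom-level information is not
discarded by the reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concat, gather, segment_mean, segment_softmax, segment_sum
from .graphs import ATOM_VOCAB, REPRESENTATIONS, VOCABULARIES, MolecularGraph


@dataclass(frozen=True)
class GraphScheme:
    """An ordered subset of representations defining one combination model."""

    representations: tuple

    def __post_init__(self):
        reps = tuple(self.representations)
        if not reps:
            raise ValueError("scheme must contain at least one representation")
        if len(set(reps)) != len(reps):
            raise ValueError("duplicate representations in scheme")
        for r in reps:
            if r not in REPRESENTATIONS:
                raise ValueError(f"unknown representation {r!r}")
        object.__setattr__(self, "representations", reps)

    @classmethod
    def parse(cls, label: str) -> "GraphScheme":
        return cls(tuple(label.split("+")))

    @property
    def label(self) -> str:
        return "+".join(self.representations)

    @property
    def uses_initial_pooling(self) -> bool:
        return "A" in self.representations and len(self.representations) > 1


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``embedding_dim`` defaults to the production width of 256; smaller
    widths train faster on toy tasks with little loss.
    """

    embedding_dim: int = 256
    message_passing_steps: int = 2          # atom graph
    reduced_message_passing_steps: int = 1  # coarser graphs need fewer hops
    readout_steps: int = 2
    dropout: float = 0.0
    task: str = "classification"

    def __post_init__(self):
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if min(self.message_passing_steps, self.reduced_message_passing_steps,
               self.readout_steps) < 1:
            raise ValueError("step counts must be >= 1")


@dataclass
class ForwardOutput:
    prediction: np.ndarray            # (n_molecules,)
    attention: dict                   # rep -> (weights (n_nodes,), graph_ids (n_nodes,))
    embeddings: dict                  # rep -> (n_molecules, embedding_dim)
    logits: "Tensor"
    raw_attention: dict               # rep -> Tensor column of attention


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def initial_pooling(atom_graph: MolecularGraph, reduced_graph: MolecularGraph) -> np.ndarray:
    """Reduced node features extended with sum-pooled atom features.

    Each reduced node's vector is concatenated with the sum of the atom
    graph's raw node features over the atoms that node covers.
    """
    pooled = np.zeros((reduced_graph.n_nodes, atom_graph.node_features.shape[1]))
    for i, atoms in enumerate(reduced_graph.atom_map):
        idx = sorted(atoms)
        if max(idx) >= atom_graph.n_nodes:
            raise IndexError("atom_map references an atom outside the atom graph")
        pooled[i] = atom_graph.node_features[idx].sum(axis=0)
    return np.concatenate([reduced_graph.node_features, pooled], axis=1)


class GraphBatch:
    """Disjoint union of molecular graphs with segment bookkeeping."""

    def __init__(self, graphs, pooled_features=None):
        if any(g.n_nodes == 0 for g in graphs):
            raise ValueError("cannot batch an empty graph")
        self.graphs = graphs
        self.n_graphs = len(graphs)
        feats = pooled_features if pooled_features is not None else [
            g.node_features for g in graphs
        ]
        self.node_features = np.concatenate(feats, axis=0)
        offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
        self.node_offsets = offsets
        self.graph_ids = np.concatenate(
            [np.full(g.n_nodes, gi, dtype=np.int64) for gi, g in enumerate(graphs)]
        )
        src, dst, ef = [], [], []
        for gi, g in enumerate(graphs):
            for ei, (i, j) in enumerate(g.edges):
                # undirected: message in both directions
                src += [i + offsets[gi], j + offsets[gi]]
                dst += [j + offsets[gi], i + offsets[gi]]
                if g.edge_features is not None and g.edge_features.shape[0]:
                    ef += [g.edge_features[ei], g.edge_features[ei]]
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)
        self.edge_features = np.asarray(ef) if ef else None
        self.n_nodes = self.node_features.shape[0]


def batch_molecules(graph_dicts, scheme: GraphScheme) -> dict:
    """Per-representation GraphBatch for a list of per-molecule graph dicts."""
    batches = {}
    for rep in scheme.representations:
        graphs = [gd[rep] for gd in graph_dicts]
        pooled = None
        if rep != "A" and scheme.uses_initial_pooling:
            pooled = [initial_pooling(gd["A"], gd[rep]) for gd in graph_dicts]
        batches[rep] = GraphBatch(graphs, pooled)
    return batches


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim, out_dim, rng):
        self.W = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x):
        return x @ self.W + self.b


class GRUCell(Module):
    """Standard gated recurrent unit update h' = (1-z)*n + z*h."""

    def __init__(self, in_dim, hidden_dim, rng):
        self.x_r = Linear(in_dim, hidden_dim, rng)
        self.x_z = Linear(in_dim, hidden_dim, rng)
        self.x_n = Linear(in_dim, hidden_dim, rng)
        self.h_r = Linear(hidden_dim, hidden_dim, rng)
        self.h_z = Linear(hidden_dim, hidden_dim, rng)
        self.h_n = Linear(hidden_dim, hidden_dim, rng)

    def __call__(self, x, h):
        r = (self.x_r(x) + self.h_r(h)).sigmoid()
        z = (self.x_z(x) + self.h_z(h)).sigmoid()
        n = (self.x_n(x) + r * self.h_n(h)).tanh()
        return (1.0 - z) * n + z * h


class GraphEncoder(Module):
    """Encoder + GIN/GRU node embedding + virtual-super-node readout for one graph."""

    def __init__(self, node_dim, edge_dim, config: ModelConfig, steps, rng):
        d = config.embedding_dim
        self.node_lin = Linear(node_dim, d, rng)
        self.edge_lin = Linear(edge_dim, d, rng) if edge_dim else None
        self.steps = steps
        self.msg_lins = [Linear(d, d, rng) for _ in range(steps)]
        self.node_gru = GRUCell(d, d, rng)
        # readout
        self.readout_steps = config.readout_steps
        self.att_proj = Linear(d, d, rng)
        self.att_score = Linear(2 * d, 1, rng)
        self.super_gru = GRUCell(d, d, rng)

    def node_embedding(self, batch: GraphBatch):
        h = self.node_lin(Tensor(batch.node_features)).relu()
        e = None
        if self.edge_lin is not None and batch.edge_features is not None:
            e = self.edge_lin(Tensor(batch.edge_features))
        for lin in self.msg_lins:
            if len(batch.src):
                msg = gather(h, batch.src)
                if e is not None:
                    msg = msg + e
                agg = segment_sum(msg.relu(), batch.dst, batch.n_nodes)
            else:
                agg = Tensor(np.zeros_like(h.data))
            h = self.node_gru(lin(agg).relu(), h)
        return h

    def readout(self, batch: GraphBatch, h):
        z = self.att_proj(h)
        s = segment_mean(h, batch.graph_ids, batch.n_graphs)
        alpha = None
        for _ in range(self.readout_steps):
            s_per_node = gather(s, batch.graph_ids)
            score = self.att_score(concat([z, self.att_proj(s_per_node)], axis=1)).leaky_relu()
            alpha = segment_softmax(score, batch.graph_ids, batch.n_graphs)
            context = segment_sum(alpha * z, batch.graph_ids, batch.n_graphs)
            s = self.super_gru(context, s)
        return s, alpha

    def __call__(self, batch: GraphBatch):
        h = self.node_embedding(batch)
        return self.readout(batch, h)


class MMGXNetwork(Module):
    """Multi-graph combination model with concatenation fusion."""

    def __init__(self, scheme: GraphScheme, config: ModelConfig, seed=0,
                 node_dims=None):
        self.scheme = scheme
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoders = []
        self._encoder_map = {}
        for rep in scheme.representations:
            vocab = VOCABULARIES[rep]
            node_dim = vocab.node_dim
            if node_dims and rep in node_dims:
                node_dim = node_dims[rep]
            elif rep != "A" and scheme.uses_initial_pooling:
                node_dim += ATOM_VOCAB.node_dim
            edge_dim = vocab.edge_dim
            steps = (config.message_passing_steps if rep == "A"
                     else config.reduced_message_passing_steps)
            enc = GraphEncoder(node_dim, edge_dim, config, steps, rng)
            self.encoders.append(enc)
            self._encoder_map[rep] = enc
        d = config.embedding_dim
        self.head_hidden = Linear(len(scheme.representations) * d, d, rng)
        self.head_out = Linear(d, 1, rng)

    def forward(self, batches: dict, rng=None, training=False) -> ForwardOutput:
        if set(batches) != set(self.scheme.representations):
            raise ValueError("batch representations do not match the scheme")
        embeddings, attention, raw_attention = [], {}, {}
        for rep in self.scheme.representations:
            emb, alpha = self._encoder_map[rep](batches[rep])
            embeddings.append(emb)
            attention[rep] = (alpha.data.reshape(-1).copy(), batches[rep].graph_ids)
            raw_attention[rep] = alpha
        fused = concat(embeddings, axis=1) if len(embeddings) > 1 else embeddings[0]
        hidden = self.head_hidden(fused).relu()
        if training and self.config.dropout > 0 and rng is not None:
            keep = (rng.random(hidden.data.shape) >= self.config.dropout).astype(float)
            hidden = hidden * Tensor(keep * (1.0 / (1.0 - self.config.dropout)))
        logits = self.head_out(hidden).reshape(-1)
        if self.config.task == "classification":
            pred = 1.0 / (1.0 + np.exp(-logits.data))
        else:
            pred = logits.data.copy()
        return ForwardOutput(
            prediction=pred,
            attention=attention,
            embeddings={rep: e.data.copy() for rep, e in
                        zip(self.scheme.representations, embeddings)},
            logits=logits,
            raw_attention=raw_attention,
        )

    def loss(self, out: ForwardOutput, targets: np.ndarray):
        y = Tensor(np.asarray(targets, dtype=np.float64))
        z = out.logits
        if self.config.task == "classification":
            # numerically stable binary cross-entropy on logits
            return (z.softplus() - y * z).mean()
        return ((z - y) * (z - y)).mean()


class Adam:
    """Adam optimizer with optional decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
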