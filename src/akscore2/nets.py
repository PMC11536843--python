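"""The three graph-attention sub-networks.

* NonDock — pocket tower (5 GATv2 layers) and ligand tower (3 layers)
  over covalent-only graphs; pooled embeddings are concatenated and an
  MLP emits an interaction logit (sigmoid applied at inference).
* DockS — shared 5-layer encoder over the complex graph; two
  independent MLP heads predict binding free energy (kcal/mol) and
  pose RMSD (A, non-negative at inference via softplus).
* DockC — as DockS with a single head emitting an RMSD-penalized
  binding free energy.

Each GATv2 layer is edge-feature aware (attention logits see the edge
vector), followed by ReLU and dropout; global mean pooling over node
embeddings yields a fixed-size graph vector.  Everything runs on the
in-repo autodiff core; self-loops with zero edge features keep the
attention softmax defined for isolated nodes.
"""

from __future__ import annotations


import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .autograd import Tensor, concat, no_grad, spmm
from .graphs import (EDGE_DIM_COMPLEX, EDGE_DIM_COVALENT, MolecularGraph,
                     NODE_DIM, FeatureSchema)


class ModeError(ValueError):
    """Raised when a graph of the wrong kind is fed to a network."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    Defaults follow the production recipe (256-dimensional embeddings,
    5 complex/protein layers, 3 ligand layers, dropout 0.1); smaller
    embeddings are used for desk-scale CPU runs.
    """
    embed_dim: int = 256
    n_layers_complex: int = 5
    n_layers_ligand: int = 3
    attention_heads: int = 4
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim <= 0 or self.embed_dim % self.attention_heads:
            raise ValueError("embed_dim must be a positive multiple of heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if min(self.n_layers_complex, self.n_layers_ligand) < 1:
            raise ValueError("layer counts must be >= 1")


# ---------------------------------------------------------------------------
# batched graphs
# ---------------------------------------------------------------------------

class GraphBatch:
    """A disjoint union of graphs with precomputed sparse operators.

    Holds the gather (edge <- node) and scatter (node <- edge) incidence
    matrices, a mean-pooling matrix (graph <- node), and a dst-sorted
    edge order for the numerically stable segment softmax.
    """

    def __init__(self, graphs: Sequence[MolecularGraph]):
        if not graphs:
            raise ValueError("empty batch")
        widths = {g.edge_features.shape[1] if g.edge_features.size
                  else None for g in graphs}
        widths.discard(None)
        if len(widths) > 1:
            raise ModeError(f"mixed edge widths in batch: {widths}")
        self.edge_width = widths.pop() if widths else EDGE_DIM_COVALENT
        xs, efs, srcs, dsts, batch_idx = [], [], [], [], []
        offset = 0
        origins = []
        for bi, g in enumerate(graphs):
            n = g.n_nodes
            xs.append(g.node_features)
            origins.append(g.node_origin)
            if g.n_edges:
                srcs.append(g.edge_index[0] + offset)
                dsts.append(g.edge_index[1] + offset)
                efs.append(g.edge_features)
            # self-loops (zero edge features) keep every node attended
            loops = np.arange(n) + offset
            srcs.append(loops)
            dsts.append(loops)
            efs.append(np.zeros((n, self.edge_width)))
            batch_idx.append(np.full(n, bi, dtype=np.intp))
            offset += n
        from .autograd import get_default_dtype
        dtype = get_default_dtype()
        self.x = np.vstack(xs).astype(dtype)
        self.edge_features = np.vstack(efs).astype(dtype)
        self.src = np.concatenate(srcs)
        self.dst = np.concatenate(dsts)
        self.batch_index = np.concatenate(batch_idx)
        self.node_origin = np.concatenate(origins)
        self.n_graphs = len(graphs)
        n_nodes, n_edges = self.x.shape[0], self.src.shape[0]
        ones = np.ones(n_edges, dtype=dtype)
        self.gather_src = sp.csr_matrix(
            (ones, (np.arange(n_edges), self.src)), shape=(n_edges, n_nodes))
        self.gather_dst = sp.csr_matrix(
            (ones, (np.arange(n_edges), self.dst)), shape=(n_edges, n_nodes))
        self.scatter_dst = self.gather_dst.T.tocsr()
        counts = np.bincount(self.batch_index, minlength=self.n_graphs)
        self.pool = sp.csr_matrix(
            ((1.0 / counts[self.batch_index]).astype(dtype),
             (self.batch_index, np.arange(n_nodes))),
            shape=(self.n_graphs, n_nodes))
        self.dst_order = np.argsort(self.dst, kind="stable")
        sorted_dst = self.dst[self.dst_order]
        self.dst_starts = np.concatenate(
            [[0], np.nonzero(np.diff(sorted_dst))[0] + 1])
        self.dst_unique = sorted_dst[self.dst_starts]

    def segment_max(self, scores: np.ndarray) -> np.ndarray:
        """Per-destination-node max of edge scores (constant w.r.t. grad)."""
        m = np.full((self.x.shape[0], scores.shape[1]), -np.inf)
        red = np.maximum.reduceat(scores[self.dst_order], self.dst_starts,
                                  axis=0)
        m[self.dst_unique] = red
        return m


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out, shape=None):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-s, s, size=shape or (fan_in, fan_out)))


class Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class GATv2Layer:
    """Edge-aware GATv2 attention with multi-head concatenation.

    Attention logit per arc: a_h . LeakyReLU(W_l x_src + W_r x_dst +
    W_e e); message: alpha * W_l x_src; heads concatenate back to the
    embedding width.
    """

    def __init__(self, rng, dim: int, heads: int, edge_dim: int):
        self.heads = heads
        self.head_dim = dim // heads
        self.W_l = _glorot(rng, dim, dim)
        self.W_r = _glorot(rng, dim, dim)
        self.W_e = _glorot(rng, edge_dim, dim)
        self.att = _glorot(rng, self.head_dim, 1, shape=(heads, self.head_dim))
        self.b = Tensor(np.zeros(dim))

    def parameters(self):
        return [self.W_l, self.W_r, self.W_e, self.att, self.b]

    def __call__(self, x: Tensor, ef: Tensor, batch: GraphBatch) -> Tensor:
        E = batch.src.shape[0]
        H, F = self.heads, self.head_dim
        xl = x @ self.W_l
        xr = x @ self.W_r
        src_l = spmm(batch.gather_src, xl)          # (E, H*F)
        dst_r = spmm(batch.gather_dst, xr)
        ee = ef @ self.W_e
        g = (src_l + dst_r + ee).leaky_relu(0.2)
        scores = (g.reshape(E, H, F) * self.att).sum(axis=2)   # (E, H)
        m_node = batch.segment_max(scores.data)                # constant shift
        m_edge = m_node[batch.dst]
        z = (scores - m_edge).exp()
        denom = spmm(batch.gather_dst, spmm(batch.scatter_dst, z))
        alpha = z / denom                                      # (E, H)
        msg = (alpha.reshape(E, H, 1) * src_l.reshape(E, H, F)).reshape(E, H * F)
        return spmm(batch.scatter_dst, msg) + self.b


class MLP:
    """Three linear layers with ReLU + dropout between them."""

    def __init__(self, rng, widths: Sequence[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(widths, widths[1:])]

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def __call__(self, x: Tensor, dropout: float, training: bool,
                 rng: Optional[np.random.Generator]) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
                x = _dropout(x, dropout, training, rng)
        return x


def _dropout(x: Tensor, p: float, training: bool,
             rng: Optional[np.random.Generator]) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs an RNG")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask, requires_grad=False)


class GraphEncoder:
    """Linear embedding 73 -> D, n GATv2 layers (ReLU, dropout), mean pool."""

    def __init__(self, rng, cfg: NetConfig, n_layers: int, edge_dim: int):
        self.cfg = cfg
        self.edge_dim = edge_dim
        self.embed = Linear(rng, NODE_DIM, cfg.embed_dim)
        self.layers = [GATv2Layer(rng, cfg.embed_dim, cfg.attention_heads,
                                  edge_dim) for _ in range(n_layers)]

    def parameters(self):
        out = self.embed.parameters()
        for l in self.layers:
            out += l.parameters()
        return out

    def __call__(self, batch: GraphBatch, training: bool = False,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
        if batch.edge_width != self.edge_dim:
            raise ModeError(
                f"encoder expects edge width {self.edge_dim}, "
                f"got {batch.edge_width}")
        x = self.embed(Tensor(batch.x, requires_grad=False))
        ef = Tensor(batch.edge_features, requires_grad=False)
        for layer in self.layers:
            x = layer(x, ef, batch).relu()
            x = _dropout(x, self.cfg.dropout, training, rng)
        return spmm(batch.pool, x)   # (B, D)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _head_widths(n_in: int, embed: int) -> list:
    return [n_in, max(embed // 2, 8), max(embed // 4, 8), 1]


class _BaseModel:
    arch = "base"

    def parameters(self) -> List[Tensor]:
        raise NotImplementedError

    def save(self, path, schema: Optional[FeatureSchema] = None) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {"arch": self.arch, "config": asdict(self.cfg),
                "schema_version": (schema or FeatureSchema()).version,
                "ablated": sorted((schema or FeatureSchema()).ablated)}
        np.savez_compressed(path, __meta__=np.array([json.dumps(meta)]),
                            **arrays)

    def load_weights(self, path) -> "_BaseModel":
        z = np.load(path, allow_pickle=False)
        for i, p in enumerate(self.parameters()):
            p.data = np.array(z[f"p{i}"])
        return self

    @staticmethod
    def checkpoint_meta(path) -> dict:
        z = np.load(path, allow_pickle=False)
        return json.loads(str(z["__meta__"][0]))


def load_model(path) -> "_BaseModel":
    meta = _BaseModel.checkpoint_meta(path)
    cfg = NetConfig(**meta["config"])
    cls = {"nondock": NonDockModel, "docks": DockSModel,
           "dockc": DockCModel}[meta["arch"]]
    model = cls(cfg)
    model.load_weights(path)
    return model


class NonDockModel(_BaseModel):
    arch = "nondock"

    def __init__(self, cfg: NetConfig = NetConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        D = cfg.embed_dim
        self.protein_encoder = GraphEncoder(rng, cfg, cfg.n_layers_complex,
                                            EDGE_DIM_COVALENT)
        self.ligand_encoder = GraphEncoder(rng, cfg, cfg.n_layers_ligand,
                                           EDGE_DIM_COVALENT)
        self.mlp = MLP(rng, _head_widths(2 * D, D))

    def parameters(self):
        return (self.protein_encoder.parameters()
                + self.ligand_encoder.parameters() + self.mlp.parameters())

    def forward(self, pocket_batch: GraphBatch, ligand_batch: GraphBatch,
                training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        """Interaction logits, one per (pocket, ligand) pair."""
        for b in (pocket_batch, ligand_batch):
            if b.edge_width != EDGE_DIM_COVALENT:
                raise ModeError("NonDock requires covalent-only graphs")
        hp = self.protein_encoder(pocket_batch, training, rng)
        hl = self.ligand_encoder(ligand_batch, training, rng)
        h = concat([hp, hl], axis=1)
        return self.mlp(h, self.cfg.dropout, training, rng).reshape(-1)

    def predict_proba(self, pocket_batch, ligand_batch) -> np.ndarray:
        """Inference-time p_pred in [0, 1] (sigmoid of the logit)."""
        with no_grad():
            return self.forward(pocket_batch, ligand_batch).sigmoid().data


class DockSModel(_BaseModel):
    arch = "docks"

    def __init__(self, cfg: NetConfig = NetConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        D = cfg.embed_dim
        self.encoder = GraphEncoder(rng, cfg, cfg.n_layers_complex,
                                    EDGE_DIM_COMPLEX)
        self.head_energy = MLP(rng, _head_widths(D, D))
        self.head_rmsd = MLP(rng, _head_widths(D, D))

    def parameters(self):
        return (self.encoder.parameters() + self.head_energy.parameters()
                + self.head_rmsd.parameters())

    def forward(self, batch: GraphBatch, training: bool = False,
                rng: Optional[np.random.Generator] = None
                ) -> Tuple[Tensor, Tensor]:
        """(E_pred, raw RMSD head); training losses use the raw head."""
        if batch.edge_width != EDGE_DIM_COMPLEX:
            raise ModeError("DockS requires complex graphs (edge width 24)")
        h = self.encoder(batch, training, rng)
        e = self.head_energy(h, self.cfg.dropout, training, rng).reshape(-1)
        r = self.head_rmsd(h, self.cfg.dropout, training, rng).reshape(-1)
        return e, r

    def predict(self, batch: GraphBatch) -> Tuple[np.ndarray, np.ndarray]:
        """Inference: (E_pred, R_pred) with R_pred >= 0 via softplus."""
        with no_grad():
            e, r = self.forward(batch)
            return e.data, r.softplus().data


def docks_inference_energy(E_pred, R_pred):
    """Final DockS score: predicted energy penalized by predicted RMSD."""
    return np.asarray(E_pred) + np.asarray(R_pred)


class DockCModel(_BaseModel):
    arch = "dockc"

    def __init__(self, cfg: NetConfig = NetConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        D = cfg.embed_dim
        self.encoder = GraphEncoder(rng, cfg, cfg.n_layers_complex,
                                    EDGE_DIM_COMPLEX)
        self.head = MLP(rng, _head_widths(D, D))

    def parameters(self):
        return self.encoder.parameters() + self.head.parameters()

    def forward(self, batch: GraphBatch, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        if batch.edge_width != EDGE_DIM_COMPLEX:
            raise ModeError("DockC requires complex graphs (edge width 24)")
        h = self.encoder(batch, training, rng)
        return self.head(h, self.cfg.dropout, training, rng).reshape(-1)

    def predict(self, batch: GraphBatch) -> np.ndarray:
        with no_grad():
            return self.forward(batch).data


def parameter_count(model: _BaseModel) -> int:
    return int(sum(p.data.size for p in model.parameters()))
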