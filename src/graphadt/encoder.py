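"""Hierarchical graph encoder: K x (GIN message passing + MVPool), with
per-layer mean||max readouts fused by a multi-layer attention mechanism into
a fixed-size graph representation.

The same encoder handles both the original molecular graph (nodes = atoms)
and its structure-remapped graph (nodes = directed bonds); only the input
feature dimension differs.  Edge features, where present, enter each GIN
layer GIN-E style: the summed incident edge features of a node are linearly
projected and added to its aggregated neighbour message.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import EmptyGraphError
from .nn import MLP, Linear, Module, Parameter


@dataclass
class EncoderConfig:
    n_layers: int = 2
    hidden_dim: int = 32
    pool_ratio: float = 0.8
    delta: float = 0.2
    k_power: int = 1
    gin_eps_learnable: bool = True
    use_edge_features: bool = True

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


class GINLayer(Module):
    """Graph Isomorphism Network step:
    ``Z'_u = MLP((1 + eps) Z_u + sum_{v in N(u)} Z_v [+ W_e e_{vu}])``."""

    def __init__(self, dim: int, edge_dim: Optional[int],
                 rng: np.random.Generator, eps_learnable: bool = True):
        self.mlp = MLP(dim, dim, dim, rng)
        if eps_learnable:
            self.eps = Parameter(np.array(0.0))
        else:
            self.eps = Tensor(np.array(0.0))
        self.edge_proj = Linear(edge_dim, dim, rng, bias=False) if edge_dim else None

    def __call__(self, Z: Tensor, A: np.ndarray,
                 edges: Optional[tuple] = None) -> Tensor:
        # neighbour aggregation uses the transpose so messages flow along
        # directed arcs v -> u into u
        agg = Tensor(np.asarray(A, dtype=float).T) @ Z
        if self.edge_proj is not None and edges is not None and edges[0].shape[0]:
            idx, feat = edges
            incoming = np.zeros((Z.shape[0], feat.shape[1]))
            np.add.at(incoming, idx[:, 1], feat)  # sum of e_{v,u} into u
            agg = agg + self.edge_proj(Tensor(incoming))
        return self.mlp(Z * (1.0 + self.eps) + agg)


def layer_readout(Z: Tensor) -> Tensor:
    """Graph summary of one layer: column-wise mean concatenated with
    column-wise max (dimension ``2 * hidden_dim``)."""
    if Z.shape[0] == 0:
        raise EmptyGraphError("readout of an empty node set")
    return ad.concatenate([Z.mean(axis=0), Z.max(axis=0)], axis=0)


class MultiLayerAttention(Module):
    """Softmax attention over the K per-layer readouts."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.w = Parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), size=dim))

    def __call__(self, readouts: List[Tensor]) -> Tensor:
        R = ad.stack(readouts, axis=0)          # (K, dim)
        weights = ad.softmax(R @ self.w, axis=0)  # (K,)
        return (R * weights.reshape(len(readouts), 1)).sum(axis=0)


class GraphEncoder(Module):
    """K-layer GIN + MVPool encoder producing one representation per graph."""

    def __init__(self, in_dim: int, config: EncoderConfig,
                 rng: np.random.Generator, edge_dim: Optional[int] = None):
        from .pooling import MVPool  # local import to avoid a cycle

        self.config = config
        h = config.hidden_dim
        self.input_proj = Linear(in_dim, h, rng)
        e_dim = edge_dim if config.use_edge_features else None
        self.gin_layers = [GINLayer(h, e_dim, rng, config.gin_eps_learnable)
                           for _ in range(config.n_layers)]
        self.pools = [MVPool(h, rng, pool_ratio=config.pool_ratio,
                             delta=config.delta, k_power=config.k_power)
                      for _ in range(config.n_layers)]
        self.attention = MultiLayerAttention(2 * h, rng)

    @property
    def out_dim(self) -> int:
        return 2 * self.config.hidden_dim

    def __call__(self, X: np.ndarray, A: np.ndarray,
                 edges: Optional[tuple] = None) -> Tensor:
        """Encode one graph given node features, adjacency and (optionally)
        COO edge features ``(idx, feat)``."""
        if X.shape[0] == 0:
            raise EmptyGraphError("cannot encode a graph with no nodes")
        Z = self.input_proj(Tensor(np.asarray(X, dtype=float))).relu()
        A_cur = np.asarray(A)
        E_cur = edges if self.config.use_edge_features else None
        readouts: List[Tensor] = []
        for gin, pool in zip(self.gin_layers, self.pools):
            Z = gin(Z, A_cur, E_cur)
            Z, A_cur, E_cur, _ = pool(Z, A_cur, E_cur)
            readouts.append(layer_readout(Z))
        return self.attention(readouts)
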