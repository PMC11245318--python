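"""Structure remapping: lift bonds to nodes and bond-atom-bond paths to edges.

Given a directed molecular graph ``G = <X, E, A>``, the remapped graph
``G^r = (X^r, E^r, A^r)`` has one node per directed arc ``u -> v`` with
feature row ``X_u || E_{u,v} || X_v``, and one directed edge per consecutive
arc pair ``(u -> v, v -> z)`` with feature ``E_{u,v} || X_v || E_{v,z}``.
This is a directed line-graph construction with concatenated features; it
moves chemical bonds to the centre of message passing.

Backtracking pairs (``z == u``) are included by default, matching the
adjacency rule ``A^r_{uv,vz} = 1 iff A_{u,v} = A_{v,z} = 1``; the
``exclude_backtrack`` flag switches to the directed-message-passing
convention that omits them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .errors import EmptyRemapError, MissingArcError
from .featurize import Arc, MolGraph

Edge = Tuple[Arc, Arc]


@dataclass
class RemappedGraph:
    Xr: np.ndarray                 # (N_arcs, 2*d_atom + d_bond)
    Er: Dict[Edge, np.ndarray]     # ((u,v),(v,z)) -> 2*d_bond + d_atom vector
    Ar: np.ndarray                 # (N_arcs, N_arcs) binary, generally asymmetric
    arc_index: Dict[Arc, int]      # arc -> row id in Xr / Ar
    origin: MolGraph

    @property
    def n_nodes(self) -> int:
        return self.Xr.shape[0]

    @property
    def arcs(self) -> List[Arc]:
        return list(self.arc_index.keys())

    def to_json(self) -> str:
        """Node table, edge table and COO adjacency for external frameworks."""
        rows, cols = np.nonzero(self.Ar)
        return json.dumps({
            "nodes": [{"arc": list(a), "features": self.Xr[i].tolist()}
                      for a, i in self.arc_index.items()],
            "edges": [{"path": [list(e[0]), list(e[1])], "features": fv.tolist()}
                      for e, fv in self.Er.items()],
            "adjacency_coo": [[int(r), int(c)] for r, c in zip(rows, cols)],
        })


def remap_feature_row(g: MolGraph, u: int, v: int) -> np.ndarray:
    """Remapped node feature ``X_u || E_{u,v} || X_v`` for arc ``u -> v``."""
    if (u, v) not in g.E:
        raise MissingArcError(f"arc {u}->{v} not in graph")
    return np.concatenate([g.X[u], g.E[(u, v)], g.X[v]])


def remap_edge_feature(g: MolGraph, u: int, v: int, z: int) -> np.ndarray:
    """Remapped edge feature ``E_{u,v} || X_v || E_{v,z}`` for the path
    ``u -> v -> z``."""
    if (u, v) not in g.E or (v, z) not in g.E:
        raise MissingArcError(f"path {u}->{v}->{z} requires both arcs")
    return np.concatenate([g.E[(u, v)], g.X[v], g.E[(v, z)]])


def remap_graph(g: MolGraph, exclude_backtrack: bool = False) -> RemappedGraph:
    """Build the structure-remapped graph of ``g``.

    Raises
    ------
    EmptyRemapError
        For bond-less molecules (no arcs to lift); callers such as the
        encoder fall back to the original-graph representation.
    """
    arcs = sorted(g.E.keys())
    if not arcs:
        raise EmptyRemapError(f"molecule {g.smiles!r} has no bonds to remap")
    arc_index = {a: i for i, a in enumerate(arcs)}
    Xr = np.stack([remap_feature_row(g, u, v) for (u, v) in arcs])
    n = len(arcs)
    Ar = np.zeros((n, n), dtype=np.int8)
    Er: Dict[Edge, np.ndarray] = {}
    out_arcs: Dict[int, List[Arc]] = {}
    for (u, v) in arcs:
        out_arcs.setdefault(u, []).append((u, v))
    for (u, v) in arcs:
        for (v2, z) in out_arcs.get(v, []):
            if exclude_backtrack and z == u:
                continue
            Ar[arc_index[(u, v)], arc_index[(v2, z)]] = 1
            Er[((u, v), (v2, z))] = remap_edge_feature(g, u, v, z)
    return RemappedGraph(Xr=Xr, Er=Er, Ar=Ar, arc_index=arc_index, origin=g)


def edge_feature_arrays(rg: RemappedGraph):
    """Remapped edges in COO form: ``(idx, feat)`` with ``idx`` an (m, 2)
    array of (source node, target node) row ids and ``feat`` the (m, d)
    feature matrix.  The encoder folds these into neighbour messages and
    subsets them alongside the adjacency as pooling coarsens the graph.
    """
    d_bond = next(iter(rg.origin.E.values())).shape[0]
    d = 2 * d_bond + rg.origin.X.shape[1]
    if not rg.Er:
        return np.zeros((0, 2), dtype=np.int64), np.zeros((0, d))
    idx = np.array([[rg.arc_index[a1], rg.arc_index[a2]]
                    for (a1, a2) in rg.Er.keys()], dtype=np.int64)
    feat = np.stack(list(rg.Er.values()))
    return idx, feat
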