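"""SMILES parsing and featurisation into a directed molecular graph.

A molecule is represented as ``G = <X, E, A>``: a per-atom feature matrix
``X``, a map from directed arcs ``u -> v`` to bond feature vectors ``E`` (each
chemical bond contributes two arcs with identical features), and a symmetric
binary adjacency ``A``.  Hydrogens are implicit: nodes are heavy atoms only,
with the hydrogen count carried as an atom feature.

Atom features: element one-hot (with an "other" slot), heavy-atom degree,
formal charge, bonded-hydrogen count, hybridisation, aromaticity flag and
atomic mass scaled by 1/100.  Bond features: bond-type one-hot over
{single, double, triple, aromatic}, conjugation flag and ring membership.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import InvalidSMILESError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

Arc = Tuple[int, int]

_HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2"]  # + "other" slot
_BOND_TYPES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


@dataclass
class FeaturizerConfig:
    """Featurisation vocabulary and caps; serialise alongside any model so
    reloaded checkpoints featurise identically."""

    element_vocab: List[str] = field(default_factory=lambda: [
        "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si"])
    max_degree: int = 6          # one-hot 0..max_degree plus overflow bucket
    max_num_h: int = 6
    charge_range: Tuple[int, int] = (-2, 2)  # one-hot with "other" slot
    keep_largest_fragment: bool = True

    @property
    def d_atom(self) -> int:
        n_elem = len(self.element_vocab) + 1
        n_deg = self.max_degree + 2
        n_charge = self.charge_range[1] - self.charge_range[0] + 2
        n_h = self.max_num_h + 2
        n_hyb = len(_HYBRIDIZATIONS) + 1
        return n_elem + n_deg + n_charge + n_h + n_hyb + 1 + 1  # +aromatic +mass

    @property
    def d_bond(self) -> int:
        return 4 + 1 + 1  # bond type one-hot + conjugated + in_ring

    def to_json(self) -> str:
        return json.dumps({
            "element_vocab": self.element_vocab,
            "max_degree": self.max_degree,
            "max_num_h": self.max_num_h,
            "charge_range": list(self.charge_range),
            "keep_largest_fragment": self.keep_largest_fragment,
        })

    @classmethod
    def from_json(cls, s: str) -> "FeaturizerConfig":
        d = json.loads(s)
        d["charge_range"] = tuple(d["charge_range"])
        return cls(**d)


@dataclass
class MolGraph:
    """Directed molecular graph G = <X, E, A>."""

    X: np.ndarray                      # (N_atoms, d_atom)
    E: Dict[Arc, np.ndarray]           # arc (u, v) -> bond feature vector
    A: np.ndarray                      # (N_atoms, N_atoms) binary, symmetric
    smiles: str

    @property
    def n_atoms(self) -> int:
        return self.X.shape[0]

    @property
    def arcs(self) -> List[Arc]:
        return list(self.E.keys())

    @property
    def n_arcs(self) -> int:
        return len(self.E)

    def bonds(self) -> List[Tuple[int, int]]:
        """Undirected bonds as sorted atom-index pairs."""
        return sorted({(min(u, v), max(u, v)) for (u, v) in self.E})

    def neighbors(self, u: int) -> List[int]:
        return [int(v) for v in np.flatnonzero(self.A[u])]


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def _capped_one_hot(value: int, cap: int) -> np.ndarray:
    """One-hot over 0..cap with a trailing overflow bucket."""
    v = np.zeros(cap + 2)
    v[min(value, cap + 1)] = 1.0
    return v


def featurize_atom(atom: Chem.Atom, config: FeaturizerConfig) -> np.ndarray:
    """Feature vector for one heavy atom; total via reserved "other" slots."""
    vocab = config.element_vocab
    sym = atom.GetSymbol()
    elem = _one_hot(vocab.index(sym) if sym in vocab else len(vocab), len(vocab) + 1)
    deg = _capped_one_hot(atom.GetDegree(), config.max_degree)
    lo, hi = config.charge_range
    q = atom.GetFormalCharge()
    n_charge = hi - lo + 2
    charge = _one_hot(q - lo if lo <= q <= hi else n_charge - 1, n_charge)
    num_h = _capped_one_hot(atom.GetTotalNumHs(), config.max_num_h)
    hyb_name = str(atom.GetHybridization())
    hyb = _one_hot(
        _HYBRIDIZATIONS.index(hyb_name) if hyb_name in _HYBRIDIZATIONS else len(_HYBRIDIZATIONS),
        len(_HYBRIDIZATIONS) + 1)
    aromatic = np.array([1.0 if atom.GetIsAromatic() else 0.0])
    mass = np.array([atom.GetMass() / 100.0])
    return np.concatenate([elem, deg, charge, num_h, hyb, aromatic, mass])


def featurize_bond(bond: Chem.Bond, config: FeaturizerConfig) -> np.ndarray:
    """Feature vector for one bond (shared by both of its directed arcs)."""
    btype = np.zeros(4)
    idx = _BOND_TYPES.get(bond.GetBondType())
    if idx is None:          # uncommon orders (dative etc.) fold into single
        idx = 0
    btype[idx] = 1.0
    conj = np.array([1.0 if bond.GetIsConjugated() else 0.0])
    ring = np.array([1.0 if bond.IsInRing() else 0.0])
    return np.concatenate([btype, conj, ring])


def _mol_from_smiles(smiles: str, config: FeaturizerConfig) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(f"unparseable SMILES: {smiles!r}")
    if config.keep_largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumAtoms())
    if mol.GetNumAtoms() == 0:
        raise InvalidSMILESError(f"no heavy atoms in SMILES: {smiles!r}")
    return mol


def parse_smiles(smiles: str, config: FeaturizerConfig | None = None) -> MolGraph:
    """Parse a SMILES string into a featurised directed graph.

    Atom ordering follows the deterministic RDKit parse order.  Multi-fragment
    inputs (salts) keep the largest fragment.  Stereochemistry is ignored.

    Raises
    ------
    InvalidSMILESError
        If the string cannot be parsed and sanitised.
    """
    config = config or FeaturizerConfig()
    mol = _mol_from_smiles(smiles, config)
    n = mol.GetNumAtoms()
    X = np.stack([featurize_atom(mol.GetAtomWithIdx(i), config) for i in range(n)])
    E: Dict[Arc, np.ndarray] = {}
    A = np.zeros((n, n), dtype=np.int8)
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        fv = featurize_bond(bond, config)
        E[(u, v)] = fv
        E[(v, u)] = fv.copy()
        A[u, v] = A[v, u] = 1
    return MolGraph(X=X, E=E, A=A, smiles=smiles)


def bond_edge_arrays(g: MolGraph):
    """Directed arcs of ``g`` in COO form ``(idx, feat)``: row ``(u, v)``
    carries the bond feature of the arc u -> v, so summing ``feat`` into the
    target index gives each atom's incident bond-feature total."""
    d_bond = next(iter(g.E.values())).shape[0] if g.E else 6
    if not g.E:
        return np.zeros((0, 2), dtype=np.int64), np.zeros((0, d_bond))
    idx = np.array(list(g.E.keys()), dtype=np.int64)
    feat = np.stack(list(g.E.values()))
    return idx, feat


def parse_smiles_batch(smiles_list, config: FeaturizerConfig | None = None):
    """Parse many SMILES; invalid entries are skipped with a logged warning.

    Returns ``(graphs, kept_indices)``.
    """
    config = config or FeaturizerConfig()
    graphs, kept = [], []
    for i, smi in enumerate(smiles_list):
        try:
            graphs.append(parse_smiles(smi, config))
            kept.append(i)
        except InvalidSMILESError as exc:
            logger.warning("skipping row %d: %s", i, exc)
    return graphs, kept
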