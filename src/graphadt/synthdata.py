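"""Synthetic molecule datasets with planted toxicophores.

Each molecule is a random small alkyl/aryl scaffold — a branched carbon
tree, optionally grown off a benzene ring — and positives additionally carry
one toxicophore fragment (nitro, trichloromethyl, cyano or ester) attached
at a random position.  The label is the presence of a toxicophore, then
flipped with probability ``label_noise``; the Bayes-optimal classifier on
such data has accuracy ``1 - label_noise``.  Scaffolds are kept small
(4-12 heavy atoms) so the full pipeline trains quickly on one CPU.

Because scaffolds contain only carbon, a negative can never accidentally
contain a nitrogen-, oxygen- or chlorine-bearing toxicophore; the planted
substructure is the sole label signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import GenerationFailureError, MalformedCSVError

# fragment SMILES -> index of its attachment atom within the fragment
DEFAULT_TOXICOPHORES = {
    "[N+](=O)[O-]": 0,   # nitro
    "C(Cl)(Cl)Cl": 0,    # trichloromethyl
    "C#N": 0,            # cyano
    "C(=O)OC": 0,        # methyl ester
}


@dataclass
class SynthConfig:
    n_molecules: int = 1000
    positive_fraction: float = 0.5
    toxicophores: List[str] = field(
        default_factory=lambda: list(DEFAULT_TOXICOPHORES))
    scaffold_size_range: Tuple[int, int] = (4, 12)
    ring_probability: float = 0.4
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0 < self.positive_fraction < 1):
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.n_molecules < 2:
            raise ValueError("n_molecules must be >= 2")
        lo, hi = self.scaffold_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid scaffold_size_range")


def _random_scaffold(rng: np.random.Generator, n_heavy: int,
                     use_ring: bool) -> Chem.RWMol:
    """Random branched carbon skeleton, optionally seeded with a benzene ring."""
    if use_ring and n_heavy >= 6:
        mol = Chem.RWMol(Chem.MolFromSmiles("c1ccccc1"))
        n_extra = n_heavy - 6
    else:
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom(6))
        n_extra = n_heavy - 1
    for _ in range(n_extra):
        candidates = [a.GetIdx() for a in mol.GetAtoms()
                      if a.GetDegree() < (3 if a.GetIsAromatic() else 4)]
        parent = int(rng.choice(candidates))
        new_idx = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(parent, new_idx, Chem.BondType.SINGLE)
    return mol


def _attach_fragment(mol: Chem.RWMol, frag_smiles: str,
                     rng: np.random.Generator) -> Chem.RWMol:
    frag = Chem.MolFromSmiles(frag_smiles)
    attach_local = DEFAULT_TOXICOPHORES.get(frag_smiles, 0)
    # attachment site: any aliphatic C with a free valence, else aromatic C
    sites = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetSymbol() == "C" and not a.GetIsAromatic()
             and a.GetDegree() < 4]
    if not sites:
        sites = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetIsAromatic() and a.GetDegree() < 3]
    site = int(rng.choice(sites))
    offset = mol.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(site, offset + attach_local, Chem.BondType.SINGLE)
    return combined


def _toxicophore_queries(toxicophores: List[str]):
    # the fragment SMILES double as SMARTS queries
    return [Chem.MolFromSmarts(s) for s in toxicophores]


def contains_toxicophore(smiles: str, toxicophores: List[str]) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    for q in _toxicophore_queries(toxicophores):
        if mol.HasSubstructMatch(q):
            return True
    return False


def _make_molecule(rng: np.random.Generator, config: SynthConfig,
                   positive: bool, max_retries: int = 20) -> str:
    lo, hi = config.scaffold_size_range
    for _ in range(max_retries):
        n_heavy = int(rng.integers(lo, hi + 1))
        use_ring = bool(rng.random() < config.ring_probability)
        mol = _random_scaffold(rng, n_heavy, use_ring)
        if positive:
            frag = config.toxicophores[int(rng.integers(len(config.toxicophores)))]
            mol = _attach_fragment(mol, frag, rng)
        try:
            out = mol.GetMol()
            Chem.SanitizeMol(out)
            smi = Chem.MolToSmiles(out)
        except Exception:
            continue
        if Chem.MolFromSmiles(smi) is None:
            continue
        if contains_toxicophore(smi, config.toxicophores) == positive:
            return smi
    raise GenerationFailureError(
        f"could not assemble a {'positive' if positive else 'negative'} "
        f"molecule after {max_retries} retries")


def generate_dataset(config: SynthConfig) -> pd.DataFrame:
    """Generate a labelled dataset; deterministic per ``config.seed``.

    Returns a DataFrame with columns ``smiles`` and ``label``; the label is
    toxicophore presence flipped with probability ``label_noise``.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.n_molecules * config.positive_fraction))
    truths = np.zeros(config.n_molecules, dtype=int)
    truths[:n_pos] = 1
    rng.shuffle(truths)
    rows = []
    for truth in truths:
        smi = _make_molecule(rng, config, positive=bool(truth))
        label = int(truth)
        if rng.random() < config.label_noise:
            label = 1 - label
        rows.append((smi, label))
    return pd.DataFrame(rows, columns=["smiles", "label"])


def write_csv(dataset: pd.DataFrame, path: str) -> None:
    dataset.to_csv(path, index=False)


def read_csv(path: str) -> pd.DataFrame:
    """Load a ``smiles,label`` CSV, validating shape and label domain."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise MalformedCSVError(f"cannot read {path}: {exc}") from exc
    missing = {"smiles", "label"} - set(df.columns)
    if missing:
        raise MalformedCSVError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise MalformedCSVError("dataset is empty")
    labels = set(df["label"].unique().tolist())
    if not labels <= {0, 1}:
        raise MalformedCSVError(f"labels must be binary 0/1, got {sorted(labels)}")
    return df[["smiles", "label"]]
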