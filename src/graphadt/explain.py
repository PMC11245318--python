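"""Bond-level attribution with Monte-Carlo Shapley values.

In the structure-remapped graph, nodes are bonds, so per-bond attributions
are Shapley values of a cooperative game whose players are the molecule's
undirected bonds and whose value function ``f`` is the model's positive-class
(toxicity) probability with the bonds outside the coalition masked: the
remapped-node feature rows of a masked bond's two directed arcs are zeroed
and their incident remapped edges removed.  The original-graph stream is
left intact, so attributions isolate what the bond graph contributes.

Molecules with at most six bonds are solved exactly by coalition
enumeration; larger ones use Monte-Carlo permutation sampling with a value
cache.  Bonds whose value reaches a threshold (default 0.2) are flagged and
matched against named functional-group SMARTS patterns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
from rdkit import Chem

from . import autodiff as ad
from .autodiff import no_grad
from .errors import (InvalidPatternError, NoBondsError, UntrainedModelError)
from .featurize import MolGraph
from .model import GraphADTClassifier, GraphPack, build_pack

Bond = Tuple[int, int]


@dataclass
class ShapleyReport:
    smiles: str
    values: Dict[Bond, float]
    stderr: Dict[Bond, float]          # zeros when computed exactly
    n_samples: int                     # 0 for exact enumeration
    seed: Optional[int]
    f_full: float
    f_empty: float
    threshold: float = 0.2
    flagged: List[Bond] = field(default_factory=list)
    group_tags: Dict[Bond, List[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "smiles": self.smiles,
            "bonds": [{"atoms": list(b), "shapley": v,
                       "stderr": self.stderr[b],
                       "flagged": b in set(self.flagged),
                       "groups": self.group_tags.get(b, [])}
                      for b, v in self.values.items()],
            "n_samples": self.n_samples,
            "seed": self.seed,
            "threshold": self.threshold,
            "f_full": self.f_full,
            "f_empty": self.f_empty,
        }, indent=2)


def load_default_group_patterns() -> Dict[str, str]:
    """Named functional-group SMARTS shipped with the package."""
    with resources.files("graphadt.data").joinpath(
            "functional_groups.json").open(encoding="utf-8") as fh:
        return json.load(fh)


class _BondGame:
    """Value function f(coalition) with per-coalition caching."""

    def __init__(self, model: GraphADTClassifier, pack: GraphPack):
        self.model = model
        self.pack = pack
        graph = pack.graph
        self.bonds: List[Bond] = graph.bonds()
        rg = pack.remapped
        self.arc_rows = {b: [rg.arc_index[(b[0], b[1])], rg.arc_index[(b[1], b[0])]]
                         for b in self.bonds}
        with no_grad():
            self._h_o = model.net_.enc_orig(pack.X, pack.A, pack.edges)
        self._cache: Dict[FrozenSet[int], float] = {}

    def value(self, coalition: FrozenSet[int]) -> float:
        """Positive-class probability with bonds outside ``coalition`` masked."""
        key = frozenset(coalition)
        if key in self._cache:
            return self._cache[key]
        pack = self.pack
        n_nodes = pack.Xr.shape[0]
        keep = np.zeros(n_nodes, dtype=bool)
        for bi in key:
            keep[self.arc_rows[self.bonds[bi]]] = True
        Xr_m = pack.Xr * keep[:, None]
        Ar_m = pack.Ar * (keep[:, None] & keep[None, :])
        idx, feat = pack.edges_r
        if idx.shape[0]:
            sel = keep[idx[:, 0]] & keep[idx[:, 1]]
            edges_m = (idx[sel], feat[sel])
        else:
            edges_m = (idx, feat)
        with no_grad():
            h_r = self.model.net_.enc_remap(Xr_m, Ar_m, edges_m)
            h = ad.concatenate([self._h_o, h_r], axis=0)
            logit = self.model.net_.head(h.reshape(1, h.shape[0])).data[0, 0]
        prob = float(1.0 / (1.0 + np.exp(-logit)))
        self._cache[key] = prob
        return prob


def _exact_shapley(game: _BondGame) -> Tuple[np.ndarray, np.ndarray]:
    m = len(game.bonds)
    values = np.zeros(m)
    fact = math.factorial
    all_ids = range(m)
    for i in all_ids:
        others = [j for j in all_ids if j != i]
        for size in range(m):
            w = fact(size) * fact(m - size - 1) / fact(m)
            for comb in combinations(others, size):
                s = frozenset(comb)
                values[i] += w * (game.value(s | {i}) - game.value(s))
    return values, np.zeros(m)


def _mc_shapley(game: _BondGame, n_samples: int,
                rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    m = len(game.bonds)
    sums = np.zeros(m)
    sq_sums = np.zeros(m)
    for _ in range(n_samples):
        perm = rng.permutation(m)
        coalition: FrozenSet[int] = frozenset()
        prev = game.value(coalition)
        for i in perm:
            coalition = coalition | {i}
            cur = game.value(coalition)
            marginal = cur - prev
            sums[i] += marginal
            sq_sums[i] += marginal * marginal
            prev = cur
    mean = sums / n_samples
    var = np.maximum(sq_sums / n_samples - mean ** 2, 0.0)
    stderr = np.sqrt(var / n_samples)
    return mean, stderr


def bond_shapley(model: GraphADTClassifier, molecule: MolGraph,
                 n_samples: int = 500, seed: Optional[int] = None,
                 threshold: float = 0.2,
                 group_patterns: Optional[Dict[str, str]] = None,
                 exact_max_bonds: int = 6) -> ShapleyReport:
    """Shapley value of every undirected bond of ``molecule``.

    The two directed arcs of a bond are masked jointly.  Exact enumeration
    is used automatically for molecules with at most ``exact_max_bonds``
    bonds; otherwise ``n_samples`` random permutations are averaged
    (deterministic given ``seed``).
    """
    if not hasattr(model, "net_"):
        raise UntrainedModelError("bond_shapley requires a fitted model")
    pack = build_pack(molecule, model.exclude_backtrack)
    if not pack.has_remap:
        raise NoBondsError(f"molecule {molecule.smiles!r} has no bonds")
    game = _BondGame(model, pack)
    m = len(game.bonds)
    if m <= exact_max_bonds:
        vals, errs = _exact_shapley(game)
        n_used = 0
    else:
        rng = np.random.default_rng(seed)
        vals, errs = _mc_shapley(game, n_samples, rng)
        n_used = n_samples
    f_full = game.value(frozenset(range(m)))
    f_empty = game.value(frozenset())
    report = ShapleyReport(
        smiles=molecule.smiles,
        values={b: float(v) for b, v in zip(game.bonds, vals)},
        stderr={b: float(e) for b, e in zip(game.bonds, errs)},
        n_samples=n_used, seed=seed, f_full=f_full, f_empty=f_empty,
        threshold=threshold)
    report.flagged = flag_key_bonds(report, threshold)
    patterns = group_patterns or load_default_group_patterns()
    report.group_tags = {
        b: _match_bond_groups(molecule.smiles, b, patterns)
        for b in report.flagged}
    return report


def flag_key_bonds(report: ShapleyReport, threshold: float = 0.2) -> List[Bond]:
    """Bonds whose Shapley value reaches ``threshold``."""
    return [b for b, v in report.values.items() if v >= threshold]


def _compiled_patterns(patterns: Dict[str, str]):
    compiled = {}
    for name, smarts in patterns.items():
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise InvalidPatternError(f"bad SMARTS for {name!r}: {smarts!r}")
        compiled[name] = q
    return compiled


def _match_bond_groups(smiles: str, bond: Bond,
                       patterns: Dict[str, str]) -> List[str]:
    """Group names whose SMARTS match contains both endpoint atoms of ``bond``."""
    mol = Chem.MolFromSmiles(smiles)
    names = []
    for name, q in _compiled_patterns(patterns).items():
        for match in mol.GetSubstructMatches(q):
            if bond[0] in match and bond[1] in match:
                names.append(name)
                break
    return names


def group_frequency(flagged: List[Tuple[str, List[Bond]]],
                    group_patterns: Optional[Dict[str, str]] = None):
    """Frequency table of functional groups among flagged bonds.

    ``flagged`` is a list of ``(smiles, bonds)`` pairs across a molecule
    set.  Returns a DataFrame with per-group flagged-bond counts and the
    fraction over all flagged bonds.  Overlapping patterns are counted per
    group, so fractions may sum above 1.
    """
    import pandas as pd

    patterns = group_patterns or load_default_group_patterns()
    _compiled_patterns(patterns)  # validate early
    counts = {name: 0 for name in patterns}
    total = 0
    for smiles, bonds in flagged:
        for b in bonds:
            total += 1
            for name in _match_bond_groups(smiles, b, patterns):
                counts[name] += 1
    rows = [(name, c, (c / total if total else 0.0))
            for name, c in counts.items()]
    return pd.DataFrame(rows, columns=["group", "count", "fraction"])
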