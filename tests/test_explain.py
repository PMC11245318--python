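"""Shapley bond attribution: exact enumeration, MC agreement, efficiency,
symmetry, thresholding and functional-group tagging."""

import numpy as np
import pytest

from graphadt import (bond_shapley, flag_key_bonds, group_frequency,
                      load_default_group_patterns, parse_smiles)
from graphadt.errors import (InvalidPatternError, NoBondsError,
                             UntrainedModelError)
from graphadt.explain import ShapleyReport, _BondGame, _mc_shapley
from graphadt.model import GraphADTClassifier, build_pack


def test_untrained_model_rejected(feat_config):
    with pytest.raises(UntrainedModelError):
        bond_shapley(GraphADTClassifier(), parse_smiles("CCO", feat_config))


def test_no_bonds_rejected(tiny_model, feat_config):
    with pytest.raises(NoBondsError):
        bond_shapley(tiny_model, parse_smiles("C", feat_config))


def test_null_game_gives_zero_values(tiny_model, feat_config):
    """With a zeroed head the value function is constant, so every marginal
    contribution, and hence every Shapley value, is exactly zero."""
    import copy

    model = copy.deepcopy(tiny_model)
    model.net_.head.W.data[:] = 0.0
    model.net_.head.b.data[:] = 0.0
    report = bond_shapley(model, parse_smiles("CCO", feat_config), seed=0)
    assert all(abs(v) < 1e-12 for v in report.values.values())


def test_single_bond_molecule_is_one_player_game(tiny_model, feat_config):
    g = parse_smiles("CO", feat_config)
    report = bond_shapley(tiny_model, g, seed=0)
    (value,) = report.values.values()
    assert abs(value - (report.f_full - report.f_empty)) < 1e-12


def test_symmetric_bonds_get_equal_values(tiny_model, feat_config):
    # dichloromethane: the two C-Cl bonds are exchangeable by symmetry
    g = parse_smiles("ClCCl", feat_config)
    report = bond_shapley(tiny_model, g, seed=0)
    vals = list(report.values.values())
    assert report.n_samples == 0  # exact enumeration
    assert abs(vals[0] - vals[1]) < 1e-10


def test_exact_vs_monte_carlo_agreement(tiny_model, feat_config):
    g = parse_smiles("CCO", feat_config)  # 2 bonds: exact is cheap
    exact = bond_shapley(tiny_model, g, seed=0)
    game = _BondGame(tiny_model, build_pack(g))
    mc_vals, mc_err = _mc_shapley(game, 400, np.random.default_rng(0))
    for b, mc, se in zip(game.bonds, mc_vals, mc_err):
        assert abs(exact.values[b] - mc) <= 2 * se + 1e-9


def test_efficiency_property(tiny_model, feat_config):
    """Shapley values sum to f(full) - f(empty)."""
    for smi in ["CCO", "CC(Cl)(Cl)Cl", "CCC[N+](=O)[O-]", "c1ccccc1C"]:
        g = parse_smiles(smi, feat_config)
        report = bond_shapley(tiny_model, g, n_samples=100, seed=1)
        total = sum(report.values.values())
        budget = 3 * np.sqrt(sum(e ** 2 for e in report.stderr.values()))
        assert abs(total - (report.f_full - report.f_empty)) <= budget + 1e-9


def test_flag_key_bonds_threshold():
    rep = ShapleyReport(smiles="CCO", values={(0, 1): 0.25, (1, 2): 0.1},
                        stderr={(0, 1): 0.0, (1, 2): 0.0}, n_samples=0,
                        seed=None, f_full=0.5, f_empty=0.2)
    assert flag_key_bonds(rep, 0.2) == [(0, 1)]
    assert flag_key_bonds(rep, 0.5) == []
    assert len(flag_key_bonds(rep, 0.0)) == 2


def test_group_frequency_nitrobenzene():
    # nitrobenzene atoms: O=[N+]([O-])c1ccccc1 -> N-O bonds flagged
    table = group_frequency([("O=[N+]([O-])c1ccccc1", [(0, 1), (1, 2)])])
    nitro = table.set_index("group").loc["nitro"]
    assert nitro["count"] >= 1
    assert table["fraction"].max() <= 1.0


def test_group_frequency_empty_and_invalid():
    table = group_frequency([])
    assert (table["count"] == 0).all()
    with pytest.raises(InvalidPatternError):
        group_frequency([("CCO", [(0, 1)])], {"bad": "((("})


def test_default_patterns_cover_named_groups():
    patterns = load_default_group_patterns()
    for name in ("nitro", "ester", "ether", "tertiary_amine", "chlorobenzene",
                 "trichloromethyl", "phenol", "cyano", "phosphoryl",
                 "halogenated_hydrocarbon"):
        assert name in patterns


def test_report_json_lists_bonds(tiny_model, feat_config):
    import json

    report = bond_shapley(tiny_model, parse_smiles("CCO", feat_config), seed=0)
    obj = json.loads(report.to_json())
    assert len(obj["bonds"]) == 2
    assert {"atoms", "shapley", "stderr", "flagged", "groups"} <= set(obj["bonds"][0])
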