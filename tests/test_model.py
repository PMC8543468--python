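"""Model containers, GPR expansion and baseline FBA utilities."""

import numpy as np
import pytest

from margeflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    extend_model,
    fba,
    max_uptake_rate,
    parse_gpr,
)
from margeflux.model import ModelError, mass_balance_residual
from margeflux.synthetic import TOY_MANIFEST, make_toy_model

from _oracle import oracle_plain_fba


# -- container invariants ---------------------------------------------------


def test_validation_rejects_inconsistent_models():
    met = [Metabolite("m1")]
    with pytest.raises(ModelError, match="undeclared"):
        MetabolicModel(met, [Reaction("r", {"nope": 1}, 0, 1)])
    with pytest.raises(ModelError, match="lb"):
        MetabolicModel(met, [Reaction("r", {"m1": 1}, 2, 1)])
    with pytest.raises(ModelError, match="exactly one"):
        MetabolicModel(
            [Metabolite("m1"), Metabolite("m2")],
            [Reaction("r", {"m1": -1, "m2": 1}, 0, 1)],
            exchange_ids={"r"},
        )


def test_native_json_roundtrip(toy_model, tmp_path):
    from margeflux.io import read_json, write_json

    path = tmp_path / "model.json"
    write_json(toy_model, path)
    again = read_json(path)
    assert again.to_dict() == toy_model.to_dict()


def test_sbml_roundtrip(toy_model, tmp_path):
    """Exchange identity survives the round trip (SBO annotation), so the
    energy sink is not misread as an exchange."""
    from margeflux.io import read_sbml, write_sbml

    path = tmp_path / "model.xml"
    write_sbml(toy_model, path)
    again = read_sbml(path)
    assert set(again.reaction_ids) == set(toy_model.reaction_ids)
    assert again.biomass_id == toy_model.biomass_id
    assert again.exchange_ids == toy_model.exchange_ids
    for rid, rule in toy_model.gpr_rules.items():
        assert set(again.gpr_rules[rid].dnf) == set(rule.dnf)
    for rid in toy_model.reaction_ids:
        assert again.reaction(rid).stoichiometry == toy_model.reaction(rid).stoichiometry


# -- extension --------------------------------------------------------------


def test_extension_column_counts_match_manifest(toy_model, toy_ext):
    """Independent enumeration: usage columns = sum over GPR reactions of
    isozymes x allowed directions; spontaneous/exchange reactions keep one."""
    expected_usage = 0
    expected_flux = 0
    for rxn in toy_model.reactions:
        rule = toy_model.gpr_rules.get(rxn.id)
        if rule is None or rxn.id in toy_model.exchange_ids:
            expected_flux += 1
        else:
            dirs = (1 if rxn.ub > 0 else 0) + (1 if rxn.lb < 0 else 0)
            expected_usage += len(rule.dnf) * dirs
    assert expected_usage == TOY_MANIFEST["n_usage_columns"]
    assert len(toy_ext.usage_indices) == expected_usage
    assert toy_ext.n_variables == expected_usage + expected_flux
    assert len(toy_model.reactions) == TOY_MANIFEST["n_reactions"]
    assert len(toy_model.metabolites) == TOY_MANIFEST["n_metabolites"]
    assert len(toy_model.gpr_rules) == TOY_MANIFEST["n_gpr_reactions"]


def test_irreversible_isozyme_pair_gets_two_forward_columns(toy_ext):
    cols = [toy_ext.variables[i] for i in toy_ext.usage_indices]
    hex_cols = [v for v in cols if v.reaction_id == "HEX"]
    assert len(hex_cols) == 2
    assert {v.direction for v in hex_cols} == {"forward"}
    # reconstruction: flux = u1 + u2
    assert all(s == 1.0 for _, s in toy_ext.reaction_map["HEX"])


def test_reversible_isozymes_get_both_directions(toy_ext):
    ldh = [toy_ext.variables[i] for i in toy_ext.usage_indices if toy_ext.variables[i].reaction_id == "LDH"]
    assert len(ldh) == 4  # 2 isozymes x 2 directions
    signs = dict(toy_ext.reaction_map["LDH"])
    assert sorted(signs.values()) == [-1.0, -1.0, 1.0, 1.0]


def test_usage_bounds_nonnegative(toy_ext):
    for i in toy_ext.usage_indices:
        assert toy_ext.lb[i] == 0.0
        assert toy_ext.ub[i] > 0


def test_gpr_on_exchange_reaction_is_ignored_with_warning():
    model = make_toy_model()
    model.gpr_rules["EX_glc"] = parse_gpr("gBOGUS")
    with pytest.warns(UserWarning, match="EX_glc"):
        ext = extend_model(model)
    assert ext.reaction_map["EX_glc"][0][1] == 1.0
    assert all(ext.variables[j].kind == "flux" for j, _ in ext.reaction_map["EX_glc"])


def test_extension_soundness_reconstructed_fluxes_feasible(toy_model, toy_ext):
    """Any optimal extended state maps to a mass-balanced, in-bounds flux
    vector of the unextended model."""
    rng = np.random.default_rng(3)
    S = toy_model.stoichiometric_matrix()
    for _ in range(10):
        rid = str(rng.choice(toy_model.reaction_ids))
        sense = "max" if rng.random() < 0.5 else "min"
        state = fba(toy_ext, rid, sense)
        if not state.optimal:
            continue
        v = np.array([state.flux[r] for r in toy_model.reaction_ids])
        assert np.abs(S @ v).max() < 1e-6
        for r in toy_model.reactions:
            assert r.lb - 1e-6 <= state.flux[r.id] <= r.ub + 1e-6
        assert mass_balance_residual(toy_ext, state) < 1e-6
        for name, val in state.usage.items():
            assert val >= -1e-9


# -- FBA --------------------------------------------------------------------


def test_fba_biomass_optimum_matches_independent_solver(toy_ext):
    # frozen once from the GLPK oracle with glucose uptake capped at 10
    state = fba(toy_ext, "BIOMASS", "max")
    assert state.optimal
    assert state.objective == pytest.approx(10.0, abs=1e-6)


def test_fba_extended_equals_unextended_for_random_objectives(toy_model, toy_ext):
    rng = np.random.default_rng(11)
    for _ in range(8):
        k = int(rng.integers(1, 4))
        rids = list(rng.choice(toy_model.reaction_ids, size=k, replace=False))
        coeffs = {rid: float(rng.normal()) for rid in rids}
        for sense in ("max", "min"):
            main = fba(toy_ext, coeffs, sense)
            status, val = oracle_plain_fba(toy_model, coeffs, sense)
            assert main.status == status == "optimal"
            assert main.objective == pytest.approx(val, abs=1e-6)


def test_fba_zero_biomass_when_uptakes_closed():
    model = make_toy_model()
    for rid in ("EX_glc", "EX_gln", "EX_lac"):
        model.reaction(rid).lb = 0.0
    state = fba(extend_model(model), "BIOMASS", "max")
    assert state.optimal
    assert state.objective == pytest.approx(0.0, abs=1e-9)


def test_fba_minimize_irreversible_reaction_is_zero(toy_ext):
    state = fba(toy_ext, "GLCT", "min")
    assert state.optimal
    assert state.objective == pytest.approx(0.0, abs=1e-9)


# -- maximum uptake ---------------------------------------------------------


def test_max_uptake_bound_limited(toy_ext):
    assert max_uptake_rate(toy_ext, "EX_glc") == pytest.approx(10.0, abs=1e-6)


def test_max_uptake_dead_end_metabolite_is_zero():
    model = make_toy_model()
    d = model.to_dict()
    d["metabolites"].append({"id": "dead_e", "name": "", "compartment": "e"})
    d["reactions"].append({"id": "EX_dead", "stoichiometry": {"dead_e": -1}, "lb": -10.0, "ub": 0.0})
    d["exchange_ids"].append("EX_dead")
    ext = extend_model(MetabolicModel.from_dict(d))
    assert max_uptake_rate(ext, "EX_dead") == pytest.approx(0.0, abs=1e-9)


def test_max_uptake_requires_exchange(toy_ext):
    with pytest.raises(ModelError, match="exchange"):
        max_uptake_rate(toy_ext, "HEX")
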