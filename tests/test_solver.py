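"""The two-step expression-coupled program and its result objects."""

import numpy as np
import pandas as pd
import pytest

from margeflux import (
    Marge,
    MargeParams,
    RelativeExpression,
    enzyme_ratios,
    extend_model,
    marge,
    pathway_flux_summary,
)
from margeflux.exo import measurements_from_frame
from margeflux.model import MetabolicModel
from margeflux.solver import MargeError
from margeflux.synthetic import BRANCH_MAP, ToyScenario, make_toy_model, simulate_condition_pair

from conftest import random_scenario
from _oracle import oracle_marge


def expr(genes):
    return RelativeExpression({g: (lfc, 0.01) for g, lfc in genes.items()})


# -- enzyme ratios ----------------------------------------------------------


def test_single_gene_isozyme_ratio(toy_ext):
    ratios = enzyme_ratios(expr({"gGLUT1": 1.0}), toy_ext)
    assert ratios[("GLCT", 0)] == pytest.approx(2.0)


def test_complex_uses_geometric_mean(toy_ext):
    # complex {gGAPDH lfc=2, gPGK lfc=0}: r = sqrt(4 * 1) = 2
    ratios = enzyme_ratios(expr({"gGAPDH": 2.0, "gPGK": 0.0}), toy_ext)
    assert ratios[("GLYC", 0)] == pytest.approx(2.0)


def test_min_rule_option(toy_ext):
    ratios = enzyme_ratios(expr({"gGAPDH": 2.0, "gPGK": 0.0}), toy_ext, method="min")
    assert ratios[("GLYC", 0)] == pytest.approx(1.0)


def test_unmeasured_isozyme_excluded(toy_ext):
    ratios = enzyme_ratios(expr({"gHK1": 1.0}), toy_ext)
    assert ("HEX", 0) in ratios  # gHK1 isozyme
    assert ("HEX", 1) not in ratios  # gHK2 unmeasured
    assert ("GLCT", 0) not in ratios


def test_forward_backward_share_one_ratio(toy_ext):
    ratios = enzyme_ratios(expr({"gLDHA": 1.0}), toy_ext)
    group = toy_ext.usage_groups[("LDH", 0)]
    assert len(group) == 2  # one ratio covers both direction columns
    assert ratios[("LDH", 0)] == pytest.approx(2.0)


def test_qvalue_filter_in_from_frame():
    df = pd.DataFrame(
        {"gene_id": ["g1", "g2"], "log2fc": [1.0, 2.0], "qvalue": [0.05, 0.5]}
    )
    rel = RelativeExpression.from_frame(df, q_threshold=0.1)
    assert set(rel.genes) == {"g1"}


# -- the two-step program ---------------------------------------------------


def null_params():
    return MargeParams(growth_frac_a=None, growth_frac_b=None)


def test_symmetric_program_has_zero_obj1_and_equal_usages(toy_ext):
    """All ratios 1 and identical constraints: perfect agreement is
    attainable (obj1 = 0) and the returned usages coincide."""
    ratios = {key: 1.0 for key in toy_ext.usage_groups}
    sol = marge(toy_ext, ratios, None, null_params())
    assert sol.optimal
    assert sol.obj1 == pytest.approx(0.0, abs=1e-9)
    for name in sol.state_a.usage:
        assert sol.state_a.usage[name] == pytest.approx(sol.state_b.usage[name], abs=1e-6)


def test_agreement_within_relaxation_of_obj1(toy_ext):
    data = simulate_condition_pair(ToyScenario(seed=2))
    cset_meas = measurements_from_frame(data.exomet)
    from margeflux import build_constraints

    cset = build_constraints(cset_meas, toy_ext)
    model = Marge(toy_ext, data.expression, cset, null_params())
    res = model.fit()
    assert res.status == "optimal"
    assert res.agreement <= res.obj1 * 1.1 + 1e-6


def test_upregulated_branch_flux_ratio_moves_toward_two(toy_ext):
    """Doubling the sole fermentative enzyme's expression with equal fixed
    substrate uptake doubles that branch's usage, oracle-checked."""
    model = make_toy_model()
    ratios = {("LDH", 0): 2.0, ("LDH", 1): 2.0}
    from margeflux.exo import ExchangeConstraint, ExchangeConstraintSet, SECRETION, UPTAKE

    cset = ExchangeConstraintSet()
    cset.constraints["EX_glc"] = ExchangeConstraint(
        "EX_glc", "glc", UPTAKE, UPTAKE, 5.0, 5.0
    )
    cset.constraints["EX_lac"] = ExchangeConstraint(
        "EX_lac", "lac", SECRETION, SECRETION, 0.1, 0.1
    )
    sol = marge(toy_ext, ratios, cset, null_params())
    assert sol.optimal
    status, o1, o2 = oracle_marge(model, ratios, cset, null_params())
    assert status == "optimal"
    assert sol.obj1 == pytest.approx(o1, abs=1e-7)
    assert sol.obj2 == pytest.approx(o2, rel=1e-5)
    ldh_a = sol.state_a.flux["LDH"]
    ldh_b = sol.state_b.flux["LDH"]
    assert ldh_b / ldh_a == pytest.approx(2.0, rel=1e-4)


def test_oracle_equivalence_on_randomized_instances():
    for seed in range(5):
        model, ext, ratios, cset, params = random_scenario(seed)
        sol = marge(ext, ratios, cset, params)
        status, o1, o2 = oracle_marge(model, ratios, cset, params)
        assert sol.status == status == "optimal"
        assert sol.obj1 == pytest.approx(o1, rel=1e-5, abs=1e-7)
        assert sol.obj2 == pytest.approx(o2, rel=1e-5, abs=1e-7)


def test_scale_consistency(toy_model):
    """Scaling all bounds, floors and budget by k scales fluxes and
    objectives by k."""
    from margeflux.exo import ExchangeConstraint, ExchangeConstraintSet, SECRETION, UPTAKE

    k = 3.0
    ratios = {("LDH", 0): 2.0, ("LDH", 1): 2.0, ("OXPHOS", 0): 0.5}

    def build(scale):
        d = make_toy_model().to_dict()
        for r in d["reactions"]:
            r["lb"] *= scale
            r["ub"] *= scale
        ext = extend_model(MetabolicModel.from_dict(d), inf_bound=1000.0 * scale)
        cset = ExchangeConstraintSet()
        cset.constraints["EX_glc"] = ExchangeConstraint(
            "EX_glc", "glc", UPTAKE, UPTAKE, 0.1 * scale, 0.1 * scale
        )
        cset.constraints["EX_lac"] = ExchangeConstraint(
            "EX_lac", "lac", SECRETION, SECRETION, 0.1 * scale, 0.1 * scale,
            ratio_interval=(1.0, 3.0),
        )
        params = MargeParams(
            u_min=0.001 * scale, growth_frac_a=None, growth_frac_b=None
        )
        return marge(ext, ratios, cset, params)

    base = build(1.0)
    scaled = build(k)
    assert base.optimal and scaled.optimal
    assert scaled.obj1 == pytest.approx(k * base.obj1, rel=1e-5, abs=1e-8)
    assert scaled.obj2 == pytest.approx(k * base.obj2, rel=1e-5, abs=1e-8)
    for rid in ("LDH", "OXPHOS", "EX_lac"):
        assert scaled.state_a.flux[rid] == pytest.approx(
            k * base.state_a.flux[rid], rel=1e-4, abs=1e-6
        )


def test_obj1_nondecreasing_in_enzyme_set(toy_ext):
    """Adding an enzyme to the Step-1 objective cannot lower the optimum:
    the objective is a sum of nonnegative terms over a fixed feasible set."""
    rng = np.random.default_rng(7)
    keys = sorted(toy_ext.usage_groups)
    full = {key: float(2.0 ** rng.normal(0, 1)) for key in keys}
    prev = None
    subset = {}
    params = MargeParams(growth_frac_a=0.5, growth_frac_b=0.5)
    for key in keys:
        subset[key] = full[key]
        sol = marge(toy_ext, dict(subset), None, params)
        assert sol.optimal
        if prev is not None:
            assert sol.obj1 >= prev - 1e-7
        prev = sol.obj1


def test_infeasible_exchange_constraints_are_diagnosed(toy_ext):
    from margeflux.exo import ExchangeConstraint, ExchangeConstraintSet, SECRETION

    cset = ExchangeConstraintSet()
    # glucose can only be taken up (ub = 0): a secretion floor is impossible
    cset.constraints["EX_glc"] = ExchangeConstraint(
        "EX_glc", "glc", SECRETION, SECRETION, 1.0, 1.0
    )
    sol = marge(toy_ext, {("GLCT", 0): 2.0}, cset, null_params())
    assert sol.status == "infeasible"
    assert any("exchange constraints" in line for line in sol.log)


def test_activation_floors_dropped_when_infeasible():
    """A ratio on an enzyme whose reaction bound sits below u_min makes the
    activation floor unsatisfiable; the solver retries without floors and
    reports it."""
    d = make_toy_model().to_dict()
    for r in d["reactions"]:
        if r["id"] == "GLS":
            r["ub"] = 0.0005  # below the default u_min of 0.001
    ext = extend_model(MetabolicModel.from_dict(d))
    sol = marge(ext, {("GLS", 0): 2.0}, None, MargeParams(growth_frac_a=None, growth_frac_b=None))
    assert sol.optimal
    assert sol.activation_dropped
    assert any("activation" in line for line in sol.log)


def test_rejects_nonpositive_ratios(toy_ext):
    with pytest.raises(MargeError, match="ratios"):
        marge(toy_ext, {("LDH", 0): -1.0}, None, null_params())


# -- pathway summaries ------------------------------------------------------


def fitted_toy(seed=2):
    ext = extend_model(make_toy_model())
    data = simulate_condition_pair(ToyScenario(seed=seed))
    from margeflux import build_constraints

    cset = build_constraints(measurements_from_frame(data.exomet), ext)
    return Marge(ext, data.expression, cset, null_params()).fit()


def test_single_pathway_share_is_one():
    res = fitted_toy()
    df = res.pathway_shares({"LDH": "only", "OXPHOS": "only"})
    assert df.loc["only", "share_a"] == pytest.approx(1.0)
    assert df.loc["only", "share_b"] == pytest.approx(1.0)
    assert df.loc["only", "share_diff"] == pytest.approx(0.0)


def test_shares_sum_to_one_and_empty_map_errors():
    res = fitted_toy()
    df = res.pathway_shares(BRANCH_MAP)
    assert df["share_a"].sum() == pytest.approx(1.0)
    assert df["share_b"].sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="empty"):
        res.pathway_shares({})


def test_fermentative_upregulation_increases_branch_share():
    res = fitted_toy(seed=4)
    df = res.pathway_shares(BRANCH_MAP)
    assert df.loc["fermentative", "share_diff"] > 0


# -- results object ---------------------------------------------------------


def test_results_tables_and_summary():
    res = fitted_toy()
    assert set(res.fluxes.columns) == {"flux_a", "flux_b", "delta"}
    assert len(res.fluxes) == 13
    assert (res.usages[["usage_a", "usage_b"]] >= -1e-9).all().all()
    text = res.summary()
    assert "obj1" in text and "EX_glc" in text


def test_results_json_roundtrip(tmp_path):
    import json

    res = fitted_toy()
    path = tmp_path / "solution.json"
    res.to_json(path)
    loaded = json.loads(path.read_text())
    assert loaded["status"] == "optimal"
    assert loaded["obj1"] == pytest.approx(res.obj1)
    assert set(loaded["flux_a"]) == set(res.fluxes.index)
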