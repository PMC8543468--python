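"""Model serialization: SBML Level 3 + fbc (via cobra/libsbml) and a
native JSON format mirroring :class:`~margeflux.model.MetabolicModel`
for small fixtures."""

from __future__ import annotations

import json
import math

from .gpr import parse_gpr
from .model import DEFAULT_INF_BOUND, MetabolicModel, Metabolite, Reaction


def read_model(path) -> MetabolicModel:
    """Dispatch on extension: .xml/.sbml -> SBML, .json -> native."""
    p = str(path)
    if p.endswith((".xml", ".sbml")):
        return read_sbml(p)
    if p.endswith(".json"):
        return read_json(p)
    raise ValueError(f"unrecognized model format: {p}")


# -- native JSON ------------------------------------------------------------


def read_json(path) -> MetabolicModel:
    with open(path) as fh:
        return MetabolicModel.from_dict(json.load(fh))


def write_json(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


# -- SBML through cobra -----------------------------------------------------


def read_sbml(path) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    mets = [Metabolite(m.id, m.name or "", m.compartment or "") for m in cm.metabolites]
    rxns = []
    gprs = {}
    exchange_ids = set()
    for r in cm.reactions:
        lb = r.lower_bound if math.isfinite(r.lower_bound) else -DEFAULT_INF_BOUND
        ub = r.upper_bound if math.isfinite(r.upper_bound) else DEFAULT_INF_BOUND
        rxns.append(
            Reaction(r.id, {m.id: c for m, c in r.metabolites.items()}, lb, ub, r.name or "")
        )
        rule = r.gene_reaction_rule
        if rule and rule.strip():
            gprs[r.id] = parse_gpr(rule)
        if r.boundary and len(r.metabolites) == 1:
            exchange_ids.add(r.id)
    # prefer explicit SBO exchange annotations when present
    sbo_exchanges = {
        r.id
        for r in cm.reactions
        if "SBO:0000627" in str(r.annotation.get("sbo", ""))
    }
    if sbo_exchanges:
        exchange_ids = sbo_exchanges
    biomass_id = None
    for r in cm.reactions:
        if r.objective_coefficient:
            biomass_id = r.id
            break
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        gpr_rules=gprs,
        exchange_ids=exchange_ids,
        biomass_id=biomass_id,
    )


def write_sbml(model: MetabolicModel, path) -> None:
    import cobra

    cm = cobra.Model("margeflux_model")
    compartments = {m.compartment or "c" for m in model.metabolites}
    cm.compartments = {c: c for c in compartments}
    cmets = {}
    for m in model.metabolites:
        cm_met = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        cmets[m.id] = cm_met
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lb, upper_bound=r.ub)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoichiometry.items()})
        rule = model.gpr_rules.get(r.id)
        if rule is not None:
            cr.gene_reaction_rule = rule.to_string()
        if r.id in model.exchange_ids:
            cr.annotation["sbo"] = "SBO:0000627"
    if model.biomass_id:
        cm.objective = model.biomass_id
    cobra.io.write_sbml_model(cm, str(path))
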