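"""Metabolic-model containers, GPR-expanded stoichiometry and baseline FBA.

The central construction is the *extended* stoichiometric system: every
reaction carrying a GPR rule is replaced by one nonnegative enzyme-usage
column per (isozyme, direction), whose stoichiometry equals the
reaction's (negated for the backward direction).  The reaction flux is
recovered as the signed sum of its usage columns, so any feasible point
of the extended system maps onto a feasible flux vector of the plain
model.  Exchange and spontaneous (GPR-free) reactions keep a single
ordinary flux column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .gpr import GPRRule, parse_gpr
from .lp import INFEASIBLE, OPTIMAL, UNBOUNDED, LinearProgram

logger = logging.getLogger(__name__)

#: Stand-in magnitude for unbounded fluxes; finite so LPs stay bounded.
DEFAULT_INF_BOUND = 1000.0

#: Absolute tolerance for mass-balance and bound checks.
MASS_BALANCE_TOL = 1e-6


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float
    ub: float
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lb < 0


@dataclass
class MetabolicModel:
    """A constraint-based model: S, bounds, GPR rules and boundary flags.

    Exchange reactions cross the system boundary and touch exactly one
    metabolite; by convention their negative flux is uptake and positive
    flux is secretion.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    gpr_rules: dict[str, GPRRule] = field(default_factory=dict)
    exchange_ids: set[str] = field(default_factory=set)
    biomass_id: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except AttributeError:
            self._rxn_index = {r.id: r for r in self.reactions}
            return self._rxn_index[rxn_id]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_ids
            if missing:
                raise ModelError(f"reaction {r.id}: undeclared metabolites {sorted(missing)}")
            if r.lb > r.ub:
                raise ModelError(f"reaction {r.id}: lb {r.lb} > ub {r.ub}")
        for ex in self.exchange_ids:
            if ex not in set(rxn_ids):
                raise ModelError(f"exchange id {ex!r} is not a reaction")
            nz = [c for c in self.reaction(ex).stoichiometry.values() if c != 0]
            if len(nz) != 1:
                raise ModelError(f"exchange {ex!r} must touch exactly one metabolite")
        for rid in self.gpr_rules:
            if rid not in set(rxn_ids):
                raise ModelError(f"GPR rule for unknown reaction {rid!r}")
        if self.biomass_id is not None and self.biomass_id not in set(rxn_ids):
            raise ModelError(f"biomass id {self.biomass_id!r} is not a reaction")

    # -- matrix view -------------------------------------------------------
    def stoichiometric_matrix(self) -> sp.csr_matrix:
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                if coef != 0:
                    rows.append(met_pos[met])
                    cols.append(j)
                    vals.append(coef)
        return sp.csr_matrix((vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions)))

    # -- native JSON format ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment} for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": dict(r.stoichiometry),
                    "lb": r.lb,
                    "ub": r.ub,
                }
                for r in self.reactions
            ],
            "gpr_rules": {rid: rule.to_string() for rid, rule in self.gpr_rules.items()},
            "exchange_ids": sorted(self.exchange_ids),
            "biomass_id": self.biomass_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        return cls(
            metabolites=[
                Metabolite(m["id"], m.get("name", ""), m.get("compartment", "")) for m in d["metabolites"]
            ],
            reactions=[
                Reaction(r["id"], dict(r["stoichiometry"]), float(r["lb"]), float(r["ub"]), r.get("name", ""))
                for r in d["reactions"]
            ],
            gpr_rules={rid: parse_gpr(s) for rid, s in d.get("gpr_rules", {}).items() if s},
            exchange_ids=set(d.get("exchange_ids", [])),
            biomass_id=d.get("biomass_id"),
        )


# ---------------------------------------------------------------------------
# GPR-expanded system
# ---------------------------------------------------------------------------

FORWARD = "forward"
BACKWARD = "backward"


@dataclass(frozen=True)
class Variable:
    """One column of the extended system."""

    name: str
    kind: str  # "flux" | "usage"
    reaction_id: str
    isozyme: int | None = None  # index into the rule's DNF, usage columns only
    direction: str | None = None  # forward | backward, usage columns only


@dataclass
class ExtendedModel:
    """GPR-expanded stoichiometric system.

    Attributes
    ----------
    variables : list of Variable
        Flux columns (one per GPR-free reaction) and enzyme-usage columns
        (one per isozyme and allowed direction of each GPR reaction),
        ordered by (reaction, isozyme, direction) for reproducibility.
    S_ext : csr_matrix
        Metabolites x variables; usage columns repeat the reaction's
        stoichiometry (negated for backward usage).
    reaction_map : dict
        reaction id -> list of (variable index, sign) reconstructing the
        reaction flux as a signed sum.
    usage_groups : dict
        (reaction id, isozyme index) -> variable indices of that enzyme's
        directions; the unit the expression ratios and the activation
        threshold apply to.
    """

    base: MetabolicModel
    variables: list[Variable]
    lb: np.ndarray
    ub: np.ndarray
    S_ext: sp.csr_matrix
    reaction_map: dict[str, list[tuple[int, float]]]
    usage_groups: dict[tuple[str, int], list[int]]
    inf_bound: float = DEFAULT_INF_BOUND

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def usage_indices(self) -> list[int]:
        return [i for i, v in enumerate(self.variables) if v.kind == "usage"]

    def reconstruct_fluxes(self, x: np.ndarray) -> dict[str, float]:
        return {rid: sum(sign * x[i] for i, sign in cols) for rid, cols in self.reaction_map.items()}


def _clip_bounds(lb: float, ub: float, inf_bound: float) -> tuple[float, float]:
    lo = max(lb, -inf_bound) if np.isfinite(-inf_bound) else lb
    hi = min(ub, inf_bound)
    lo = -inf_bound if not np.isfinite(lb) else max(lb, -inf_bound)
    hi = inf_bound if not np.isfinite(ub) else min(ub, inf_bound)
    return lo, hi


def extend_model(model: MetabolicModel, inf_bound: float = DEFAULT_INF_BOUND) -> ExtendedModel:
    """Expand GPR reactions into per-isozyme, per-direction usage columns.

    Usage columns are nonnegative with upper bound equal to the magnitude
    of the corresponding reaction bound; the original reaction bounds are
    additionally enforced on the signed sum of a reaction's usage columns
    so the expansion never enlarges the feasible flux set.  GPR rules on
    exchange reactions are ignored with a warning (transport across the
    system boundary is treated as non-enzymatic).
    """
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    variables: list[Variable] = []
    lbs: list[float] = []
    ubs: list[float] = []
    rows, cols, vals = [], [], []
    reaction_map: dict[str, list[tuple[int, float]]] = {}
    usage_groups: dict[tuple[str, int], list[int]] = {}

    def add_column(var: Variable, lo: float, hi: float, stoich: dict[str, float], sign: float) -> int:
        j = len(variables)
        variables.append(var)
        lbs.append(lo)
        ubs.append(hi)
        for met, coef in stoich.items():
            if coef != 0:
                rows.append(met_pos[met])
                cols.append(j)
                vals.append(sign * coef)
        return j

    for rxn in model.reactions:
        lo, hi = _clip_bounds(rxn.lb, rxn.ub, inf_bound)
        rule = model.gpr_rules.get(rxn.id)
        if rule is not None and rxn.id in model.exchange_ids:
            warnings.warn(
                f"GPR rule on exchange reaction {rxn.id!r} ignored; treated as non-enzymatic",
                stacklevel=2,
            )
            rule = None
        if rule is None:
            j = add_column(Variable(f"v[{rxn.id}]", "flux", rxn.id), lo, hi, rxn.stoichiometry, 1.0)
            reaction_map[rxn.id] = [(j, 1.0)]
            continue

        entries: list[tuple[int, float]] = []
        for iso_idx in range(len(rule.dnf)):
            group: list[int] = []
            if hi > 0:
                j = add_column(
                    Variable(f"u[{rxn.id}|{iso_idx}|fwd]", "usage", rxn.id, iso_idx, FORWARD),
                    0.0,
                    hi,
                    rxn.stoichiometry,
                    1.0,
                )
                entries.append((j, 1.0))
                group.append(j)
            if lo < 0:
                j = add_column(
                    Variable(f"u[{rxn.id}|{iso_idx}|bwd]", "usage", rxn.id, iso_idx, BACKWARD),
                    0.0,
                    -lo,
                    rxn.stoichiometry,
                    -1.0,
                )
                entries.append((j, -1.0))
                group.append(j)
            if group:
                usage_groups[(rxn.id, iso_idx)] = group
        if not entries:
            # fully blocked reaction (lb = ub = 0): keep a pinned flux column
            j = add_column(Variable(f"v[{rxn.id}]", "flux", rxn.id), 0.0, 0.0, rxn.stoichiometry, 1.0)
            entries = [(j, 1.0)]
        reaction_map[rxn.id] = entries

    S_ext = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(variables))
    )
    return ExtendedModel(
        base=model,
        variables=variables,
        lb=np.asarray(lbs),
        ub=np.asarray(ubs),
        S_ext=S_ext,
        reaction_map=reaction_map,
        usage_groups=usage_groups,
        inf_bound=inf_bound,
    )


# ---------------------------------------------------------------------------
# FBA on the extended system
# ---------------------------------------------------------------------------


@dataclass
class FluxState:
    """Solution of one LP over the extended system."""

    flux: dict[str, float]
    usage: dict[str, float]
    objective: float | None
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


def add_system(lp: LinearProgram, ext: ExtendedModel, prefix: str = "") -> int:
    """Append one copy of the extended system (variables, mass balance,
    reaction-bound rows) to `lp`; returns the column offset of the copy."""
    offset = lp.n_variables
    for var, lo, hi in zip(ext.variables, ext.lb, ext.ub):
        lp.add_variable(prefix + var.name, lo, hi)
    S = ext.S_ext.tocsr()
    for i in range(S.shape[0]):
        row = S.getrow(i)
        if row.nnz:
            lp.add_constraint(
                dict(zip((offset + int(j) for j in row.indices), row.data)), "==", 0.0
            )
    # original reaction bounds on the signed sum of multi-column reactions
    for rid, entries in ext.reaction_map.items():
        if len(entries) > 1:
            rxn = ext.base.reaction(rid)
            lo, hi = _clip_bounds(rxn.lb, rxn.ub, ext.inf_bound)
            lp.add_range_constraint({offset + j: s for j, s in entries}, lo, hi)
    return offset


def build_lp(ext: ExtendedModel) -> LinearProgram:
    """Mass balance + bounds of the extended system as a fresh LP."""
    lp = LinearProgram()
    add_system(lp, ext)
    return lp


def _flux_state(ext: ExtendedModel, res) -> FluxState:
    if not res.optimal:
        return FluxState({}, {}, None, res.status)
    x = res.x
    flux = ext.reconstruct_fluxes(x)
    usage = {ext.variables[i].name: float(x[i]) for i in ext.usage_indices}
    return FluxState(flux, usage, res.objective, res.status)


def fba(
    ext: ExtendedModel,
    objective: str | dict[str, float],
    sense: str = "max",
    extra_constraints: list[tuple[dict[str, float], str, float]] | None = None,
) -> FluxState:
    """Flux balance analysis: optimize a reaction flux (or a linear
    combination of reaction fluxes, given as a coefficient map).

    `extra_constraints` entries are (reaction-coefficient map, sense, rhs)
    over reaction fluxes; they are expanded onto the usage columns.
    """
    obj_coeffs = objective if isinstance(objective, dict) else {objective: 1.0}
    unknown = set(obj_coeffs) - set(ext.reaction_map)
    if unknown:
        raise ModelError(f"objective references unknown reactions {sorted(unknown)}")
    lp = build_lp(ext)
    if extra_constraints:
        for coeffs, con_sense, rhs in extra_constraints:
            expanded: dict[int, float] = {}
            for rid, c in coeffs.items():
                for j, s in ext.reaction_map[rid]:
                    expanded[j] = expanded.get(j, 0.0) + c * s
            lp.add_constraint(expanded, con_sense, rhs)
    obj: dict[int, float] = {}
    for rid, c in obj_coeffs.items():
        for j, s in ext.reaction_map[rid]:
            obj[j] = obj.get(j, 0.0) + c * s
    res = lp.solve(obj, sense=sense)
    return _flux_state(ext, res)


def max_uptake_rate(ext: ExtendedModel, exchange_id: str) -> float:
    """Largest feasible uptake magnitude of an exchange reaction (FVA-style).

    Uptake is negative exchange flux, so this minimizes the exchange flux
    and returns max(0, -minimum).
    """
    if exchange_id not in ext.base.exchange_ids:
        raise ModelError(f"{exchange_id!r} is not an exchange reaction")
    state = fba(ext, exchange_id, sense="min")
    if state.status == INFEASIBLE:
        raise ModelError(f"model infeasible while computing max uptake of {exchange_id!r}")
    if state.status == UNBOUNDED:  # pragma: no cover - finite default bounds prevent this
        raise ModelError(f"uptake of {exchange_id!r} is unbounded")
    return max(0.0, -state.flux[exchange_id])


def mass_balance_residual(ext: ExtendedModel, state: FluxState) -> float:
    """Max |S v| of the reconstructed flux vector in the unextended model."""
    S = ext.base.stoichiometric_matrix()
    v = np.array([state.flux[rid] for rid in ext.base.reaction_ids])
    return float(np.abs(S @ v).max(initial=0.0))
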