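"""Independent LP oracle used to cross-check the main implementation.

Deliberately coded from scratch against a different backend (GLPK via
optlang instead of scipy/HiGHS) with a different encoding: reaction
fluxes are explicit bounded variables tied to usage sums by equality
rows, and absolute values are split into nonnegative positive/negative
parts (x = p - m, |x| = p + m under minimization) rather than a single
deviation variable with two inequality rows.
"""

from __future__ import annotations

import itertools

from optlang.glpk_interface import Constraint, Model, Objective, Variable

from margeflux.exo import SECRETION, UPTAKE
from margeflux.model import MetabolicModel
from margeflux.solver import MargeParams


def _clip(lo, hi, big=1000.0):
    lo = max(lo, -big)
    hi = min(hi, big)
    return lo, hi


class _System:
    """One condition's variables: explicit v per reaction, u per (iso, dir)."""

    def __init__(self, model: MetabolicModel, tag: str):
        self.v = {}
        self.u = {}  # (rxn, iso) -> list of (var, sign)
        self.vars = []
        self.cons = []
        for rxn in model.reactions:
            lo, hi = _clip(rxn.lb, rxn.ub)
            v = Variable(f"{tag}_v_{rxn.id}", lb=lo, ub=hi)
            self.v[rxn.id] = v
            self.vars.append(v)
            rule = model.gpr_rules.get(rxn.id)
            if rule is None or rxn.id in model.exchange_ids:
                continue
            terms = []
            for k, iso in enumerate(rule.dnf):
                pair = []
                if hi > 0:
                    uf = Variable(f"{tag}_u_{rxn.id}_{k}_f", lb=0, ub=hi)
                    self.vars.append(uf)
                    pair.append((uf, 1.0))
                if lo < 0:
                    ub_ = Variable(f"{tag}_u_{rxn.id}_{k}_b", lb=0, ub=-lo)
                    self.vars.append(ub_)
                    pair.append((ub_, -1.0))
                if pair:
                    self.u[(rxn.id, k)] = pair
                    terms.extend(pair)
            if terms:
                expr = self.v[rxn.id] - sum(s * var for var, s in terms)
                self.cons.append(Constraint(expr, lb=0, ub=0))
        # mass balance
        by_met: dict[str, list] = {}
        for rxn in model.reactions:
            for met, coef in rxn.stoichiometry.items():
                if coef:
                    by_met.setdefault(met, []).append(coef * self.v[rxn.id])
        for met, terms in by_met.items():
            self.cons.append(Constraint(sum(terms), lb=0, ub=0))

    def total_usage(self):
        return sum(var for pairs in self.u.values() for var, _ in pairs)


def _solve(variables, constraints, objective, direction):
    m = Model()
    m.add(variables)
    m.add(constraints)
    m.objective = Objective(objective, direction=direction)
    status = m.optimize()
    if status != "optimal":
        return status, None
    return status, m.objective.value


def oracle_fba(model: MetabolicModel, objective: str, sense: str = "max",
               extra: list | None = None):
    """FBA optimum on the *unextended* network (single flux var per reaction),
    plus usage structure so GPR extension cannot change the optimum."""
    sys_ = _System(model, "x")
    cons = list(sys_.cons)
    if extra:
        for coeffs, con_sense, rhs in extra:
            expr = sum(c * sys_.v[r] for r, c in coeffs.items())
            if con_sense == "<=":
                cons.append(Constraint(expr, ub=rhs))
            elif con_sense == ">=":
                cons.append(Constraint(expr, lb=rhs))
            else:
                cons.append(Constraint(expr, lb=rhs, ub=rhs))
    direction = "max" if sense == "max" else "min"
    if isinstance(objective, dict):
        expr = sum(c * sys_.v[r] for r, c in objective.items())
    else:
        expr = 1.0 * sys_.v[objective]
    return _solve(sys_.vars, cons, expr, direction)


def oracle_plain_fba(model: MetabolicModel, objective: str, sense: str = "max"):
    """FBA without any GPR structure at all (pure S v = 0)."""
    variables = {}
    for rxn in model.reactions:
        lo, hi = _clip(rxn.lb, rxn.ub)
        variables[rxn.id] = Variable(f"p_v_{rxn.id}", lb=lo, ub=hi)
    cons = []
    by_met: dict[str, list] = {}
    for rxn in model.reactions:
        for met, coef in rxn.stoichiometry.items():
            if coef:
                by_met.setdefault(met, []).append(coef * variables[rxn.id])
    for met, terms in by_met.items():
        cons.append(Constraint(sum(terms), lb=0, ub=0))
    direction = "max" if sense == "max" else "min"
    if isinstance(objective, dict):
        expr = sum(c * variables[r] for r, c in objective.items())
    else:
        expr = 1.0 * variables[objective]
    return _solve(list(variables.values()), cons, expr, direction)


def oracle_max_uptake(model: MetabolicModel, exchange_id: str) -> float:
    status, val = oracle_fba(model, exchange_id, sense="min")
    assert status == "optimal"
    return max(0.0, -val)


def _condition_extras(cset, condition):
    out = []
    if cset is None:
        return out
    for con in cset:
        direction = con.direction_a if condition == "a" else con.direction_b
        floor = con.abs_floor_a if condition == "a" else con.abs_floor_b
        if direction == UPTAKE:
            out.append(({con.exchange_id: 1.0}, "<=", -floor))
        elif direction == SECRETION:
            out.append(({con.exchange_id: 1.0}, ">=", floor))
    return out


def oracle_marge(model: MetabolicModel, ratios, cset=None, params: MargeParams | None = None):
    """Two-step program, independently encoded.  Returns (obj1, obj2)."""
    params = params or MargeParams()
    sys_a = _System(model, "a")
    sys_b = _System(model, "b")
    variables = sys_a.vars + sys_b.vars
    cons = sys_a.cons + sys_b.cons

    if cset is not None:
        for con in cset:
            for sys_, direction, floor in (
                (sys_a, con.direction_a, con.abs_floor_a),
                (sys_b, con.direction_b, con.abs_floor_b),
            ):
                v = sys_.v[con.exchange_id]
                if direction == UPTAKE:
                    cons.append(Constraint(1.0 * v, ub=-floor))
                elif direction == SECRETION:
                    cons.append(Constraint(1.0 * v, lb=floor))
            if con.ratio_interval is not None:
                low, high = con.ratio_interval
                sa = -1.0 if con.direction_a == UPTAKE else 1.0
                sb = -1.0 if con.direction_b == UPTAKE else 1.0
                ma = sa * sys_a.v[con.exchange_id]
                mb = sb * sys_b.v[con.exchange_id]
                cons.append(Constraint(mb - high * ma, ub=0))
                cons.append(Constraint(mb - low * ma, lb=0))

    if model.biomass_id is not None:
        for sys_, frac, cond in ((sys_a, params.growth_frac_a, "a"), (sys_b, params.growth_frac_b, "b")):
            if frac:
                status, vmax = oracle_fba(model, model.biomass_id, "max", _condition_extras(cset, cond))
                assert status == "optimal", f"growth reference FBA {status}"
                cons.append(Constraint(1.0 * sys_.v[model.biomass_id], lb=frac * vmax))

    if params.total_flux_budget is not None:
        for sys_ in (sys_a, sys_b):
            cons.append(Constraint(sys_.total_usage(), lb=params.total_flux_budget,
                                   ub=params.total_flux_budget))

    # activation + split-variable absolute deviations
    pm_terms = []
    abs_expr_terms = []
    for key in sorted(ratios):
        r = ratios[key]
        ua = sys_a.u.get(key)
        ub = sys_b.u.get(key)
        if not ua or not ub:
            continue
        cons.append(Constraint(sum(var for var, _ in ua), lb=params.u_min))
        cons.append(Constraint(sum(var for var, _ in ub), lb=params.u_min))
        for (va, sa_), (vb, sb_) in zip(ua, ub):
            p = Variable(f"p_{vb.name}", lb=0)
            m = Variable(f"m_{vb.name}", lb=0)
            variables += [p, m]
            cons.append(Constraint(vb - r * va - p + m, lb=0, ub=0))
            pm_terms.append(p + m)
            abs_expr_terms.append((va, vb, r))

    m = Model()
    m.add(variables)
    m.add(cons)
    m.objective = Objective(sum(pm_terms) if pm_terms else 0.0, direction="min")
    status = m.optimize()
    if status != "optimal":
        return status, None, None
    obj1 = m.objective.value
    if pm_terms:
        cap = obj1 * (1.0 + params.epsilon) + 1e-9
        m.add(Constraint(sum(pm_terms), ub=cap))
    m.objective = Objective(sys_a.total_usage() + sys_b.total_usage(), direction="min")
    status = m.optimize()
    if status != "optimal":
        return status, obj1, None
    return status, obj1, m.objective.value
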