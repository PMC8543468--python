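"""Two-step linear program coupling two conditions through relative expression.

Step 1 finds flux/usage states for both conditions that agree best with
the measured expression ratios: it minimizes

    obj1 = sum_i | u_i^b - r_i * u_i^a |

over all enzyme-usage variables i whose enzyme has a measured ratio
r_i = e_b/e_a, subject to mass balance of the GPR-extended system in
both conditions, flux bounds, the exometabolome-derived exchange
constraints, optional growth floors and an optional total-usage budget,
plus activation floors (u >= u_min) on every enzyme with measured
expression.  Step 2 re-optimizes for parsimonious enzyme usage,
minimizing sum(u^a) + sum(u^b) while keeping the expression agreement
within a relaxation factor (1 + eps) of the Step-1 optimum.

Absolute values are linearized with one nonnegative deviation variable
per term and two inequality rows.  The whole construction is a pure LP;
simultaneous forward+backward usage of a reversible enzyme is not
forbidden by binaries but is suppressed by the Step-2 parsimony
objective.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exo import SECRETION, UNCONSTRAINED, UPTAKE, ExchangeConstraintSet
from .lp import INFEASIBLE, OPTIMAL, LinearProgram
from .model import (
    ExtendedModel,
    FluxState,
    MetabolicModel,
    add_system,
    extend_model,
    fba,
)

logger = logging.getLogger(__name__)


class MargeError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# relative expression
# ---------------------------------------------------------------------------


@dataclass
class RelativeExpression:
    """Per-gene log2 fold changes (condition b over a) with q-values.

    Only genes passing the caller's significance convention should be
    present; a q-value filter is applied by :meth:`from_frame`.
    """

    genes: dict[str, tuple[float, float]]  # gene -> (log2fc, qvalue)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, q_threshold: float | None = 0.1) -> "RelativeExpression":
        required = {"gene_id", "log2fc", "qvalue"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"expression table missing columns {sorted(missing)}")
        genes = {}
        for row in df.itertuples(index=False):
            lfc, q = float(row.log2fc), float(row.qvalue)
            if not np.isfinite(lfc):
                raise ValueError(f"gene {row.gene_id}: non-finite log2fc")
            if q_threshold is None or q < q_threshold:
                genes[str(row.gene_id)] = (lfc, q)
        return cls(genes)

    @classmethod
    def from_tsv(cls, path, q_threshold: float | None = 0.1) -> "RelativeExpression":
        return cls.from_frame(pd.read_csv(path, sep="\t"), q_threshold)


def enzyme_ratios(
    expr: RelativeExpression,
    ext: ExtendedModel,
    method: str = "geomean",
) -> dict[tuple[str, int], float]:
    """Aggregate gene-level fold changes to enzyme (isozyme) ratios.

    Each usage-variable group (reaction, isozyme) gets one linear-scale
    ratio r = e_b/e_a shared by its forward and backward directions:
    the geometric mean of 2**log2fc over the complex's member genes
    present in the input (``method="geomean"``), or the smallest member
    fold change (``method="min"``, limiting-subunit reading).  Groups
    with no measured member gene are excluded and hence do not enter the
    Step-1 objective.
    """
    if method not in ("geomean", "min"):
        raise ValueError(f"unknown aggregation method {method!r}")
    ratios: dict[tuple[str, int], float] = {}
    for (rxn_id, iso_idx) in ext.usage_groups:
        rule = ext.base.gpr_rules.get(rxn_id)
        if rule is None:  # pragma: no cover - usage groups imply a rule
            continue
        members = rule.dnf[iso_idx]
        lfcs = [expr.genes[g][0] for g in sorted(members) if g in expr.genes]
        if not lfcs:
            continue
        if method == "geomean":
            ratios[(rxn_id, iso_idx)] = float(2.0 ** np.mean(lfcs))
        else:
            ratios[(rxn_id, iso_idx)] = float(2.0 ** np.min(lfcs))
    return ratios


# ---------------------------------------------------------------------------
# parameters and solution containers
# ---------------------------------------------------------------------------


@dataclass
class MargeParams:
    """Tunable parameters of the two-step program.

    u_min
        Flux activation threshold: enzymes with measured expression must
        carry at least this much total usage in each condition.
    epsilon
        Step-2 relaxation (``step2_tol``): the Step-2 solution's
        expression-agreement value may exceed the Step-1 optimum by this
        relative factor.
    growth_frac_a / growth_frac_b
        Optional biomass floors as fractions of each condition's own FBA
        maximum (computed under that condition's exchange constraints).
    total_flux_budget
        Optional constant total enzyme usage per condition, implementing
        a constant-total-metabolic-flux assumption.
    """

    u_min: float = 0.001
    epsilon: float = 0.1
    growth_frac_a: float | None = 0.8
    growth_frac_b: float | None = 0.8
    total_flux_budget: float | None = None
    unit_ratio_for_unmeasured: bool = False
    ratio_method: str = "geomean"
    feasibility_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.u_min <= 0:
            raise ValueError("u_min must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        for frac in (self.growth_frac_a, self.growth_frac_b):
            if frac is not None and not (0.0 <= frac <= 1.0):
                raise ValueError("growth fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "u_min": self.u_min,
            "epsilon": self.epsilon,
            "growth_frac_a": self.growth_frac_a,
            "growth_frac_b": self.growth_frac_b,
            "total_flux_budget": self.total_flux_budget,
            "unit_ratio_for_unmeasured": self.unit_ratio_for_unmeasured,
            "ratio_method": self.ratio_method,
        }


@dataclass
class MargeSolution:
    state_a: FluxState
    state_b: FluxState
    obj1: float | None
    obj2: float | None
    agreement: float | None
    status: str
    activation_dropped: bool = False
    log: list[str] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


# ---------------------------------------------------------------------------
# program assembly
# ---------------------------------------------------------------------------


def _apply_exchange_constraints(
    lp: LinearProgram,
    ext: ExtendedModel,
    constraints: ExchangeConstraintSet | None,
    off_a: int,
    off_b: int,
) -> None:
    if constraints is None:
        return
    for con in constraints:
        entries = ext.reaction_map[con.exchange_id]
        if len(entries) != 1:  # pragma: no cover - exchanges are never GPR-split
            raise MargeError(f"exchange {con.exchange_id} unexpectedly split")
        j, sign = entries[0]
        ja, jb = off_a + j, off_b + j
        for idx, direction, floor in (
            (ja, con.direction_a, con.abs_floor_a),
            (jb, con.direction_b, con.abs_floor_b),
        ):
            if direction == UPTAKE:
                lp.add_constraint({idx: sign}, "<=", -floor)
            elif direction == SECRETION:
                lp.add_constraint({idx: sign}, ">=", floor)
        if con.ratio_interval is not None:
            low, high = con.ratio_interval
            sa = -sign if con.direction_a == UPTAKE else sign
            sb = -sign if con.direction_b == UPTAKE else sign
            # magnitude_b <= high * magnitude_a ; magnitude_b >= low * magnitude_a
            lp.add_constraint({jb: sb, ja: -high * sa}, "<=", 0.0)
            lp.add_constraint({jb: sb, ja: -low * sa}, ">=", 0.0)


def _condition_constraints(
    constraints: ExchangeConstraintSet | None, condition: str
) -> list[tuple[dict[str, float], str, float]]:
    """One condition's floors/directions as plain reaction constraints."""
    out: list[tuple[dict[str, float], str, float]] = []
    if constraints is None:
        return out
    for con in constraints:
        direction = con.direction_a if condition == "a" else con.direction_b
        floor = con.abs_floor_a if condition == "a" else con.abs_floor_b
        if direction == UPTAKE:
            out.append(({con.exchange_id: 1.0}, "<=", -floor))
        elif direction == SECRETION:
            out.append(({con.exchange_id: 1.0}, ">=", floor))
    return out


def _growth_floor(
    ext: ExtendedModel,
    constraints: ExchangeConstraintSet | None,
    condition: str,
    frac: float,
) -> float:
    """frac times the condition-wise FBA biomass maximum."""
    state = fba(
        ext,
        ext.base.biomass_id,
        sense="max",
        extra_constraints=_condition_constraints(constraints, condition),
    )
    if not state.optimal:
        raise MargeError(
            f"biomass FBA for condition {condition} is {state.status}; "
            "exchange constraints alone may be inconsistent"
        )
    return frac * state.objective


class _Program:
    """The assembled joint LP plus the bookkeeping needed for both steps."""

    def __init__(
        self,
        ext: ExtendedModel,
        ratios: dict[tuple[str, int], float],
        constraints: ExchangeConstraintSet | None,
        params: MargeParams,
        activation: bool,
    ) -> None:
        self.ext = ext
        lp = LinearProgram()
        self.off_a = add_system(lp, ext, "a:")
        self.off_b = add_system(lp, ext, "b:")
        _apply_exchange_constraints(lp, ext, constraints, self.off_a, self.off_b)

        if ext.base.biomass_id is not None:
            bio_entries = ext.reaction_map[ext.base.biomass_id]
            for off, frac, cond in (
                (self.off_a, params.growth_frac_a, "a"),
                (self.off_b, params.growth_frac_b, "b"),
            ):
                if frac:
                    floor = _growth_floor(ext, constraints, cond, frac)
                    lp.add_constraint({off + j: s for j, s in bio_entries}, ">=", floor)

        usage = ext.usage_indices
        self.usage_a = [self.off_a + j for j in usage]
        self.usage_b = [self.off_b + j for j in usage]
        if params.total_flux_budget is not None:
            for idxs in (self.usage_a, self.usage_b):
                lp.add_constraint({i: 1.0 for i in idxs}, "==", params.total_flux_budget)

        # expression coupling: deviation variables and activation floors,
        # ordered by (reaction id, isozyme index) for reproducibility
        self.dev_indices: list[int] = []
        self.dev_terms: list[tuple[int, int, float]] = []  # (idx_a, idx_b, r) per usage var
        for (rxn_id, iso_idx) in sorted(ratios):
            r = ratios[(rxn_id, iso_idx)]
            group = ext.usage_groups.get((rxn_id, iso_idx))
            if group is None:  # enzyme of a fully blocked reaction
                logger.warning("ratio for blocked enzyme (%s, %d) ignored", rxn_id, iso_idx)
                continue
            if activation:
                lp.add_constraint({self.off_a + j: 1.0 for j in group}, ">=", params.u_min)
                lp.add_constraint({self.off_b + j: 1.0 for j in group}, ">=", params.u_min)
            for j in group:
                ia, ib = self.off_a + j, self.off_b + j
                d = lp.add_variable(f"d[{ext.variables[j].name}]", 0.0, np.inf)
                # d >= u_b - r*u_a  and  d >= -(u_b - r*u_a)
                lp.add_constraint({d: 1.0, ib: -1.0, ia: r}, ">=", 0.0)
                lp.add_constraint({d: 1.0, ib: 1.0, ia: -r}, ">=", 0.0)
                self.dev_indices.append(d)
                self.dev_terms.append((ia, ib, r))
        self.lp = lp

    def step1(self):
        return self.lp.solve({d: 1.0 for d in self.dev_indices}, sense="min")

    def step2(self, obj1: float, epsilon: float, slack: float):
        self.lp.add_constraint(
            {d: 1.0 for d in self.dev_indices}, "<=", obj1 * (1.0 + epsilon) + slack
        )
        obj = {i: 1.0 for i in self.usage_a}
        obj.update({i: 1.0 for i in self.usage_b})
        return self.lp.solve(obj, sense="min")

    def agreement(self, x: np.ndarray) -> float:
        return float(sum(abs(x[ib] - r * x[ia]) for ia, ib, r in self.dev_terms))

    def states(self, x: np.ndarray, obj: float) -> tuple[FluxState, FluxState]:
        out = []
        for off in (self.off_a, self.off_b):
            flux = {
                rid: float(sum(s * x[off + j] for j, s in cols))
                for rid, cols in self.ext.reaction_map.items()
            }
            usage = {self.ext.variables[j].name: float(x[off + j]) for j in self.ext.usage_indices}
            out.append(FluxState(flux, usage, obj, OPTIMAL))
        return out[0], out[1]


def _diagnose_infeasibility(
    ext: ExtendedModel,
    ratios: dict[tuple[str, int], float],
    constraints: ExchangeConstraintSet | None,
    params: MargeParams,
) -> str:
    """Name the first constraint group whose addition makes the LP infeasible."""
    stages = [
        ("mass balance and bounds", replace(params, growth_frac_a=None, growth_frac_b=None, total_flux_budget=None), None, {}),
        ("exchange constraints", replace(params, growth_frac_a=None, growth_frac_b=None, total_flux_budget=None), constraints, {}),
        ("growth-fraction floors", replace(params, total_flux_budget=None), constraints, {}),
        ("total-flux budget", params, constraints, {}),
        ("expression coupling", params, constraints, ratios),
    ]
    for name, p, cons, rs in stages:
        try:
            prog = _Program(ext, rs, cons, p, activation=False)
        except MargeError:
            return name
        if not prog.step1().optimal:
            return name
    return "unknown"


def marge(
    ext: ExtendedModel,
    ratios: dict[tuple[str, int], float],
    constraints: ExchangeConstraintSet | None = None,
    params: MargeParams | None = None,
) -> MargeSolution:
    """Run the two-step program and return the Step-2 (parsimonious) optimum.

    If Step 1 is infeasible, the activation floors are dropped first
    (logged); if the program is still infeasible the returned solution
    carries status ``infeasible`` and a log entry naming the first
    violated constraint group.
    """
    params = params or MargeParams()
    bad = [k for k, r in ratios.items() if not (r > 0 and np.isfinite(r))]
    if bad:
        raise MargeError(f"non-positive or non-finite enzyme ratios for {bad[:5]}")
    log: list[str] = []
    activation_dropped = False

    prog = _Program(ext, ratios, constraints, params, activation=True)
    res1 = prog.step1()
    if res1.status == INFEASIBLE and ratios:
        activation_dropped = True
        msg = "Step 1 infeasible with activation floors; retrying without them"
        logger.warning(msg)
        log.append(msg)
        prog = _Program(ext, ratios, constraints, params, activation=False)
        res1 = prog.step1()
    if res1.status == INFEASIBLE:
        group = _diagnose_infeasibility(ext, ratios, constraints, params)
        msg = f"program infeasible; first violated constraint group: {group}"
        logger.error(msg)
        log.append(msg)
        empty = FluxState({}, {}, None, INFEASIBLE)
        return MargeSolution(empty, empty, None, None, None, INFEASIBLE, activation_dropped, log)
    if not res1.optimal:
        raise MargeError(f"Step 1 ended with solver status {res1.status!r}")

    obj1 = res1.objective
    res2 = prog.step2(obj1, params.epsilon, params.feasibility_tol)
    if not res2.optimal:
        # the Step-1 point satisfies the cap, so this is a numerical failure
        raise MargeError(f"Step 2 ended with solver status {res2.status!r}")
    obj2 = res2.objective
    state_a, state_b = prog.states(res2.x, obj2)
    agreement = prog.agreement(res2.x)
    return MargeSolution(state_a, state_b, obj1, obj2, agreement, OPTIMAL, activation_dropped, log)


# ---------------------------------------------------------------------------
# pathway summaries
# ---------------------------------------------------------------------------


def pathway_flux_summary(
    sol: MargeSolution, pathway_map: dict[str, str]
) -> pd.DataFrame:
    """Per-pathway share of total absolute flux in each condition.

    Shares are |flux| sums over the mapped reactions, normalized per
    condition; the ``share_diff`` column is share_b - share_a.
    """
    if not pathway_map:
        raise ValueError("pathway map is empty")
    if not sol.optimal:
        raise MargeError("cannot summarize a non-optimal solution")
    rows = {}
    for rid, label in pathway_map.items():
        if rid not in sol.state_a.flux:
            raise KeyError(f"pathway map references unknown reaction {rid!r}")
        acc = rows.setdefault(label, [0.0, 0.0])
        acc[0] += abs(sol.state_a.flux[rid])
        acc[1] += abs(sol.state_b.flux[rid])
    tot_a = sum(v[0] for v in rows.values())
    tot_b = sum(v[1] for v in rows.values())
    if tot_a == 0 or tot_b == 0:
        raise MargeError("total mapped flux is zero in at least one condition")
    df = pd.DataFrame(
        {
            "share_a": {k: v[0] / tot_a for k, v in rows.items()},
            "share_b": {k: v[1] / tot_b for k, v in rows.items()},
        }
    ).sort_index()
    df["share_diff"] = df["share_b"] - df["share_a"]
    df.index.name = "pathway"
    return df


# ---------------------------------------------------------------------------
# model-object surface
# ---------------------------------------------------------------------------


class Marge:
    """Two-condition flux model built from a metabolic network, relative
    expression, and exometabolome-derived exchange constraints.

    Parameters
    ----------
    model : MetabolicModel or ExtendedModel
        The network; a plain model is GPR-extended automatically.
    expression : RelativeExpression or DataFrame, optional
        Per-gene log2 fold changes (b over a) with q-values.  A DataFrame
        needs columns gene_id / log2fc / qvalue and is filtered at
        q < 0.1.
    constraints : ExchangeConstraintSet, optional
        Output of :func:`margeflux.exo.build_constraints`.
    params : MargeParams, optional

    Examples
    --------
    >>> from margeflux import Marge, synthetic
    >>> data = synthetic.simulate_condition_pair(synthetic.ToyScenario(seed=17))
    >>> res = Marge(synthetic.make_toy_model(), data.expression,
    ...             params=MargeParams(growth_frac_a=None, growth_frac_b=None)).fit()
    >>> res.obj1 >= 0
    True
    """

    def __init__(
        self,
        model: MetabolicModel | ExtendedModel,
        expression: RelativeExpression | pd.DataFrame | None = None,
        constraints: ExchangeConstraintSet | None = None,
        params: MargeParams | None = None,
    ) -> None:
        self.ext = model if isinstance(model, ExtendedModel) else extend_model(model)
        if isinstance(expression, pd.DataFrame):
            expression = RelativeExpression.from_frame(expression)
        self.expression = expression
        self.constraints = constraints
        self.params = params or MargeParams()

    def enzyme_ratios(self) -> dict[tuple[str, int], float]:
        ratios: dict[tuple[str, int], float] = {}
        if self.expression is not None:
            ratios = enzyme_ratios(self.expression, self.ext, self.params.ratio_method)
        if self.params.unit_ratio_for_unmeasured:
            for key in self.ext.usage_groups:
                ratios.setdefault(key, 1.0)
        return ratios

    def fit(self) -> "MargeResults":
        sol = marge(self.ext, self.enzyme_ratios(), self.constraints, self.params)
        return MargeResults(self, sol)


class MargeResults:
    """Fitted fluxes and enzyme usages for both conditions."""

    def __init__(self, model: Marge, solution: MargeSolution) -> None:
        self.model = model
        self.solution = solution

    # -- scalar results ----------------------------------------------------
    @property
    def status(self) -> str:
        return self.solution.status

    @property
    def obj1(self) -> float | None:
        """Step-1 optimum: best attainable expression disagreement."""
        return self.solution.obj1

    @property
    def obj2(self) -> float | None:
        """Step-2 optimum: minimal total enzyme usage under the cap."""
        return self.solution.obj2

    @property
    def agreement(self) -> float | None:
        """Expression disagreement of the returned (Step-2) solution."""
        return self.solution.agreement

    # -- tabular results ---------------------------------------------------
    @property
    def fluxes(self) -> pd.DataFrame:
        if not self.solution.optimal:
            raise MargeError("no fluxes: solution is not optimal")
        ids = self.model.ext.base.reaction_ids
        df = pd.DataFrame(
            {
                "flux_a": [self.solution.state_a.flux[r] for r in ids],
                "flux_b": [self.solution.state_b.flux[r] for r in ids],
            },
            index=pd.Index(ids, name="reaction"),
        )
        df["delta"] = df["flux_b"] - df["flux_a"]
        return df

    @property
    def usages(self) -> pd.DataFrame:
        if not self.solution.optimal:
            raise MargeError("no usages: solution is not optimal")
        names = sorted(self.solution.state_a.usage)
        return pd.DataFrame(
            {
                "usage_a": [self.solution.state_a.usage[n] for n in names],
                "usage_b": [self.solution.state_b.usage[n] for n in names],
            },
            index=pd.Index(names, name="usage_variable"),
        )

    def pathway_shares(self, pathway_map: dict[str, str]) -> pd.DataFrame:
        return pathway_flux_summary(self.solution, pathway_map)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        p = self.model.params
        lines = [
            "MARGE two-condition flux fit",
            "=" * 46,
            f"status:                {self.status}",
            f"reactions:             {len(self.model.ext.base.reactions)}",
            f"usage variables:       {len(self.model.ext.usage_indices)}",
            f"enzymes with ratios:   {len(self.model.enzyme_ratios())}",
            f"u_min:                 {p.u_min}",
            f"epsilon (step2_tol):   {p.epsilon}",
            f"growth fractions:      {p.growth_frac_a}, {p.growth_frac_b}",
            f"total flux budget:     {p.total_flux_budget}",
        ]
        if self.solution.optimal:
            lines += [
                f"obj1 (expr disagreement): {self.obj1:.6g}",
                f"obj2 (total usage):       {self.obj2:.6g}",
                f"returned agreement:       {self.agreement:.6g}",
            ]
            ex = [r for r in self.model.ext.base.exchange_ids]
            if ex:
                lines.append("-" * 46)
                lines.append(f"{'exchange':<20}{'flux_a':>12}{'flux_b':>12}")
                for rid in sorted(ex):
                    fa = self.solution.state_a.flux[rid]
                    fb = self.solution.state_b.flux[rid]
                    lines.append(f"{rid:<20}{fa:>12.4f}{fb:>12.4f}")
        for msg in self.solution.log:
            lines.append(f"note: {msg}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        sol = self.solution
        out = {
            "status": sol.status,
            "obj1": sol.obj1,
            "obj2": sol.obj2,
            "agreement": sol.agreement,
            "activation_dropped": sol.activation_dropped,
            "params": self.model.params.to_dict(),
            "log": list(sol.log),
        }
        if sol.optimal:
            out["flux_a"] = sol.state_a.flux
            out["flux_b"] = sol.state_b.flux
            out["usage_a"] = sol.state_a.usage
            out["usage_b"] = sol.state_b.usage
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
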