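"""Small deterministic linear-programming layer.

Wraps :func:`scipy.optimize.linprog` (HiGHS) behind an incremental
builder so the modelling code can talk in named variables and
constraints instead of matrix slices.  Variables are kept in insertion
order, which makes degenerate optima reproducible for a fixed solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"

_STATUS = {0: OPTIMAL, 1: FAILED, 2: INFEASIBLE, 3: UNBOUNDED, 4: FAILED}


@dataclass
class LPResult:
    status: str
    objective: float | None
    x: np.ndarray | None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class _Constraint:
    indices: list[int]
    coeffs: list[float]
    sense: str  # "<=", ">=", "=="
    rhs: float


class LinearProgram:
    """Incrementally assembled LP: min/max c'x s.t. A x {<=,>=,==} b, l <= x <= u."""

    def __init__(self) -> None:
        self._names: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._constraints: list[_Constraint] = []

    # -- variables ---------------------------------------------------------
    def add_variable(self, name: str, lb: float, ub: float) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        if lb > ub:
            raise ValueError(f"variable {name!r}: lb {lb} > ub {ub}")
        idx = len(self._names)
        self._names.append(name)
        self._index[name] = idx
        self._lb.append(lb)
        self._ub.append(ub)
        return idx

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_variables(self) -> int:
        return len(self._names)

    # -- constraints -------------------------------------------------------
    def add_constraint(self, coeffs: dict[int | str, float], sense: str, rhs: float) -> None:
        if sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad sense {sense!r}")
        idx = [c if isinstance(c, int) else self._index[c] for c in coeffs]
        self._constraints.append(_Constraint(idx, list(coeffs.values()), sense, rhs))

    def add_range_constraint(self, coeffs: dict[int | str, float], lo: float, hi: float) -> None:
        if lo > -np.inf:
            self.add_constraint(coeffs, ">=", lo)
        if hi < np.inf:
            self.add_constraint(coeffs, "<=", hi)

    # -- solve -------------------------------------------------------------
    def solve(self, objective: dict[int | str, float], sense: str = "min") -> LPResult:
        n = self.n_variables
        c = np.zeros(n)
        for k, v in objective.items():
            c[k if isinstance(k, int) else self._index[k]] += v
        sign = 1.0 if sense == "min" else -1.0

        rows_ub, cols_ub, vals_ub, b_ub = [], [], [], []
        rows_eq, cols_eq, vals_eq, b_eq = [], [], [], []
        for con in self._constraints:
            if con.sense == "==":
                r = len(b_eq)
                rows_eq.extend([r] * len(con.indices))
                cols_eq.extend(con.indices)
                vals_eq.extend(con.coeffs)
                b_eq.append(con.rhs)
            else:
                flip = 1.0 if con.sense == "<=" else -1.0
                r = len(b_ub)
                rows_ub.extend([r] * len(con.indices))
                cols_ub.extend(con.indices)
                vals_ub.extend(flip * v for v in con.coeffs)
                b_ub.append(flip * con.rhs)

        A_ub = sp.csr_matrix((vals_ub, (rows_ub, cols_ub)), shape=(len(b_ub), n)) if b_ub else None
        A_eq = sp.csr_matrix((vals_eq, (rows_eq, cols_eq)), shape=(len(b_eq), n)) if b_eq else None

        res = linprog(
            sign * c,
            A_ub=A_ub,
            b_ub=np.asarray(b_ub) if b_ub else None,
            A_eq=A_eq,
            b_eq=np.asarray(b_eq) if b_eq else None,
            bounds=list(zip(self._lb, self._ub)),
            method="highs",
        )
        status = _STATUS.get(res.status, FAILED)
        if status != OPTIMAL:
            return LPResult(status, None, None)
        return LPResult(OPTIMAL, sign * res.fun, res.x)
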