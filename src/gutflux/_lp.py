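"""Thin linear-programming layer on top of scipy's HiGHS interface.

Every flux computation in the package (FBA, FVA, consistency checks,
coupled community models, the FASTCORE subproblems) reduces to::

    max/min  c.x   s.t.  A_eq.x = b_eq,  A_ub.x <= b_ub,  lb <= x <= ub

HiGHS (via :func:`scipy.optimize.linprog`) is deterministic for a fixed
problem, which the pipeline relies on for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

#: feasibility tolerance handed to HiGHS
FEAS_TOL = 1e-9
#: tolerance used when reporting / comparing fluxes
REPORT_TOL = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """LP backend failed in a way other than infeasible/unbounded."""


@dataclass
class LinearProgram:
    """Mutable LP builder with named variables and rows."""

    _names: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _eq_rows: list[dict[int, float]] = field(default_factory=list)
    _eq_rhs: list[float] = field(default_factory=list)
    _ub_rows: list[dict[int, float]] = field(default_factory=list)
    _ub_rhs: list[float] = field(default_factory=list)

    # -- construction ------------------------------------------------
    def add_var(self, name: str, lb: float, ub: float) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        if lb > ub:
            raise ValueError(f"variable {name!r} has lb {lb} > ub {ub}")
        i = len(self._names)
        self._names.append(name)
        self._index[name] = i
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        return i

    def var_index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_vars(self) -> int:
        return len(self._names)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._index[name]
        self._lb[i] = float(lb)
        self._ub[i] = float(ub)

    def get_bounds(self, name: str) -> tuple[float, float]:
        i = self._index[name]
        return self._lb[i], self._ub[i]

    def add_eq(self, coeffs: dict[str, float], rhs: float = 0.0) -> None:
        self._eq_rows.append({self._index[k]: float(v) for k, v in coeffs.items()})
        self._eq_rhs.append(float(rhs))

    def add_le(self, coeffs: dict[str, float], rhs: float) -> None:
        """Add a row  sum(coeffs.x) <= rhs."""
        self._ub_rows.append({self._index[k]: float(v) for k, v in coeffs.items()})
        self._ub_rhs.append(float(rhs))

    # -- solving -----------------------------------------------------
    def _matrix(self, rows: list[dict[int, float]]) -> sparse.csr_matrix | None:
        if not rows:
            return None
        data, ri, ci = [], [], []
        for r, row in enumerate(rows):
            for c, v in row.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
        return sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(rows), self.n_vars)
        )

    def solve(
        self, objective: dict[str, float], sense: str = "max"
    ) -> tuple[str, float, np.ndarray]:
        """Optimise ``objective`` and return (status, value, x).

        ``sense`` is ``"max"`` or ``"min"``; the returned value is on the
        requested scale (not negated).
        """
        if sense not in ("max", "min"):
            raise ValueError(f"unknown sense {sense!r}")
        c = np.zeros(self.n_vars)
        for k, v in objective.items():
            c[self._index[k]] = v
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(
            sign * c,
            A_eq=self._matrix(self._eq_rows),
            b_eq=np.asarray(self._eq_rhs) if self._eq_rhs else None,
            A_ub=self._matrix(self._ub_rows),
            b_ub=np.asarray(self._ub_rhs) if self._ub_rhs else None,
            bounds=list(zip(self._lb, self._ub)),
            method="highs",
            options={"primal_feasibility_tolerance": FEAS_TOL,
                     "dual_feasibility_tolerance": FEAS_TOL},
        )
        if res.status == 0:
            return OPTIMAL, sign * res.fun, res.x
        if res.status == 2:
            return INFEASIBLE, np.nan, np.full(self.n_vars, np.nan)
        if res.status == 3:
            return UNBOUNDED, np.inf if sense == "max" else -np.inf, np.full(
                self.n_vars, np.nan
            )
        raise SolverError(f"HiGHS failure: status={res.status} message={res.message}")
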