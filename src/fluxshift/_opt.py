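"""Thin deterministic LP/MILP layer over scipy's HiGHS interfaces.

All optimisation in the package funnels through these two entry points so
that solver options (presolve, tolerances, determinism) are set in one
place. Variables are dense-indexed; constraint matrices are built sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = ["LinearProblem", "InfeasibleProblemError"]


class InfeasibleProblemError(RuntimeError):
    pass


@dataclass
class LinearProblem:
    """Incrementally built LP/MILP. Maximisation by default.

    Rows and columns keep insertion order, which (with single-threaded
    HiGHS) makes solves reproducible across runs.
    """

    maximize: bool = True
    _names: list[str] = field(default_factory=list)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _integer: list[bool] = field(default_factory=list)
    _obj: list[float] = field(default_factory=list)
    _rows: list[dict[int, float]] = field(default_factory=list)
    _row_lb: list[float] = field(default_factory=list)
    _row_ub: list[float] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict)

    def add_var(self, name: str, lb: float = 0.0, ub: float = np.inf,
                obj: float = 0.0, integer: bool = False) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        idx = len(self._names)
        self._index[name] = idx
        self._names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        self._obj.append(obj)
        self._integer.append(integer)
        return idx

    def var(self, name: str) -> int:
        return self._index[name]

    def set_objective(self, coeffs: dict[str, float]) -> None:
        self._obj = [0.0] * len(self._names)
        for name, c in coeffs.items():
            self._obj[self._index[name]] = c

    def add_constraint(self, coeffs: dict[str, float], lb: float = -np.inf,
                       ub: float = np.inf) -> int:
        row = {self._index[k]: v for k, v in coeffs.items() if v != 0.0}
        self._rows.append(row)
        self._row_lb.append(lb)
        self._row_ub.append(ub)
        return len(self._rows) - 1

    def set_var_bounds(self, name: str, lb: float, ub: float) -> None:
        idx = self._index[name]
        self._lb[idx] = lb
        self._ub[idx] = ub

    @property
    def n_vars(self) -> int:
        return len(self._names)

    def _matrix(self) -> sparse.csr_matrix:
        data, ri, ci = [], [], []
        for i, row in enumerate(self._rows):
            for j, v in row.items():
                ri.append(i)
                ci.append(j)
                data.append(v)
        return sparse.csr_matrix((data, (ri, ci)), shape=(len(self._rows), self.n_vars))

    def solve(self, time_limit: Optional[float] = None, mip_gap: float = 0.0):
        """Solve and return (objective value, value vector by name).

        Raises InfeasibleProblemError on infeasibility; RuntimeError on any
        other solver failure.
        """
        c = np.asarray(self._obj, dtype=float)
        sign = -1.0 if self.maximize else 1.0
        A = self._matrix()
        any_int = any(self._integer)
        if any_int:
            options: dict = {"mip_rel_gap": mip_gap}
            if time_limit is not None:
                options["time_limit"] = time_limit
            res = milp(
                c=sign * c,
                constraints=[LinearConstraint(A, np.asarray(self._row_lb), np.asarray(self._row_ub))]
                if len(self._rows) else [],
                integrality=np.asarray(self._integer, dtype=int),
                bounds=Bounds(np.asarray(self._lb), np.asarray(self._ub)),
                options=options,
            )
            if res.status == 2:
                raise InfeasibleProblemError("MILP infeasible")
            if res.x is None:
                raise RuntimeError(f"MILP solve failed: {res.message}")
        else:
            kwargs = {}
            if len(self._rows):
                ub_arr = np.asarray(self._row_ub, dtype=float)
                lb_arr = np.asarray(self._row_lb, dtype=float)
                keep_ub = np.isfinite(ub_arr)
                keep_lb = np.isfinite(lb_arr)
                kwargs["A_ub"] = sparse.vstack([A[keep_ub], -A[keep_lb]], format="csr")
                kwargs["b_ub"] = np.concatenate([ub_arr[keep_ub], -lb_arr[keep_lb]])
            res = linprog(
                sign * c,
                bounds=np.column_stack([self._lb, self._ub]),
                method="highs",
                **kwargs,
            )
            if res.status == 2:
                raise InfeasibleProblemError("LP infeasible")
            if res.x is None:
                raise RuntimeError(f"LP solve failed: {res.message}")
        values = {name: float(res.x[i]) for i, name in enumerate(self._names)}
        return sign * float(res.fun), values
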