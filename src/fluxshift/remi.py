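"""Relative-expression consistency MILP.

Given reaction-level deregulation calls between a control condition (A)
and a treated condition (B), find the largest subset of calls that a pair
of steady-state flux vectors can satisfy simultaneously:

* an upregulated reaction r with ratio k must have activity t_B >= k * t_A,
* a downregulated one t_B <= k * t_A,
* in both cases t_A >= epsilon so the constraint is not satisfied vacuously,

where t is the unsigned flux (absolute value, linearised with forward /
backward splits and a direction binary for reversible reactions). A binary
y_r switches each constraint on or off via big-M relaxation and the MILP
maximises sum(y). Alternative optima are enumerated with integer cuts and
their intersection is the consensus set carried into flux sampling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._opt import InfeasibleProblemError, LinearProblem
from .expression import ReactionDeregulation
from .model import MetabolicModel, flux_variability

__all__ = [
    "RemiParams",
    "JointFluxModel",
    "ConsistencySolution",
    "build_remi_problem",
    "solve_max_consistency",
    "enumerate_alternative_optima",
    "brute_force_consistency",
    "verify_witness",
]

CONDITIONS = ("A", "B")


@dataclass(frozen=True)
class RemiParams:
    """Linearisation and enumeration constants.

    epsilon_min: minimal control-condition activity for a constrained
        reaction (flux units); prevents 0 >= 0 vacuous satisfaction.
    big_m_margin: per-reaction big-M is the FVA activity range times this.
    mip_gap: 0 so the reported maximum is proved, not approximate.
    """

    epsilon_min: float = 1e-3
    big_m_margin: float = 1.1
    mip_gap: float = 0.0
    max_alternatives: int = 50
    solver_time_limit_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.epsilon_min <= 0:
            raise ValueError("epsilon_min must be positive")
        if self.big_m_margin < 1.0:
            raise ValueError("big_m_margin must be >= 1")


@dataclass
class JointFluxModel:
    """Two-condition MILP description over one shared network."""

    model: MetabolicModel
    dereg: ReactionDeregulation
    params: RemiParams
    activity_max: dict[str, float]  # reaction -> max |flux| from FVA

    @property
    def constrained_reactions(self) -> list[str]:
        return sorted(self.dereg)


@dataclass
class ConsistencySolution:
    m_max: int
    alternative_sets: list[frozenset[str]]
    consensus: frozenset[str]
    witnesses: list[tuple[dict[str, float], dict[str, float]]]
    proved_optimal: bool = True
    exhausted: bool = True
    capped: bool = False


def build_remi_problem(
    model: MetabolicModel,
    dereg: ReactionDeregulation,
    params: RemiParams = RemiParams(),
    fva: Optional[dict[str, tuple[float, float]]] = None,
) -> JointFluxModel:
    """Prepare the joint two-condition MILP description.

    FVA ranges supply the per-reaction big-M constants; they are computed
    here (fraction_of_optimum = 0) unless passed in.
    """
    for rid, call in dereg.items():
        if call.ratio <= 0:
            raise ValueError(f"reaction {rid}: ratio must be positive, got {call.ratio}")
        if not model.has_reaction(rid):
            raise ValueError(f"deregulated reaction {rid} not in model")
    if fva is None:
        fva = flux_variability(model, fraction_of_optimum=0.0)
    activity_max = {}
    for rid in dereg:
        lo, hi = fva[rid]
        activity_max[rid] = max(abs(lo), abs(hi))
    return JointFluxModel(model=model, dereg=dereg, params=params, activity_max=activity_max)


def _add_condition_block(prob: LinearProblem, joint: JointFluxModel, cond: str) -> None:
    """Flux variables + steady state + activity linearisation for one condition."""
    model = joint.model
    for r in model.reactions:
        prob.add_var(f"v_{cond}_{r.id}", lb=r.lower_bound, ub=r.upper_bound)
    S = model.stoichiometric_matrix().tocsr()
    rids = model.reaction_ids()
    for i in range(S.shape[0]):
        row = S.getrow(i)
        coeffs = {f"v_{cond}_{rids[j]}": float(v) for j, v in zip(row.indices, row.data)}
        prob.add_constraint(coeffs, lb=0.0, ub=0.0)
    for rid in joint.constrained_reactions:
        r = model.reaction(rid)
        v = f"v_{cond}_{rid}"
        t = f"t_{cond}_{rid}"
        amax = max(joint.activity_max[rid], joint.params.epsilon_min)
        prob.add_var(t, lb=0.0, ub=amax * joint.params.big_m_margin)
        if r.lower_bound >= 0:
            prob.add_constraint({t: 1.0, v: -1.0}, lb=0.0, ub=0.0)
        elif r.upper_bound <= 0:
            prob.add_constraint({t: 1.0, v: 1.0}, lb=0.0, ub=0.0)
        else:
            vp, vn, d = f"vp_{cond}_{rid}", f"vn_{cond}_{rid}", f"dir_{cond}_{rid}"
            prob.add_var(vp, lb=0.0, ub=r.upper_bound)
            prob.add_var(vn, lb=0.0, ub=-r.lower_bound)
            prob.add_var(d, lb=0.0, ub=1.0, integer=True)
            prob.add_constraint({v: 1.0, vp: -1.0, vn: 1.0}, lb=0.0, ub=0.0)
            prob.add_constraint({t: 1.0, vp: -1.0, vn: -1.0}, lb=0.0, ub=0.0)
            # direction binary forces one split side to zero so t = |v|
            prob.add_constraint({vp: 1.0, d: -r.upper_bound}, ub=0.0)
            prob.add_constraint({vn: 1.0, d: -r.lower_bound}, ub=-r.lower_bound)


def _build_milp(
    joint: JointFluxModel,
    cuts: list[frozenset[str]] = [],
    total_equals: Optional[int] = None,
    force_on: Optional[frozenset[str]] = None,
) -> LinearProblem:
    params = joint.params
    prob = LinearProblem(maximize=True)
    for cond in CONDITIONS:
        _add_condition_block(prob, joint, cond)
    eps = params.epsilon_min
    for rid in joint.constrained_reactions:
        call = joint.dereg[rid]
        k = call.ratio
        y = f"y_{rid}"
        forced = force_on is not None and rid in force_on
        prob.add_var(y, lb=1.0 if forced else 0.0, ub=1.0, obj=1.0, integer=True)
        ta, tb = f"t_A_{rid}", f"t_B_{rid}"
        amax = max(joint.activity_max[rid], eps) * params.big_m_margin
        if call.direction == "up":
            big_m = k * amax + 1e-6
            # y=1  =>  t_B - k t_A >= 0
            prob.add_constraint({tb: 1.0, ta: -k, y: -big_m}, lb=-big_m)
        else:
            big_m = amax + 1e-6
            # y=1  =>  k t_A - t_B >= 0
            prob.add_constraint({ta: k, tb: -1.0, y: -big_m}, lb=-big_m)
        # y=1  =>  t_A >= eps (activity in the control condition)
        prob.add_constraint({ta: 1.0, y: -eps}, lb=0.0)
    if total_equals is not None:
        prob.add_constraint({f"y_{rid}": 1.0 for rid in joint.constrained_reactions},
                            lb=total_equals, ub=total_equals)
    for cut in cuts:
        prob.add_constraint({f"y_{rid}": 1.0 for rid in cut}, ub=len(cut) - 1)
    return prob


def _extract(joint: JointFluxModel, values: dict[str, float]):
    selected = frozenset(
        rid for rid in joint.constrained_reactions if values[f"y_{rid}"] > 0.5
    )
    v_a = {r.id: values[f"v_A_{r.id}"] for r in joint.model.reactions}
    v_b = {r.id: values[f"v_B_{r.id}"] for r in joint.model.reactions}
    return selected, (v_a, v_b)


def solve_max_consistency(joint: JointFluxModel) -> ConsistencySolution:
    """Proved-optimal maximum number of simultaneously satisfiable calls."""
    if not joint.dereg:
        zero = {r.id: 0.0 for r in joint.model.reactions}
        return ConsistencySolution(0, [frozenset()], frozenset(), [(zero, zero)])
    prob = _build_milp(joint)
    obj, values = prob.solve(time_limit=joint.params.solver_time_limit_s,
                             mip_gap=joint.params.mip_gap)
    selected, witness = _extract(joint, values)
    m_max = int(round(obj))
    return ConsistencySolution(
        m_max=m_max,
        alternative_sets=[selected],
        consensus=selected,
        witnesses=[witness],
        proved_optimal=True,
        exhausted=False,
    )


def enumerate_alternative_optima(
    joint: JointFluxModel, m_max: Optional[int] = None
) -> ConsistencySolution:
    """All distinct optimal constraint sets, via set-exclusion integer cuts.

    Repeatedly solves the MILP with sum(y) fixed at the optimum and one cut
    per already-found set; stops when infeasible (exhausted) or when the
    ``max_alternatives`` cap is hit. Consensus is the intersection of the
    family found.
    """
    if m_max is None:
        m_max = solve_max_consistency(joint).m_max
    if m_max == 0:
        zero = {r.id: 0.0 for r in joint.model.reactions}
        return ConsistencySolution(0, [frozenset()], frozenset(), [(zero, zero)])
    sets: list[frozenset[str]] = []
    witnesses = []
    exhausted = False
    while len(sets) < joint.params.max_alternatives:
        prob = _build_milp(joint, cuts=sets, total_equals=m_max)
        try:
            _, values = prob.solve(time_limit=joint.params.solver_time_limit_s,
                                   mip_gap=joint.params.mip_gap)
        except InfeasibleProblemError:
            exhausted = True
            break
        selected, witness = _extract(joint, values)
        sets.append(selected)
        witnesses.append(witness)
    consensus = frozenset.intersection(*sets) if sets else frozenset()
    return ConsistencySolution(
        m_max=m_max,
        alternative_sets=sets,
        consensus=consensus,
        witnesses=witnesses,
        proved_optimal=True,
        exhausted=exhausted,
        capped=not exhausted,
    )


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def _subset_feasible(
    model: MetabolicModel,
    dereg: ReactionDeregulation,
    subset: frozenset[str],
    eps: float,
) -> bool:
    """LP feasibility of forcing every call in *subset* simultaneously.

    Reversible constrained reactions get their orthant enumerated per
    condition so that |v| is linear inside each LP — this keeps the oracle
    free of integer variables and independent of the MILP path.
    """
    free_signs: list[tuple[str, str]] = []
    fixed_sign: dict[tuple[str, str], float] = {}
    for rid in subset:
        r = model.reaction(rid)
        for cond in CONDITIONS:
            if r.lower_bound >= 0:
                fixed_sign[(cond, rid)] = 1.0
            elif r.upper_bound <= 0:
                fixed_sign[(cond, rid)] = -1.0
            else:
                free_signs.append((cond, rid))
    if len(free_signs) > 10:
        raise ValueError("too many reversible constrained reactions for the oracle")
    for pattern in itertools.product((1.0, -1.0), repeat=len(free_signs)):
        signs = dict(fixed_sign)
        signs.update(dict(zip(free_signs, pattern)))
        prob = LinearProblem(maximize=True)
        for cond in CONDITIONS:
            for r in model.reactions:
                prob.add_var(f"v_{cond}_{r.id}", lb=r.lower_bound, ub=r.upper_bound)
            S = model.stoichiometric_matrix().tocsr()
            rids = model.reaction_ids()
            for i in range(S.shape[0]):
                row = S.getrow(i)
                coeffs = {f"v_{cond}_{rids[j]}": float(v) for j, v in zip(row.indices, row.data)}
                prob.add_constraint(coeffs, lb=0.0, ub=0.0)
        for rid in subset:
            call = dereg[rid]
            s_a, s_b = signs[("A", rid)], signs[("B", rid)]
            va, vb = f"v_A_{rid}", f"v_B_{rid}"
            prob.add_constraint({va: s_a}, lb=eps)      # t_A >= eps in this orthant
            prob.add_constraint({vb: s_b}, lb=0.0)
            if call.direction == "up":
                prob.add_constraint({vb: s_b, va: -call.ratio * s_a}, lb=0.0)
            else:
                prob.add_constraint({va: call.ratio * s_a, vb: -s_b}, lb=0.0)
        try:
            prob.solve()
            return True
        except InfeasibleProblemError:
            continue
    return False


def brute_force_consistency(
    model: MetabolicModel,
    dereg: ReactionDeregulation,
    params: RemiParams = RemiParams(),
) -> tuple[int, list[frozenset[str]]]:
    """Definitional oracle: enumerate subsets descending by size.

    Returns (M_max, all maximum-cardinality feasible subsets). Guarded to
    at most 12 constraints.
    """
    rids = sorted(dereg)
    if len(rids) > 12:
        raise ValueError(f"brute force limited to 12 constraints, got {len(rids)}")
    eps = params.epsilon_min
    for size in range(len(rids), 0, -1):
        hits = [
            frozenset(sub)
            for sub in itertools.combinations(rids, size)
            if _subset_feasible(model, dereg, frozenset(sub), eps)
        ]
        if hits:
            return size, hits
    return 0, [frozenset()]


def verify_witness(
    model: MetabolicModel,
    dereg: ReactionDeregulation,
    selected: frozenset[str],
    v_a: dict[str, float],
    v_b: dict[str, float],
    eps: float,
    tol: float = 1e-6,
) -> None:
    """Assert a witness flux pair actually supports the selected calls."""
    S = model.stoichiometric_matrix()
    rids = model.reaction_ids()
    for name, v in (("A", v_a), ("B", v_b)):
        vec = np.array([v[r] for r in rids])
        resid = np.abs(S @ vec).max()
        if resid > tol:
            raise AssertionError(f"condition {name}: |S v| = {resid:.2e} > {tol}")
        lb, ub = model.bounds_arrays()
        if (vec < lb - tol).any() or (vec > ub + tol).any():
            raise AssertionError(f"condition {name}: bounds violated")
    for rid in selected:
        call = dereg[rid]
        ta, tb = abs(v_a[rid]), abs(v_b[rid])
        if ta < eps - tol:
            raise AssertionError(f"{rid}: control activity {ta:.3g} < eps")
        if call.direction == "up" and tb - call.ratio * ta < -tol:
            raise AssertionError(f"{rid}: up-constraint violated")
        if call.direction == "down" and call.ratio * ta - tb < -tol:
            raise AssertionError(f"{rid}: down-constraint violated")
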