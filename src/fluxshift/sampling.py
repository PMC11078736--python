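"""Uniform sampling of the consensus-constrained flux space.

The joint polytope couples the two conditions' steady-state flux vectors
through the consensus ratio constraints. By default each consensus ratio is
fixed as an equality on activities (t_B = k * t_A); the one-sided
inequality form is available via ``mode="inequality"``. Because activities
are absolute fluxes, the sign of every consensus reaction (per condition)
is pinned to the sign of the MILP witness so the ratio constraint is
linear inside the sampled region.

Sampling uses artificial-centering hit-and-run (ACHR) in null-space
coordinates of the equality system, so equalities hold exactly by
construction and only the inequalities bound the chords.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import linalg

from ._opt import InfeasibleProblemError, LinearProblem
from .expression import ReactionDeregulation
from .model import MetabolicModel
from .remi import CONDITIONS, JointFluxModel, _build_milp, _extract

__all__ = [
    "FluxPolytope",
    "FluxSamples",
    "FluxSummary",
    "build_sampling_polytope",
    "achr_sample",
    "summarize_fold_changes",
]


@dataclass
class FluxPolytope:
    """Affine-parametrised convex polytope {x : A_eq x = b_eq, A_ub x <= b_ub}.

    ``basis`` spans null(A_eq) and ``x0`` is a feasible particular solution,
    so points are x = x0 + basis @ z and equalities are exact by
    construction.
    """

    names: list[str]
    A_ub: np.ndarray
    b_ub: np.ndarray
    A_eq: Optional[np.ndarray] = None
    b_eq: Optional[np.ndarray] = None
    x0: np.ndarray = None  # type: ignore[assignment]
    basis: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.A_eq is None or self.A_eq.size == 0:
            self.A_eq = np.zeros((0, n))
            self.b_eq = np.zeros(0)
        if self.basis is None:
            self.basis = linalg.null_space(self.A_eq) if self.A_eq.shape[0] else np.eye(n)
        if self.x0 is None:
            self.x0 = self._feasible_point()
        resid = np.abs(self.A_eq @ self.x0 - self.b_eq).max() if self.A_eq.shape[0] else 0.0
        if resid > 1e-9:
            raise ValueError(f"x0 violates equalities by {resid:.2e}")

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    def _feasible_point(self) -> np.ndarray:
        prob = LinearProblem(maximize=True)
        for name in self.names:
            prob.add_var(name, lb=-np.inf, ub=np.inf)
        for row, b in zip(self.A_eq, self.b_eq):
            prob.add_constraint(
                {self.names[j]: row[j] for j in np.nonzero(row)[0]}, lb=b, ub=b
            )
        # maximise the common slack to land strictly inside when possible
        prob.add_var("_slack", lb=0.0, ub=1.0, obj=1.0)
        for row, b in zip(self.A_ub, self.b_ub):
            coeffs = {self.names[j]: row[j] for j in np.nonzero(row)[0]}
            coeffs["_slack"] = float(np.linalg.norm(row))
            prob.add_constraint(coeffs, ub=b)
        try:
            _, values = prob.solve()
        except InfeasibleProblemError as exc:
            raise InfeasibleProblemError("polytope is empty") from exc
        return np.array([values[n] for n in self.names])

    def contains(self, x: np.ndarray, tol: float = 1e-7) -> bool:
        ok_eq = (
            np.abs(self.A_eq @ x - self.b_eq).max() <= max(tol, 1e-6)
            if self.A_eq.shape[0]
            else True
        )
        ok_ub = (self.A_ub @ x - self.b_ub).max() <= tol if self.A_ub.shape[0] else True
        return bool(ok_eq and ok_ub)


def _box_rows(names, lbs, ubs):
    """Bound pairs as inequality rows (x <= ub, -x <= -lb)."""
    n = len(names)
    rows, rhs = [], []
    for j, (lb, ub) in enumerate(zip(lbs, ubs)):
        if not np.isfinite(lb) or not np.isfinite(ub):
            raise ValueError(f"variable {names[j]}: sampling needs finite bounds")
        e = np.zeros(n)
        e[j] = 1.0
        rows.append(e.copy())
        rhs.append(ub)
        rows.append(-e)
        rhs.append(-lb)
    return np.array(rows), np.array(rhs)


def build_sampling_polytope(
    joint: JointFluxModel,
    consensus: frozenset[str] | set[str],
    dereg: Optional[ReactionDeregulation] = None,
    mode: Literal["equality", "inequality"] = "equality",
) -> FluxPolytope:
    """Joint two-condition polytope with consensus ratios imposed.

    The consensus is first re-solved with every call forced on, both to
    verify feasibility and to obtain the witness whose flux signs pin the
    orthant of each constrained reaction.
    """
    dereg = dereg if dereg is not None else joint.dereg
    consensus = frozenset(consensus)
    model = joint.model
    prob = _build_milp(joint, force_on=consensus)
    try:
        _, values = prob.solve()
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            f"consensus of {len(consensus)} constraints is jointly infeasible"
        ) from exc
    _, (w_a, w_b) = _extract(joint, values)
    witness = {"A": w_a, "B": w_b}

    names = [f"v_{cond}_{r.id}" for cond in CONDITIONS for r in model.reactions]
    idx = {n: j for j, n in enumerate(names)}
    n = len(names)
    S = model.stoichiometric_matrix().toarray()
    n_met, n_rxn = S.shape
    eq_rows = np.zeros((2 * n_met, n))
    eq_rows[:n_met, :n_rxn] = S
    eq_rows[n_met:, n_rxn:] = S
    eq_rhs = np.zeros(2 * n_met)

    lbs = [model.reaction(nm.split("_", 2)[2]).lower_bound for nm in names]
    ubs = [model.reaction(nm.split("_", 2)[2]).upper_bound for nm in names]
    ub_rows, ub_rhs = _box_rows(names, lbs, ubs)
    extra_ub, extra_rhs = [], []
    extra_eq, extra_eq_rhs = [], []
    eps = joint.params.epsilon_min

    def sign_of(cond: str, rid: str) -> float:
        v = witness[cond][rid]
        if abs(v) > 1e-9:
            return 1.0 if v > 0 else -1.0
        r = model.reaction(rid)
        return -1.0 if r.upper_bound <= 0 else 1.0

    for rid in sorted(consensus):
        call = dereg[rid]
        s_a, s_b = sign_of("A", rid), sign_of("B", rid)
        ja, jb = idx[f"v_A_{rid}"], idx[f"v_B_{rid}"]
        row = np.zeros(n)
        row[ja] = -s_a
        extra_ub.append(row.copy())
        extra_rhs.append(-eps)  # s_A v_A >= eps
        row = np.zeros(n)
        row[jb] = -s_b
        extra_ub.append(row)
        extra_rhs.append(0.0)  # s_B v_B >= 0
        ratio_row = np.zeros(n)
        ratio_row[jb] = s_b
        ratio_row[ja] = -call.ratio * s_a
        if mode == "equality":
            extra_eq.append(ratio_row)
            extra_eq_rhs.append(0.0)
        else:
            if call.direction == "up":  # s_B v_B - k s_A v_A >= 0
                extra_ub.append(-ratio_row)
                extra_rhs.append(0.0)
            else:
                extra_ub.append(ratio_row)
                extra_rhs.append(0.0)

    A_eq = np.vstack([eq_rows] + ([np.array(extra_eq)] if extra_eq else []))
    b_eq = np.concatenate([eq_rhs, np.array(extra_eq_rhs)] if extra_eq else [eq_rhs])
    A_ub = np.vstack([ub_rows] + ([np.array(extra_ub)] if extra_ub else []))
    b_ub = np.concatenate([ub_rhs, np.array(extra_rhs)] if extra_ub else [ub_rhs])
    return FluxPolytope(names=names, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq)


# ---------------------------------------------------------------------------
# ACHR sampler
# ---------------------------------------------------------------------------

@dataclass
class FluxSamples:
    """Sampled points, split per condition when the polytope is a joint one."""

    reaction_ids: list[str]
    samples_a: np.ndarray  # n_samples x n_reactions (or full X when not joint)
    samples_b: Optional[np.ndarray]
    seed: int
    n_warmup: int
    thinning: int
    diagnostics: dict = field(default_factory=dict)


def achr_sample(
    polytope: FluxPolytope,
    n_samples: int,
    seed: int = 0,
    n_warmup: Optional[int] = None,
    thinning: int = 10,
    check_every: int = 512,
) -> FluxSamples:
    """Artificial-centering hit-and-run over the polytope.

    Warmup points are vertices from LPs along random directions; each step
    draws a direction through the running centre from a stored point,
    intersects it with every inequality to get the chord, and steps to a
    uniform point on it. Every batch of accepted points is checked against
    the constraints. Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    d = polytope.dim
    if d == 0:  # single point
        X = np.tile(polytope.x0, (n_samples, 1))
        return _pack(polytope, X, seed, 0, thinning, {"degenerate_chords": 0})
    n_warmup = n_warmup if n_warmup is not None else max(2 * d, 20)
    G = polytope.A_ub @ polytope.basis
    h = polytope.b_ub - polytope.A_ub @ polytope.x0

    warm = np.empty((n_warmup, d))
    for i in range(n_warmup):
        direction = rng.standard_normal(d)
        prob = LinearProblem(maximize=True)
        for j in range(d):
            prob.add_var(f"z{j}", lb=-np.inf, ub=np.inf, obj=float(direction[j]))
        for row, b in zip(G, h):
            prob.add_constraint({f"z{j}": row[j] for j in np.nonzero(row)[0]}, ub=float(b))
        _, values = prob.solve()
        warm[i] = [values[f"z{j}"] for j in range(d)]

    if np.ptp(warm, axis=0).max() < 1e-9:
        # inequalities pin the region to one point even without equalities
        X = np.tile(polytope.x0 + polytope.basis @ warm[0], (n_samples, 1))
        return _pack(polytope, X, seed, n_warmup, thinning, {"degenerate_chords": 0})
    store = warm.copy()
    center = warm.mean(axis=0)
    z = center.copy()
    n_accepted = 0
    degenerate = 0
    samples_z = np.empty((n_samples, d))
    kept = 0
    tol = 1e-12
    while kept < n_samples:
        p = store[rng.integers(len(store))]
        direction = p - center
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            degenerate += 1
            if degenerate > 10_000:
                raise RuntimeError("ACHR: persistent degenerate directions")
            continue
        u = direction / norm
        gu = G @ u
        slack = h - G @ z
        slack = np.maximum(slack, 0.0)
        pos = gu > tol
        neg = gu < -tol
        a_hi = np.min(slack[pos] / gu[pos]) if pos.any() else np.inf
        a_lo = np.max(slack[neg] / gu[neg]) if neg.any() else -np.inf
        if not np.isfinite(a_hi) or not np.isfinite(a_lo) or a_hi - a_lo < 1e-12:
            degenerate += 1
            if degenerate > 10_000:
                raise RuntimeError("ACHR: chord degenerate too often")
            continue
        z = z + (a_lo + (a_hi - a_lo) * rng.random()) * u
        n_accepted += 1
        center = center + (z - center) / (n_warmup + n_accepted)
        store[rng.integers(len(store))] = z
        if n_accepted % thinning == 0:
            samples_z[kept] = z
            kept += 1
    X = polytope.x0[None, :] + samples_z @ polytope.basis.T
    viol = (polytope.A_ub @ X.T - polytope.b_ub[:, None]).max() if len(polytope.b_ub) else 0.0
    if viol > 1e-7:
        raise AssertionError(f"ACHR sample violates inequalities by {viol:.2e}")
    return _pack(polytope, X, seed, n_warmup, thinning, {"degenerate_chords": degenerate})


def _pack(polytope, X, seed, n_warmup, thinning, diagnostics) -> FluxSamples:
    names = polytope.names
    a_cols = [j for j, nm in enumerate(names) if nm.startswith("v_A_")]
    b_cols = [j for j, nm in enumerate(names) if nm.startswith("v_B_")]
    if a_cols and b_cols and len(a_cols) == len(b_cols):
        rids = [names[j][len("v_A_"):] for j in a_cols]
        return FluxSamples(rids, X[:, a_cols], X[:, b_cols], seed, n_warmup, thinning, diagnostics)
    return FluxSamples(list(names), X, None, seed, n_warmup, thinning, diagnostics)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class FluxSummary:
    per_reaction: pd.DataFrame  # reaction_id, subsystem, mean_a, mean_b, fold_change, log2_fc, sign_change
    per_subsystem: pd.DataFrame  # subsystem, n, mean_log2_fc, median_log2_fc


def summarize_fold_changes(
    samples: FluxSamples,
    model: MetabolicModel,
    delta: Optional[float] = None,
) -> FluxSummary:
    """Mean rates and between-condition fold changes, with subsystem rollup.

    fold_change = (|mean_B| + delta) / (|mean_A| + delta); the delta floor
    defaults to 1e-6 times the largest bound magnitude so near-zero means
    do not blow up the ratio. ``sign_change`` flags reactions whose mean
    flux flips direction between conditions.
    """
    if samples.samples_b is None:
        raise ValueError("summary needs a joint two-condition sample set")
    if delta is None:
        lb, ub = model.bounds_arrays()
        delta = 1e-6 * float(np.max(np.abs(np.concatenate([lb, ub]))))
    mean_a = samples.samples_a.mean(axis=0)
    mean_b = samples.samples_b.mean(axis=0)
    fc = (np.abs(mean_b) + delta) / (np.abs(mean_a) + delta)
    rows = pd.DataFrame(
        {
            "reaction_id": samples.reaction_ids,
            "subsystem": [model.reaction(r).subsystem for r in samples.reaction_ids],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "sign_change": mean_a * mean_b < -delta**2,
        }
    )
    sub = (
        rows.groupby("subsystem")["log2_fc"]
        .agg(n="size", mean_log2_fc="mean", median_log2_fc="median")
        .reset_index()
    )
    return FluxSummary(per_reaction=rows, per_subsystem=sub)
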