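"""Constraint-based metabolic model container and I/O.

The model is a plain stoichiometric network: metabolites, reactions with
bounds and GPR rules, a biomass pseudo-reaction whose flux is the growth
rate, and subsystem labels used by the downstream fold-change summaries.
Files are read and written in the COBRA community JSON dialect so that
fixtures remain human-readable and interoperable with cobrapy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import sparse

from ._opt import InfeasibleProblemError, LinearProblem
from .gpr import GprExpr, parse_gpr, serialize_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Environment",
    "ModelFormatError",
    "ModelValidationError",
    "read_model",
    "write_model",
    "apply_environment",
    "flux_variability",
    "optimize_biomass",
    "DEFAULT_INORGANIC_IDS",
]

#: species treated as freely exchangeable inorganics when an Environment
#: opens them (matched on the metabolite id with its compartment tag removed)
DEFAULT_INORGANIC_IDS = ("h2o", "h", "o2", "co2", "pi", "nh4", "so4")


class ModelFormatError(ValueError):
    """File could not be parsed as a COBRA-style JSON model."""


class ModelValidationError(ValueError):
    """Parsed model violates a structural invariant; lists offending ids."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite id -> signed coefficient
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GprExpr] = None
    subsystem: str = ""
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)


@dataclass
class MetabolicModel:
    name: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.gpr is not None:
                for g in sorted(r.gpr.genes()):
                    seen.setdefault(g)
        return list(seen)

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def set_reaction(self, rxn: Reaction) -> None:
        self.reactions[self._rxn_index[rxn.id]] = rxn

    # -- structure -------------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with shape (n_metabolites, n_reactions); steady state is S v = 0."""
        data, ri, ci = [], [], []
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                ri.append(self._met_index[mid])
                ci.append(j)
                data.append(coef)
        return sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def validate(self) -> None:
        problems: list[str] = []
        if len(self._met_index) != len(self.metabolites):
            problems.append("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            problems.append("duplicate reaction ids")
        for m in self.metabolites:
            if not m.compartment:
                problems.append(f"metabolite {m.id}: empty compartment tag")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                problems.append(f"reaction {r.id}: lower_bound > upper_bound")
            missing = [mid for mid in r.stoichiometry if mid not in self._met_index]
            if missing:
                problems.append(f"reaction {r.id}: unknown metabolites {missing}")
        if self.biomass_reaction_id not in self._rxn_index:
            problems.append(f"biomass reaction {self.biomass_reaction_id!r} not found")
        if problems:
            raise ModelValidationError("; ".join(problems))

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            name=self.name,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            biomass_reaction_id=self.biomass_reaction_id,
            metadata=json.loads(json.dumps(self.metadata)),
        )


@dataclass(frozen=True)
class Environment:
    """Growth environment: medium exchange bounds and a growth-rate cap.

    ``doubling_time_h`` is a *maximum* doubling time T_d; it caps growth at
    mu <= ln(2)/T_d (slower growth stays feasible). When ``inorganic_open``
    the exchanges of the configured inorganic species are opened in both
    directions.
    """

    medium: dict[str, tuple[float, float]] = field(default_factory=dict)
    inorganic_open: bool = True
    doubling_time_h: float = 24.0
    inorganic_ids: tuple[str, ...] = DEFAULT_INORGANIC_IDS
    inorganic_limit: float = 1000.0

    def __post_init__(self) -> None:
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be positive")

    @property
    def growth_rate_cap(self) -> float:
        return math.log(2.0) / self.doubling_time_h


def apply_environment(model: MetabolicModel, env: Environment) -> MetabolicModel:
    """Return a copy of *model* with medium, inorganic policy and growth cap set."""
    out = model.copy()
    for rid, (lb, ub) in env.medium.items():
        if not out.has_reaction(rid):
            raise ModelValidationError(f"medium exchange {rid!r} not in model")
        if not out.reaction(rid).is_exchange:
            raise ModelValidationError(f"medium entry {rid!r} is not an exchange reaction")
        out.set_reaction(out.reaction(rid).with_bounds(lb, ub))
    if env.inorganic_open:
        bare = set(env.inorganic_ids)
        for r in out.reactions:
            if not r.is_exchange:
                continue
            mid = next(iter(r.stoichiometry))
            stem = mid.rsplit("_", 1)[0] if "_" in mid else mid
            if stem in bare:
                out.set_reaction(r.with_bounds(-env.inorganic_limit, env.inorganic_limit))
    bio = out.reaction(out.biomass_reaction_id)
    out.set_reaction(bio.with_bounds(bio.lower_bound, env.growth_rate_cap))
    return out


# ---------------------------------------------------------------------------
# flux balance utilities
# ---------------------------------------------------------------------------

def _steady_state_problem(model: MetabolicModel, maximize: bool = True) -> LinearProblem:
    prob = LinearProblem(maximize=maximize)
    for r in model.reactions:
        prob.add_var(r.id, lb=r.lower_bound, ub=r.upper_bound)
    S = model.stoichiometric_matrix().tocsr()
    rids = model.reaction_ids()
    for i in range(S.shape[0]):
        row = S.getrow(i)
        coeffs = {rids[j]: float(v) for j, v in zip(row.indices, row.data)}
        prob.add_constraint(coeffs, lb=0.0, ub=0.0)
    return prob


def optimize_biomass(model: MetabolicModel) -> tuple[float, dict[str, float]]:
    """FBA: maximise biomass flux; returns (optimum, flux vector)."""
    prob = _steady_state_problem(model)
    prob.set_objective({model.biomass_reaction_id: 1.0})
    return prob.solve()


def flux_variability(
    model: MetabolicModel, fraction_of_optimum: float = 0.0
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux min/max over the steady-state polytope.

    With ``fraction_of_optimum`` > 0 the biomass flux is additionally held
    at or above that fraction of its FBA optimum. Blocked reactions come
    back as (0, 0).
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    try:
        opt, _ = optimize_biomass(model)
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            f"model {model.name!r} infeasible under its environment"
        ) from exc
    prob = _steady_state_problem(model)
    if fraction_of_optimum > 0.0:
        prob.add_constraint({model.biomass_reaction_id: 1.0}, lb=fraction_of_optimum * opt)
    out: dict[str, tuple[float, float]] = {}
    for r in model.reactions:
        prob.set_objective({r.id: 1.0})
        prob.maximize = False
        vmin, _ = prob.solve()
        prob.maximize = True
        vmax, _ = prob.solve()
        # clip solver noise so blocked reactions are exactly (0, 0)
        if abs(vmin) < 1e-9:
            vmin = 0.0
        if abs(vmax) < 1e-9:
            vmax = 0.0
        out[r.id] = (vmin, vmax)
    return out


# ---------------------------------------------------------------------------
# COBRA-community JSON I/O
# ---------------------------------------------------------------------------

def read_model(path: str | Path) -> MetabolicModel:
    """Load a COBRA-style JSON model file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in raw:
            raise ModelFormatError(f"{path}: missing top-level key {key!r}")
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
        )
        for m in raw["metabolites"]
    ]
    reactions = []
    biomass_id = None
    for r in raw["reactions"]:
        try:
            rxn = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                subsystem=r.get("subsystem", "") or "",
                name=r.get("name", ""),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"{path}: reaction {r.get('id', '?')!r}: {exc}") from exc
        reactions.append(rxn)
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            biomass_id = rxn.id
    if biomass_id is None:
        biomass_id = raw.get("notes", {}).get("biomass_reaction_id")
    if biomass_id is None:
        raise ModelFormatError(f"{path}: no objective/biomass reaction declared")
    metadata = raw.get("notes", {}).get("fluxshift", {})
    return MetabolicModel(
        name=raw.get("id", path.stem),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        metadata=metadata,
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as COBRA-style JSON (stable key order)."""
    doc = {
        "id": model.name,
        "version": "1",
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": serialize_gpr(r.gpr),
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.biomass_reaction_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
        "compartments": {c: c for c in sorted({m.compartment for m in model.metabolites})},
        "notes": {"biomass_reaction_id": model.biomass_reaction_id, "fluxshift": model.metadata},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")
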