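"""Minimal network enrichment analysis (MiNEA).

Seven canonical metabolic tasks are derived from the biomass reaction and
model metadata: synthesis of the four macromolecule classes (protein,
lipid, DNA, RNA), ATP production (a generic hydrolysis demand), superoxide
production, and lipid-droplet production. For each task a MILP finds the
minimum number of reactions able to carry the task's demand at steady
state, plus all alternative minimal networks; tasks are then scored for
enrichment in deregulated reactions (hypergeometric over-representation)
or for their mean sampled flux shift (permutation null).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._opt import InfeasibleProblemError, LinearProblem
from .expression import ReactionDeregulation
from .model import MetabolicModel, Reaction

__all__ = [
    "MetabolicTask",
    "MinimalNetwork",
    "EnrichmentResult",
    "CANONICAL_TASKS",
    "derive_tasks_from_biomass",
    "minimal_network",
    "brute_force_minimal",
    "minea_enrichment",
]

CANONICAL_TASKS = ("protein", "lipid", "dna", "rna", "atp", "superoxide", "lipid_droplet")


@dataclass(frozen=True)
class MetabolicTask:
    """A demanded production capability.

    ``demand_stoichiometry`` is the pseudo-reaction consuming the task
    target (negative coefficients) and releasing any by-products; the task
    is met when this demand can carry at least ``min_rate`` flux.
    """

    id: str
    name: str
    demand_stoichiometry: dict[str, float]
    min_rate: float = 0.1


@dataclass(frozen=True)
class MinimalNetwork:
    task_id: str
    reactions: frozenset[str]
    size: int
    alternative_index: int
    witness: dict[str, float]


@dataclass
class EnrichmentResult:
    task_id: str
    n_network: int
    n_dereg_in_network: int
    n_background: int
    n_dereg_background: int
    p_value: float
    q_value: float = float("nan")
    mean_log2_fc: float = float("nan")


def derive_tasks_from_biomass(model: MetabolicModel) -> list[MetabolicTask]:
    """Build the task list from biomass composition and model metadata.

    Metadata (``model.metadata``) declares the target species:
    ``precursor_classes`` maps protein/lipid/dna/rna to metabolite lists,
    ``atp``/``adp``/``pi``/``h2o`` name the hydrolysis species,
    ``superoxide`` and ``lipid_droplet`` name single metabolites. Classes
    whose targets are missing from the model or absent from biomass (zero
    coefficient) are skipped with a warning entry in the returned list
    order; the canonical model yields exactly seven tasks.
    """
    import warnings

    if not model.has_reaction(model.biomass_reaction_id):
        raise ValueError("model has no biomass reaction")
    biomass = model.reaction(model.biomass_reaction_id)
    meta = model.metadata
    classes: dict[str, list[str]] = meta.get("precursor_classes", {})
    met_ids = {m.id for m in model.metabolites}
    tasks: list[MetabolicTask] = []

    for cls in ("protein", "lipid", "dna", "rna"):
        targets = [m for m in classes.get(cls, []) if m in met_ids]
        targets = [m for m in targets if biomass.stoichiometry.get(m, 0.0) < 0.0]
        if not targets:
            warnings.warn(f"task {cls!r} skipped: no biomass precursor target in model")
            continue
        tasks.append(
            MetabolicTask(cls, f"{cls} synthesis", {m: -1.0 for m in targets})
        )

    atp, adp, pi = meta.get("atp"), meta.get("adp"), meta.get("pi")
    if atp in met_ids and adp in met_ids and pi in met_ids:
        demand = {atp: -1.0, adp: 1.0, pi: 1.0}
        h2o = meta.get("h2o")
        if h2o in met_ids:
            demand[h2o] = -1.0
        tasks.append(MetabolicTask("atp", "ATP hydrolysis demand", demand))
    else:
        warnings.warn("task 'atp' skipped: hydrolysis species missing")

    for tid, key in (("superoxide", "superoxide"), ("lipid_droplet", "lipid_droplet")):
        target = meta.get(key)
        if target in met_ids:
            tasks.append(MetabolicTask(tid, f"{tid} production", {target: -1.0}))
        else:
            warnings.warn(f"task {tid!r} skipped: target metabolite missing")
    return tasks


def _with_demand(model: MetabolicModel, task: MetabolicTask) -> tuple[MetabolicModel, str]:
    """Copy of the model with the task demand added as an open reaction."""
    demand_id = f"DM_task_{task.id}"
    out = model.copy()
    out.reactions.append(
        Reaction(id=demand_id, stoichiometry=dict(task.demand_stoichiometry),
                 lower_bound=0.0, upper_bound=1000.0, subsystem="task_demand")
    )
    return (
        MetabolicModel(
            name=out.name,
            metabolites=out.metabolites,
            reactions=out.reactions,
            biomass_reaction_id=out.biomass_reaction_id,
            metadata=out.metadata,
        ),
        demand_id,
    )


def _task_milp(model: MetabolicModel, demand_id: str, min_rate: float,
               cuts: list[frozenset[str]], size_equals: Optional[int]) -> LinearProblem:
    prob = LinearProblem(maximize=False)
    countable = [r.id for r in model.reactions if r.id != demand_id]
    for r in model.reactions:
        prob.add_var(f"v_{r.id}", lb=r.lower_bound, ub=r.upper_bound)
    S = model.stoichiometric_matrix().tocsr()
    rids = model.reaction_ids()
    for i in range(S.shape[0]):
        row = S.getrow(i)
        prob.add_constraint(
            {f"v_{rids[j]}": float(v) for j, v in zip(row.indices, row.data)}, lb=0.0, ub=0.0
        )
    for rid in countable:
        r = model.reaction(rid)
        prob.add_var(f"z_{rid}", lb=0.0, ub=1.0, obj=1.0, integer=True)
        # v is forced to 0 unless the reaction is switched on
        if r.upper_bound > 0:
            prob.add_constraint({f"v_{rid}": 1.0, f"z_{rid}": -r.upper_bound}, ub=0.0)
        if r.lower_bound < 0:
            prob.add_constraint({f"v_{rid}": -1.0, f"z_{rid}": r.lower_bound}, ub=0.0)
        if r.lower_bound >= 0 and r.upper_bound <= 0:
            prob.set_var_bounds(f"v_{rid}", 0.0, 0.0)
    prob.add_constraint({f"v_{demand_id}": 1.0}, lb=min_rate)
    if size_equals is not None:
        prob.add_constraint({f"z_{rid}": 1.0 for rid in countable},
                            lb=size_equals, ub=size_equals)
    for cut in cuts:
        prob.add_constraint({f"z_{rid}": 1.0 for rid in cut}, ub=len(cut) - 1)
    return prob


def minimal_network(
    model: MetabolicModel,
    task: MetabolicTask,
    max_alternatives: int = 20,
) -> list[MinimalNetwork]:
    """Minimum-cardinality reaction sets able to carry the task demand.

    MILP with one on/off binary per reaction; alternatives enumerated at
    the fixed minimum size via integer cuts until exhausted or capped.
    Returns [] when the task is infeasible under the current medium.
    """
    ext, demand_id = _with_demand(model, task)
    try:
        prob = _task_milp(ext, demand_id, task.min_rate, [], None)
        obj, values = prob.solve()
    except InfeasibleProblemError:
        return []
    min_size = int(round(obj))
    networks: list[MinimalNetwork] = []
    cuts: list[frozenset[str]] = []
    while len(networks) < max_alternatives:
        try:
            prob = _task_milp(ext, demand_id, task.min_rate, cuts, min_size)
            _, values = prob.solve()
        except InfeasibleProblemError:
            break
        chosen = frozenset(
            r.id for r in ext.reactions
            if r.id != demand_id and values.get(f"z_{r.id}", 0.0) > 0.5
        )
        witness = {r.id: values[f"v_{r.id}"] for r in ext.reactions}
        networks.append(
            MinimalNetwork(task.id, chosen, len(chosen), len(networks), witness)
        )
        cuts.append(chosen)
    return networks


def brute_force_minimal(
    model: MetabolicModel, task: MetabolicTask
) -> tuple[float, list[frozenset[str]]]:
    """Oracle: ascending subset enumeration with LP feasibility.

    Returns (min size, all minimal sets); (inf, []) when infeasible.
    Guarded to models with at most 15 reactions.
    """
    rids = [r.id for r in model.reactions]
    if len(rids) > 15:
        raise ValueError("brute force limited to models with <= 15 reactions")
    ext, demand_id = _with_demand(model, task)

    def feasible(subset: frozenset[str]) -> bool:
        prob = LinearProblem(maximize=True)
        for r in ext.reactions:
            off = r.id != demand_id and r.id not in subset
            prob.add_var(f"v_{r.id}",
                         lb=0.0 if off else r.lower_bound,
                         ub=0.0 if off else r.upper_bound)
        S = ext.stoichiometric_matrix().tocsr()
        all_ids = ext.reaction_ids()
        for i in range(S.shape[0]):
            row = S.getrow(i)
            prob.add_constraint(
                {f"v_{all_ids[j]}": float(v) for j, v in zip(row.indices, row.data)},
                lb=0.0, ub=0.0,
            )
        prob.add_constraint({f"v_{demand_id}": 1.0}, lb=task.min_rate)
        try:
            prob.solve()
            return True
        except InfeasibleProblemError:
            return False

    if not feasible(frozenset(rids)):
        return float("inf"), []
    for size in range(0, len(rids) + 1):
        hits = [
            frozenset(sub)
            for sub in itertools.combinations(rids, size)
            if feasible(frozenset(sub))
        ]
        if hits:
            return size, hits
    return float("inf"), []  # pragma: no cover


def minea_enrichment(
    networks_by_task: dict[str, list[MinimalNetwork]],
    dereg: Optional[ReactionDeregulation] = None,
    flux_log2_fc: Optional[pd.Series] = None,
    background: Optional[list[str]] = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    use_union: bool = True,
) -> list[EnrichmentResult]:
    """Score each task's minimal-network union for deregulation enrichment.

    Expression mode (``dereg`` given): exact hypergeometric upper tail
    P(X >= k) of the overlap between deregulated reactions and the task's
    network union, BH-adjusted across tasks. Flux mode (``flux_log2_fc``
    given, indexed by reaction): mean log2 fold change over the union with
    a permutation p (mean |log2FC| of equally sized random reaction sets).
    """
    if background is None or not background:
        raise ValueError("background reaction list must be non-empty")
    bg = list(dict.fromkeys(background))
    results: list[EnrichmentResult] = []
    rng = np.random.default_rng(seed)
    dereg_set = set(dereg) & set(bg) if dereg is not None else set()

    for task_id, networks in networks_by_task.items():
        if not networks:
            continue
        if use_union:
            union: set[str] = set().union(*(nw.reactions for nw in networks))
        else:
            union = set.intersection(*(set(nw.reactions) for nw in networks))
        union &= set(bg)
        res = EnrichmentResult(
            task_id=task_id,
            n_network=len(union),
            n_dereg_in_network=len(union & dereg_set),
            n_background=len(bg),
            n_dereg_background=len(dereg_set),
            p_value=1.0,
        )
        if dereg is not None:
            k, n, K, N = res.n_dereg_in_network, res.n_network, res.n_dereg_background, res.n_background
            res.p_value = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        if flux_log2_fc is not None:
            member = [r for r in union if r in flux_log2_fc.index]
            if member:
                obs = float(flux_log2_fc.loc[member].mean())
                res.mean_log2_fc = obs
                pool = flux_log2_fc.loc[[r for r in bg if r in flux_log2_fc.index]].to_numpy()
                draws = np.array([
                    pool[rng.choice(len(pool), size=len(member), replace=False)].mean()
                    for _ in range(n_permutations)
                ])
                res.p_value = float((np.sum(np.abs(draws) >= abs(obs)) + 1) / (n_permutations + 1))
        results.append(res)

    if results and dereg is not None:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {"task": r.task_id, "n_network": r.n_network, "overlap": r.n_dereg_in_network,
         "p": r.p_value, "q": r.q_value, "mean_log2fc": r.mean_log2_fc}
        for r in results
    ]
    return pd.DataFrame(rows, columns=["task", "n_network", "overlap", "p", "q", "mean_log2fc"])
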