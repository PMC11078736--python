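"""End-to-end orchestration of the flux-shift pipeline.

Stages: expression normalisation / fold-change averaging → GPR evaluation
and deregulation calling → maximum-consistency MILP with alternative
enumeration and consensus → consensus-constrained ACHR sampling →
per-reaction and per-subsystem fold-change summaries → minimal-network
enrichment of the metabolic tasks. A run writes machine-readable TSV/JSON
artefacts plus a manifest with config hash and seeds; deterministic stages
rerun bit-identically, stochastic stages are exactly reproducible per seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .expression import (
    DeregulationParams,
    average_fold_change,
    classify_deregulations,
    deregulation_table,
    reaction_fold_change,
    read_expression_tsv,
    rpkm_log2,
)
from .minea import derive_tasks_from_biomass, enrichment_table, minea_enrichment, minimal_network
from .model import Environment, apply_environment, read_model, write_model
from .remi import RemiParams, build_remi_problem, enumerate_alternative_optima, solve_max_consistency
from .sampling import achr_sample, build_sampling_polytope, summarize_fold_changes
from .synthetic import (
    ToySpec,
    default_environment,
    make_toy_model,
    plant_flux_truth,
    synthesize_expression,
)

__all__ = ["PipelineConfig", "run_flux_pipeline", "run_recovery_study", "write_simulation_bundle"]


@dataclass
class PipelineConfig:
    model_path: str
    expression_path: str
    condition_a: str = "control"
    condition_b: str = "treated"
    condition_of: dict = field(default_factory=dict)
    normalization: str = "none"  # none | rpkm_log2
    fold_change_delta: float = 1.0
    doubling_time_h: Optional[float] = 24.0
    deregulation: DeregulationParams = field(default_factory=DeregulationParams)
    remi: RemiParams = field(default_factory=RemiParams)
    n_samples: int = 5000
    sampling_seed: int = 1
    thinning: int = 5
    sampling_mode: str = "equality"
    minea_max_alternatives: int = 10
    minea_permutations: int = 2000
    out_dir: str = "fluxshift_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("model_path", "expression_path"):
            if key not in raw:
                raise KeyError(f"config missing required key {key!r}")
        dereg = DeregulationParams(**raw.pop("deregulation", {}))
        remi = RemiParams(**raw.pop("remi", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(deregulation=dereg, remi=remi, **raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_flux_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[str] = []

    model = read_model(config.model_path)
    if config.doubling_time_h is not None:
        # only re-cap growth; the model file already carries its medium
        env = Environment(doubling_time_h=config.doubling_time_h, inorganic_open=False)
        model = apply_environment(model, env)

    expr = read_expression_tsv(config.expression_path, config.condition_of)
    if config.normalization == "rpkm_log2":
        expr = rpkm_log2(expr)
    elif config.normalization != "none":
        raise ValueError(f"unknown normalization {config.normalization!r}")

    gene_fc = average_fold_change(expr, config.condition_a, config.condition_b,
                                  delta=config.fold_change_delta)
    rxn_fc = reaction_fold_change(model, gene_fc)
    dereg = classify_deregulations(rxn_fc, config.deregulation,
                                   gene_table=gene_fc, model=model)
    deregulation_table(dereg).to_csv(out / "deregulations.tsv", sep="\t", index=False)
    stages.append("deregulations.tsv")

    joint = build_remi_problem(model, dereg, config.remi)
    best = solve_max_consistency(joint)
    full = enumerate_alternative_optima(joint, best.m_max)
    consistency = {
        "m_max": full.m_max,
        "n_deregulations": len(dereg),
        "n_alternatives": len(full.alternative_sets),
        "consensus_size": len(full.consensus),
        "consensus": sorted(full.consensus),
        "exhausted": full.exhausted,
        "capped": full.capped,
    }
    (out / "consistency.json").write_text(json.dumps(consistency, indent=1))
    rows = deregulation_table(dereg)
    rows["in_consensus"] = rows["reaction_id"].isin(full.consensus)
    rows.to_csv(out / "consensus.tsv", sep="\t", index=False)
    stages += ["consistency.json", "consensus.tsv"]

    polytope = build_sampling_polytope(joint, full.consensus, mode=config.sampling_mode)
    samples = achr_sample(polytope, config.n_samples, seed=config.sampling_seed,
                          thinning=config.thinning)
    summary = summarize_fold_changes(samples, model)
    summary.per_reaction.to_csv(out / "flux_summary.tsv", sep="\t", index=False)
    summary.per_subsystem.to_csv(out / "subsystem_summary.tsv", sep="\t", index=False)
    stages += ["flux_summary.tsv", "subsystem_summary.tsv"]

    tasks = derive_tasks_from_biomass(model)
    networks = {t.id: minimal_network(model, t, config.minea_max_alternatives) for t in tasks}
    background = model.reaction_ids()
    expr_mode = minea_enrichment(networks, dereg=dereg, background=background)
    flux_fc = summary.per_reaction.set_index("reaction_id")["log2_fc"]
    flux_mode = minea_enrichment(networks, flux_log2_fc=flux_fc, background=background,
                                 n_permutations=config.minea_permutations,
                                 seed=config.sampling_seed)
    minea_df = enrichment_table(expr_mode).merge(
        enrichment_table(flux_mode)[["task", "p", "mean_log2fc"]],
        on="task", suffixes=("_expr", "_flux"),
    )
    minea_df.to_csv(out / "minea.tsv", sep="\t", index=False)
    stages.append("minea.tsv")

    manifest = {
        "config_digest": config.digest(),
        "version": __version__,
        "seeds": {"sampling": config.sampling_seed},
        "stage_outputs": stages,
        "elapsed_s": round(time.time() - t0, 2),
        "consistency": {k: consistency[k] for k in ("m_max", "n_alternatives", "consensus_size")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# simulation bundle + recovery study
# ---------------------------------------------------------------------------

def write_simulation_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_up: int = 3,
    n_down: int = 2,
    n_contradictory: int = 2,
    noise_sd: float = 0.0,
) -> dict:
    """Write a complete synthetic input bundle (model, expression, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = apply_environment(make_toy_model(ToySpec(seed=seed)), default_environment())
    truth = plant_flux_truth(model, seed=seed, n_up=n_up, n_down=n_down,
                             n_contradictory=n_contradictory)
    expr, gene_fc = synthesize_expression(truth, model, noise_sd=noise_sd, seed=seed)
    write_model(model, out / "model.json")
    df = expr.values.reset_index()
    df.to_csv(out / "expression.tsv", sep="\t", index=False)
    truth_doc = {
        "planted": {r: dataclasses.asdict(c) for r, c in truth.planted.items()},
        "contradictory": {r: dataclasses.asdict(c) for r, c in truth.contradictory.items()},
        "gene_fold_changes": gene_fc,
        "condition_of": expr.condition_of,
        "seed": seed,
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    return truth_doc


def run_recovery_study(
    seeds: range | list[int] = range(10),
    noise_levels: tuple[float, ...] = (0.0,),
    n_up: int = 3,
    n_down: int = 2,
    n_contradictory: int = 2,
    n_samples: int = 2000,
    sample_fluxes: bool = True,
) -> pd.DataFrame:
    """Planted-truth recovery across seeds and expression noise levels.

    For each (seed, noise) cell: build a toy model, plant a flux truth,
    synthesise expression, classify, run the consistency MILP with
    alternative enumeration, and compare the consensus with the planted
    constraints. Optionally sample the consensus polytope and check that
    the sign of each consensus reaction's flux fold change matches the
    planted direction. Returns one row per cell.
    """
    records = []
    for noise in noise_levels:
        for seed in seeds:
            model = apply_environment(make_toy_model(ToySpec(seed=seed)), default_environment())
            truth = plant_flux_truth(model, seed=seed, n_up=n_up, n_down=n_down,
                                     n_contradictory=n_contradictory)
            expr, _ = synthesize_expression(truth, model, noise_sd=noise, seed=seed + 1)
            gene_fc = average_fold_change(expr, "control", "treated", delta=0.0)
            rxn_fc = reaction_fold_change(model, gene_fc)
            dereg = classify_deregulations(rxn_fc)
            joint = build_remi_problem(model, dereg)
            sol = enumerate_alternative_optima(joint)
            planted = set(truth.planted)
            contradictory = set(truth.contradictory)
            consensus = set(sol.consensus)
            rec = {
                "seed": seed,
                "noise_sd": noise,
                "n_dereg_called": len(dereg),
                "m_max": sol.m_max,
                "n_alternatives": len(sol.alternative_sets),
                "recall": len(consensus & planted) / len(planted) if planted else 1.0,
                "precision": (len(consensus & planted) / len(consensus)) if consensus else 1.0,
                "n_contradictory_in_consensus": len(consensus & contradictory),
            }
            if sample_fluxes and consensus:
                polytope = build_sampling_polytope(joint, frozenset(consensus))
                samples = achr_sample(polytope, n_samples, seed=seed, thinning=2)
                summary = summarize_fold_changes(samples, model).per_reaction.set_index("reaction_id")
                correct = 0
                scored = 0
                for rid in consensus & set(dereg):
                    want_up = dereg[rid].direction == "up"
                    lfc = summary.loc[rid, "log2_fc"]
                    scored += 1
                    correct += int((lfc > 0) == want_up)
                rec["flux_sign_accuracy"] = correct / scored if scored else float("nan")
            records.append(rec)
    return pd.DataFrame(records)
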