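"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a small
multi-subsystem metabolic network with a biomass reaction (a desk-scale
stand-in for a reduced T cell genome-scale model), two-condition
steady-state flux truths with planted relative deregulations (optionally
including mutually contradictory pairs on stoichiometrically coupled
reactions), replicate gene expression tables whose GPR evaluation
reproduces the planted ratios, single-cell gene-rank matrices with a
spiked signature, and power-law clonotype repertoires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._opt import InfeasibleProblemError, LinearProblem
from .expression import DeregulationCall, ExpressionMatrix, ReactionDeregulation
from .model import Environment, MetabolicModel, Metabolite, Reaction
from .gpr import parse_gpr
from .readouts import GeneSignature

__all__ = [
    "ToySpec",
    "PlantedTruth",
    "make_toy_model",
    "default_environment",
    "plant_flux_truth",
    "synthesize_expression",
    "synthesize_cell_matrix",
    "synthesize_repertoire",
]


@dataclass(frozen=True)
class ToySpec:
    """Knobs of the toy network generator.

    ``subsystem_extra`` adds that many duplicated parallel isozyme
    reactions per named subsystem (ids suffixed ``_iso<i>``), which grows
    the model without changing what it can produce. Duplication skips the
    reactions used as stoichiometrically coupled pairs so planted
    contradictions stay valid.
    """

    seed: int = 0
    include_lipid_droplet: bool = True
    subsystem_extra: dict = field(default_factory=dict)


# reactions kept free of isozyme duplicates; used for coupled-pair contradictions
COUPLED_PAIRS = (("CS", "ICDH", 1.0), ("GLCt", "HEX1", 1.0), ("RNDR", "DNAS", 2.0))
_NO_DUPLICATE = {r for pair in COUPLED_PAIRS for r in pair[:2]}

_GPR_PATTERNS = ("single", "iso2", "complex2", "complex_or")


def _template(include_ld: bool):
    """(id, subsystem, stoichiometry, lb, ub) rows of the base network."""
    rows = [
        # exchanges; negative flux = uptake
        ("EX_glc_e", "exchange", {"glc_e": -1}, -10, 0),
        ("EX_gln_e", "exchange", {"gln_e": -1}, -5, 0),
        ("EX_o2_e", "exchange", {"o2_e": -1}, -20, 0),
        ("EX_lac_e", "exchange", {"lac_e": -1}, 0, 20),
        ("EX_nh4_e", "exchange", {"nh4_e": -1}, -50, 50),
        ("EX_pi_e", "exchange", {"pi_e": -1}, -50, 50),
        ("EX_co2_e", "exchange", {"co2_e": -1}, -50, 50),
        ("EX_h2o_e", "exchange", {"h2o_e": -1}, -50, 50),
        ("EX_h_e", "exchange", {"h_e": -1}, -50, 50),
        # transport
        ("GLCt", "transport", {"glc_e": -1, "glc_c": 1}, 0, 10),
        ("GLNt", "transport", {"gln_e": -1, "gln_c": 1}, 0, 5),
        ("O2t", "transport", {"o2_e": -1, "o2_c": 1}, 0, 20),
        ("LACt", "transport", {"lac_c": -1, "lac_e": 1}, 0, 20),
        ("NH4t", "transport", {"nh4_e": -1, "nh4_c": 1}, -50, 50),
        ("PIt", "transport", {"pi_e": -1, "pi_c": 1}, -50, 50),
        ("CO2t", "transport", {"co2_c": -1, "co2_e": 1}, -50, 50),
        ("H2Ot", "transport", {"h2o_c": -1, "h2o_e": 1}, -50, 50),
        ("Ht", "transport", {"h_c": -1, "h_e": 1}, -50, 50),
        # glycolysis
        ("HEX1", "glycolysis", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}, 0, 10),
        ("PYK", "glycolysis",
         {"g6p_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
          "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2}, 0, 10),
        ("LDH", "glycolysis",
         {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac_c": 1, "nad_c": 1}, -20, 20),
        # pentose phosphate
        ("G6PDH", "pentose_phosphate",
         {"g6p_c": -1, "nad_c": -2, "r5p_c": 1, "co2_c": 1, "nadh_c": 2}, 0, 10),
        # TCA
        ("PDH", "tca_cycle", {"pyr_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, 20),
        ("PC", "tca_cycle",
         {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "oaa_c": 1, "adp_c": 1, "pi_c": 1}, 0, 20),
        ("CS", "tca_cycle", {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "cit_c": 1}, 0, 20),
        ("ICDH", "tca_cycle", {"cit_c": -1, "nad_c": -1, "akg_c": 1, "co2_c": 1, "nadh_c": 1}, 0, 20),
        ("AKGDH", "tca_cycle",
         {"akg_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
          "succ_c": 1, "co2_c": 1, "nadh_c": 1, "atp_c": 1}, 0, 20),
        ("SDH_MDH", "tca_cycle", {"succ_c": -1, "nad_c": -2, "oaa_c": 1, "nadh_c": 2}, 0, 20),
        # oxidative phosphorylation
        ("ETC", "oxidative_phosphorylation",
         {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2.5, "pi_c": -2.5, "h_c": -1,
          "nad_c": 1, "atp_c": 2.5, "h2o_c": 1}, 0, 60),
        ("ATPM", "oxidative_phosphorylation",
         {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}, 0, 50),
        # ROS / glutathione
        ("ROSGEN", "glutathione_ros", {"nadh_c": -1, "o2_c": -1, "nad_c": 1, "o2s_c": 1}, 0, 5),
        ("GSHS", "glutathione_ros",
         {"glu_c": -1, "atp_c": -1, "gsh_c": 1, "adp_c": 1, "pi_c": 1}, 0, 5),
        ("ROSDET", "glutathione_ros", {"o2s_c": -1, "gsh_c": -1, "h2o_c": 1}, 0, 5),
        # amino acids
        ("GLNASE", "amino_acid", {"gln_c": -1, "h2o_c": -1, "glu_c": 1, "nh4_c": 1}, 0, 5),
        ("GDH", "amino_acid",
         {"glu_c": -1, "nad_c": -1, "h2o_c": -1, "akg_c": 1, "nh4_c": 1, "nadh_c": 1}, -10, 10),
        ("ALATA", "amino_acid", {"pyr_c": -1, "glu_c": -1, "ala_c": 1, "akg_c": 1}, -10, 10),
        ("ASPTA", "amino_acid", {"oaa_c": -1, "glu_c": -1, "asp_c": 1, "akg_c": 1}, -10, 10),
        # nucleotides
        ("NTPS", "nucleotide",
         {"r5p_c": -1, "gln_c": -1, "atp_c": -2,
          "ntp_c": 1, "glu_c": 1, "adp_c": 2, "pi_c": 1}, 0, 5),
        ("RNDR", "nucleotide",
         {"ntp_c": -1, "nadh_c": -1, "dntp_c": 1, "nad_c": 1, "h2o_c": 1}, 0, 5),
        ("RNAS", "nucleotide", {"ntp_c": -2, "rna_c": 1, "pi_c": 2}, 0, 5),
        ("DNAS", "nucleotide", {"dntp_c": -2, "dna_c": 1, "pi_c": 2}, 0, 5),
        # lipid
        ("FAS", "lipid",
         {"accoa_c": -4, "nadh_c": -2, "atp_c": -1,
          "fa_c": 1, "nad_c": 2, "adp_c": 1, "pi_c": 1}, 0, 5),
        ("LIPS", "lipid", {"fa_c": -2, "atp_c": -1, "lipid_c": 1, "adp_c": 1, "pi_c": 1}, 0, 5),
        ("FAO", "lipid", {"fa_c": -1, "nad_c": -2, "h2o_c": -1, "accoa_c": 4, "nadh_c": 2}, 0, 5),
        # protein and growth
        ("PROTS", "protein_synthesis",
         {"ala_c": -2, "asp_c": -1, "glu_c": -1, "atp_c": -4,
          "prot_c": 1, "adp_c": 4, "pi_c": 4}, 0, 5),
        ("BIOMASS", "growth",
         {"prot_c": -0.5, "lipid_c": -0.1, "dna_c": -0.05, "rna_c": -0.05,
          "atp_c": -20, "h2o_c": -20, "adp_c": 20, "pi_c": 20, "h_c": 20}, 0, 10),
    ]
    if include_ld:
        rows.append(("LDSYN", "lipid", {"lipid_c": -1, "fa_c": -1, "lipdrop_c": 1}, 0, 5))
        rows.append(("DM_lipdrop", "lipid", {"lipdrop_c": -1}, 0, 5))
    return rows


def _gpr_for(rid: str, pattern: str) -> str:
    g = lambda i: f"g_{rid}_{i}"
    if pattern == "single":
        return g(1)
    if pattern == "iso2":
        return f"{g(1)} or {g(2)}"
    if pattern == "complex2":
        return f"{g(1)} and {g(2)}"
    return f"({g(1)} and {g(2)}) or ({g(3)} and {g(4)})"


def make_toy_model(spec: ToySpec = ToySpec()) -> MetabolicModel:
    """Deterministic (per seed) toy metabolic model.

    Ten subsystems, ~45-80 reactions, biomass with protein / lipid / DNA /
    RNA precursor classes plus ATP hydrolysis species, a superoxide
    species and (optionally) a lipid-droplet species, all declared in
    model metadata for task derivation. Every enzymatic (non-exchange)
    reaction carries a GPR over genes private to that reaction, mixing
    complexes and isozymes so GPR aggregation is exercised.
    """
    rng = np.random.default_rng(spec.seed)
    rows = _template(spec.include_lipid_droplet)
    for subsystem, extra in sorted(spec.subsystem_extra.items()):
        candidates = [r for r in rows if r[1] == subsystem
                      and r[0] not in _NO_DUPLICATE and not r[0].startswith(("EX_", "DM_"))]
        for i in range(extra):
            rid, sub, stoich, lb, ub = candidates[i % len(candidates)]
            rows.append((f"{rid}_iso{i + 1}", sub, dict(stoich), lb, ub))

    met_ids: dict[str, None] = {}
    for _, _, stoich, _, _ in rows:
        for mid in stoich:
            met_ids.setdefault(mid)
    metabolites = [
        Metabolite(id=mid, name=mid.rsplit("_", 1)[0], compartment=mid.rsplit("_", 1)[1])
        for mid in met_ids
    ]
    patterns = [_GPR_PATTERNS[i % len(_GPR_PATTERNS)] for i in range(len(rows))]
    rng.shuffle(patterns)
    reactions = []
    for (rid, sub, stoich, lb, ub), pattern in zip(rows, patterns):
        gpr = None
        if not rid.startswith(("EX_", "DM_")) and rid != "BIOMASS":
            gpr = parse_gpr(_gpr_for(rid, pattern))
        reactions.append(
            Reaction(id=rid, stoichiometry={k: float(v) for k, v in stoich.items()},
                     lower_bound=float(lb), upper_bound=float(ub), gpr=gpr, subsystem=sub)
        )
    metadata = {
        "precursor_classes": {
            "protein": ["prot_c"],
            "lipid": ["lipid_c"],
            "dna": ["dna_c"],
            "rna": ["rna_c"],
        },
        "atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h2o": "h2o_c",
        "superoxide": "o2s_c",
        "lipid_droplet": "lipdrop_c" if spec.include_lipid_droplet else None,
    }
    return MetabolicModel(
        name=f"toy_tcell_seed{spec.seed}",
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
        metadata=metadata,
    )


def default_environment(doubling_time_h: float = 24.0) -> Environment:
    """Glucose/glutamine/oxygen medium with free inorganics."""
    return Environment(
        medium={
            "EX_glc_e": (-10.0, 0.0),
            "EX_gln_e": (-5.0, 0.0),
            "EX_o2_e": (-20.0, 0.0),
            "EX_lac_e": (0.0, 20.0),
        },
        inorganic_open=True,
        doubling_time_h=doubling_time_h,
        inorganic_limit=50.0,
    )


# ---------------------------------------------------------------------------
# planted flux truths
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    v_a: dict[str, float]
    v_b: dict[str, float]
    planted: ReactionDeregulation          # jointly satisfiable calls
    contradictory: ReactionDeregulation    # calls on coupled pairs, mutually exclusive

    @property
    def dereg(self) -> ReactionDeregulation:
        return {**self.planted, **self.contradictory}


def _steady_state_lp(model: MetabolicModel) -> LinearProblem:
    prob = LinearProblem(maximize=True)
    for r in model.reactions:
        prob.add_var(r.id, lb=r.lower_bound, ub=r.upper_bound)
    S = model.stoichiometric_matrix().tocsr()
    rids = model.reaction_ids()
    for i in range(S.shape[0]):
        row = S.getrow(i)
        prob.add_constraint({rids[j]: float(v) for j, v in zip(row.indices, row.data)},
                            lb=0.0, ub=0.0)
    return prob


def _is_coupled(model: MetabolicModel, r1: str, r2: str, ratio: float) -> bool:
    """True when v_r1 = ratio * v_r2 over the whole flux polytope."""
    for maximize in (True, False):
        prob = _steady_state_lp(model)
        prob.maximize = maximize
        prob.set_objective({r1: 1.0, r2: -ratio})
        val, _ = prob.solve()
        if abs(val) > 1e-7:
            return False
    return True


def plant_flux_truth(
    model: MetabolicModel,
    seed: int = 0,
    n_up: int = 3,
    n_down: int = 2,
    n_contradictory: int = 0,
    up_range: tuple[float, float] = (1.6, 2.5),
    down_range: tuple[float, float] = (0.4, 0.65),
    min_activity: float = 0.05,
    max_tries: int = 30,
) -> PlantedTruth:
    """Plant a pair of steady-state flux vectors with known deregulations.

    The control vector v_A is an interior point; v_B is solved to satisfy
    each planted ratio *exactly* (v_B,r = k_r * v_A,r), so equality-mode
    sampling of the planted consensus is feasible by construction.
    Contradictory calls (n_contradictory must be even) demand opposite
    directions on fully coupled reaction pairs: each is individually
    satisfiable alongside the planted calls, but a pair can never hold
    jointly.
    """
    if n_contradictory % 2:
        raise ValueError("n_contradictory must be even (contradictions come in pairs)")
    rng = np.random.default_rng(seed)
    rids = model.reaction_ids()
    bio = model.biomass_reaction_id
    grow_floor = 0.3 * model.reaction(bio).upper_bound

    def joint_lp(planted: ReactionDeregulation,
                 extra_call: Optional[tuple[str, DeregulationCall]] = None) -> LinearProblem:
        """Both conditions as one LP; planted ratios as exact equalities."""
        prob = LinearProblem(maximize=True)
        for tag in ("a", "b"):
            for r in model.reactions:
                prob.add_var(f"{tag}_{r.id}", lb=r.lower_bound, ub=r.upper_bound)
            S = model.stoichiometric_matrix().tocsr()
            for i in range(S.shape[0]):
                row = S.getrow(i)
                prob.add_constraint(
                    {f"{tag}_{rids[j]}": float(v) for j, v in zip(row.indices, row.data)},
                    lb=0.0, ub=0.0)
            prob.add_constraint({f"{tag}_{bio}": 1.0}, lb=grow_floor)
        for rid, call in planted.items():
            prob.add_constraint({f"b_{rid}": 1.0, f"a_{rid}": -call.ratio}, lb=0.0, ub=0.0)
            prob.add_constraint({f"a_{rid}": 1.0}, lb=min_activity)
        if extra_call is not None:
            rid, call = extra_call
            prob.add_constraint({f"a_{rid}": 1.0}, lb=1e-3)
            if call.direction == "up":
                prob.add_constraint({f"b_{rid}": 1.0, f"a_{rid}": -call.ratio}, lb=0.0)
            else:
                prob.add_constraint({f"a_{rid}": call.ratio, f"b_{rid}": -1.0}, lb=0.0)
                prob.add_constraint({f"b_{rid}": 1.0}, lb=0.0)
        return prob

    # quick per-reaction attainable maxima, for candidate filtering
    fva_max: dict[str, float] = {}
    base_candidates = [
        r.id for r in model.reactions
        if r.gpr is not None and r.lower_bound >= 0.0
        and r.id != bio and r.id not in _NO_DUPLICATE
    ]
    for rid in base_candidates:
        prob = _steady_state_lp(model)
        prob.set_objective({rid: 1.0})
        fva_max[rid], _ = prob.solve()
    candidates = [r for r in base_candidates
                  if fva_max[r] >= 1.1 * up_range[1] * min_activity]

    for attempt in range(max_tries):
        if len(candidates) < n_up + n_down:
            break
        picks = [str(r) for r in rng.choice(candidates, size=n_up + n_down, replace=False)]
        planted: ReactionDeregulation = {}
        for rid in picks[:n_up]:
            planted[rid] = DeregulationCall("up", float(rng.uniform(*up_range)))
        for rid in picks[n_up:]:
            planted[rid] = DeregulationCall("down", float(rng.uniform(*down_range)))

        contradictory: ReactionDeregulation = {}
        pairs_needed = n_contradictory // 2
        usable = [
            (r1, r2, c) for r1, r2, c in COUPLED_PAIRS
            if model.has_reaction(r1) and model.has_reaction(r2)
            and r1 not in planted and r2 not in planted
            and _is_coupled(model, r1, r2, c)
        ]
        if len(usable) < pairs_needed:
            continue
        for r1, r2, _ in usable[:pairs_needed]:
            contradictory[r1] = DeregulationCall("up", 2.0)
            contradictory[r2] = DeregulationCall("down", 0.5)

        try:
            # interior point of the joint (equality-constrained) truth polytope
            sols = []
            for _ in range(6):
                prob = joint_lp(planted)
                prob.set_objective({f"{tag}_{rid}": float(c) for (tag, rid), c in zip(
                    [(t, r) for t in ("a", "b") for r in rids],
                    rng.standard_normal(2 * len(rids)))})
                _, values = prob.solve()
                sols.append(values)
            # each contradictory call must be satisfiable next to the planted set
            for rid, call in contradictory.items():
                joint_lp(planted, extra_call=(rid, call)).solve()
        except InfeasibleProblemError:
            continue
        v_a = {r: float(np.mean([s[f"a_{r}"] for s in sols])) for r in rids}
        v_b = {r: float(np.mean([s[f"b_{r}"] for s in sols])) for r in rids}
        return PlantedTruth(v_a=v_a, v_b=v_b, planted=planted, contradictory=contradictory)
    raise RuntimeError(f"could not plant requested truth in {max_tries} attempts")


# ---------------------------------------------------------------------------
# expression synthesis
# ---------------------------------------------------------------------------

def synthesize_expression(
    truth: PlantedTruth,
    model: MetabolicModel,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    baseline_log_mean: float = np.log(200.0),
    baseline_log_sd: float = 0.6,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Replicate expression tables whose GPR evaluation encodes the truth.

    Every gene of a planted (or contradictory) reaction's GPR gets the
    planted ratio as its condition-B/condition-A fold change; all other
    genes get 1. Replicates add multiplicative lognormal noise of the
    given log-scale standard deviation. With noise_sd = 0, replicate
    averaging (delta = 0) followed by GPR evaluation reproduces the
    planted ratios exactly.
    """
    rng = np.random.default_rng(seed)
    gene_fc: dict[str, float] = {}
    for rid, call in truth.dereg.items():
        r = model.reaction(rid)
        if r.gpr is None:
            raise ValueError(f"planted reaction {rid} has no GPR")
        for g in r.gpr.genes():
            if g in gene_fc and gene_fc[g] != call.ratio:
                raise ValueError(f"gene {g} shared between planted reactions")
            gene_fc[g] = call.ratio
    all_genes = model.genes
    fc = np.array([gene_fc.get(g, 1.0) for g in all_genes])
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=len(all_genes)))
    data = {}
    cond_of = {}
    for i in range(n_replicates):
        noise_a = np.exp(rng.normal(0.0, noise_sd, len(all_genes))) if noise_sd else 1.0
        noise_b = np.exp(rng.normal(0.0, noise_sd, len(all_genes))) if noise_sd else 1.0
        data[f"ctrl_{i + 1}"] = base * noise_a
        data[f"treat_{i + 1}"] = base * fc * noise_b
        cond_of[f"ctrl_{i + 1}"] = "control"
        cond_of[f"treat_{i + 1}"] = "treated"
    values = pd.DataFrame(data, index=pd.Index(all_genes, name="gene"))
    return ExpressionMatrix(values=values, condition_of=cond_of), gene_fc


# ---------------------------------------------------------------------------
# single-cell rank matrices and repertoires
# ---------------------------------------------------------------------------

def synthesize_cell_matrix(
    n_cells: int,
    n_genes: int,
    sig: GeneSignature,
    effect: float = 1.0,
    seed: int = 0,
    positive_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-cell gene rankings with the signature spiked in positive cells.

    Gene scores are standard normal; in "positive" cells the signature
    genes get +effect added before ranking (effect = 0 makes all genes
    exchangeable). Returns (rank matrix genes x cells, 1 = top;
    cell -> 'pos'/'neg' labels).
    """
    if len(sig) >= n_genes:
        raise ValueError("signature must be smaller than the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i}" for i in range(n_genes)]
    for i, g in enumerate(sig.genes):  # signature genes live in the universe
        genes[i] = g
    scores = rng.standard_normal((n_genes, n_cells))
    n_pos = int(round(positive_fraction * n_cells))
    sig_rows = [i for i, g in enumerate(genes) if g in set(sig.genes)]
    scores[np.ix_(sig_rows, range(n_pos))] += effect
    order = np.argsort(-scores, axis=0, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(n_cells)
    ranks[order, cols] = np.arange(1, n_genes + 1)[:, None]
    cells = [f"cell{i}" for i in range(n_cells)]
    labels = {c: ("pos" if i < n_pos else "neg") for i, c in enumerate(cells)}
    return pd.DataFrame(ranks, index=genes, columns=cells), labels


_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Seq import Seq

        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    codon = b1 + b2 + b3
                    aa = str(Seq(codon).translate())
                    if aa in _AA:
                        _CODONS.setdefault(aa, []).append(codon)
    return _CODONS


def synthesize_repertoire(
    n_clones: int = 100,
    power_exponent: float = 1.0,
    depth: int = 20_000,
    seed: int = 0,
    out_of_frame_fraction: float = 0.1,
    variant_fraction: float = 0.3,
    singleton_count: int = 3,
    aa_length: int = 12,
) -> pd.DataFrame:
    """Raw clonotype reads: power-law abundances plus preprocessing bait.

    Clone frequencies follow rank^(-power_exponent); a fraction of clones
    is emitted as two synonymous nucleotide variants of the same protein,
    and out-of-frame entries and in-frame singletons are appended so the
    preprocessing filters have work to do.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    table = _codon_table()
    freqs = (np.arange(1, n_clones + 1, dtype=float)) ** (-power_exponent)
    freqs /= freqs.sum()
    counts = rng.multinomial(depth, freqs)

    def nt_for(aa_seq: str) -> str:
        return "".join(table[aa][rng.integers(len(table[aa]))] for aa in aa_seq)

    rows = []
    seen_aa = set()
    for count in counts:
        if count < 2:
            continue
        while (aa_seq := "".join(rng.choice(list(_AA), size=aa_length))) in seen_aa:
            pass
        seen_aa.add(aa_seq)
        if rng.random() < variant_fraction and count >= 4:
            c1 = int(rng.integers(1, count))
            rows.append({"nt_seq": nt_for(aa_seq), "frame": "in", "count": c1})
            rows.append({"nt_seq": nt_for(aa_seq), "frame": "in", "count": int(count - c1)})
        else:
            rows.append({"nt_seq": nt_for(aa_seq), "frame": "in", "count": int(count)})
    n_oof = max(1, int(out_of_frame_fraction * n_clones))
    for _ in range(n_oof):
        seq = "".join(rng.choice(list("ACGT"), size=3 * aa_length + 1))
        rows.append({"nt_seq": seq, "frame": "out", "count": int(rng.integers(2, 50))})
    for _ in range(singleton_count):
        while (aa_seq := "".join(rng.choice(list(_AA), size=aa_length))) in seen_aa:
            pass
        seen_aa.add(aa_seq)
        rows.append({"nt_seq": nt_for(aa_seq), "frame": "in", "count": 1})
    return pd.DataFrame(rows, columns=["nt_seq", "frame", "count"])
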