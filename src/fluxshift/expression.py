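"""Expression → reaction deregulation calls.

Normalise replicate count data (RPKM, log2 with pseudo-count 1), average
fold changes across replicates, propagate gene fold changes through GPR
rules to enzyme level (AND = min over complex subunits, OR = max over
isozymes), and classify reactions as up- or downregulated against the
1.3 / 0.77 thresholds (or the 1.2-fold + p <= 0.5 gene-level variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .model import MetabolicModel

__all__ = [
    "ExpressionMatrix",
    "DeregulationParams",
    "DeregulationCall",
    "ReactionDeregulation",
    "read_expression_tsv",
    "rpkm_log2",
    "average_fold_change",
    "reaction_fold_change",
    "classify_deregulations",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with sample→condition labels.

    ``values`` holds raw counts or already-normalised values; ``lengths_bp``
    (per gene) is required only for RPKM normalisation.
    """

    values: pd.DataFrame  # index: gene, columns: sample
    condition_of: dict[str, str]  # sample -> condition label
    lengths_bp: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if self.lengths_bp is not None:
            self.lengths_bp = self.lengths_bp.reindex(self.values.index)
            if (self.lengths_bp <= 0).any() or self.lengths_bp.isna().any():
                raise ValueError("gene lengths must be positive for all genes")

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.condition_of[s] == condition]
        if not out:
            raise KeyError(f"no samples labelled {condition!r}")
        return out


def read_expression_tsv(path: str | Path, condition_of: dict[str, str]) -> ExpressionMatrix:
    """Read TSV with columns ``gene, length_bp, <sample...>``."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError(f"{path}: missing 'gene' column")
    df = df.set_index("gene")
    lengths = df.pop("length_bp") if "length_bp" in df.columns else None
    return ExpressionMatrix(values=df, condition_of=condition_of, lengths_bp=lengths)


def rpkm_log2(expr: ExpressionMatrix, pseudo_count: float = 1.0) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalisation, then log2(x + pseudo).

    RPKM = count / (length_kb * library_size_millions), computed per sample
    column independently.
    """
    if expr.lengths_bp is None:
        raise ValueError("RPKM normalisation requires per-gene lengths")
    totals = expr.values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total reads in sample(s) {bad}")
    length_kb = expr.lengths_bp / 1000.0
    rpkm = expr.values.div(totals / 1e6, axis=1).div(length_kb, axis=0)
    return ExpressionMatrix(
        values=np.log2(rpkm + pseudo_count),
        condition_of=dict(expr.condition_of),
        lengths_bp=expr.lengths_bp.copy(),
    )


def average_fold_change(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    delta: float = 1.0,
) -> pd.DataFrame:
    """Replicate-averaged per-gene linear fold change of B over A.

    The fold change is the geometric mean of the per-replicate ratios
    ``(b_i + delta) / (a_i + delta)`` — replicates are paired positionally
    when the two conditions have equal counts, otherwise all cross pairs
    enter the mean (identical result: the geometric mean factorises).

    Returns a DataFrame indexed by gene with a ``fc`` column (linear scale).
    """
    a = expr.values[expr.samples_of(cond_a)].to_numpy(dtype=float) + delta
    b = expr.values[expr.samples_of(cond_b)].to_numpy(dtype=float) + delta
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("values + delta must be positive for fold changes")
    if a.shape[1] == b.shape[1]:
        log_ratios = np.log(b) - np.log(a)
    else:
        log_ratios = np.log(b).mean(axis=1, keepdims=True) - np.log(a).mean(axis=1, keepdims=True)
    fc = np.exp(log_ratios.mean(axis=1))
    return pd.DataFrame({"fc": fc}, index=expr.values.index)


def reaction_fold_change(
    model: MetabolicModel, gene_fc: pd.DataFrame | dict[str, float]
) -> dict[str, float]:
    """Enzyme-level fold change per reaction via GPR evaluation.

    AND nodes take the minimum of their children, OR nodes the maximum;
    unmeasured genes are skipped, and reactions with no GPR or with no
    measured gene are absent from the result.
    """
    if isinstance(gene_fc, pd.DataFrame):
        values = gene_fc["fc"].to_dict()
    else:
        values = dict(gene_fc)
    out: dict[str, float] = {}
    for r in model.reactions:
        if r.gpr is None:
            continue
        fc = r.gpr.evaluate(values)
        if fc is not None:
            out[r.id] = float(fc)
    return out


@dataclass(frozen=True)
class DeregulationParams:
    """Thresholds for calling reactions up/down.

    ``enzyme_fc`` variant: strict comparisons on the GPR-aggregated enzyme
    fold change (up if fc > theta_up = 1.3, down if fc < theta_down = 0.77).
    ``gene_fc_with_p`` variant: genes pass a two-sided 1.2-fold filter with
    p <= 0.5, and the passing genes are then mapped to reactions via GPR.
    """

    theta_up: float = 1.3
    theta_down: float = 0.77
    variant: Literal["enzyme_fc", "gene_fc_with_p"] = "enzyme_fc"
    fc_min: float = 1.2
    p_max: float = 0.5

    def __post_init__(self) -> None:
        if not self.theta_down < 1.0 < self.theta_up:
            raise ValueError("need theta_down < 1 < theta_up")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must be in (0, 1]")


@dataclass(frozen=True)
class DeregulationCall:
    direction: Literal["up", "down"]
    ratio: float  # linear fold change used as the flux-ratio bound
    source_genes: tuple[str, ...] = ()


#: reaction id -> call; the constraint currency of the consistency MILP
ReactionDeregulation = dict[str, DeregulationCall]


def classify_deregulations(
    reaction_fc: dict[str, float],
    params: DeregulationParams = DeregulationParams(),
    gene_table: Optional[pd.DataFrame] = None,
    model: Optional[MetabolicModel] = None,
) -> ReactionDeregulation:
    """Call each reaction up/down (or leave it unclassified).

    For the ``gene_fc_with_p`` variant *gene_table* must carry ``fc`` and
    ``p`` columns and *model* must be given (GPRs are re-evaluated on the
    genes passing the filter).
    """
    out: ReactionDeregulation = {}
    if params.variant == "enzyme_fc":
        for rid, fc in reaction_fc.items():
            if fc > params.theta_up:
                out[rid] = DeregulationCall("up", float(fc))
            elif fc < params.theta_down:
                out[rid] = DeregulationCall("down", float(fc))
        return out
    # gene-level variant with a p-value gate
    if gene_table is None or model is None:
        raise ValueError("gene_fc_with_p variant needs gene_table and model")
    if "p" not in gene_table.columns:
        raise ValueError("gene_fc_with_p variant requires a 'p' column")
    fcs = gene_table["fc"]
    ps = gene_table["p"]
    passing = gene_table.index[
        ((fcs >= params.fc_min) | (fcs <= 1.0 / params.fc_min)) & (ps <= params.p_max)
    ]
    selected = {g: float(fcs[g]) for g in passing}
    for r in model.reactions:
        if r.gpr is None:
            continue
        hit = sorted(r.gpr.genes() & selected.keys())
        if not hit:
            continue
        ratio = r.gpr.evaluate(selected)
        if ratio is None or ratio == 1.0:
            continue
        out[r.id] = DeregulationCall(
            "up" if ratio > 1.0 else "down", float(ratio), tuple(hit)
        )
    return out


def deregulation_table(dereg: ReactionDeregulation) -> pd.DataFrame:
    """Flat TSV-ready view of a set of deregulation calls."""
    rows = [
        {"reaction_id": rid, "direction": c.direction, "ratio": c.ratio,
         "source_genes": ";".join(c.source_genes)}
        for rid, c in sorted(dereg.items())
    ]
    return pd.DataFrame(rows, columns=["reaction_id", "direction", "ratio", "source_genes"])
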