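"""Non-flux readout statistics.

Signature derivation from a differential-expression table (top-k
FDR-significant upregulated genes), per-cell AUC recovery scoring of a
gene set (AUCell-style), single-sample GSEA scoring, pseudobulk
aggregation, and bulk TCR-beta repertoire preprocessing and diversity
metrics (richness, Shannon entropy, Pielou evenness / clonality,
expanded-clone counts against the median clone frequency).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneSignature",
    "RepertoireMetrics",
    "derive_signature",
    "auc_signature_score",
    "ssgsea_score",
    "pseudobulk_mean",
    "preprocess_repertoire",
    "repertoire_metrics",
    "read_gmt",
]


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path) -> dict[str, GeneSignature]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    out = {}
    for line in open(path):
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            out[parts[0]] = GeneSignature(parts[0], tuple(g for g in parts[2:] if g))
    return out


def derive_signature(
    de: pd.DataFrame,
    fdr_max: float = 0.05,
    fc_min_log2: float = 0.0,
    top_k: int = 63,
    name: str = "signature",
) -> GeneSignature:
    """Top-k significant upregulated genes from a DE table.

    *de* is indexed by gene with columns ``log2_fc`` and ``fdr``. Genes
    with FDR < fdr_max and log2 fold change > fc_min_log2 are ranked by
    ascending FDR (ties: larger fold change first, then gene id) and the
    first *top_k* are kept; a warning is issued if fewer survive.
    """
    if de.empty:
        raise ValueError("DE table is empty")
    for col in ("log2_fc", "fdr"):
        if col not in de.columns:
            raise ValueError(f"DE table missing {col!r} column")
    passing = de[(de["fdr"] < fdr_max) & (de["log2_fc"] > fc_min_log2)].copy()
    passing["_gene"] = passing.index
    passing = passing.sort_values(
        ["fdr", "log2_fc", "_gene"], ascending=[True, False, True], kind="mergesort"
    )
    genes = tuple(passing.index[:top_k])
    if len(genes) < top_k:
        warnings.warn(
            f"only {len(genes)} genes pass the filters (requested top {top_k})"
        )
    return GeneSignature(name, genes)


def auc_signature_score(
    rankings: pd.DataFrame,
    sig: GeneSignature,
    top_frac: float = 0.05,
) -> pd.Series:
    """AUCell-style per-cell recovery AUC of the signature.

    *rankings* is genes x cells of ranks (1 = highest expressed). The score
    is the area under the step recovery curve within the top
    ceil(top_frac * n_genes) ranks, normalised by its maximum (every set
    gene at the very top). Set genes missing from the ranking never
    recover. Scores are in [0, 1].
    """
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must be in (0, 1]")
    n_genes = rankings.shape[0]
    threshold = math.ceil(top_frac * n_genes)
    present = [g for g in sig.genes if g in rankings.index]
    k = len(sig.genes)
    max_auc = sum(min(x, k) for x in range(1, threshold + 1))
    scores = {}
    ranks = rankings.loc[present].to_numpy() if present else np.empty((0, rankings.shape[1]))
    for ci, cell in enumerate(rankings.columns):
        if present:
            r = np.sort(ranks[:, ci])
            r = r[r <= threshold]
            # step curve: recovery y(x) = #set genes with rank <= x
            auc = int(np.sum(threshold - r + 1)) if len(r) else 0
        else:
            auc = 0
        scores[cell] = auc / max_auc if max_auc else 0.0
    return pd.Series(scores, name=f"auc_{sig.name}")


def ssgsea_score(
    expr: pd.DataFrame | pd.Series,
    sig: GeneSignature,
    alpha: float = 0.25,
) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    Genes are ranked by decreasing expression; the score is the sum over
    all ranking positions of the difference between the weighted in-set
    ECDF (weights |rank|^alpha, i.e. position-from-bottom weighting of the
    standard formulation) and the unweighted out-of-set ECDF. alpha = 0
    reduces to the unweighted ECDF difference.
    """
    if isinstance(expr, pd.Series):
        expr = expr.to_frame()
    in_set = expr.index.isin(sig.genes)
    if not in_set.any():
        raise ValueError("signature has no genes in the expression index")
    n = expr.shape[0]
    scores = {}
    for col in expr.columns:
        order = np.argsort(-expr[col].to_numpy(), kind="mergesort")
        member = in_set[order]
        # weight by rank from the bottom: top gene gets weight n^alpha
        weight = (n - np.arange(n)).astype(float) ** alpha
        w_in = np.where(member, weight, 0.0)
        denom_in = w_in.sum()
        cdf_in = np.cumsum(w_in) / denom_in
        out = ~member
        cdf_out = np.cumsum(out) / out.sum()
        scores[col] = float(np.sum(cdf_in - cdf_out))
    return pd.Series(scores, name=f"ssgsea_{sig.name}")


def pseudobulk_mean(cell_scores: pd.Series, labels: Mapping[str, str]) -> pd.Series:
    """Arithmetic mean of per-cell scores within each patient/sample."""
    missing = [c for c in cell_scores.index if c not in labels]
    if missing:
        raise ValueError(f"cells without patient label: {missing[:5]}")
    groups = pd.Series({c: labels[c] for c in cell_scores.index})
    return cell_scores.groupby(groups).mean()


# ---------------------------------------------------------------------------
# TCR repertoire
# ---------------------------------------------------------------------------

_DNA_RE = re.compile(r"^[ACGTacgt]+$")


def preprocess_repertoire(raw: pd.DataFrame) -> pd.DataFrame:
    """Pool nucleotide clonotypes at the protein level and filter.

    *raw* needs columns ``nt_seq``, ``frame`` ("in"/"out") and ``count``.
    Steps: drop out-of-frame entries, translate and pool reads of
    nucleotide variants coding for the same protein sequence, then drop
    clonotypes whose pooled abundance is a single read. Returns a table
    indexed by protein sequence with a ``count`` column.
    """
    for col in ("nt_seq", "frame", "count"):
        if col not in raw.columns:
            raise ValueError(f"repertoire table missing {col!r} column")
    bad = raw.loc[~raw["nt_seq"].astype(str).str.match(_DNA_RE), "nt_seq"]
    if len(bad):
        raise ValueError(f"non-DNA characters in sequences: {list(bad[:3])}")
    in_frame = raw[raw["frame"].astype(str).str.lower().isin(["in", "in_frame", "true", "1"])]
    if in_frame.empty:
        return pd.DataFrame({"count": pd.Series(dtype=int)})
    aa = in_frame["nt_seq"].map(
        lambda s: str(Seq(s[: 3 * (len(s) // 3)].upper()).translate())
    )
    pooled = in_frame.assign(aa_seq=aa).groupby("aa_seq")["count"].sum()
    pooled = pooled[pooled >= 2]
    return pooled.sort_values(ascending=False).to_frame()


@dataclass(frozen=True)
class RepertoireMetrics:
    richness: int
    shannon_entropy: float  # nats
    pielou_evenness: float
    clonality: float  # 1 - Pielou
    n_exp10: int
    n_exp100: int


def repertoire_metrics(table: pd.DataFrame) -> RepertoireMetrics:
    """Diversity metrics of a preprocessed clonotype table.

    Richness is the number of distinct clonotypes; Shannon entropy is in
    natural log; Pielou evenness H/ln(richness) (1 for a single clone by
    convention); clonality is 1 - Pielou. Expanded-clone counts are the
    clonotypes whose frequency is at least 10x (100x) the median clone
    frequency of the repertoire.
    """
    if table.empty:
        raise ValueError("empty clonotype table")
    counts = table["count"].to_numpy(dtype=float)
    total = counts.sum()
    p = counts / total
    richness = len(counts)
    shannon = float(-(p * np.log(p)).sum())
    pielou = 1.0 if richness == 1 else shannon / math.log(richness)
    med = float(np.median(p))
    return RepertoireMetrics(
        richness=richness,
        shannon_entropy=shannon,
        pielou_evenness=pielou,
        clonality=1.0 - pielou,
        n_exp10=int(np.sum(p >= 10.0 * med)),
        n_exp100=int(np.sum(p >= 100.0 * med)),
    )
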