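"""Expression normalisation and GPR-derived flux correction factors.

Metatranscriptomic read counts are normalised to transcripts per million
(TPM). Per-reaction activity scores f(g~) are obtained by pushing the TPM
values theta(g) through each reaction's GPR tree (AND -> min, a complex is
limited by its scarcest subunit; OR -> sum, isozymes add capacity). Scores
are rescaled by the community-wide maximum M so that f/M in [0, 1] can
multiply a reaction's maximum flux, E-flux style.

Genes that occur in a GPR but are missing from the expression table are
valued 0: metatranscriptomes are sparse, and the growth LP's relaxation
variables exist precisely to rescue reactions silenced by such dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .community import CommunityModel
from .gpr import GprTree

__all__ = [
    "ExpressionProfile",
    "CorrectionFactors",
    "ExpressionError",
    "compute_tpm",
    "evaluate_gpr",
    "correction_factors",
    "read_expression_table",
    "unmatched_genes",
]


class ExpressionError(ValueError):
    """Fatal problem with expression data."""


@dataclass
class ExpressionProfile:
    """Per-sample expression: (member_id, gene_id) -> TPM."""

    sample_id: str
    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if v < 0}
        if bad:
            raise ExpressionError(
                f"sample {self.sample_id!r}: negative TPM for {sorted(bad)[:3]}"
            )

    def theta(self, member_id: str) -> dict[str, float]:
        """Gene -> TPM map restricted to one member."""
        return {g: v for (m, g), v in self.values.items() if m == member_id}


@dataclass
class CorrectionFactors:
    """GPR-derived activity scores for one sample.

    ``raw`` maps (member_id, reaction_id) -> f(g~) for every GPR-bearing
    reaction; ``scale`` is the community-wide maximum M; ``scaled`` is
    raw/M in [0, 1]. Forward and reverse columns of a split reversible
    reaction share one factor (one enzyme catalyses both directions).
    """

    sample_id: str
    raw: dict[tuple[str, str], float]
    scale: float
    scaled: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ExpressionError(
                f"sample {self.sample_id!r}: expression data provide no "
                "constraints (community-wide maximum factor is zero)"
            )
        if not self.scaled:
            self.scaled = {k: v / self.scale for k, v in self.raw.items()}


def compute_tpm(
    counts: dict[str, float], lengths: dict[str, float]
) -> dict[str, float]:
    """Transcripts-per-million from raw counts and gene lengths (bp).

    TPM_g = 1e6 * (count_g / length_g) / sum_h (count_h / length_h).
    All-zero counts yield all-zero TPM.
    """
    missing = [g for g in counts if g not in lengths]
    if missing:
        raise ExpressionError(f"genes with counts but no length: {missing[:5]}")
    bad = [g for g, L in lengths.items() if g in counts and L <= 0]
    if bad:
        raise ExpressionError(f"nonpositive gene lengths: {bad[:5]}")
    rates = {g: counts[g] / lengths[g] for g in counts}
    total = sum(rates.values())
    if total == 0:
        return {g: 0.0 for g in counts}
    return {g: 1e6 * r / total for g, r in rates.items()}


def evaluate_gpr(tree: GprTree, theta: dict[str, float]) -> float:
    """Evaluate a GPR tree against gene expression values.

    leaf -> theta(gene) (0 when absent); AND -> min of children;
    OR -> sum of children. Total and monotone in every theta(g).
    """
    if tree.op == "gene":
        return float(theta.get(tree.gene, 0.0))
    child_vals = [evaluate_gpr(c, theta) for c in tree.children]
    if tree.op == "and":
        return min(child_vals)
    return float(sum(child_vals))


def correction_factors(
    model: CommunityModel, profile: ExpressionProfile
) -> CorrectionFactors:
    """Compute f(g~) for every GPR-bearing reaction and scale by M.

    M is the maximum raw factor across all members of the community (one
    scale per sample). Reactions without a GPR are absent from the result;
    their flux bound stays 0 <= v <= v_max.
    """
    raw: dict[tuple[str, str], float] = {}
    theta_cache: dict[str, dict[str, float]] = {}
    for (member, original_id), tree in model.gpr_reactions().items():
        if member not in theta_cache:
            theta_cache[member] = profile.theta(member)
        raw[(member, original_id)] = evaluate_gpr(tree, theta_cache[member])
    if not raw:
        raise ExpressionError("community model has no GPR-bearing reactions")
    M = max(raw.values())
    if M <= 0:
        raise ExpressionError(
            f"sample {profile.sample_id!r}: expression data provide no "
            "constraints (all GPR scores are zero)"
        )
    return CorrectionFactors(sample_id=profile.sample_id, raw=raw, scale=M)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path, from_counts: bool = False
) -> dict[str, ExpressionProfile]:
    """Read a long-format expression TSV into per-sample profiles.

    Expected columns: ``sample_id, member_id, gene_id, tpm`` — or, with
    ``from_counts=True``, ``sample_id, member_id, gene_id, count,
    length_bp`` (TPM is then computed per sample across all members).
    """
    df = pd.read_csv(path, sep="\t")
    base = {"sample_id", "member_id", "gene_id"}
    if not base <= set(df.columns):
        raise ExpressionError(
            f"expression table {path} must have columns {sorted(base)}"
        )
    profiles: dict[str, ExpressionProfile] = {}
    for sample_id, chunk in df.groupby("sample_id", sort=True):
        keys = list(zip(chunk["member_id"].astype(str),
                        chunk["gene_id"].astype(str)))
        if from_counts:
            if not {"count", "length_bp"} <= set(df.columns):
                raise ExpressionError(
                    "from_counts requires 'count' and 'length_bp' columns"
                )
            uid = [f"{m}\t{g}" for m, g in keys]
            tpm = compute_tpm(
                dict(zip(uid, chunk["count"].astype(float))),
                dict(zip(uid, chunk["length_bp"].astype(float))),
            )
            values = {k: tpm[u] for k, u in zip(keys, uid)}
        else:
            if "tpm" not in df.columns:
                raise ExpressionError("expression table must have a 'tpm' column")
            values = dict(zip(keys, chunk["tpm"].astype(float)))
        profiles[str(sample_id)] = ExpressionProfile(str(sample_id), values)
    return profiles


def unmatched_genes(
    model: CommunityModel, profile: ExpressionProfile
) -> pd.DataFrame:
    """Report expression gene ids that match no model gene, and vice versa.

    Returns a table (member_id, gene_id, status) where status is
    ``expression_only`` or ``model_only``; emits a warning when the
    expression table contains ids absent from the model.
    """
    rows = []
    model_genes = {m: model.genes_of_member(m) for m in model.members}
    expr_genes: dict[str, set[str]] = {}
    for (member, gene) in profile.values:
        expr_genes.setdefault(member, set()).add(gene)
    for member in sorted(set(model_genes) | set(expr_genes)):
        mg = model_genes.get(member, set())
        eg = expr_genes.get(member, set())
        for g in sorted(eg - mg):
            rows.append((member, g, "expression_only"))
        for g in sorted(mg - eg):
            rows.append((member, g, "model_only"))
    report = pd.DataFrame(rows, columns=["member_id", "gene_id", "status"])
    n_extra = int((report["status"] == "expression_only").sum())
    if n_extra:
        warnings.warn(
            f"sample {profile.sample_id!r}: {n_extra} expression gene ids "
            "match no model gene", stacklevel=2)
    return report
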