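"""Teratoma tissue-composition scoring from RNA-seq FPKM profiles.

A teratoma grown from a genuinely pluripotent cell line contains
derivatives of all three embryonic germ layers plus extra-embryonic
membranes.  This module quantifies that from bulk RNA-seq:

* :func:`derive_signature` builds a 100-gene signature of tissue-specific
  genes from a normal-tissue reference panel: each gene must be expressed
  >8-fold higher in its source tissue than the mean of all other tissues
  and >4-fold higher in reference teratomas than in undifferentiated PSCs.
  Central/peripheral nervous system and small intestine/colon are merged
  into single tissue groups.
* :func:`lineage_expression` expresses a sample's signature genes as a
  percentage of their source-tissue reference level and averages per
  tissue group and per lineage.
* :func:`grade` multiplies the four lineage means (ectoderm, mesoderm,
  endoderm, extraembryonic) and divides by 100; a pure tissue annihilates
  the product, a balanced teratoma does not.  A grade above 10 classifies
  the tumor as balanced-trilineage.
* :func:`undiff_marker_screen` reports residual undifferentiated-PSC/yolk
  sac marker expression relative to PSCs and flags samples above the
  cohort mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

LINEAGES = ("ectoderm", "mesoderm", "endoderm", "extraembryonic")

#: Tissue groups whose specific-gene expression is too similar to separate.
DEFAULT_MERGE_MAP = {
    "central_nervous_system": "cns_pns",
    "peripheral_nervous_system": "cns_pns",
    "small_intestine": "intestine",
    "colon": "intestine",
}

SIGNATURE_SIZE = 100
TISSUE_FOLD = 8.0
TERATOMA_FOLD = 4.0
GRADE_THRESHOLD = 10.0
LOW_LINEAGE_PERCENT = 4.0  # lineages below this are flagged as distinctly low


@dataclass
class ExpressionProfile:
    """Gene-level FPKM vector for one sample."""

    values: pd.Series  # gene -> FPKM
    label: str
    role: str  # "teratoma" | "psc" | "tissue"
    tissue: str | None = None
    lineage: str | None = None

    def __post_init__(self):
        if self.role not in ("teratoma", "psc", "tissue"):
            raise InputError(f"unknown role {self.role!r}")
        if (self.values < 0).any():
            raise InputError("FPKM values must be non-negative")
        if self.role == "tissue" and (self.tissue is None or self.lineage is None):
            raise InputError("tissue profiles need tissue and lineage labels")
        if self.lineage is not None and self.lineage not in LINEAGES:
            raise InputError(f"unknown lineage {self.lineage!r}")


@dataclass
class Signature:
    """Tissue-specific signature table.

    ``table`` columns: gene, tissue (source tissue), group (merged tissue
    group), lineage, reference_level (mean FPKM in the source tissue).
    """

    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


@dataclass
class TeratoScoreResult:
    sample: str
    lineage_means: dict[str, float]  # percentage of reference per lineage
    group_means: dict[str, float]
    grade: float
    classification: str  # "balanced-trilineage" | "deficient"
    low_lineages: list[str] = field(default_factory=list)
    undiff_percent: float | None = None


def _tissue_mean_matrix(tissues: list[ExpressionProfile]) -> tuple[pd.DataFrame, dict, dict]:
    by_tissue: dict[str, list[pd.Series]] = {}
    lineage_of: dict[str, str] = {}
    for p in tissues:
        if p.role != "tissue":
            raise InputError(f"profile {p.label!r} is not a tissue profile")
        by_tissue.setdefault(p.tissue, []).append(p.values)
        lineage_of[p.tissue] = p.lineage
    means = pd.DataFrame({t: pd.concat(v, axis=1).mean(axis=1) for t, v in by_tissue.items()})
    counts = {t: len(v) for t, v in by_tissue.items()}
    return means.fillna(0.0), lineage_of, counts


def derive_signature(
    tissues: list[ExpressionProfile],
    teratomas: list[ExpressionProfile],
    pscs: list[ExpressionProfile],
    tissue_fold: float = TISSUE_FOLD,
    teratoma_fold: float = TERATOMA_FOLD,
    size: int = SIGNATURE_SIZE,
    merge_map: dict[str, str] | None = None,
) -> Signature:
    """Double-filtered, round-robin-trimmed tissue-specific signature.

    Rule 1: mean FPKM in the source tissue > ``tissue_fold`` x the mean of
    all other tissues.  Rule 2: mean FPKM in reference teratomas >
    ``teratoma_fold`` x the mean in PSCs.  Candidates are ranked within each
    (merged) tissue group by rule-1 fold and taken round-robin across groups
    until ``size`` genes are collected.
    """
    if not teratomas or not pscs:
        raise InputError("need at least one reference teratoma and one PSC profile")
    merge_map = DEFAULT_MERGE_MAP if merge_map is None else merge_map

    tissue_mean, lineage_of, counts = _tissue_mean_matrix(tissues)
    per_lineage = {}
    for t, lin in lineage_of.items():
        per_lineage.setdefault(lin, []).append(t)
    for lin, ts in per_lineage.items():
        if len(ts) < 2:
            logger.warning("lineage %s represented by only %d tissue(s)", lin, len(ts))

    ter_mean = pd.concat([p.values for p in teratomas], axis=1).mean(axis=1)
    psc_mean = pd.concat([p.values for p in pscs], axis=1).mean(axis=1)

    n_t = tissue_mean.shape[1]
    if n_t < 2:
        raise InputError("need at least 2 tissues to assess specificity")
    total = tissue_mean.sum(axis=1)

    candidates = []
    for t in tissue_mean.columns:
        own = tissue_mean[t]
        other_mean = (total - own) / (n_t - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold1 = own / other_mean
        fold1 = fold1.where(other_mean > 0, np.inf).where(own > 0, 0.0)
        rule1 = fold1 > tissue_fold
        tm = ter_mean.reindex(own.index).fillna(0.0)
        pm = psc_mean.reindex(own.index).fillna(0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold2 = tm / pm
        fold2 = fold2.where(pm > 0, np.inf).where(tm > 0, 0.0)
        rule2 = fold2 > teratoma_fold
        for g in own.index[rule1 & rule2]:
            candidates.append(
                {
                    "gene": g,
                    "tissue": t,
                    "group": merge_map.get(t, t),
                    "lineage": lineage_of[t],
                    "reference_level": float(own[g]),
                    "fold": float(fold1[g]),
                }
            )
    cand = pd.DataFrame(candidates)
    if cand.empty:
        raise InputError("no genes pass both signature rules")
    # a gene specific at >8-fold can qualify for only one tissue, but guard anyway
    cand = cand.sort_values(["fold", "gene"], ascending=[False, True]).drop_duplicates("gene")

    groups = sorted(cand["group"].unique())
    queues = {
        grp: list(
            cand[cand["group"] == grp]
            .sort_values(["fold", "gene"], ascending=[False, True])
            .index
        )
        for grp in groups
    }
    for grp in groups:
        if not queues[grp]:
            logger.warning("tissue group %s contributed no signature genes", grp)

    chosen: list[int] = []
    while len(chosen) < size and any(queues.values()):
        for grp in groups:
            if queues[grp] and len(chosen) < size:
                chosen.append(queues[grp].pop(0))
    if len(chosen) < size:
        logger.warning("signature shortfall: only %d of %d genes available", len(chosen), size)

    table = (
        cand.loc[chosen, ["gene", "tissue", "group", "lineage", "reference_level"]]
        .sort_values(["lineage", "group", "gene"])
        .reset_index(drop=True)
    )
    return Signature(table=table)


@dataclass
class LineageExpression:
    """Per-lineage and per-tissue-group mean percentages for one sample."""

    sample: str
    lineage_means: dict[str, float]
    group_means: dict[str, float]
    n_genes_used: int


def lineage_expression(sample: ExpressionProfile, signature: Signature) -> LineageExpression:
    """Mean percentage of the reference level per tissue group and lineage.

    Per gene: ``100 * FPKM_sample / reference_level``.  Genes with a zero
    reference level are dropped with a warning; at least 80% of signature
    genes must be present in the sample.
    """
    sig = signature.table
    present = sig["gene"].isin(sample.values.index)
    if present.mean() < 0.80:
        missing = sig.loc[~present, "gene"].tolist()
        raise InputError(
            f"sample {sample.label!r} lacks {len(missing)} of {len(sig)} signature genes: "
            f"{missing[:10]}..."
        )
    sig = sig[present].copy()
    zero_ref = sig["reference_level"] <= 0
    if zero_ref.any():
        logger.warning(
            "dropping %d signature genes with zero reference level", int(zero_ref.sum())
        )
        sig = sig[~zero_ref]
    pct = 100.0 * sample.values[sig["gene"]].to_numpy() / sig["reference_level"].to_numpy()
    sig = sig.assign(pct=pct)
    group_means = sig.groupby("group")["pct"].mean().to_dict()
    lineage_means = sig.groupby("lineage")["pct"].mean().to_dict()
    return LineageExpression(
        sample=sample.label,
        lineage_means=lineage_means,
        group_means=group_means,
        n_genes_used=len(sig),
    )


def grade(lineage_means) -> float:
    """Unified grade: product of the four per-lineage mean percentages / 100."""
    if isinstance(lineage_means, dict):
        missing = [lin for lin in LINEAGES if lin not in lineage_means]
        if missing:
            raise InputError(f"missing lineage means for {missing}")
        vals = [float(lineage_means[lin]) for lin in LINEAGES]
    else:
        vals = [float(v) for v in lineage_means]
    if len(vals) != 4:
        raise InputError("grade requires exactly four lineage means")
    if any(v < 0 for v in vals):
        raise InputError("lineage means must be non-negative")
    return math.prod(vals) / 100.0


def classify(
    grade_value: float,
    lineage_means: dict[str, float] | None = None,
    threshold: float = GRADE_THRESHOLD,
    low_percent: float = LOW_LINEAGE_PERCENT,
) -> tuple[str, list[str]]:
    """Balanced-trilineage iff grade > threshold (strict); flags low lineages.

    Returns ``(classification, low_lineages)`` where ``low_lineages`` lists
    lineages expressed below ``low_percent`` of the reference level.
    """
    if grade_value < 0:
        raise InputError("grade must be non-negative")
    classification = "balanced-trilineage" if grade_value > threshold else "deficient"
    low = []
    if lineage_means is not None:
        low = [lin for lin in LINEAGES if lineage_means.get(lin, 0.0) < low_percent]
    return classification, low


def score_sample(
    sample: ExpressionProfile,
    signature: Signature,
    threshold: float = GRADE_THRESHOLD,
) -> TeratoScoreResult:
    """End-to-end scoring of one sample: lineage means, grade, classification."""
    expr = lineage_expression(sample, signature)
    means = {lin: expr.lineage_means.get(lin, 0.0) for lin in LINEAGES}
    g = grade(means)
    classification, low = classify(g, means, threshold=threshold)
    return TeratoScoreResult(
        sample=sample.label,
        lineage_means=means,
        group_means=expr.group_means,
        grade=g,
        classification=classification,
        low_lineages=low,
    )


def undiff_marker_screen(
    samples: list[ExpressionProfile],
    pscs: list[ExpressionProfile],
    panel: list[str],
) -> pd.DataFrame:
    """Residual undifferentiated-marker expression relative to PSCs.

    Per sample: mean over the marker panel of ``100 * FPKM / mean PSC FPKM``.
    Samples whose percentage strictly exceeds the cohort mean are flagged.
    """
    if not samples:
        raise InputError("empty sample cohort")
    if not pscs:
        raise InputError("need at least one PSC reference profile")
    psc_mean = pd.concat([p.values for p in pscs], axis=1).mean(axis=1)
    missing = [g for g in panel if g not in psc_mean.index or psc_mean[g] <= 0]
    if missing:
        raise InputError(f"panel genes absent or zero in the PSC reference: {missing}")
    ref = psc_mean[list(panel)]
    rows = []
    for s in samples:
        vals = s.values.reindex(list(panel)).fillna(0.0)
        rows.append({"sample": s.label, "undiff_percent": float((100.0 * vals / ref).mean())})
    out = pd.DataFrame(rows)
    cohort_mean = out["undiff_percent"].mean()
    out["flagged"] = out["undiff_percent"] > cohort_mean
    out.attrs["cohort_mean"] = float(cohort_mean)
    return out
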