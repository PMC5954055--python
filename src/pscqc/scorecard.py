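"""Embryoid-body lineage scorecard from a 190-gene qPCR panel.

PSC lines are differentiated as embryoid bodies under a neutral condition
and under ectoderm-, mesoderm- and endoderm-directed conditions, with qPCR
cycle-threshold (Ct) measurements at days 0/4/10/16.  The pipeline:

* :func:`qc_filter` drops low-quality samples (<33% of the expected panel
  detected).
* :func:`normalize` caps Ct at 35, scales to the control genes
  (ACTB, GAPDH), quantile-normalizes across samples, and inverts so that
  larger values mean stronger expression.
* :func:`select_markers` picks 15 marker genes per lineage by ranking the
  day-16 vs day-0 expression change per condition (median rank across cell
  lines), plus 15 consistently down-regulated genes as markers of the
  undifferentiated state.
* :func:`moderated_t` computes empirical-Bayes moderated t-statistics
  (per-gene variances shrunk toward a prior fitted by method of moments on
  the log sample variances).
* :func:`lineage_score` is a parametric (PAGE-style) gene-set enrichment
  z-score of a marker set within the t-ordered gene list.
* :func:`build_scorecard` assembles per-(line, lineage) "potential"
  (directed condition) and "propensity" (neutral condition) scores with
  categorical grades: +++ (>3), ++ (2-3), + (1-2), +/- (<1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .errors import EmptyResultError, InputError, PanelError

logger = logging.getLogger(__name__)

CONTROL_GENES = ("ACTB", "GAPDH")
DIRECTED_CONDITIONS = ("ectoderm", "mesoderm", "endoderm")
CONDITIONS = ("neutral",) + DIRECTED_CONDITIONS
CT_CAP = 35.0
MARKERS_PER_SET = 15


@dataclass
class CtMatrix:
    """Long-format qPCR Ct measurements with per-sample metadata.

    ``data`` columns: gene, sample, ct (NaN marks a non-detect — deliberately
    distinct from a capped Ct of 35, because the detected-fraction QC rule
    and the cap are different rules).  ``samples`` is indexed by sample label
    with columns line, condition, day, replicate.  ``panel`` is the full
    expected gene panel used by the QC rule.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    panel: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.data["sample"].unique()) - set(self.samples.index)
        if missing:
            raise InputError(f"samples without metadata: {sorted(missing)[:5]}")

    def detected_fraction(self) -> pd.Series:
        """Fraction of the expected panel detected (non-NaN Ct) per sample."""
        det = self.data.dropna(subset=["ct"]).groupby("sample")["gene"].nunique()
        det = det.reindex(self.samples.index, fill_value=0)
        return det / len(self.panel)


@dataclass
class NormalizedExpressionMatrix:
    """Inverted, normalized expression (genes x samples); higher = more expressed.

    All values lie in [0, cap].  ``provenance`` records each normalization
    step including the affine map used to return quantile-normalized values
    to the [0, cap] scale before inversion.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict
    cap: float = CT_CAP


@dataclass
class MarkerSets:
    """Four pairwise-disjoint sets of 15 marker genes."""

    ectoderm: list[str]
    mesoderm: list[str]
    endoderm: list[str]
    undifferentiated: list[str]

    def __post_init__(self):
        sets = self.as_dict()
        for name, genes in sets.items():
            if len(genes) != len(set(genes)):
                raise InputError(f"duplicate genes inside marker set {name}")
        all_genes = sum(sets.values(), [])
        if len(all_genes) != len(set(all_genes)):
            raise InputError("marker sets must be pairwise disjoint")

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "ectoderm": list(self.ectoderm),
            "mesoderm": list(self.mesoderm),
            "endoderm": list(self.endoderm),
            "undifferentiated": list(self.undifferentiated),
        }


@dataclass
class LineageScorecard:
    """Per (cell line, lineage) potential/propensity scores and grades.

    ``table`` columns: line, lineage, potential, potential_grade,
    propensity, propensity_grade.  Scores are NaN and grades "nd" where the
    required condition/day combination is missing.
    """

    table: pd.DataFrame


def qc_filter(matrix: CtMatrix, min_detected_fraction: float = 0.33) -> CtMatrix:
    """Remove samples detecting less than ``min_detected_fraction`` of the panel.

    The rule is a strict less-than: a sample at exactly the threshold is
    retained.
    """
    frac = matrix.detected_fraction()
    bad = frac.index[frac < min_detected_fraction]
    for s in bad:
        logger.info("QC: removing sample %s (%.1f%% of panel detected)", s, 100 * frac[s])
    keep = frac.index[frac >= min_detected_fraction]
    if len(keep) == 0:
        raise EmptyResultError(
            "qc_filter", f"all samples below the {min_detected_fraction:.0%} detection threshold"
        )
    return CtMatrix(
        data=matrix.data[matrix.data["sample"].isin(keep)].reset_index(drop=True),
        samples=matrix.samples.loc[keep],
        panel=list(matrix.panel),
        meta=dict(matrix.meta),
    )


# ---------------------------------------------------------------- normalization

def cap_values(wide: pd.DataFrame, cap: float = CT_CAP) -> pd.DataFrame:
    """Cap Ct values at ``cap`` and set non-detects (NaN) to ``cap``."""
    return wide.clip(upper=cap).fillna(cap)


def delta_ct_scale(wide: pd.DataFrame, control_genes=CONTROL_GENES) -> pd.DataFrame:
    """Per sample, subtract the mean Ct of the control genes (delta-Ct)."""
    missing = [g for g in control_genes if g not in wide.index]
    if missing:
        raise PanelError(f"control genes missing from the panel: {missing}")
    control_mean = wide.loc[list(control_genes)].mean(axis=0)
    return wide.sub(control_mean, axis=1)


def quantile_normalize(wide: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean empirical distribution.

    Target distribution = mean of the sorted per-sample vectors; tied input
    values within a sample share the average of their assigned targets.
    """
    X = wide.to_numpy(dtype=float)
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        qn = np.empty(len(target))
        qn[order] = target
        out[:, j] = pd.Series(qn).groupby(X[:, j]).transform("mean").to_numpy()
    return pd.DataFrame(out, index=wide.index, columns=wide.columns)


def normalize(
    matrix: CtMatrix,
    cap: float = CT_CAP,
    control_genes=CONTROL_GENES,
) -> NormalizedExpressionMatrix:
    """Cap, delta-Ct scale, quantile-normalize, then invert onto [0, cap].

    Step 4 first maps the quantile-normalized values onto [0, cap] by an
    affine transformation (recorded in provenance) and then inverts them as
    ``cap - value`` so that larger numbers represent stronger expression.
    """
    for s, grp in matrix.data.groupby("sample"):
        detected = set(grp.dropna(subset=["ct"])["gene"])
        lacking = [g for g in control_genes if g not in detected]
        if lacking:
            raise PanelError(f"sample {s!r} is missing control gene(s) {lacking}")

    wide = matrix.data.pivot_table(index="gene", columns="sample", values="ct", dropna=False)
    wide = wide[matrix.samples.index.intersection(wide.columns)]

    capped = cap_values(wide, cap=cap)
    delta = delta_ct_scale(capped, control_genes=control_genes)
    qn = quantile_normalize(delta)

    lo, hi = float(qn.to_numpy().min()), float(qn.to_numpy().max())
    scale = cap / (hi - lo) if hi > lo else 0.0
    rescaled = (qn - lo) * scale
    inverted = cap - rescaled

    provenance = {
        "cap": cap,
        "control_genes": tuple(control_genes),
        "affine": {"offset": lo, "scale": scale},
        "steps": ["cap", "delta_ct", "quantile_normalize", "affine_rescale+invert"],
    }
    return NormalizedExpressionMatrix(
        values=inverted, samples=matrix.samples.copy(), provenance=provenance, cap=cap
    )


# ------------------------------------------------------------- marker selection

def _condition_ranks(
    norm: NormalizedExpressionMatrix,
    genes: list[str],
    condition: str,
    day: int = 16,
    baseline_day: int = 0,
) -> pd.Series:
    """Median across lines of the per-line gene ranks (1 = largest increase)."""
    meta = norm.samples
    ranks_by_line = []
    for line in meta["line"].unique():
        grp = meta[(meta["line"] == line) & (meta["condition"] == condition) & (meta["day"] == day)]
        base = meta[(meta["line"] == line) & (meta["day"] == baseline_day)]
        if grp.empty or base.empty:
            continue
        change = (
            norm.values.loc[genes, grp.index].mean(axis=1)
            - norm.values.loc[genes, base.index].mean(axis=1)
        )
        order = sorted(genes, key=lambda g: (-change[g], g))
        ranks_by_line.append(pd.Series(np.arange(1, len(genes) + 1), index=order))
    if not ranks_by_line:
        raise InputError(f"no (day {day}, day {baseline_day}) data for condition {condition!r}")
    return pd.concat(ranks_by_line, axis=1).median(axis=1)


def select_markers(
    norm: NormalizedExpressionMatrix,
    n_per_set: int = MARKERS_PER_SET,
    control_genes=CONTROL_GENES,
) -> MarkerSets:
    """Rank-based marker selection, 15 genes per lineage plus 15 undifferentiated.

    Per directed condition, genes are ranked by day-16 minus day-0 expression
    change within each line (rank 1 = largest increase) and the median rank
    across lines taken; the top ``n_per_set`` become that lineage's markers.
    A gene topping several conditions is assigned to the condition where its
    median rank is best; runner-up sets move to the next-ranked gene, which
    keeps the four sets disjoint.  The undifferentiated set is the
    ``n_per_set`` genes most consistently *down*-regulated across all four
    conditions.  Control genes are excluded a priori.
    """
    genes = [g for g in norm.values.index if g not in set(control_genes)]
    if len(genes) < 4 * n_per_set:
        raise InputError(
            f"need at least {4 * n_per_set} eligible genes, have {len(genes)}"
        )

    med_rank = {c: _condition_ranks(norm, genes, c) for c in DIRECTED_CONDITIONS}
    try:
        neutral_rank = _condition_ranks(norm, genes, "neutral")
        all_ranks = pd.concat([neutral_rank, *med_rank.values()], axis=1)
    except InputError:
        all_ranks = pd.concat(list(med_rank.values()), axis=1)

    order = {
        c: sorted(genes, key=lambda g: (med_rank[c][g], g)) for c in DIRECTED_CONDITIONS
    }
    assigned: dict[str, str] = {}  # gene -> condition
    while True:
        picks = {}
        for c in DIRECTED_CONDITIONS:
            avail = [g for g in order[c] if assigned.get(g, c) == c]
            picks[c] = avail[:n_per_set]
        contested = {}
        for c, gs in picks.items():
            for g in gs:
                contested.setdefault(g, []).append(c)
        conflicts = {g: cs for g, cs in contested.items() if len(cs) > 1}
        if not conflicts:
            break
        for g, cs in conflicts.items():
            winner = min(cs, key=lambda c: (med_rank[c][g], DIRECTED_CONDITIONS.index(c)))
            assigned[g] = winner

    directed = {c: picks[c] for c in DIRECTED_CONDITIONS}
    taken = set().union(*directed.values())

    # Most consistently decreased = largest mean rank when rank 1 is the
    # largest increase.
    mean_rank = all_ranks.mean(axis=1)
    undiff = sorted(
        (g for g in genes if g not in taken), key=lambda g: (-mean_rank[g], g)
    )[:n_per_set]

    return MarkerSets(
        ectoderm=directed["ectoderm"],
        mesoderm=directed["mesoderm"],
        endoderm=directed["endoderm"],
        undifferentiated=undiff,
    )


# ------------------------------------------------------------------ moderated t

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    Uses the scaled-F model for the moderated t: the log sample variances
    have mean ``log s0^2 + psi(df/2) - log(df/2) - (psi(d0/2) - log(d0/2))``
    and excess variance ``psi'(d0/2)`` beyond the sampling term
    ``psi'(df/2)``.  Returns ``d0 = inf`` when the observed spread is no
    larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s02 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class ModeratedTResult:
    t: pd.Series  # per-gene moderated t
    prior_df: float
    prior_s2: float
    residual_df: float

    @property
    def total_df(self) -> float:
        return self.prior_df + self.residual_df


def moderated_t(
    matrix,
    group_a,
    group_b,
    prior_df: float | None = None,
    prior_s2: float | None = None,
) -> ModeratedTResult:
    """Two-group moderated t per gene: (mean A - mean B) / (s~ * sqrt(1/nA + 1/nB)).

    ``s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)`` with the prior ``(d0, s0^2)``
    fitted by :func:`fit_variance_prior` unless overridden via ``prior_df`` /
    ``prior_s2`` (``prior_df=0`` recovers the ordinary pooled t,
    ``prior_df=inf`` the full-shrinkage limit).

    ``matrix`` may be a :class:`NormalizedExpressionMatrix` or a plain
    genes x samples DataFrame.
    """
    X = matrix.values if isinstance(matrix, NormalizedExpressionMatrix) else matrix
    A = X[list(group_a)]
    B = X[list(group_b)]
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < 2 or n_b < 2:
        raise InputError("each group needs at least 2 samples")
    df = n_a + n_b - 2

    rss = ((A.sub(A.mean(axis=1), axis=0)) ** 2).sum(axis=1) + (
        (B.sub(B.mean(axis=1), axis=0)) ** 2
    ).sum(axis=1)
    s2 = rss / df

    if prior_df is None:
        if (s2 <= 0).all():
            logger.warning("zero within-group variance everywhere; falling back to ordinary t")
            d0, s02 = 0.0, 0.0
        else:
            d0, s02 = fit_variance_prior(s2.to_numpy(), df)
    else:
        d0 = float(prior_df)
        s02 = float(prior_s2) if prior_s2 is not None else float(np.median(s2[s2 > 0]))

    if np.isinf(d0):
        s2_tilde = pd.Series(s02, index=s2.index)
    else:
        s2_tilde = (d0 * s02 + df * s2) / (d0 + df)

    diff = A.mean(axis=1) - B.mean(axis=1)
    denom = np.sqrt(s2_tilde * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    return ModeratedTResult(t=t, prior_df=d0, prior_s2=s02, residual_df=float(df))


def lineage_score(t_scores: pd.Series, markers) -> float:
    """Parametric (PAGE-style) enrichment z-score of a marker set.

    ``(mean t over markers - mean t over all genes) * sqrt(m) / sd(t)``,
    with the population standard deviation of the full t vector.  The sign
    carries direction (positive = markers up-regulated).
    """
    markers = list(markers)
    if not markers:
        raise InputError("marker set is empty")
    missing = [m for m in markers if m not in t_scores.index]
    if missing:
        raise InputError(f"markers missing from scored genes: {missing[:5]}")
    sd = float(t_scores.std(ddof=0))
    if sd == 0:
        raise InputError("t-scores have zero spread; enrichment undefined")
    return float(
        (t_scores[markers].mean() - t_scores.mean()) * np.sqrt(len(markers)) / sd
    )


GRADE_BINS = "+++: score >3; ++: score 2-3; +: score 1-2 (2 excluded); +/-: score <1"


def grade_for_score(score: float) -> str:
    """Deterministic grade bins: >3 '+++', [2,3] '++', [1,2) '+', <1 '+/-'."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "nd"
    if score > 3:
        return "+++"
    if score >= 2:
        return "++"
    if score >= 1:
        return "+"
    return "+/-"


def build_scorecard(
    norm: NormalizedExpressionMatrix,
    markers: MarkerSets,
    day: int = 16,
    baseline_day: int = 0,
) -> LineageScorecard:
    """Potential and propensity scores per (cell line, lineage).

    Potential: lineage score of the lineage's markers on moderated t of
    (line, matched directed condition, day 16) vs the pooled day-0 baseline.
    Propensity: the same under the neutral condition.  Missing
    condition/day combinations yield an ``nd`` (not analyzed) entry.
    """
    meta = norm.samples
    baseline = meta.index[meta["day"] == baseline_day]
    if len(baseline) < 2:
        raise InputError(f"need >= 2 baseline (day {baseline_day}) samples")

    marker_sets = markers.as_dict()
    rows = []
    for line in meta["line"].unique():
        for lineage in DIRECTED_CONDITIONS:
            row = {"line": line, "lineage": lineage}
            for kind, condition in (("potential", lineage), ("propensity", "neutral")):
                grp = meta.index[
                    (meta["line"] == line)
                    & (meta["condition"] == condition)
                    & (meta["day"] == day)
                ]
                if len(grp) < 2:
                    row[kind] = np.nan
                    row[f"{kind}_grade"] = "nd"
                    continue
                t = moderated_t(norm, grp, baseline).t
                score = lineage_score(t, marker_sets[lineage])
                row[kind] = score
                row[f"{kind}_grade"] = grade_for_score(score)
            rows.append(row)
    return LineageScorecard(table=pd.DataFrame(rows))
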