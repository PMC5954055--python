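"""Projection-based pluripotency scoring with H9 platform-shift correction.

The classifier compares a sample transcriptome to a trained low-rank model
of pluripotent and differentiated expression: component weights summarize
how "pluripotent" the profile looks (Pluripotency Score), while the
reconstruction residual measures expression the model cannot explain
(Novelty Score).  When the assay platform changes, the whole dataset shifts
relative to the training data; the correction used here subtracts a shift
vector — the difference between the row-wise mean of the current study's H9
reference-line samples and the model's stored H9 reference profile.  Since
the corrected data are no longer non-negative, component weights are
estimated by ordinary least squares (the non-negativity constraint of the
original multiplicative NMF update is relaxed).

Default thresholds: Pluripotency >= 20 to pass, Novelty >= 1.67 to flag.
The trained model is an input (see :class:`ProjectionModel` and the toy
model built by :func:`pscqc.synthetic.gen_projection_model`); the novelty
calibration mapping residuals onto the published scale is the identity by
default and configurable per model file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError

PLURIPOTENCY_THRESHOLD = 20.0
NOVELTY_THRESHOLD = 1.67


@dataclass
class ProjectionModel:
    """Trained projection model: basis, score weights, H9 reference, thresholds."""

    basis: pd.DataFrame  # genes x k, non-negative components
    score_weights: pd.Series  # length k
    h9_reference: pd.Series  # gene-length profile
    pluripotency_threshold: float = PLURIPOTENCY_THRESHOLD
    novelty_threshold: float = NOVELTY_THRESHOLD
    novelty_calibration: tuple[float, float] = (0.0, 1.0)  # (intercept, slope)

    def __post_init__(self):
        if len(self.score_weights) != self.basis.shape[1]:
            raise InputError("score_weights length must match the basis column count")
        if not self.basis.index.equals(self.h9_reference.index):
            raise InputError("basis and h9_reference gene labels must align")
        if np.linalg.matrix_rank(self.basis.to_numpy()) < self.basis.shape[1]:
            raise InputError("basis is rank-deficient")

    @property
    def genes(self) -> pd.Index:
        return self.basis.index


@dataclass(frozen=True)
class PluriTestResult:
    sample: str
    pluripotency: float
    novelty: float
    classification: str  # pass | flag-novelty | flag-pluripotency | flag-both


def _align(profile: pd.Series, model: ProjectionModel, min_overlap: float = 0.95) -> pd.Index:
    common = model.genes.intersection(profile.index)
    if len(common) == 0:
        raise AlignmentError("no overlapping genes between profile and model")
    if len(common) / len(model.genes) < min_overlap:
        raise AlignmentError(
            f"only {len(common)}/{len(model.genes)} model genes present "
            f"(< {min_overlap:.0%} overlap)"
        )
    return common


def compute_shift_vector(study_h9, model: ProjectionModel) -> pd.Series:
    """Row-wise mean of the study's H9 profiles minus the model's H9 reference."""
    if isinstance(study_h9, pd.DataFrame):
        profiles = [study_h9[c] for c in study_h9.columns]
    elif isinstance(study_h9, pd.Series):
        profiles = [study_h9]
    else:
        profiles = list(study_h9)
    if not profiles:
        raise InputError("need at least one study H9 profile")
    stacked = pd.concat(profiles, axis=1)
    common = _align(stacked.mean(axis=1), model)
    return stacked.loc[common].mean(axis=1) - model.h9_reference.loc[common]


def project(
    sample: pd.Series,
    model: ProjectionModel,
    shift: pd.Series | None = None,
) -> tuple[pd.Series, float]:
    """Unconstrained least-squares projection of a (shift-corrected) sample.

    Returns ``(weights, residual_rms)`` where ``weights`` solves
    ``argmin_h ||x' - B h||_2`` on the aligned gene set and ``residual_rms``
    is the root-mean-square elementwise residual.
    """
    common = _align(sample, model)
    x = sample.loc[common].to_numpy(dtype=float)
    if shift is not None:
        x = x - shift.reindex(common).fillna(0.0).to_numpy()
    B = model.basis.loc[common].to_numpy(dtype=float)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise InputError("basis is rank-deficient on the aligned gene set")
    h, _, _, _ = np.linalg.lstsq(B, x, rcond=None)
    resid = x - B @ h
    rms = float(np.sqrt(np.mean(resid**2)))
    return pd.Series(h, index=model.basis.columns), rms


def score_and_classify(
    weights: pd.Series,
    residual: float,
    model: ProjectionModel,
    sample: str = "",
) -> PluriTestResult:
    """Map projection weights and residual to scores and a pass/flag call.

    Pluripotency = score_weights . weights; Novelty = the model's (affine,
    identity by default) calibration of the residual RMS.  A sample passes
    iff pluripotency >= theta_P and novelty < theta_N; both comparisons
    follow the published ">=" convention for flagging.
    """
    pluripotency = float(model.score_weights @ weights.reindex(model.score_weights.index))
    a, b = model.novelty_calibration
    novelty = float(a + b * residual)
    low_pluri = pluripotency < model.pluripotency_threshold
    high_novelty = novelty >= model.novelty_threshold
    if low_pluri and high_novelty:
        classification = "flag-both"
    elif high_novelty:
        classification = "flag-novelty"
    elif low_pluri:
        classification = "flag-pluripotency"
    else:
        classification = "pass"
    return PluriTestResult(
        sample=sample, pluripotency=pluripotency, novelty=novelty, classification=classification
    )


def replicate_report(
    results: dict[str, list[PluriTestResult]],
    novelty_delta: float = 0.5,
) -> pd.DataFrame:
    """Line-level calls from per-replicate results.

    A line passes when any replicate passes; lines whose replicates are all
    flagged are reported for further investigation.  Replicate disagreement
    (novelty spread above ``novelty_delta``) is annotated either way.
    """
    rows = []
    for line, reps in results.items():
        if not reps:
            raise InputError(f"line {line!r} has no replicates")
        any_pass = any(r.classification == "pass" for r in reps)
        novelties = [r.novelty for r in reps]
        spread = max(novelties) - min(novelties)
        rows.append(
            {
                "line": line,
                "n_replicates": len(reps),
                "call": "pass" if any_pass else "investigate",
                "novelty_spread": spread,
                "replicate_disagreement": spread > novelty_delta,
                "classifications": ";".join(r.classification for r in reps),
            }
        )
    return pd.DataFrame(rows)
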