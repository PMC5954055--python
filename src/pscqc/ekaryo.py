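"""Expression-based karyotyping (e-Karyotyping).

Chromosomal gains and losses leave a regional footprint in expression
microarray data: a trisomy raises the intensity of (nearly) every probe on
the affected chromosome by roughly ``log2(3/2)`` on the log2 scale, and a
mosaic gain carried by a fraction ``f`` of cells by
``log2(((1 - f) * 2 + f * 2 * fc) / 2)``.  The pipeline here makes that
footprint visible and testable:

1. :func:`preprocess` — floor low intensities at the boundary of the top
   third of the pooled distribution, remove probes that are unexpressed in
   too many samples, median-center each probe across samples, and drop the
   most variable probes (which would otherwise dominate regional averages).
2. :func:`moving_average` — a 300-gene sliding mean along each chromosome,
   the classic comparative-genomic-hybridization style readout.
3. :func:`call_aberrations` — a permutation test that replaces visual
   inspection of the moving-average plot with reproducible per-chromosome
   calls (Bonferroni-corrected within each sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import chrom_sort_key
from .errors import AnnotationError, EmptyResultError, InputError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 300  # probes per moving-average window


@dataclass
class ProbeExpressionMatrix:
    """Log2 probe intensities (probes x samples) with genomic annotation.

    ``annotation`` is indexed like ``values`` and has columns ``chromosome``
    (string label, NaN when the probe is unannotated) and ``position``
    (ordinal genomic coordinate).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self):
        missing = self.values.index.difference(self.annotation.index)
        if len(missing):
            raise AnnotationError(
                f"{len(missing)} probes have no annotation row (e.g. {missing[0]!r})"
            )
        self.annotation = self.annotation.loc[self.values.index]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RelativeExpressionMatrix:
    """Median-centered log2 expression after preprocessing.

    Probes are sorted by (chromosome, position); every retained probe has a
    cross-sample median of zero.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    floor_threshold: float


@dataclass
class MovingAverageTrack:
    """Sliding-window means per (sample, chromosome).

    ``data`` columns: sample, chromosome, start, end (ordinal probe indices
    within the chromosome, end exclusive), position (genomic position of the
    window's central probe) and mean.  ``source`` keeps the relative matrix
    the track was computed from so that permutation nulls can be built
    without re-plumbing the probe values.
    """

    data: pd.DataFrame
    window: int
    source: RelativeExpressionMatrix | None = field(default=None, repr=False)


@dataclass(frozen=True)
class ChromosomeCall:
    sample: str
    chromosome: str
    mean_deviation: float  # log2 units, mean of window means
    p_value: float  # raw two-sided permutation tail probability
    direction: str  # "gain" or "loss"


def preprocess(
    matrix: ProbeExpressionMatrix,
    presence_fraction: float = 0.20,
    variability_fraction: float = 0.10,
) -> RelativeExpressionMatrix:
    """Prepare a probe matrix for regional averaging.

    Steps, in order: (1) drop unannotated probes; (2) floor all values at the
    boundary of the top third of the pooled log2 distribution; (3) drop
    probes whose pre-floor value fell below the floor in more than
    ``presence_fraction`` of samples; (4) subtract each probe's cross-sample
    median; (5) drop the ``variability_fraction`` most variable probes by sum
    of squared relative values (ties broken by probe label); (6) sort by
    chromosome and position.
    """
    if matrix.values.shape[1] < 2:
        raise InputError("preprocess requires at least 2 samples")

    ann = matrix.annotation
    keep = ann["chromosome"].notna()
    values = matrix.values.loc[keep]
    ann = ann.loc[keep]
    if values.empty:
        raise EmptyResultError("annotation removal")

    floor = float(np.quantile(values.to_numpy().ravel(), 2.0 / 3.0))
    below = values < floor
    floored = values.clip(lower=floor)

    expressed_ok = below.mean(axis=1) <= presence_fraction
    floored = floored.loc[expressed_ok]
    ann = ann.loc[expressed_ok]
    if floored.empty:
        raise EmptyResultError("presence filter")

    rel = floored.sub(floored.median(axis=1), axis=0)

    n_drop = int(round(variability_fraction * len(rel)))
    if n_drop:
        ss = (rel**2).sum(axis=1)
        order = sorted(rel.index, key=lambda p: (-ss[p], p))
        rel = rel.drop(index=order[:n_drop])
        ann = ann.loc[rel.index]
    if rel.empty:
        raise EmptyResultError("variability filter")

    order = sorted(
        rel.index,
        key=lambda p: (chrom_sort_key(ann.at[p, "chromosome"]), ann.at[p, "position"], p),
    )
    rel = rel.loc[order]
    ann = ann.loc[order]
    return RelativeExpressionMatrix(values=rel, annotation=ann, floor_threshold=floor)


def moving_average(rel: RelativeExpressionMatrix, window: int = DEFAULT_WINDOW) -> MovingAverageTrack:
    """Sliding-window (stride 1) means per sample along each chromosome.

    Chromosomes with fewer probes than ``window`` yield no windows; a warning
    is logged for each.
    """
    if window < 1:
        raise InputError("window must be >= 1")

    frames = []
    for chrom, idx in rel.annotation.groupby("chromosome", sort=False).groups.items():
        block = rel.values.loc[idx]
        n = len(block)
        if n < window:
            logger.warning("chromosome %s has %d probes < window %d; empty track", chrom, n, window)
            continue
        means = block.rolling(window).mean().iloc[window - 1 :]
        centers = rel.annotation.loc[idx, "position"].to_numpy()
        center_pos = centers[(window - 1) // 2 : (window - 1) // 2 + len(means)]
        for sample in block.columns:
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chromosome": str(chrom),
                        "start": np.arange(len(means)),
                        "end": np.arange(len(means)) + window,
                        "position": center_pos,
                        "mean": means[sample].to_numpy(),
                    }
                )
            )
    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["sample", "chromosome", "start", "end", "position", "mean"])
    )
    return MovingAverageTrack(data=data, window=window, source=rel)


def _window_weights(n_probes: int, window: int) -> np.ndarray:
    """Weights turning 'mean of all window means' into a single dot product.

    Probe i belongs to ``min(i, w-1, m-1, n-1-i) + 1`` of the ``m = n-w+1``
    windows; dividing by ``m*w`` gives weights summing to 1.
    """
    i = np.arange(n_probes)
    m = n_probes - window + 1
    counts = np.minimum.reduce([i + 1, np.full(n_probes, window), np.full(n_probes, m), n_probes - i]) # noqa: E501
    return counts / (m * window)


def aberration_scan(
    track: MovingAverageTrack,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values for every (sample, chromosome) with windows.

    The statistic is the mean of window means (equivalently a weighted probe
    mean).  The null permutes the probe-to-position assignment within the
    sample ``n_permutations`` times; p-values are two-sided tail
    probabilities with the +1 correction.
    """
    if track.source is None:
        raise InputError("track has no source matrix; recompute it with moving_average()")
    if track.data.empty:
        raise InputError("track is empty")
    if n_permutations < 100:
        logger.warning("n_permutations=%d < 100; p-values will be coarse", n_permutations)

    rel = track.source
    chroms = [c for c in track.data["chromosome"].unique()]
    n_total = len(rel.values)

    # probe-slot -> chromosome weight matrix (n_total x n_chrom)
    W = np.zeros((n_total, len(chroms)))
    pos_of = {p: i for i, p in enumerate(rel.values.index)}
    for j, chrom in enumerate(chroms):
        idx = rel.annotation.index[rel.annotation["chromosome"] == chrom]
        slots = np.array([pos_of[p] for p in idx])
        W[slots, j] = _window_weights(len(slots), track.window)

    rng = np.random.default_rng(seed)
    rows = []
    X = rel.values.to_numpy()
    for s_i, sample in enumerate(rel.values.columns):
        x = X[:, s_i]
        obs = x @ W
        exceed = np.zeros(len(chroms), dtype=int)
        chunk = max(1, min(n_permutations, int(2e7 // max(n_total, 1))))
        done = 0
        while done < n_permutations:
            k = min(chunk, n_permutations - done)
            shuffled = np.tile(x, (k, 1))
            rng.permuted(shuffled, axis=1, out=shuffled)
            null = shuffled @ W
            exceed += (np.abs(null) >= np.abs(obs)).sum(axis=0)
            done += k
        pvals = (1 + exceed) / (n_permutations + 1)
        for j, chrom in enumerate(chroms):
            rows.append(
                {
                    "sample": sample,
                    "chromosome": chrom,
                    "mean_deviation": obs[j],
                    "p_value": pvals[j],
                    "n_chromosomes": len(chroms),
                }
            )
    return pd.DataFrame(rows)


def call_aberrations(
    track: MovingAverageTrack,
    n_permutations: int = 1000,
    alpha: float = 0.01,
    seed: int | None = None,
) -> list[ChromosomeCall]:
    """Per-chromosome gain/loss calls at Bonferroni-corrected level ``alpha``."""
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    scan = aberration_scan(track, n_permutations=n_permutations, seed=seed)
    calls = []
    for _, row in scan.iterrows():
        if row["p_value"] * row["n_chromosomes"] <= alpha:
            calls.append(
                ChromosomeCall(
                    sample=row["sample"],
                    chromosome=row["chromosome"],
                    mean_deviation=float(row["mean_deviation"]),
                    p_value=float(row["p_value"]),
                    direction="gain" if row["mean_deviation"] > 0 else "loss",
                )
            )
    return calls
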