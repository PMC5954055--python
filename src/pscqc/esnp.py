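"""eSNP-karyotyping: chromosomal aberrations from allelic imbalance.

A diploid heterozygous SNP expresses its two alleles at roughly equal
levels, so the major/minor read-count ratio hovers just above 1 (it exceeds
1 even under perfect balance because the ratio is max/min of a binomial
draw).  A trisomy breaks the symmetry: the duplicated haplotype contributes
2 of 3 copies, the expected allele fraction becomes 2/3, and the ratio
concentrates near 2.  Sliding medians of the ratio along each chromosome
(window of 151 SNPs) smooth the heavy-tailed per-SNP ratios into a track
whose elevation is the aberration signal.

Because the null ratio depends on read depth, imbalance is called against a
permutation null assembled from the *other* chromosomes of the same sample
rather than against a fixed cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import chrom_sort_key
from .errors import InputError
from .ekaryo import ChromosomeCall

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 151  # SNPs per moving-median window
DEFAULT_MIN_DEPTH = 20  # "<20 transcripts discarded"
DEFAULT_MIN_MINOR = 3  # heterozygosity proxy


@dataclass
class SnpAlleleTable:
    """Per-SNP allele read counts for one sample.

    ``data`` columns: chromosome, position (1-based), ref_count, alt_count.
    Rows are kept sorted by (chromosome, position).
    """

    data: pd.DataFrame
    sample: str

    def __post_init__(self):
        d = self.data
        if (d[["ref_count", "alt_count"]].to_numpy() < 0).any():
            raise InputError("allele counts must be non-negative")
        order = sorted(
            d.index, key=lambda i: (chrom_sort_key(d.at[i, "chromosome"]), d.at[i, "position"])
        )
        self.data = d.loc[order].reset_index(drop=True)


@dataclass
class AllelicRatioTrack:
    """Moving medians of major/minor ratios along each chromosome.

    ``data`` columns: chromosome, position (windowed median of positions),
    ratio (windowed median of per-SNP major/minor ratios).  ``source`` keeps
    the filtered SNP table the track was computed from so the permutation
    null in :func:`call_imbalance` can resample per-SNP ratios.
    """

    data: pd.DataFrame
    sample: str
    window: int
    source: "SnpAlleleTable | None" = None


def major_minor_ratio(count_a, count_b):
    """max/min of the two allele counts; vectorized; always >= 1.

    Both counts must be >= 1 — zero minor counts are uninformative for
    imbalance and must be removed by :func:`filter_snps` first.
    """
    a = np.asarray(count_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    if (np.minimum(a, b) <= 0).any():
        raise InputError("major_minor_ratio requires both allele counts >= 1")
    out = np.maximum(a, b) / np.minimum(a, b)
    return float(out) if out.ndim == 0 else out


def filter_snps(
    table: SnpAlleleTable,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_minor_count: int = DEFAULT_MIN_MINOR,
) -> SnpAlleleTable:
    """Keep SNPs with total depth >= min_depth and minor count >= min_minor_count."""
    d = table.data
    depth = d["ref_count"] + d["alt_count"]
    minor = d[["ref_count", "alt_count"]].min(axis=1)
    kept = d[(depth >= min_depth) & (minor >= min_minor_count)].reset_index(drop=True)
    if kept.empty:
        logger.warning("sample %s: no SNPs survive filtering", table.sample)
    return SnpAlleleTable(data=kept, sample=table.sample)


def moving_median_track(table: SnpAlleleTable, window: int = DEFAULT_WINDOW) -> AllelicRatioTrack:
    """Sliding medians (stride 1) of ratio and position per chromosome.

    The window must be odd so the median is centered.  Chromosomes with
    fewer SNPs than the window yield no windows (warning logged).
    """
    if window < 1 or window % 2 == 0:
        raise InputError("window must be an odd integer >= 1")
    frames = []
    for chrom, block in table.data.groupby("chromosome", sort=False):
        if len(block) < window:
            logger.warning(
                "sample %s chromosome %s: %d SNPs < window %d",
                table.sample, chrom, len(block), window,
            )
            continue
        ratios = pd.Series(major_minor_ratio(block["ref_count"], block["alt_count"]))
        med_ratio = ratios.rolling(window).median().iloc[window - 1 :]
        med_pos = (
            block["position"].astype(float).reset_index(drop=True)
            .rolling(window).median().iloc[window - 1 :]
        )
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": str(chrom),
                    "position": med_pos.to_numpy(),
                    "ratio": med_ratio.to_numpy(),
                }
            )
        )
    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chromosome", "position", "ratio"])
    )
    return AllelicRatioTrack(data=data, sample=table.sample, window=window, source=table)


def _null_statistics(
    pool: np.ndarray, n_snps: int, window: int, n_permutations: int, rng
) -> np.ndarray:
    """Median-of-windowed-medians under resampled SNP-to-chromosome assignment.

    Each permutation draws ``n_snps`` per-SNP ratios from ``pool`` and
    recomputes the exact track statistic, reproducing the sampling law of a
    diploid chromosome's median windowed ratio.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    null = np.empty(n_permutations)
    chunk = max(1, int(4e6 // max(n_snps * window, 1)))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        draws = rng.choice(pool, size=(k, n_snps), replace=True)
        win_med = np.median(sliding_window_view(draws, window, axis=1), axis=2)
        null[done : done + k] = np.median(win_med, axis=1)
        done += k
    return null


def call_imbalance(
    track: AllelicRatioTrack,
    diploid_reference: np.ndarray | None = None,
    alpha: float = 0.01,
    n_permutations: int = 200,
    seed: int | None = None,
) -> list[ChromosomeCall]:
    """Call chromosomes whose median windowed ratio exceeds the permutation null.

    The statistic for chromosome c is the median of its windowed medians.
    The null permutes the SNP-to-chromosome assignment: per-SNP ratios are
    resampled from all *other* chromosomes of the sample — or from
    ``diploid_reference`` (a 1-D array of baseline per-SNP ratios) when one
    is supplied — and the full windowed statistic recomputed.  A call is
    made when the statistic exceeds the null's (1 - alpha) quantile.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if track.data.empty:
        return []
    if track.source is None and diploid_reference is None:
        raise InputError("track has no source table; recompute it with moving_median_track()")
    chroms = list(track.data["chromosome"].unique())
    if diploid_reference is None and len(chroms) < 2:
        raise InputError(
            "need >= 2 chromosomes with windows (or a diploid_reference) to build a null"
        )

    snp_ratios: dict[str, np.ndarray] = {}
    if track.source is not None:
        for chrom, block in track.source.data.groupby("chromosome", sort=False):
            if chrom in chroms:
                snp_ratios[str(chrom)] = major_minor_ratio(
                    block["ref_count"], block["alt_count"]
                )

    rng = np.random.default_rng(seed)
    by_chrom = {c: g["ratio"].to_numpy() for c, g in track.data.groupby("chromosome", sort=False)}
    calls = []
    for chrom in chroms:
        obs = float(np.median(by_chrom[chrom]))
        n_snps = len(snp_ratios.get(chrom, [])) or len(by_chrom[chrom]) + track.window - 1
        if diploid_reference is not None:
            pool = np.asarray(diploid_reference, dtype=float)
        else:
            pool = np.concatenate([v for c, v in snp_ratios.items() if c != chrom])
        null = _null_statistics(pool, n_snps, track.window, n_permutations, rng)
        threshold = float(np.quantile(null, 1 - alpha))
        if obs > threshold:
            p = float((1 + np.sum(null >= obs)) / (n_permutations + 1))
            calls.append(
                ChromosomeCall(
                    sample=track.sample,
                    chromosome=chrom,
                    mean_deviation=obs,
                    p_value=p,
                    direction="gain",
                )
            )
    return calls


def read_vcf(path: str) -> list[SnpAlleleTable]:
    """Minimal VCF ingestion via cyvcf2 using the AD (allele depth) field.

    Bi-allelic sites only; multi-allelic records are dropped with a logged
    count.  Returns one table per sample in the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: dict[str, list] = {s: [] for s in samples}
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            continue
        for i, s in enumerate(samples):
            ref_c, alt_c = int(ad[i][0]), int(ad[i][1])
            if ref_c < 0 or alt_c < 0:  # missing encoded as negative
                continue
            rows[s].append((str(variant.CHROM), int(variant.POS), ref_c, alt_c))
    if n_multi:
        logger.info("dropped %d multi-allelic sites", n_multi)
    return [
        SnpAlleleTable(
            data=pd.DataFrame(rows[s], columns=["chromosome", "position", "ref_count", "alt_count"]),
            sample=s,
        )
        for s in samples
    ]
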