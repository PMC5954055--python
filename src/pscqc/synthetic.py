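"""Synthetic data with the statistical structure the assays assume.

Every downstream module in this package consumes one of four input classes
(probe intensity matrices, per-SNP allele-count tables, qPCR Ct time
courses, gene-level FPKM panels) plus a projection model.  The generators
here emulate each of them, including the features the pipelines key on:

* mosaic chromosomal gains that shift probe intensities by
  ``log2(((1 - f) * 2 + f * 2 * fc) / 2)``,
* trisomic allelic imbalance (expressed allele fraction 2/3 instead of 1/2)
  under overdispersed (negative-binomial) read depth,
* lineage-directed differentiation time courses with planted marker genes
  and consistently down-regulated pluripotency genes,
* teratomas as noisy mixtures of tissue-specific signatures with an
  optional residual PSC fraction,
* a toy low-rank projection model whose H9 reference lies in the basis
  span.

Everything is driven by :class:`SimulationConfig`; a fixed seed yields
byte-identical output (each generator draws from its own tagged stream, so
outputs do not depend on call order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import derived_rng
from .errors import AnnotationError, InputError, PanelError
from .ekaryo import ProbeExpressionMatrix
from .esnp import SnpAlleleTable
from .pluritest import ProjectionModel
from .scorecard import CONDITIONS, CONTROL_GENES, CtMatrix, DIRECTED_CONDITIONS
from .teratoscore import ExpressionProfile

__all__ = [
    "AberrationSpec",
    "SimulationConfig",
    "gen_probe_matrix",
    "gen_snp_table",
    "gen_ct_timecourse",
    "gen_tissue_panel_and_teratomas",
    "gen_projection_model",
    "default_panel",
    "default_lineage_effects",
    "default_tissue_lineages",
    "UNDIFF_PANEL",
    "PLANTED_MARKERS",
]

# RNG stream tags, one per generator
_TAG_PROBE, _TAG_SNP, _TAG_CT, _TAG_TISSUE, _TAG_MODEL = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class AberrationSpec:
    """A (possibly mosaic) chromosomal copy-number gain or loss.

    ``fold_change`` is the copy number relative to diploid (1.5 for a full
    trisomy); ``mosaic_fraction`` is the fraction of cells carrying it.
    """

    chromosome: str
    fold_change: float = 1.5
    mosaic_fraction: float = 1.0

    def __post_init__(self):
        if self.fold_change <= 0:
            raise InputError("fold_change must be > 0")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise InputError("mosaic_fraction must be in [0, 1]")

    @property
    def expression_shift(self) -> float:
        """Implied log2 expression shift of the affected chromosome."""
        f = self.mosaic_fraction
        return math.log2(((1 - f) * 2 + f * 2 * self.fold_change) / 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Shared configuration for all generators.

    Defaults are platform-ish scale: ~2000 annotated probes and 500
    transcribed heterozygous SNPs per chromosome, mean SNP read depth 60
    with negative-binomial overdispersion, 14 reference tissues.  Noise
    magnitudes (Gaussian on log2/Ct scales, multiplicative log-normal on
    FPKM) are minimal standard models chosen to preserve the assumptions the
    analyses make.
    """

    seed: int = 0
    chromosomes: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)
    # probe matrix
    n_probes_per_chromosome: int = 2000
    unannotated_fraction: float = 0.02
    noise_sd: float = 0.30  # log2-scale Gaussian sd
    expressed_fraction: float = 0.60  # bimodal probe population
    # SNP tables
    n_snps_per_chromosome: int = 500
    read_depth_mean: float = 60.0
    read_depth_dispersion: float | None = 4.0  # NB size; None = constant depth
    # Ct time course
    ct_replicate_sd: float = 0.30
    ct_detection_limit: float = 33.0  # Ct above this is a non-detect
    # FPKM panel
    n_tissues: int = 14
    genes_per_tissue: int = 12
    tissue_level: float = 100.0
    tissue_background: float = 0.5
    fpkm_noise_sd: float = 0.30  # natural-log multiplicative sd
    mixture_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_probes_per_chromosome < 1 or self.n_snps_per_chromosome < 1:
            raise InputError("per-chromosome counts must be positive")
        if self.read_depth_mean <= 0:
            raise InputError("read_depth_mean must be > 0")
        if not 0 <= self.unannotated_fraction < 1:
            raise InputError("unannotated_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.ct_replicate_sd < 0 or self.fpkm_noise_sd < 0:
            raise InputError("noise magnitudes must be non-negative")
        if self.mixture_weights is not None:
            w = np.asarray(self.mixture_weights, dtype=float)
            if (w < 0).any():
                raise InputError("mixture weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise InputError("mixture weights must sum to 1 within 1e-9")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ------------------------------------------------------------- probe matrices

def gen_probe_matrix(
    config: SimulationConfig,
    aberrations: list[AberrationSpec] = (),
    n_samples: int = 4,
    aberrant_samples: list[int] | None = None,
) -> ProbeExpressionMatrix:
    """Illumina HT-12-style log2 probe matrix with optional mosaic gains.

    Probe means are bimodal (expressed vs background populations) so that
    the top-third expression floor used by the e-karyotype preprocessing
    retains the expressed population.  ``aberrant_samples`` lists the sample
    indices carrying the aberrations (default: the last sample).  A
    ``config.unannotated_fraction`` of probes carries no chromosome
    annotation, to exercise the annotation-removal rule.
    """
    if n_samples < 2:
        raise InputError("n_samples must be >= 2")
    unknown = [a.chromosome for a in aberrations if a.chromosome not in config.chromosomes]
    if unknown:
        raise AnnotationError(f"aberration chromosomes not in the annotation: {unknown}")
    if aberrant_samples is None:
        aberrant_samples = [n_samples - 1] if aberrations else []
    if any(not 0 <= i < n_samples for i in aberrant_samples):
        raise InputError("aberrant_samples indices out of range")

    rng = derived_rng(config.seed, _TAG_PROBE)
    n_per = config.n_probes_per_chromosome
    probes, chrom_col, pos_col = [], [], []
    for chrom in config.chromosomes:
        gaps = rng.integers(5_000, 150_000, size=n_per)
        positions = np.cumsum(gaps) + 50_000
        for i, pos in enumerate(positions):
            probes.append(f"probe_{chrom}_{i:05d}")
            chrom_col.append(chrom)
            pos_col.append(int(pos))
    n_probes = len(probes)

    expressed = rng.random(n_probes) < config.expressed_fraction
    mean = np.where(
        expressed,
        rng.normal(9.5, 1.0, size=n_probes),
        rng.normal(6.5, 0.8, size=n_probes),
    )
    values = mean[:, None] + rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))

    chrom_arr = np.array(chrom_col)
    for ab in aberrations:
        on_chrom = chrom_arr == ab.chromosome
        for s in aberrant_samples:
            values[on_chrom, s] += ab.expression_shift

    samples = [f"sample_{i + 1}" for i in range(n_samples)]
    vdf = pd.DataFrame(values, index=probes, columns=samples)

    ann = pd.DataFrame({"chromosome": chrom_col, "position": pos_col}, index=probes)
    if config.unannotated_fraction > 0:
        n_drop = int(round(config.unannotated_fraction * n_probes))
        drop_idx = rng.choice(n_probes, size=n_drop, replace=False)
        ann.iloc[drop_idx, ann.columns.get_loc("chromosome")] = np.nan
    return ProbeExpressionMatrix(values=vdf, annotation=ann)


# ----------------------------------------------------------------- SNP tables

def gen_snp_table(
    config: SimulationConfig,
    trisomic_chromosomes: list[str] = (),
    n_samples: int = 1,
) -> list[SnpAlleleTable]:
    """Heterozygous-SNP allele counts per sample.

    Diploid chromosomes draw the reference-allele count from Binomial(depth,
    1/2); trisomic chromosomes use allele fraction 2/3 or 1/3 (the
    duplicated haplotype chosen at random per SNP).  Depth is negative
    binomial with mean ``read_depth_mean`` and size ``read_depth_dispersion``
    (constant depth when the dispersion is None).  Positions are strictly
    increasing within each chromosome.
    """
    unknown = [c for c in trisomic_chromosomes if c not in config.chromosomes]
    if unknown:
        raise AnnotationError(f"trisomic chromosomes not in the annotation: {unknown}")
    rng = derived_rng(config.seed, _TAG_SNP)
    tables = []
    for s in range(n_samples):
        rows = []
        for chrom in config.chromosomes:
            n = config.n_snps_per_chromosome
            positions = np.cumsum(rng.integers(1_000, 400_000, size=n)) + 10_000
            if config.read_depth_dispersion is None:
                depth = np.full(n, int(round(config.read_depth_mean)))
            else:
                r = config.read_depth_dispersion
                p = r / (r + config.read_depth_mean)
                depth = rng.negative_binomial(r, p, size=n)
            if chrom in trisomic_chromosomes:
                p_ref = np.where(rng.random(n) < 0.5, 2.0 / 3.0, 1.0 / 3.0)
            else:
                p_ref = np.full(n, 0.5)
            ref = rng.binomial(depth, p_ref)
            alt = depth - ref
            rows.append(
                pd.DataFrame(
                    {
                        "chromosome": chrom,
                        "position": positions.astype(int),
                        "ref_count": ref.astype(int),
                        "alt_count": alt.astype(int),
                    }
                )
            )
        tables.append(
            SnpAlleleTable(data=pd.concat(rows, ignore_index=True), sample=f"sample_{s + 1}")
        )
    return tables


# -------------------------------------------------------------- Ct time course

#: Planted marker genes per lineage (15 each) used by the default panel.
PLANTED_MARKERS = {
    "ectoderm": [f"ECT{i:03d}" for i in range(1, 16)],
    "mesoderm": [f"MES{i:03d}" for i in range(1, 16)],
    "endoderm": [f"END{i:03d}" for i in range(1, 16)],
    "undifferentiated": [f"UND{i:03d}" for i in range(1, 16)],
}


def default_panel() -> list[str]:
    """A 190-gene qPCR panel: 2 controls, 60 planted markers, 128 background."""
    panel = list(CONTROL_GENES)
    for genes in PLANTED_MARKERS.values():
        panel.extend(genes)
    panel.extend(f"BKG{i:03d}" for i in range(1, 129))
    return panel


def default_lineage_effects(
    panel: list[str] | None = None,
    effect_size: float = 6.0,
    neutral_effect: float = 2.0,
    undiff_effect: float = -4.0,
) -> dict[tuple[str, str], float]:
    """Day-16 Ct-decrease effects planting condition-specific responders.

    Positive effect = expression up (Ct down) by that many cycles at day 16
    under the given condition.  Lineage markers respond strongly to their
    matched directed condition (with a small within-set gradient so ranks
    are unambiguous), mildly under neutral conditions; undifferentiated
    markers are down-regulated under every condition.
    """
    panel = default_panel() if panel is None else panel
    effects: dict[tuple[str, str], float] = {}
    for lineage in DIRECTED_CONDITIONS:
        for i, gene in enumerate(PLANTED_MARKERS[lineage]):
            if gene in panel:
                effects[(gene, lineage)] = effect_size + 0.1 * i
                effects[(gene, "neutral")] = neutral_effect
    for gene in PLANTED_MARKERS["undifferentiated"]:
        if gene in panel:
            for cond in CONDITIONS:
                effects[(gene, cond)] = undiff_effect
    return effects


def gen_ct_timecourse(
    config: SimulationConfig,
    panel: list[str] | None = None,
    lines: list[str] = ("line_1", "line_2", "line_3", "line_4"),
    lineage_effects: dict[tuple[str, str], float] | None = None,
    days: tuple[int, ...] = (0, 4, 10, 16),
    n_replicates: int = 2,
    n_low_quality: int = 0,
) -> CtMatrix:
    """qPCR Ct time course over lines x conditions x days x replicates.

    ``Ct(gene, day) = baseline - effect * day/16 + N(0, ct_replicate_sd)``,
    so genes with positive effects drop in Ct (rise in expression) toward
    day 16.  Day-0 samples are shared per line (labelled with the neutral
    condition).  Ct values beyond ``config.ct_detection_limit`` become
    non-detects (NaN).  ``n_low_quality`` extra samples are generated with
    ~70% of genes knocked out to exercise the detection-fraction QC rule;
    their labels are recorded in ``CtMatrix.meta['low_quality_samples']``.
    """
    panel = default_panel() if panel is None else list(panel)
    missing_controls = [g for g in CONTROL_GENES if g not in panel]
    if missing_controls:
        raise PanelError(f"panel lacks control genes {missing_controls}")
    if len(panel) - len(CONTROL_GENES) < 60:
        raise PanelError("panel needs at least 60 non-control genes")
    if lineage_effects is None:
        lineage_effects = default_lineage_effects(panel)

    rng = derived_rng(config.seed, _TAG_CT)
    baseline = {}
    for g in panel:
        if g in CONTROL_GENES:
            baseline[g] = rng.normal(16.0, 0.5)
        elif any(g in PLANTED_MARKERS[k] for k in PLANTED_MARKERS):
            baseline[g] = rng.normal(26.0, 1.5)
        else:
            baseline[g] = rng.normal(24.0, 3.0)

    records, meta_rows = [], []

    def emit(sample, line, condition, day, replicate):
        meta_rows.append(
            {"sample": sample, "line": line, "condition": condition, "day": day,
             "replicate": replicate}
        )
        for g in panel:
            eff = 0.0 if g in CONTROL_GENES else lineage_effects.get((g, condition), 0.0)
            ct = baseline[g] - eff * (day / 16.0) + rng.normal(0.0, config.ct_replicate_sd)
            ct = float(np.clip(ct, 5.0, 40.0))
            records.append(
                {"gene": g, "sample": sample, "ct": np.nan if ct > config.ct_detection_limit else ct}
            )

    for line in lines:
        for rep in range(1, n_replicates + 1):
            emit(f"{line}_d0_r{rep}", line, "neutral", 0, rep)
        for condition in CONDITIONS:
            for day in [d for d in days if d != 0]:
                for rep in range(1, n_replicates + 1):
                    emit(f"{line}_{condition}_d{day}_r{rep}", line, condition, day, rep)

    low_quality = []
    for i in range(n_low_quality):
        sample = f"lowq_{i + 1}"
        emit(sample, lines[0], "neutral", 16, 1)
        low_quality.append(sample)

    data = pd.DataFrame(records)
    if low_quality:
        for sample in low_quality:
            mask = data["sample"] == sample
            idx = data.index[mask]
            knock = rng.choice(idx, size=int(round(0.70 * len(idx))), replace=False)
            data.loc[knock, "ct"] = np.nan
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CtMatrix(
        data=data, samples=samples, panel=panel,
        meta={"low_quality_samples": low_quality},
    )


# ------------------------------------------------------------------ FPKM panel

#: Ten undifferentiated-PSC / yolk-sac marker genes expressed by PSCs.
UNDIFF_PANEL = [
    "POU5F1", "NANOG", "SOX2", "LIN28A", "DNMT3B",
    "TDGF1", "ZFP42", "SALL4", "LEFTY1", "GDF3",
]

_DEFAULT_TISSUES = [
    ("central_nervous_system", "ectoderm"),
    ("peripheral_nervous_system", "ectoderm"),
    ("skin", "ectoderm"),
    ("adipose", "mesoderm"),
    ("kidney", "mesoderm"),
    ("skeletal_muscle", "mesoderm"),
    ("blood", "mesoderm"),
    ("heart", "mesoderm"),
    ("pancreas", "endoderm"),
    ("liver", "endoderm"),
    ("small_intestine", "endoderm"),
    ("colon", "endoderm"),
    ("lung", "endoderm"),
    ("placenta", "extraembryonic"),
]


def default_tissue_lineages(n_tissues: int = 14) -> dict[str, str]:
    """The default tissue -> lineage map (14 tissues across four lineages)."""
    if n_tissues > len(_DEFAULT_TISSUES):
        raise InputError(f"at most {len(_DEFAULT_TISSUES)} default tissues available")
    return dict(_DEFAULT_TISSUES[:n_tissues])


def gen_tissue_panel_and_teratomas(
    config: SimulationConfig,
    lineage_map: dict[str, str] | None = None,
    mixtures: list | None = None,
    psc_fractions: list[float] | None = None,
    n_replicates_per_tissue: int = 5,
    n_psc: int = 3,
) -> tuple[list[ExpressionProfile], list[ExpressionProfile], list[ExpressionProfile]]:
    """Reference tissue panel, PSC profiles and teratoma mixtures.

    Each tissue owns ``config.genes_per_tissue`` private genes expressed at
    ``tissue_level`` in the source tissue and at ``tissue_background``
    elsewhere (well above the 8-fold specificity rule).  PSCs express the
    10-gene undifferentiated panel highly and tissue genes near zero.  Each
    teratoma is a weighted sum of tissue signatures (weights normalized to
    sum to 1), optionally blended with a PSC fraction, under multiplicative
    log-normal noise.

    ``mixtures`` is a list of per-tissue weight vectors (dicts keyed by
    tissue or arrays in tissue order); the default is three balanced
    teratomas.  Returns ``(tissue_profiles, psc_profiles, teratoma_profiles)``.
    """
    lineage_map = default_tissue_lineages(config.n_tissues) if lineage_map is None else lineage_map
    bad = [lin for lin in set(lineage_map.values())
           if lin not in ("ectoderm", "mesoderm", "endoderm", "extraembryonic")]
    if bad:
        raise InputError(f"unknown lineages in lineage_map: {bad}")
    tissues = list(lineage_map)

    rng = derived_rng(config.seed, _TAG_TISSUE)

    genes = []
    owner = {}
    for t in tissues:
        for i in range(config.genes_per_tissue):
            g = f"{t.upper()}_G{i + 1:02d}"
            genes.append(g)
            owner[g] = t
    genes += UNDIFF_PANEL
    housekeeping = [f"HK{i + 1:03d}" for i in range(30)]
    genes += housekeeping
    gene_index = pd.Index(genes)

    def signature_for(tissue: str) -> pd.Series:
        base = pd.Series(config.tissue_background, index=gene_index)
        base[[g for g in genes if owner.get(g) == tissue]] = config.tissue_level
        base[UNDIFF_PANEL] = 0.2
        base[housekeeping] = 50.0
        return base

    psc_signature = pd.Series(0.5, index=gene_index)
    psc_signature[UNDIFF_PANEL] = 100.0
    psc_signature[housekeeping] = 50.0

    def noisy(base: pd.Series) -> pd.Series:
        if config.fpkm_noise_sd == 0:
            return base.copy()
        return base * np.exp(rng.normal(0.0, config.fpkm_noise_sd, size=len(base)))

    tissue_profiles = []
    for t in tissues:
        sig = signature_for(t)
        for rep in range(1, n_replicates_per_tissue + 1):
            tissue_profiles.append(
                ExpressionProfile(
                    values=noisy(sig), label=f"{t}_r{rep}", role="tissue",
                    tissue=t, lineage=lineage_map[t],
                )
            )

    psc_profiles = [
        ExpressionProfile(values=noisy(psc_signature), label=f"psc_r{i + 1}", role="psc")
        for i in range(n_psc)
    ]

    if mixtures is None:
        mixtures = [np.ones(len(tissues))] * 3
    if psc_fractions is None:
        psc_fractions = [0.0] * len(mixtures)
    if len(psc_fractions) != len(mixtures):
        raise InputError("psc_fractions must match mixtures in length")

    signatures = {t: signature_for(t) for t in tissues}
    teratoma_profiles = []
    for i, mix in enumerate(mixtures):
        if isinstance(mix, dict):
            w = np.array([float(mix.get(t, 0.0)) for t in tissues])
        else:
            w = np.asarray(mix, dtype=float)
            if len(w) != len(tissues):
                raise InputError("mixture weight vector length must match tissue count")
        if (w < 0).any():
            raise InputError("mixture weights must be non-negative")
        if w.sum() <= 0:
            raise InputError("degenerate mixture: all weights zero")
        w = w / w.sum()
        base = sum(w[j] * signatures[t] for j, t in enumerate(tissues))
        pf = float(psc_fractions[i])
        if not 0.0 <= pf <= 1.0:
            raise InputError("psc fraction must be in [0, 1]")
        base = (1.0 - pf) * base + pf * psc_signature
        teratoma_profiles.append(
            ExpressionProfile(values=noisy(base), label=f"teratoma_{i + 1}", role="teratoma")
        )
    return tissue_profiles, psc_profiles, teratoma_profiles


# ------------------------------------------------------------ projection model

def gen_projection_model(
    config: SimulationConfig,
    k: int = 4,
    n_genes: int = 200,
    pluripotency_weight: float = 30.0,
    other_weight: float = -5.0,
) -> ProjectionModel:
    """Toy low-rank projection model for the pluripotency classifier.

    Component 0 is the designated pluripotency component: the stored H9
    reference equals that basis column exactly (so it lies in the basis
    span), and the score weights map a pure pluripotency loading to a score
    of ``pluripotency_weight`` (above the pass threshold) while loadings on
    the differentiation components pull the score down.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    if k > n_genes:
        raise InputError("k may not exceed the gene count")
    rng = derived_rng(config.seed, _TAG_MODEL)
    genes = pd.Index([f"g{i + 1:04d}" for i in range(n_genes)])
    components = pd.Index([f"component_{j}" for j in range(k)])

    # block structure: each component dominates its own slice of genes,
    # giving a well-conditioned non-negative basis
    basis = rng.lognormal(mean=0.0, sigma=0.3, size=(n_genes, k)) * 0.5
    block = n_genes // k
    for j in range(k):
        basis[j * block : (j + 1) * block, j] += rng.lognormal(2.0, 0.3, size=block)
    basis_df = pd.DataFrame(basis, index=genes, columns=components)

    weights = pd.Series(other_weight, index=components)
    weights.iloc[0] = pluripotency_weight
    h9_reference = basis_df.iloc[:, 0].copy()
    h9_reference.name = None
    return ProjectionModel(
        basis=basis_df, score_weights=weights, h9_reference=h9_reference
    )
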