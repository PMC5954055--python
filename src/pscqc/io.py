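"""TSV readers and writers for every data class in the package.

All formats are plain tab-separated text so that simulated datasets,
intermediate tracks and results can be inspected, diffed and versioned.
Floats round-trip losslessly (shortest-repr writing, exact float64 parse).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ekaryo import MovingAverageTrack, ProbeExpressionMatrix, ChromosomeCall
from .esnp import AllelicRatioTrack, SnpAlleleTable
from .pluritest import ProjectionModel
from .scorecard import CtMatrix, LineageScorecard, MarkerSets
from .teratoscore import ExpressionProfile, Signature

_SEP = "\t"


# ------------------------------------------------------------- probe matrices

def write_probe_matrix(pm: ProbeExpressionMatrix, matrix_path, annotation_path) -> None:
    pm.values.rename_axis("probe").to_csv(matrix_path, sep=_SEP)
    pm.annotation.rename_axis("probe").to_csv(annotation_path, sep=_SEP)


def read_probe_matrix(matrix_path, annotation_path) -> ProbeExpressionMatrix:
    values = pd.read_csv(matrix_path, sep=_SEP, index_col="probe", float_precision="round_trip").rename_axis(None)
    ann = pd.read_csv(
        annotation_path, sep=_SEP, index_col="probe", dtype={"chromosome": "string"}
    , float_precision="round_trip").rename_axis(None)
    ann["chromosome"] = ann["chromosome"].astype(object).where(ann["chromosome"].notna(), np.nan)
    return ProbeExpressionMatrix(values=values, annotation=ann)


# ----------------------------------------------------------------- SNP tables

def write_snp_tables(tables: list[SnpAlleleTable], path) -> None:
    """Minimal VCF-like TSV: CHROM, POS, REF_COUNT, ALT_COUNT, SAMPLE."""
    frames = []
    for t in tables:
        d = t.data.rename(
            columns={
                "chromosome": "CHROM", "position": "POS",
                "ref_count": "REF_COUNT", "alt_count": "ALT_COUNT",
            }
        )
        d["SAMPLE"] = t.sample
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_SEP, index=False)


def read_snp_tables(path) -> list[SnpAlleleTable]:
    df = pd.read_csv(path, sep=_SEP, dtype={"CHROM": str}, float_precision="round_trip")
    tables = []
    for sample, grp in df.groupby("SAMPLE", sort=False):
        data = grp.rename(
            columns={
                "CHROM": "chromosome", "POS": "position",
                "REF_COUNT": "ref_count", "ALT_COUNT": "alt_count",
            }
        )[["chromosome", "position", "ref_count", "alt_count"]].reset_index(drop=True)
        tables.append(SnpAlleleTable(data=data, sample=str(sample)))
    return tables


# ----------------------------------------------------------------- Ct matrices

def write_ct_matrix(ct: CtMatrix, path) -> None:
    """Long-format TSV with metadata columns; empty ct field = non-detect."""
    merged = ct.data.merge(ct.samples, left_on="sample", right_index=True)
    merged.to_csv(path, sep=_SEP, index=False)


def read_ct_matrix(path, panel: list[str] | None = None) -> CtMatrix:
    df = pd.read_csv(path, sep=_SEP, float_precision="round_trip")
    data = df[["gene", "sample", "ct"]].copy()
    samples = (
        df[["sample", "line", "condition", "day", "replicate"]]
        .drop_duplicates("sample")
        .set_index("sample")
    )
    return CtMatrix(data=data, samples=samples, panel=panel or sorted(data["gene"].unique()))


# --------------------------------------------------------------- FPKM profiles

def write_expression_profiles(profiles: list[ExpressionProfile], fpkm_path, meta_path) -> None:
    """Genes x samples TSV plus a sample sidecar TSV (role/tissue/lineage)."""
    wide = pd.concat({p.label: p.values for p in profiles}, axis=1).fillna(0.0)
    wide.rename_axis("gene").to_csv(fpkm_path, sep=_SEP)
    meta = pd.DataFrame(
        [
            {"sample": p.label, "role": p.role, "tissue": p.tissue or "", "lineage": p.lineage or ""}
            for p in profiles
        ]
    )
    meta.to_csv(meta_path, sep=_SEP, index=False)


def read_expression_profiles(fpkm_path, meta_path) -> list[ExpressionProfile]:
    wide = pd.read_csv(fpkm_path, sep=_SEP, index_col="gene", float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep=_SEP, keep_default_na=False, float_precision="round_trip").set_index("sample")
    profiles = []
    for label in wide.columns:
        row = meta.loc[label]
        profiles.append(
            ExpressionProfile(
                values=wide[label],
                label=label,
                role=row["role"],
                tissue=row["tissue"] or None,
                lineage=row["lineage"] or None,
            )
        )
    return profiles


def write_signature(sig: Signature, path) -> None:
    sig.table.to_csv(path, sep=_SEP, index=False)


def read_signature(path) -> Signature:
    return Signature(table=pd.read_csv(path, sep=_SEP, float_precision="round_trip"))


# ------------------------------------------------------------------ marker sets

def write_marker_sets(markers: MarkerSets, path) -> None:
    rows = [
        {"set": name, "gene": g}
        for name, genes in markers.as_dict().items()
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep=_SEP, index=False)


def read_marker_sets(path) -> MarkerSets:
    df = pd.read_csv(path, sep=_SEP, float_precision="round_trip")
    sets = {name: grp["gene"].tolist() for name, grp in df.groupby("set", sort=False)}
    return MarkerSets(
        ectoderm=sets.get("ectoderm", []),
        mesoderm=sets.get("mesoderm", []),
        endoderm=sets.get("endoderm", []),
        undifferentiated=sets.get("undifferentiated", []),
    )


# ----------------------------------------------------------------- tracks/calls

def write_moving_average_track(track: MovingAverageTrack, path) -> None:
    """BED-like TSV: chromosome, window start/end ordinals, sample, mean."""
    track.data[["chromosome", "start", "end", "sample", "mean"]].to_csv(
        path, sep=_SEP, index=False
    )


def write_ratio_track(track: AllelicRatioTrack, path) -> None:
    out = track.data.copy()
    out["sample"] = track.sample
    out.to_csv(path, sep=_SEP, index=False)


def write_calls(calls: list[ChromosomeCall], path) -> None:
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(path, sep=_SEP, index=False)


def write_scorecard(card: LineageScorecard, path) -> None:
    card.table.to_csv(path, sep=_SEP, index=False)


# ------------------------------------------------------------ projection model

def write_projection_model(model: ProjectionModel, directory) -> None:
    """Model bundle: basis/score-weights/H9-reference TSVs plus a manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    model.basis.rename_axis("gene").to_csv(d / "basis.tsv", sep=_SEP)
    model.score_weights.rename_axis("component").rename("weight").to_csv(
        d / "score_weights.tsv", sep=_SEP
    )
    model.h9_reference.rename_axis("gene").rename("value").to_csv(
        d / "h9_reference.tsv", sep=_SEP
    )
    manifest = {
        "pluripotency_threshold": model.pluripotency_threshold,
        "novelty_threshold": model.novelty_threshold,
        "novelty_calibration": list(model.novelty_calibration),
        "files": {
            "basis": "basis.tsv",
            "score_weights": "score_weights.tsv",
            "h9_reference": "h9_reference.tsv",
        },
    }
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_projection_model(directory) -> ProjectionModel:
    d = Path(directory)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    files = manifest["files"]
    basis = pd.read_csv(d / files["basis"], sep=_SEP, index_col="gene", float_precision="round_trip").rename_axis(None)
    weights = pd.read_csv(d / files["score_weights"], sep=_SEP, index_col="component", float_precision="round_trip")[
        "weight"
    ].rename_axis(None)
    weights.name = None
    h9 = pd.read_csv(d / files["h9_reference"], sep=_SEP, index_col="gene", float_precision="round_trip")["value"].rename_axis(None)
    h9.name = None
    return ProjectionModel(
        basis=basis,
        score_weights=weights,
        h9_reference=h9,
        pluripotency_threshold=float(manifest["pluripotency_threshold"]),
        novelty_threshold=float(manifest["novelty_threshold"]),
        novelty_calibration=tuple(manifest["novelty_calibration"]),
    )


# -------------------------------------------------------------------- results

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
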