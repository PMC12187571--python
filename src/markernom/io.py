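"""Readers and writers for the plain-text formats the pipeline touches.

TSV for matrices and tables, BED for intervals, GMT for gene sets. Every
reader rejects malformed input with an error naming the offending line or
feature; every writer produces a file its paired reader parses back to an
equal object.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BED_COLUMNS,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    MethylationMatrix,
    PeakSet,
)

__all__ = [
    "read_expression_matrix", "write_expression_matrix",
    "read_gmt", "write_gmt",
    "read_bed", "write_bed",
    "read_gene_annotation", "write_gene_annotation",
    "read_methylation", "write_methylation",
    "read_kd_table", "write_kd_table",
    "read_irs_table",
]

# 17 significant digits round-trip IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def _read_labels(label_path: str | Path) -> pd.Series:
    labels = pd.read_csv(label_path, sep="\t", dtype=str)
    if list(labels.columns[:2]) != ["sample", "entity"]:
        raise ValueError(
            f"{label_path}: expected header 'sample<TAB>entity', "
            f"got {list(labels.columns)}")
    if labels["sample"].duplicated().any():
        dups = labels["sample"][labels["sample"].duplicated()].tolist()
        raise ValueError(f"{label_path}: duplicate sample labels: {dups}")
    return labels.set_index("sample")["entity"]


def read_expression_matrix(path: str | Path,
                           label_path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples log2 TSV plus a sample->entity label file.

    Missing values are rejected rather than imputed.
    """
    values = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    if values.index.duplicated().any():
        dups = sorted(set(values.index[values.index.duplicated()]))
        raise ValueError(f"{path}: duplicate feature ids: {', '.join(dups)}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values=values, entity_labels=_read_labels(label_path))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            label_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                       index_label="feature")
    expr.entity_labels.rename("entity").rename_axis("sample").to_csv(
        label_path, sep="\t")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, members... per tab-separated line.

    Members are deduplicated preserving first occurrence.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                f"fields (name, description, members...), got {len(fields)}")
        name, description, *members = fields
        members = [m for m in members if m]
        sets.append(GeneSet(name=name, members=members, description=description))
    return sets


def write_gmt(gene_sets: list[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, gs.description or "na", *gs.members])
        for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3+ intervals (optional name and score columns).

    Coordinates are 0-based half-open; ``start >= end`` is an error naming
    the line. Input order is preserved (sorting is the caller's job).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
        chrom, start_s, end_s = fields[0], fields[1], fields[2]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(
                f"{path}: line {lineno}: non-integer coordinate") from exc
        if start >= end:
            raise ValueError(
                f"{path}: line {lineno}: empty/inverted interval "
                f"[{start}, {end})")
        name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
        score = float(fields[4]) if len(fields) > 4 else 0.0
        rows.append((chrom, start, end, name, score))
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    peaks.df.to_csv(path, sep="\t", header=False, index=False,
                    float_format=_FLOAT_FMT)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene_id": str, "chrom": str, "strand": str})
    return GeneAnnotation(df[["gene_id", "chrom", "start", "end", "strand"]])


def write_gene_annotation(genes: GeneAnnotation, path: str | Path) -> None:
    genes.df[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False)


def read_methylation(beta_path: str | Path, cpg_bed: str | Path,
                     label_path: str | Path) -> MethylationMatrix:
    beta = pd.read_csv(beta_path, sep="\t", index_col=0,
                       float_precision="round_trip").astype(float)
    cpgs = read_bed(cpg_bed)
    coords = cpgs.df.rename(columns={"name": "cpg_id", "start": "position"})
    coords = coords[["cpg_id", "chrom", "position"]]
    return MethylationMatrix(beta=beta, coords=coords,
                             entity_labels=_read_labels(label_path))


def write_methylation(meth: MethylationMatrix, beta_path: str | Path,
                      cpg_bed: str | Path, label_path: str | Path) -> None:
    meth.beta.to_csv(beta_path, sep="\t", float_format=_FLOAT_FMT,
                     index_label="cpg")
    bed = meth.coords.assign(
        start=meth.coords["position"],
        end=meth.coords["position"] + 1,
        score=0.0,
    ).rename(columns={"cpg_id": "name"})[BED_COLUMNS]
    write_bed(PeakSet(bed), cpg_bed)
    meth.entity_labels.rename("entity").rename_axis("sample").to_csv(
        label_path, sep="\t")


def read_kd_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read replicate-level knockdown abundances.

    Columns prefixed ``ctrl_`` are control replicates, ``kd_`` knockdown
    replicates. Returns (control, knockdown) frames sharing the protein index.
    """
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip").astype(float)
    ctrl = df[[c for c in df.columns if c.startswith("ctrl_")]]
    kd = df[[c for c in df.columns if c.startswith("kd_")]]
    if ctrl.empty or kd.empty:
        raise ValueError(
            f"{path}: need 'ctrl_*' and 'kd_*' replicate columns, "
            f"got {list(df.columns)}")
    return ctrl, kd


def write_kd_table(ctrl: pd.DataFrame, kd: pd.DataFrame,
                   path: str | Path) -> None:
    pd.concat([ctrl, kd], axis=1).to_csv(path, sep="\t",
                                         float_format=_FLOAT_FMT,
                                         index_label="protein")


def read_irs_table(path: str | Path) -> pd.DataFrame:
    """Read IHC scoring records (sample_id, entity, intensity,
    percent_positive and/or precomputed irs)."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "entity"}
    if missing := need - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_raw = {"intensity", "percent_positive"} <= set(df.columns)
    if not has_raw and "irs" not in df.columns:
        raise ValueError(
            f"{path}: need either intensity+percent_positive or irs column")
    return df
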