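"""Readers and writers for the TSV/GMT interchange formats.

All tabular inputs are headered, tab-separated text.  The expression
matrix has ``probe_id`` as its first column and one column per sample;
metadata and annotation are long-form tables keyed by sample/probe id.
Gene sets use the MSigDB GMT dialect (name, description, then genes,
tab-separated, one set per line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CqTable,
    ExpressionMatrix,
    GeneSetCollection,
    MTITable,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)


def read_matrix(path, scale: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise ValidationError(
            f"{path}: first column must be 'probe_id', got {df.columns[0]!r}"
        )
    df = df.set_index("probe_id")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-numeric cell in column {col!r}") from exc
    return ExpressionMatrix(df, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'sample_id' column")
    if "cohort" not in df.columns:
        df["cohort"] = "discovery"
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(metadata: SampleMetadata, path) -> None:
    out = metadata.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "probe_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'probe_id' column")
    if "species_tag" not in df.columns:
        df["species_tag"] = "human"
    return ProbeAnnotation(df.set_index("probe_id"))


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    out = annotation.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_expression(
    matrix_path, metadata_path, annotation_path=None, scale: str = "log2"
) -> tuple[ExpressionMatrix, SampleMetadata, ProbeAnnotation | None]:
    """Read and cross-validate the matrix / metadata / annotation bundle.

    Every matrix sample must have exactly one age in the metadata, and
    (when an annotation is given) every probe must be annotated.
    """
    matrix = read_matrix(matrix_path, scale=scale)
    metadata = read_metadata(metadata_path)
    metadata.require_samples(matrix.sample_ids)
    annotation = None
    if annotation_path is not None:
        annotation = read_annotation(annotation_path)
        annotation.require_probes(matrix.probe_ids)
    return matrix, metadata, annotation


def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line are collapsed.  A line with fewer than three fields
    (i.e. no genes) is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            name, description, *genes = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in genes if g)
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_mti(path) -> MTITable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return MTITable(df)


def read_cq(path) -> CqTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay": str})
    if "cq" in df.columns:
        df["cq"] = pd.to_numeric(df["cq"])
    return CqTable(df)


def write_cq(cq: CqTable, path) -> None:
    cq.table.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write an analysis result table as TSV with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
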