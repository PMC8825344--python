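"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices are tab-delimited with genes in rows and a header of
sample ids; metadata and Ct tables are CSV; GO annotation is two-column
TSV plus a term-metadata TSV; models, truth and run manifests are JSON.
All readers validate schemas and report offending values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GOAnnotation
from .expression import ExpressionMatrix, SampleMetadata
from .forecast import ROLES
from .modules import ModulePartition

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_ct_table",
    "write_ct_table",
    "read_annotation",
    "write_annotation",
    "write_partition",
    "read_gene_lengths",
    "write_json",
    "read_json",
]


def read_matrix(path, unit: str = "FPKM", lengths_path=None) -> ExpressionMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"{path}: cannot parse expression matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (is the header tab-delimited?)")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        for c in non_numeric:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()]
            if len(bad):
                line = df.index.get_loc(bad.index[0]) + 2  # header is line 1
                raise ValueError(
                    f"{path}: non-numeric value {bad[c].iloc[0]!r} in column {c!r} (line {line})"
                )
    if df.isna().any().any():
        gid = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value for gene {gid!r}")
    df.index.name = None
    df.columns.name = None
    lengths = read_gene_lengths(lengths_path) if lengths_path else None
    return ExpressionMatrix(df, unit=unit, gene_lengths=lengths)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length"} <= set(df.columns):
        raise ValueError(f"{path}: gene-length table needs columns gene_id, length")
    s = df.set_index("gene_id")["length"].astype(float)
    if (s <= 0).any():
        bad = s.index[s <= 0][0]
        raise ValueError(f"{path}: non-positive length for gene {bad!r}")
    return s


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path)
    missing = [c for c in SampleMetadata.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    off = pd.to_numeric(df["day_offset"], errors="coerce")
    if off.isna().any():
        i = int(off.index[off.isna()][0])
        raise ValueError(
            f"{path}: non-numeric day_offset {df['day_offset'].iloc[i]!r} (line {i + 2})"
        )
    df["day_offset"] = off.astype(int)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"sample_id", "role", "ct"}
    if not req <= set(df.columns):
        raise ValueError(f"{path}: Ct table missing columns {sorted(req - set(df.columns))}")
    bad = df.loc[~df["role"].isin(ROLES)]
    if len(bad):
        i = int(bad.index[0])
        raise ValueError(
            f"{path}: unknown role {bad['role'].iloc[0]!r} (line {i + 2}); expected {ROLES}"
        )
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any():
        i = int(ct.index[ct.isna()][0])
        raise ValueError(f"{path}: non-numeric ct {df['ct'].iloc[i]!r} (line {i + 2})")
    df["ct"] = ct
    if df.duplicated(subset=["sample_id", "role"]).any():
        d = df.loc[df.duplicated(subset=["sample_id", "role"]), ["sample_id", "role"]]
        raise ValueError(f"{path}: duplicate (sample_id, role): {d.values.tolist()[:5]}")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_annotation(path, term_meta_path=None) -> GOAnnotation:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
    gene_to_terms: dict[str, set[str]] = {}
    for gid, tid in zip(df["gene_id"], df["term_id"]):
        gene_to_terms.setdefault(str(gid), set()).add(str(tid))
    if term_meta_path is not None:
        meta = pd.read_csv(term_meta_path, sep="\t")
    else:
        terms = sorted(set(df["term_id"].astype(str)))
        meta = pd.DataFrame(
            {"term_id": terms, "name": terms, "ontology": ["BP"] * len(terms)}
        )
    return GOAnnotation(gene_to_terms=gene_to_terms, term_meta=meta)


def write_annotation(annotation: GOAnnotation, path, term_meta_path=None) -> None:
    rows = []
    for gid in sorted(annotation.gene_to_terms):
        for tid in sorted(annotation.gene_to_terms[gid]):
            rows.append((gid, tid))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
    if term_meta_path is not None:
        annotation.term_meta.to_csv(term_meta_path, sep="\t", index=False)


def write_partition(partition: ModulePartition, path) -> None:
    rows = []
    for m in partition.modules:
        for g in m.gene_ids:
            rows.append(
                {
                    "gene_id": g,
                    "module_label": m.label,
                    "stage": m.stage or "",
                    "peak_day": "" if m.peak_day is None else m.peak_day,
                }
            )
    for g in partition.unassigned_gene_ids:
        rows.append({"gene_id": g, "module_label": "unassigned", "stage": "", "peak_day": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_eigengenes(partition: ModulePartition, path) -> None:
    data = {
        m.label: np.asarray(m.eigengene)
        for m in partition.modules
        if m.eigengene is not None
    }
    pd.DataFrame(data, index=partition.sample_ids).rename_axis("sample_id").to_csv(
        path, sep="\t"
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
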