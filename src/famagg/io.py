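"""Readers and writers for the pipeline's text formats.

Formats (all plain text):

* expression TSV — rows are genes, first column ``gene``, remaining columns
  sample ids, values log-scale expression;
* centroid CSV — header ``gene,<subtype1>,...,<subtypeK>``;
* annotation CSV — ``sample_id,family_id,subtype[,methylated]``;
* families CSV — ``family_id,sample_id``;
* labels CSV — ``sample_id,subtype``;
* methylation ratios CSV — ``sample,probe,ratio``;
* signature CSV — ``#``-prefixed metadata lines (positive_class,
  negative_class, intercept, subtype) then ``gene,weight`` rows.

Loading validates the schema strictly: duplicate ids, non-finite values and
malformed headers are errors.  Duplicate gene ids in an expression file are
resolved by keeping the row with the highest variance across samples (the
usual many-probes-per-symbol convention).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from famagg.aggregation import FamilyTable
from famagg.brca_like import SignatureModel

__all__ = [
    "read_expression", "write_expression",
    "read_centroids", "write_centroids",
    "read_annotation", "write_annotation",
    "read_families", "write_families",
    "read_labels", "write_labels",
    "read_ratios", "write_ratios",
    "read_signature", "write_signature",
    "write_json",
]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column of an expression TSV must be 'gene', "
                         f"got {df.columns[0]!r}")
    df = df.set_index("gene")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if df.index.has_duplicates:
        # many probes per gene symbol: keep the most variant row per gene
        var = df.var(axis=1, ddof=1)
        df = df.assign(_var=var).sort_values("_var", ascending=False)
        df = df[~df.index.duplicated(keep="first")].drop(columns="_var")
        df = df.sort_index()
    values = df.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite expression values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t")


def read_centroids(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: centroid CSV header must start with 'gene'")
    df = df.set_index("gene")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids in centroid table")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate subtype names in centroid table")
    if len(df.index) < 2:
        raise ValueError(f"{path}: a centroid table needs >= 2 genes")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_centroids(centroids: pd.DataFrame, path) -> None:
    centroids.rename_axis("gene").to_csv(path)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "family_id": str, "subtype": str})
    required = {"sample_id", "family_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)


def read_families(path) -> FamilyTable:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["family_id", "sample_id"]:
        raise ValueError(f"{path}: families CSV must have header family_id,sample_id")
    fams: dict[str, list[str]] = {}
    for fam, sample in zip(df["family_id"], df["sample_id"]):
        fams.setdefault(fam, []).append(sample)
    return FamilyTable(fams)


def write_families(families: FamilyTable, path) -> None:
    rows = [(f, s) for f, ss in families for s in ss]
    pd.DataFrame(rows, columns=["family_id", "sample_id"]).to_csv(path, index=False)


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "subtype"]:
        raise ValueError(f"{path}: labels CSV must have header sample_id,subtype")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in labels file")
    return dict(zip(df["sample_id"], df["subtype"]))


def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["sample_id", "subtype"]).to_csv(
        path, index=False
    )


def read_ratios(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample": str, "probe": str})
    if not {"sample", "probe", "ratio"}.issubset(df.columns):
        raise ValueError(f"{path}: ratios CSV must have header sample,probe,ratio")
    df["ratio"] = df["ratio"].astype(float)
    if (df["ratio"] < 0).any():
        raise ValueError(f"{path}: negative methylation ratios")
    return df


def write_ratios(table: pd.DataFrame, path) -> None:
    table[["sample", "probe", "ratio"]].to_csv(path, index=False)


def read_signature(path) -> SignatureModel:
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "gene,weight":
                    raise ValueError(f"{path}: expected 'gene,weight' header, got {line!r}")
                header_seen = True
                continue
            gene, _, weight = line.partition(",")
            rows.append((gene.strip(), float(weight)))
    for key in ("positive_class", "negative_class", "intercept", "subtype"):
        if key not in meta:
            raise ValueError(f"{path}: missing '#{key}=' metadata line")
    return SignatureModel(
        signature_gene_ids=tuple(g for g, _ in rows),
        weights=tuple(w for _, w in rows),
        intercept=float(meta["intercept"]),
        positive_class=meta["positive_class"],
        negative_class=meta["negative_class"],
        applicable_subtype=meta["subtype"],
    )


def write_signature(model: SignatureModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#positive_class={model.positive_class}\n")
        fh.write(f"#negative_class={model.negative_class}\n")
        fh.write(f"#intercept={model.intercept!r}\n")
        fh.write(f"#subtype={model.applicable_subtype}\n")
        fh.write("gene,weight\n")
        for g, w in zip(model.signature_gene_ids, model.weights):
            fh.write(f"{g},{w!r}\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
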