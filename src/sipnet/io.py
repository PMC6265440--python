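"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text:

- OTU counts: UTF-8 TSV, samples in rows, OTUs in columns, leading
  ``#SampleID`` header cell.
- Taxonomy side-file: ``otu_id<TAB>lineage`` with a semicolon-ranked
  lineage string.
- Sample metadata side-file: TSV with ``#SampleID`` plus species,
  strategy, compartment, replicate.
- BIOM 1.0 dense JSON (self-contained counts + taxonomy + metadata).
- Gradient profiles and activity tables as simple labeled TSVs.

All writers are deterministic (stable column order, fixed float
formatting) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .gradient import GradientProfile
from .otu import OtuTable

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
_BIOM_URL = "http://biom-format.org"


# ---------------------------------------------------------------------
# OTU table — TSV triplet
# ---------------------------------------------------------------------

def write_counts_tsv(table: OtuTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_taxonomy_tsv(table: OtuTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#OTU_ID\tlineage\n")
        for otu_id in table.otu_ids:
            fh.write(f"{otu_id}\t{table.taxonomy[otu_id]}\n")


def read_taxonomy_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df["lineage"]
    s.index.name = None
    return s


def write_sample_meta_tsv(table: OtuTable, path: str | Path) -> None:
    meta = table.sample_meta.copy()
    meta.index.name = "#SampleID"
    meta.to_csv(path, sep="\t")


def read_sample_meta_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_otu_table_tsv(table: OtuTable, prefix: str | Path) -> dict[str, Path]:
    """Write counts + taxonomy + metadata as three TSVs sharing a prefix."""
    prefix = Path(prefix)
    paths = {
        "counts": prefix.with_name(prefix.name + ".counts.tsv"),
        "taxonomy": prefix.with_name(prefix.name + ".taxonomy.tsv"),
        "sample_meta": prefix.with_name(prefix.name + ".samples.tsv"),
    }
    write_counts_tsv(table, paths["counts"])
    write_taxonomy_tsv(table, paths["taxonomy"])
    write_sample_meta_tsv(table, paths["sample_meta"])
    return paths


def read_otu_table_tsv(prefix: str | Path) -> OtuTable:
    prefix = Path(prefix)
    counts = read_counts_tsv(prefix.with_name(prefix.name + ".counts.tsv"))
    taxonomy = read_taxonomy_tsv(prefix.with_name(prefix.name + ".taxonomy.tsv"))
    meta = read_sample_meta_tsv(prefix.with_name(prefix.name + ".samples.tsv"))
    return OtuTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


# ---------------------------------------------------------------------
# OTU table — BIOM 1.0 dense JSON
# ---------------------------------------------------------------------

def write_biom_json(table: OtuTable, path: str | Path, generated_by: str = "sipnet") -> None:
    """Write the table as BIOM format 1.0, dense matrix variant.

    Rows are observations (OTUs), columns are samples, per the BIOM
    convention; taxonomy is stored as the per-observation ``taxonomy``
    metadata list and sample metadata on the columns.
    """
    data = table.counts.T  # observations × samples
    integral = bool(np.all(np.equal(np.mod(data.to_numpy(), 1), 0)))
    doc = {
        "id": None,
        "format": _BIOM_FORMAT,
        "format_url": _BIOM_URL,
        "type": "OTU table",
        "generated_by": generated_by,
        "date": datetime(2000, 1, 1, tzinfo=timezone.utc).isoformat(),
        "matrix_type": "dense",
        "matrix_element_type": "int" if integral else "float",
        "shape": [int(data.shape[0]), int(data.shape[1])],
        "rows": [
            {
                "id": otu_id,
                "metadata": {"taxonomy": str(table.taxonomy[otu_id]).split(";")},
            }
            for otu_id in data.index
        ],
        "columns": [
            {
                "id": sample_id,
                "metadata": {
                    k: (v.item() if isinstance(v, np.generic) else v)
                    for k, v in table.sample_meta.loc[sample_id].items()
                },
            }
            for sample_id in data.columns
        ],
        "data": [[int(x) if integral else float(x) for x in row] for row in data.to_numpy()],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_biom_json(path: str | Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ValueError("only dense BIOM 1.0 matrices are supported")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    data = np.asarray(doc["data"])
    counts = pd.DataFrame(data.T, index=sample_ids, columns=otu_ids)
    if doc.get("matrix_element_type") == "int":
        counts = counts.astype(np.int64)
    taxonomy = pd.Series(
        {r["id"]: ";".join((r.get("metadata") or {}).get("taxonomy", [])) for r in doc["rows"]}
    )
    meta = pd.DataFrame(
        {c["id"]: (c.get("metadata") or {}) for c in doc["columns"]}
    ).T.loc[sample_ids]
    return OtuTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


# ---------------------------------------------------------------------
# Gradient profiles / activity tables / distance matrices
# ---------------------------------------------------------------------

def write_gradient_tsv(profile: GradientProfile, path: str | Path) -> None:
    df = profile.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gradient_tsv(path: str | Path, label: str = "") -> GradientProfile:
    df = pd.read_csv(path, sep="\t")
    return GradientProfile.from_frame(df, label=label or Path(path).stem)


def write_activity_tsv(activity: pd.DataFrame, path: str | Path) -> None:
    df = activity.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_activity_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_distance_matrix_tsv(labels: list[str], values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_distance_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
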