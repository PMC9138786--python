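"""Tabular I/O: header-validated TSV readers and writers.

All tabular artifacts are tab-separated with a mandatory header line.
Readers validate the schema and report the offending file and line on
malformed input; every writer's output round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

DRUGS_SCHEMA = ("drug_id", "smiles")
EDGES_SCHEMA = ("drug_id_a", "drug_id_b")
ASSOC_SCHEMA = ("drug_id", "receptor_id", "function_type")


class TableFormatError(ValueError):
    """Malformed tabular input (named file, line and expected schema)."""


def read_table(path, required_cols) -> pd.DataFrame:
    """Read a TSV with a mandatory header containing ``required_cols``.

    Raises :class:`TableFormatError` naming the file, the line number and
    the expected schema on a missing header column or a row with the
    wrong number of fields.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TableFormatError(
            f"{path}: line 1: empty file; expected header with columns "
            f"{list(required_cols)}")
    header = lines[0].split("\t")
    missing = [c for c in required_cols if c not in header]
    if missing:
        raise TableFormatError(
            f"{path}: line 1: missing column(s) {missing}; expected "
            f"header with columns {list(required_cols)}")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TableFormatError(
                f"{path}: line {ln}: expected {len(header)} tab-separated "
                f"fields, got {len(fields)}")
        rows.append(fields)
    return pd.DataFrame(rows, columns=header)


def read_drugs(path) -> pd.DataFrame:
    return read_table(path, DRUGS_SCHEMA)


def read_edges(path) -> pd.DataFrame:
    return read_table(path, EDGES_SCHEMA)


def read_associations(path) -> pd.DataFrame:
    return read_table(path, ASSOC_SCHEMA)


def write_embeddings_tsv(path, names, vectors) -> None:
    """Write ``name\\tv1...vd`` rows with a header (token or node table)."""
    vectors = np.asarray(vectors)
    cols = [f"v{j}" for j in range(vectors.shape[1])]
    df = pd.DataFrame(vectors, columns=cols)
    df.insert(0, "id", list(names))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_embeddings_tsv(path):
    df = read_table(path, ("id",))
    names = df["id"].tolist()
    vecs = df.drop(columns="id").astype(float).to_numpy()
    return names, vecs


def write_matrix_tsv(path, matrix, labels) -> None:
    """Write an N x N matrix with drug-id header row and column."""
    df = pd.DataFrame(np.asarray(matrix), index=list(labels),
                      columns=list(labels))
    df.index.name = "drug_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.index.tolist(), df.to_numpy(dtype=float)


def write_metrics_json(path, result: dict) -> None:
    """Serialise a protocol result (fold reports + summary) to JSON."""
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and obj != obj:
            return None
        return obj
    keep = {k: v for k, v in result.items()
            if k in ("folds", "report", "summary", "config", "protocol")}
    if "report" in keep and hasattr(keep["report"], "as_dict"):
        keep["report"] = keep["report"].as_dict()
    with open(path, "w") as fh:
        json.dump(clean(keep), fh, indent=2, sort_keys=True)
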