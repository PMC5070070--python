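"""Readers and writers for the pipeline's tabular artifacts.

Counts travel as TSV (genes x subjects, header row of subject ids) or as
MatrixMarket with ``.rows``/``.cols`` sidecar files; phenotypes, evidence
and all result tables as TSV; the synthetic truth ledger and run reports as
JSON. Gene-set collections are read from GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse


def read_counts(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path).toarray()
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_counts(counts: pd.DataFrame, path, mtx: bool = False) -> None:
    path = Path(path)
    if mtx or path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        counts.to_csv(path, sep="\t")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" in df.columns:
        df = df.set_index("subject_id", drop=False)
        df.index.name = None
    return df


def read_evidence(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            continue
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")
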