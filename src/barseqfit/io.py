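"""Plain-text readers and writers for the pipeline's tabular interfaces.

Everything is TSV with a header (or JSON for summaries), so every stage's
output can be audited and re-loaded without the in-memory originals.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import CountMatrix

CATALOG_COLUMNS = ["strain_id", "gene", "up_tag", "down_tag", "collection"]
SAMPLESHEET_COLUMNS = ["sample_id", "index", "condition", "replicate", "generations"]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    if df["strain_id"].duplicated().any():
        raise ValueError("duplicate strain_id in catalog")
    for col in ("up_tag", "down_tag"):
        if (df[col].str.len() != 20).any():
            raise ValueError(f"{col} entries must be 20-mers")
    return df[CATALOG_COLUMNS]


def read_samplesheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLESHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["index"].duplicated().any():
        raise ValueError("duplicate multiplex index in sample sheet")
    bad_t0 = (df["condition"] == "t0") & (df["generations"] != 0)
    if bad_t0.any():
        raise ValueError("t0 samples must have generations = 0")
    return df[SAMPLESHEET_COLUMNS]


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError("annotation needs columns gene, term")
    return df[["gene", "term"]]


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_count_matrix(cm: CountMatrix, counts_path, ledger_path=None) -> None:
    write_tsv(cm.counts, counts_path, index=True)
    if ledger_path is not None:
        write_tsv(cm.ledger, ledger_path, index=True)


def read_count_matrix(counts_path, ledger_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if ledger_path is not None and Path(ledger_path).exists():
        ledger = pd.read_csv(ledger_path, sep="\t", index_col=0)
    else:
        ledger = pd.DataFrame(index=pd.Index([], name="sample_id"))
    return CountMatrix(counts=counts, ledger=ledger)


def write_fitness_table(table: pd.DataFrame, path) -> None:
    out = table.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fitness_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
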