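"""Tab-separated table I/O with column validation.

All tabular interchange formats are one-line-header TSV.  Column vocabularies
(version 1):

========================  =====================================================
table                     columns
========================  =====================================================
peptide quantification    protein_id, peptide_id, condition, replicate, xic
contaminant frequencies   protein_id, n_detected, n_total
compartment reference     protein_id, compartment
immunogold counts         compartment, field_id, Ngo, P
flow-cytometry events     FSC_A, FSC_H, SSC, GFP, AF647
========================  =====================================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

TABLE_FORMAT_VERSION = 1

PEPTIDE_COLUMNS = ["protein_id", "peptide_id", "condition", "replicate", "xic"]
CONTAMINANT_COLUMNS = ["protein_id", "n_detected", "n_total"]
REFERENCE_COLUMNS = ["protein_id", "compartment"]
GOLD_COLUMNS = ["compartment", "field_id", "Ngo", "P"]
FLOW_COLUMNS = ["FSC_A", "FSC_H", "SSC", "GFP", "AF647"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV (one header line, no index).

    Output is byte-deterministic for a given DataFrame.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a TSV table, optionally checking that ``required`` columns exist."""
    df = pd.read_csv(path, sep="\t")
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {missing}; "
                f"found {list(df.columns)}"
            )
    return df


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, PEPTIDE_COLUMNS)


def read_contaminant_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, CONTAMINANT_COLUMNS)


def read_reference_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, REFERENCE_COLUMNS)


def read_gold_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, GOLD_COLUMNS)


def read_flow_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, FLOW_COLUMNS)
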