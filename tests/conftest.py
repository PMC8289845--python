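import numpy as np
import pandas as pd
import pytest


def peptide_rows(protein, peptide, xics_by_condition):
    """Build long-format peptide rows: {condition: [xic per replicate]}."""
    rows = []
    for cond, vals in xics_by_condition.items():
        for rep, x in enumerate(vals, start=1):
            if x is not None:
                rows.append((protein, peptide, cond, rep, float(x)))
    return rows


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "peptide_id", "condition", "replicate", "xic"]
    )


@pytest.fixture
def fourfold_table():
    """Three peptides, every A value exactly 4x its B counterpart, no noise."""
    rows = []
    for j, base in enumerate([100.0, 400.0, 1600.0], start=1):
        rows += peptide_rows(
            "PROT1", f"pep{j}", {"A": [4 * base] * 3, "B": [base] * 3}
        )
    return make_table(rows)


@pytest.fixture
def constant_table():
    """All XICs identical across two conditions (null data)."""
    rows = []
    for pid in ("P1", "P2"):
        for j in (1, 2):
            rows += peptide_rows(pid, f"pep{j}", {"A": [500.0] * 3, "B": [500.0] * 3})
    return make_table(rows)


def make_diff(records):
    """Build a differential table from dicts with sensible defaults."""
    defaults = dict(
        log2fc=0.0,
        p_value=0.5,
        p_adj=0.5,
        n_peptides_a=3,
        n_peptides_b=3,
        n_replicates_with_evidence_a=3,
        n_replicates_with_evidence_b=3,
        quantifiable_a=True,
        quantifiable_b=True,
        flag="",
    )
    rows = []
    for rec in records:
        row = dict(defaults)
        row.update(rec)
        rows.append(row)
    return pd.DataFrame(rows)
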