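"""Specificity filtering and EV marker categorization.

Two-stage cascade applied to immuno-isolated EV proteomes:

1. :func:`specificity_filter` removes non-specifically isolated proteins.
   A protein is retained iff, in at least one GFP-bait condition, it is
   quantifiable (>= 2 peptides in >= 2 biological replicates) with a
   log2 fold change > 0 versus the non-transfected control, and it is not a
   recurrent affinity-purification contaminant (recovered in more than
   200/411 repository IP analyses, strict inequality).

2. :func:`categorize` assigns each retained protein one label from
   {enriched_A, enriched_B, common, unique_A, unique_B} from the CD63-vs-CD9
   differential: enriched requires |log2FC| >= 1 with adjusted p < 0.05;
   -1 < log2FC < 1 is common; peptides detected exclusively in one condition
   (with the 2-peptides-in-2-replicates evidence rule) are unique to it.

Boundary semantics are taken literally: "more than 200/411" is strict,
the fold-change cut ">= 1 or <= -1" is inclusive, "less than 0.05" strict.
Proteins with |log2FC| >= 1 but adjusted p >= 0.05 fall in no printed rule
and are assigned ``common`` with the audit flag ``not_significant_large_fc``
so that the category partition stays exhaustive.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("enriched_A", "enriched_B", "common", "unique_A", "unique_B")
EXCLUSION_REASONS = ("nonspecific_vs_NT", "crapome_contaminant", "insufficient_evidence")

DEFAULT_CONTAMINANT_FRAC = 200.0 / 411.0


def specificity_filter(
    diff_vs_nt: Mapping[str, pd.DataFrame],
    contaminants: pd.DataFrame,
    threshold_frac: float = DEFAULT_CONTAMINANT_FRAC,
) -> pd.DataFrame:
    """Partition proteins into retained / excluded-with-reason.

    Parameters
    ----------
    diff_vs_nt:
        Mapping GFP-condition label -> differential table of that condition
        versus the non-transfected control (GFP condition as side A, so a
        positive log2fc means enriched over the control; +inf sentinel counts
        as > 0).
    contaminants:
        Repository frequency table (protein_id, n_detected, n_total).
        Proteins absent from it are treated as never-detected (n_detected=0).
    threshold_frac:
        A protein is a contaminant when n_detected/n_total is strictly
        greater than this fraction (default 200/411).

    Returns a DataFrame with protein_id, retained (bool), reason (empty for
    retained), and per-condition pass bookkeeping.
    """
    contam = contaminants.set_index("protein_id")
    universe: set[str] = set()
    for d in diff_vs_nt.values():
        universe |= set(d["protein_id"])

    per_cond: dict[str, pd.DataFrame] = {
        cond: d.set_index("protein_id") for cond, d in diff_vs_nt.items()
    }
    rows = []
    for pid in sorted(universe):
        quantifiable_somewhere = False
        passes_any = False
        for cond, d in per_cond.items():
            if pid not in d.index:
                continue
            rec = d.loc[pid]
            if bool(rec["quantifiable_a"]):
                quantifiable_somewhere = True
                if rec["log2fc"] > 0:  # +inf sentinel compares > 0
                    passes_any = True
        if pid in contam.index:
            rec = contam.loc[pid]
            frac = float(rec["n_detected"]) / float(rec["n_total"])
        else:
            logger.info("protein %s absent from contaminant table; assuming 0", pid)
            frac = 0.0
        is_contam = frac > threshold_frac + 1e-12

        # first failing reason in the order nonspecific -> contaminant ->
        # insufficient evidence
        if quantifiable_somewhere and not passes_any:
            retained, reason = False, "nonspecific_vs_NT"
        elif is_contam:
            retained, reason = False, "crapome_contaminant"
        elif not quantifiable_somewhere:
            retained, reason = False, "insufficient_evidence"
        else:
            retained, reason = True, ""
        rows.append((pid, retained, reason, quantifiable_somewhere, passes_any, is_contam))
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "retained",
            "reason",
            "quantifiable_any_gfp",
            "specific_any_gfp",
            "crapome_contaminant",
        ],
    )


def categorize(
    diff_ab: pd.DataFrame,
    retained: Iterable[str],
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Assign marker categories from the A-vs-B (CD63 vs CD9) differential.

    Every protein in ``retained`` receives exactly one record: either a
    category or an exclusion reason (mutually exclusive).  Statistics from
    the differential are carried through for auditability.
    """
    retained_ids = sorted(set(retained))
    d = diff_ab.set_index("protein_id")
    rows = []
    for pid in retained_ids:
        if pid not in d.index:
            rows.append(_record(pid, None, "insufficient_evidence"))
            continue
        rec = d.loc[pid]
        quant_a, quant_b = bool(rec["quantifiable_a"]), bool(rec["quantifiable_b"])
        fc, padj = float(rec["log2fc"]), float(rec["p_adj"])
        if not quant_a and not quant_b:
            rows.append(_record(pid, None, "insufficient_evidence", rec))
        elif rec["n_peptides_b"] == 0:  # peptides exclusively in A
            if quant_a:
                rows.append(_record(pid, "unique_A", "", rec))
            else:
                rows.append(_record(pid, None, "insufficient_evidence", rec))
        elif rec["n_peptides_a"] == 0:  # peptides exclusively in B
            if quant_b:
                rows.append(_record(pid, "unique_B", "", rec))
            else:
                rows.append(_record(pid, None, "insufficient_evidence", rec))
        elif fc >= fc_threshold and not np.isnan(padj) and padj < alpha:
            rows.append(_record(pid, "enriched_A", "", rec))
        elif fc <= -fc_threshold and not np.isnan(padj) and padj < alpha:
            rows.append(_record(pid, "enriched_B", "", rec))
        elif -fc_threshold < fc < fc_threshold:
            rows.append(_record(pid, "common", "", rec))
        else:
            # |log2fc| >= threshold but not significant: kept in the partition
            # as common, flagged for audit
            rows.append(_record(pid, "common", "", rec, flag="not_significant_large_fc"))
    return pd.DataFrame(rows)


def _record(pid, category, reason, rec=None, flag=""):
    return {
        "protein_id": pid,
        "category": category if category else "",
        "excluded": reason,
        "flag": flag,
        "log2fc": float(rec["log2fc"]) if rec is not None else np.nan,
        "p_adj": float(rec["p_adj"]) if rec is not None else np.nan,
        "n_peptides_a": int(rec["n_peptides_a"]) if rec is not None else 0,
        "n_peptides_b": int(rec["n_peptides_b"]) if rec is not None else 0,
    }


def summarize_categories(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-category protein counts (excluded proteins grouped by reason)."""
    lab = assignments.apply(
        lambda r: r["category"] if r["category"] else f"excluded:{r['excluded']}", axis=1
    )
    return lab.value_counts().rename_axis("category").reset_index(name="n_proteins")
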