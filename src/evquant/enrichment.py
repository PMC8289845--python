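"""Subcellular-compartment enrichment by the hypergeometric upper tail.

Given a protein list and a reference annotation (protein -> set of
compartments, e.g. a spatial-proteome database), each compartment is tested
for over-representation: with N annotated reference proteins of which K carry
the compartment, and n list proteins found in the reference of which k carry
it, the reported p-value is the exact hypergeometric upper tail P(X >= k).
P-values are reported uncorrected (a BH-adjusted column is emitted as an
extension, clearly labeled).

Proteins are multi-label: a protein counts once per compartment it carries.
List proteins absent from the reference are excluded from n (the reference is
the universe) and reported in the coverage attributes.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from evquant.lfq import adjust_bh

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = [
    "compartment",
    "k",
    "n",
    "K",
    "N",
    "percent_list",
    "percent_reference",
    "p_value",
    "p_adj_bh_extension",
]


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters follow the sampling reading: N population size, K marked,
    n drawn, k marked among the drawn.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"require 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        return 0.0
    # sf(k-1) = P(X >= k); scipy's hypergeom is exact
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_list(
    protein_list: Iterable[str], reference: pd.DataFrame
) -> pd.DataFrame:
    """Compartment enrichment of a protein list against a reference.

    Parameters
    ----------
    protein_list:
        Protein identifiers (duplicates ignored).
    reference:
        Long-format annotation, columns protein_id and compartment.

    Returns one row per compartment present in the reference, sorted by
    p-value ascending.  ``.attrs`` carries coverage bookkeeping:
    ``n_listed``, ``n_in_reference``, ``n_unmapped``.
    """
    listed = set(protein_list)
    if not listed:
        raise ValueError("protein list is empty")
    ref = reference.drop_duplicates(subset=["protein_id", "compartment"])
    ref_proteins = set(ref["protein_id"])
    N = len(ref_proteins)
    in_ref = listed & ref_proteins
    n = len(in_ref)
    unmapped = len(listed) - n
    if unmapped:
        logger.warning("%d of %d list proteins absent from the reference", unmapped, len(listed))
    rows = []
    if n:
        by_comp = ref.groupby("compartment")["protein_id"]
        for comp, members in by_comp:
            member_set = set(members)
            K = len(member_set)
            k = len(in_ref & member_set)
            rows.append(
                {
                    "compartment": comp,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "percent_list": 100.0 * k / n,
                    "percent_reference": 100.0 * K / N,
                    "p_value": hypergeom_upper(k, n, K, N),
                }
            )
    else:
        logger.warning("no overlap between list and reference; empty result")
    out = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c != "p_adj_bh_extension"])
    if len(out):
        out["p_adj_bh_extension"] = adjust_bh(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["p_adj_bh_extension"] = pd.Series(dtype=float)
    out.attrs.update(n_listed=len(listed), n_in_reference=n, n_unmapped=unmapped)
    return out
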