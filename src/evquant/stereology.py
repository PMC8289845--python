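"""Immunogold stereology: labeling density, relative labeling index, chi-square.

For each compartment c with observed gold count ``Ngo_c`` and superimposed
grid-point count ``P_c``:

* labeling density       LD_c  = Ngo_c / P_c   (golds per test point)
* whole-cell density     LD    = sum(Ngo) / sum(P)
* relative labeling idx  RLI_c = LD_c / LD     (1 = random labeling)
* expected golds         Nge_c = sum(Ngo) * P_c / sum(P)
* partial chi-square     (Ngo_c - Nge_c)^2 / Nge_c

The observed and expected distributions are compared by a chi-square test
with (analyzed compartments - 1) degrees of freedom.  A compartment is
flagged as preferentially labeled when its partial chi-square accounts for at
least 10% of the total AND it is over-labeled (Ngo > Nge); under-labeled
compartments meeting the 10% cutoff get a separate ``depleted`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PARTIAL_CHI2_CUTOFF = 0.10


@dataclass
class RLIResult:
    """Per-compartment stereology table plus test summary.

    ``table`` columns: compartment, Ngo, P, LD, RLI, Nge, partial_chi2,
    included (entered the chi-square), preferential, depleted.
    """

    table: pd.DataFrame
    ld_cell: float
    total_chi2: float
    df: int
    p_value: float
    all_undefined: bool = False


def _pool(table: pd.DataFrame) -> pd.DataFrame:
    """Pool counts across fields, preserving first-appearance order."""
    pooled = (
        table.groupby("compartment", sort=False)[["Ngo", "P"]].sum().reset_index()
    )
    return pooled


def compute_rli(table: pd.DataFrame) -> RLIResult:
    """Labeling densities, RLI and partial chi-squares from a count table.

    ``table`` needs columns compartment, Ngo, P (a field_id column, if
    present, is pooled over).  Compartments with P = 0 get undefined LD/RLI
    and are excluded from the chi-square (df reduced).  A table with zero
    total golds returns an all-undefined, explicitly flagged result.
    """
    pooled = _pool(table)
    ngo = pooled["Ngo"].to_numpy(dtype=float)
    p = pooled["P"].to_numpy(dtype=float)
    if np.any(ngo < 0) or np.any(p < 0):
        raise ValueError("counts must be >= 0")
    total_p = p.sum()
    total_g = ngo.sum()
    if total_p <= 0:
        raise ValueError("total grid points must be > 0")

    out = pooled.copy()
    if total_g == 0:
        logger.warning("zero observed golds: LD/RLI undefined for all compartments")
        for col in ("LD", "RLI", "Nge", "partial_chi2"):
            out[col] = np.nan
        out["included"] = False
        out["preferential"] = False
        out["depleted"] = False
        return RLIResult(out, np.nan, np.nan, 0, np.nan, all_undefined=True)

    ld_cell = total_g / total_p
    with np.errstate(divide="ignore", invalid="ignore"):
        ld = np.where(p > 0, ngo / np.where(p > 0, p, 1.0), np.nan)
        rli = ld / ld_cell
    nge = total_g * p / total_p
    included = p > 0
    if np.any(~included & (ngo > 0)):
        logger.warning(
            "compartment(s) with golds but no grid points excluded from chi-square"
        )
    partial = np.full(len(ngo), np.nan)
    partial[included] = (ngo[included] - nge[included]) ** 2 / nge[included]
    total_chi2 = float(np.nansum(partial[included]))
    df = int(included.sum()) - 1
    if df >= 1:
        p_value = float(stats.chi2.sf(total_chi2, df))
    else:
        p_value = np.nan

    over = ngo > nge
    big = np.where(
        np.isnan(partial) | (total_chi2 <= 0),
        False,
        partial >= PARTIAL_CHI2_CUTOFF * total_chi2,
    )
    out["LD"] = ld
    out["RLI"] = rli
    out["Nge"] = nge
    out["partial_chi2"] = partial
    out["included"] = included
    out["preferential"] = big & over & included
    out["depleted"] = big & ~over & included
    return RLIResult(out, float(ld_cell), total_chi2, df, p_value)


def chi2_distribution_test(
    table: pd.DataFrame,
) -> tuple[float, int, float, pd.DataFrame]:
    """Observed-vs-expected chi-square comparison across compartments.

    Returns (total_chi2, df, p_value, per-compartment table with partials
    and preferential/depleted flags).  Requires at least two compartments
    with grid points (df >= 1).
    """
    res = compute_rli(table)
    if res.all_undefined:
        raise ValueError("zero observed golds: chi-square test undefined")
    if res.df < 1:
        raise ValueError("need >= 2 compartments with grid points (df >= 1)")
    return res.total_chi2, res.df, res.p_value, res.table
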