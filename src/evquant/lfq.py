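"""Label-free quantification statistics at the peptide level.

The differential-abundance model works on log2 XIC intensities of peptides
shared between the two compared conditions and fits, per protein, the
fixed-effects linear model

    log2(xic) = condition + peptide + replicate + error

by ordinary least squares.  The protein's log2 fold change is the estimated
condition contrast (A − B) and its p-value a two-tailed t-test on that
contrast with residual degrees of freedom.  Proteins detected in only one
condition receive a signed-infinity fold-change sentinel (they are handled
downstream by the "unique" categorization rule).  P-values are adjusted with
the Benjamini–Hochberg step-up procedure.

Before model fitting, per-sample median/scale normalization on the total
signal aligns each biological replicate's log2 intensity distribution
(median and median absolute deviation) to the pooled values.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DIFF_COLUMNS = [
    "protein_id",
    "log2fc",
    "p_value",
    "p_adj",
    "n_peptides_a",
    "n_peptides_b",
    "n_replicates_with_evidence_a",
    "n_replicates_with_evidence_b",
    "quantifiable_a",
    "quantifiable_b",
    "flag",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_total_signal(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median and scale normalization of XICs per biological replicate.

    On the log2 scale, each (condition, replicate) sample is shifted and
    rescaled so its median equals the across-sample median of per-sample
    medians and its median absolute deviation (MAD) equals the across-sample
    median of per-sample MADs.  Per-sample targets make the transform of one
    sample invariant to a pure rescaling of another, so fold changes are
    unaffected by instrument-level intensity drift.  Samples with fewer than
    two observed values, or zero MAD, are left unscaled (warning logged).

    Returns the normalized table (row order preserved) and a report with one
    row per sample: the log2 location subtracted (``shift``), the scale
    factor applied (``scale``) and the target median — enough to invert the
    transform exactly.
    """
    if table.empty:
        raise ValueError("peptide table is empty")
    out = table.copy()
    log2x = np.log2(out["xic"].to_numpy(dtype=float))

    samples = list(
        out[["condition", "replicate"]].drop_duplicates().itertuples(index=False)
    )
    stats_by_sample: dict[tuple, tuple[np.ndarray, float, float]] = {}
    for cond, rep in samples:
        pos = ((out["condition"] == cond) & (out["replicate"] == rep)).to_numpy()
        vals = log2x[pos]
        med = float(np.median(vals)) if len(vals) else np.nan
        mad = float(np.median(np.abs(vals - med))) if len(vals) else np.nan
        stats_by_sample[(cond, rep)] = (pos, med, mad)
    usable = [(m, s) for pos, m, s in stats_by_sample.values() if pos.sum() >= 2]
    if usable:
        grand_med = float(np.median([m for m, _ in usable]))
        grand_mad = float(np.median([s for _, s in usable]))
    else:  # no sample is scalable; targets are moot
        grand_med, grand_mad = float(np.median(log2x)), 0.0

    report_rows = []
    new = log2x.copy()
    for cond, rep in samples:
        pos, med, mad = stats_by_sample[(cond, rep)]
        if pos.sum() < 2:
            logger.warning(
                "sample (%s, rep %s) has <2 observed XICs; left unscaled", cond, rep
            )
            report_rows.append((cond, rep, 0.0, 1.0, grand_med, int(pos.sum())))
            continue
        scale = grand_mad / mad if mad > 0 and grand_mad > 0 else 1.0
        new[pos] = (log2x[pos] - med) * scale + grand_med
        report_rows.append((cond, rep, med, scale, grand_med, int(pos.sum())))
    out["xic"] = 2.0**new
    report = pd.DataFrame(
        report_rows,
        columns=["condition", "replicate", "shift", "scale", "target_median", "n_obs"],
    )
    return out, report


def denormalize(table: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`normalize_total_signal` using its report."""
    out = table.copy()
    log2x = np.log2(out["xic"].to_numpy(dtype=float))
    for row in report.itertuples(index=False):
        sel = (
            (out["condition"] == row.condition) & (out["replicate"] == row.replicate)
        ).to_numpy()
        log2x[sel] = (log2x[sel] - row.target_median) / row.scale + row.shift
    out["xic"] = 2.0**log2x
    return out


# ---------------------------------------------------------------------------
# per-protein linear model
# ---------------------------------------------------------------------------

def _evidence_counts(sub: pd.DataFrame) -> tuple[int, int, bool]:
    """Peptide count, replicate-evidence count and quantifiable flag.

    A replicate provides evidence when it contains >= 2 quantified peptides;
    a protein is quantifiable in a condition when >= 2 replicates provide
    evidence ("at least 2 peptides in 2 replicates").
    """
    n_pep = sub["peptide_id"].nunique()
    per_rep = sub.groupby("replicate")["peptide_id"].nunique()
    n_rep_evidence = int((per_rep >= 2).sum())
    return int(n_pep), n_rep_evidence, n_rep_evidence >= 2


def _fit_protein(sub: pd.DataFrame, cond_a: str) -> tuple[float, float]:
    """OLS fit of condition + peptide + replicate on log2 XIC.

    Returns (log2fc, p_value); p is NaN when the residual df is zero or the
    contrast is not estimable.
    """
    y = np.log2(sub["xic"].to_numpy(dtype=float))
    n = len(y)
    cond = (sub["condition"] == cond_a).to_numpy(dtype=float)
    cols = [np.ones(n), cond]
    for factor in ("peptide_id", "replicate"):
        levels = pd.unique(sub[factor])
        for lev in levels[1:]:
            cols.append((sub[factor] == lev).to_numpy(dtype=float))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    df_resid = n - rank
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    log2fc = float(beta[1])
    if df_resid <= 0:
        return log2fc, np.nan
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df_resid
    var_b = sigma2 * XtX_inv[1, 1]
    if var_b <= 1e-20 * max(1.0, float(y @ y)):
        # degenerate noiseless fit: a zero contrast is exactly null (p = 1);
        # a non-zero contrast has no valid test
        return log2fc, 1.0 if abs(log2fc) < 1e-12 else np.nan
    t = log2fc / np.sqrt(var_b)
    p = 2.0 * stats.t.sf(abs(t), df_resid)
    return log2fc, float(p)


def protein_differential(
    table: pd.DataFrame, cond_a: str, cond_b: str, adjust: bool = True
) -> pd.DataFrame:
    """Per-protein differential abundance between two conditions.

    Parameters
    ----------
    table:
        Long-format peptide quantification table (protein_id, peptide_id,
        condition, replicate, xic); missing XICs are simply absent rows.
    cond_a, cond_b:
        Condition labels; the reported log2 fold change is A over B.
    adjust:
        Add a Benjamini–Hochberg adjusted p-value column (over the proteins
        of this comparison).

    Returns a DataFrame with one row per protein (columns ``DIFF_COLUMNS``).
    Proteins with fewer than 2 total observations are excluded (logged).
    Proteins observed in only one condition get a signed-infinity log2fc and
    no p-value.
    """
    present = set(table["condition"].unique())
    for c in (cond_a, cond_b):
        if c not in present:
            raise ValueError(f"condition {c!r} not present in table")
    sub_all = table[table["condition"].isin([cond_a, cond_b])]

    rows = []
    for pid, sub in sub_all.groupby("protein_id", sort=True):
        if len(sub) < 2:
            logger.info("protein %s excluded: <2 observations", pid)
            continue
        sub_a = sub[sub["condition"] == cond_a]
        sub_b = sub[sub["condition"] == cond_b]
        n_pep_a, n_rep_a, quant_a = _evidence_counts(sub_a)
        n_pep_b, n_rep_b, quant_b = _evidence_counts(sub_b)
        flag = ""
        if n_pep_b == 0:
            log2fc, p = np.inf, np.nan
        elif n_pep_a == 0:
            log2fc, p = -np.inf, np.nan
        else:
            shared = set(sub_a["peptide_id"]) & set(sub_b["peptide_id"])
            if not shared:
                # no peptide bridges the conditions: report the unadjusted
                # mean difference, with no valid test
                log2fc = float(
                    np.log2(sub_a["xic"]).mean() - np.log2(sub_b["xic"]).mean()
                )
                p = np.nan
                flag = "no_shared_peptides"
            else:
                fit_sub = sub[sub["peptide_id"].isin(shared)]
                log2fc, p = _fit_protein(fit_sub, cond_a)
                if np.isnan(p):
                    flag = "zero_residual_df"
        rows.append(
            (pid, log2fc, p, np.nan, n_pep_a, n_pep_b, n_rep_a, n_rep_b,
             quant_a, quant_b, flag)
        )
    diff = pd.DataFrame(rows, columns=DIFF_COLUMNS)
    if adjust and len(diff):
        diff["p_adj"] = adjust_bh(diff["p_value"].to_numpy())
    return diff


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def adjust_bh(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs pass through unchanged."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
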