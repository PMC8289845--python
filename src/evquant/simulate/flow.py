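"""Synthetic flow-cytometry event tables.

Events are drawn as log-normal fluorescence clouds with configurable median
intensities (the median of a log-normal is exp(mu), so planted medians are
exact population targets), plus forward/side-scatter structure: an intact-cell
population, a low-scatter debris fraction, and a doublet fraction whose
FSC-A is about twice its FSC-H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FlowSimConfig:
    n_events: int = 10_000
    mfi_gfp: float = 5_000.0
    mfi_af647: float = 1_000.0
    sigma_log: float = 0.5  # log-space SD of the fluorescence clouds
    debris_frac: float = 0.10
    doublet_frac: float = 0.05
    fsc_center: float = 100_000.0
    fsc_sd: float = 12_000.0
    ssc_center: float = 60_000.0
    ssc_sd: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 100:
            raise ValueError("n_events must be >= 100")
        if self.mfi_gfp < 0 or self.mfi_af647 < 0:
            raise ValueError("median intensities must be >= 0")
        if self.debris_frac + self.doublet_frac > 1.0:
            raise ValueError("debris_frac + doublet_frac must be <= 1")
        if not (0 <= self.debris_frac <= 1 and 0 <= self.doublet_frac <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


def _lognormal_median(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    if median == 0:
        return np.zeros(n)
    return np.exp(rng.normal(np.log(median), sigma, size=n))


def gen_flow_events(config: FlowSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one event table and its ground truth.

    Returns
    -------
    events : DataFrame
        Columns FSC_A, FSC_H, SSC, GFP, AF647 plus an ``event_kind`` column
        ("cell", "debris", "doublet") retained for bookkeeping.
    truth : DataFrame
        Single row with the planted medians and population fractions.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_events
    n_debris = int(round(cfg.debris_frac * n))
    n_doublet = int(round(cfg.doublet_frac * n))
    n_cell = n - n_debris - n_doublet

    kind = np.array(["cell"] * n_cell + ["debris"] * n_debris + ["doublet"] * n_doublet)

    fsc_a = np.empty(n)
    fsc_h = np.empty(n)
    ssc = np.empty(n)
    # intact singlet cells: FSC-A ~ FSC-H
    fsc_a[:n_cell] = rng.normal(cfg.fsc_center, cfg.fsc_sd, n_cell)
    fsc_h[:n_cell] = fsc_a[:n_cell] * rng.normal(1.0, 0.02, n_cell)
    ssc[:n_cell] = rng.normal(cfg.ssc_center, cfg.ssc_sd, n_cell)
    # debris: low scatter
    sl = slice(n_cell, n_cell + n_debris)
    fsc_a[sl] = np.abs(rng.normal(0.12 * cfg.fsc_center, 0.05 * cfg.fsc_center, n_debris))
    fsc_h[sl] = fsc_a[sl] * rng.normal(1.0, 0.05, n_debris)
    ssc[sl] = np.abs(rng.normal(0.10 * cfg.ssc_center, 0.05 * cfg.ssc_center, n_debris))
    # doublets: FSC-A about twice FSC-H
    sl = slice(n_cell + n_debris, n)
    fsc_a[sl] = rng.normal(2 * cfg.fsc_center, 1.5 * cfg.fsc_sd, n_doublet)
    fsc_h[sl] = fsc_a[sl] / 2.0 * rng.normal(1.0, 0.02, n_doublet)
    ssc[sl] = rng.normal(1.5 * cfg.ssc_center, cfg.ssc_sd, n_doublet)

    gfp = _lognormal_median(rng, cfg.mfi_gfp, cfg.sigma_log, n)
    af647 = _lognormal_median(rng, cfg.mfi_af647, cfg.sigma_log, n)

    events = pd.DataFrame(
        {
            "FSC_A": np.clip(fsc_a, 0, None),
            "FSC_H": np.clip(fsc_h, 0, None),
            "SSC": np.clip(ssc, 0, None),
            "GFP": gfp,
            "AF647": af647,
            "event_kind": kind,
        }
    )
    truth = pd.DataFrame(
        [
            {
                "mfi_gfp": cfg.mfi_gfp,
                "mfi_af647": cfg.mfi_af647,
                "debris_frac": n_debris / n,
                "doublet_frac": n_doublet / n,
                "cell_frac": n_cell / n,
            }
        ]
    )
    return events, truth
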