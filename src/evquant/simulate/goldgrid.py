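"""Synthetic immunogold count tables over cellular compartments.

Emulates quantitative immuno-EM sampling: a digital point grid superimposed on
micrograph fields yields per-compartment point counts P (area proxies), and
gold particles are distributed over compartments according to the compartment
areas modulated by planted relative labeling indices (RLI).

The last compartment acts as the residual ("rest of cell"): it absorbs the
probability mass left after the named compartments take ``point_fraction x
true_rli`` each, so the configured RLI of every non-residual compartment is
realized exactly in expectation (RLI = 1 everywhere reproduces random
labeling).  The realized residual RLI is recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EMSimConfig:
    """Sampling design for one synthetic immuno-EM experiment.

    Defaults mirror the compartments analyzed in the study system (MVBs, ER,
    Golgi, PM) plus a residual "rest" category, with 7 fields per experiment.
    """

    compartments: tuple[str, ...] = ("MVB", "ER", "Golgi", "PM", "rest")
    point_fractions: tuple[float, ...] = (0.05, 0.15, 0.10, 0.20, 0.50)
    true_rli: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    total_golds: int = 1000
    total_points: int = 2000
    n_fields: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.compartments)
        if k < 2:
            raise ValueError("need at least 2 compartments")
        if len(self.point_fractions) != k or len(self.true_rli) != k:
            raise ValueError("point_fractions and true_rli must match compartments")
        f = np.asarray(self.point_fractions, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"point_fractions sum to {f.sum():.12f}, expected 1")
        if np.any(f < 0):
            raise ValueError("point_fractions must be >= 0")
        if np.any(np.asarray(self.true_rli) < 0):
            raise ValueError("true_rli must be >= 0")
        if self.total_points <= 0:
            raise ValueError("total_points must be > 0")
        if self.total_golds < 0:
            raise ValueError("total_golds must be >= 0")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if self._gold_probs()[-1] < -1e-12:
            raise ValueError(
                "configured point_fractions x true_rli exceed 1; the residual "
                "compartment would need negative probability"
            )

    def _gold_probs(self) -> np.ndarray:
        f = np.asarray(self.point_fractions, dtype=float)
        r = np.asarray(self.true_rli, dtype=float)
        p = f * r
        p[-1] = 1.0 - p[:-1].sum()
        return p


def gen_gold_counts(config: EMSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gold-count table and its ground truth.

    Returns
    -------
    table : DataFrame
        Long format: compartment, field_id, Ngo, P.  Ngo sums to
        ``total_golds`` and P to ``total_points`` exactly.
    truth : DataFrame
        compartment, point_fraction, true_rli (realized expectation,
        including the residual compartment's absorbed value).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    f = np.asarray(cfg.point_fractions, dtype=float)
    probs = cfg._gold_probs()
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()

    golds = rng.multinomial(cfg.total_golds, probs)
    # grid points apportioned deterministically (largest remainder): the
    # digital point array samples fixed compartment areas, so P carries no
    # sampling noise of its own
    raw = f * cfg.total_points
    points = np.floor(raw).astype(int)
    remainder = cfg.total_points - points.sum()
    order = np.argsort(-(raw - points), kind="stable")
    points[order[:remainder]] += 1

    # split each compartment's counts uniformly across fields
    field_share = np.full(cfg.n_fields, 1.0 / cfg.n_fields)
    rows = []
    for ci, comp in enumerate(cfg.compartments):
        g_split = rng.multinomial(golds[ci], field_share)
        p_split = rng.multinomial(points[ci], field_share)
        for fi in range(cfg.n_fields):
            rows.append((comp, fi + 1, int(g_split[fi]), int(p_split[fi])))
    table = pd.DataFrame(rows, columns=["compartment", "field_id", "Ngo", "P"])

    realized_rli = np.where(f > 0, probs / np.where(f > 0, f, 1.0), np.nan)
    truth = pd.DataFrame(
        {
            "compartment": list(cfg.compartments),
            "point_fraction": f,
            "true_rli": realized_rli,
        }
    )
    return table, truth
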