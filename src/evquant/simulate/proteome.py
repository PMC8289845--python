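"""Synthetic peptide-level quantification tables with planted protein classes.

The generator plants eight protein classes:

``enriched_A`` / ``enriched_B``
    present in both GFP pulldowns, true |log2FC| = ``effect_log2fc`` between
    CD63-eGFP (A) and CD9-eGFP (B) vesicles.
``common``
    present in both GFP pulldowns at equal abundance.
``unique_A`` / ``unique_B``
    peptides detected exclusively in one GFP condition.
``contaminant``
    abundant in all conditions and carrying a high recovery frequency in the
    affinity-purification contaminant repository (the CRAPome), so the
    frequency filter removes it.
``nonspecific``
    at least as abundant in the non-transfected control as in the GFP
    pulldowns (log2FC GFP vs NT <= 0), so the specificity filter removes it.
``background`` (remainder)
    a single low-evidence peptide, failing the two-peptides-in-two-replicates
    rule everywhere.

XIC intensities are log-normal on the log2 scale; per-sample (condition x
replicate) offsets create the between-replicate location/scale differences
that total-signal normalization is meant to remove.  Missing values are
completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

COND_CD63 = "CD63-eGFP"
COND_CD9 = "CD9-eGFP"
COND_NT = "NT"

CLASSES = (
    "enriched_A",
    "enriched_B",
    "common",
    "unique_A",
    "unique_B",
    "contaminant",
    "nonspecific",
    "background",
)

# Subcellular compartment vocabulary and per-class annotation profiles.
# Endosome-derived (CD63) proteins are biased towards lysosomal/late-endosomal
# labels, plasma-membrane-derived (CD9) proteins towards the PM.
_COMPARTMENTS = (
    "lysosome",
    "late endosome",
    "plasma membrane",
    "cytoplasm",
    "Golgi apparatus",
    "endoplasmic reticulum",
    "nucleus",
)
_BASE_RATES = np.array([0.02, 0.02, 0.14, 0.35, 0.07, 0.10, 0.30])
_CLASS_PROFILE = {
    "enriched_A": np.array([0.40, 0.30, 0.05, 0.10, 0.05, 0.05, 0.05]),
    "unique_A": np.array([0.40, 0.30, 0.05, 0.10, 0.05, 0.05, 0.05]),
    "enriched_B": np.array([0.03, 0.02, 0.65, 0.15, 0.05, 0.05, 0.05]),
    "unique_B": np.array([0.03, 0.02, 0.65, 0.15, 0.05, 0.05, 0.05]),
    "common": np.array([0.10, 0.10, 0.30, 0.30, 0.05, 0.05, 0.10]),
}


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Study conditions for the synthetic immuno-isolation proteome.

    Defaults mirror the deposited experiment: three conditions (CD63-eGFP,
    CD9-eGFP, non-transfected) with four biological replicates each and a
    contaminant-repository size of 411 affinity-purification runs.
    """

    n_proteins: int = 400
    frac_enriched_a: float = 0.10
    frac_enriched_b: float = 0.10
    frac_common: float = 0.30
    frac_unique_a: float = 0.075
    frac_unique_b: float = 0.075
    frac_contaminant: float = 0.05
    frac_nonspecific: float = 0.10
    peptides_per_protein: tuple[int, int] = (3, 8)
    n_replicates: int = 4
    effect_log2fc: float = 2.0
    noise_sd_log2: float = 0.3
    missing_rate: float = 0.05
    # SD of per-sample (condition x replicate) location offsets, removed by
    # total-signal normalization
    replicate_shift_sd: float = 0.25
    crapome_total: int = 411
    n_reference_decoys: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.class_fractions()
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {name}={f} outside [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ValueError(f"class fractions sum to {sum(fracs.values()):.4f} > 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must be a valid range with min >= 1")

    def class_fractions(self) -> dict[str, float]:
        return {
            "enriched_A": self.frac_enriched_a,
            "enriched_B": self.frac_enriched_b,
            "common": self.frac_common,
            "unique_A": self.frac_unique_a,
            "unique_B": self.frac_unique_b,
            "contaminant": self.frac_contaminant,
            "nonspecific": self.frac_nonspecific,
        }

    def class_counts(self) -> dict[str, int]:
        """Deterministic integer class sizes (largest-remainder rounding)."""
        fracs = self.class_fractions()
        raw = {k: f * self.n_proteins for k, f in fracs.items()}
        counts = {k: int(np.floor(v)) for k, v in raw.items()}
        leftover = [(raw[k] - counts[k], k) for k in fracs]
        n_extra = int(round(sum(raw.values()))) - sum(counts.values())
        for _, k in sorted(leftover, reverse=True)[:n_extra]:
            counts[k] += 1
        counts["background"] = self.n_proteins - sum(counts.values())
        return counts


def _class_condition_means(
    cls: str, base: float, cfg: ProteomeSimConfig
) -> dict[str, float | None]:
    """Mean log2 abundance per condition; None = protein absent there.

    Specifically isolated proteins are absent from the non-transfected
    control pulldown (no GFP bait to capture them), so their GFP-vs-NT fold
    change is the +infinity sentinel; contaminants and nonspecific material
    are present in the control at comparable or higher abundance.
    """
    eff = cfg.effect_log2fc
    if cls == "enriched_A":
        return {COND_CD63: base + eff / 2, COND_CD9: base - eff / 2, COND_NT: None}
    if cls == "enriched_B":
        return {COND_CD63: base - eff / 2, COND_CD9: base + eff / 2, COND_NT: None}
    if cls == "common":
        return {COND_CD63: base, COND_CD9: base, COND_NT: None}
    if cls == "unique_A":
        return {COND_CD63: base, COND_CD9: None, COND_NT: None}
    if cls == "unique_B":
        return {COND_CD63: None, COND_CD9: base, COND_NT: None}
    if cls == "contaminant":
        # abundant everywhere; slightly above NT so only the repository
        # frequency filter removes it
        return {COND_CD63: base, COND_CD9: base, COND_NT: base - 0.5}
    if cls == "nonspecific":
        # more abundant in the non-transfected control than in the pulldowns
        return {COND_CD63: base, COND_CD9: base, COND_NT: base + 1.0}
    if cls == "background":
        return {COND_CD63: base, COND_CD9: base, COND_NT: base}
    raise ValueError(cls)


def _true_log2fc(cls: str, cfg: ProteomeSimConfig) -> float:
    if cls == "enriched_A":
        return cfg.effect_log2fc
    if cls == "enriched_B":
        return -cfg.effect_log2fc
    if cls == "unique_A":
        return np.inf
    if cls == "unique_B":
        return -np.inf
    if cls in ("common", "contaminant", "nonspecific"):
        return 0.0
    return np.nan


def gen_peptide_table(
    config: ProteomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a peptide XIC table plus its companion inputs.

    Returns
    -------
    peptides : DataFrame
        Long-format columns protein_id, peptide_id, condition, replicate, xic.
    contaminants : DataFrame
        protein_id, n_detected, n_total (repository frequencies).
    reference : DataFrame
        protein_id, compartment (multi-label subcellular annotation; includes
        decoy reference-only proteins forming the enrichment universe).
    truth : DataFrame
        protein_id, true_class, true_log2fc, n_peptides.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.class_counts()
    labels: list[str] = []
    for cls in CLASSES:
        labels.extend([cls] * counts[cls])
    width = max(4, len(str(cfg.n_proteins)))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(cfg.n_proteins)]

    # per-sample location offsets shared across proteins (normalization target)
    conditions = (COND_CD63, COND_CD9, COND_NT)
    sample_shift = {
        (c, r): rng.normal(0.0, cfg.replicate_shift_sd)
        for c in conditions
        for r in range(1, cfg.n_replicates + 1)
    }

    lo, hi = cfg.peptides_per_protein
    rows: list[tuple[str, str, str, int, float]] = []
    truth_rows: list[tuple[str, str, float, int]] = []
    for pid, cls in zip(protein_ids, labels):
        base = rng.uniform(22.0, 28.0)
        n_pep = 1 if cls == "background" else int(rng.integers(lo, hi + 1))
        pep_offsets = rng.normal(0.0, 1.5, size=n_pep)
        means = _class_condition_means(cls, base, cfg)
        truth_rows.append((pid, cls, _true_log2fc(cls, cfg), n_pep))
        for j in range(n_pep):
            pep_id = f"{pid}_pep{j + 1:02d}"
            for cond in conditions:
                mu = means[cond]
                if mu is None:
                    continue
                for rep in range(1, cfg.n_replicates + 1):
                    if cls == "background" and rep > 1:
                        continue  # single-replicate evidence only
                    if rng.uniform() < cfg.missing_rate:
                        continue
                    log2x = (
                        mu
                        + pep_offsets[j]
                        + sample_shift[(cond, rep)]
                        + rng.normal(0.0, cfg.noise_sd_log2)
                    )
                    rows.append((pid, pep_id, cond, rep, float(2.0**log2x)))

    peptides = pd.DataFrame(
        rows, columns=["protein_id", "peptide_id", "condition", "replicate", "xic"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "true_class", "true_log2fc", "n_peptides"]
    )

    # contaminant repository frequencies
    is_contam = truth["true_class"].to_numpy() == "contaminant"
    threshold = int(round(cfg.crapome_total * 200 / 411))
    n_det = rng.integers(0, max(threshold // 2, 1) + 1, size=cfg.n_proteins)
    n_det[is_contam] = rng.integers(
        threshold + 1, cfg.crapome_total + 1, size=int(is_contam.sum())
    )
    contaminants = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "n_detected": n_det,
            "n_total": cfg.crapome_total,
        }
    )

    reference = _gen_reference(truth, cfg, rng)
    return peptides, contaminants, reference, truth


def _gen_reference(
    truth: pd.DataFrame, cfg: ProteomeSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Multi-label compartment annotation for generated + decoy proteins."""
    comps = np.array(_COMPARTMENTS)
    rows: list[tuple[str, str]] = []
    for pid, cls in zip(truth["protein_id"], truth["true_class"]):
        profile = _CLASS_PROFILE.get(cls, _BASE_RATES)
        primary = rng.choice(comps, p=profile / profile.sum())
        rows.append((pid, str(primary)))
        if rng.uniform() < 0.3:  # multi-compartment proteins
            second = rng.choice(comps, p=_BASE_RATES / _BASE_RATES.sum())
            if second != primary:
                rows.append((pid, str(second)))
    for i in range(cfg.n_reference_decoys):
        pid = f"REF{i + 1:05d}"
        primary = rng.choice(comps, p=_BASE_RATES / _BASE_RATES.sum())
        rows.append((pid, str(primary)))
        if rng.uniform() < 0.3:
            second = rng.choice(comps, p=_BASE_RATES / _BASE_RATES.sum())
            if second != primary:
                rows.append((pid, str(second)))
    return pd.DataFrame(rows, columns=["protein_id", "compartment"])
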