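"""End-to-end orchestration: generator -> statistics -> categorization -> report.

A :class:`PipelineConfig` toggles four stages (proteomics, immuno-EM,
imaging, flow cytometry), each running on synthetic inputs generated from a
single master seed.  The master seed fans out to per-stage sub-seeds via
``numpy.random.SeedSequence(seed).spawn``, so each stage is independently
reproducible.  Every run writes its resolved configuration next to its
outputs; re-running with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from evquant import categorize as cat
from evquant import coloc, enrichment, flowcyto, lfq
from evquant import stereology
from evquant.io import write_tsv
from evquant.simulate import (
    COND_CD63,
    COND_CD9,
    COND_NT,
    EMSimConfig,
    FlowSimConfig,
    ImageSimConfig,
    ProteomeSimConfig,
    gen_coloc_stack,
    gen_flow_events,
    gen_gold_counts,
    gen_peptide_table,
)

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1
_STAGES = ("proteomics", "immunoem", "imaging", "flow")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Thresholds default to the study's analysis settings: log2 fold-change
    cut 1, significance 0.05, contaminant-repository cut 200/411, small /
    Golgi size thresholds 15 / 20 px, median radius 1 px, rolling-ball
    radius in 10-50 px.
    """

    seed: int = 0
    out_dir: str = "evquant_run"
    stages: tuple[str, ...] = _STAGES
    # proteomics
    n_proteins: int = 400
    effect_log2fc: float = 2.0
    noise_sd_log2: float = 0.3
    n_replicates: int = 4
    alpha: float = 0.05
    fc_threshold: float = 1.0
    contaminant_threshold_frac: float = cat.DEFAULT_CONTAMINANT_FRAC
    # immuno-EM
    em_true_rli: tuple[float, ...] = (3.0, 1.0, 1.0, 1.5, 1.0)
    em_total_golds: int = 2000
    em_total_points: int = 4000
    # imaging
    overlap_fraction: float = 0.5
    n_compartments: int = 40
    manders_threshold: float = 30.0
    # flow
    flow_n_events: int = 10_000
    internalization_mfis: tuple[float, float, float, float] = (85.0, 100.0, 5.0, 100.0)
    config_version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.config_version != CONFIG_VERSION:
            raise ValueError(
                f"config version {self.config_version} unsupported (expected {CONFIG_VERSION})"
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("stages", "em_true_rli", "internalization_mfis"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return the summary dict.

    Outputs are written under ``config.out_dir``: per-stage TSV tables, the
    resolved config (``config.yaml``) and ``summary.json``.  A stage failure
    raises immediately with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(dataclasses.asdict(config)), fh, sort_keys=True)

    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    for stage in config.stages:
        runner = {
            "proteomics": _run_proteomics,
            "immunoem": _run_immunoem,
            "imaging": _run_imaging,
            "flow": _run_flow,
        }[stage]
        try:
            summary[stage] = runner(config, seeds[stage], out)
        except Exception as exc:  # halt with a stage-named error
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _run_proteomics(config: PipelineConfig, seed: int, out: Path) -> dict:
    sim = ProteomeSimConfig(
        n_proteins=config.n_proteins,
        effect_log2fc=config.effect_log2fc,
        noise_sd_log2=config.noise_sd_log2,
        n_replicates=config.n_replicates,
        seed=seed,
    )
    peptides, contaminants, reference, truth = gen_peptide_table(sim)
    normed, norm_report = lfq.normalize_total_signal(peptides)
    diff_ab = lfq.protein_differential(normed, COND_CD63, COND_CD9)
    diffs_nt = {
        cond: lfq.protein_differential(normed, cond, COND_NT)
        for cond in (COND_CD63, COND_CD9)
    }
    filt = cat.specificity_filter(
        diffs_nt, contaminants, threshold_frac=config.contaminant_threshold_frac
    )
    retained = filt.loc[filt["retained"], "protein_id"]
    assignments = cat.categorize(
        diff_ab, retained, alpha=config.alpha, fc_threshold=config.fc_threshold
    )
    counts = cat.summarize_categories(assignments)

    enrich_results = {}
    for category in ("enriched_A", "enriched_B", "common"):
        ids = assignments.loc[assignments["category"] == category, "protein_id"]
        if len(ids):
            res = enrichment.enrich_list(ids, reference)
            write_tsv(res, out / f"enrichment_{category}.tsv")
            top = res.iloc[0]
            enrich_results[category] = {
                "top_compartment": str(top["compartment"]),
                "percent_list": float(top["percent_list"]),
                "percent_reference": float(top["percent_reference"]),
                "p_value": float(top["p_value"]),
            }

    for name, df in [
        ("peptides", peptides),
        ("contaminants", contaminants),
        ("compartment_reference", reference),
        ("ground_truth_proteome", truth),
        ("normalization_report", norm_report),
        ("differential_cd63_vs_cd9", diff_ab),
        ("specificity_filter", filt),
        ("categories", assignments),
        ("category_counts", counts),
    ]:
        write_tsv(df, out / f"{name}.tsv")

    return {
        "n_proteins": config.n_proteins,
        "n_retained": int(filt["retained"].sum()),
        "category_counts": dict(zip(counts["category"], counts["n_proteins"].astype(int))),
        "top_enrichment": enrich_results,
    }


def _run_immunoem(config: PipelineConfig, seed: int, out: Path) -> dict:
    sim = EMSimConfig(
        true_rli=config.em_true_rli,
        total_golds=config.em_total_golds,
        total_points=config.em_total_points,
        seed=seed,
    )
    table, truth = gen_gold_counts(sim)
    res = stereology.compute_rli(table)
    write_tsv(table, out / "gold_counts.tsv")
    write_tsv(truth, out / "ground_truth_em.tsv")
    write_tsv(res.table, out / "rli_table.tsv")
    return {
        "rli": dict(zip(res.table["compartment"], res.table["RLI"].round(4))),
        "total_chi2": res.total_chi2,
        "df": res.df,
        "p_value": res.p_value,
    }


def _run_imaging(config: PipelineConfig, seed: int, out: Path) -> dict:
    sim = ImageSimConfig(
        overlap_fraction=config.overlap_fraction,
        n_compartments=config.n_compartments,
        seed=seed,
    )
    stack, masks, truth = gen_coloc_stack(sim)
    ch1, ch2 = stack[0, 0], stack[0, 1]
    thr = config.manders_threshold
    m1, m2 = coloc.manders(ch1, ch2, thr, thr)
    r = coloc.pearson_in_mask(ch1, ch2)
    write_tsv(truth, out / "ground_truth_imaging.tsv")
    result = pd.DataFrame(
        [{"timepoint": 0, "pearson_r": r, "manders_m1": m1, "manders_m2": m2}]
    )
    write_tsv(result, out / "coloc_metrics.tsv")
    return {
        "pearson_r": r,
        "manders_m1": m1,
        "manders_m2": m2,
        "true_overlap_fraction": float(truth["overlap_fraction"].iloc[0]),
    }


def _run_flow(config: PipelineConfig, seed: int, out: Path) -> dict:
    seeds = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    m = config.internalization_mfis  # (strip37, nostrip37, strip4, nostrip4)
    samples = {}
    for name, mfi_af647, s in zip(
        ("strip_37", "nostrip_37", "strip_4", "nostrip_4"), m, sub
    ):
        events, _ = gen_flow_events(
            FlowSimConfig(n_events=config.flow_n_events, mfi_af647=mfi_af647, seed=s)
        )
        gated, report = flowcyto.gate_events(events)
        samples[name] = gated
        write_tsv(report, out / f"gating_report_{name}.tsv")
    pct = flowcyto.internalization_percent(
        samples["strip_37"], samples["nostrip_37"], samples["strip_4"], samples["nostrip_4"]
    )
    planted = 100.0 * m[0] / m[1] - 100.0 * m[2] / m[3]
    return {"internalization_percent": pct, "planted_internalization_percent": planted}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
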