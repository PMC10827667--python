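"""End-to-end orchestration: filter -> normalize -> harmonize ->
DE report -> screen -> exhaustive search -> consensus panel -> evaluation.

A single :class:`PipelineConfig` drives a run; every artifact records the
seed and a hash of the configuration so re-runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, diffexpr, featselect, harmonize, simcohort

log = logging.getLogger("lithopredict")

__all__ = ["PipelineConfig", "run_pipeline"]

_TASK_DEFAULTS = {
    "response": {"panel_size": 7, "label_column": "response", "groups": ("LR", "NR")},
    "diagnosis": {"panel_size": 5, "label_column": "diagnosis", "groups": ("BD", "CTRL")},
}


@dataclass
class PipelineConfig:
    task: str = "response"
    input_prefix: str | None = None            # read_cohort prefix; None -> simulate
    simulation: simcohort.SimulationConfig | None = None
    min_total_count: int = 10
    fdr: float = 0.05
    min_abs_log2fc: float = 1.0
    ig_expression_threshold: float = 100.0
    protect_covariates: bool = True
    screen_k: int = 20
    min_subset_size: int = 1
    max_subset_size: int = 7
    accuracy_threshold: float = 0.93
    panel_size: int | None = None              # None -> task default (7 / 5)
    n_reps: int = 50
    test_fraction: float = 0.5
    classifier_kinds: tuple[str, ...] = classify.CLASSIFIER_KINDS
    seed: int = 0
    output_dir: str = "lithopredict_run"

    def __post_init__(self) -> None:
        if self.task not in _TASK_DEFAULTS:
            raise ValueError(f"task must be one of {sorted(_TASK_DEFAULTS)}")
        if self.panel_size is None:
            self.panel_size = _TASK_DEFAULTS[self.task]["panel_size"]
        if not self.panel_size <= self.screen_k:
            raise ValueError("panel_size must be <= screen_k")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # where results land is not science
        if self.simulation is not None:
            payload["simulation"] = self.simulation.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _task_view(task, counts, metadata):
    """Subset samples to the task's two groups and return per-sample labels."""
    spec = _TASK_DEFAULTS[task]
    col = spec["label_column"]
    meta = metadata.set_index("sample_id").loc[counts.columns]
    keep = meta[col].isin(spec["groups"]).to_numpy()
    return counts.loc[:, keep], metadata[metadata["sample_id"].isin(counts.columns[keep])]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes artifacts under ``config.output_dir``
    and returns them in memory as a dict bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_info = {"seed": config.seed, "config_hash": config.config_hash()}

    # ---- inputs ----
    if config.input_prefix is not None:
        counts, metadata, annotation = simcohort.read_cohort(config.input_prefix)
        log.info("loaded cohort from %s", config.input_prefix)
    else:
        sim = config.simulation or simcohort.cohort1_config(seed=config.seed)
        counts, metadata, annotation = simcohort.generate_cohort(sim)
        log.info("simulated cohort: %d genes x %d samples", *counts.shape)

    counts, metadata = _task_view(config.task, counts, metadata)
    label_col = _TASK_DEFAULTS[config.task]["label_column"]

    # ---- filter + normalize + harmonize ----
    counts = diffexpr.filter_low_counts(counts, config.min_total_count)
    X = harmonize.log_normalize(counts)
    meta_idx = metadata.set_index("sample_id").loc[X.columns]
    batches = meta_idx["batch"].to_numpy()
    diag = {"batch_association_before": harmonize.batch_association(X, batches)}
    if len(np.unique(batches)) > 1:
        covariates = meta_idx[label_col].to_numpy() if config.protect_covariates else None
        Xc = harmonize.combat(X, batches, covariates)
        resid = harmonize.residualize_batch(
            X, batches, design=meta_idx[label_col].to_numpy()
        )
    else:
        Xc, resid = X.copy(), X.copy()
    diag["batch_association_after"] = harmonize.batch_association(Xc, batches)
    diag["batch_association_residualized"] = harmonize.batch_association(resid, batches)

    # ---- DE report (on counts; replicates collapsed) ----
    groups = meta_idx[label_col].to_numpy()
    de = diffexpr.de_test(counts, groups, metadata=metadata, collapse=True)
    degs = diffexpr.call_degs(de, fdr=config.fdr, min_abs_log2fc=config.min_abs_log2fc)
    enrichment = None
    if degs:
        enrichment = diffexpr.ig_fraction(
            degs, annotation, counts, config.ig_expression_threshold
        )

    # ---- feature selection on harmonized, subject-collapsed expression ----
    Xsubj, subj_meta = diffexpr.collapse_replicates(Xc, metadata)
    labels = subj_meta.set_index("subject_id").loc[Xsubj.columns, label_col].to_numpy()
    panel, screen, search = featselect.select_features(
        Xsubj,
        labels,
        k=config.screen_k,
        min_size=config.min_subset_size,
        max_size=config.max_subset_size,
        accuracy_threshold=config.accuracy_threshold,
        panel_size=config.panel_size,
        seed=config.seed,
    )

    # ---- evaluation ----
    specs = [
        classify.ClassifierSpec(kind=k, seed=config.seed)
        for k in config.classifier_kinds
    ]
    report = classify.repeated_split_eval(
        Xsubj.loc[panel.gene_ids],
        labels,
        subject_ids=Xsubj.columns.to_numpy(),
        specs=specs,
        n_reps=config.n_reps,
        test_fraction=config.test_fraction,
        seed=config.seed,
    )

    # ---- artifacts ----
    de.to_csv(outdir / "de_results.csv", index=False)
    (outdir / "degs.txt").write_text("\n".join(degs) + ("\n" if degs else ""))
    pd.DataFrame(diag, index=[0]).to_csv(outdir / "batch_diagnostics.csv", index=False)
    with open(outdir / "panel.json", "w") as fh:
        json.dump({**panel.to_dict(), **meta_info}, fh, indent=2, sort_keys=True)
    with open(outdir / "eval_report.json", "w") as fh:
        json.dump({**report.to_dict(), **meta_info}, fh, indent=2, sort_keys=True)
    report.records.to_csv(outdir / "eval_records.csv", index=False)
    if enrichment is not None:
        with open(outdir / "ig_enrichment.json", "w") as fh:
            json.dump({**enrichment.to_dict(), **meta_info}, fh, indent=2, sort_keys=True)
    with open(outdir / "run_info.json", "w") as fh:
        json.dump(meta_info, fh, indent=2, sort_keys=True)
    log.info("wrote artifacts to %s", outdir)

    return {
        "counts": counts,
        "expression": Xc,
        "de_results": de,
        "degs": degs,
        "enrichment": enrichment,
        "diagnostics": diag,
        "panel": panel,
        "screen": screen,
        "search": search,
        "report": report,
        "run_info": meta_info,
    }
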