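"""End-to-end orchestration: simulate -> analyze -> report.

A run is fully specified by a :class:`RunConfig`; the same config and seed
always produce byte-identical summary output.  The root seed is expanded
into named per-stage substreams so a stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .behavior import BehaviorModel
from .config import TaskConfig
from .dataset import Dataset, read_dataset, write_dataset
from .population import PopulationModel, project_outcome_responses
from .simulate import simulate_dataset
from .tuning import NeuronTuningModel

log = logging.getLogger(__name__)

STAGES = ("schedule", "spikes", "behavior", "analysis")


def stage_seed(root_seed: int, stage: str) -> int:
    """Named, reproducible substream seed derived from the root seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(root_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with standard analysis defaults."""

    output_dir: str = "lhvalence_run"
    seed: int = 0
    dataset_path: Optional[str] = None   # analyze an existing dataset
    n_sessions: int = 1                  # otherwise simulate this many
    alpha: float = 0.05
    slide_win_ms: int = 200
    slide_step_ms: int = 10
    psth_bin_ms: int = 200
    psth_step_ms: int = 50
    pca_bin_ms: int = 100
    log_level: str = "INFO"
    task: TaskConfig = field(default_factory=TaskConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Writes the (simulated) dataset, per-neuron classification TSV, taxonomy
    counts, behaviour statistics, sliding-correlation series, PCA
    coordinates and a machine-readable ``summary.json``; returns the
    summary dict.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "stages": {}}

    def _stage(name):
        log.info("stage %s", name)
        summary["stages"][name] = "ok"

    try:
        if config.dataset_path:
            _stage("load")
            ds = read_dataset(config.dataset_path)
        else:
            _stage("simulate")
            ds = simulate_dataset(stage_seed(config.seed, "spikes"),
                                  config=config.task)
            write_dataset(ds, out / "dataset")
    except Exception as e:  # pragma: no cover - defensive
        summary["stages"]["input"] = f"failed: {e}"
        raise RuntimeError(f"input stage failed: {e}") from e

    _stage("classification")
    tuning = NeuronTuningModel(ds, alpha=config.alpha).fit()
    tuning.to_frame().to_csv(out / "classification.tsv", sep="\t",
                             index=False)
    counts = {fam: tuning.counts(fam) for fam in tuning.model.families}
    summary["classification"] = counts

    _stage("population")
    pop = PopulationModel(ds, alpha=config.alpha,
                          psth_bin_ms=config.psth_bin_ms,
                          psth_step_ms=config.psth_step_ms,
                          slide_win_ms=config.slide_win_ms,
                          slide_step_ms=config.slide_step_ms,
                          pca_bin_ms=config.pca_bin_ms).fit()
    pop.block_comparison.to_csv(out / "block_comparison.tsv", sep="\t",
                                index=False)
    for (fam, pair), s in pop.sensitivity_series.items():
        s.to_frame().to_csv(out / f"sensitivity_{fam}_{pair[0]}_{pair[1]}.tsv",
                            sep="\t", index=False)
    pop.pca.trajectory_frame().to_csv(out / "pca_trajectories.tsv", sep="\t",
                                      index=False)
    project_outcome_responses(pop.pca, ds).to_csv(
        out / "pca_outcome_projections.tsv", sep="\t", index=False)
    summary["population"] = {
        "significant_bins": int(pop.block_comparison["significant"].sum()),
        "n_bins": int(len(pop.block_comparison)),
        "pca_explained_variance": [round(float(v), 6) for v in
                                   pop.pca.explained_variance_ratio[:5]],
        "context_stats": {
            w: {"per_cell_fraction": round(st["per_cell_fraction"], 6),
                "population_F": round(st["population_F"], 6),
                "population_p": round(st["population_p"], 6),
                "pairwise_counts": st["pairwise_counts"]}
            for w, st in pop.context_stats.items()},
        "sensitivity": {
            f"{fam}_{a}_{b}": {
                "median_rho": round(float(np.nanmedian(s.rho)), 6),
                "frac_significant": round(float(np.nanmean(s.significant)), 6)}
            for (fam, (a, b)), s in pop.sensitivity_series.items()},
    }

    if ds.behavior is not None and len(ds.behavior):
        _stage("behavior")
        beh = BehaviorModel(ds, alpha=config.alpha).fit()
        beh.normalized.to_csv(out / "behavior_normalized.tsv", sep="\t",
                              index=False)
        beh.ladder_tests.to_csv(out / "behavior_ladder.tsv", sep="\t",
                                index=False)
        summary["behavior"] = {
            "ladder_significant": int(beh.ladder_tests["significant"].sum())
            if len(beh.ladder_tests) else 0}
        if beh.blink_anova is not None:
            beh.blink_anova.to_csv(out / "behavior_blink_anova.tsv", sep="\t")
            summary["behavior"]["blink_context_F"] = round(
                float(beh.blink_anova.loc["context", "F"]), 6)
            summary["behavior"]["blink_context_p"] = float(
                beh.blink_anova.loc["context", "PR(>F)"])
    else:
        summary["stages"]["behavior"] = "skipped: not available"

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
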