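"""End-to-end pipeline: validate -> screen -> stepwise SSVS -> final RE and
FE fits -> summaries -> combination profiling, with a run manifest.

Each stage writes its outputs under the run directory as it completes, so a
failed run leaves everything up to the failing stage on disk, and re-running
with the same config and seed reproduces identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import combinations as combos
from .config import ModelConfig
from .data import AnalysisDataset, read_dataset
from .model import fit
from .reporting import RunManifest, forest_table, render_forest
from .screening import flag_pairs
from .ssvs import stepwise_selection

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    data_path: str | Path,
    config: ModelConfig,
    out_dir: str | Path,
    profile_combinations: bool = True,
) -> Path:
    """Run the full analysis and write all outputs to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.for_run(
        config.to_dict(), config.seed, {"data": Path(data_path)}
    )

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage
                raise StageError(name, exc) from exc
            manifest.record(name)
            manifest.write(out / "manifest.json")
            return result

        return deco

    @stage("validate")
    def dataset() -> AnalysisDataset:
        ds, report = read_dataset(data_path, config)
        report.to_csv(out / "validation_report.csv", index=False)
        logger.info("validated %d observations in %d trials (%d rows dropped)",
                    ds.n_observations, ds.n_trials, len(report))
        return ds

    @stage("screen")
    def screening():
        report = flag_pairs(dataset.indicator_frame())
        report.to_frame().to_csv(out / "screening_report.csv", index=False)
        return report

    @stage("ssvs")
    def selection():
        res = stepwise_selection(dataset, config)
        res.age_stage.table.to_csv(out / "ssvs_age_stage.csv")
        res.behaviour_stage.table.to_csv(out / "ssvs_behaviour_stage.csv")
        return res

    results = {}
    for mode in ("random", "fixed"):
        tag = "re" if mode == "random" else "fe"

        @stage(f"fit_{tag}")
        def fitted(mode=mode, tag=tag):
            cfg = config.replace(effects_mode=mode)
            # each mode takes its own selected interaction set
            sel = (
                selection
                if mode == config.effects_mode
                else stepwise_selection(dataset, cfg)
            )
            res = fit(dataset, cfg, interactions=sel.final_interactions)
            summary = res.summary()
            summary.to_csv(out / f"summary_{tag}.csv")
            table = forest_table(summary)
            table.to_csv(out / f"forest_{tag}.csv", index=False)
            (out / f"forest_{tag}.txt").write_text(render_forest(table) + "\n")
            pd.DataFrame(
                res.theta.reshape(-1, len(res.columns)), columns=res.columns
            ).to_csv(out / f"samples_{tag}.csv.gz", index=False)
            return res

        results[tag] = fitted

    if profile_combinations:

        @stage("combinations")
        def profile():
            prof = combos.extremes_from_fit(results["re"])
            pd.DataFrame(
                {
                    "prevalence_best": prof.prevalence_best,
                    "prevalence_worst": prof.prevalence_worst,
                }
            ).to_csv(out / "combination_profile.csv")
            prof.best_rows.to_csv(out / "best_combinations.csv", index=False)
            prof.worst_rows.to_csv(out / "worst_combinations.csv", index=False)
            return prof

    return out
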