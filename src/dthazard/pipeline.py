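"""End-to-end orchestration: simulate -> expand -> fit ladder -> evaluate -> report.

A single :class:`RunConfig` (plain YAML on disk) drives the whole analysis:
cohort simulation under a named outcome preset, person-month expansion and
weighted standardization, the within-month correlation series, the two-step
model ladder, odds ratios of the selected model, ventile evaluation of the
administrative-only / survey-only / best models with proportional
improvements, and the actuarial survival curve. All randomness flows from
one root seed; outputs are delimited tables plus a manifest with row counts
and checksums, so a rerun under the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim  # the submodule, not the convenience function
from .actuarial import life_table, median_iqr_event_time
from .concentration import ventile_report
from .correlation import summarize_series, trend_correlation, within_month_correlations
from .ladder import LadderResults, run_model_ladder
from .model import DiscreteTimeHazardModel, ModelSpec
from .personmonth import SurveyDesign, expand_to_person_months, standardize_scores

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_tables"]

logger = logging.getLogger("dthazard")

#: survey-score-only comparison model (month effects + S), used for the
#: survey-only column of the performance table
NSS_ONLY_SPEC = ModelSpec("S_only", ("S",))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    preset: str = "victimization"
    n_subjects: int | None = None
    sim_overrides: dict = field(default_factory=dict)
    alpha: float = 0.05
    correction: str = "holm"
    horizon: int = 36
    ranking_method: str = "cumulative"
    weighted: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.preset not in sim.PRESET_NAMES and self.preset != "custom":
            raise ValueError(f"unknown preset {self.preset!r}")
        if not 1 <= self.horizon <= 44:
            raise ValueError("horizon must be in 1..44")

    def sim_config(self) -> sim.SimConfig:
        if self.preset == "custom":
            config = sim.SimConfig(seed=self.seed, **self.sim_overrides)
        else:
            config = sim.preset(self.preset, n_subjects=self.n_subjects, seed=self.seed)
            if self.sim_overrides:
                config = config.replace(**self.sim_overrides)
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class ReportBundle:
    """All outputs of one pipeline run."""

    config: RunConfig
    cohort: sim.Cohort
    array: pd.DataFrame
    correlations: pd.DataFrame
    correlation_summary: dict
    ladder: LadderResults
    odds_ratios: pd.DataFrame
    performance: pd.DataFrame
    life_table: pd.DataFrame
    event_time_summary: dict


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis under ``config``; any stage failure aborts with
    the stage name attached."""
    stage = "simulate"
    try:
        t0 = _stage(stage)
        sconf = config.sim_config()
        logger.info("effective simulation config: %s", sconf)
        cohort = sim.simulate(sconf)
        n_events = int(cohort.subjects["event_month"].notna().sum())
        logger.info(
            "simulated %d subjects, %d events (%.1fs)",
            len(cohort.subjects), n_events, time.perf_counter() - t0,
        )

        stage = "expand"
        t0 = _stage(stage)
        design = SurveyDesign.from_subjects(cohort.subjects)
        if not config.weighted:
            design = SurveyDesign(
                weights=pd.Series(1.0, index=design.weights.index),
                clusters=design.clusters,
            )
        array = expand_to_person_months(cohort.subjects, cohort.scores, design)
        array = standardize_scores(array, design)
        logger.info("%d person-month rows (%.1fs)", len(array), time.perf_counter() - t0)

        stage = "correlations"
        t0 = _stage(stage)
        series = within_month_correlations(array)
        med, q25, q75 = summarize_series(series)
        corr_summary = {
            "median": med, "q25": q25, "q75": q75,
            "trend": trend_correlation(series),
        }
        corr_table = series.table.copy()
        corr_table.insert(0, "month", corr_table.index.astype(str))

        stage = "ladder"
        t0 = _stage(stage)
        ladder = run_model_ladder(array, alpha=config.alpha, correction=config.correction)
        logger.info(
            "ladder selected %s (base %s) (%.1fs)",
            ladder.selected_name, ladder.base_name, time.perf_counter() - t0,
        )

        stage = "evaluate"
        t0 = _stage(stage)
        nss_fit = DiscreteTimeHazardModel(array, NSS_ONLY_SPEC).fit()
        fits = {
            "hads_only": ladder.base,
            "nss_only": nss_fit,
            "best": ladder.selected,
        }
        subjects = cohort.subjects
        horizon = min(config.horizon, 36)
        performance = ventile_report(
            fits, array, subjects, design=design, horizon=horizon,
            ranking_method=config.ranking_method,
        )
        lt = life_table(subjects, design=design, horizon=horizon)
        lt_table = lt.table.copy()
        lt_table.insert(0, "month", lt_table.index)
        med_t, q25_t, q75_t = median_iqr_event_time(subjects, design)
        logger.info("evaluation done (%.1fs)", time.perf_counter() - t0)

        return ReportBundle(
            config=config,
            cohort=cohort,
            array=array,
            correlations=corr_table.reset_index(drop=True),
            correlation_summary=corr_summary,
            ladder=ladder,
            odds_ratios=ladder.selected.coefficient_table(),
            performance=performance,
            life_table=lt_table.reset_index(drop=True),
            event_time_summary={"median": med_t, "q25": q25_t, "q75": q75_t},
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_tables(bundle: ReportBundle, outdir: str | Path) -> dict:
    """Write the report tables and a manifest; returns the manifest dict.

    Tables: correlations, model_tests, odds_ratios, performance, life_table,
    plus a YAML run summary. The manifest lists file names, row counts and
    sha256 checksums.
    """
    if bundle is None or bundle.performance.empty:
        raise ValueError("report bundle is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables = {
        "correlations.csv": bundle.correlations,
        "model_tests.csv": bundle.ladder.tests,
        "odds_ratios.csv": bundle.odds_ratios,
        "performance.csv": bundle.performance,
        "life_table.csv": bundle.life_table,
    }
    manifest: dict = {"files": {}, "config": dataclasses.asdict(bundle.config)}
    for name, df in tables.items():
        path = outdir / name
        _write_csv(df, path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {"rows": int(len(df)), "sha256": digest}

    summary = {
        "selected_model": bundle.ladder.selected_name,
        "base_model": bundle.ladder.base_name,
        "correlation_summary": {k: float(v) for k, v in bundle.correlation_summary.items()},
        "event_time_summary": {k: float(v) for k, v in bundle.event_time_summary.items()},
        "n_subjects": int(len(bundle.cohort.subjects)),
        "n_person_months": int(len(bundle.array)),
        "n_events": int(bundle.cohort.subjects["event_month"].notna().sum()),
    }
    summary_path = outdir / "summary.yaml"
    summary_path.write_text(yaml.safe_dump(summary, sort_keys=True))
    manifest["files"]["summary.yaml"] = {
        "rows": len(summary),
        "sha256": hashlib.sha256(summary_path.read_bytes()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
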