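"""End-to-end orchestration: data in, BMD tables, correlation report, plots out.

``run_pipeline`` ties the stages together: load (or simulate) continuous and
quantal data, fit the shared-shape clusters, compute per-compound profile
BMD intervals, drop fully unbounded compounds, pair the two systems, fit or
adopt the unity-slope band, emit predictions (and an optional MOE screen),
and write CSV tables, plots and a log.  Given the same configuration and
seed the CSV outputs are byte-identical.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cluster import fit_continuous_cluster, fit_quantal_cluster
from .correlation import (
    PotencyInterval,
    UnitySlopeBand,
    margin_of_exposure,
    pair_intervals,
)
from .io import RunConfig, read_continuous_csv, read_quantal_csv, write_table
from .models import BmrSpec
from .profile import bmd_table, classify_and_filter, profile_ci
from .simulate import simulate_correlated_systems

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("bmdpotency")


@dataclass
class PipelineResult:
    """Bundle of everything a pipeline run produced."""

    config: RunConfig
    continuous_fit: object
    quantal_fit: object
    continuous_results: list
    quantal_results: list
    excluded: list
    pairs: list
    unmatched: dict
    band: object
    report: pd.DataFrame
    moe: object | None = None
    truth: pd.DataFrame | None = None
    timings: dict = field(default_factory=dict)


def _stage(name, timings):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = dt
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; any stage failure aborts with the stage name."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings: dict = {}
    meta = {"config_hash": config.hash(), "seed": config.seed}
    truth = None
    try:
        with _stage("load", timings):
            if config.continuous_path:
                continuous = read_continuous_csv(config.continuous_path)
                quantal = (
                    read_quantal_csv(config.quantal_path) if config.quantal_path else []
                )
            else:
                continuous, quantal, truth = simulate_correlated_systems(
                    seed=config.seed, **config.simulate
                )

        with _stage("fit-continuous", timings):
            cfit = fit_continuous_cluster(
                continuous,
                bmr=config.continuous_bmr,
                n_starts=config.n_starts,
                random_state=config.seed,
            )
        qfit = None
        if quantal:
            with _stage("fit-quantal", timings):
                qfit = fit_quantal_cluster(
                    quantal,
                    bmr=config.quantal_bmr,
                    n_starts=config.n_starts,
                    random_state=config.seed,
                )

        with _stage("bmd-continuous", timings):
            cont_results = [
                profile_ci(
                    cfit,
                    comp,
                    level=config.level,
                    ceiling_multiplier=config.ceiling_multiplier,
                )
                for comp in cfit.members
            ]
            retained, excluded, counts = classify_and_filter(cont_results)
            log.info("continuous BMD status counts: %s", counts)
            write_table(bmd_table(cont_results), outdir / "bmd_continuous.csv", meta)

        quant_results: list = []
        if qfit is not None:
            with _stage("bmd-quantal", timings):
                quant_results = [
                    profile_ci(
                        qfit,
                        mid,
                        level=config.level,
                        ceiling_multiplier=config.ceiling_multiplier,
                    )
                    for mid in qfit.members
                ]
                quant_results = [r for r in quant_results if r.status != "unbounded"]
                write_table(bmd_table(quant_results), outdir / "bmd_quantal.csv", meta)

        pairs, unmatched, band, report, moe = [], {}, None, pd.DataFrame(), None
        if quant_results:
            with _stage("correlate", timings):
                x_int = [
                    PotencyInterval.from_result(r, "in-vitro-MN", "ug/ml") for r in retained
                ]
                y_int = [
                    PotencyInterval.from_result(r, "cancer", "mg/kg/day")
                    for r in quant_results
                ]
                pairs, unmatched = pair_intervals(x_int, y_int)
                if config.band_mode == "manual":
                    bander = UnitySlopeBand(intercepts=config.band_intercepts)
                else:
                    bander = UnitySlopeBand(coverage=config.band_coverage)
                bander.fit(pairs)
                band = bander.band_
                report = bander.report(pairs)
                write_table(report, outdir / "pair_report.csv", meta)
                from .plots import plot_correlation

                plot_correlation(pairs, band, outdir / "correlation.png")

            if config.exposure is not None and len(report):
                with _stage("moe", timings):
                    worst = report.loc[report["pred_y_lo"].idxmin()]
                    moe = margin_of_exposure(
                        worst["pred_y_lo"],
                        worst["pred_y_hi"] if math.isfinite(worst["pred_y_hi"]) else math.inf,
                        config.exposure,
                    )
                    log.info("MOE verdict: %s", moe.verdict)

        if excluded:
            log.info("excluded (2-sided unbounded): %s", [r.compound for r in excluded])
        return PipelineResult(
            config=config,
            continuous_fit=cfit,
            quantal_fit=qfit,
            continuous_results=cont_results,
            quantal_results=quant_results,
            excluded=excluded,
            pairs=pairs,
            unmatched=unmatched,
            band=band,
            report=report,
            moe=moe,
            truth=truth,
            timings=timings,
        )
    finally:
        log.removeHandler(handler)
        handler.close()
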