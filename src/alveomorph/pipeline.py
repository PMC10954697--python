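"""End-to-end reproducible pipeline: simulate -> (render -> segment | measure)
-> summarize -> compare -> regress.

One :class:`~alveomorph.io.PipelineConfig` drives the whole run. Outputs are
written under the configured directory:

* ``traces.csv`` — every generated (or segmented) border trace
* ``records.csv`` — per-alveolus morphometry
* ``animal_means.csv`` — per-animal aggregation
* ``report.json`` — summaries, comparisons, regression, per-stage counts

The run is fully deterministic for a fixed seed: two runs with the same
config produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import AlveomorphError, InsufficientDataError
from .geometry import Condition, measure_cohort
from .io import PipelineConfig, write_records, write_traces
from .segmentation import segment_alveolus
from .stats import (
    VARIABLES,
    aggregate_by_animal,
    compare_groups,
    regress_mq_on_score,
    summarize_distribution,
)
from .synthetic import (
    center_in_field,
    make_cohort,
    make_injury_scores,
    records_to_frame,
    render_image,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(AlveomorphError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _measure_stage(traces, config: PipelineConfig):
    """Measure each alveolus, optionally via the render -> segment route."""
    counts = {"input": len(traces), "measured": 0, "discarded": 0}
    if not config.use_segmentation:
        records = measure_cohort(traces)
        counts["measured"] = len(records)
        return records, counts
    records = []
    for i, trace in enumerate(traces):
        try:
            placed = center_in_field(trace, config.render)
            image = render_image([placed], config.render, seed=config.seed + i)
            segmented = segment_alveolus(
                image,
                config.segmentation,
                pixel_size=config.render.pixel_size,
                alveolus_id=trace.alveolus_id,
            )
        except AlveomorphError as exc:
            counts["discarded"] += 1
            logger.warning("segmentation discarded %s: %s", trace.alveolus_id, exc)
            continue
        segmented = replace(
            segmented,
            alveolus_id=trace.alveolus_id,
            animal_id=trace.animal_id,
            condition=trace.condition,
        )
        records.append(measure_cohort([segmented])[0])
    counts["measured"] = len(records)
    return records, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-cohort analysis; returns the report dict.

    Stages: generate the hierarchical cohort; measure every alveolus (either
    directly from the generated traces, or through the render-and-segment
    route when ``use_segmentation`` is set); summarise the per-alveolus
    distributions per condition; compare conditions at the animal level with
    the normality-driven test; regress emulated cumulative injury scores on
    per-animal MQ. Any stage failure aborts with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "alveomorph_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    stage = "simulate"
    try:
        cohort_spec = replace(config.cohort, seed=config.seed)
        traces, ground_truth = make_cohort(cohort_spec)
        write_traces(traces, out_dir / "traces.csv")
        ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        report["stages"][stage] = {"n_traces": len(traces)}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "measure"
    try:
        records, counts = _measure_stage(traces, config)
        if not records:
            raise InsufficientDataError("no alveoli survived measurement")
        write_records(records, out_dir / "records.csv")
        report["stages"][stage] = counts
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "summarize"
    try:
        frame = records_to_frame(records)
        summaries = {}
        for condition in (Condition.BASELINE, Condition.INJURY):
            sub = frame[frame["condition"] == condition.value]
            if len(sub) < 3:
                continue
            summaries[condition.value] = {
                var: summarize_distribution(
                    sub[var].to_numpy(),
                    var,
                    config.bin_widths.get(var),
                ).to_dict()
                for var in VARIABLES
            }
        report["summaries"] = summaries
        report["stages"][stage] = {"n_conditions": len(summaries)}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "aggregate"
    try:
        animal_means = aggregate_by_animal(frame)
        animal_means.to_csv(out_dir / "animal_means.csv", index=False)
        report["stages"][stage] = {"n_animals": len(animal_means)}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "compare"
    comparisons = {}
    base = animal_means[animal_means["condition"] == Condition.BASELINE.value]
    inj = animal_means[animal_means["condition"] == Condition.INJURY.value]
    for var in VARIABLES:
        try:
            comparisons[var] = compare_groups(
                base[var].to_numpy(), inj[var].to_numpy(), var, alpha=config.alpha
            ).to_dict()
        except InsufficientDataError as exc:
            comparisons[var] = {"error": str(exc)}
            logger.warning("comparison skipped for %s: %s", var, exc)
    report["comparisons"] = comparisons
    report["stages"][stage] = {"n_compared": sum("error" not in c for c in comparisons.values())}

    stage = "regress"
    try:
        mq = animal_means["mq"].to_numpy()
        scores = make_injury_scores(
            mq,
            slope=config.score_slope,
            intercept=config.score_intercept,
            noise_sd=config.score_noise_sd,
            seed=config.seed,
        )
        pd.DataFrame(
            {
                "animal_id": animal_means["animal_id"],
                "condition": animal_means["condition"],
                "mq": mq,
                "cumulative_score": scores,
            }
        ).to_csv(out_dir / "injury_scores.csv", index=False)
        try:
            report["regression"] = regress_mq_on_score(mq, scores).to_dict()
        except (InsufficientDataError, AlveomorphError) as exc:
            report["regression"] = {"error": str(exc)}
            logger.warning("regression skipped: %s", exc)
        report["stages"][stage] = {"n_animals": int(mq.size)}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete; report at %s", report_path)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and obj != obj:  # NaN -> null for valid JSON
        return None
    return obj
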