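"""End-to-end orchestration: simulate -> analyze -> stats -> report.

`run_analyze` turns trial recordings into the long results table (one row
per trial x effector x measure), `run_stats` reproduces the statistical
design (two-way finger x phalanx RM-ANOVA per measure, twelve per-task
effector ANOVAs, post-hoc pairwise tables), and `run_report` tabulates the
group means and standard errors the figures summarise.

All module parameters are gathered in :class:`PipelineConfig`, which can be
loaded from a JSON file; unknown keys are rejected so that typos do not
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import (
    ALL_TASKS,
    RESULT_MEASURES,
    TrialRecording,
    ValidationError,
    validate_results,
)
from .metrics import SalConfig, compute_trial_metrics
from .preprocess import kinematic_series, to_wrist_frame
from .segmentation import SegmentationConfig, segment_onward
from .stats import (
    RmAnovaResult,
    participant_means,
    posthoc_pairwise,
    rm_anova_2way,
    rm_anova_effector,
)
from .synthetic import THUMB_SENSOR

logger = logging.getLogger("oppokin")

__all__ = ["PipelineConfig", "run_analyze", "run_stats", "run_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis chain, with protocol defaults."""

    filter_cutoff_hz: float = 5.0
    filter_order: int = 2
    rest_samples: int = 20
    threshold_frac: float = 0.05
    min_duration_s: float = 0.1
    min_displacement_frac: float = 0.1
    resample_points: int = 100
    sal_f_max_hz: float = 10.0
    sal_pad_factor: int = 16
    adaptive_cutoff: bool = False
    posthoc_method: str = "bonferroni"

    @property
    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            threshold_frac=self.threshold_frac,
            min_duration_s=self.min_duration_s,
            min_displacement_frac=self.min_displacement_frac,
        )

    @property
    def sal(self) -> SalConfig:
        return SalConfig(
            f_max_hz=self.sal_f_max_hz,
            pad_factor=self.sal_pad_factor,
            adaptive_cutoff=self.adaptive_cutoff,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def analyze_trial(
    rec: TrialRecording, config: PipelineConfig = PipelineConfig()
) -> list[dict]:
    """Per-trial analysis: wrist frame, filtering, kinematics, independent
    thumb/finger segmentation, and all outcome measures as long-format rows."""
    wrist = to_wrist_frame(rec)
    series = {
        "thumb": kinematic_series(
            wrist, THUMB_SENSOR, "thumb",
            cutoff=config.filter_cutoff_hz, order=config.filter_order,
            n_rest=config.rest_samples,
        ),
        "finger": kinematic_series(
            wrist, rec.task.target_sensor.name, "finger",
            cutoff=config.filter_cutoff_hz, order=config.filter_order,
            n_rest=config.rest_samples,
        ),
    }
    segs = {
        eff: segment_onward(s, config.segmentation) for eff, s in series.items()
    }
    tm = compute_trial_metrics(
        series["thumb"].rd, segs["thumb"],
        series["finger"].rd, segs["finger"],
        series["thumb"].rv, series["finger"].rv,
        rec.fs, config.sal,
    )
    base = {
        "participant": rec.participant_id,
        "task": rec.task.code,
        "trial": rec.trial_index,
    }
    values = {
        "thumb": {
            "displacement": tm.thumb_displacement,
            "D": tm.d_t,
            "z_D": tm.z_d_t,
            "SAL": tm.sal_thumb,
        },
        "finger": {
            "displacement": tm.finger_displacement,
            "D": tm.d_f,
            "z_D": tm.z_d_f,
            "SAL": tm.sal_finger,
        },
    }
    rows = []
    for eff in ("thumb", "finger"):
        for measure in RESULT_MEASURES:
            rows.append(
                base
                | {
                    "effector": eff,
                    "measure": measure,
                    "value": values[eff][measure],
                    "fallback": segs[eff].fallback,
                }
            )
    return rows


def run_analyze(
    recordings: Iterable[TrialRecording],
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Analyze every trial; returns the validated long results table.

    Trials whose segmentation needed the automatic fallback are kept and
    flagged; trials with no detectable movement are excluded and logged, so
    every input trial is accounted for either in the table or in the log.
    """
    rows: list[dict] = []
    n_trials = n_fallback = 0
    excluded: list[int] = []
    for rec in recordings:
        n_trials += 1
        try:
            trial_rows = analyze_trial(rec, config)
        except ValidationError:
            raise
        except ValueError as exc:
            excluded.append(rec.trial_index)
            logger.warning("trial %d excluded: %s", rec.trial_index, exc)
            continue
        if trial_rows[0]["fallback"] or trial_rows[-1]["fallback"]:
            n_fallback += 1
        rows.extend(trial_rows)
    if not rows:
        raise ValidationError("no analysable trials")
    table = pd.DataFrame(rows).drop(columns="fallback")
    logger.info(
        "analyzed %d trials: %d ok, %d via fallback segmentation (%.1f%%), %d excluded",
        n_trials, n_trials - len(excluded), n_fallback,
        100.0 * n_fallback / max(1, n_trials), len(excluded),
    )
    return validate_results(table)


# --------------------------------------------------------------------------
# Statistics over the results table
# --------------------------------------------------------------------------

_TWOWAY_MEASURES = {
    "z_d_t": ("z_D", "thumb"),
    "z_d_f": ("z_D", "finger"),
    "sal_thumb": ("SAL", "thumb"),
    "sal_finger": ("SAL", "finger"),
}


def _with_factors(cells: pd.DataFrame) -> pd.DataFrame:
    out = cells.copy()
    out["finger"] = out["task"].str[0]
    out["phalanx"] = out["task"].str[1]
    return out


def _anova_row(measure: str, res: RmAnovaResult) -> dict:
    return {
        "measure": measure,
        "effect": res.effect,
        "F": res.f_value,
        "df1": res.df_effect,
        "df2": res.df_error,
        "epsilon_hf": res.epsilon_hf,
        "adj_df1": res.adjusted_df[0],
        "adj_df2": res.adjusted_df[1],
        "p": res.p_value,
        "p_uncorrected": res.p_uncorrected,
    }


def run_stats(
    results: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> dict[str, pd.DataFrame]:
    """Reproduce the statistical design on a results table.

    Returns tables ``anova2`` (finger x phalanx RM-ANOVA per measure),
    ``anova_effector`` (one per task, thumb vs finger on z_D), and
    ``pairwise`` (post-hoc paired comparisons per measure and factor).
    """
    validate_results(results)
    if results["participant"].nunique() < 2:
        raise ValidationError("design error: at least 2 participants required")

    anova2_rows, pairwise_rows = [], []
    for name, (measure, effector) in _TWOWAY_MEASURES.items():
        cells = participant_means(results[results["effector"] == effector], measure)
        cells = _with_factors(cells)
        for effect, res in rm_anova_2way(cells).items():
            anova2_rows.append(_anova_row(name, res))
        for factor in ("finger", "phalanx"):
            for pr in posthoc_pairwise(
                cells, factor, method=config.posthoc_method
            ):
                pairwise_rows.append(
                    {
                        "measure": name,
                        "factor": factor,
                        "level_a": pr.level_a,
                        "level_b": pr.level_b,
                        "mean_diff": pr.mean_diff,
                        "t": pr.t_value,
                        "p_raw": pr.p_raw,
                        "p_adjusted": pr.p_adjusted,
                        "method": pr.method,
                    }
                )

    effector_rows = []
    zd = participant_means(results, "z_D")
    for task in sorted(zd["task"].unique()):
        res = rm_anova_effector(zd[zd["task"] == task])
        row = _anova_row("z_D", res)
        row["task"] = task
        effector_rows.append(row)

    return {
        "anova2": pd.DataFrame(anova2_rows),
        "anova_effector": pd.DataFrame(effector_rows),
        "pairwise": pd.DataFrame(pairwise_rows),
    }


def run_report(results: pd.DataFrame) -> pd.DataFrame:
    """Group means and standard errors per task x effector x measure.

    Participant means are the unit of averaging, so the SEM is across
    participants — the quantity the summary figures display.
    """
    validate_results(results)
    cells = participant_means(results)
    grouped = cells.groupby(["task", "effector", "measure"], observed=True)["value"]
    out = grouped.agg(
        mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n_participants="size",
    ).reset_index()
    return out.sort_values(["measure", "task", "effector"]).reset_index(drop=True)
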