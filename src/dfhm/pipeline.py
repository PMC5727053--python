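"""End-to-end orchestration: recording -> cleaned segments -> band powers ->
personalized z-maps -> head maps -> 5 s workload index -> per-task portions.

These helpers wire the stage modules together with the default settings
(0.5-40 Hz order-100 FIR, 10 s / 5 s segmentation, first-minute baselines,
theta/alpha bands) while leaving every knob overridable.  Cohort-level
evaluation streams subjects one at a time, so full-session recordings never
have to coexist in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classifier import ModelPair
from .errors import ValidationError
from .index import TaskPortions, WorkloadIndexSeries, index_series, portions_by_task
from .io import Recording, validate_montage
from .maps import DFHM, make_dfhm
from .montage import Montage, default_montage
from .personalize import BaselineStats, collect_baseline, fit_baseline, zscore
from .preprocess import bandpass_filter, remove_artifacts, rereference_average, segment
from .spectral import ALPHA, THETA, BandPowerVector, band_power
from .synthetic import CohortSpec, SubjectRecording, generate_cohort

__all__ = [
    "PipelineConfig",
    "recording_band_powers",
    "subject_baseline",
    "subject_maps",
    "subject_index_series",
    "SubjectResult",
    "evaluate_cohort",
    "condition_means",
    "WorkloadStudy",
    "run_workload_study",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Stage settings for the standard processing chain."""

    low_hz: float = 0.5
    high_hz: float = 40.0
    filter_order: int = 100
    ica_policy: object = "default"
    ica_seed: int = 97
    window_s: float = 10.0
    step_s: float = 5.0
    bands: tuple = (THETA, ALPHA)


def recording_band_powers(rec: Recording, montage: Montage | None = None,
                          config: PipelineConfig = PipelineConfig()) -> list[BandPowerVector]:
    """Clean one recording and return per-segment band-power vectors."""
    montage = montage or default_montage()
    rec = validate_montage(rec, montage)
    rec = bandpass_filter(rec, config.low_hz, config.high_hz, config.filter_order)
    rec = remove_artifacts(rec, config.ica_policy, seed=config.ica_seed)
    rec = rereference_average(rec)
    segs = segment(rec, config.window_s, config.step_s)
    return [band_power(s, config.bands) for s in segs]


def subject_baseline(powers: Sequence[BandPowerVector], subject_id: str, *,
                     window_s: float = 10.0, include_tasks=None) -> BaselineStats:
    """Fit the personalization parameters from first-minute segments."""
    first_minute = [p for p in powers
                    if p.offset_in_block_s + window_s <= 60.0 + 1e-9
                    and (include_tasks is None or p.task_id in include_tasks)]
    return fit_baseline(first_minute, subject_id)


def subject_maps(powers: Sequence[BandPowerVector], base: BaselineStats,
                 montage: Montage | None = None) -> list[DFHM]:
    montage = montage or default_montage()
    return [make_dfhm(zscore(p, base), montage) for p in powers]


def subject_index_series(maps: Sequence[DFHM], models: ModelPair, *,
                         training: set | None = None, cadence_s: float = 5.0,
                         ) -> WorkloadIndexSeries:
    return index_series(maps, models, training=training, cadence_s=cadence_s)


@dataclass
class SubjectResult:
    subject_id: str
    series: WorkloadIndexSeries
    portions: dict[str, TaskPortions]
    truth: dict[str, str] = field(default_factory=dict)


def evaluate_cohort(subjects: Iterable[SubjectRecording], models: ModelPair,
                    montage: Montage | None = None,
                    config: PipelineConfig = PipelineConfig(), *,
                    training: set | None = None) -> list[SubjectResult]:
    """Run the full chain for each subject against a frozen model pair.

    The classifiers are never retrained here — new subjects and new tasks are
    classified with the models as given, which is the method's central
    portability claim (only the per-subject baseline is subject-specific).
    """
    montage = montage or default_montage()
    out = []
    for sub in subjects:
        powers = recording_band_powers(sub.recording, montage, config)
        base = subject_baseline(powers, sub.subject_id, window_s=config.window_s)
        maps = subject_maps(powers, base, montage)
        series = subject_index_series(maps, models, training=training,
                                      cadence_s=config.step_s)
        out.append(
            SubjectResult(
                subject_id=sub.subject_id,
                series=series,
                portions=portions_by_task(series),
                truth=dict(sub.truth),
            )
        )
    return out


@dataclass
class WorkloadStudy:
    """Results of a frozen-model cohort study (training + evaluation cohorts)."""

    models: ModelPair
    cfg_note: str
    results: list[SubjectResult]

    def condition_means(self, measure: str = "pct_high") -> dict[str, float]:
        return condition_means(self.results, measure)


def run_workload_study(train_subjects: int = 4, eval_subjects: int = 8, *,
                       train_seed: int = 101, eval_seed: int = 777,
                       battery_scale: float = 0.2, held_out_task: bool = True,
                       select_hyperparameters: bool = True,
                       config: PipelineConfig | None = None,
                       montage: Montage | None = None, seed: int = 0) -> WorkloadStudy:
    """Train a frozen classifier pair on one cohort, evaluate on another.

    Protocol: generate a training cohort, rule-label every one of its head
    maps, empirically select the SVM hyperparameters on that corpus by Monte
    Carlo CV (mirroring the original empirical selection), train the pair
    once, and freeze it.  Then generate a fresh evaluation cohort — new
    subjects, optionally with an additional task type never seen in training
    — and index it without any retraining.  ``battery_scale`` shrinks the
    session to keep desk-scale studies fast (durations floored at 60 s).
    """
    from .classifier import (
        DEFAULT_HIGH_SVM,
        DEFAULT_LOW_SVM,
        select_svm_configs,
        train_pair,
    )
    from .maps import auto_label
    from .synthetic import default_battery, scale_battery, with_held_out_task

    montage = montage or default_montage()
    config = config or PipelineConfig(ica_policy="none")
    battery = scale_battery(default_battery(), battery_scale)

    train_spec = CohortSpec(n_subjects=train_subjects, seed=train_seed, battery=battery,
                            montage=montage, subject_prefix="train")
    labeled = []
    for sub in generate_cohort(train_spec):
        powers = recording_band_powers(sub.recording, montage, config)
        base = subject_baseline(powers, sub.subject_id, window_s=config.window_s)
        maps = subject_maps(powers, base, montage)
        for m in maps:
            m.label = auto_label(m)
        labeled.extend(maps)
    if select_hyperparameters:
        cfg_low, cfg_high = select_svm_configs(labeled, reps=3, seed=seed)
        note = f"grid-selected: low {cfg_low}, high {cfg_high}"
    else:
        cfg_low, cfg_high = DEFAULT_LOW_SVM, DEFAULT_HIGH_SVM
        note = "published defaults"
    models = train_pair(labeled, cfg_low, cfg_high, seed=seed, channels=montage.labels)

    eval_battery = with_held_out_task(battery) if held_out_task else battery
    eval_spec = CohortSpec(n_subjects=eval_subjects, seed=eval_seed, battery=eval_battery,
                           montage=montage, subject_prefix="eval")
    results = evaluate_cohort(generate_cohort(eval_spec), models, montage, config)
    return WorkloadStudy(models=models, cfg_note=note, results=results)


def condition_means(results: Sequence[SubjectResult], measure: str = "pct_high",
                    ) -> dict[str, float]:
    """Mean portion per ground-truth condition, averaged over subjects and tasks."""
    if not results:
        raise ValidationError("no subject results")
    acc: dict[str, list[float]] = {}
    for r in results:
        for task, portions in r.portions.items():
            cond = r.truth.get(task)
            if cond is None:
                continue
            acc.setdefault(cond, []).append(getattr(portions, measure))
    return {c: float(np.mean(v)) for c, v in acc.items()}
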