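"""The 5-second workload index, per-task load portions, and cohort statistics.

Each analysis segment yields one three-class index value by logically
combining the two SVM decisions: low-detector only → low; high-detector only
→ high; neither → moderate; both (a conflict the detectors should not
produce) → moderate by default, the least-committal class, or an error when
auditing.  Per task, the percentages of low/moderate/high segments (LLS /
MLS / HLS) summarize the induced load, and a one-way repeated-measures ANOVA
with Greenhouse-Geisser correction plus Bonferroni-corrected paired
comparisons tests for differences across tasks within subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import ModelPair, classify_map
from .errors import ValidationError
from .maps import DFHM

__all__ = [
    "combine",
    "IndexEntry",
    "WorkloadIndexSeries",
    "index_series",
    "TaskPortions",
    "task_portions",
    "portions_by_task",
    "cohort_table",
    "RmAnovaResult",
    "rm_anova_gg",
]

CLASSES = ("low", "moderate", "high")


def combine(is_low: bool, is_high: bool, *, conflict: str = "moderate") -> str:
    """Logical combination of the two detector outputs into one class.

    ``(True, False)`` → low, ``(False, True)`` → high, ``(False, False)`` →
    moderate.  ``(True, True)`` is a detector conflict: mapped to moderate by
    default, or raises if ``conflict="error"``.
    """
    if is_low and is_high:
        if conflict == "error":
            raise ValidationError("both detectors fired on the same map")
        return "moderate"
    if is_low:
        return "low"
    if is_high:
        return "high"
    return "moderate"


@dataclass(frozen=True)
class IndexEntry:
    time_s: float
    task_id: str
    label: str
    is_training: bool = False


@dataclass
class WorkloadIndexSeries:
    """Ordered per-segment workload classes at a fixed cadence."""

    entries: list[IndexEntry]
    cadence_s: float = 5.0
    subject_id: str | None = None

    def __post_init__(self):
        for a, b in zip(self.entries, self.entries[1:]):
            if b.time_s <= a.time_s:
                raise ValidationError("index times must be strictly increasing")
            if a.task_id == b.task_id and abs((b.time_s - a.time_s) - self.cadence_s) > 1e-6:
                raise ValidationError(
                    f"non-constant cadence within task {a.task_id!r}: "
                    f"{b.time_s - a.time_s:g} s vs {self.cadence_s:g} s"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time_s, e.task_id, e.label, e.is_training) for e in self.entries],
            columns=["time_s", "task", "class", "is_training"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def index_series(maps: Sequence[DFHM], models: ModelPair, *, cadence_s: float = 5.0,
                 training: set | None = None, subject_id: str | None = None,
                 conflict: str = "moderate") -> WorkloadIndexSeries:
    """Classify each map and emit the index series.

    ``training`` is an optional set of ``(subject, task, start_s)`` keys (see
    :func:`dfhm.maps.training_keys`); matching entries are still indexed but
    flagged so evaluation summaries can exclude them.
    """
    ordered = sorted(maps, key=lambda m: m.start_s)
    entries = []
    for m in ordered:
        is_low, is_high = classify_map(m, models)
        key = (m.subject_id, m.task_id, m.start_s)
        entries.append(
            IndexEntry(
                time_s=m.start_s,
                task_id=m.task_id,
                label=combine(is_low, is_high, conflict=conflict),
                is_training=bool(training and key in training) or m.is_training,
            )
        )
    sid = subject_id or (ordered[0].subject_id if ordered else None)
    return WorkloadIndexSeries(entries=entries, cadence_s=cadence_s, subject_id=sid)


@dataclass(frozen=True)
class TaskPortions:
    """Percentages of low/moderate/high segments within one task."""

    pct_low: float
    pct_moderate: float
    pct_high: float
    n_segments: int

    def __post_init__(self):
        total = self.pct_low + self.pct_moderate + self.pct_high
        if self.n_segments < 1:
            raise ValidationError("n_segments must be >= 1")
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"portions must sum to 100, got {total}")


def _portions(labels: Sequence[str]) -> TaskPortions:
    n = len(labels)
    if n == 0:
        raise ValidationError("cannot compute portions of an empty series")
    counts = {c: sum(1 for l in labels if l == c) for c in CLASSES}
    return TaskPortions(
        pct_low=100.0 * counts["low"] / n,
        pct_moderate=100.0 * counts["moderate"] / n,
        pct_high=100.0 * counts["high"] / n,
        n_segments=n,
    )


def task_portions(series: WorkloadIndexSeries, task_id: str | None = None, *,
                  exclude_training: bool = True) -> TaskPortions:
    """Class percentages over the series (optionally restricted to one task).

    Training-flagged entries are excluded from the summary by default,
    mirroring the exclusion of the labeled first-minute segments from
    classifier evaluation.
    """
    labels = [e.label for e in series.entries
              if (task_id is None or e.task_id == task_id)
              and not (exclude_training and e.is_training)]
    return _portions(labels)


def portions_by_task(series: WorkloadIndexSeries, *, exclude_training: bool = True
                     ) -> dict[str, TaskPortions]:
    tasks = list(dict.fromkeys(e.task_id for e in series.entries))
    return {t: task_portions(series, t, exclude_training=exclude_training) for t in tasks}


def cohort_table(cohort: Mapping[str, Mapping[str, TaskPortions]], measure: str = "pct_high",
                 ) -> pd.DataFrame:
    """Wide subjects x tasks table of one portion measure.

    Missing subject/task cells are explicit NaN, never silently dropped.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    if measure not in ("pct_low", "pct_moderate", "pct_high"):
        raise ValidationError(f"unknown measure {measure!r}")
    tasks = list(dict.fromkeys(t for by_task in cohort.values() for t in by_task))
    data = {
        subj: {t: getattr(by_task[t], measure) if t in by_task else np.nan for t in tasks}
        for subj, by_task in cohort.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=tasks)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    """One-way repeated-measures ANOVA with sphericity correction."""

    F: float
    df1: float
    df2: float
    p: float
    epsilon: float
    pairwise: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        n_sig = int((self.pairwise["p_bonf"] < 0.05).sum()) if self.pairwise is not None else 0
        return (
            f"Greenhouse-Geisser: F({self.df1:.2f}, {self.df2:.2f}) = {self.F:.3f}, "
            f"p = {self.p:.3g}, epsilon = {self.epsilon:.3f}; "
            f"{n_sig}/{len(self.pairwise)} Bonferroni-corrected pairwise "
            f"comparisons significant at alpha = 0.05"
        )


def rm_anova_gg(table: pd.DataFrame, alpha: float = 0.05) -> RmAnovaResult:
    """Within-subject ANOVA over a subjects x levels table, GG-corrected.

    All levels must be observed for every subject (listwise completeness);
    pairwise post-hocs are paired t tests with Bonferroni adjustment over the
    full family of level pairs.
    """
    import pingouin as pg

    if table.shape[1] < 2:
        raise ValidationError("need at least 2 within-subject levels")
    if table.shape[0] < 3:
        raise ValidationError("need at least 3 subjects")
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValidationError(f"incomplete cases (listwise completeness required): {bad}")

    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="level", value_name="value"
    )
    aov = pg.rm_anova(data=long, dv="value", within="level", subject="subject",
                      correction=True, detailed=True)
    effect = aov.loc[aov["Source"] == "level"].iloc[0]
    error = aov.loc[aov["Source"] == "Error"].iloc[0]
    if "F" not in effect.index or not np.isfinite(float(effect["F"])):
        raise ValidationError(
            "repeated-measures ANOVA undefined (no variance in the table?)"
        )
    # eps is absent/NaN when pingouin skips the sphericity estimate (e.g. k = 2)
    eps = float(effect["eps"]) if "eps" in effect.index and pd.notna(effect["eps"]) else 1.0
    df1, df2 = float(effect["DF"]), float(error["DF"])
    p_gg = float(effect["p_GG_corr"]) if pd.notna(effect.get("p_GG_corr", np.nan)) \
        else float(effect["p_unc"])

    post = pg.pairwise_tests(data=long, dv="value", within="level", subject="subject",
                             padjust="bonf")
    pairwise = post.rename(columns={"A": "level_a", "B": "level_b", "p_corr": "p_bonf",
                                    "p_unc": "p_uncorrected", "T": "t"})
    keep = [c for c in ("level_a", "level_b", "t", "dof", "p_uncorrected", "p_bonf") if c in pairwise]
    pairwise = pairwise[keep]
    if "p_bonf" not in pairwise:  # only one comparison: no correction applied
        pairwise["p_bonf"] = pairwise["p_uncorrected"]
    return RmAnovaResult(F=float(effect["F"]), df1=eps * df1, df2=eps * df2, p=p_gg,
                         epsilon=eps, pairwise=pairwise.reset_index(drop=True))
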