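"""Per-subject baseline statistics and z-scoring.

The only subject-specific parameters of the whole method are, per electrode,
the mean and standard deviation of theta and alpha band power ("four values
per electrode") estimated from the first minute of every task block.  The
first minutes sample the subject's oscillation range across workload
conditions without fatigue or monotony effects; rest blocks are included by
default (configurable) to widen that range.  Given the baseline, every
segment's band powers are converted to dimensionless z-scores, which is what
makes the downstream classifiers subject-independent.

Baselines serialize to a small JSON sidecar so classification can run
without re-reading the baseline recordings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateBaselineError, ValidationError
from .preprocess import Segment
from .spectral import BandPowerVector

logger = logging.getLogger(__name__)

__all__ = ["BaselineStats", "ZMap", "collect_baseline", "fit_baseline", "zscore"]

BASELINE_WINDOW_S = 60.0


@dataclass
class BaselineStats:
    """Per-electrode, per-band baseline mean and standard deviation (uV^2)."""

    subject_id: str
    channels: list[str]
    mean_theta: np.ndarray
    sd_theta: np.ndarray
    mean_alpha: np.ndarray
    sd_alpha: np.ndarray
    source: list[str]

    def __post_init__(self):
        for name in ("mean_theta", "sd_theta", "mean_alpha", "sd_alpha"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.channels)
        if any(getattr(self, a).shape != (n,) for a in
               ("mean_theta", "sd_theta", "mean_alpha", "sd_alpha")):
            raise ValidationError("baseline arrays must be 1-D with one value per electrode")
        bad = [(self.channels[i], band)
               for band, sd in (("theta", self.sd_theta), ("alpha", self.sd_alpha))
               for i in np.flatnonzero(sd <= 0)]
        if bad:
            raise DegenerateBaselineError(bad)

    def to_json(self, path) -> None:
        doc = {
            "subject_id": self.subject_id,
            "channels": self.channels,
            "mean_theta": self.mean_theta.tolist(),
            "sd_theta": self.sd_theta.tolist(),
            "mean_alpha": self.mean_alpha.tolist(),
            "sd_alpha": self.sd_alpha.tolist(),
            "source": self.source,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "BaselineStats":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)


@dataclass
class ZMap:
    """Dimensionless theta/alpha z-scores per electrode for one segment."""

    z_theta: np.ndarray
    z_alpha: np.ndarray
    channels: list[str]
    start_s: float
    task_id: str
    subject_id: str | None = None
    offset_in_block_s: float = 0.0

    def __post_init__(self):
        self.z_theta = np.asarray(self.z_theta, dtype=float)
        self.z_alpha = np.asarray(self.z_alpha, dtype=float)
        if not (np.isfinite(self.z_theta).all() and np.isfinite(self.z_alpha).all()):
            raise ValidationError("z-scores must be finite")


def collect_baseline(segments: Sequence[Segment], *, include_tasks: Iterable[str] | None = None,
                     window_s: float = BASELINE_WINDOW_S) -> list[Segment]:
    """Select the baseline segments: windows fully inside each block's first minute.

    With 10 s windows stepped by 5 s this yields 11 segments per block.
    Windows crossing the 60 s boundary are excluded (conservative,
    deterministic).  ``include_tasks`` restricts the contributing blocks
    (default: all blocks, rests included).  Blocks shorter than the segment
    window contribute nothing and are skipped with a warning upstream.
    """
    keep = None if include_tasks is None else set(include_tasks)
    out = []
    for s in segments:
        if keep is not None and s.task_id not in keep:
            continue
        if s.offset_in_block_s + s.window_s <= window_s + 1e-9:
            out.append(s)
    return out


def fit_baseline(powers: Sequence[BandPowerVector], subject_id: str) -> BaselineStats:
    """Fit per-electrode/band mean and sample SD (n-1) over baseline segments."""
    if len(powers) < 2:
        raise ValidationError(
            f"baseline needs at least 2 contributing segments, got {len(powers)}"
        )
    channels = list(powers[0].channels)
    for p in powers:
        if list(p.channels) != channels:
            raise ValidationError("all baseline power vectors must share the channel order")
    theta = np.stack([p.theta for p in powers])
    alpha = np.stack([p.alpha for p in powers])
    return BaselineStats(
        subject_id=subject_id,
        channels=channels,
        mean_theta=theta.mean(axis=0),
        sd_theta=theta.std(axis=0, ddof=1),
        mean_alpha=alpha.mean(axis=0),
        sd_alpha=alpha.std(axis=0, ddof=1),
        source=[f"{p.task_id}@{p.start_s:g}s" for p in powers],
    )


def zscore(power: BandPowerVector, base: BaselineStats) -> ZMap:
    """Standardize one segment's band powers against the subject baseline."""
    if list(power.channels) != list(base.channels):
        raise ValidationError("baseline does not cover the power vector's electrodes")
    return ZMap(
        z_theta=(power.theta - base.mean_theta) / base.sd_theta,
        z_alpha=(power.alpha - base.mean_alpha) / base.sd_alpha,
        channels=list(power.channels),
        start_s=power.start_s,
        task_id=power.task_id,
        subject_id=power.subject_id or base.subject_id,
        offset_in_block_s=power.offset_in_block_s,
    )
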