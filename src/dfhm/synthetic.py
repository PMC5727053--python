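"""Synthetic EEG cohorts with controllable workload signatures.

The generator emulates the statistical structure the workload index relies
on, at the channel level (no biophysical forward model): a pink-noise (1/f)
background on every channel, amplitude-modulated theta bursts (4-8 Hz) on
frontal channels whose amplitude rises with workload, amplitude-modulated
alpha bursts (8-12 Hz) on parietal channels whose amplitude falls with
workload, and optional blink-like transients on the fronto-polar channels.
Sessions follow a task battery of blocks with per-block workload profiles;
per-subject gain jitter models inter-individual amplitude differences.
Everything is seed-deterministic.

Oscillations are bursts (smoothly varying random envelopes), not continuous
sinusoids, so band power varies from segment to segment and baseline
standard deviations are non-degenerate.

A second generator works directly in z-map space: rule-consistent labeled
head maps drawn from low/moderate/high archetypes with controllable margin
and jitter, used to train and stress the classifier pair without running the
signal pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import Block, Recording
from .maps import DFHM, LabelRule, auto_label
from .montage import FRONTAL, Montage, default_montage

__all__ = [
    "WorkloadProfile",
    "DEFAULT_PROFILES",
    "BatteryBlock",
    "default_battery",
    "scale_battery",
    "with_held_out_task",
    "CohortSpec",
    "SubjectRecording",
    "generate_recording",
    "generate_cohort",
    "generate_labeled_dfhm_set",
    "generate_map_cohort",
]


@dataclass(frozen=True)
class WorkloadProfile:
    """Per-condition oscillation gains and the ground-truth condition label."""

    theta_gain_frontal: float
    alpha_gain_parietal: float
    label: str  # ground-truth condition: low / moderate / high

    def __post_init__(self):
        if self.theta_gain_frontal <= 0 or self.alpha_gain_parietal <= 0:
            raise ValidationError("profile gains must be positive")
        if self.label not in ("low", "moderate", "high"):
            raise ValidationError(f"profile label must be low/moderate/high, got {self.label!r}")


#: Graded profiles: frontal theta rises and parietal alpha falls with load.
#: ``stop_signal`` sits between moderate and high (a held-out validation task).
DEFAULT_PROFILES: dict[str, WorkloadProfile] = {
    "low": WorkloadProfile(0.6, 1.5, "low"),
    "moderate": WorkloadProfile(1.0, 1.0, "moderate"),
    "high": WorkloadProfile(1.7, 0.5, "high"),
    "stop_signal": WorkloadProfile(1.35, 0.7, "high"),
}


@dataclass(frozen=True)
class BatteryBlock:
    task_id: str
    duration_s: float
    condition: str  # key into the profiles mapping


#: Standard session: two rests framing nine cognitive tasks, 81 min total.
_DEFAULT_BATTERY: tuple[BatteryBlock, ...] = (
    BatteryBlock("rest_start", 180.0, "low"),
    BatteryBlock("zero_back", 300.0, "low"),
    BatteryBlock("two_back", 300.0, "moderate"),
    BatteryBlock("sternberg", 600.0, "moderate"),
    BatteryBlock("serial_sternberg", 600.0, "moderate"),
    BatteryBlock("stroop", 300.0, "moderate"),
    BatteryBlock("switch_par", 300.0, "low"),
    BatteryBlock("switch_num", 300.0, "low"),
    BatteryBlock("switch_xxx", 600.0, "moderate"),
    BatteryBlock("aospan", 1200.0, "high"),
    BatteryBlock("rest_end", 180.0, "low"),
)


def default_battery() -> tuple[BatteryBlock, ...]:
    return _DEFAULT_BATTERY


def scale_battery(battery: Sequence[BatteryBlock], factor: float,
                  min_duration_s: float = 60.0) -> tuple[BatteryBlock, ...]:
    """Shrink block durations by ``factor`` for fast studies.

    Durations are floored at 60 s (the baseline first minute must exist) and
    snapped to whole 5 s steps so segment grids stay aligned.
    """
    out = []
    for b in battery:
        d = max(min_duration_s, 5.0 * round(b.duration_s * factor / 5.0))
        out.append(replace(b, duration_s=d))
    return tuple(out)


def with_held_out_task(battery: Sequence[BatteryBlock], task_id: str = "stop_signal",
                       duration_s: float = 300.0, condition: str = "stop_signal",
                       ) -> tuple[BatteryBlock, ...]:
    """Append a block type unseen during training (generalization protocol)."""
    return tuple(battery) + (BatteryBlock(task_id, duration_s, condition),)


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Amplitudes are calibrated so the theta/alpha band-power SNR of the
    workload signature against the pink background is ~2 under the moderate
    profile; ``subject_jitter_sd`` is the SD of a per-subject lognormal gain
    multiplier drawn once per subject and band.
    """

    n_subjects: int
    seed: int
    battery: tuple[BatteryBlock, ...] = _DEFAULT_BATTERY
    profiles: Mapping[str, WorkloadProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    montage: Montage = field(default_factory=default_montage)
    rate: float = 500.0
    noise_exponent: float = 1.0
    noise_amplitude_uv: float = 10.0
    theta_amp_uv: float = 6.5
    alpha_amp_uv: float = 5.0
    envelope_sd: float = 0.1
    envelope_node_s: float = 2.0
    state_drift_sd: float = 0.35
    state_node_s: float = 5.0
    state_ar: float = 0.6
    subject_jitter_sd: float = 0.1
    artifact_rate_hz: float = 0.0
    subject_prefix: str = "sub"

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for b in self.battery:
            if b.duration_s < 60.0:
                raise ValidationError(
                    f"block {b.task_id!r} shorter than 60 s: no baseline minute"
                )
            if b.condition not in self.profiles:
                raise ValidationError(f"block {b.task_id!r} uses unknown profile {b.condition!r}")


@dataclass
class SubjectRecording:
    subject_id: str
    recording: Recording
    truth: dict[str, str]  # task_id -> ground-truth condition label


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise of length n."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst(n: int, rate: float, band: tuple[float, float], amplitude: float,
           envelope_sd: float, node_s: float, rng: np.random.Generator,
           state_env: np.ndarray | None = None) -> np.ndarray:
    """Amplitude-modulated sinusoid: random carrier in band, smooth random envelope.

    ``state_env`` is an optional shared (region-coherent) slow amplitude
    modulation — the latent workload-state drift — multiplied on top of the
    channel's own envelope.
    """
    t = np.arange(n) / rate
    f = rng.uniform(*band)
    phase = rng.uniform(0, 2 * np.pi)
    n_nodes = max(2, int(np.ceil(t[-1] / node_s)) + 1)
    nodes = np.maximum(0.05, 1.0 + envelope_sd * rng.standard_normal(n_nodes))
    env = np.interp(t, np.linspace(0, t[-1], n_nodes), nodes)
    if state_env is not None:
        env = env * state_env
    return amplitude * env * np.sin(2 * np.pi * f * t + phase)


def _state_drift(n: int, rate: float, node_s: float, ar: float, rng: np.random.Generator,
                 ) -> np.ndarray:
    """Standardized latent workload-state series (AR(1) at ``node_s`` nodes).

    The instantaneous mental state wanders within a task block — that
    within-task mixture is what makes per-task class *portions* a graded
    statistic rather than 0/100.  Returned at sample resolution, mean ~0.
    """
    t = np.arange(n) / rate
    n_nodes = max(2, int(np.ceil(t[-1] / node_s)) + 1)
    s = np.empty(n_nodes)
    s[0] = rng.standard_normal()
    innov = rng.standard_normal(n_nodes - 1)
    for k in range(1, n_nodes):
        s[k] = ar * s[k - 1] + np.sqrt(1 - ar**2) * innov[k - 1]
    return np.interp(t, np.linspace(0, t[-1], n_nodes), s)


def _blinks(n: int, rate: float, rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude blink waveform train (raised-cosine, ~400 ms)."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_hz * n / rate)
    width = int(0.4 * rate)
    template = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    for t0 in np.sort(rng.integers(0, max(1, n - width), size=n_events)):
        out[t0 : t0 + width] += template
    return out


def generate_recording(spec: CohortSpec, subject_index: int) -> SubjectRecording:
    """Generate one subject's full-session recording (seed-deterministic).

    The per-subject stream is derived from ``(spec.seed, subject_index)``, so
    any subject can be regenerated independently of cohort size.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(subject_index)]))
    montage = spec.montage
    n_ch = len(montage)
    frontal = np.array([r == FRONTAL for r in montage.regions()])
    jitter_theta, jitter_alpha = np.exp(spec.subject_jitter_sd * rng.standard_normal(2))

    pieces, blocks, truth = [], [], {}
    t0 = 0.0
    for blk in spec.battery:
        profile = spec.profiles[blk.condition]
        n = int(round(blk.duration_s * spec.rate))
        # one latent workload state per block, shared across channels:
        # theta amplitude rises and alpha amplitude falls when the state rises
        state = _state_drift(n, spec.rate, spec.state_node_s, spec.state_ar, rng)
        theta_state = np.exp(spec.state_drift_sd * state)
        alpha_state = np.exp(-spec.state_drift_sd * state)
        data = np.empty((n_ch, n), dtype=np.float32)
        for ci in range(n_ch):
            x = spec.noise_amplitude_uv * _pink_noise(n, spec.noise_exponent, rng)
            if frontal[ci]:
                x += _burst(n, spec.rate, (4.0, 8.0),
                            spec.theta_amp_uv * profile.theta_gain_frontal * jitter_theta,
                            spec.envelope_sd, spec.envelope_node_s, rng,
                            state_env=theta_state)
            else:
                x += _burst(n, spec.rate, (8.0, 12.0),
                            spec.alpha_amp_uv * profile.alpha_gain_parietal * jitter_alpha,
                            spec.envelope_sd, spec.envelope_node_s, rng,
                            state_env=alpha_state)
            data[ci] = x
        if spec.artifact_rate_hz > 0:
            blink = _blinks(n, spec.rate, spec.artifact_rate_hz, rng)
            for ci, ch in enumerate(montage.labels):
                if ch.upper().startswith("FP"):
                    data[ci] += (120.0 * blink).astype(np.float32)
                elif ch in ("F3", "F4", "Fz", "F7", "F8"):
                    data[ci] += (45.0 * blink).astype(np.float32)
        pieces.append(data)
        blocks.append(Block(blk.task_id, t0, t0 + blk.duration_s))
        truth[blk.task_id] = profile.label
        t0 += blk.duration_s

    subject_id = f"{spec.subject_prefix}{subject_index:02d}"
    rec = Recording(
        samples=np.concatenate(pieces, axis=1),
        rate=spec.rate,
        channels=list(montage.labels),
        reference="Cz",
        blocks=blocks,
        subject_id=subject_id,
    )
    return SubjectRecording(subject_id=subject_id, recording=rec, truth=truth)


def generate_cohort(spec: CohortSpec) -> Iterator[SubjectRecording]:
    """Yield the cohort's subjects one at a time (recordings are large)."""
    for i in range(spec.n_subjects):
        yield generate_recording(spec, i)


# ---------------------------------------------------------------------------
# Direct z-map generators (classifier-level synthesis)
# ---------------------------------------------------------------------------

_ARCHETYPES = {"low": (-1.0, 1.0), "moderate": (0.0, 0.0), "high": (1.0, -1.0)}


def _archetype_map(condition: str, margin: float, region_jitter: float,
                   electrode_jitter: float, montage: Montage,
                   rng: np.random.Generator, **meta) -> DFHM:
    f0, p0 = _ARCHETYPES[condition]
    F = margin * f0 + region_jitter * rng.standard_normal()
    P = margin * p0 + region_jitter * rng.standard_normal()
    regions = montage.regions()
    base = np.where([r == FRONTAL for r in regions], F, P)
    values = base + electrode_jitter * rng.standard_normal(len(montage))
    return DFHM(values=values, region=regions, channels=list(montage.labels), **meta)


def generate_labeled_dfhm_set(n_maps: int = 540, margin: float = 1.0,
                              region_jitter: float = 0.05, electrode_jitter: float = 0.05,
                              label_noise: float = 0.0, rule: LabelRule = LabelRule(),
                              montage: Montage | None = None, seed: int = 0) -> list[DFHM]:
    """Rule-labeled head maps drawn around low/moderate/high archetypes.

    Archetype region means are ``(-margin, +margin)``, ``(0, 0)`` and
    ``(+margin, -margin)`` for (frontal, parietal); each map adds a region-
    coherent jitter and per-electrode jitter, then receives its label from
    the threshold rule (so labels are rule-consistent by construction).
    ``label_noise`` randomly reassigns that fraction of labels (control
    experiments).  The default jitters reproduce the tight archetype
    clustering implied by the narrow high-load kernel width; see the methods
    documentation.
    """
    if n_maps < 1:
        raise ValidationError("n_maps must be >= 1")
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    conditions = ("low", "moderate", "high")
    out = []
    for i in range(n_maps):
        m = _archetype_map(conditions[i % 3], margin, region_jitter, electrode_jitter,
                           montage, rng, start_s=float(i), task_id="synthetic",
                           subject_id="synthetic")
        m.label = auto_label(m, rule)
        if label_noise > 0 and rng.random() < label_noise:
            m.label = conditions[rng.integers(3)]
        out.append(m)
    return out


def generate_map_cohort(n_subjects: int, battery: Sequence[BatteryBlock] | None = None,
                        profiles: Mapping[str, WorkloadProfile] | None = None,
                        window_s: float = 10.0, step_s: float = 5.0,
                        margin: float = 1.0, region_jitter: float = 0.05,
                        electrode_jitter: float = 0.05,
                        montage: Montage | None = None, seed: int = 0,
                        ) -> dict[str, list[DFHM]]:
    """Per-subject lists of unlabeled head maps mirroring a session's segment grid.

    Each battery block contributes one map per analysis window (same
    ``floor((T - window)/step) + 1`` bookkeeping as the signal pipeline),
    drawn from the block condition's archetype.  This is the cheap route to
    cohort-scale map inventories for training-set selection.
    """
    from .preprocess import segment_count

    battery = tuple(battery) if battery is not None else _DEFAULT_BATTERY
    profiles = dict(profiles) if profiles is not None else dict(DEFAULT_PROFILES)
    montage = montage or default_montage()
    cohort: dict[str, list[DFHM]] = {}
    for si in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), si]))
        subject_id = f"sub{si:02d}"
        maps: list[DFHM] = []
        t0 = 0.0
        for blk in battery:
            cond = profiles[blk.condition].label
            for k in range(segment_count(blk.duration_s, window_s, step_s)):
                maps.append(
                    _archetype_map(cond, margin, region_jitter, electrode_jitter, montage,
                                   rng, start_s=t0 + k * step_s, task_id=blk.task_id,
                                   subject_id=subject_id)
                )
            t0 += blk.duration_s
        cohort[subject_id] = maps
    return cohort
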