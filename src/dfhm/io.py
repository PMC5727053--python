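"""Reading and writing EEG recordings and session manifests.

Recordings are held in memory as a channels x time matrix in microvolts,
together with the sampling rate, channel labels, reference annotation and the
task-block layout of the session.  BrainVision triplets and EDF files are read
through MNE; compact writers for both formats are provided so that synthetic
cohorts can be saved and re-read through the same code path as real data.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import FormatError, MissingChannelError, ValidationError
from .montage import Montage

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "Recording",
    "ManifestEntry",
    "read_recording",
    "validate_montage",
    "read_manifest",
    "write_manifest",
    "write_brainvision",
    "write_edf",
]


@dataclass(frozen=True)
class Block:
    """One task block: identifier plus start/end offsets in seconds."""

    task_id: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"block {self.task_id!r}: end ({self.end_s}) must be after start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _check_blocks(blocks: Sequence[Block], duration_s: float | None = None) -> None:
    ordered = sorted(blocks, key=lambda b: b.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ValidationError(f"blocks {a.task_id!r} and {b.task_id!r} overlap")
    if duration_s is not None:
        for b in ordered:
            if b.start_s < -1e-9 or b.end_s > duration_s + 1e-9:
                raise ValidationError(
                    f"block {b.task_id!r} [{b.start_s}, {b.end_s}] s exceeds the "
                    f"recording duration ({duration_s:.3f} s)"
                )


@dataclass
class Recording:
    """Multichannel EEG in microvolts.

    Attributes
    ----------
    samples
        ``(n_channels, n_times)`` float array, microvolts.
    rate
        Sampling rate in Hz.
    channels
        Ordered channel labels (10-20 names).
    reference
        Reference annotation, e.g. ``"Cz"`` or ``"average"``.
    blocks
        Task blocks ``(task_id, start_s, end_s)`` within the recording.
    subject_id
        Optional subject identifier carried through the pipeline.
    """

    samples: np.ndarray
    rate: float
    channels: list[str]
    reference: str = "unknown"
    blocks: list[Block] = field(default_factory=list)
    subject_id: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time array")
        if self.rate <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        if self.samples.shape[0] != len(self.channels):
            raise ValidationError(
                f"samples has {self.samples.shape[0]} rows but {len(self.channels)} channel labels"
            )
        _check_blocks(self.blocks, self.duration_s)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.rate

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    subject_id: str
    blocks: tuple[Block, ...]
    format: str = "brainvision"
    reference: str | None = None


def read_recording(path, format: str = "auto", *, reference: str | None = None,
                   blocks: Sequence[Block] = (), subject_id: str | None = None) -> Recording:
    """Read a BrainVision (.vhdr) or EDF recording into microvolts.

    ``format`` may be ``"brainvision"``, ``"edf"`` or ``"auto"`` (by suffix).
    ``reference`` overrides the reference annotation (e.g. from a manifest);
    ``blocks`` attaches the session's task blocks.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {"": "brainvision", ".vhdr": "brainvision", ".edf": "edf"}.get(suffix, "")
        if not format:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")
    try:
        if format == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif format == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValidationError(f"unknown format {format!r}")
    except ValidationError:
        raise
    except Exception as exc:  # mne raises assorted exceptions on malformed input
        raise FormatError(f"could not read {path} as {format}: {exc}") from exc
    rate = float(raw.info["sfreq"])
    if rate <= 0:
        raise ValidationError(f"declared sampling rate must be positive, got {rate}")
    data_uv = raw.get_data(units="uV")
    if data_uv.size == 0:
        raise FormatError(f"{path}: no samples")
    ref = reference if reference is not None else _sidecar_reference(path)
    return Recording(
        samples=data_uv,
        rate=rate,
        channels=list(raw.ch_names),
        reference=ref or "unknown",
        blocks=list(blocks),
        subject_id=subject_id,
    )


def _sidecar_reference(path: Path) -> str | None:
    """BrainVision headers written by :func:`write_brainvision` carry the reference."""
    if path.suffix.lower() != ".vhdr":
        return None
    try:
        text = path.read_text(errors="replace")
    except OSError:
        return None
    for line in text.splitlines():
        if line.lower().startswith("; reference:"):
            return line.split(":", 1)[1].strip()
    return None


def validate_montage(rec: Recording, montage: Montage) -> Recording:
    """Reorder channels to montage order, dropping channels outside the montage.

    Raises :class:`MissingChannelError` if any montage label is absent.
    Idempotent: applying twice equals applying once.
    """
    present = {c: i for i, c in enumerate(rec.channels)}
    missing = [l for l in montage.labels if l not in present]
    if missing:
        raise MissingChannelError(missing)
    extra = [c for c in rec.channels if c not in montage.groups]
    if extra:
        logger.warning("dropping %d channel(s) outside the montage: %s", len(extra), extra)
    order = [present[l] for l in montage.labels]
    return rec.copy_with(samples=rec.samples[order], channels=list(montage.labels))


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def _block_from_mapping(d: dict) -> Block:
    task = d.get("task") or d.get("task_id")
    if task is None:
        raise ValidationError(f"manifest block without a task id: {d}")
    start = float(d["start_s"])
    if "end_s" in d:
        end = float(d["end_s"])
    elif "duration_s" in d:
        end = start + float(d["duration_s"])
    elif "duration_min" in d:
        end = start + 60.0 * float(d["duration_min"])
    else:
        raise ValidationError(f"block {task!r} needs end_s, duration_s or duration_min")
    return Block(task_id=str(task), start_s=start, end_s=end)


def read_manifest(path) -> list[ManifestEntry]:
    """Read a YAML/JSON session manifest.

    Schema: a list (or ``{"recordings": [...]}``) of entries with fields
    ``subject``, ``path``, optional ``format`` and ``reference``, and
    ``blocks`` — each block ``{task, start_s, end_s|duration_s|duration_min}``.
    Durations are normalized to seconds; overlapping blocks are rejected.
    """
    path = Path(path)
    text = path.read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"manifest {path} is not valid YAML/JSON: {exc}") from exc
    if doc is None:
        return []
    if isinstance(doc, dict):
        doc = doc.get("recordings", [])
    entries = []
    for item in doc:
        blocks = tuple(_block_from_mapping(b) for b in item.get("blocks", []))
        _check_blocks(blocks)
        rec_path = Path(item["path"])
        if not rec_path.is_absolute():
            rec_path = path.parent / rec_path
        entries.append(
            ManifestEntry(
                path=rec_path,
                subject_id=str(item["subject"]),
                blocks=blocks,
                format=item.get("format", "auto"),
                reference=item.get("reference"),
            )
        )
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path) -> None:
    doc = [
        {
            "subject": e.subject_id,
            "path": str(e.path),
            "format": e.format,
            **({"reference": e.reference} if e.reference else {}),
            "blocks": [
                {"task": b.task_id, "start_s": b.start_s, "end_s": b.end_s} for b in e.blocks
            ],
        }
        for e in entries
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Writers (used to persist synthetic cohorts and build test fixtures)
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, vhdr_path) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, multiplexed IEEE float32).

    Samples are stored as float32 microvolts: float32-valued data round-trips
    bit-for-bit through :func:`read_recording`.
    """
    vhdr_path = Path(vhdr_path)
    if vhdr_path.suffix.lower() != ".vhdr":
        vhdr_path = vhdr_path.with_suffix(".vhdr")
    stem = vhdr_path.stem
    eeg_path = vhdr_path.with_suffix(".eeg")
    vmrk_path = vhdr_path.with_suffix(".vmrk")

    interval_us = 1e6 / rec.rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        f"; Written by dfhm on {_dt.date.today().isoformat()}",
        f"; Reference: {rec.reference}",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:.10g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channels, start=1):
        lines.append(f"Ch{i}={ch},,1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for j, b in enumerate(rec.blocks, start=2):
        pos = int(round(b.start_s * rec.rate)) + 1
        dur = int(round(b.duration_s * rec.rate))
        vmrk.append(f"Mk{j}=Stimulus,{b.task_id},{pos},{dur},0")
    vmrk_path.write_text("\n".join(vmrk) + "\n", encoding="utf-8")

    data = np.asarray(rec.samples, dtype=np.float32)
    eeg_path.write_bytes(data.T.tobytes(order="C"))  # multiplexed: time-major
    return vhdr_path


def write_edf(rec: Recording, path) -> Path:
    """Write a minimal EDF file (16-bit, 1-second data records).

    EDF quantizes to 16 bits over the per-channel physical range, so the
    round trip is accurate to ~(range / 2^16), not bit-exact.  The recording
    length is truncated to a whole number of seconds.
    """
    path = Path(path)
    if path.suffix.lower() != ".edf":
        path = path.with_suffix(".edf")
    ns_per_record = int(round(rec.rate))
    if abs(ns_per_record - rec.rate) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    n_records = rec.n_times // ns_per_record
    if n_records == 0:
        raise ValidationError("recording shorter than one EDF data record (1 s)")
    nchan = rec.n_channels
    data = np.asarray(rec.samples[:, : n_records * ns_per_record], dtype=np.float64)

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767

    def _pad(value, width) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    startdate = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"subject {rec.subject_id or 'X'}", 80),
            _pad("dfhm synthetic recording", 80),
            _pad(startdate.strftime("%d.%m.%y"), 8),
            _pad(startdate.strftime("%H.%M.%S"), 8),
            _pad(256 * (nchan + 1), 8),
            _pad("", 44),
            _pad(n_records, 8),
            _pad("1", 8),
            _pad(nchan, 4),
        ]
    )
    header += b"".join(_pad(ch, 16) for ch in rec.channels)
    header += b"".join(_pad("AgAgCl electrode", 80) for _ in range(nchan))
    header += b"".join(_pad("uV", 8) for _ in range(nchan))
    header += b"".join(_pad(f"{phys_min[i]:.6g}", 8) for i in range(nchan))
    header += b"".join(_pad(f"{phys_max[i]:.6g}", 8) for i in range(nchan))
    header += b"".join(_pad(dig_min, 8) for _ in range(nchan))
    header += b"".join(_pad(dig_max, 8) for _ in range(nchan))
    header += b"".join(_pad("", 80) for _ in range(nchan))
    header += b"".join(_pad(ns_per_record, 8) for _ in range(nchan))
    header += b"".join(_pad("", 32) for _ in range(nchan))

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    with path.open("wb") as fh:
        fh.write(header)
        for r in range(n_records):
            chunk = data[:, r * ns_per_record : (r + 1) * ns_per_record]
            dig = np.rint((chunk - phys_min[:, None]) * gain[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes(order="C"))
    return path


def save_ground_truth(rows: Sequence[dict], path) -> None:
    """Persist per-block ground-truth condition labels as JSON."""
    Path(path).write_text(json.dumps(list(rows), indent=1))
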