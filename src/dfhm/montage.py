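"""Electrode montage: 10-20 labels partitioned into frontal and parietal regions.

The workload index reads frontal electrodes in the theta band and parietal
electrodes in the alpha band, so every electrode must belong to exactly one
of the two regions.  The default 25-channel montage below is a reconstructed
10-20 layout for a Cz-referenced cap (Cz itself is the reference and carries
no signal); it is configurable — pass your own label/region mapping if your
cap differs.  The central row (T7/C3/C4/T8) is grouped with the parietal
region so that the frontal region is purely fronto-polar/frontal/fronto-central.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError

FRONTAL = "frontal"
PARIETAL = "parietal"

#: Reconstructed default 25-channel layout (configurable).
_DEFAULT_GROUPS: dict[str, str] = {
    # fronto-polar / frontal / fronto-central rows
    "Fp1": FRONTAL, "Fp2": FRONTAL,
    "F7": FRONTAL, "F3": FRONTAL, "Fz": FRONTAL, "F4": FRONTAL, "F8": FRONTAL,
    "FC5": FRONTAL, "FC1": FRONTAL, "FC2": FRONTAL, "FC6": FRONTAL,
    # central / centro-parietal / parietal / occipital rows
    "T7": PARIETAL, "C3": PARIETAL, "C4": PARIETAL, "T8": PARIETAL,
    "CP5": PARIETAL, "CP1": PARIETAL, "CP2": PARIETAL, "CP6": PARIETAL,
    "P7": PARIETAL, "P3": PARIETAL, "Pz": PARIETAL, "P4": PARIETAL, "P8": PARIETAL,
    "Oz": PARIETAL,
}


@dataclass(frozen=True)
class Montage:
    """An ordered electrode list with a frontal/parietal region for each label.

    Parameters
    ----------
    labels
        Electrode names in canonical order (the order of every downstream
        feature vector).
    groups
        Mapping from each label to ``"frontal"`` or ``"parietal"``.
    """

    labels: tuple[str, ...]
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValidationError("montage labels must be unique")
        missing = [l for l in labels if l not in self.groups]
        if missing:
            raise ValidationError(f"labels without a region assignment: {missing}")
        bad = {l: g for l, g in self.groups.items() if g not in (FRONTAL, PARIETAL)}
        if bad:
            raise ValidationError(f"regions must be 'frontal' or 'parietal', got {bad}")
        if not self.frontal or not self.parietal:
            raise ValidationError("both frontal and parietal regions must be non-empty")

    @property
    def frontal(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if self.groups[l] == FRONTAL)

    @property
    def parietal(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if self.groups[l] == PARIETAL)

    def regions(self) -> tuple[str, ...]:
        """Region of each electrode, in label order."""
        return tuple(self.groups[l] for l in self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_groups(cls, groups: Mapping[str, str], order: Iterable[str] | None = None) -> "Montage":
        labels = tuple(order) if order is not None else tuple(groups)
        return cls(labels=labels, groups=dict(groups))


def default_montage() -> Montage:
    """The reconstructed 25-channel 10-20 montage (11 frontal, 14 parietal)."""
    return Montage.from_groups(_DEFAULT_GROUPS)
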