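"""Shared domain types: recordings, windowed samples, labeled datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["STATES", "RawRecording", "Sample", "LabeledDataset"]

#: The two recording conditions used as class labels: undisturbed task
#: performance ("concentration") vs deliberately disturbed ("immersion").
STATES: tuple[str, str] = ("concentration", "immersion")


@dataclass
class RawRecording:
    """A continuous single-channel EEG signal with its sampling rate."""

    signal: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.signal.size / self.fs


@dataclass(eq=False)
class Sample:
    """One fixed-length window; the unit of classification.

    Compared by identity (the payload is an array).
    """

    values: np.ndarray
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in STATES:
            raise ValueError(f"unknown state label {self.label!r}")


@dataclass
class LabeledDataset:
    samples: list[Sample]
    fs: float

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STATES}
        for smp in self.samples:
            counts[smp.label] = counts.get(smp.label, 0) + 1
        return counts

    def by_class(self) -> dict[str, list[Sample]]:
        out: dict[str, list[Sample]] = {}
        for smp in self.samples:
            out.setdefault(smp.label, []).append(smp)
        return out
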