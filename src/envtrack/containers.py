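"""Lightweight in-memory containers shared by all pipeline stages.

EEG is held as a plain ``channels x samples`` float array in microvolts;
events live in a pandas DataFrame with a fixed schema (``onset_s``,
``sample``, ``type``, ``block``, ``condition``). Audio and envelopes are
thin sampled-signal wrappers. Nothing here owns file formats — see
:mod:`envtrack.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["onset_s", "sample", "type", "block", "condition"]
EVENT_TYPES = {"name", "control", "block_start"}
CONDITIONS = {"higher", "lower", "none"}


def make_event_table(
    onsets_s: Sequence[float],
    types: Sequence[str],
    fs: float,
    block: int | Sequence[int] = 1,
    condition: str | Sequence[str] = "none",
) -> pd.DataFrame:
    """Build a schema-conformant event table from onset times in seconds."""
    onsets = np.asarray(onsets_s, dtype=float)
    n = onsets.size
    blocks = np.full(n, block) if np.isscalar(block) else np.asarray(block)
    conds = np.full(n, condition, dtype=object) if isinstance(condition, str) else list(condition)
    table = pd.DataFrame(
        {
            "onset_s": onsets,
            "sample": np.round(onsets * fs).astype(int),
            "type": list(types),
            "block": blocks,
            "condition": conds,
        }
    )
    validate_event_table(table)
    return table


def validate_event_table(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    bad_types = set(events["type"]) - EVENT_TYPES
    if bad_types:
        raise ValueError(f"unknown event types: {sorted(bad_types)}")
    bad_conds = set(events["condition"]) - CONDITIONS
    if bad_conds:
        raise ValueError(f"unknown conditions: {sorted(bad_conds)}")


@dataclass
class AudioTrack:
    """Mono audio, full-scale normalized amplitude."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioTrack is mono: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioTrack contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class Envelope:
    """Non-negative speech envelope sampled at the EEG rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Envelope must be 1-D")
        if np.any(self.samples < -1e-12):
            raise ValueError("Envelope must be non-negative (half-wave rectified)")
        self.samples = np.maximum(self.samples, 0.0)

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class EegRecording:
    """Continuous multichannel EEG in microvolts with attached events."""

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    ch_names: list[str]
    reference: str = "nose"
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains NaN/Inf")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(self.events):
            validate_event_table(self.events)
            smp = self.events["sample"].to_numpy()
            if smp.min() < 0 or smp.max() >= self.n_samples:
                raise ValueError("event samples outside data range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EegRecording":
        out = replace(self, **kwargs)
        return out

    def pick(self, labels: Sequence[str]) -> "EegRecording":
        idx = [self.ch_names.index(l) for l in labels]
        return self.copy_with(data=self.data[idx], ch_names=list(labels))
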