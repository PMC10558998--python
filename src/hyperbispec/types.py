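"""Core domain containers for hyperscanning sessions.

Conventions
-----------
* Session clock: seconds from recording start, 0-based; all intervals are
  half-open ``[start, end)``.
* EEG data are microvolts, arrays of shape ``(n_channels, n_samples)``.
* EOG channels are identified by ``channel_kinds`` metadata, never by
  montage label (several 10-10 labels are physically repurposed as EOG).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import AlignmentError, MissingChannelError

EEG = "EEG"
EOG = "EOG"

PASSIVE_PASSIVE = "passive-passive"
PASSIVE_ACTIVE = "passive-active"
ACTIVE_ACTIVE = "active-active"


@dataclass
class MultichannelRecording:
    """One participant's time-aligned EEG+EOG block.

    Parameters
    ----------
    participant_id
        Label such as ``"P1"``.
    channel_labels
        Unique montage labels, one per data row.
    channel_kinds
        ``"EEG"`` or ``"EOG"`` per channel.
    fs
        Sampling rate in Hz.
    data
        ``(n_channels, n_samples)`` array in microvolts.
    start_time
        Seconds in the session clock of the first sample.
    meta
        Free-form metadata (reference channel, preprocessing history, ...).
    """

    participant_id: str
    channel_labels: list[str]
    channel_kinds: list[str]
    fs: float
    data: np.ndarray
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("channel labels must be unique")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.channel_kinds) != len(self.channel_labels):
            raise ValueError("channel_kinds length mismatch")
        bad = set(self.channel_kinds) - {EEG, EOG}
        if bad:
            raise ValueError(f"unknown channel kinds: {bad}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(label) from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == EEG], int)

    @property
    def eog_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == EOG], int)

    @property
    def eeg_labels(self) -> list[str]:
        return [self.channel_labels[i] for i in self.eeg_indices]

    def with_data(self, data: np.ndarray, note: str | None = None) -> "MultichannelRecording":
        """Return a copy carrying ``data``; appends ``note`` to the history log."""
        meta = dict(self.meta)
        if note:
            meta.setdefault("history", [])
            meta["history"] = list(meta["history"]) + [note]
        return replace(self, data=np.asarray(data, float), meta=meta,
                       channel_labels=list(self.channel_labels),
                       channel_kinds=list(self.channel_kinds))


@dataclass(frozen=True)
class SegmentDesign:
    """One (trial, segment) performance interval and its active musicians."""

    trial: int
    segment: int
    active_set: frozenset
    interval: tuple  # (start s, end s), half-open

    def condition(self, dyad: Sequence[str]) -> str:
        """Dyad condition: passive-passive / passive-active / active-active."""
        n = sum(p in self.active_set for p in dyad)
        return (PASSIVE_PASSIVE, PASSIVE_ACTIVE, ACTIVE_ACTIVE)[n]

    def contains(self, t: float) -> bool:
        return self.interval[0] <= t < self.interval[1]


@dataclass(frozen=True)
class BaselineBlock:
    """Resting baseline: eyes-open (EO) or eyes-closed (EC), pre or post."""

    phase: str  # "pre" | "post"
    kind: str   # "EO" | "EC"
    interval: tuple


@dataclass(frozen=True)
class EventAnnotation:
    """One annotated synchronized (SP) / desynchronized (DP) performance event."""

    event_type: str  # "SP" | "DP"
    time: float      # seconds, session clock
    label: str = ""

    def __post_init__(self):
        if self.event_type not in ("SP", "DP"):
            raise ValueError(f"event_type must be SP or DP, got {self.event_type!r}")


@dataclass
class HyperscanSession:
    """Co-registered recordings of all participants plus the session design."""

    recordings: list
    design: list
    baselines: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    masked: list = field(default_factory=list)  # invalid [start, end) spans
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        fss = {r.fs for r in self.recordings}
        if len(fss) > 1:
            raise AlignmentError(f"recordings disagree on fs: {sorted(fss)}")
        ns = {r.n_samples for r in self.recordings}
        if len(ns) > 1:
            raise AlignmentError("recordings have unequal durations")
        ivals = sorted(d.interval for d in self.design)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError("design segments overlap")

    @property
    def fs(self) -> float:
        return self.recordings[0].fs

    @property
    def duration(self) -> float:
        return self.recordings[0].duration

    @property
    def participants(self) -> list[str]:
        return [r.participant_id for r in self.recordings]

    def recording(self, participant_id: str) -> MultichannelRecording:
        for r in self.recordings:
            if r.participant_id == participant_id:
                return r
        raise MissingChannelError(participant_id)

    def dyads(self) -> list[tuple]:
        """Ordered participant pairs (a, b), a != b, in listed order."""
        ids = self.participants
        return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]

    def segment(self, trial: int, segment: int) -> SegmentDesign:
        for d in self.design:
            if d.trial == trial and d.segment == segment:
                return d
        raise KeyError((trial, segment))

    def segment_at(self, t: float) -> SegmentDesign | None:
        for d in self.design:
            if d.contains(t):
                return d
        return None

    def baseline(self, phase: str = "pre", kind: str = "EO") -> BaselineBlock:
        for b in self.baselines:
            if b.phase == phase and b.kind == kind:
                return b
        raise KeyError((phase, kind))
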