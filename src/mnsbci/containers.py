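"""In-memory containers shared by every pipeline stage.

The pipeline moves data through three array-backed containers:

``RawRecording``
    one continuous multichannel run (channels x samples, microvolts) plus an
    event stream (cue beeps, median-nerve stimulation pulses).
``EpochSet``
    trials x channels x samples, cut around an alignment event, carrying the
    condition label of every trial and the band-pass bookkeeping needed by the
    ERD/ERS stage.
``ERDSCurve`` / ``ERSPMap``
    derived time courses and time-frequency maps (see :mod:`mnsbci.erders`
    and :mod:`mnsbci.tfr`).

Everything is a plain dataclass over numpy arrays: the classification stage
consumes the bare ``.data`` arrays, so the containers stay deliberately thin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: The four experimental conditions.
RM = "RM"
MI = "MI"
MI_MNS = "MI+MNS"
MNS = "MNS"
CONDITIONS = (RM, MI, MI_MNS, MNS)

#: Conditions in which a median-nerve stimulation pulse is delivered.
MNS_CONDITIONS = (MI_MNS, MNS)

#: Event kinds carried by a recording.
BEEP1 = "beep1"   # go cue (low-frequency beep), t = 0 of a trial
BEEP2 = "beep2"   # end-of-task cue, 2 s after beep1
MNS_EVENT = "mns"  # stimulation pulse, 750 ms after beep1

EMG_LABEL = "EMG"


@dataclass(frozen=True)
class Event:
    """One marker in a continuous recording (time in seconds from run start)."""

    time: float
    kind: str
    trial: int
    condition: str


@dataclass
class RawRecording:
    """One continuous run: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    channels: list[str]
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        for ev in self.events:
            if not 0.0 <= ev.time < self.duration:
                raise ValueError(
                    f"event {ev.kind!r} at t={ev.time:.3f}s outside the "
                    f"recording (duration {self.duration:.3f}s)"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def eeg_picks(self) -> np.ndarray:
        """Indices of EEG channels (everything that is not the EMG lead)."""
        return np.array(
            [i for i, c in enumerate(self.channels) if c != EMG_LABEL], dtype=int
        )

    def events_of_kind(self, kind: str) -> list[Event]:
        return [ev for ev in self.events if ev.kind == kind]

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy(), events=list(self.events),
                       channels=list(self.channels), meta=dict(self.meta))


@dataclass
class EpochSet:
    """Trials x channels x samples, aligned to one event kind.

    ``tmin`` is the window start relative to the alignment event; sample ``i``
    sits at ``tmin + i / rate`` (half-open window ``[tmin, tmax)``).  ``band``
    is ``(low, high, order)`` once a band-pass has been applied, else None.
    """

    data: np.ndarray
    rate: float
    channels: list[str]
    labels: np.ndarray
    tmin: float = -2.0
    align: str = BEEP1
    band: Optional[tuple] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel labels do not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def tmax(self) -> float:
        return self.tmin + self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.rate

    @property
    def eeg_picks(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c != EMG_LABEL], dtype=int
        )

    def time_slice(self, start: float, stop: float) -> slice:
        """Sample slice for the half-open interval ``[start, stop)`` seconds."""
        i0 = int(round((start - self.tmin) * self.rate))
        i1 = int(round((stop - self.tmin) * self.rate))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(
                f"window [{start}, {stop}) s exceeds epoch support "
                f"[{self.tmin}, {self.tmax}) s"
            )
        return slice(i0, i1)

    def select(self, mask: Sequence[bool] | np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        return replace(self, data=self.data[mask], labels=self.labels[mask],
                       channels=list(self.channels), meta=dict(self.meta))

    def select_condition(self, condition: str) -> "EpochSet":
        return self.select(self.labels == condition)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), labels=self.labels.copy(),
                       channels=list(self.channels), meta=dict(self.meta))


def concat_epochs(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack epoch sets from several runs (axes must agree)."""
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if (s.rate != first.rate or s.channels != first.channels
                or s.tmin != first.tmin or s.n_samples != first.n_samples
                or s.band != first.band):
            raise ValueError("epoch sets have mismatched axes or band")
    return replace(
        first,
        data=np.concatenate([s.data for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets], axis=0),
        channels=list(first.channels),
        meta=dict(first.meta),
    )
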