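"""Referencing, resampling, epoching, filtering and trial rejection.

The default chain mirrors a standard sensorimotor-EEG workflow: common
average reference over the EEG leads (the EMG lead never enters the
average), polyphase resampling to 128 Hz, 9 s epochs spanning 2 s before to
7 s after the go cue, zero-phase Butterworth band-pass filtering, and a
two-criterion trial rejection (EMG bursts during the task window of
imagery-family trials; band-power outlier trajectories).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Union

import numpy as np
from scipy import signal

from .containers import (
    BEEP1,
    EMG_LABEL,
    MI,
    MI_MNS,
    RM,
    EpochSet,
    Event,
    RawRecording,
)

EPOCH_WINDOW = (-2.0, 7.0)  # seconds around the go cue
TARGET_RATE = 128.0


def _car_array(data: np.ndarray, eeg_picks: np.ndarray, axis_ch: int
               ) -> np.ndarray:
    out = np.array(data, copy=True)
    if axis_ch == 0:
        eeg = out[eeg_picks]
        out[eeg_picks] = eeg - eeg.mean(axis=0, keepdims=True)
    else:
        eeg = out[:, eeg_picks]
        out[:, eeg_picks] = eeg - eeg.mean(axis=1, keepdims=True)
    return out


def common_average_reference(obj: Union[RawRecording, EpochSet]
                             ) -> Union[RawRecording, EpochSet]:
    """Subtract the instantaneous mean over EEG channels (EMG untouched)."""
    picks = obj.eeg_picks
    if picks.size < 2:
        raise ValueError("common average reference needs >= 2 EEG channels")
    axis_ch = 0 if isinstance(obj, RawRecording) else 1
    data = _car_array(obj.data, picks, axis_ch)
    if isinstance(obj, RawRecording):
        return replace(obj, data=data, events=list(obj.events),
                       channels=list(obj.channels), meta=dict(obj.meta))
    return replace(obj, data=data, labels=obj.labels.copy(),
                   channels=list(obj.channels), meta=dict(obj.meta))


def resample_to(obj: Union[RawRecording, EpochSet], target_rate: float
                ) -> Union[RawRecording, EpochSet]:
    """Anti-aliased (polyphase) downsampling; duration is preserved."""
    if target_rate > obj.rate:
        raise ValueError(
            f"upsampling {obj.rate} -> {target_rate} Hz is not supported")
    if target_rate == obj.rate:
        return obj
    frac = Fraction(target_rate / obj.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(obj.data, up, down, axis=-1)
    if isinstance(obj, RawRecording):
        return replace(obj, data=data, rate=target_rate,
                       events=list(obj.events), channels=list(obj.channels),
                       meta=dict(obj.meta))
    return replace(obj, data=data, rate=target_rate, labels=obj.labels.copy(),
                   channels=list(obj.channels), meta=dict(obj.meta))


def epoch(recording: RawRecording, align: str = BEEP1,
          window: tuple[float, float] = EPOCH_WINDOW) -> EpochSet:
    """Cut one epoch per alignment event; time 0 sits at the event.

    The window is half-open ``[start, end)``: a 9 s window at 128 Hz yields
    exactly 1152 samples, and the sample at t = 0 equals the recording sample
    at the event time.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed its start")
    n_win = int(round((end - start) * recording.rate))
    trials, labels, kept_events = [], [], []
    for ev in recording.events_of_kind(align):
        i_ev = int(round(ev.time * recording.rate))
        i0 = i_ev + int(round(start * recording.rate))
        i1 = i0 + n_win
        if i0 < 0 or i1 > recording.n_samples:
            raise ValueError(
                f"trial {ev.trial} ({ev.condition}) at t={ev.time:.2f}s: "
                f"window [{start}, {end}) s exceeds the recording")
        trials.append(recording.data[:, i0:i1])
        labels.append(ev.condition)
        kept_events.append(ev)
    data = (np.stack(trials) if trials
            else np.empty((0, len(recording.channels), n_win)))
    return EpochSet(data=data, rate=recording.rate,
                    channels=list(recording.channels),
                    labels=np.array(labels, dtype=object), tmin=start,
                    align=align,
                    meta={"trial_ids": [ev.trial for ev in kept_events]})


def bandpass(epochs: EpochSet, band: tuple[float, float], order: int = 4
             ) -> EpochSet:
    """Zero-phase (forward-backward) Butterworth band-pass.

    Forward-backward application doubles the effective order and cancels
    phase, so ERD/ERS latencies are not shifted by the filter.
    """
    low, high = band
    nyq = epochs.rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=epochs.rate,
                        output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=data, band=(low, high, order),
                   labels=epochs.labels.copy(), channels=list(epochs.channels),
                   meta=dict(epochs.meta))


# ---------------------------------------------------------------------------
# trial rejection


@dataclass
class RejectionCriteria:
    """Thresholds for the two rejection rules.

    ``emg_ratio``: flag a trial when task-window EMG rms exceeds this multiple
    of its rest-window EMG rms (imagery-family conditions only — a real
    movement is supposed to produce EMG).  ``outlier_sd``: flag a trial whose
    smoothed band-power trajectory stays outside the across-trial mean +/-
    this many SDs for longer than ``outlier_min_duration`` seconds.
    """

    emg_ratio: float = 3.0
    emg_enabled: bool = True
    outlier_sd: float = 2.5
    outlier_enabled: bool = True
    outlier_min_duration: float = 1.0
    outlier_band: tuple[float, float] = (8.0, 30.0)
    task_window: tuple[float, float] = (0.0, 2.2)
    rest_window: tuple[float, float] = (-2.0, -0.2)


@dataclass
class RejectionReport:
    """Per-condition rejection bookkeeping."""

    total: dict[str, int]
    removed: dict[str, int]
    reasons: dict[int, str] = field(default_factory=dict)  # trial index -> reason

    @property
    def fractions(self) -> dict[str, float]:
        return {c: (self.removed[c] / self.total[c] if self.total[c] else 0.0)
                for c in self.total}


def _smoothed_power(x: np.ndarray, rate: float, win_s: float = 0.25
                    ) -> np.ndarray:
    """Boxcar-smoothed instantaneous power along the last axis."""
    from scipy.ndimage import uniform_filter1d

    n_win = max(1, int(round(win_s * rate)))
    return uniform_filter1d(x ** 2, size=n_win, axis=-1, mode="nearest")


def reject_trials(epochs: EpochSet,
                  criteria: Optional[RejectionCriteria] = None,
                  emg_channel: str = EMG_LABEL,
                  ) -> tuple[EpochSet, RejectionReport]:
    """Drop EMG-contaminated and band-power-outlier trials.

    Returns the surviving epochs (samples untouched) and a report with
    per-condition counts, fractions and per-trial reasons.
    """
    crit = criteria if criteria is not None else RejectionCriteria()
    labels = epochs.labels
    reasons: dict[int, str] = {}

    if crit.emg_enabled:
        if emg_channel not in epochs.channels:
            raise ValueError(
                f"EMG criterion enabled but channel {emg_channel!r} missing")
        emg_idx = epochs.channels.index(emg_channel)
        task = epochs.time_slice(*crit.task_window)
        rest = epochs.time_slice(*crit.rest_window)
        task_rms = np.sqrt((epochs.data[:, emg_idx, task] ** 2).mean(axis=-1))
        rest_rms = np.sqrt((epochs.data[:, emg_idx, rest] ** 2).mean(axis=-1))
        ratio = task_rms / np.maximum(rest_rms, 1e-30)
        for i in range(epochs.n_trials):
            if labels[i] in (MI, MI_MNS) and ratio[i] > crit.emg_ratio:
                reasons[i] = "EMG"

    if crit.outlier_enabled and epochs.n_trials >= 3:
        picks = epochs.eeg_picks
        if epochs.band is None:
            filt = bandpass(epochs, crit.outlier_band)
        else:
            filt = epochs
        # mean over EEG channels of the smoothed power trajectory
        power = _smoothed_power(filt.data[:, picks, :], epochs.rate)
        traj = power.mean(axis=1)  # trials x samples
        for cond in np.unique(labels):
            idx = np.flatnonzero(labels == cond)
            if idx.size < 3:
                continue
            grp = traj[idx]
            mean, sd = grp.mean(axis=0), grp.std(axis=0, ddof=1)
            outside = np.abs(grp - mean) > crit.outlier_sd * sd
            min_run = int(round(crit.outlier_min_duration * epochs.rate))
            for j, row in zip(idx, outside):
                if j in reasons:
                    continue
                if _longest_run(row) >= min_run:
                    reasons[j] = "outlier"

    keep = np.array([i not in reasons for i in range(epochs.n_trials)])
    conditions = [str(c) for c in np.unique(labels)]
    report = RejectionReport(
        total={c: int((labels == c).sum()) for c in conditions},
        removed={c: int(sum(1 for i, r in reasons.items() if labels[i] == c))
                 for c in conditions},
        reasons=reasons,
    )
    return epochs.select(keep), report


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def preprocess_runs(runs: list[RawRecording],
                    target_rate: float = TARGET_RATE,
                    window: tuple[float, float] = EPOCH_WINDOW,
                    criteria: Optional[RejectionCriteria] = None,
                    ) -> tuple[EpochSet, RejectionReport]:
    """Full default chain over a subject's runs: CAR -> resample -> epoch ->
    reject, concatenating epochs across runs."""
    from .containers import concat_epochs

    sets = []
    for rec in runs:
        rec = common_average_reference(rec)
        rec = resample_to(rec, target_rate)
        sets.append(epoch(rec, window=window))
    merged = concat_epochs(sets)
    return reject_trials(merged, criteria=criteria)
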