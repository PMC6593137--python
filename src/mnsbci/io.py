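"""Persistence: an internal compressed trial store, JSON configs, EDF import.

The trial store is a compressed ``.npz`` holding an :class:`EpochSet` or
:class:`RawRecording` with its metadata serialized as JSON.  Subject
parameters and schedules round-trip through plain JSON dictionaries so runs
can be reproduced from a config file alone.  EDF recordings are imported
through :func:`mne.io.read_raw_edf` (annotations become events); there is no
EDF writer here — exports use the trial store.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np

from .containers import EpochSet, Event, RawRecording
from .synth import ProtocolSchedule, SubjectParams, TrialSpec


def save_epochs(path: Union[str, Path], epochs: EpochSet) -> None:
    meta = {"tmin": epochs.tmin, "align": epochs.align, "band": epochs.band,
            "meta": _jsonable(epochs.meta)}
    np.savez_compressed(path, kind="epochs", data=epochs.data,
                        rate=epochs.rate,
                        channels=np.array(epochs.channels),
                        labels=epochs.labels.astype(str),
                        meta=json.dumps(meta))


def save_recording(path: Union[str, Path], rec: RawRecording) -> None:
    ev = np.array([(e.time, e.kind, e.trial, e.condition)
                   for e in rec.events], dtype=object)
    np.savez_compressed(path, kind="recording", data=rec.data, rate=rec.rate,
                        channels=np.array(rec.channels),
                        events=ev, meta=json.dumps(_jsonable(rec.meta)))


def load_store(path: Union[str, Path]) -> Union[EpochSet, RawRecording]:
    with np.load(path, allow_pickle=True) as z:
        kind = str(z["kind"])
        if kind == "epochs":
            meta = json.loads(str(z["meta"]))
            band = tuple(meta["band"]) if meta["band"] else None
            return EpochSet(data=z["data"], rate=float(z["rate"]),
                            channels=[str(c) for c in z["channels"]],
                            labels=z["labels"].astype(object),
                            tmin=meta["tmin"], align=meta["align"], band=band,
                            meta=meta.get("meta", {}))
        events = [Event(float(t), str(k), int(tr), str(c))
                  for t, k, tr, c in z["events"]]
        return RawRecording(data=z["data"], rate=float(z["rate"]),
                            channels=[str(c) for c in z["channels"]],
                            events=events,
                            meta=json.loads(str(z["meta"])))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# JSON config schema


def params_to_dict(params: SubjectParams) -> dict:
    d = dataclasses.asdict(params)
    d["montage"] = {k: list(v) for k, v in params.montage.items()}
    d["emg_contaminated_trials"] = list(params.emg_contaminated_trials)
    d["outlier_trials"] = list(params.outlier_trials)
    return d


def params_from_dict(d: dict) -> SubjectParams:
    d = dict(d)
    if "montage" in d:
        d["montage"] = {k: tuple(v) for k, v in d["montage"].items()}
    for key in ("emg_contaminated_trials", "outlier_trials"):
        if key in d:
            d[key] = tuple(d[key])
    return SubjectParams(**d)


def schedule_to_dict(schedule: ProtocolSchedule) -> dict:
    return {
        "seed": schedule.seed,
        "n_runs": schedule.n_runs,
        "trials": [dataclasses.asdict(t) for t in schedule.trials],
    }


def schedule_from_dict(d: dict) -> ProtocolSchedule:
    trials = [TrialSpec(**t) for t in d["trials"]]
    return ProtocolSchedule(trials=trials, n_runs=d["n_runs"], seed=d["seed"])


def save_params(path: Union[str, Path], params: SubjectParams) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=2))


def load_params(path: Union[str, Path]) -> SubjectParams:
    return params_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# EDF import


def read_edf(path: Union[str, Path], emg_channel: str | None = None
             ) -> RawRecording:
    """Import an EDF recording; annotations map to events.

    Annotation descriptions of the form ``"<kind>:<condition>:<trial>"``
    (e.g. ``"beep1:MI:12"``) populate the event stream; other annotations
    are skipped.  Requires ``mne``.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne uses volts; the pipeline uses uV
    channels = list(raw.ch_names)
    if emg_channel and emg_channel in channels:
        idx = channels.index(emg_channel)
        channels[idx] = "EMG"
    events = []
    for onset, desc in zip(raw.annotations.onset,
                           raw.annotations.description):
        parts = str(desc).split(":")
        if len(parts) == 3:
            kind, condition, trial = parts
            events.append(Event(float(onset), kind, int(trial), condition))
    return RawRecording(data=data, rate=float(raw.info["sfreq"]),
                        channels=channels, events=events,
                        meta={"source": str(path)})
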