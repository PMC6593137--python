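"""Shared fixtures: small synthetic subjects and hand-built epoch sets."""

from __future__ import annotations

import numpy as np
import pytest

import mnsbci as m
from mnsbci import preprocess as pp
from mnsbci.containers import EpochSet, concat_epochs


def make_epochs(data: np.ndarray, rate: float = 128.0, tmin: float = -2.0,
                channels=None, labels=None, band=None) -> EpochSet:
    """Wrap a (trials, channels, samples) array in an EpochSet."""
    n, c, _ = data.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(c)]
    if labels is None:
        labels = np.array(["MI"] * n, dtype=object)
    return EpochSet(data=data, rate=rate, channels=list(channels),
                    labels=np.asarray(labels, dtype=object), tmin=tmin,
                    band=band)


def preprocess_subject(runs, window=(-2.0, 7.0)):
    runs = [pp.resample_to(pp.common_average_reference(r), 128.0)
            for r in runs]
    return concat_epochs([pp.epoch(r, window=window) for r in runs])


@pytest.fixture(scope="session")
def mi_subject():
    """One subject's 52 motor-imagery trials, preprocessed to 128 Hz epochs."""
    params = m.SubjectParams(seed=5)
    _, runs = m.simulate_subject(params, n_trials_per_condition=52,
                                 rate=512.0, conditions=("MI",))
    return params, preprocess_subject(runs)


@pytest.fixture(scope="session")
def full_subject():
    """A full four-condition subject, epoched [-3, 7] s for classification."""
    params = m.SubjectParams(seed=21)
    _, runs = m.simulate_subject(params, n_trials_per_condition=52,
                                 rate=512.0)
    epochs = preprocess_subject(runs, window=(-3.0, 7.0))
    epochs, _ = pp.reject_trials(epochs)
    return params, pp.bandpass(epochs, (8.0, 30.0), order=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
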