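"""Event-related (de)synchronization as a percentage of baseline band power.

The band-power method: band-pass the epochs, square every sample, average
across trials, smooth with a 250 ms sliding window advancing in 100 ms
steps, and express each value relative to the mean power of a 1.5 s baseline
segment starting 2 s before the cue,

    ERD/ERS% = (P(t) - P_baseline) / P_baseline * 100 .

Negative values are desynchronizations (ERD), positive values
synchronizations (ERS).  Because power is non-negative the curve is bounded
below by -100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import EpochSet

BASELINE_WINDOW = (-2.0, -0.5)
SMOOTH_WINDOW = 0.25   # seconds
SMOOTH_STEP = 0.1      # seconds


@dataclass
class ERDSCurve:
    """Time-resolved ERD/ERS% per channel.

    ``values`` is channels x times and always equals
    ``(x2_mean - bl_mean) / bl_mean * 100`` exactly; ``x2_mean`` is the
    smoothed trial-averaged squared signal (uV^2) and ``bl_mean`` the baseline
    power per channel.
    """

    times: np.ndarray
    values: np.ndarray
    channels: list[str]
    band: Optional[tuple]
    x2_mean: np.ndarray
    bl_mean: np.ndarray
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    n_trials: int = 0

    def __post_init__(self) -> None:
        if np.any(self.bl_mean <= 0):
            raise ValueError("baseline power must be strictly positive")
        if self.values.shape != (len(self.channels), self.times.size):
            raise ValueError("values must be channels x times")

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channels.index(name)]


def _window_means(avg: np.ndarray, times: np.ndarray, centers: np.ndarray,
                  half: float) -> np.ndarray:
    """Mean of ``avg`` (ch x samples) in centred windows (edges truncated)."""
    out = np.empty((avg.shape[0], centers.size))
    for k, c in enumerate(centers):
        lo = np.searchsorted(times, c - half - 1e-12)
        hi = np.searchsorted(times, c + half + 1e-12, side="right")
        out[:, k] = avg[:, lo:hi].mean(axis=-1)
    return out


def erd_ers_curve(epochs: EpochSet,
                  band: Optional[tuple[float, float]] = None,
                  baseline_window: tuple[float, float] = BASELINE_WINDOW,
                  smooth_window: float = SMOOTH_WINDOW,
                  step: float = SMOOTH_STEP,
                  average: str = "power") -> ERDSCurve:
    """Compute the ERD/ERS% curve for every channel.

    If ``band`` is given and the epochs are not yet band-passed, a 4th-order
    zero-phase Butterworth filter is applied first.  ``average`` selects the
    estimator: ``"power"`` squares, averages across trials, then smooths and
    normalizes by the trial-averaged baseline power (the band-power method);
    ``"percentage"`` normalizes every trial by its own baseline before
    averaging, which weights trials equally regardless of amplitude.
    """
    if epochs.n_trials == 0:
        raise ValueError("no trials to average")
    if average not in ("power", "percentage"):
        raise ValueError("average must be 'power' or 'percentage'")
    if band is not None and epochs.band is None:
        from .preprocess import bandpass

        epochs = bandpass(epochs, band, order=4)
    b0, b1 = baseline_window
    if b0 < epochs.tmin or b1 > epochs.tmax:
        raise ValueError(
            f"baseline [{b0}, {b1}) s outside epoch support "
            f"[{epochs.tmin}, {epochs.tmax}) s")
    times = epochs.times
    half = smooth_window / 2.0
    n_centers = int(np.floor((epochs.tmax - epochs.tmin) / step)) + 1
    centers = epochs.tmin + step * np.arange(n_centers)
    centers = centers[centers < epochs.tmax - 1e-12]
    bl_slice = epochs.time_slice(b0, b1)

    sq = epochs.data ** 2
    if average == "power":
        avg = sq.mean(axis=0)                      # channels x samples
        x2 = _window_means(avg, times, centers, half)
        bl = avg[:, bl_slice].mean(axis=-1)
    else:
        bl_trial = sq[:, :, bl_slice].mean(axis=-1)  # trials x channels
        if np.any(bl_trial <= 0):
            raise ValueError("a trial has zero baseline power")
        norm = sq / bl_trial[:, :, None]
        avg = norm.mean(axis=0)
        x2 = _window_means(avg, times, centers, half)
        bl = avg[:, bl_slice].mean(axis=-1)
    if np.any(bl <= 0):
        raise ValueError("baseline power is zero on some channel")
    values = (x2 - bl[:, None]) / bl[:, None] * 100.0
    band_meta = epochs.band[:2] if epochs.band else None
    return ERDSCurve(times=centers, values=values,
                     channels=list(epochs.channels), band=band_meta,
                     x2_mean=x2, bl_mean=bl, baseline_window=baseline_window,
                     n_trials=epochs.n_trials)


def grand_average(curves: Sequence[ERDSCurve]) -> ERDSCurve:
    """Pointwise mean of per-subject curves (axes must agree exactly).

    The averaged curve stores baseline-normalized power (``bl_mean`` = 1), so
    its values remain an exact transform of its stored power.
    """
    if not curves:
        raise ValueError("no curves to average")
    first = curves[0]
    for c in curves[1:]:
        if (c.channels != first.channels or c.band != first.band
                or c.times.shape != first.times.shape
                or not np.allclose(c.times, first.times)):
            raise ValueError("curves have mismatched axes")
    norm = np.mean([c.x2_mean / c.bl_mean[:, None] for c in curves], axis=0)
    bl = np.ones(len(first.channels))
    return ERDSCurve(times=first.times.copy(),
                     values=(norm - 1.0) * 100.0,
                     channels=list(first.channels), band=first.band,
                     x2_mean=norm, bl_mean=bl,
                     baseline_window=first.baseline_window,
                     n_trials=sum(c.n_trials for c in curves))


def to_frame(curve: ERDSCurve):
    """Tidy export: one row per (time, channel) with the band attached."""
    import pandas as pd

    band = f"{curve.band[0]:g}-{curve.band[1]:g}" if curve.band else "broad"
    rows = [
        {"time": float(t), "channel": ch, "band": band,
         "erd_ers_pct": float(curve.values[i, k])}
        for i, ch in enumerate(curve.channels)
        for k, t in enumerate(curve.times)
    ]
    return pd.DataFrame(rows)


def plot_curves(curves: dict[str, ERDSCurve], channel: str = "C3", ax=None):
    """Overlay per-condition ERD/ERS% curves for one channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(curve.times, curve.channel(channel), label=label)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ERD/ERS (%)")
    ax.set_title(channel)
    ax.legend()
    return ax
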