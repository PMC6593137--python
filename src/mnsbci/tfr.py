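"""Event-related spectral perturbation (ERSP) maps and significance testing.

The ERSP is the trial-averaged short-time power spectrum expressed in dB
relative to the mean pre-event baseline spectrum:
``10 * log10(P(f, t) / P_baseline(f))``.  The default analysis uses a
256-sample Hann window zero-padded 4x (frequency bin spacing
``rate / (nfft * padratio)``), a hop of a quarter window, and the 8-35 Hz
analysis range.  Condition differences are assessed with a surrogate
permutation test (label exchange between the two trial pools, two-tailed,
with the (r+1)/(n+1) small-sample correction) and, across channels, a
Benjamini-Hochberg false-discovery-rate correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import signal

from .containers import EpochSet

FREQ_RANGE = (8.0, 35.0)
BASELINE_WINDOW = (-2.0, -0.5)


@dataclass
class ERSPMap:
    """Baseline-normalized spectral perturbation, channels x freqs x times (dB)."""

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray
    channels: list[str]
    baseline_window: tuple[float, float]
    n_trials: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ERSP values must be finite")

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channels.index(name)]


@dataclass
class SignificanceMask:
    """Boolean significance decisions with their p-values."""

    mask: np.ndarray
    pvalues: np.ndarray
    alpha: float
    n_permutations: int = 0
    corrected: bool = False

    @property
    def min_attainable_p(self) -> float:
        return (1.0 / (self.n_permutations + 1.0)
                if self.n_permutations else 0.0)


def _spectrograms(epochs: EpochSet, nfft: int, padratio: int,
                  fmin: float, fmax: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial sliding-FFT power: (trials, channels, freqs, frames)."""
    if nfft > epochs.n_samples:
        raise ValueError(
            f"FFT window ({nfft}) exceeds epoch length ({epochs.n_samples})")
    hop = nfft // 4
    freqs, t, pxx = signal.spectrogram(
        epochs.data, fs=epochs.rate, window="hann", nperseg=nfft,
        noverlap=nfft - hop, nfft=nfft * padratio, axis=-1, mode="psd")
    sel = (freqs >= fmin) & (freqs <= fmax)
    return freqs[sel], epochs.tmin + t, pxx[:, :, sel, :]


def _baseline_frames(times: np.ndarray, window: tuple[float, float]
                     ) -> np.ndarray:
    lo, hi = window
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        # fall back to the earliest frame if no centre lands in the window
        sel = times == times.min()
    return sel


def ersp(epochs: EpochSet, nfft: int = 256, padratio: int = 4,
         baseline_window: tuple[float, float] = BASELINE_WINDOW,
         fmin: float = FREQ_RANGE[0], fmax: float = FREQ_RANGE[1]) -> ERSPMap:
    """Trial-averaged ERSP in dB relative to the mean baseline spectrum."""
    if epochs.n_trials == 0:
        raise ValueError("no trials")
    freqs, times, pxx = _spectrograms(epochs, nfft, padratio, fmin, fmax)
    avg = pxx.mean(axis=0)                       # channels x freqs x frames
    bl_sel = _baseline_frames(times, baseline_window)
    bl = avg[:, :, bl_sel].mean(axis=-1)         # channels x freqs
    if np.any(bl <= 0):
        raise ValueError("baseline power is zero at some frequency")
    values = 10.0 * np.log10(avg / bl[:, :, None])
    return ERSPMap(freqs=freqs, times=times, values=values,
                   channels=list(epochs.channels),
                   baseline_window=baseline_window, n_trials=epochs.n_trials)


def trial_ersp_features(epochs: EpochSet, nfft: int = 256, padratio: int = 4,
                        baseline_window: tuple[float, float] = BASELINE_WINDOW,
                        fmin: float = FREQ_RANGE[0],
                        fmax: float = FREQ_RANGE[1]) -> np.ndarray:
    """Per-trial log-power maps normalized by each trial's own baseline.

    Returns (trials, channels, freqs, frames) dB values — the exchangeable
    per-trial quantities fed to :func:`permutation_test`.
    """
    _, times, pxx = _spectrograms(epochs, nfft, padratio, fmin, fmax)
    bl_sel = _baseline_frames(times, baseline_window)
    bl = pxx[:, :, :, bl_sel].mean(axis=-1)
    bl = np.maximum(bl, np.finfo(float).tiny)
    return 10.0 * np.log10(np.maximum(pxx, np.finfo(float).tiny)
                           / bl[:, :, :, None])


def permutation_test(a: Union[EpochSet, np.ndarray],
                     b: Union[EpochSet, np.ndarray],
                     statistic: Optional[Callable] = None,
                     n_perm: int = 2000, alpha: float = 0.05,
                     paired: bool = False, seed: int = 0,
                     **feature_kw) -> SignificanceMask:
    """Surrogate permutation test between two trial pools.

    ``a`` and ``b`` are per-trial feature arrays (first axis = trials) or
    :class:`EpochSet` objects (converted with
    :func:`trial_ersp_features`).  The default statistic is the pointwise
    difference of the two trial means.  The null is built by shuffling
    condition labels across the pooled trials (or sign-flipping paired
    differences when ``paired=True``); two-tailed p-values use the
    ``(r + 1) / (n_perm + 1)`` convention, so the smallest attainable p is
    ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(a, EpochSet):
        a = trial_ersp_features(a, **feature_kw)
    if isinstance(b, EpochSet):
        b = trial_ersp_features(b, **feature_kw)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("trial pools must share feature axes")
    if statistic is None:
        statistic = lambda x, y: x.mean(axis=0) - y.mean(axis=0)  # noqa: E731
    rng = np.random.default_rng(seed)
    observed = statistic(a, b)
    exceed = np.zeros_like(observed, dtype=int)
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test needs equal trial counts")
        for _ in range(n_perm):
            flip = rng.random(a.shape[0]) < 0.5
            pa, pb = a.copy(), b.copy()
            pa[flip], pb[flip] = b[flip], a[flip]
            exceed += np.abs(statistic(pa, pb)) >= np.abs(observed)
    else:
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        for _ in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            exceed += np.abs(
                statistic(pooled[perm[:na]], pooled[perm[na:]])
            ) >= np.abs(observed)
    pvalues = (exceed + 1.0) / (n_perm + 1.0)
    return SignificanceMask(mask=pvalues <= alpha, pvalues=pvalues,
                            alpha=alpha, n_permutations=n_perm)


def fdr_correct(pvalues: np.ndarray, q: float = 0.05) -> SignificanceMask:
    """Benjamini-Hochberg step-up over the supplied p-value family."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return SignificanceMask(mask=reject.reshape(p.shape),
                            pvalues=p_adj.reshape(p.shape), alpha=q,
                            corrected=True)


# ---------------------------------------------------------------------------
# band topographies


def band_topography(epochs: EpochSet, band: tuple[float, float] = (8.0, 30.0),
                    frame_times: Sequence[float] = (),
                    nfft: int = 256, padratio: int = 4,
                    baseline_window: tuple[float, float] = BASELINE_WINDOW,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged ERSP per channel at the requested frame times.

    Returns ``(values, times)`` with ``values`` of shape
    (channels, len(frame_times)); each requested time maps to the nearest
    computed frame centre.
    """
    if len(frame_times) == 0:
        raise ValueError("frame_times must not be empty")
    emap = ersp(epochs, nfft=nfft, padratio=padratio,
                baseline_window=baseline_window,
                fmin=min(band[0], FREQ_RANGE[0]), fmax=FREQ_RANGE[1])
    fsel = (emap.freqs >= band[0]) & (emap.freqs <= band[1])
    band_vals = emap.values[:, fsel, :].mean(axis=1)   # channels x frames
    idx = [int(np.argmin(np.abs(emap.times - t))) for t in frame_times]
    return band_vals[:, idx], emap.times[idx]


def compare_topographies(epochs_a: EpochSet, epochs_b: EpochSet,
                         band: tuple[float, float] = (8.0, 30.0),
                         frame_times: Sequence[float] = (),
                         n_perm: int = 2000, alpha: float = 0.05, q: float = 0.05,
                         seed: int = 0, nfft: int = 256, padratio: int = 4,
                         baseline_window: tuple[float, float] = BASELINE_WINDOW,
                         ) -> dict:
    """Per-channel band topography difference with permutation + FDR masks.

    The FDR family is all channels within each time frame.
    """
    if len(frame_times) == 0:
        raise ValueError("frame_times must not be empty")

    def trial_band_values(ep: EpochSet) -> np.ndarray:
        feats = trial_ersp_features(ep, nfft=nfft, padratio=padratio,
                                    baseline_window=baseline_window,
                                    fmin=min(band[0], FREQ_RANGE[0]),
                                    fmax=FREQ_RANGE[1])
        _, times, _ = _spectrograms(ep, nfft, padratio, band[0], band[1])
        freqs, _, _ = _spectrograms(ep, nfft, padratio,
                                    min(band[0], FREQ_RANGE[0]),
                                    FREQ_RANGE[1])
        fsel = (freqs >= band[0]) & (freqs <= band[1])
        vals = feats[:, :, fsel, :].mean(axis=2)  # trials x channels x frames
        idx = [int(np.argmin(np.abs(times - t))) for t in frame_times]
        return vals[:, :, idx]

    xa, xb = trial_band_values(epochs_a), trial_band_values(epochs_b)
    perm = permutation_test(xa, xb, n_perm=n_perm, alpha=alpha, seed=seed)
    masks, p_adj = [], []
    for k in range(len(frame_times)):
        fdr = fdr_correct(perm.pvalues[:, k], q=q)
        masks.append(fdr.mask)
        p_adj.append(fdr.pvalues)
    values_a, times = band_topography(epochs_a, band, frame_times, nfft,
                                      padratio, baseline_window)
    values_b, _ = band_topography(epochs_b, band, frame_times, nfft,
                                  padratio, baseline_window)
    return {
        "times": times,
        "values_a": values_a,
        "values_b": values_b,
        "difference": xa.mean(axis=0) - xb.mean(axis=0),
        "pvalues": perm.pvalues,
        "mask_uncorrected": perm.mask,
        "mask_fdr": np.stack(masks, axis=1),
        "pvalues_fdr": np.stack(p_adj, axis=1),
    }
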