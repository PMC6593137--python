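"""Seeded synthetic sensorimotor EEG/EMG cohorts.

The generator emulates a four-condition cued motor protocol — real movement
(RM), kinesthetic motor imagery (MI), motor imagery with a median-nerve
stimulation delivered 750 ms after the go cue (MI+MNS), and stimulation at
rest (MNS) — with 52 trials per condition split into per-condition runs of at
most 26 trials, trial lengths jittered uniformly in [7, 9] s, a 2 s motor
task bounded by two beeps, and a ~6 s rest tail.

The signal model is deliberately phenomenological: two band-limited
stochastic sources (mu 7-13 Hz, beta 15-30 Hz) are placed over a C3-centred
left sensorimotor patch (with a weaker C4 mirror that carries only the
stimulation-locked responses), amplitude-modulated by condition-specific
power envelopes, spatially mixed into a 16-channel motor-centred montage,
and buried in broadband noise.  The envelopes encode the effect structure of
interest:

* MI: sustained event-related desynchronization (ERD) from 0.3 to 3.2 s;
* RM: ERD interrupted by a mid-task synchronization, then a post-movement
  beta rebound;
* MNS at rest: an early post-stimulation rebound (PSR, 0-250 ms after the
  pulse), a stimulation ERD (250-750 ms), then a beta rebound;
* MI+MNS: the MI ERD with the PSR almost abolished, the stimulation ERD
  unchanged, the beta rebound attenuated, and a stronger post-task rebound
  peaking near 4.5 s.

Power gains are applied as amplitude x sqrt(gain), so a band-power ERD/ERS
analysis recovers the configured percentages in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .containers import (
    BEEP1,
    BEEP2,
    CONDITIONS,
    EMG_LABEL,
    MI,
    MI_MNS,
    MNS,
    MNS_CONDITIONS,
    MNS_EVENT,
    RM,
    Event,
    RawRecording,
)

MU_BAND = (7.0, 13.0)
BETA_BAND = (15.0, 30.0)
BANDS = {"mu": MU_BAND, "beta": BETA_BAND}

#: Protocol timings (seconds, relative to the go beep).
TASK_DURATION = 2.0          # beep1 -> beep2
MNS_DELAY = 0.75             # beep1 -> stimulation pulse
PSR_DURATION = 0.25          # post-stimulation rebound extent
TRIAL_LENGTH_RANGE = (7.0, 9.0)
RUN_SIZE = 26
RUN_LEAD_IN = 15.0           # relaxed period at the start of each run
RUN_TAIL = 9.0               # padding so the last epoch window fits

#: Default montage: a motor-centred 16-channel EEG subset plus one EMG lead.
#: Positions are schematic head coordinates (x: left negative, y: anterior
#: positive) used only to shape the spatial gain maps.
DEFAULT_MONTAGE: dict[str, tuple[float, float]] = {
    "FC5": (-0.75, 0.3), "FC3": (-0.45, 0.3), "FC1": (-0.15, 0.3),
    "FCz": (0.0, 0.3), "FC2": (0.15, 0.3), "FC4": (0.45, 0.3),
    "FC6": (0.75, 0.3),
    "C5": (-0.75, 0.0), "C3": (-0.45, 0.0), "C1": (-0.15, 0.0),
    "Cz": (0.0, 0.0), "C2": (0.15, 0.0), "C4": (0.45, 0.0),
    "C6": (0.75, 0.0),
    "CP3": (-0.45, -0.3), "CP4": (0.45, -0.3),
}


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial; ``onset`` is seconds from the start of its run."""

    condition: str
    onset: float
    length: float
    run: int
    trial: int

    @property
    def beep1_offset(self) -> float:
        return 0.0

    @property
    def beep2_offset(self) -> Optional[float]:
        return TASK_DURATION if self.condition != MNS else None

    @property
    def mns_offset(self) -> Optional[float]:
        return MNS_DELAY if self.condition in MNS_CONDITIONS else None


@dataclass
class ProtocolSchedule:
    """Trials grouped into per-condition runs, in randomized run order."""

    trials: list[TrialSpec]
    n_runs: int
    seed: int

    def run_trials(self, run: int) -> list[TrialSpec]:
        return [t for t in self.trials if t.run == run]

    def run_duration(self, run: int) -> float:
        trials = self.run_trials(run)
        if not trials:
            return RUN_LEAD_IN + RUN_TAIL
        last = max(trials, key=lambda t: t.onset)
        return last.onset + last.length + RUN_TAIL

    def count(self, condition: str) -> int:
        return sum(t.condition == condition for t in self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class SubjectParams:
    """Effect sizes, source amplitudes and montage for one simulated subject.

    Depths and gains are percentages of baseline band power (an ERD depth of
    -15 means task power is 85% of baseline power); amplitudes are microvolt
    rms values of the band-limited sources at their peak channel.
    """

    mu_erd_depth: float = -15.0        # sustained MI/RM ERD, mu band (%)
    beta_erd_depth: float = -15.0      # sustained MI/RM ERD, beta band (%)
    psr_gain: float = 50.0             # PSR power increase 0-250 ms post-MNS (%)
    psr_abolition: float = 0.9         # fraction of the PSR removed under MI
    rebound_gain: float = 30.0         # post-stimulation / post-movement beta rebound (%)
    rebound_attenuation: float = 0.5   # fraction of the MNS beta rebound lost under MI
    post_task_rebound: float = 33.0    # beta rebound near 4.5 s in MI+MNS (%)
    rm_ers_gain: float = 10.0          # mid-task beta ERS interrupting the RM ERD (%)
    ramp: float = 0.15                 # raised-cosine envelope transition (s)
    mu_amp: float = 6.0                # mu source rms at the peak channel (uV)
    beta_amp: float = 4.0              # beta source rms at the peak channel (uV)
    noise_floor: float = 3.0           # broadband noise rms per channel (uV)
    ipsi_gain: float = 0.5             # amplitude of the C4 mirror source
    spatial_sigma: float = 0.35        # width of the Gaussian gain bumps
    emg_rest_amp: float = 0.5          # EMG lead noise at rest (uV)
    emg_task_amp: float = 20.0         # EMG burst amplitude during RM / artifacts (uV)
    montage: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MONTAGE))
    stim_artifact: bool = False        # 1-sample spike at the MNS pulse
    stim_artifact_amp: float = 50.0
    emg_contaminated_trials: tuple[int, ...] = ()  # trial ids given EMG bursts
    outlier_trials: tuple[int, ...] = ()           # trial ids with 5x EEG power
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_erd_depth", "beta_erd_depth"):
            if getattr(self, name) <= -100:
                raise ValueError(f"{name} must be > -100 (power is non-negative)")
        for name in ("psr_gain", "rebound_gain", "post_task_rebound",
                     "rm_ers_gain"):
            if not -100 < getattr(self, name) <= 500:
                raise ValueError(f"{name} out of range (-100, 500]")
        for name in ("psr_abolition", "rebound_attenuation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("mu_amp", "beta_amp", "noise_floor", "ipsi_gain",
                     "emg_rest_amp", "emg_task_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def channels(self) -> list[str]:
        return list(self.montage) + [EMG_LABEL]

    def erd_depth(self, band: str) -> float:
        return self.mu_erd_depth if band == "mu" else self.beta_erd_depth

    def spatial_map(self, center: str = "C3") -> np.ndarray:
        """Non-negative per-channel gains: Gaussian bump around ``center``."""
        cx, cy = self.montage[center]
        gains = np.array(
            [np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                    / (2 * self.spatial_sigma ** 2))
             for x, y in self.montage.values()]
        )
        return np.append(gains, 0.0)  # EMG lead carries no cortical signal

    def replace(self, **kw) -> "SubjectParams":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# protocol


def build_protocol(n_trials_per_condition: int, seed: int,
                   conditions: Sequence[str] = CONDITIONS,
                   run_size: int = RUN_SIZE) -> ProtocolSchedule:
    """Schedule ``n`` trials per condition into randomized per-condition runs.

    Trial lengths are drawn uniformly from [7, 9] s; each trial holds a 2 s
    motor task (or a bare stimulation for the MNS condition) followed by a
    rest tail.  Runs hold at most ``run_size`` trials of a single condition
    and their order is shuffled.
    """
    if n_trials_per_condition < 0:
        raise ValueError("n_trials_per_condition must be >= 0")
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}")
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, int]] = []   # (condition, n_trials_in_run)
    for cond in conditions:
        left = n_trials_per_condition
        while left > 0:
            take = min(run_size, left)
            blocks.append((cond, take))
            left -= take
    order = rng.permutation(len(blocks))
    trials: list[TrialSpec] = []
    trial_id = 0
    for run_idx, block_idx in enumerate(order):
        cond, n_in_run = blocks[block_idx]
        lengths = rng.uniform(*TRIAL_LENGTH_RANGE, size=n_in_run)
        onset = RUN_LEAD_IN
        for length in lengths:
            trials.append(TrialSpec(condition=cond, onset=onset,
                                    length=float(length), run=run_idx,
                                    trial=trial_id))
            onset += float(length)
            trial_id += 1
    return ProtocolSchedule(trials=trials, n_runs=len(blocks), seed=seed)


# ---------------------------------------------------------------------------
# envelopes


def _edge(t: np.ndarray, t0: float, ramp: float) -> np.ndarray:
    """Raised-cosine step 0 -> 1 over [t0, t0 + ramp]."""
    if ramp <= 0:
        return (t >= t0).astype(float)
    x = np.clip((t - t0) / ramp, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))

def _bump(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """Plateau of height 1 on [start, end] with raised-cosine flanks inside."""
    r = min(ramp, (end - start) / 2.0)
    return _edge(t, start, r) - _edge(t, end - r, r)


def _mi_gain(t: np.ndarray, band: str, p: SubjectParams) -> np.ndarray:
    """Sustained motor-imagery ERD from 0.3 s to 3.2 s."""
    return 1.0 + (p.erd_depth(band) / 100.0) * _bump(t, 0.3, 3.2, p.ramp)


def _rm_gain(t: np.ndarray, band: str, p: SubjectParams) -> np.ndarray:
    """Real movement: ERD - mid-task ERS - ERD, then a post-movement rebound."""
    d = p.erd_depth(band) / 100.0
    if band == "beta":
        g = (d * _bump(t, 0.3, 1.3, p.ramp)
             + (p.rm_ers_gain / 100.0) * _bump(t, 1.3, 2.0, p.ramp)
             + d * _bump(t, 2.0, 2.75, p.ramp)
             + (p.rebound_gain / 100.0) * _bump(t, 2.75, 4.0, p.ramp))
    else:
        g = (d * _bump(t, 0.3, 2.75, p.ramp)
             + 0.5 * (p.rebound_gain / 100.0) * _bump(t, 3.0, 4.25, p.ramp))
    return 1.0 + g


def _mns_gain(t: np.ndarray, band: str, p: SubjectParams,
              psr_scale: float = 1.0, rebound_scale: float = 1.0) -> np.ndarray:
    """Stimulation-locked responses: PSR, stimulation ERD, beta rebound."""
    s = MNS_DELAY
    ramp = min(p.ramp, 0.08)  # stimulation responses are fast transients
    d = p.erd_depth(band) / 100.0
    g = ((p.psr_gain / 100.0) * psr_scale * _bump(t, s, s + PSR_DURATION, ramp)
         + d * _bump(t, s + 0.25, s + 0.75, ramp))
    reb = (p.rebound_gain / 100.0) * rebound_scale
    if band == "mu":
        reb *= 0.5  # rebound is predominantly a beta phenomenon
    g = g + reb * _bump(t, s + 0.75, s + 2.25, p.ramp)
    return 1.0 + g


def modulation_envelope(condition: str, band: str, t, params: SubjectParams
                        ) -> np.ndarray | float:
    """Power gain (1 = baseline) at time ``t`` (s, relative to the go beep).

    Gains combine multiplicatively where effects overlap: the MI+MNS envelope
    is the MI ERD times the stimulation response with the PSR scaled by
    ``(1 - psr_abolition)`` and the beta rebound by
    ``(1 - rebound_attenuation)``, times a post-task rebound peaking near
    4.5 s.  With abolition and attenuation at zero the stimulation component
    reduces exactly to the MNS-only one.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r} (expected 'mu' or 'beta')")
    t_arr = np.asarray(t, dtype=float)
    p = params
    if condition == MI:
        g = _mi_gain(t_arr, band, p)
        if band == "beta":
            g = g * (1.0 + 0.6 * (p.post_task_rebound / 100.0)
                     * _bump(t_arr, 4.0, 5.0, p.ramp))
    elif condition == RM:
        g = _rm_gain(t_arr, band, p)
    elif condition == MNS:
        g = _mns_gain(t_arr, band, p)
    else:  # MI + MNS
        g = (_mi_gain(t_arr, band, p)
             * _mns_gain(t_arr, band, p, psr_scale=1.0 - p.psr_abolition,
                         rebound_scale=1.0 - p.rebound_attenuation))
        post = (p.post_task_rebound / 100.0) * (1.0 if band == "beta" else 0.3)
        g = g * (1.0 + post * _bump(t_arr, 4.0, 5.0, p.ramp))
    return g if np.ndim(t) else float(g)


# ---------------------------------------------------------------------------
# signal synthesis


def _band_source(rng: np.random.Generator, n: int, band: tuple[float, float],
                 rate: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _trial_envelope(times: np.ndarray, trials: list[TrialSpec], band: str,
                    params: SubjectParams, stim_only: bool) -> np.ndarray:
    """Per-sample power gain over a run; 1 between trials."""
    env = np.ones_like(times)
    for tr in trials:
        lo = np.searchsorted(times, tr.onset - 0.1)
        hi = np.searchsorted(times, tr.onset + 7.5)
        t_rel = times[lo:hi] - tr.onset
        if stim_only:
            if tr.condition not in MNS_CONDITIONS:
                continue
            psr = 1.0 - params.psr_abolition if tr.condition == MI_MNS else 1.0
            reb = (1.0 - params.rebound_attenuation
                   if tr.condition == MI_MNS else 1.0)
            env[lo:hi] *= _mns_gain(t_rel, band, params, psr, reb)
        else:
            env[lo:hi] *= np.asarray(
                modulation_envelope(tr.condition, band, t_rel, params))
    return env


def simulate_run(schedule: ProtocolSchedule, run: int, params: SubjectParams,
                 rate: float = 512.0) -> RawRecording:
    """Render one run of the schedule into a continuous recording."""
    if rate < 128.0:
        raise ValueError("rate must be >= 128 Hz (>= 2x the top band edge)")
    trials = schedule.run_trials(run)
    duration = schedule.run_duration(run)
    n = int(round(duration * rate))
    times = np.arange(n) / rate
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), int(run)]))

    channels = params.channels
    n_eeg = len(channels) - 1
    g_contra = params.spatial_map("C3")[:n_eeg]
    g_ipsi = params.spatial_map("C4")[:n_eeg]
    amps = {"mu": params.mu_amp, "beta": params.beta_amp}

    eeg = np.zeros((n_eeg, n))
    for band_name, band in BANDS.items():
        src_c = _band_source(rng, n, band, rate) * amps[band_name]
        src_i = (_band_source(rng, n, band, rate)
                 * amps[band_name] * params.ipsi_gain)
        env_c = _trial_envelope(times, trials, band_name, params,
                                stim_only=False)
        env_i = _trial_envelope(times, trials, band_name, params,
                                stim_only=True)
        mod_c = src_c * np.sqrt(env_c)
        mod_i = src_i * np.sqrt(env_i)
        eeg += g_contra[:, None] * mod_c[None, :]
        eeg += g_ipsi[:, None] * mod_i[None, :]
    eeg += params.noise_floor * rng.standard_normal((n_eeg, n))

    emg = params.emg_rest_amp * rng.standard_normal(n)
    for tr in trials:
        burst = tr.condition == RM or tr.trial in params.emg_contaminated_trials
        if burst:
            win = _bump(times - tr.onset, 0.0, 2.2, 0.1)
            emg = emg + params.emg_task_amp * rng.standard_normal(n) * win
        if tr.trial in params.outlier_trials:
            sl = slice(np.searchsorted(times, tr.onset),
                       np.searchsorted(times, tr.onset + tr.length))
            eeg[:, sl] *= 5.0
        if params.stim_artifact and tr.mns_offset is not None:
            idx = int(round((tr.onset + tr.mns_offset) * rate))
            if 0 <= idx < n:
                eeg[:, idx] += params.stim_artifact_amp

    data = np.vstack([eeg, emg[None, :]])
    events: list[Event] = []
    for tr in trials:
        events.append(Event(tr.onset, BEEP1, tr.trial, tr.condition))
        if tr.beep2_offset is not None:
            events.append(Event(tr.onset + tr.beep2_offset, BEEP2, tr.trial,
                                tr.condition))
        if tr.mns_offset is not None:
            events.append(Event(tr.onset + tr.mns_offset, MNS_EVENT, tr.trial,
                                tr.condition))
    events.sort(key=lambda e: e.time)
    return RawRecording(data=data, rate=rate, channels=channels,
                        events=events, meta={"run": run, "seed": params.seed})


def simulate_recording(schedule: ProtocolSchedule, params: SubjectParams,
                       rate: float = 512.0) -> RawRecording:
    """Render the whole schedule as one continuous recording (runs abutted)."""
    if schedule.n_runs == 0:
        return RawRecording(data=np.zeros((len(params.channels), 0)),
                            rate=rate, channels=params.channels, events=[])
    runs = [simulate_run(schedule, r, params, rate)
            for r in range(schedule.n_runs)]
    offsets = np.cumsum([0.0] + [r.duration for r in runs[:-1]])
    data = np.concatenate([r.data for r in runs], axis=1)
    events = [Event(ev.time + off, ev.kind, ev.trial, ev.condition)
              for r, off in zip(runs, offsets) for ev in r.events]
    return RawRecording(data=data, rate=rate, channels=params.channels,
                        events=events, meta={"seed": params.seed})


def simulate_subject(params: SubjectParams,
                     n_trials_per_condition: int = 52,
                     rate: float = 512.0,
                     conditions: Sequence[str] = CONDITIONS,
                     ) -> tuple[ProtocolSchedule, list[RawRecording]]:
    """Build a subject's protocol and render every run."""
    schedule = build_protocol(n_trials_per_condition, seed=params.seed,
                              conditions=conditions)
    runs = [simulate_run(schedule, r, params, rate)
            for r in range(schedule.n_runs)]
    return schedule, runs


@dataclass
class CohortVariability:
    """Lognormal-style multiplicative jitter applied to per-subject effects.

    Each listed field of :class:`SubjectParams` is multiplied by
    ``exp(sigma * z)`` with ``z ~ N(0, 1)``; fractions (``psr_abolition``,
    ``rebound_attenuation``) are jittered additively and clipped to [0, 1].
    """

    effect_sigma: float = 0.2      # depths, gains, rebound percentages
    amplitude_sigma: float = 0.15  # source amplitudes and noise floor
    fraction_sigma: float = 0.05   # abolition / attenuation fractions


def draw_subject_params(base: SubjectParams, variability: CohortVariability,
                        seed: int) -> SubjectParams:
    rng = np.random.default_rng(seed)

    def jitter(value: float, sigma: float) -> float:
        return float(value * np.exp(sigma * rng.standard_normal()))

    es, am, fs = (variability.effect_sigma, variability.amplitude_sigma,
                  variability.fraction_sigma)
    return base.replace(
        mu_erd_depth=max(-95.0, jitter(base.mu_erd_depth, es)),
        beta_erd_depth=max(-95.0, jitter(base.beta_erd_depth, es)),
        psr_gain=jitter(base.psr_gain, es),
        rebound_gain=jitter(base.rebound_gain, es),
        post_task_rebound=jitter(base.post_task_rebound, es),
        mu_amp=jitter(base.mu_amp, am),
        beta_amp=jitter(base.beta_amp, am),
        noise_floor=jitter(base.noise_floor, am),
        psr_abolition=float(np.clip(
            base.psr_abolition + fs * rng.standard_normal(), 0.0, 1.0)),
        rebound_attenuation=float(np.clip(
            base.rebound_attenuation + fs * rng.standard_normal(), 0.0, 1.0)),
        seed=seed,
    )


def simulate_cohort(n_subjects: int,
                    base_params: Optional[SubjectParams] = None,
                    variability: Optional[CohortVariability] = None,
                    seed: int = 0,
                    n_trials_per_condition: int = 52,
                    rate: float = 512.0,
                    conditions: Sequence[str] = CONDITIONS,
                    ) -> list[dict]:
    """Simulate a cohort; returns one dict per subject.

    Each entry holds ``params`` (the subject's drawn :class:`SubjectParams`),
    ``schedule`` and ``runs`` (one :class:`RawRecording` per run).  Subject
    seeds derive deterministically from the master ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_params if base_params is not None else SubjectParams()
    var = variability if variability is not None else CohortVariability()
    subject_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    cohort = []
    for i, s_seed in enumerate(subject_seeds):
        params = draw_subject_params(base, var, seed=int(s_seed) % (2 ** 31))
        schedule, runs = simulate_subject(
            params, n_trials_per_condition, rate, conditions)
        cohort.append({"subject": i, "params": params,
                       "schedule": schedule, "runs": runs})
    return cohort
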