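"""Referencing, resampling, epoching, filtering and rejection behaviour."""

import numpy as np
import pytest

import mnsbci as m
from mnsbci import preprocess as pp
from mnsbci.containers import EMG_LABEL, Event, RawRecording

from conftest import make_epochs, preprocess_subject


def _toy_recording(rng, n_ch=4, dur=20.0, rate=128.0, with_emg=True):
    channels = [f"E{i}" for i in range(n_ch)]
    if with_emg:
        channels[-1] = EMG_LABEL
    data = rng.standard_normal((n_ch, int(dur * rate)))
    return RawRecording(data=data, rate=rate, channels=channels, events=[])


class TestCAR:
    def test_eeg_mean_is_zero_and_emg_untouched(self, rng):
        rec = _toy_recording(rng)
        out = pp.common_average_reference(rec)
        eeg_mean = out.data[out.eeg_picks].mean(axis=0)
        assert np.max(np.abs(eeg_mean)) < 1e-9
        assert np.array_equal(out.data[-1], rec.data[-1])

    def test_idempotent(self, rng):
        rec = _toy_recording(rng)
        once = pp.common_average_reference(rec)
        twice = pp.common_average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_common_offset_removed_exactly(self, rng):
        rec = _toy_recording(rng)
        shifted = rec.copy()
        shifted.data[shifted.eeg_picks] += 10.0  # common 10 uV offset
        a = pp.common_average_reference(rec)
        b = pp.common_average_reference(shifted)
        assert np.allclose(a.data[a.eeg_picks], b.data[b.eeg_picks],
                           atol=1e-9)

    def test_single_eeg_channel_raises(self, rng):
        rec = _toy_recording(rng, n_ch=2)  # one EEG + EMG
        with pytest.raises(ValueError):
            pp.common_average_reference(rec)

    def test_works_on_epochs(self, rng):
        ep = make_epochs(rng.standard_normal((3, 4, 128)))
        out = pp.common_average_reference(ep)
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-9


class TestResample:
    def test_nine_second_epoch_sample_count(self, rng):
        ep = make_epochs(rng.standard_normal((2, 3, 9 * 512)), rate=512.0)
        out = pp.resample_to(ep, 128.0)
        assert out.n_samples == 1152
        assert out.rate == 128.0

    def test_sine_amplitude_preserved(self):
        t = np.arange(int(10 * 512)) / 512.0
        x = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        out = pp.resample_to(make_epochs(x, rate=512.0, tmin=0.0), 128.0)
        y = out.data[0, 0]
        interior = y[128:-128]  # avoid polyphase edge transients
        amp = np.sqrt(2.0) * interior.std()
        assert abs(amp - 1.0) < 0.01

    def test_identity_and_upsampling_error(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, 256)), rate=128.0)
        assert pp.resample_to(ep, 128.0) is ep
        with pytest.raises(ValueError):
            pp.resample_to(ep, 256.0)


class TestEpoch:
    def test_one_epoch_per_event(self):
        sched = m.build_protocol(26, seed=4, conditions=("MI",))
        rec = m.simulate_run(sched, 0, m.SubjectParams(seed=4), rate=512.0)
        ep = pp.epoch(rec)
        assert ep.n_trials == 26
        assert np.all(ep.labels == "MI")

    def test_empty_event_list(self, rng):
        rec = _toy_recording(rng)
        ep = pp.epoch(rec, window=(-1.0, 1.0))
        assert ep.n_trials == 0
        assert ep.n_samples == int(2.0 * rec.rate)

    def test_sample_at_zero_matches_recording(self, rng):
        rec = _toy_recording(rng, dur=30.0)
        ev_time = 10.0
        rec.events.append(Event(ev_time, "beep1", 0, "MI"))
        ep = pp.epoch(rec, window=(-2.0, 7.0))
        i_zero = int(round(2.0 * rec.rate))
        i_rec = int(round(ev_time * rec.rate))
        assert np.array_equal(ep.data[0, :, i_zero], rec.data[:, i_rec])
        assert ep.times[i_zero] == 0.0

    def test_window_outside_recording_names_trial(self, rng):
        rec = _toy_recording(rng, dur=5.0)
        rec.events.append(Event(1.0, "beep1", 7, "MI"))
        with pytest.raises(ValueError, match="trial 7"):
            pp.epoch(rec, window=(-2.0, 7.0))


class TestBandpass:
    def test_dc_removed(self):
        ep = make_epochs(np.full((1, 1, 1152), 5.0))
        out = pp.bandpass(ep, (8.0, 30.0), order=4)
        assert abs(out.data.mean()) < 1e-6

    def test_passband_and_stopband(self):
        t = np.arange(1152) / 128.0
        for freq, check in ((20.0, "pass"), (50.0, "stop")):
            x = np.sin(2 * np.pi * freq * t)[None, None, :]
            out = pp.bandpass(make_epochs(x), (8.0, 30.0), order=4)
            amp = np.sqrt(2.0) * out.data[0, 0, 200:-200].std()
            if check == "pass":
                assert abs(amp - 1.0) < 0.05
            else:
                assert 20.0 * np.log10(1.0 / amp) > 20.0

    def test_band_metadata_recorded(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, 256)))
        out = pp.bandpass(ep, (8.0, 30.0), order=5)
        assert out.band == (8.0, 30.0, 5)

    def test_invalid_band_raises(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, 256)), rate=128.0)
        with pytest.raises(ValueError):
            pp.bandpass(ep, (8.0, 70.0), order=4)

    def test_car_and_bandpass_commute(self, rng):
        ep = make_epochs(rng.standard_normal((2, 5, 1152)))
        a = pp.bandpass(pp.common_average_reference(ep), (8.0, 30.0))
        b = pp.common_average_reference(pp.bandpass(ep, (8.0, 30.0)))
        scale = np.abs(a.data).max()
        assert np.allclose(a.data, b.data, atol=1e-6 * scale)


class TestRejection:
    def test_clean_run_keeps_everything(self, mi_subject):
        _, epochs = mi_subject
        kept, report = pp.reject_trials(epochs)
        assert sum(report.removed.values()) == 0
        assert kept.n_trials == epochs.n_trials

    def test_injected_emg_bursts_flagged_exactly(self):
        sched = m.build_protocol(20, seed=13, conditions=("MI",))
        bad = tuple(t.trial for t in sched.trials[:3])
        params = m.SubjectParams(seed=13, emg_contaminated_trials=bad)
        runs = [m.simulate_run(sched, r, params, 512.0)
                for r in range(sched.n_runs)]
        epochs = preprocess_subject(runs)
        ids = np.array(epochs.meta["trial_ids"])
        kept, report = pp.reject_trials(epochs)
        flagged = {ids[i] for i, r in report.reasons.items() if r == "EMG"}
        assert flagged == set(bad)

    def test_outlier_trial_flagged(self):
        # last trial of the run, so the scaled samples stay inside one epoch
        sched = m.build_protocol(20, seed=14, conditions=("MI",))
        bad = (sched.run_trials(0)[-1].trial,)
        params = m.SubjectParams(seed=14, outlier_trials=bad)
        runs = [m.simulate_run(sched, r, params, 512.0)
                for r in range(sched.n_runs)]
        epochs = preprocess_subject(runs)
        ids = np.array(epochs.meta["trial_ids"])
        kept, report = pp.reject_trials(epochs)
        flagged = {ids[i] for i, r in report.reasons.items()
                   if r == "outlier"}
        assert flagged == set(bad)

    def test_report_bookkeeping(self):
        sched = m.build_protocol(20, seed=13, conditions=("MI",))
        bad = tuple(t.trial for t in sched.trials[:3])
        params = m.SubjectParams(seed=13, emg_contaminated_trials=bad)
        runs = [m.simulate_run(sched, r, params, 512.0)
                for r in range(sched.n_runs)]
        epochs = preprocess_subject(runs)
        kept, report = pp.reject_trials(epochs)
        assert report.total["MI"] == 20
        assert report.removed["MI"] == 3
        assert report.fractions["MI"] == 3 / 20
        assert kept.n_trials == 17

    def test_survivors_untouched(self, rng):
        ep = make_epochs(rng.standard_normal((6, 3, 1152)))
        kept, _ = pp.reject_trials(
            ep, criteria=pp.RejectionCriteria(emg_enabled=False))
        for i in range(kept.n_trials):
            assert np.array_equal(kept.data[i], ep.data[i])

    def test_missing_emg_channel_raises(self, rng):
        ep = make_epochs(rng.standard_normal((4, 3, 1152)))
        with pytest.raises(ValueError):
            pp.reject_trials(ep)
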