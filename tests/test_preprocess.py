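import logging

import numpy as np
import pytest
from scipy import signal as sps

from dtw100 import (
    Modality,
    RunConfig,
    SignalTrace,
    TrialSet,
    ValidationError,
    average_trials,
    bandpass_filter,
    build_reference,
    extract_epochs,
    notch_filter,
    preprocess_trials,
    remove_baseline,
)
from dtw100.preprocess import decimate_trials, design_bandpass, design_notch

from .conftest import make_tone


def central_rms(x, frac=0.5):
    n = len(x)
    lo = int(n * (1 - frac) / 2)
    return np.sqrt(np.mean(np.asarray(x)[lo : n - lo] ** 2))


class TestNotch:
    def test_mains_tone_suppressed(self):
        tone = make_tone(50.0)
        out = notch_filter(tone)
        assert central_rms(out.samples) <= 0.1 * central_rms(tone.samples)

    def test_distant_tone_preserved(self):
        tone = make_tone(10.0)
        out = notch_filter(tone)
        assert central_rms(out.samples) >= 0.95 * central_rms(tone.samples)

    def test_analytic_response(self):
        # forward-backward application squares the magnitude response
        b, a = design_notch(2000.0, 50.0, 30.0)
        freqs, h = sps.freqz(b, a, worN=[50.0, 40.0], fs=2000.0)
        assert np.abs(h[0]) ** 2 <= 0.1
        assert np.abs(h[1]) ** 2 >= 10 ** (-1 / 20)  # within 1 dB at 40 Hz

    def test_zero_in_zero_out(self):
        z = SignalTrace(np.zeros(1000), 2000.0, "LFP")
        assert np.allclose(notch_filter(z).samples, 0.0)

    def test_rejects_frequency_at_nyquist(self):
        tone = make_tone(10.0, rate=100.0, seconds=1.0)
        with pytest.raises(ValidationError):
            notch_filter(tone, freq=60.0)


class TestBaselineRemoval:
    def test_constant_removed_exactly(self):
        tr = SignalTrace(np.full(2000, 7.25), 2000.0, "LFP")
        assert np.allclose(remove_baseline(tr).samples, 0.0, atol=1e-12)

    def test_slow_drift_removed_fast_tone_kept(self):
        rate, seconds = 2000.0, 4.0
        t = np.arange(int(rate * seconds)) / rate
        slow = np.sin(2 * np.pi * 0.1 * t)
        fast = np.sin(2 * np.pi * 40.0 * t)
        out = remove_baseline(SignalTrace(slow + fast, rate, "LFP"), 1.0).samples
        n = len(t)
        sl = slice(n // 4, 3 * n // 4)
        # projections onto the two components over the central half
        fast_amp = 2 * np.mean(out[sl] * fast[sl])
        slow_amp = 2 * np.mean(out[sl] * slow[sl])
        assert abs(fast_amp - 1.0) <= 0.1
        assert abs(slow_amp) <= 0.1

    def test_zero_trace(self):
        z = SignalTrace(np.zeros(100), 100.0, "EMG")
        assert np.allclose(remove_baseline(z, 0.5).samples, 0.0)

    def test_window_too_short(self):
        tr = SignalTrace(np.zeros(100), 100.0, "LFP")
        with pytest.raises(ValidationError):
            remove_baseline(tr, window_seconds=0.01)


class TestBandpass:
    def test_stopband_tone_attenuated(self):
        tone = make_tone(300.0)
        out = bandpass_filter(tone, (0.5, 200.0))
        assert central_rms(out.samples) <= 0.1 * central_rms(tone.samples)

    def test_passband_tone_preserved(self):
        tone = make_tone(40.0, modality=Modality.EMG)
        out = bandpass_filter(tone, (10.0, 200.0))
        assert central_rms(out.samples) >= 0.9 * central_rms(tone.samples)

    def test_octave_outside_band_attenuation(self):
        sos = design_bandpass(2000.0, (0.5, 200.0))
        freqs, h = sps.sosfreqz(sos, worN=[400.0], fs=2000.0)
        assert np.abs(h[0]) ** 2 <= 0.1  # >= 20 dB after zero-phase pass

    def test_inverted_band_rejected(self):
        tone = make_tone(40.0)
        with pytest.raises(ValidationError):
            bandpass_filter(tone, (200.0, 10.0))

    def test_zero_trace(self):
        z = SignalTrace(np.zeros(1000), 2000.0, "LFP")
        assert np.allclose(bandpass_filter(z, (0.5, 200.0)).samples, 0.0)


class TestChainProperties:
    def test_chain_is_zero_phase(self):
        # the 40 Hz component must come through with zero lag: the peak of
        # the cross-correlation with the input tone sits exactly at shift 0
        cfg = RunConfig()
        tone = make_tone(40.0)
        ts = TrialSet([tone], epoch_seconds=4.0)
        out = preprocess_trials(ts, cfg).trials[0].samples
        n = len(out)
        sl = slice(n // 4, 3 * n // 4)
        max_lag = 25  # half a 40 Hz cycle
        lags = np.arange(-max_lag, max_lag + 1)
        xc = [np.dot(out[sl], np.roll(tone.samples, lag)[sl]) for lag in lags]
        assert lags[np.argmax(xc)] == 0

    def test_notch_and_bandpass_commute(self, rng):
        # both stages are LTI when zero-phase, so they commute wherever the
        # 0.5 Hz corner's edge transients (seconds long) have settled: check
        # the central third of a 60 s record
        x = SignalTrace(rng.normal(size=120_000), 2000.0, "LFP")
        ab = bandpass_filter(notch_filter(x), (0.5, 200.0)).samples
        ba = notch_filter(bandpass_filter(x, (0.5, 200.0))).samples
        rms = np.sqrt(np.mean(x.samples**2))
        core = slice(40_000, 80_000)
        assert np.max(np.abs(ab[core] - ba[core])) < 1e-6 * rms

    def test_decimation_preserves_in_band_tone(self):
        tone = make_tone(40.0)
        ts = TrialSet([tone], epoch_seconds=4.0)
        dec = decimate_trials(ts, 4)
        assert dec.rate == 500.0
        assert dec.n_samples == 2000
        assert abs(central_rms(dec.trials[0].samples) - central_rms(tone.samples)) < 0.02


class TestExtractEpochs:
    def test_regular_onsets_tile_the_recording(self):
        rate, epoch = 100.0, 1.0
        n_epoch = 100
        x = SignalTrace(np.arange(10 * n_epoch, dtype=float), rate, "LFP")
        onsets = list(range(0, 10 * n_epoch, n_epoch))
        ts = extract_epochs(x, onsets, epoch, "post_stimulus")
        assert ts.n_trials == 10
        np.testing.assert_array_equal(np.concatenate(ts.as_array()), x.samples)

    def test_edge_onset_skipped_with_warning(self, caplog):
        x = SignalTrace(np.arange(300, dtype=float), 100.0, "LFP")
        with caplog.at_level(logging.WARNING, logger="dtw100.preprocess"):
            ts = extract_epochs(x, [0, 150], 1.0, "pre_stimulus")
        assert ts.n_trials == 1
        assert any("skipping onset 0" in r.message for r in caplog.records)

    def test_all_onsets_unusable_is_an_error(self):
        x = SignalTrace(np.arange(50, dtype=float), 100.0, "LFP")
        with pytest.raises(ValidationError):
            extract_epochs(x, [0], 1.0, "pre_stimulus")

    def test_pre_and_post_windows_are_adjacent(self):
        x = SignalTrace(np.arange(400, dtype=float), 100.0, "LFP")
        pre = extract_epochs(x, [200], 1.0, "pre_stimulus").trials[0].samples
        post = extract_epochs(x, [200], 1.0, "post_stimulus").trials[0].samples
        np.testing.assert_array_equal(np.concatenate([pre, post]), x.samples[100:300])


class TestAveraging:
    def test_pointwise_mean(self):
        ts = TrialSet.from_array(np.array([[1.0] * 10, [3.0] * 10]), 10.0, "LFP")
        np.testing.assert_array_equal(average_trials(ts).samples, np.full(10, 2.0))

    def test_single_trial_identity(self, rng):
        row = rng.normal(size=20)
        ts = TrialSet.from_array(row[None, :], 10.0, "EMG")
        np.testing.assert_array_equal(average_trials(ts).samples, row)

    def test_noise_reduction_matches_standard_error(self, rng):
        ts = TrialSet.from_array(rng.normal(size=(30, 4000)), 1000.0, "LFP")
        sd = average_trials(ts).samples.std()
        expected = 1.0 / np.sqrt(30)
        assert abs(sd - expected) <= 0.2 * expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            average_trials(TrialSet([], epoch_seconds=1.0))


class TestReference:
    def _ts(self, arr, modality):
        return TrialSet.from_array(np.asarray(arr, dtype=float), 10.0, modality)

    def test_grand_mean_of_subject_means(self, rng):
        subs = [rng.normal(size=(4, 20)) for _ in range(3)]
        ref = build_reference(
            [self._ts(s, "LFP") for s in subs], [self._ts(s, "EMG") for s in subs]
        )
        expected = np.mean([s.mean(axis=0) for s in subs], axis=0)
        np.testing.assert_allclose(ref.lfp_ref.samples, expected)
        assert ref.n_source_trials == 3

    def test_single_subject_equals_own_average(self, rng):
        s = rng.normal(size=(5, 20))
        ref = build_reference([self._ts(s, "LFP")], [self._ts(s, "EMG")])
        np.testing.assert_allclose(ref.emg_ref.samples, s.mean(axis=0))

    def test_opposite_subjects_cancel(self, rng):
        a = rng.normal(size=(2, 20))
        ref = build_reference(
            [self._ts(a, "LFP"), self._ts(-a, "LFP")],
            [self._ts(a, "EMG"), self._ts(-a, "EMG")],
        )
        np.testing.assert_allclose(ref.lfp_ref.samples, 0.0, atol=1e-15)

    def test_mismatched_lengths_rejected(self, rng):
        a = self._ts(rng.normal(size=(2, 20)), "LFP")
        b = TrialSet.from_array(rng.normal(size=(2, 30)), 10.0, "LFP")
        e = self._ts(rng.normal(size=(2, 20)), "EMG")
        with pytest.raises(ValidationError, match="length"):
            build_reference([a, b], [e, e])
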