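"""Conditioning chain: referencing, resampling, filtering, epoching, power."""

from __future__ import annotations

import numpy as np
import pytest

import eegmarkers as em
from eegmarkers import preprocessing as pp

from conftest import make_recording


def _sine(freq, fs, dur, amp=1.0, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestRecording:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            em.Recording(("a", "a"), 250.0, np.zeros((2, 10)))

    def test_non_finite_rejected(self):
        data = np.zeros((2, 10))
        data[1, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            em.Recording(("a", "b"), 250.0, data)

    def test_drop_unknown_label_lists_it(self, noise_recording):
        with pytest.raises(KeyError, match="nope"):
            noise_recording.drop(["nope"])


class TestPreprocess:
    def test_average_reference_zeroes_identical_channels(self):
        rec = make_recording(np.full((3, 250 * 20), 7.5))
        out = pp.preprocess(rec)
        assert np.allclose(out.data, 0.0, atol=1e-8)

    def test_column_sums_zero_after_reference(self, rng):
        data = rng.standard_normal((5, 250 * 20))
        ref = pp.average_reference(data)
        assert np.allclose(ref.sum(axis=0), 0.0, atol=1e-10)

    def test_downsamples_1khz_to_250(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000 * 20)), fs=1000.0)
        out = pp.preprocess(rec)
        assert out.fs_hz == 250.0
        assert abs(out.n_samples - rec.n_samples / 4) <= 1

    def test_low_rate_input_skips_resampling(self, rng):
        rec = make_recording(rng.standard_normal((2, 250 * 20)), fs=250.0)
        out = pp.preprocess(rec)
        assert out.fs_hz == 250.0
        assert out.n_samples == rec.n_samples

    def test_notch_attenuates_60hz_by_20db(self):
        # 60 Hz sinusoid against a reference channel of noise
        rng = np.random.default_rng(0)
        data = np.vstack([_sine(60.0, 1000.0, 20.0),
                          rng.standard_normal(20000) * 0.01])
        rec = make_recording(data, fs=1000.0)
        out = pp.preprocess(rec)
        ep = em.epoch(out, 10.0)
        p_out = pp.band_power(ep, 58.0, 62.0)[0]
        # compare against the same chain with the notch disabled
        in_band_before = pp.band_power(
            em.epoch(make_recording(pp.average_reference(data), 1000.0), 10.0),
            58.0, 62.0)[0] / 4  # downsampling preserves band power density
        assert 10 * np.log10(in_band_before / p_out) >= 20.0

    def test_drop_then_reference_order(self):
        # a huge artifact channel must not leak into the reference
        clean = _sine(10.0, 250.0, 20.0)
        bad = 1e4 * np.ones_like(clean)
        rec = make_recording(np.vstack([clean, -clean, bad]))
        out = pp.preprocess(rec, drop_labels={"ch02"})
        assert out.labels == ("ch00", "ch01")
        assert np.abs(out.data).max() < 10.0

    def test_dropping_to_single_channel_errors(self, noise_recording):
        with pytest.raises(ValueError, match="fewer than 2"):
            pp.preprocess(noise_recording,
                          drop_labels={"ch00", "ch01", "ch02"})


class TestEpoch:
    def test_300s_gives_30_windows_of_2500(self, rng):
        rec = make_recording(rng.standard_normal((2, 250 * 300)))
        ep = em.epoch(rec, 10.0)
        assert ep.n_windows == 30
        assert ep.n_samples == 2500

    def test_trailing_remainder_discarded(self, rng):
        rec = make_recording(rng.standard_normal((2, 250 * 25)))
        ep = em.epoch(rec, 10.0)
        assert ep.n_windows == 2

    def test_too_short_recording_errors(self, rng):
        rec = make_recording(rng.standard_normal((2, int(250 * 9.9))))
        with pytest.raises(ValueError, match="shorter than one"):
            em.epoch(rec, 10.0)

    def test_label_keyed_not_index_keyed(self, rng):
        """preprocess∘epoch commutes with channel-order permutation."""
        data = rng.standard_normal((4, 250 * 20))
        rec = make_recording(data)
        perm = [2, 0, 3, 1]
        rec_p = em.Recording(tuple(rec.labels[i] for i in perm), 250.0,
                             data[perm])
        out = em.epoch(pp.preprocess(rec), 10.0)
        out_p = em.epoch(pp.preprocess(rec_p), 10.0)
        for l in rec.labels:
            a = out.windows[0][out.labels.index(l)]
            b = out_p.windows[0][out_p.labels.index(l)]
            np.testing.assert_allclose(a, b, atol=1e-10)


class TestAlphaBand:
    def test_passband_10hz_preserved(self):
        rec = make_recording(_sine(10.0, 250.0, 30.0)[None, :])
        ep = em.bandpass_alpha(em.epoch(rec, 10.0))
        out = ep.windows[1][0]
        expected = _sine(10.0, 250.0, 30.0)[2500:5000]
        ratio = out.std() / expected.std()
        assert 0.95 < ratio < 1.05

    def test_stopband_2hz_suppressed(self):
        rec = make_recording(_sine(2.0, 250.0, 30.0)[None, :])
        ep = em.bandpass_alpha(em.epoch(rec, 10.0))
        assert ep.windows[1][0].std() < 0.05 * _sine(2.0, 250.0, 30.0).std()

    def test_white_noise_concentrates_in_band(self, rng):
        rec = make_recording(rng.standard_normal((1, 250 * 30)))
        ep = em.bandpass_alpha(em.epoch(rec, 10.0))
        in_band = pp.band_power(ep, 8.0, 13.0)[0]
        total = pp.band_power(ep, 0.5, 124.0)[0]
        assert in_band / total > 0.9

    def test_zero_phase_no_shift_at_band_center(self):
        x = _sine(10.0, 250.0, 30.0)
        rec = make_recording(x[None, :])
        ep = em.bandpass_alpha(em.epoch(rec, 10.0))
        y = ep.windows[1][0]
        x_mid = x[2500:5000]
        # phase of the exact 10 Hz Fourier coefficient (bin 100 of 2500)
        ph_in = np.angle(np.fft.rfft(x_mid)[100])
        ph_out = np.angle(np.fft.rfft(y)[100])
        shift = np.degrees(np.angle(np.exp(1j * (ph_out - ph_in))))
        assert abs(shift) < 1.0

    def test_low_fs_rejected(self, rng):
        rec = make_recording(rng.standard_normal((1, 20 * 30)), fs=20.0)
        with pytest.raises(ValueError, match="too low"):
            em.bandpass_alpha(em.epoch(rec, 10.0))


class TestBandPower:
    def test_sine_power_concentrated_in_band(self):
        rec = make_recording(_sine(10.0, 250.0, 30.0)[None, :])
        ep = em.epoch(rec, 10.0)
        in_band = pp.band_power(ep, 8.0, 13.0)[0]
        total = pp.band_power(ep, 0.5, 124.0)[0]
        assert in_band / total > 0.99
        assert abs(in_band - 0.5) < 0.02  # unit sine has power 1/2

    def test_quadratic_amplitude_scaling(self):
        p1 = pp.band_power(
            em.epoch(make_recording(_sine(10, 250, 30)[None, :]), 10), 8, 13)[0]
        p2 = pp.band_power(
            em.epoch(make_recording(_sine(10, 250, 30, amp=2)[None, :]), 10),
            8, 13)[0]
        assert abs(p2 / p1 - 4.0) < 0.01

    def test_out_of_band_sine_near_zero(self):
        rec = make_recording(_sine(10.0, 250.0, 30.0)[None, :])
        p = pp.band_power(em.epoch(rec, 10.0), 20.0, 40.0)[0]
        assert p < 1e-4

    def test_invalid_band_rejected(self, noise_recording):
        ep = em.epoch(noise_recording, 10.0)
        with pytest.raises(ValueError, match="invalid band"):
            pp.band_power(ep, 40.0, 20.0)


class TestArtifactRejection:
    def test_windows_above_threshold_dropped(self, rng):
        data = rng.standard_normal((2, 250 * 30))
        data[0, 3000] = 500.0  # spike in the second window
        ep = em.epoch(make_recording(data), 10.0)
        kept = pp.reject_artifact_windows(ep, threshold_uv=150.0)
        assert kept.n_windows == 2

    def test_all_rejected_raises(self, rng):
        data = 200.0 * np.ones((2, 250 * 30))
        ep = em.epoch(make_recording(data), 10.0)
        with pytest.raises(ValueError, match="every window"):
            pp.reject_artifact_windows(ep, threshold_uv=150.0)
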