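"""Filtering, resampling, interpolation, referencing, epoching, rejection."""

import numpy as np
import pytest

import eegmdd as em
from eegmdd import montage, preprocess as pp

from conftest import make_tone_recording


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


def central_rms(rec, trim_s=5.0):
    """RMS away from the recording edges, where the narrow notch settles."""
    k = int(trim_s * rec.fs)
    return rms(rec.signal[:, k:-k])


class TestFilter:
    def test_notch_kills_50hz_tone(self):
        rec = make_tone_recording([(50.0, 10.0)], duration_s=30.0)
        out = pp.filter_recording(rec)
        assert central_rms(out) < 0.1 * central_rms(rec)

    def test_passband_preserves_10hz_tone(self):
        rec = make_tone_recording([(10.0, 10.0)], duration_s=30.0)
        out = pp.filter_recording(rec)
        assert abs(central_rms(out) - central_rms(rec)) < 0.05 * central_rms(rec)

    def test_highpass_removes_dc(self):
        rec = make_tone_recording([(10.0, 0.0)])
        rec.signal[:] = 25.0
        out = pp.filter_recording(rec)
        assert np.abs(out.signal).max() < 0.5

    def test_50hz_attenuated_at_least_20db_relative_to_40hz(self):
        r50 = pp.filter_recording(make_tone_recording([(50.0, 10.0)], duration_s=30.0))
        r40 = pp.filter_recording(make_tone_recording([(40.0, 10.0)], duration_s=30.0))
        ratio = central_rms(r50) / central_rms(r40)
        assert 20 * np.log10(1 / ratio) >= 20

    def test_band_above_nyquist_rejected(self):
        rec = make_tone_recording([(10.0, 1.0)], fs=500.0)
        with pytest.raises(ValueError):
            pp.filter_recording(rec, band_hi=250.0)

    def test_commutes_with_channel_permutation(self):
        cfg = em.CohortConfig(n_per_group=1, duration_s=6.0, fs=500.0,
                              artifact_rate=0.0, seed=3)
        rec = em.generate_subject(cfg, "HC", 0)
        perm = np.random.default_rng(0).permutation(len(rec.channels))
        rec_p = em.Recording("p", tuple(rec.channels[i] for i in perm),
                             rec.fs, rec.signal[perm])
        out = pp.filter_recording(rec)
        out_p = pp.filter_recording(rec_p)
        np.testing.assert_allclose(out_p.signal, out.signal[perm], atol=1e-9)


class TestDownsample:
    def test_preserves_10hz_spectral_peak(self):
        rec = make_tone_recording([(10.0, 5.0)], fs=1000.0, duration_s=8.0)
        out = pp.downsample(rec, 500.0)
        spec = np.abs(np.fft.rfft(out.signal[0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.fs)
        assert freqs[spec.argmax()] == pytest.approx(10.0, abs=0.2)

    def test_identity_when_rate_matches(self):
        rec = make_tone_recording([(10.0, 5.0)], fs=500.0)
        out = pp.downsample(rec, 500.0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_length_arithmetic(self):
        rec = em.Recording("x", montage.CHANNELS, 1000.0,
                           np.zeros((29, 600_000)))
        out = pp.downsample(rec, 500.0)
        assert out.n_samples == 300_000
        assert out.fs == 500.0

    def test_rejects_rate_too_low_for_gamma(self):
        rec = make_tone_recording([(10.0, 5.0)], fs=1000.0)
        with pytest.raises(ValueError):
            pp.downsample(rec, 160.0)


class TestInterpolation:
    @staticmethod
    def _dipole_field(positions, r0, moment):
        d = positions - r0
        return (d @ moment) / np.linalg.norm(d, axis=1) ** 3

    def test_no_bads_is_identity(self):
        rec = make_tone_recording([(10.0, 5.0)])
        out = pp.interpolate_bad_channels(rec, [])
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_constant_field_reproduced(self):
        """If every channel carries the same signal, the spline estimate of a
        'bad' channel reproduces it within 1% RMS."""
        t = np.linspace(0, 2, 1000)
        common = 10 * np.sin(2 * np.pi * 7 * t)
        rec = em.Recording("c", montage.CHANNELS, 500.0,
                           np.tile(common, (29, 1)))
        out = pp.interpolate_bad_channels(rec, ["CP2"])
        i = montage.CHANNELS.index("CP2")
        assert rms(out.signal[i] - common) < 0.01 * rms(common)

    def test_beats_nearest_neighbor_on_smooth_field(self):
        """Dipolar potential sampled on the montage: spline interpolation of a
        removed channel has lower RMS error than copying its nearest
        neighbour."""
        pos = montage.channel_positions()
        field = self._dipole_field(pos, np.array([0.0, 0.02, 0.04]),
                                   np.array([0.0, 1e-4, 1e-4]))
        t = np.linspace(0, 1, 500)
        mod = np.sin(2 * np.pi * 5 * t)
        data = np.outer(field, mod) * 50
        rec = em.Recording("d", montage.CHANNELS, 500.0, data)
        target = "CP1"
        i = montage.CHANNELS.index(target)
        corrupted = em.Recording("d", montage.CHANNELS, 500.0, data.copy())
        corrupted.signal[i] = 0.0
        out = pp.interpolate_bad_channels(corrupted, [target])
        spline_err = rms(out.signal[i] - data[i])
        dists = np.linalg.norm(pos - pos[i], axis=1)
        dists[i] = np.inf
        nn_err = rms(data[dists.argmin()] - data[i])
        assert spline_err < nn_err

    def test_all_bad_rejected(self):
        rec = make_tone_recording([(10.0, 5.0)], n_channels=5)
        with pytest.raises(ValueError):
            pp.interpolate_bad_channels(rec, list(rec.channels))

    def test_unknown_bad_channel_rejected(self):
        rec = make_tone_recording([(10.0, 5.0)])
        with pytest.raises(KeyError):
            pp.interpolate_bad_channels(rec, ["FT7"])


class TestRereference:
    def test_column_means_vanish(self, clean_subject):
        _, rec = clean_subject
        out = pp.rereference_average(rec)
        assert np.abs(out.signal.mean(axis=0)).max() < 1e-9
        assert out.reference == "common_average"

    def test_idempotent(self, clean_subject):
        _, rec = clean_subject
        once = pp.rereference_average(rec)
        twice = pp.rereference_average(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-12)

    def test_bipolar_pairs_invariant(self, clean_subject):
        _, rec = clean_subject
        out = pp.rereference_average(rec)
        np.testing.assert_allclose(
            out.signal[3] - out.signal[7], rec.signal[3] - rec.signal[7], atol=1e-9
        )


class TestEpoching:
    def test_600s_at_500hz_gives_300_epochs_of_1000_samples(self):
        rec = em.Recording("x", ("C3", "C4"), 500.0, np.zeros((2, 300_000)))
        ep = pp.epoch(rec, 2.0)
        assert ep.n_epochs == 300
        assert ep.n_samples == 1000

    def test_trailing_remainder_discarded(self):
        rec = em.Recording("x", ("C3",), 500.0, np.zeros((1, 2500)))
        ep = pp.epoch(rec, 2.0)
        assert ep.n_epochs == 2

    def test_partition_property(self, clean_subject):
        _, rec = clean_subject
        ep = pp.epoch(rec, 2.0)
        n = ep.n_epochs * ep.n_samples
        rebuilt = np.concatenate([ep.data[k] for k in range(ep.n_epochs)], axis=1)
        np.testing.assert_array_equal(rebuilt, rec.signal[:, :n])

    def test_too_short_recording_rejected(self):
        rec = em.Recording("x", ("C3",), 500.0, np.zeros((1, 500)))
        with pytest.raises(ValueError):
            pp.epoch(rec, 2.0)


class TestRejection:
    def _epochs(self, data):
        return em.EpochArray("x", ("C3", "C4"), 500.0, 2.0, data,
                             np.arange(data.shape[0]))

    def test_clean_epochs_untouched(self):
        data = np.random.default_rng(0).normal(0, 5, (4, 2, 1000))
        ep = self._epochs(np.clip(data, -79, 79))
        out = pp.reject_epochs(ep, 80.0)
        assert out.n_epochs == 4

    def test_single_spiked_epoch_removed(self):
        data = np.random.default_rng(0).normal(0, 5, (5, 2, 1000)).clip(-79, 79)
        data[2, 1, 137] = 150.0
        out = pp.reject_epochs(self._epochs(data), 80.0)
        assert list(out.kept_epoch_indices) == [0, 1, 3, 4]

    def test_infinite_threshold_is_identity(self):
        data = np.random.default_rng(0).normal(0, 50, (3, 2, 1000))
        out = pp.reject_epochs(self._epochs(data), np.inf)
        assert out.n_epochs == 3

    def test_all_rejected_raises_diagnostic(self):
        data = np.full((3, 2, 1000), 200.0)
        with pytest.raises(ValueError, match="all 3 epochs"):
            pp.reject_epochs(self._epochs(data), 80.0)


class TestPipeline:
    def test_artifact_free_subject_keeps_every_epoch(self, clean_subject, clean_epochs):
        cfg, rec = clean_subject
        assert clean_epochs.n_epochs == int(rec.duration_s // 2)

    def test_history_records_pipeline_order(self, clean_epochs):
        steps = [h.split("(")[0] for h in clean_epochs.history]
        assert steps == ["synth", "filter", "downsample", "interpolate",
                         "epoch", "reject", "rereference"]

    def test_epochs_are_car_referenced_and_below_threshold(self, clean_epochs):
        assert np.abs(clean_epochs.data.mean(axis=1)).max() < 1e-9
        # rejection ran before CAR, on the recording reference; post-CAR
        # amplitudes stay in a physiological range
        assert np.abs(clean_epochs.data).max() < 120.0
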