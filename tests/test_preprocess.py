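"""Zero-phase filtering, downsampling, channel repair and artifact rejection."""
import numpy as np
import pytest
from scipy import signal as sps

from doc_eeg.errors import DataQualityError, ParameterError
from doc_eeg.preprocess import (FilterSpec, PreprocessConfig, average_reference,
                                detect_bad_channels, downsample, fir_filter,
                                interpolate_channels, preprocess,
                                reject_artifact_segments)
from doc_eeg.spectral import BandDef, band_power_linear, multitaper_psd

from conftest import make_recording

TRIM = slice(2000, -2000)


class TestFIRFilter:
    def test_highpass_removes_dc(self):
        rec = make_recording(np.full((2, 20000), 10.0), fs=2000.0)
        out = fir_filter(rec, FilterSpec("highpass", 0.1, 3300))
        assert np.abs(out.data[:, TRIM]).max() < 1e-6 * 10.0

    def test_lowpass_preserves_passband_sinusoid(self):
        t = np.arange(6000) / 100.0
        x = np.sin(2 * np.pi * 10 * t)
        rec = make_recording(x, fs=100.0)
        out = fir_filter(rec, FilterSpec("lowpass", 45.0, 200))
        trim = slice(500, -500)
        ratio = np.abs(out.data[0, trim]).max() / np.abs(x[trim]).max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_lowpass_attenuates_stopband(self):
        t = np.arange(40000) / 2000.0
        x = np.sin(2 * np.pi * 60 * t)
        rec = make_recording(np.tile(x, (2, 1)), fs=2000.0)
        out = fir_filter(rec, FilterSpec("lowpass", 45.0, 500))
        rms_in = np.sqrt(np.mean(x[TRIM] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, TRIM] ** 2))
        assert 20 * np.log10(rms_out / rms_in) < -20

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = make_recording(np.zeros((2, 100)), fs=100.0)
        with pytest.raises(ParameterError):
            fir_filter(rec, FilterSpec("lowpass", 60.0, 50))

    def test_linearity(self, rng):
        a, b = 2.5, -1.3
        x = rng.standard_normal((2, 4000))
        y = rng.standard_normal((2, 4000))
        spec = FilterSpec("lowpass", 30.0, 100)
        fx = fir_filter(make_recording(x), spec).data
        fy = fir_filter(make_recording(y), spec).data
        fxy = fir_filter(make_recording(a * x + b * y), spec).data
        np.testing.assert_allclose(fxy, a * fx + b * fy, rtol=1e-9, atol=1e-9)

    def test_zero_phase_peak_at_lag_zero(self, rng):
        x = rng.standard_normal(8000)
        rec = make_recording(np.tile(x, (2, 1)), fs=100.0)
        out = fir_filter(rec, FilterSpec("lowpass", 20.0, 200)).data[0]
        xc = sps.correlate(out[1000:-1000], x[1000:-1000], mode="full")
        lag = np.argmax(xc) - (len(x) - 2000 - 1)
        assert lag == 0


class TestDownsample:
    def test_decimation_arithmetic(self, rng):
        rec = make_recording(rng.standard_normal((2, 120000)), fs=2000.0)
        out = downsample(rec, 100.0)
        assert out.fs == 100.0
        assert abs(out.n_samples - 6000) <= 1

    def test_band_power_preserved(self):
        t = np.arange(120000) / 2000.0
        x = np.sin(2 * np.pi * 10 * t)
        rec = make_recording(np.tile(x, (2, 1)), fs=2000.0)
        out = downsample(rec, 100.0)
        band = BandDef("alpha", 7, 12)
        before = band_power_linear(multitaper_psd(x, 2000.0), band)[0]
        after = band_power_linear(multitaper_psd(out.data[0], 100.0), band)[0]
        assert after == pytest.approx(before, rel=0.05)

    def test_identity_target_warns(self, noise_recording, caplog):
        with caplog.at_level("WARNING", logger="doc_eeg.preprocess"):
            out = downsample(noise_recording, 100.0)
        np.testing.assert_array_equal(out.data, noise_recording.data)
        assert any("no-op" in r.message for r in caplog.records)

    def test_upsampling_rejected(self, noise_recording):
        with pytest.raises(ParameterError):
            downsample(noise_recording, 200.0)


class TestBadChannels:
    def test_loud_channel_flagged(self, rng):
        data = rng.standard_normal((19, 5000))
        data[7] *= 100
        from doc_eeg.montage import CHANNELS_19
        rec = make_recording(data, channels=list(CHANNELS_19))
        assert detect_bad_channels(rec) == [CHANNELS_19[7]]

    def test_identical_statistics_no_flags(self, rng):
        from doc_eeg.montage import CHANNELS_19
        rec = make_recording(rng.standard_normal((19, 5000)),
                             channels=list(CHANNELS_19))
        assert detect_bad_channels(rec) == []

    def test_flat_channel_flagged(self, rng):
        data = rng.standard_normal((4, 1000))
        data[2] = 0.0
        rec = make_recording(data)
        assert detect_bad_channels(rec) == ["C3"]


class TestInterpolation:
    def test_mean_of_identical_neighbors(self, rng):
        s = np.sin(np.arange(1000) / 10.0)
        channels = ["C3", "F3", "P3", "Cz", "T3"]
        data = np.tile(s, (5, 1))
        data[0] = rng.standard_normal(1000) * 50  # corrupt C3
        rec = make_recording(data, channels=channels)
        out, interpolated, dropped = interpolate_channels(rec, ["C3"])
        assert interpolated == ["C3"] and not dropped
        np.testing.assert_allclose(out.channel("C3"), s, atol=1e-12)

    def test_mean_of_distinct_constants(self):
        channels = ["C3", "F3", "P3", "Cz", "T3"]
        data = np.stack([np.zeros(100), np.full(100, 2.0), np.full(100, 4.0),
                         np.full(100, 6.0), np.full(100, 8.0)])
        rec = make_recording(data, channels=channels)
        out, _, _ = interpolate_channels(rec, ["C3"])
        np.testing.assert_allclose(out.channel("C3"), 5.0)

    def test_no_bad_channels_is_identity(self, noise_recording):
        out, interpolated, dropped = interpolate_channels(noise_recording, [])
        np.testing.assert_array_equal(out.data, noise_recording.data)
        assert not interpolated and not dropped

    def test_isolated_channel_dropped(self, rng):
        rec = make_recording(rng.standard_normal((4, 500)),
                             channels=["O2", "F3", "F4", "Fz"])
        out, interpolated, dropped = interpolate_channels(rec, ["O2"])
        assert dropped == ["O2"] and "O2" not in out.channels


class TestArtifactRejection:
    def test_clean_recording_untouched(self, noise_recording):
        out, report = reject_artifact_segments(noise_recording)
        assert report.rejected_segments == []
        assert out.n_samples == noise_recording.n_samples

    def test_spike_excised_with_padding(self, rng):
        data = rng.standard_normal((2, 6000))
        data[0, 1000] = 500.0  # spike at t = 10 s
        rec = make_recording(data, fs=100.0)
        out, report = reject_artifact_segments(rec)
        assert len(report.rejected_segments) == 1
        start, end, reason = report.rejected_segments[0]
        assert start <= 10.0 <= end and reason == "amplitude"
        assert out.n_samples < rec.n_samples

    def test_everything_bad_is_quality_error(self):
        rec = make_recording(np.full((2, 1000), 200.0), fs=100.0)
        with pytest.raises(DataQualityError):
            reject_artifact_segments(rec)


class TestAverageReference:
    def test_zero_mean_pair_unchanged(self):
        rec = make_recording(np.stack([np.ones(100), -np.ones(100)]))
        out = average_reference(rec)
        np.testing.assert_allclose(out.data, rec.data)

    def test_identical_channels_become_zero(self):
        rec = make_recording(np.tile(np.sin(np.arange(100)), (3, 1)))
        assert np.abs(average_reference(rec).data).max() < 1e-12

    def test_columnwise_mean_zero_and_idempotent(self, noise_recording):
        out = average_reference(noise_recording)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(average_reference(out).data, out.data,
                                   atol=1e-12)


def test_full_chain_produces_report(rng):
    from doc_eeg.montage import CHANNELS_19
    data = rng.standard_normal((19, 40000)) * 20
    # sustained 400 uV artifact burst (a single-sample spike would be
    # legitimately smoothed below threshold by the 45 Hz low-pass)
    data[3, 20000:21000] += 400.0
    rec = make_recording(data, fs=2000.0, channels=list(CHANNELS_19))
    out, report = preprocess(rec, PreprocessConfig())
    assert out.fs == 100.0
    assert np.abs(out.data.mean(axis=0)).max() < 1e-9
    assert report.final_fs == 100.0
    assert report.bad_channels == []
    assert len(report.rejected_segments) == 1
    assert any("highpass" in a for a in report.actions)
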