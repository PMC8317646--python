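import numpy as np
import pytest

import eegstress as es

FS = 256.0


def sine(freq_hz, duration_s, amplitude=10.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestNotchFilter:
    def test_line_frequency_strongly_attenuated(self, make_recording):
        rec = make_recording(sine(50.0, 30.0))
        out = es.notch_filter(rec)
        core = slice(int(2 * FS), -int(2 * FS))  # skip filter edge transients
        ratio = rms(out.data[0, core]) / rms(rec.data[0, core])
        assert ratio < 0.10
        assert 20 * np.log10(ratio) < -20.0

    def test_eeg_passband_untouched(self, make_recording):
        rec = make_recording(sine(10.0, 30.0))
        out = es.notch_filter(rec)
        core = slice(int(2 * FS), -int(2 * FS))
        assert rms(out.data[0, core]) == pytest.approx(rms(rec.data[0, core]), rel=0.05)

    def test_zero_in_zero_out(self, make_recording):
        rec = make_recording(np.zeros(int(10 * FS)))
        assert np.allclose(es.notch_filter(rec).data, 0.0)

    def test_non_finite_input_rejected(self, make_recording):
        x = sine(10.0, 5.0)
        x[100] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            es.notch_filter(make_recording(x))


class TestBandpassFilter:
    @pytest.mark.parametrize("freq", [0.2, 60.0])
    def test_out_of_band_probes_attenuated(self, make_recording, freq):
        rec = make_recording(sine(freq, 60.0))
        out = es.bandpass_filter(rec)
        core = slice(int(10 * FS), -int(10 * FS))
        ratio = rms(out.data[0, core]) / rms(rec.data[0, core])
        assert ratio < 0.10

    @pytest.mark.parametrize("freq, min_db", [(1.0, 20.0), (60.0, 20.0)])
    def test_stopband_attenuation_at_least_20_db(self, make_recording, freq, min_db):
        rec = make_recording(sine(freq, 60.0))
        out = es.bandpass_filter(rec)
        core = slice(int(10 * FS), -int(10 * FS))
        ratio = rms(out.data[0, core]) / rms(rec.data[0, core])
        assert 20 * np.log10(ratio) < -min_db

    def test_zero_phase_on_in_band_probe(self, make_recording):
        rec = make_recording(sine(10.0, 10.0))
        out = es.bandpass_filter(rec)
        xc = np.correlate(out.data[0], rec.data[0], mode="full")
        lag = int(np.argmax(xc)) - (rec.n_samples - 1)
        assert lag == 0


class TestResample:
    def test_jittered_mist_recording_forced_to_nominal_count(self, make_recording):
        rec = make_recording(np.random.default_rng(0).normal(size=int(363 * FS)), nominal_s=360.0)
        out = es.resample_to_nominal(rec)
        assert out.n_samples == 92160

    def test_nominal_relax_count(self, make_recording):
        rec = make_recording(np.random.default_rng(0).normal(size=int(297 * FS)), nominal_s=300.0)
        assert es.resample_to_nominal(rec).n_samples == 76800

    def test_already_nominal_is_identity(self, make_recording):
        rec = make_recording(sine(10.0, 360.0), nominal_s=360.0)
        out = es.resample_to_nominal(rec)
        assert out.n_samples == rec.n_samples
        assert np.allclose(out.data, rec.data)

    def test_probe_tone_power_preserved(self, make_recording):
        rec = make_recording(sine(10.0, 363.0, amplitude=1.0), nominal_s=360.0)
        out = es.resample_to_nominal(rec)
        core_in = rec.data[0][int(5 * FS) : -int(5 * FS)]
        core_out = out.data[0][int(5 * FS) : -int(5 * FS)]
        assert np.var(core_out) == pytest.approx(np.var(core_in), rel=0.02)

    def test_length_far_from_nominal_rejected(self, make_recording):
        rec = make_recording(np.zeros(int(200 * FS)), nominal_s=360.0)
        with pytest.raises(ValueError, match="outside"):
            es.resample_to_nominal(rec)


class TestEpoching:
    @pytest.mark.parametrize("duration_s, expected", [(360.0, 180), (300.0, 150), (60.0, 30)])
    def test_per_phase_epoch_counts(self, make_recording, duration_s, expected):
        rec = make_recording(np.zeros(int(duration_s * FS)), nominal_s=duration_s)
        ep = es.epoch(rec)
        assert ep.n_epochs == expected
        assert ep.epochs.shape == (expected, 4, 512)

    def test_non_multiple_length_rejected(self, make_recording):
        rec = make_recording(np.zeros(700), nominal_s=700 / FS)
        with pytest.raises(ValueError, match="multiple"):
            es.epoch(rec)

    def test_epochs_partition_the_recording(self, make_recording):
        x = np.arange(int(10 * FS), dtype=float)
        ep = es.epoch(make_recording(x, nominal_s=10.0))
        assert np.array_equal(ep.epochs[:, 0, :].ravel(), x)


class TestCentralMinute:
    @pytest.mark.parametrize(
        "duration_s, start_s", [(120.0, 30.0), (100.0, 20.0), (60.0, 0.0)]
    )
    def test_centered_window(self, make_recording, duration_s, start_s):
        x = np.arange(int(duration_s * FS), dtype=float)
        out = es.extract_central_minute(make_recording(x, nominal_s=60.0))
        assert out.n_samples == int(60 * FS)
        assert out.data[0, 0] == start_s * FS

    def test_too_short_rejected(self, make_recording):
        rec = make_recording(np.zeros(int(30 * FS)), nominal_s=60.0)
        with pytest.raises(ValueError, match="central"):
            es.extract_central_minute(rec)


class TestOutlierRejection:
    def test_single_sample_exceedance_zeroes_whole_epoch(self, make_recording):
        rec = make_recording(np.zeros(int(10 * FS)), nominal_s=10.0)
        ep = es.epoch(rec)
        ep.epochs[2, 2, 100] = 80.0  # one sample on F5
        out = es.zero_outlier_epochs(ep)
        assert out.outlier_mask.tolist() == [False, False, True, False, False]
        assert np.all(out.epochs[2] == 0.0)

    def test_within_threshold_is_a_no_op(self, make_recording):
        rec = make_recording(sine(10.0, 10.0, amplitude=74.0), nominal_s=10.0)
        ep = es.epoch(rec)
        out = es.zero_outlier_epochs(ep)
        assert not out.outlier_mask.any()
        assert np.array_equal(out.epochs, ep.epochs)

    def test_recovers_exactly_the_injected_artifact_epochs(self, default_session, preprocessed, schedule):
        _, _, truth = default_session
        mask = np.concatenate([preprocessed[p.name].outlier_mask for p in schedule.phases])
        assert np.array_equal(np.flatnonzero(mask), truth.session_artifact_epochs)
        assert mask.sum() == len(truth.session_artifact_epochs) > 0

    def test_mask_monotone_in_threshold(self, default_session):
        _, recordings, _ = default_session
        rec = es.bandpass_filter(es.notch_filter(recordings[0]))
        ep = es.epoch(es.resample_to_nominal(rec))
        counts = [
            es.zero_outlier_epochs(ep, thr).outlier_mask.sum()
            for thr in (25.0, 50.0, 75.0, 100.0, 150.0, 200.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDetrendStandardize:
    def test_standardized_moments(self, preprocessed):
        ep = preprocessed["mist_test"]
        live = ~ep.outlier_mask
        means = ep.epochs[live].mean(axis=-1)
        sds = ep.epochs[live].std(axis=-1)
        assert np.abs(means).max() < 1e-9
        assert np.abs(sds - 1.0).max() < 1e-9

    def test_pure_ramp_is_degenerate(self, make_recording):
        t = np.arange(int(4 * FS), dtype=float)
        ep = es.epoch(make_recording(3.0 * t + 1.0, nominal_s=4.0))
        out = es.detrend_standardize(ep)
        assert out.outlier_mask.all()
        assert np.all(out.epochs == 0.0)

    def test_masked_epochs_stay_zero(self, make_recording):
        rec = make_recording(np.zeros(int(10 * FS)), nominal_s=10.0)
        ep = es.epoch(rec)
        ep.epochs[1, :, 50] = 90.0
        out = es.detrend_standardize(es.zero_outlier_epochs(ep))
        assert out.outlier_mask[1]
        assert np.all(out.epochs[1] == 0.0)

    def test_idempotent(self, preprocessed):
        ep = preprocessed["relax"]
        again = es.detrend_standardize(ep)
        assert np.allclose(again.epochs, ep.epochs, atol=1e-9)
        assert np.array_equal(again.outlier_mask, ep.outlier_mask)
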