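import numpy as np
import pytest

import eegstress as es
from eegstress.features import BAND_NAMES, FEATURE_COLUMNS

FS = 256.0
CH = ("Fp1", "Fp2", "F5", "F6")


def epochs_from(arrays, phase="mist_test"):
    """EpochArray from a list of (4, 512) or per-epoch 1-d signals."""
    eps = []
    for a in arrays:
        a = np.asarray(a, dtype=float)
        eps.append(np.tile(a, (4, 1)) if a.ndim == 1 else a)
    eps = np.stack(eps)
    return es.EpochArray(
        epochs=eps,
        outlier_mask=np.zeros(len(eps), dtype=bool),
        channels=CH,
        phase=phase,
    )


def tone(freq_hz, amplitude=1.0, n=512):
    t = np.arange(n) / FS
    return amplitude * np.sqrt(2) * np.sin(2 * np.pi * freq_hz * t)  # unit variance at A=1


class TestBandPowers:
    def test_zero_epoch_has_zero_power(self):
        p = es.epoch_band_powers(epochs_from([np.zeros(512)]))
        assert np.all(p == 0.0)

    def test_alpha_tone_lands_in_alpha_band(self):
        p = es.epoch_band_powers(epochs_from([tone(10.0)]))[0, 0]
        alpha = p[BAND_NAMES.index("Alpha")]
        for b, name in enumerate(BAND_NAMES):
            if name != "Alpha":
                assert alpha > 10 * p[b]

    def test_tone_band_power_matches_time_domain_variance(self):
        """Parseval oracle: integrated PSD of an in-band tone equals the
        epoch's time-domain power within 1%."""
        x = tone(10.0)
        p = es.epoch_band_powers(epochs_from([x]))[0, 0]
        assert p.sum() == pytest.approx(np.mean(x**2), rel=0.01)

    def test_white_noise_power_proportional_to_bandwidth(self):
        rng = np.random.default_rng(0)
        ep = epochs_from([rng.standard_normal((4, 512)) for _ in range(100)])
        p = es.epoch_band_powers(ep).mean(axis=(0, 1))  # per-band average
        # integration covers [low, high) at 0.5 Hz resolution
        widths = np.array([hi - 0.5 - lo for (_, lo, hi) in es.BANDS])
        per_hz = p / widths
        assert np.all(np.abs(per_hz / per_hz.mean() - 1.0) < 0.25)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scale_equivariance(self, c):
        x = np.random.default_rng(1).standard_normal((4, 512))
        p1 = es.epoch_band_powers(epochs_from([x]))
        p2 = es.epoch_band_powers(epochs_from([c * x]))
        assert np.allclose(p2, c**2 * p1, rtol=1e-9)


class TestCompositeFeatures:
    @pytest.mark.parametrize(
        "g, a, t, expected", [(1, 1, 1, 0.5), (0, 2, 3, 0.0), (2, 3, 1, 0.5), (1, 0, 0, 0.0)]
    )
    def test_relative_gamma(self, g, a, t, expected):
        assert es.relative_gamma(g, a, t) == pytest.approx(expected)

    @pytest.mark.parametrize("f6, f5, expected", [(3, 1, 2.0), (2, 2, 0.0), (1, 4, -3.0)])
    def test_alpha_asymmetry(self, f6, f5, expected):
        assert es.alpha_asymmetry(f6, f5) == pytest.approx(expected)

    def test_rg_invariant_and_aa_sign_preserved_under_scaling(self):
        x = np.random.default_rng(2).standard_normal((4, 512))
        fm1 = es.assemble_features(epochs_from([x]))
        fm2 = es.assemble_features(epochs_from([2.5 * x]))
        rg = FEATURE_COLUMNS.index("RG")
        aa = FEATURE_COLUMNS.index("AA")
        assert fm1.values[0, rg] == pytest.approx(fm2.values[0, rg], rel=1e-9)
        assert np.sign(fm1.values[0, aa]) == np.sign(fm2.values[0, aa])

    def test_lateralized_alpha_gain_yields_positive_asymmetry(self, schedule):
        cfg = es.SynthConfig(
            seed=6,
            line_noise_uv=0.0,
            artifact_prob=0.0,
            channel_band_gain={"F6": {"Alpha": 2.0}},
        )
        recordings, _ = es.simulate_session(schedule, cfg)
        fm = es.extract_session_features(recordings, schedule, es.RunConfig())
        aa = fm.values[~fm.mask, FEATURE_COLUMNS.index("AA")]
        assert (aa > 0).mean() >= 0.90


class TestAssembly:
    def test_identical_channels_average_to_single_channel(self):
        x = np.random.default_rng(3).standard_normal(512)
        ep = epochs_from([x])
        fm = es.assemble_features(ep)
        single = es.epoch_band_powers(ep)[0, 0]
        assert np.allclose(fm.values[0, :5], single)
        assert fm.values[0, FEATURE_COLUMNS.index("AA")] == pytest.approx(0.0, abs=1e-12)

    def test_nominal_session_is_360_by_7(self, session_features):
        assert session_features.values.shape == (360, 7)
        assert session_features.columns == FEATURE_COLUMNS
        assert np.all(session_features.values[:, :6] >= 0.0)  # powers and RG

    def test_zeroed_epoch_gives_all_zero_row(self):
        ep = epochs_from([np.zeros(512), tone(10.0)])
        ep.outlier_mask[0] = True
        fm = es.assemble_features(ep)
        assert np.all(fm.values[0] == 0.0)

    def test_missing_asymmetry_channel_rejected(self):
        ep = epochs_from([tone(10.0)])
        ep.channels = ("Fp1", "Fp2", "C3", "C4")
        with pytest.raises(ValueError, match="F[56]"):
            es.assemble_features(ep)


def flat_matrix(n, phase="mist_test", column=0, values=None):
    v = np.zeros((n, 7))
    if values is not None:
        v[:, column] = values
    return es.FeatureMatrix(
        values=v,
        phase=np.full(n, phase, dtype=object),
        epoch_start_s=np.arange(n) * 2.0,
        mask=np.zeros(n, dtype=bool),
    )


class TestSmoothing:
    def test_constant_column_unchanged(self):
        fm = flat_matrix(100, values=np.full(100, 3.3))
        out = es.smooth_features(fm)
        assert np.allclose(out.values, fm.values)

    def test_single_epoch_window_is_identity(self):
        vals = np.random.default_rng(4).random(50)
        fm = flat_matrix(50, values=vals)
        out = es.smooth_features(fm, window_s=2.0)
        assert np.allclose(out.values[:, 0], vals)

    def test_impulse_response_matches_direct_convolution(self):
        imp = np.zeros(180)
        imp[50] = 1.0
        fm = flat_matrix(180, values=imp)
        out = es.smooth_features(fm, window_s=30.0)
        oracle = np.convolve(imp, np.ones(15) / 15, mode="same")
        assert np.allclose(out.values[:, 0], oracle, atol=1e-12)
        assert np.allclose(out.values[43:58, 0], 1.0 / 15)
        assert np.all(out.values[:43, 0] == 0.0) and np.all(out.values[58:, 0] == 0.0)

    def test_interior_support_preserves_column_sum(self):
        imp = np.zeros(180)
        imp[90] = 1.0
        out = es.smooth_features(flat_matrix(180, values=imp), window_s=30.0)
        assert out.values[:, 0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_smoothing_respects_phase_boundaries(self):
        v = np.zeros((60, 7))
        v[29, 0] = 1.0  # last epoch of the first phase
        phases = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        fm = es.FeatureMatrix(v, phases, np.arange(60) * 2.0, np.zeros(60, bool))
        out = es.smooth_features(fm, window_s=30.0)
        assert np.all(out.values[30:, 0] == 0.0)  # nothing leaks into phase b

    def test_subepoch_window_rejected(self, session_features):
        with pytest.raises(ValueError, match="window"):
            es.smooth_features(session_features, window_s=0.5)
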