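import numpy as np
import pandas as pd
import pytest

from sfica import features as F
from sfica.simulate import make_audio

FS = 4000.0


@pytest.fixture(scope="module")
def am4():
    return make_audio("amplitude-modulated-noise", 3.0, fs=FS, seed=1,
                      rate=4.0)


@pytest.fixture(scope="module")
def white():
    return make_audio("amplitude-modulated-noise", 3.0, fs=FS, seed=1,
                      depth=0.0)


class TestFrameAudio:
    def test_one_frame_per_second(self):
        wave = np.random.default_rng(0).standard_normal(int(512 * 100))
        assert F.frame_audio(wave, fs=100.0).shape[0] == 512

    def test_three_second_audio_gives_three_frames(self):
        frames = F.frame_audio(np.ones(int(3 * FS)), fs=FS)
        assert frames.shape == (3, int(3 * FS))

    def test_hop_is_exactly_one_second(self):
        # a lone impulse moves backward one second per successive frame
        wave = np.zeros(int(10 * FS))
        wave[int(5.5 * FS)] = 1.0
        frames = F.frame_audio(wave, fs=FS)
        pos5 = np.argmax(np.abs(frames[5]))
        pos6 = np.argmax(np.abs(frames[6]))
        assert pos5 - pos6 == int(FS)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            F.frame_audio(np.array([]), fs=FS)


class TestFluctuation:
    def test_silence_gives_zero_spectrum(self):
        _, spec = F.fluctuation_spectrum(np.zeros(int(3 * FS)), FS)
        assert not spec.any()

    def test_am_noise_peaks_at_modulation_rate(self, am4):
        freqs, spec = F.fluctuation_spectrum(am4, FS)
        assert abs(freqs[np.argmax(spec)] - 4.0) <= 0.5

    def test_unmodulated_noise_is_flatter(self, am4, white):
        _, s_am = F.fluctuation_spectrum(am4, FS)
        _, s_wn = F.fluctuation_spectrum(white, FS)
        assert F.fluctuation_entropy(s_wn) > F.fluctuation_entropy(s_am)

    def test_centroid_single_bin(self):
        freqs = np.array([0.0, 2.0, 4.0, 6.0])
        spec = np.array([0.0, 0.0, 5.0, 0.0])
        assert F.fluctuation_centroid(spec, freqs) == 4.0
        assert F.fluctuation_entropy(spec) == 0.0

    def test_entropy_uniform_is_log_k(self):
        assert np.isclose(F.fluctuation_entropy(np.ones(100)), np.log(100))

    def test_centroid_symmetry(self):
        freqs = np.array([2.0, 4.0, 6.0])
        assert F.fluctuation_centroid(np.array([1.0, 0.0, 1.0]), freqs) == 4.0

    def test_zero_spectrum_conventions(self):
        assert F.fluctuation_centroid(np.zeros(4), np.arange(4)) == 0.0
        assert F.fluctuation_entropy(np.zeros(4)) == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            F.fluctuation_centroid(np.array([-1.0, 1.0]), np.arange(2))
        with pytest.raises(ValueError):
            F.fluctuation_entropy(np.array([-1.0, 1.0]))


class TestKeyMode:
    def test_profile_correlates_perfectly_with_itself(self):
        kc, mode = F.key_mode_from_chroma(F._KK_MAJOR)
        assert np.isclose(kc, 1.0)
        assert mode > 0

    def test_major_fixture_has_positive_mode(self):
        kt = make_audio("key-tones", 3.0, fs=FS, key="C", mode="major")
        kc, mode = F.key_mode(kt, FS)
        assert mode > 0.1 and kc > 0.9

    def test_minor_fixture_has_negative_mode(self):
        km = make_audio("key-tones", 3.0, fs=FS, key="A", mode="minor")
        _, mode = F.key_mode(km, FS)
        assert mode < -0.1

    def test_noise_is_less_tonally_clear(self, white):
        kt = make_audio("key-tones", 3.0, fs=FS)
        assert F.key_mode(white, FS)[0] < F.key_mode(kt, FS)[0]

    def test_silence_gives_zero(self):
        assert F.key_mode(np.zeros(int(FS)), FS) == (0.0, 0.0)


class TestPulseClarity:
    def test_click_track_peaks_at_beat_period(self):
        ct = make_audio("click-track", 3.0, fs=FS, bpm=120, seed=2)
        _, lag = F.pulse_clarity(ct, FS, return_lag=True)
        assert abs(lag - 0.5) <= 0.05

    def test_silence_is_zero(self):
        assert F.pulse_clarity(np.zeros(int(3 * FS)), FS) == 0.0

    def test_clicks_beat_noise(self, white):
        ct = make_audio("click-track", 3.0, fs=FS, bpm=120, seed=2)
        assert F.pulse_clarity(ct, FS) > F.pulse_clarity(white, FS)


class TestGainInvariance:
    def test_all_features_ignore_global_gain(self, am4):
        a = F.extract_features(am4, FS)
        b = F.extract_features(10.0 * am4, FS)
        assert np.allclose(a.series, b.series, atol=1e-6)


class TestFeatureCsv:
    def test_roundtrip(self, tmp_path):
        fs = F.FeatureSet(names=F.FEATURE_NAMES,
                          series=np.arange(5 * 512.0).reshape(5, 512))
        path = tmp_path / "feats.csv"
        F.save_features_csv(path, fs)
        loaded = F.load_features_csv(path)
        assert loaded.n_samples == 512
        assert np.allclose(loaded.series, fs.series)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(F.FEATURE_NAMES) + "\n")
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            F.load_features_csv(path)

    def test_unknown_column_named_in_error(self, tmp_path):
        df = pd.DataFrame(np.zeros((3, 6)),
                          columns=list(F.FEATURE_NAMES) + ["Tempo"])
        path = tmp_path / "extra.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Tempo"):
            F.load_features_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        df = pd.DataFrame(np.zeros((3, 4)),
                          columns=list(F.FEATURE_NAMES[:4]))
        path = tmp_path / "missing.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            F.load_features_csv(path)

    def test_nan_cell_rejected(self, tmp_path):
        arr = np.zeros((3, 5))
        arr[1, 2] = np.nan
        df = pd.DataFrame(arr, columns=list(F.FEATURE_NAMES))
        path = tmp_path / "nan.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="NaN"):
            F.load_features_csv(path)
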