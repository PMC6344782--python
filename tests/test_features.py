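import numpy as np
import pytest

from cryseg.emd import SiftConfig, decompose
from cryseg.features import (
    FEATURE_DIM, LOG_FLOOR, MelFilterbank, emd_mfcc, fft_mfcc, hz_to_mel,
    mel_band_weights, mel_filterbank, mel_to_hz, we_dct, we_dct_core,
)
from cryseg.signal_io import AudioRecord, FrameSpec, frame_signal
from cryseg.wpt import SubbandEnergies, WaveletSpec, band_edges_hz, packet_tree, subband_energies


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert hz_to_mel(0.0) == 0.0

    def test_700hz_value(self):
        assert float(hz_to_mel(700.0)) == pytest.approx(2595.0 * np.log10(2.0), abs=1e-9)

    def test_strictly_increasing_and_invertible(self):
        f = np.linspace(0, 22050, 500)
        m = hz_to_mel(f)
        assert np.all(np.diff(m) > 0)
        assert np.allclose(mel_to_hz(m), f, rtol=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)


class TestMelFilterbank:
    def test_weights_nonnegative_and_cover_midband(self):
        fb = mel_filterbank(44100, 2048)
        assert np.all(fb.weights >= 0)
        coverage = fb.weights.sum(axis=0)
        assert np.all(coverage[10:-10] > 0)

    def test_peaks_equally_spaced_in_mel(self):
        fb = mel_filterbank(16000, 1024, n_filters=20)
        bin_hz = np.arange(513) * 16000 / 1024
        peaks_mel = np.asarray(hz_to_mel(bin_hz[np.argmax(fb.weights, axis=1)]))
        spacing = np.diff(peaks_mel)
        assert np.std(spacing) < 0.15 * np.mean(spacing)


def _frames_of(x, rate=16000, window_s=0.032):
    return frame_signal(AudioRecord(x, rate, "t"), FrameSpec(window_s=window_s))


class TestFftMfcc:
    def test_width_13_and_finite(self, rng):
        feats = fft_mfcc(_frames_of(rng.standard_normal(16000)))
        assert feats.vectors.shape[1] == FEATURE_DIM
        assert np.all(np.isfinite(feats.vectors))

    def test_zero_signal_finite_with_floor_energy(self):
        feats = fft_mfcc(_frames_of(np.zeros(16000)))
        assert np.all(np.isfinite(feats.vectors))
        assert np.allclose(feats.vectors[:, :12], 0.0, atol=1e-9)
        assert np.allclose(feats.vectors[:, 12], np.log(LOG_FLOOR))

    def test_scaling_leaves_cepstra_invariant(self, rng):
        x = rng.standard_normal(16000)
        f1 = fft_mfcc(_frames_of(x))
        f2 = fft_mfcc(_frames_of(10.0 * x))
        assert np.allclose(f1.vectors[:, :12], f2.vectors[:, :12], atol=1e-8)
        assert np.allclose(f2.vectors[:, 12] - f1.vectors[:, 12], 2 * np.log(10.0))

    def test_hop_shift_leaves_noise_statistics_stable(self, rng):
        # stationary noise: starting one hop later must not move the
        # per-frame feature statistics appreciably
        x = rng.standard_normal(32000)
        hop = FrameSpec(window_s=0.032).hop(16000)
        m1 = fft_mfcc(_frames_of(x[:-hop])).vectors.mean(axis=0)
        m2 = fft_mfcc(_frames_of(x[hop:])).vectors.mean(axis=0)
        assert np.linalg.norm(m1 - m2) < 0.3

    def test_tone_and_noise_separate(self, rng):
        t = np.arange(16000) / 16000
        tone = fft_mfcc(_frames_of(np.sin(2 * np.pi * 500 * t))).vectors.mean(axis=0)
        noise = fft_mfcc(_frames_of(rng.standard_normal(16000))).vectors.mean(axis=0)
        assert np.linalg.norm(tone[:12] - noise[:12]) > 1.0


class TestWeDct:
    def test_zero_energies_give_zero(self):
        out = we_dct_core(np.zeros(32))
        assert np.allclose(out, 0.0)

    def test_constant_energies_give_zero_nonzero_terms(self):
        out = we_dct_core(np.full(32, 7.5))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_single_band_hand_value(self):
        s = np.zeros(32)
        s[0] = 9.0                     # log10(9 + 1) = 1
        out = we_dct_core(s)
        n = np.arange(1, 13)
        assert np.allclose(out, np.cos(n * 0.5 * np.pi / 32), atol=1e-12)

    def test_bound_on_magnitude(self, rng):
        s = rng.uniform(0, 100, 32)
        out = we_dct_core(s)
        assert np.all(np.abs(out) <= 32 * np.log10(1 + s.max()) + 1e-9)

    def test_full_vector_is_13_dim(self, rng):
        e = SubbandEnergies(energies=rng.uniform(0, 1, 32))
        edges = band_edges_hz(WaveletSpec("db10", 5), 44100)
        vec = we_dct(e, mel_weights=mel_band_weights(edges))
        assert vec.shape == (13,) and np.all(np.isfinite(vec))

    def test_mel_band_weights_rows_cover_all_triangles(self):
        edges = band_edges_hz(WaveletSpec("db10", 5), 44100)
        w = mel_band_weights(edges)
        assert w.shape == (32, 32)
        assert np.all(w >= 0)
        assert np.all(w.sum(axis=1) > 0)   # no triangle falls between bands


class TestFeatureMatrixIO:
    @pytest.fixture()
    def feats(self, rng):
        return fft_mfcc(_frames_of(rng.standard_normal(16000)))

    def test_text_roundtrip(self, feats, tmp_path):
        p = tmp_path / "f.tsv"
        feats.save_text(p)
        back = type(feats).load_text(p)
        assert back.feature_kind == feats.feature_kind
        assert np.allclose(back.vectors, feats.vectors, rtol=1e-10)
        assert np.allclose(back.frame_start_s, feats.frame_start_s, rtol=1e-10)

    def test_npz_roundtrip_exact(self, feats, tmp_path):
        p = tmp_path / "f.npz"
        feats.save_npz(p)
        back = type(feats).load_npz(p)
        assert back.feature_kind == feats.feature_kind
        assert np.array_equal(back.vectors, feats.vectors)
        assert np.array_equal(back.frame_start_s, feats.frame_start_s)


@pytest.fixture(scope="module")
def record():
    rng = np.random.default_rng(3)
    fs = 8000
    t = np.arange(4 * fs) / fs
    x = (np.sin(2 * np.pi * 900 * t) + 0.7 * np.sin(2 * np.pi * 180 * t)
         + 0.4 * np.sin(2 * np.pi * 40 * t) + 0.05 * rng.standard_normal(t.size))
    return AudioRecord(x, fs, "emdtest")


class TestEmdMfcc:

    def test_width_13_for_every_set(self, record):
        d = decompose(record.samples, SiftConfig())
        if d.n_imfs < 5:
            pytest.skip("fixture produced fewer than 5 IMFs")
        for name in ("IMF34", "IMF45", "IMF234", "IMF345"):
            feats = emd_mfcc(record, name, FrameSpec(window_s=0.032), decomposition=d)
            assert feats.vectors.shape[1] == FEATURE_DIM
            assert feats.feature_kind == f"EMD_MFCC({name})"

    def test_uses_only_selected_imfs(self, record):
        from cryseg.emd import combine_imfs
        d = decompose(record.samples, SiftConfig())
        if d.n_imfs < 5:
            pytest.skip("fixture produced fewer than 5 IMFs")
        combined = combine_imfs(d, "IMF345")
        direct = fft_mfcc(frame_signal(
            AudioRecord(combined, record.rate, "c"), FrameSpec(window_s=0.032)))
        via = emd_mfcc(record, "IMF345", FrameSpec(window_s=0.032), decomposition=d)
        assert np.allclose(via.vectors, direct.vectors)

    def test_deficit_error_names_count(self, record):
        d = decompose(record.samples, SiftConfig(max_imfs=2))
        with pytest.raises(ValueError, match="2"):
            emd_mfcc(record, "IMF345", FrameSpec(window_s=0.032), decomposition=d)

    def test_unknown_set_rejected(self, record):
        with pytest.raises(ValueError, match="IMF9"):
            emd_mfcc(record, "IMF9", FrameSpec(window_s=0.032))
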