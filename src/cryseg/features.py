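"""13-dimensional cepstral feature vectors for cry-frame classification.

Three front-ends produce the same vector shape (12 cepstra + log-energy):

``fft_mfcc``
    Classic Mel-frequency cepstral coefficients: Hamming window, power
    spectrum, triangular Mel filterbank, log, DCT-II, keep c_1..c_12.
``we_dct``
    Wavelet-energy cepstra: Mel-weighted aggregation S_p of the 2^level
    wavelet-packet sub-band energies, then
    WE_DCT(n) = sum_p log10(S_p + 1) * cos[n (p + 1/2) pi / B].
    The ``+1`` inside the log keeps every term nonnegative for S_p >= 0.
``emd_mfcc``
    MFCCs of a reconstructed IMF combination (e.g. IMF3+IMF4+IMF5)
    instead of the raw signal: the whole recording (or segment) is
    decomposed once by EMD, the selected IMFs are summed, and the sum is
    framed and run through the MFCC front-end.

The Mel scale is Mel(f) = 2595 * log10(1 + f / 700).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

from cryseg import emd as emd_mod
from cryseg.signal_io import AudioRecord, FrameMatrix, FrameSpec, frame_signal, hamming_window
from cryseg.wpt import SubbandEnergies

__all__ = [
    "MelFilterbank", "FeatureMatrix",
    "hz_to_mel", "mel_to_hz", "mel_filterbank",
    "fft_mfcc", "we_dct", "mel_band_weights", "emd_mfcc",
]

#: Floor applied before every log to keep silent frames finite.
LOG_FLOOR = 1e-10

#: Number of cepstral coefficients kept (c_1..c_12) plus one energy term.
N_CEPSTRA = 12
FEATURE_DIM = N_CEPSTRA + 1


def hz_to_mel(f) -> np.ndarray:
    """Mel(f) = 2595 * log10(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


@dataclass
class MelFilterbank:
    """Triangular filters with peaks equally spaced on the Mel scale."""

    n_filters: int
    fft_size: int
    rate: float
    weights: np.ndarray  # (n_filters, fft_size//2 + 1)


def mel_filterbank(rate: float, fft_size: int, n_filters: int = 24) -> MelFilterbank:
    """Standard triangular Mel filterbank over [0, rate/2]."""
    edges_mel = np.linspace(0.0, float(hz_to_mel(rate / 2.0)), n_filters + 2)
    edges_hz = mel_to_hz(edges_mel)
    bin_hz = np.arange(fft_size // 2 + 1) * rate / fft_size
    weights = np.zeros((n_filters, bin_hz.size))
    for i in range(n_filters):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (bin_hz - lo) / max(mid - lo, 1e-12)
        down = (hi - bin_hz) / max(hi - mid, 1e-12)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
    return MelFilterbank(n_filters=n_filters, fft_size=fft_size, rate=rate, weights=weights)


@dataclass
class FeatureMatrix:
    """Per-frame feature vectors (frame_count x 13) with timing metadata."""

    vectors: np.ndarray
    frame_start_s: np.ndarray
    feature_kind: str

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    def save_text(self, path) -> None:
        """Tabular text: one frame per row, start_s then the 13 features."""
        header = f"{self.feature_kind}\nstart_s\t" + "\t".join(
            f"c{i}" for i in range(1, self.vectors.shape[1])) + "\tlog_energy"
        np.savetxt(path, np.column_stack([self.frame_start_s, self.vectors]),
                   fmt="%.12g", delimiter="\t", header=header)

    @classmethod
    def load_text(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            kind = fh.readline().lstrip("# ").strip()
        data = np.loadtxt(path, delimiter="\t", skiprows=2, ndmin=2)
        return cls(vectors=data[:, 1:], frame_start_s=data[:, 0], feature_kind=kind)

    def save_npz(self, path) -> None:
        np.savez(path, vectors=self.vectors, frame_start_s=self.frame_start_s,
                 feature_kind=np.array(self.feature_kind))

    @classmethod
    def load_npz(cls, path) -> "FeatureMatrix":
        with np.load(path) as z:
            return cls(vectors=z["vectors"], frame_start_s=z["frame_start_s"],
                       feature_kind=str(z["feature_kind"]))


def default_fft_size(samples_per_frame: int) -> int:
    """Next power of two >= the frame length."""
    return 1 << int(np.ceil(np.log2(samples_per_frame)))


def fft_mfcc(frames: FrameMatrix, fb: MelFilterbank | None = None,
             n_cepstra: int = N_CEPSTRA) -> FeatureMatrix:
    """MFCC front-end: Hamming window -> power spectrum -> Mel energies
    -> log -> DCT-II (orthonormal); keep c_1..c_K plus log frame energy.

    The DC cepstrum c_0 is excluded: it carries overall level, which the
    separate log-energy term already represents.
    """
    if fb is None:
        fb = mel_filterbank(frames.rate, default_fft_size(frames.samples_per_frame))
    if fb.rate != frames.rate:
        raise ValueError("filterbank rate does not match frame rate")
    win = hamming_window(frames.samples_per_frame)
    windowed = frames.frames * win[None, :]
    spec = rfft(windowed, n=fb.fft_size, axis=1)
    power = np.abs(spec) ** 2
    mel_e = power @ fb.weights.T
    log_mel = np.log(np.maximum(mel_e, LOG_FLOOR))
    ceps = dct(log_mel, type=2, norm="ortho", axis=1)
    energy = np.log(np.maximum(np.sum(frames.frames**2, axis=1), LOG_FLOOR))
    vectors = np.hstack([ceps[:, 1:n_cepstra + 1], energy[:, None]])
    return FeatureMatrix(vectors=vectors, frame_start_s=frames.frame_start_s.copy(),
                         feature_kind="FFT_MFCC")


def mel_band_weights(band_edges_hz: np.ndarray, n_filters: int | None = None) -> np.ndarray:
    """Mel-triangle aggregation weights over uniform sub-bands.

    Row p gives the average value of the p-th Mel triangle over each
    uniform band interval (overlap integral / band width), so every
    triangle contributes to the bands it overlaps even when it is
    narrower than one band.
    """
    band_edges_hz = np.asarray(band_edges_hz, dtype=np.float64)
    n_bands = band_edges_hz.size - 1
    if n_filters is None:
        n_filters = n_bands
    f_max = band_edges_hz[-1]
    tri_mel = np.linspace(0.0, float(hz_to_mel(f_max)), n_filters + 2)
    tri_hz = mel_to_hz(tri_mel)
    weights = np.zeros((n_filters, n_bands))
    for p in range(n_filters):
        lo, mid, hi = tri_hz[p], tri_hz[p + 1], tri_hz[p + 2]
        for j in range(n_bands):
            a, b = band_edges_hz[j], band_edges_hz[j + 1]
            weights[p, j] = _triangle_average(lo, mid, hi, a, b)
    return weights


def _triangle_average(lo: float, mid: float, hi: float, a: float, b: float) -> float:
    """Average of the (lo, mid, hi) unit triangle over [a, b]."""
    def integral(x0, x1, y0, y1, u, v):
        # integral of the line through (x0,y0)-(x1,y1) over [u, v]
        u, v = max(u, x0), min(v, x1)
        if v <= u or x1 <= x0:
            return 0.0
        slope = (y1 - y0) / (x1 - x0)
        ym = y0 + slope * ((u + v) / 2.0 - x0)
        return ym * (v - u)

    total = integral(lo, mid, 0.0, 1.0, a, b) + integral(mid, hi, 1.0, 0.0, a, b)
    return total / max(b - a, 1e-12)


def we_dct_core(s: np.ndarray, n_cepstra: int = N_CEPSTRA) -> np.ndarray:
    """WE_DCT(n) = sum_p log10(S_p + 1) cos[n (p + 1/2) pi / B], n=1..K."""
    s = np.asarray(s, dtype=np.float64)
    b = s.size
    logs = np.log10(s + 1.0)
    n = np.arange(1, n_cepstra + 1)[:, None]
    p = np.arange(b)[None, :]
    kernel = np.cos(n * (p + 0.5) * np.pi / b)
    return kernel @ logs


def we_dct(energies: SubbandEnergies, mel_weights: np.ndarray | None = None,
           n_cepstra: int = N_CEPSTRA) -> np.ndarray:
    """13-vector from one frame's wavelet sub-band energies.

    S_p is the Mel-weighted aggregation of the raw band energies (rows of
    ``mel_weights``); the 13th component is the log of the total sub-band
    energy.
    """
    e = energies.energies
    if mel_weights is not None:
        s = mel_weights @ e
    else:
        s = e
    coeffs = we_dct_core(s, n_cepstra=n_cepstra)
    energy = np.log(np.maximum(np.sum(e), LOG_FLOOR))
    return np.concatenate([coeffs, [energy]])


def emd_mfcc(record: AudioRecord, set_name: str, spec: FrameSpec,
             fb: MelFilterbank | None = None,
             sift_cfg: emd_mod.SiftConfig | None = None,
             decomposition: emd_mod.IMFDecomposition | None = None) -> FeatureMatrix:
    """MFCCs of an IMF combination of a whole recording or segment.

    The signal is EMD-decomposed once (pass ``decomposition`` to reuse a
    cached one), the preset IMF set is summed, and the summed signal is
    framed and sent through :func:`fft_mfcc`.
    """
    if set_name not in emd_mod.IMF_SETS:
        raise ValueError(f"unknown IMF set {set_name!r}")
    d = decomposition
    if d is None:
        d = emd_mod.decompose(record.samples, sift_cfg)
    needed = max(emd_mod.IMF_SETS[set_name])
    if d.n_imfs < needed:
        raise ValueError(
            f"IMF set {set_name} needs {needed} IMFs but the decomposition "
            f"produced only {d.n_imfs}"
        )
    combined = emd_mod.combine_imfs(d, set_name)
    frames = frame_signal(AudioRecord(samples=combined, rate=record.rate,
                                      source_id=record.source_id), spec)
    feats = fft_mfcc(frames, fb)
    feats.feature_kind = f"EMD_MFCC({set_name})"
    return feats
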