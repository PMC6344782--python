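"""Synthetic labeled cry corpora.

Real newborn cry corpora are clinical recordings and rarely shareable,
so this module generates recordings with the acoustic *structure* the
segmentation systems must separate:

* **EXP** — voiced expiratory phases: a harmonic source with a high
  fundamental (350-600 Hz, slow vibrato), low-pass spectral tilt over
  8 harmonics, an attack/decay amplitude envelope and a little additive
  noise.  Durations 0.3-2.0 s.
* **INS** — audible inspirations: short (0.1-0.6 s), breathy, high-
  frequency-weighted noise (spectral centroid above ~2 kHz) with only a
  weak harmonic component (harmonic-to-noise ratio <= 0 dB).
* **OTHER** — heterogeneous non-cry material: silence, pink-ish noise,
  a low-pitched amplitude-modulated speech-like buzz (f0 100-200 Hz,
  below any EXP fundamental), and pure-tone machine beeps.

A recording is a gap-free concatenation of such segments (inspiration
usually directly follows an expiration, mimicking the natural alternating
cry pattern) with an exact ground-truth label track.  The ``realistic``
difficulty adds babble-like background noise at 10 dB SNR over the whole
recording; ``separable`` leaves segments clean.

All parameter ranges are fixture constants chosen to be plausible for
newborn cries; they are design choices of this generator, not measured
corpus statistics.  All randomness flows through one seeded generator
per corpus, so a corpus is bit-reproducible from its spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt

from cryseg.signal_io import AudioRecord, LabelTrack

__all__ = ["CorpusSpec", "gen_expiration", "gen_inspiration", "gen_other",
           "gen_recording", "gen_corpus"]

#: Default expected fraction of recording time per class.  Expiration
#: dominates audible cry time and inspirations are brief, as in real
#: cry recordings; "other" fills the rest.
DEFAULT_CLASS_MIX = {"EXP": 0.45, "INS": 0.10, "OTHER": 0.45}


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one generated corpus."""

    n_recordings: int = 20
    rate: float = 44100.0
    duration_s: float = 10.0
    class_mix: tuple = (0.45, 0.10, 0.45)      # EXP, INS, OTHER time fractions
    difficulty: str = "separable"              # separable | realistic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recordings < 1 or self.duration_s <= 0 or self.rate <= 0:
            raise ValueError("n_recordings, duration_s and rate must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise ValueError("class_mix must be nonnegative and sum to 1")
        if self.difficulty not in ("separable", "realistic"):
            raise ValueError("difficulty must be 'separable' or 'realistic'")


def _envelope(n: int, attack_frac: float, decay_frac: float) -> np.ndarray:
    a = max(1, int(attack_frac * n))
    d = max(1, int(decay_frac * n))
    env = np.ones(n)
    env[:a] = np.linspace(0.0, 1.0, a)
    env[n - d:] = np.linspace(1.0, 0.0, d)
    return env


def gen_expiration(duration_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Voiced, harmonic, high-pitched expiratory phase."""
    if not 0.3 <= duration_s <= 2.0:
        raise ValueError("expiration duration must be in [0.3, 2.0] s")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    f0 = rng.uniform(350.0, 600.0)
    vib_rate = rng.uniform(4.0, 7.0)
    vib_depth = rng.uniform(0.01, 0.03)
    inst_f0 = f0 * (1.0 + vib_depth * np.sin(2 * np.pi * vib_rate * t + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(inst_f0) / rate
    x = np.zeros(n)
    for h in range(1, 9):                      # 8 harmonics, low-pass tilt
        if h * f0 * 1.1 >= rate / 2:
            break
        amp = h ** -1.2
        x += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    x *= _envelope(n, attack_frac=0.12, decay_frac=0.20)
    x /= max(np.max(np.abs(x)), 1e-12)
    snr_db = rng.uniform(25.0, 35.0)
    noise = rng.standard_normal(n)
    noise *= np.sqrt(np.mean(x**2)) / np.sqrt(np.mean(noise**2)) * 10 ** (-snr_db / 20)
    return 0.6 * (x + noise)


def gen_inspiration(duration_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Short, breathy, high-frequency-weighted inspiratory phase."""
    if not 0.1 <= duration_s <= 0.6:
        raise ValueError("inspiration duration must be in [0.1, 0.6] s")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    noise = rng.standard_normal(n)
    sos = butter(4, min(2500.0, 0.45 * rate), btype="highpass", fs=rate, output="sos")
    breath = sosfilt(sos, noise)
    breath /= max(np.sqrt(np.mean(breath**2)), 1e-12)
    f0 = rng.uniform(400.0, 700.0)
    harm = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(4 * np.pi * f0 * t)
    harm /= max(np.sqrt(np.mean(harm**2)), 1e-12)
    hnr_db = rng.uniform(-8.0, -2.0)           # harmonic part stays below the noise
    x = breath + harm * 10 ** (hnr_db / 20)
    x *= _envelope(n, attack_frac=0.25, decay_frac=0.30)
    peak = max(np.max(np.abs(x)), 1e-12)
    return 0.35 * x / peak


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.maximum(np.fft.rfftfreq(n), 1.0 / n)
    spec /= np.sqrt(freqs / freqs[1])
    x = np.fft.irfft(spec, n)
    return x / max(np.max(np.abs(x)), 1e-12)


def gen_other(duration_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Non-cry material: silence, pink noise, speech-like buzz, or a beep."""
    if duration_s < 0.1:
        raise ValueError("other segments must last >= 0.1 s")
    n = int(round(duration_s * rate))
    kind = rng.choice(["silence", "noise", "buzz", "beep"])
    if kind == "silence":
        return 1e-5 * rng.standard_normal(n)
    if kind == "noise":
        return 0.2 * _pink_noise(n, rng)
    t = np.arange(n) / rate
    if kind == "buzz":
        f0 = rng.uniform(100.0, 200.0)         # below any EXP fundamental
        x = sum(h ** -1.0 * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
                for h in range(1, 7))
        am = 0.5 * (1.0 + np.sin(2 * np.pi * rng.uniform(2.0, 6.0) * t))
        x = x * am
        return 0.3 * x / max(np.max(np.abs(x)), 1e-12)
    freq = rng.uniform(800.0, 3000.0)          # beep
    x = np.sin(2 * np.pi * freq * t) * _envelope(n, 0.05, 0.05)
    return 0.3 * x


def gen_recording(spec: CorpusSpec, rng: np.random.Generator,
                  source_id: str = "synthetic") -> tuple[AudioRecord, LabelTrack]:
    """One gap-free recording of alternating EXP / INS / OTHER segments."""
    rate = spec.rate
    total_n = int(round(spec.duration_s * rate))
    target = dict(zip(("EXP", "INS", "OTHER"), spec.class_mix))
    chunks: list[np.ndarray] = []
    segments: list[tuple[float, float, str]] = []
    elapsed = dict.fromkeys(target, 0.0)
    cursor = 0

    def append(label: str, signal: np.ndarray) -> None:
        nonlocal cursor
        chunks.append(signal)
        start, end = cursor / rate, (cursor + signal.size) / rate
        segments.append((start, end, label))
        elapsed[label] += signal.size / rate
        cursor += signal.size

    while cursor < total_n:
        remaining_s = (total_n - cursor) / rate
        total_elapsed = max(sum(elapsed.values()), 1e-9)
        # pick the class furthest behind its target time share
        deficit = {c: target[c] - elapsed[c] / total_elapsed for c in target}
        label = max(deficit, key=lambda c: (deficit[c], c == "OTHER"))
        if label == "EXP" and remaining_s >= 0.35:
            dur = min(rng.uniform(0.5, 1.6), 2.0, remaining_s)
            dur = max(dur, 0.3)
            append("EXP", gen_expiration(dur, rate, rng))
            # inspiration usually follows an expiration directly
            rem = (total_n - cursor) / rate
            if rem >= 0.12 and rng.uniform() < 0.8:
                dur = min(rng.uniform(0.15, 0.45), 0.6, rem)
                dur = max(dur, 0.1)
                append("INS", gen_inspiration(dur, rate, rng))
        elif label == "INS" and remaining_s >= 0.12:
            dur = max(0.1, min(rng.uniform(0.15, 0.45), 0.6, remaining_s))
            append("INS", gen_inspiration(dur, rate, rng))
        else:
            dur = max(0.1, min(rng.uniform(0.4, 1.8), remaining_s))
            append("OTHER", gen_other(dur, rate, rng))

    samples = np.concatenate(chunks)[:total_n]
    # truncation can shorten the final segment; keep the track tiling exact
    last = segments[-1]
    segments[-1] = (last[0], total_n / rate, last[2])
    segments = [s for s in segments if s[1] - s[0] > 1e-9]

    if spec.difficulty == "realistic":
        babble = _pink_noise(total_n, rng)
        sos = butter(4, [100.0, 4000.0], btype="bandpass", fs=rate, output="sos")
        babble = sosfilt(sos, babble)
        am = 1.0 + 0.4 * np.sin(2 * np.pi * 3.0 * np.arange(total_n) / rate
                                + rng.uniform(0, 2 * np.pi))
        babble = babble * am
        sig_rms = max(np.sqrt(np.mean(samples**2)), 1e-9)
        babble *= sig_rms / max(np.sqrt(np.mean(babble**2)), 1e-12) * 10 ** (-10 / 20)
        samples = samples + babble

    peak = np.max(np.abs(samples))
    if peak > 0.9:
        samples = 0.9 * samples / peak
    record = AudioRecord(samples=samples, rate=rate, source_id=source_id)
    return record, LabelTrack(segments=segments)


def gen_corpus(spec: CorpusSpec) -> list[tuple[AudioRecord, LabelTrack]]:
    """Generate ``spec.n_recordings`` labeled recordings, bit-reproducibly."""
    rng = np.random.default_rng(spec.seed)
    corpus = []
    for i in range(spec.n_recordings):
        child = np.random.default_rng(rng.integers(0, 2**31))
        corpus.append(gen_recording(spec, child, source_id=f"rec{i:03d}"))
    return corpus
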