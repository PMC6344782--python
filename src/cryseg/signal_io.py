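"""Audio and label-track I/O plus frame slicing.

The unit of analysis is a mono PCM recording (reference condition
44.1 kHz / 16-bit) with a time-aligned transcription assigning every
segment one of three acoustic classes:

* ``EXP``   — audible expiratory cry phase (voiced, harmonic),
* ``INS``   — audible inspiratory phase (short, breathy),
* ``OTHER`` — everything else: pauses, background noise, speech,
  machine sounds.

Label tracks are plain text, one segment per line::

    <start_seconds> <end_seconds> <label>

which is the transcription layout WaveSurfer-style annotation tools
produce.  All front-ends share the same frame slicing: fixed-length
windows (30 or 50 ms reference) with fractional overlap (30 % reference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

log = logging.getLogger(__name__)

#: Canonical class order; ties in classification are broken in this order.
CLASSES = ("EXP", "INS", "OTHER")

#: Aliases seen in manual transcriptions, mapped onto the canonical classes.
#: "INSV" (audible/voiced inspiration) and "P" (pause) come from the usual
#: annotation conventions for cry corpora.
LABEL_ALIASES = {
    "EXP": "EXP",
    "EXPIRATION": "EXP",
    "INS": "INS",
    "INSV": "INS",
    "INSPIRATION": "INS",
    "OTHER": "OTHER",
}


class LabelTrackError(ValueError):
    """Raised for malformed or inconsistent label tracks."""


class AudioFormatError(ValueError):
    """Raised when a file is not readable as PCM WAV audio."""


@dataclass
class AudioRecord:
    """A mono waveform with amplitudes normalized to [-1, 1]."""

    samples: np.ndarray
    rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class LabelTrack:
    """Ordered, non-overlapping labeled time segments."""

    segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, label in self.segments:
            if not start < end:
                raise LabelTrackError(f"segment ({start}, {end}) is empty or reversed")
            if start < prev_end:
                raise LabelTrackError(f"segment starting at {start} overlaps its predecessor")
            if label not in CLASSES:
                raise LabelTrackError(f"label {label!r} not in {CLASSES}")
            prev_end = end

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


@dataclass(frozen=True)
class FrameSpec:
    """Frame slicing parameters (reference: 30/50 ms windows, 30 % overlap)."""

    window_s: float = 0.030
    overlap_fraction: float = 0.30
    window_kind: str = "hamming"

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window_kind != "hamming":
            raise ValueError("only the hamming window is supported")

    def samples_per_frame(self, rate: float) -> int:
        return int(round(self.window_s * rate))

    def hop(self, rate: float) -> int:
        # Overlap is given as a fraction only; hop is rounded to the
        # nearest sample (one consistent choice).
        return max(1, int(round((1.0 - self.overlap_fraction) * self.samples_per_frame(rate))))


@dataclass
class FrameMatrix:
    """Frames of one recording: (frame_count, samples_per_frame)."""

    frames: np.ndarray
    frame_start_s: np.ndarray
    spec: FrameSpec
    rate: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def samples_per_frame(self) -> int:
        return self.frames.shape[1]


def read_wav(path: str | Path) -> AudioRecord:
    """Read a PCM WAV file as a normalized mono :class:`AudioRecord`.

    Integer PCM is scaled by the full-scale value of its bit depth;
    multi-channel input is averaged down to mono.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # chunk warnings on odd metadata
            rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample format {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecord(samples=samples, rate=float(rate), source_id=path.stem)


def write_wav(path: str | Path, record: AudioRecord, *, dtype: str = "int16") -> None:
    """Write a record as PCM 16-bit (default) or float32 WAV."""
    path = Path(path)
    if dtype == "int16":
        clipped = np.clip(record.samples, -1.0, 1.0 - 1.0 / 32768)
        wavfile.write(path, int(record.rate), np.round(clipped * 32768.0).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, int(record.rate), record.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def canonical_label(raw: str) -> str:
    """Map a free-text annotation label onto {EXP, INS, OTHER}.

    Unknown labels (pauses "P", "speech", "noise", ...) collapse to OTHER.
    """
    key = raw.strip().upper()
    if key in LABEL_ALIASES:
        return LABEL_ALIASES[key]
    if key not in ("P", "PAUSE", "SIL", "SILENCE", "NOISE", "SPEECH"):
        log.warning("unknown label %r mapped to OTHER", raw)
    return "OTHER"


def read_label_track(path: str | Path) -> LabelTrack:
    """Parse a plain-text transcription (start end label per line)."""
    segments: list[tuple[float, float, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise LabelTrackError(f"{path}:{lineno}: expected 'start end label', got {line!r}")
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise LabelTrackError(f"{path}:{lineno}: non-numeric time in {line!r}") from exc
        if not start < end:
            raise LabelTrackError(f"{path}:{lineno}: reversed or empty interval ({start}, {end})")
        segments.append((start, end, canonical_label(parts[2])))
    segments.sort(key=lambda s: s[0])
    for i in range(1, len(segments)):
        if segments[i][0] < segments[i - 1][1]:
            raise LabelTrackError(
                f"{path}: segments starting at {segments[i - 1][0]} and {segments[i][0]} overlap"
            )
    return LabelTrack(segments=segments)


def write_label_track(path: str | Path, track: LabelTrack) -> None:
    lines = [f"{s:.6f} {e:.6f} {lab}" for s, e, lab in track]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def hamming_window(n: int) -> np.ndarray:
    """Hamming weights w(k) = 0.54 - 0.46 cos(2 pi k / (n - 1)), k = 0..n-1."""
    if n < 2:
        raise ValueError("hamming window needs at least 2 samples")
    k = np.arange((n + 1) // 2)
    half = 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (n - 1))
    w = np.empty(n)
    w[: half.size] = half
    w[n - half.size:] = half[::-1]      # mirrored, so symmetry is exact
    return w


def frame_signal(record: AudioRecord, spec: FrameSpec) -> FrameMatrix:
    """Slice a recording into overlapping frames.

    Trailing samples shorter than one window are dropped (no zero
    padding, which would fabricate silent frames).
    """
    n = spec.samples_per_frame(record.rate)
    hop = spec.hop(record.rate)
    if record.samples.size < n:
        raise ValueError(
            f"recording of {record.samples.size} samples is shorter than one "
            f"{n}-sample window"
        )
    count = (record.samples.size - n) // hop + 1
    idx = np.arange(n)[None, :] + hop * np.arange(count)[:, None]
    frames = record.samples[idx]
    starts = hop * np.arange(count) / record.rate
    return FrameMatrix(frames=frames, frame_start_s=starts, spec=spec, rate=record.rate)


def label_frames(frames: FrameMatrix, track: LabelTrack) -> np.ndarray:
    """Assign each frame the class owning the majority of its time span.

    Time not covered by any segment counts as OTHER.  Ties go to the
    class whose owning interval starts earliest.
    """
    n = frames.samples_per_frame
    win_s = n / frames.rate
    labels = np.empty(frames.n_frames, dtype=object)
    for i, t0 in enumerate(frames.frame_start_s):
        t1 = t0 + win_s
        # per-class overlap mass and earliest contributing interval start
        mass = dict.fromkeys(CLASSES, 0.0)
        first = dict.fromkeys(CLASSES, np.inf)
        cursor = t0
        for s, e, lab in track:
            if e <= t0:
                continue
            if s >= t1:
                break
            if s > cursor:  # uncovered gap before this segment
                mass["OTHER"] += min(s, t1) - cursor
                first["OTHER"] = min(first["OTHER"], cursor)
            ov0, ov1 = max(s, t0), min(e, t1)
            if ov1 > ov0:
                mass[lab] += ov1 - ov0
                first[lab] = min(first[lab], s)
            cursor = max(cursor, e)
        if cursor < t1:  # uncovered tail
            mass["OTHER"] += t1 - cursor
            first["OTHER"] = min(first["OTHER"], cursor)
        best = max(CLASSES, key=lambda c: (mass[c], -first[c]))
        labels[i] = best
    return labels
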