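"""k-fold cross-validated training/testing and CER reporting.

A *system* is one combination of decomposition, feature and classifier
(nine reference combinations: {FFT, WPT, EMD} front-ends x {GMM, 4-state
HMM, 5-state HMM}).  Recordings — not frames — are partitioned into k
folds (k = 10 reference) so adjacent frames of one recording never
straddle the train/test split.  The headline metric is the
classification error rate

    CER = 100 - 100 * (correctly classified observations / total)

averaged over folds.  GMM systems naturally classify frames and HMM
systems classify labeled segments, so every fold report carries *both*
a per-frame and a per-segment confusion matrix; the CER field uses the
classifier's native unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cryseg import features as feat
from cryseg import emd as emd_mod
from cryseg.classifiers import (
    ClassModelSet, classify, classify_frames, gmm_fit,
    hmm_init_viterbi, hmm_reestimate_baum_welch,
)
from cryseg.signal_io import (
    CLASSES, AudioRecord, FrameSpec, LabelTrack, frame_signal, label_frames,
)
from cryseg.wpt import WaveletSpec, band_edges_hz, packet_tree, subband_energies

log = logging.getLogger(__name__)

__all__ = ["SystemConfig", "FoldReport", "SystemResult", "REFERENCE_SYSTEMS",
           "make_folds", "compute_cer", "extract_features", "train_models",
           "run_system"]

_DECOMP_FOR_FEATURE = {"FFT_MFCC": "FFT", "WE_DCT": "WPT"}

#: The nine reference system combinations.
REFERENCE_SYSTEMS = [
    ("FFT", "FFT_MFCC", "GMM"),
    ("FFT", "FFT_MFCC", "HMM4"),
    ("FFT", "FFT_MFCC", "HMM5"),
    ("WPT", "WE_DCT", "GMM"),
    ("WPT", "WE_DCT", "HMM4"),
    ("WPT", "WE_DCT", "HMM5"),
    ("EMD", "EMD_MFCC(IMF345)", "GMM"),
    ("EMD", "EMD_MFCC(IMF345)", "HMM4"),
    ("EMD", "EMD_MFCC(IMF345)", "HMM5"),
]


@dataclass(frozen=True)
class SystemConfig:
    """One evaluated system: decomposition + feature + classifier."""

    decomposition: str = "FFT"       # FFT | WPT | EMD
    feature: str = "FFT_MFCC"        # FFT_MFCC | WE_DCT | EMD_MFCC(<set>)
    classifier: str = "GMM"          # GMM | HMM4 | HMM5
    window_s: float = 0.030
    overlap_fraction: float = 0.30
    mixtures: int = 40
    hmm_mixtures: int = 16
    wavelet: str = "db10"
    wavelet_level: int = 5
    # whether frames are Hamming-windowed before the WPT; off by default
    # (windowing ahead of an orthogonal transform double-tapers)
    wpt_hamming: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("GMM", "HMM4", "HMM5"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.feature.startswith("EMD_MFCC"):
            if self.decomposition != "EMD":
                raise ValueError("EMD_MFCC features require EMD decomposition")
            set_name = self.imf_set
            if set_name not in emd_mod.IMF_SETS:
                raise ValueError(f"unknown IMF set {set_name!r}")
        elif _DECOMP_FOR_FEATURE.get(self.feature) != self.decomposition:
            raise ValueError(
                f"feature {self.feature!r} incompatible with decomposition "
                f"{self.decomposition!r}"
            )

    @property
    def imf_set(self) -> str | None:
        if not self.feature.startswith("EMD_MFCC"):
            return None
        return self.feature[len("EMD_MFCC("):-1] if "(" in self.feature else "IMF345"

    @property
    def n_states(self) -> int | None:
        return {"HMM4": 4, "HMM5": 5}.get(self.classifier)

    @property
    def frame_spec(self) -> FrameSpec:
        return FrameSpec(window_s=self.window_s, overlap_fraction=self.overlap_fraction)


@dataclass
class FoldReport:
    """Per-fold confusion counts and CER (classifier's native unit)."""

    fold_id: int
    confusion_frames: np.ndarray          # 3x3, rows = truth, cols = predicted
    confusion_segments: np.ndarray        # 3x3
    cer: float
    n_test_observations: int
    skipped: bool = False


@dataclass
class SystemResult:
    config: SystemConfig
    folds: list[FoldReport]
    mean_cer: float
    std_cer: float


def make_folds(corpus: list, k: int = 10, seed: int = 0) -> list[tuple[list[int], list[int]]]:
    """Partition recording indices into k (train, test) splits.

    Deterministic under ``seed``; every recording appears in exactly one
    test fold.
    """
    n = len(corpus)
    if k > n:
        raise ValueError(f"k={k} exceeds corpus size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    groups = [sorted(order[i::k].tolist()) for i in range(k)]
    folds = []
    for g in groups:
        test = g
        train = sorted(set(range(n)) - set(g))
        folds.append((train, test))
    return folds


def compute_cer(confusion: np.ndarray) -> float:
    """CER = 100 - 100 * trace / total, in percent."""
    confusion = np.asarray(confusion, dtype=np.float64)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix: CER undefined")
    return 100.0 - 100.0 * np.trace(confusion) / total


def precision_recall(confusion: np.ndarray) -> dict:
    """Per-class precision and recall from a 3x3 confusion matrix."""
    confusion = np.asarray(confusion, dtype=np.float64)
    out = {}
    for i, c in enumerate(CLASSES):
        tp = confusion[i, i]
        out[c] = {
            "recall": tp / confusion[i, :].sum() if confusion[i, :].sum() else np.nan,
            "precision": tp / confusion[:, i].sum() if confusion[:, i].sum() else np.nan,
        }
    return out


def _per_frame_features(record: AudioRecord, cfg: SystemConfig,
                        emd_cache: dict | None = None) -> feat.FeatureMatrix:
    spec = cfg.frame_spec
    if cfg.feature == "FFT_MFCC":
        return feat.fft_mfcc(frame_signal(record, spec))
    if cfg.feature == "WE_DCT":
        frames = frame_signal(record, spec)
        wspec = WaveletSpec(family=cfg.wavelet, level=cfg.wavelet_level)
        edges = band_edges_hz(wspec, record.rate)
        mel_w = feat.mel_band_weights(edges)
        raw = frames.frames
        if cfg.wpt_hamming:
            from cryseg.signal_io import hamming_window
            raw = raw * hamming_window(frames.samples_per_frame)[None, :]
        vecs = np.empty((frames.n_frames, feat.FEATURE_DIM))
        for i in range(frames.n_frames):
            tree = packet_tree(raw[i], wspec)
            vecs[i] = feat.we_dct(subband_energies(tree), mel_weights=mel_w)
        return feat.FeatureMatrix(vectors=vecs, frame_start_s=frames.frame_start_s.copy(),
                                  feature_kind="WE_DCT")
    # EMD_MFCC
    d = None
    if emd_cache is not None:
        d = emd_cache.get(record.source_id)
    if d is None:
        d = emd_mod.decompose(record.samples)
        if emd_cache is not None:
            emd_cache[record.source_id] = d
    return feat.emd_mfcc(record, cfg.imf_set, spec, decomposition=d)


def extract_features(corpus: list[tuple[AudioRecord, LabelTrack]], cfg: SystemConfig,
                     emd_cache: dict | None = None) -> list[dict]:
    """Per-recording features, per-frame labels, and segment frame spans."""
    out = []
    for record, track in corpus:
        feats = _per_frame_features(record, cfg, emd_cache)
        frames = frame_signal(record, cfg.frame_spec)
        labels = label_frames(frames, track)
        segments = _segment_spans(frames, track)
        out.append({"features": feats, "labels": labels, "segments": segments})
    return out


def _segment_spans(frames, track: LabelTrack) -> list[tuple[int, int, str]]:
    """Map labeled segments to [first_frame, last_frame) index spans.

    A frame belongs to the segment containing its center.
    """
    centers = frames.frame_start_s + 0.5 * frames.samples_per_frame / frames.rate
    spans = []
    for s, e, lab in track:
        inside = np.flatnonzero((centers >= s) & (centers < e))
        if inside.size:
            spans.append((int(inside[0]), int(inside[-1]) + 1, lab))
    return spans


def train_models(train_data: list[dict], cfg: SystemConfig) -> ClassModelSet:
    """Train one generative model per class from extracted features."""
    meta = {"feature_kind": train_data[0]["features"].feature_kind,
            "window_s": cfg.window_s, "overlap_fraction": cfg.overlap_fraction,
            "mixtures": cfg.mixtures, "classifier": cfg.classifier,
            "seed": cfg.seed}
    if cfg.classifier == "GMM":
        models = {}
        for c in CLASSES:
            x = np.vstack([d["features"].vectors[d["labels"] == c]
                           for d in train_data])
            if x.shape[0] == 0:
                log.warning("class %s absent from training data", c)
                continue
            j = min(cfg.mixtures, x.shape[0])
            models[c] = gmm_fit(x, j, seed=cfg.seed)
        return ClassModelSet(models=models, kind="GMM", train_meta=meta)

    n_states = cfg.n_states
    models = {}
    for c in CLASSES:
        seqs = []
        for d in train_data:
            for f0, f1, lab in d["segments"]:
                if lab == c and f1 - f0 >= n_states:
                    seqs.append(d["features"].vectors[f0:f1])
        if not seqs:
            log.warning("class %s has no usable training sequences", c)
            continue
        n_frames = sum(s.shape[0] for s in seqs)
        # clip mixtures so every component can expect a few frames
        m = max(1, min(cfg.hmm_mixtures, n_frames // (4 * n_states)))
        model = hmm_init_viterbi(seqs, n_states, m, seed=cfg.seed)
        hmm_reestimate_baum_welch(model, seqs)
        models[c] = model
    meta["states"] = n_states
    return ClassModelSet(models=models, kind="HMM", train_meta=meta)


def _evaluate_fold(models: ClassModelSet, test_data: list[dict]) -> tuple[np.ndarray, np.ndarray]:
    """Frame- and segment-level confusion matrices over one test fold."""
    idx = {c: i for i, c in enumerate(CLASSES)}
    conf_f = np.zeros((3, 3), dtype=int)
    conf_s = np.zeros((3, 3), dtype=int)
    for d in test_data:
        vec = d["features"].vectors
        if models.kind == "GMM":
            pred = classify_frames(models, vec)
            for t, p in zip(d["labels"], pred):
                conf_f[idx[t], idx[p]] += 1
            for f0, f1, lab in d["segments"]:
                if f1 <= f0:
                    continue
                votes = pred[f0:f1]
                counts = [np.sum(votes == c) for c in CLASSES]
                conf_s[idx[lab], int(np.argmax(counts))] += 1
        else:
            for f0, f1, lab in d["segments"]:
                p, _ = classify(models, vec[f0:f1])
                conf_s[idx[lab], idx[p]] += 1
                conf_f[idx[lab], idx[p]] += f1 - f0
    return conf_f, conf_s


def run_system(cfg: SystemConfig, corpus: list[tuple[AudioRecord, LabelTrack]],
               k: int = 10, emd_cache: dict | None = None) -> SystemResult:
    """k-fold cross-validated evaluation of one system configuration.

    Features are extracted once per recording and reused across folds.
    A fold whose training split lacks a class is skipped with a warning.
    Fully deterministic for a fixed ``cfg.seed``.
    """
    data = extract_features(corpus, cfg, emd_cache)
    folds = make_folds(corpus, k=k, seed=cfg.seed)
    reports = []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        train = [data[i] for i in train_idx]
        test = [data[i] for i in test_idx]
        try:
            models = train_models(train, cfg)
        except ValueError as exc:
            log.warning("fold %d skipped: %s", fold_id, exc)
            reports.append(FoldReport(fold_id, np.zeros((3, 3), int),
                                      np.zeros((3, 3), int), np.nan, 0, skipped=True))
            continue
        conf_f, conf_s = _evaluate_fold(models, test)
        native = conf_f if cfg.classifier == "GMM" else conf_s
        reports.append(FoldReport(
            fold_id=fold_id, confusion_frames=conf_f, confusion_segments=conf_s,
            cer=compute_cer(native), n_test_observations=int(native.sum())))
    cers = np.array([r.cer for r in reports if not r.skipped])
    return SystemResult(config=cfg, folds=reports,
                        mean_cer=float(np.mean(cers)) if cers.size else np.nan,
                        std_cer=float(np.std(cers)) if cers.size else np.nan)
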