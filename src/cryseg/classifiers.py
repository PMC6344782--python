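"""Generative frame/segment classifiers: diagonal GMMs and left-to-right HMMs.

One model is trained per acoustic class (EXP, INS, OTHER); a test item is
assigned to the class whose model gives it maximum likelihood.  GMMs score
individual frames; HMMs score whole frame sequences (one labeled segment
= one observation sequence), which lets them use the temporal evolution
of the features.

The GMM is p(o | lambda) = sum_j w_j N(o; mu_j, Sigma_j) with diagonal
Sigma_j, fitted by EM from a k-means start.  Each M-step applies a
variance floor (a small fraction of the global per-dimension variance),
and the per-iteration mean log-likelihood history is recorded; EM
guarantees it is nondecreasing.

The HMM is a strict left-to-right chain (self-loop or advance, no skips,
pi = (1, 0, ..., 0)) with a diagonal-covariance Gaussian-mixture emission
per state.  Initialization is segmental: uniform-duration state
assignment, per-state GMM fits, then Viterbi realignment iterated until
the alignment likelihood stops improving.  Re-estimation is standard
Baum-Welch (scaled forward-backward, via hmmlearn's GMMHMM).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from hmmlearn.hmm import GMMHMM
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from cryseg.signal_io import CLASSES

log = logging.getLogger(__name__)

__all__ = [
    "DiagonalGMM", "LeftRightHMM", "ClassModelSet",
    "gmm_fit", "hmm_init_viterbi", "hmm_reestimate_baum_welch",
    "sequence_loglik", "classify", "classify_frames",
]

#: Variance floor as a fraction of the global per-dimension variance.
VARIANCE_FLOOR_FRACTION = 1e-4


@dataclass
class DiagonalGMM:
    """Weighted sum of diagonal-covariance Gaussians."""

    weights: np.ndarray          # (J,)
    means: np.ndarray            # (J, D)
    variances: np.ndarray        # (J, D), all >= floor
    history: list = field(default_factory=list)   # mean log-lik per EM iteration
    converged: bool = False

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_density(self, obs: np.ndarray):
        """Log p(o | lambda) per row of ``obs`` (scalar for a single vector)."""
        obs = np.asarray(obs, dtype=np.float64)
        single = obs.ndim == 1
        obs = np.atleast_2d(obs)
        if obs.shape[1] != self.dim:
            raise ValueError(f"observation dim {obs.shape[1]} != model dim {self.dim}")
        out = logsumexp(self._component_log_density(obs) + np.log(self.weights), axis=1)
        return float(out[0]) if single else out

    def density(self, obs: np.ndarray):
        return np.exp(self.log_density(obs))

    def _component_log_density(self, obs: np.ndarray) -> np.ndarray:
        # (n, J) log N(o; mu_j, diag sigma2_j)
        inv = 1.0 / self.variances                              # (J, D)
        quad = (obs**2) @ inv.T - 2.0 * obs @ (self.means * inv).T \
            + np.sum(self.means**2 * inv, axis=1)
        log_norm = -0.5 * (self.dim * np.log(2.0 * np.pi)
                           + np.sum(np.log(self.variances), axis=1))
        return log_norm - 0.5 * quad

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiagonalGMM":
        return cls(weights=np.array(d["weights"]), means=np.array(d["means"]),
                   variances=np.array(d["variances"]))


def gmm_fit(data: np.ndarray, n_components: int, seed: int = 0,
            tol: float = 1e-4, max_iter: int = 200) -> DiagonalGMM:
    """Fit a diagonal GMM by EM from a k-means initialization.

    ``tol`` is relative: EM stops when the mean log-likelihood improves
    by less than ``tol * |previous|``.  Components that lose all their
    responsibility mass are re-seeded at the worst-explained data point.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n, d = data.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds sample count {n}")

    global_var = np.var(data, axis=0)
    floor = np.maximum(VARIANCE_FLOOR_FRACTION * global_var, 1e-10)

    if n_components == 1:
        means = data.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=n_components, n_init=1, random_state=seed)
        km.fit(data)
        means = km.cluster_centers_.copy()
    variances = np.tile(np.maximum(global_var, floor), (n_components, 1))
    weights = np.full(n_components, 1.0 / n_components)
    model = DiagonalGMM(weights=weights, means=means, variances=variances)

    prev = -np.inf
    for _ in range(max_iter):
        comp_ll = (model._component_log_density(data)
                   + np.log(np.maximum(model.weights, 1e-300)))
        total_ll = logsumexp(comp_ll, axis=1)
        mean_ll = float(np.mean(total_ll))
        model.history.append(mean_ll)

        resp = np.exp(comp_ll - total_ll[:, None])              # (n, J)
        mass = resp.sum(axis=0)                                  # (J,)
        empty = np.flatnonzero(mass < 1e-10)
        if empty.size:
            # hand each empty component its own worst-explained point
            worst_order = np.argsort(total_ll)
            for k, j in enumerate(empty):
                log.warning("re-seeding empty GMM component %d", j)
                worst = int(worst_order[min(k, n - 1)])
                resp[:, j] = 0.0
                resp[worst, :] = 0.0
                resp[worst, j] = 1.0
            mass = resp.sum(axis=0)

        model.weights = mass / n
        model.means = (resp.T @ data) / mass[:, None]
        sq = (resp.T @ (data**2)) / mass[:, None] - model.means**2
        model.variances = np.maximum(sq, floor)

        if mean_ll - prev < tol * abs(prev) and np.isfinite(prev):
            model.converged = True
            break
        prev = mean_ll
    return model


def _left_right_transmat(n_states: int) -> np.ndarray:
    a = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        a[i, i] = a[i, i + 1] = 0.5
    a[-1, -1] = 1.0
    return a


def _make_gmmhmm(n_states: int, n_mix: int, dim: int, seed: int = 0) -> GMMHMM:
    model = GMMHMM(n_components=n_states, n_mix=n_mix, covariance_type="diag",
                   init_params="", params="tmcw", random_state=seed,
                   # covars_prior=-1.5 makes the diag M-step denominator the
                   # plain-ML posterior mass (keeping EM monotone); the tiny
                   # covars_weight keeps starved components' variances > 0
                   covars_prior=-1.5, covars_weight=1e-9,
                   means_prior=0.0, means_weight=0.0, weights_prior=1.0)
    model.startprob_ = np.zeros(n_states)
    model.startprob_[0] = 1.0
    model.transmat_ = _left_right_transmat(n_states)
    model.means_ = np.zeros((n_states, n_mix, dim))
    model.covars_ = np.ones((n_states, n_mix, dim))
    model.weights_ = np.full((n_states, n_mix), 1.0 / n_mix)
    return model


@dataclass
class LeftRightHMM:
    """Strict left-to-right HMM with Gaussian-mixture emissions per state."""

    hmm: GMMHMM
    history: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.hmm.n_components

    @property
    def n_mix(self) -> int:
        return self.hmm.n_mix

    @property
    def transmat(self) -> np.ndarray:
        return self.hmm.transmat_

    @property
    def startprob(self) -> np.ndarray:
        return self.hmm.startprob_

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "n_mix": self.n_mix,
            "startprob": self.hmm.startprob_.tolist(),
            "transmat": self.hmm.transmat_.tolist(),
            "means": self.hmm.means_.tolist(),
            "covars": self.hmm.covars_.tolist(),
            "weights": self.hmm.weights_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LeftRightHMM":
        means = np.array(d["means"])
        model = _make_gmmhmm(d["n_states"], d["n_mix"], means.shape[2])
        model.startprob_ = np.array(d["startprob"])
        model.transmat_ = np.array(d["transmat"])
        model.means_ = means
        model.covars_ = np.array(d["covars"])
        model.weights_ = np.array(d["weights"])
        return cls(hmm=model)


def _uniform_assignments(lengths: list[int], n_states: int) -> list[np.ndarray]:
    out = []
    for t in lengths:
        edges = np.floor(np.arange(n_states + 1) * t / n_states).astype(int)
        a = np.empty(t, dtype=int)
        for s in range(n_states):
            a[edges[s]:edges[s + 1]] = s
        out.append(a)
    return out


def _fit_emissions(model: GMMHMM, sequences: list[np.ndarray],
                   assignments: list[np.ndarray], seed: int) -> None:
    n_states, n_mix = model.n_components, model.n_mix
    all_obs = np.vstack(sequences)
    all_assign = np.concatenate(assignments)
    dim = all_obs.shape[1]
    for s in range(n_states):
        pool = all_obs[all_assign == s]
        if pool.shape[0] == 0:
            pool = all_obs  # unreachable for uniform init; Viterbi can starve a state
        j = max(1, min(n_mix, pool.shape[0]))
        g = gmm_fit(pool, j, seed=seed + s)
        # pad with tiny-weight copies if the pool supported fewer than n_mix
        w = np.full(n_mix, 1e-8)
        w[:j] = g.weights
        w /= w.sum()
        model.weights_[s] = w
        model.means_[s] = np.vstack([g.means, np.tile(g.means[-1:], (n_mix - j, 1))])
        model.covars_[s] = np.vstack([g.variances, np.tile(g.variances[-1:], (n_mix - j, 1))])


def _estimate_transmat(assignments: list[np.ndarray], n_states: int) -> np.ndarray:
    counts = np.zeros((n_states, n_states))
    for a in assignments:
        for i, j in zip(a[:-1], a[1:]):
            counts[i, j] += 1
    trans = _left_right_transmat(n_states)
    for i in range(n_states):
        stay = counts[i, i]
        go = counts[i, i + 1] if i + 1 < n_states else 0.0
        tot = stay + go
        if i + 1 < n_states and tot > 0:
            trans[i, i] = max(stay, 0.5) / max(tot, 1.0)
            trans[i, i + 1] = 1.0 - trans[i, i]
    return trans


def hmm_init_viterbi(sequences: list[np.ndarray], n_states: int, n_mix: int,
                     seed: int = 0, tol: float = 1e-4,
                     max_align_iters: int = 10) -> LeftRightHMM:
    """Segmental initialization of a left-to-right HMM.

    Uniform-duration state assignment, per-state GMM fits, then iterated
    Viterbi realignment + refit until the total alignment log-likelihood
    stops improving.  Sequences shorter than ``n_states`` frames are
    skipped with a warning.
    """
    usable = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in sequences]
    skipped = [s for s in usable if s.shape[0] < n_states]
    if skipped:
        log.warning("skipping %d sequences shorter than %d frames",
                    len(skipped), n_states)
    usable = [s for s in usable if s.shape[0] >= n_states]
    if not usable:
        raise ValueError(f"no training sequence has >= {n_states} frames")

    dim = usable[0].shape[1]
    model = _make_gmmhmm(n_states, n_mix, dim, seed=seed)
    assignments = _uniform_assignments([s.shape[0] for s in usable], n_states)

    prev = -np.inf
    for _ in range(max_align_iters):
        _fit_emissions(model, usable, assignments, seed)
        model.transmat_ = _estimate_transmat(assignments, n_states)
        total = 0.0
        new_assignments = []
        for s in usable:
            lp, states = model.decode(s, algorithm="viterbi")
            total += lp
            new_assignments.append(states)
        if total - prev < tol * abs(prev) and np.isfinite(prev):
            break
        prev = total
        assignments = new_assignments
    return LeftRightHMM(hmm=model)


def hmm_reestimate_baum_welch(model: LeftRightHMM, sequences: list[np.ndarray],
                              tol: float = 1e-4, max_iter: int = 20) -> LeftRightHMM:
    """Baum-Welch re-estimation; structural zeros of A stay zero.

    The per-iteration total log-likelihoods are appended to
    ``model.history``.
    """
    usable = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in sequences
              if np.asarray(s).shape[0] >= model.n_states]
    x = np.vstack(usable)
    lengths = [s.shape[0] for s in usable]
    model.hmm.n_iter = max_iter
    model.hmm.tol = tol
    model.hmm.fit(x, lengths)
    model.history.extend(list(model.hmm.monitor_.history))
    assert np.all(np.isfinite(model.hmm.transmat_)), "Baum-Welch diverged"
    # EM cannot resurrect a zero transition, but guard against drift
    mask = _left_right_transmat(model.n_states) > 0
    assert np.all(model.hmm.transmat_[~mask] <= 1e-300), "structural zero violated"
    model.hmm.transmat_[~mask] = 0.0
    # starved states keep a zero row after normalization; restore the
    # structural self-loop so the matrix stays row-stochastic
    for i in np.flatnonzero(model.hmm.transmat_.sum(axis=1) == 0):
        model.hmm.transmat_[i, i] = 1.0
    np.maximum(model.hmm.covars_, 1e-6, out=model.hmm.covars_)
    return model


def sequence_loglik(model: LeftRightHMM, seq: np.ndarray) -> float:
    """Exact marginal log p(sequence | model) by the scaled forward pass."""
    seq = np.atleast_2d(np.asarray(seq, dtype=np.float64))
    return float(model.hmm.score(seq))


def viterbi_loglik(model: LeftRightHMM, seq: np.ndarray) -> float:
    """Log-likelihood of the single best state path."""
    seq = np.atleast_2d(np.asarray(seq, dtype=np.float64))
    lp, _ = model.hmm.decode(seq, algorithm="viterbi")
    return float(lp)


@dataclass
class ClassModelSet:
    """Trained generative models keyed by acoustic class.

    Normally all three classes are present; a degenerate training corpus
    (e.g. a single-class one) yields a partial set that classifies among
    the classes it has, which is logged.
    """

    models: dict
    kind: str                       # "GMM" or "HMM"
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model set is empty")
        missing = [c for c in CLASSES if c not in self.models]
        if missing:
            log.warning("partial model set: no models for %s", missing)
        if self.kind not in ("GMM", "HMM"):
            raise ValueError("kind must be GMM or HMM")

    @property
    def classes(self) -> tuple:
        return tuple(c for c in CLASSES if c in self.models)

    def save(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "train_meta": self.train_meta,
            "models": {c: self.models[c].to_dict() for c in self.classes},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ClassModelSet":
        payload = json.loads(Path(path).read_text())
        loader = DiagonalGMM.from_dict if payload["kind"] == "GMM" else LeftRightHMM.from_dict
        return cls(models={c: loader(d) for c, d in payload["models"].items()},
                   kind=payload["kind"], train_meta=payload.get("train_meta", {}))


def classify(models: ClassModelSet, item: np.ndarray,
             priors: dict | None = None) -> tuple[str, dict]:
    """Maximum-likelihood class of a frame (GMM) or sequence (either kind).

    Priors are uniform (pure maximum likelihood) unless an explicit
    ``priors`` map {class: probability} is given.  Ties break in
    canonical class order EXP < INS < OTHER.  Returns the winning label
    and the per-class (prior-weighted) log-likelihood scores.
    """
    item = np.asarray(item, dtype=np.float64)
    scores = {}
    for c in models.classes:
        m = models.models[c]
        if models.kind == "GMM":
            scores[c] = float(np.sum(m.log_density(np.atleast_2d(item))))
        else:
            scores[c] = sequence_loglik(m, item)
        if priors is not None:
            scores[c] += float(np.log(priors[c]))
    arr = np.array([scores[c] for c in models.classes])
    return models.classes[int(np.argmax(arr))], scores


def classify_frames(models: ClassModelSet, frames: np.ndarray,
                    priors: dict | None = None) -> np.ndarray:
    """Vectorized per-frame maximum-likelihood labels under GMM models."""
    if models.kind != "GMM":
        raise ValueError("per-frame classification requires GMM models")
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    classes = models.classes
    ll = np.stack([models.models[c].log_density(frames) for c in classes], axis=1)
    if priors is not None:
        ll = ll + np.log([priors[c] for c in classes])[None, :]
    idx = np.argmax(ll, axis=1)      # argmax takes the first max: EXP < INS < OTHER
    return np.asarray(classes, dtype=object)[idx]
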