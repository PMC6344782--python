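import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from cryseg.classifiers import (
    ClassModelSet, DiagonalGMM, classify, classify_frames, gmm_fit,
    hmm_init_viterbi, hmm_reestimate_baum_welch, sequence_loglik,
    viterbi_loglik, _left_right_transmat,
)


def _mix_logpdf(model, o):
    """Independent diagonal-mixture log-density (used by the HMM oracle)."""
    comps = []
    for w, mu, var in zip(model["weights"], model["means"], model["vars"]):
        q = np.sum((o - mu) ** 2 / var)
        norm = -0.5 * (len(o) * np.log(2 * np.pi) + np.sum(np.log(var)))
        comps.append(np.log(w) + norm - 0.5 * q)
    return logsumexp(comps)


def brute_force_loglik(startprob, transmat, emissions, seq):
    """Sum over every state path by explicit enumeration."""
    n = len(startprob)
    t_len = seq.shape[0]
    terms = []
    for path in itertools.product(range(n), repeat=t_len):
        lp = np.log(startprob[path[0]]) if startprob[path[0]] > 0 else -np.inf
        for a, b in zip(path[:-1], path[1:]):
            lp += np.log(transmat[a, b]) if transmat[a, b] > 0 else -np.inf
        if np.isinf(lp):
            continue
        for t, s in enumerate(path):
            lp += _mix_logpdf(emissions[s], seq[t])
        terms.append(lp)
    return logsumexp(terms)


class TestGmmDensity:
    def test_standard_normal_at_mode(self):
        g = DiagonalGMM(weights=np.array([1.0]), means=np.zeros((1, 1)),
                        variances=np.ones((1, 1)))
        assert float(g.density(np.array([0.0]))) == pytest.approx((2 * np.pi) ** -0.5,
                                                                  abs=1e-9)

    def test_density_integrates_to_one(self):
        from scipy.integrate import quad
        g = DiagonalGMM(weights=np.array([0.3, 0.7]),
                        means=np.array([[-2.0], [1.5]]),
                        variances=np.array([[0.5], [2.0]]))
        val, _ = quad(lambda x: float(g.density(np.array([x]))), -30, 30)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_duplicate_components_equal_single(self, rng):
        mu, var = np.array([[1.0, -1.0]]), np.array([[0.5, 2.0]])
        one = DiagonalGMM(np.array([1.0]), mu, var)
        two = DiagonalGMM(np.array([0.5, 0.5]), np.vstack([mu, mu]),
                          np.vstack([var, var]))
        x = rng.standard_normal((50, 2))
        assert np.allclose(one.log_density(x), two.log_density(x), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        g = DiagonalGMM(np.array([1.0]), np.zeros((1, 3)), np.ones((1, 3)))
        with pytest.raises(ValueError, match="dim"):
            g.log_density(np.zeros((5, 2)))


class TestGmmFit:
    def test_single_component_closed_form(self, rng):
        x = rng.standard_normal((500, 3)) * [1.0, 2.0, 0.5] + [0.0, 1.0, -2.0]
        g = gmm_fit(x, 1)
        assert np.allclose(g.means[0], x.mean(axis=0), atol=1e-10)
        assert np.allclose(g.variances[0], x.var(axis=0), atol=1e-10)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(-5, 1, 1000), rng.normal(5, 1, 1000)])[:, None]
        g = gmm_fit(x, 2, seed=0)
        means = np.sort(g.means[:, 0])
        assert abs(means[0] + 5) < 0.15 and abs(means[1] - 5) < 0.15
        assert np.all(np.abs(g.weights - 0.5) < 0.05)

    def test_loglik_nondecreasing(self, rng):
        x = rng.standard_normal((400, 4))
        g = gmm_fit(x, 8, seed=1)
        h = np.array(g.history)
        assert np.all(np.diff(h) >= -1e-8)

    def test_matches_sklearn_loglik(self):
        # independent route: sklearn's EM should land on a comparable optimum
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-3, 1, 500), rng.normal(3, 1, 500)])[:, None]
        ours = gmm_fit(x, 2, seed=0)
        sk = GaussianMixture(2, covariance_type="diag", random_state=0).fit(x)
        assert float(np.mean(ours.log_density(x))) == pytest.approx(
            float(sk.score(x)), abs=0.01)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            gmm_fit(rng.standard_normal((5, 2)), 10)


def _toy_hmm(n_states=3, n_mix=2, dim=2, seed=0):
    rng = np.random.default_rng(seed)
    seqs = [rng.standard_normal((rng.integers(6, 15), dim)) + 3 * np.arange(dim)
            for _ in range(12)]
    model = hmm_init_viterbi(seqs, n_states, n_mix, seed=seed)
    return model, seqs


class TestHmmStructure:
    def test_left_right_invariants_after_training(self):
        model, seqs = _toy_hmm()
        hmm_reestimate_baum_welch(model, seqs)
        a = model.transmat
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-10)
        mask = _left_right_transmat(model.n_states) > 0
        assert np.all(a[~mask] == 0.0)
        pi = model.startprob
        assert pi[0] == 1.0 and np.all(pi[1:] == 0.0)

    def test_structural_zeros_survive_many_iterations(self):
        model, seqs = _toy_hmm(seed=3)
        hmm_reestimate_baum_welch(model, seqs, max_iter=50)
        mask = _left_right_transmat(model.n_states) > 0
        assert np.all(model.transmat[~mask] == 0.0)

    def test_short_sequences_skipped(self, rng):
        seqs = [rng.standard_normal((2, 2)) for _ in range(3)]
        with pytest.raises(ValueError, match="frames"):
            hmm_init_viterbi(seqs, 4, 1)


class TestForwardOracle:
    @pytest.mark.parametrize("n_states,t_len", [(2, 4), (3, 5), (3, 6)])
    def test_forward_equals_path_enumeration(self, n_states, t_len):
        rng = np.random.default_rng(n_states * 100 + t_len)
        seqs = [rng.standard_normal((10, 2)) for _ in range(6)]
        model = hmm_init_viterbi(seqs, n_states, 2, seed=1)
        seq = rng.standard_normal((t_len, 2))
        emissions = [{"weights": model.hmm.weights_[s],
                      "means": model.hmm.means_[s],
                      "vars": model.hmm.covars_[s]}
                     for s in range(n_states)]
        expected = brute_force_loglik(model.startprob, model.transmat,
                                      emissions, seq)
        assert sequence_loglik(model, seq) == pytest.approx(expected, abs=1e-10)

    def test_viterbi_bounded_by_forward(self, rng):
        model, _ = _toy_hmm(seed=9)
        for _ in range(5):
            seq = rng.standard_normal((8, 2))
            assert viterbi_loglik(model, seq) <= sequence_loglik(model, seq) + 1e-12


class TestTraining:
    def test_viterbi_init_finds_change_point(self):
        rng = np.random.default_rng(0)
        first = rng.normal(0.0, 1.0, (30, 1))
        second = rng.normal(10.0, 1.0, (30, 1))
        seq = np.vstack([first, second])
        model = hmm_init_viterbi([seq], 2, 1, seed=0)
        _, states = model.hmm.decode(seq, algorithm="viterbi")
        change = int(np.argmax(states == 1))
        assert abs(change - 30) <= 2

    def test_baum_welch_loglik_nondecreasing(self):
        model, seqs = _toy_hmm(seed=11)
        hmm_reestimate_baum_welch(model, seqs, max_iter=15)
        h = np.array(model.history)
        assert np.all(np.diff(h) >= -1e-6 * np.abs(h[:-1]))

    def test_self_transition_recovery(self):
        # simulate a 3-state left-right chain, dwell ~10 frames per state
        rng = np.random.default_rng(2024)
        a_true = np.array([[0.9, 0.1, 0.0], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]])
        means = np.array([-5.0, 0.0, 5.0])
        seqs = []
        for _ in range(200):
            s, obs = 0, []
            for _t in range(30):
                obs.append(rng.normal(means[s], 1.0))
                s = rng.choice(3, p=a_true[s])
            seqs.append(np.array(obs)[:, None])
        model = hmm_init_viterbi(seqs, 3, 1, seed=0)
        hmm_reestimate_baum_welch(model, seqs, max_iter=30)
        a = model.transmat
        assert abs(a[0, 0] - 0.9) < 0.05
        assert abs(a[1, 1] - 0.9) < 0.05


def _toy_model_set(kind="GMM"):
    def gmm(mu):
        return DiagonalGMM(np.array([1.0]), np.array([[mu]]), np.array([[1.0]]))
    return ClassModelSet(models={"EXP": gmm(-3.0), "INS": gmm(0.0), "OTHER": gmm(3.0)},
                         kind="GMM", train_meta={"feature_kind": "TOY"})


class TestClassify:
    def test_assigns_to_generating_class(self, rng):
        ms = _toy_model_set()
        label, scores = classify(ms, np.array([-3.1]))
        assert label == "EXP"
        assert all(np.isfinite(v) for v in scores.values())

    def test_tie_breaks_in_canonical_order(self):
        g = DiagonalGMM(np.array([1.0]), np.array([[0.0]]), np.array([[1.0]]))
        ms = ClassModelSet(models={"EXP": g, "INS": g, "OTHER": g}, kind="GMM")
        label, _ = classify(ms, np.array([1.23]))
        assert label == "EXP"

    def test_prior_weighting_can_flip_a_borderline_decision(self):
        ms = _toy_model_set()
        x = np.array([-1.4])                 # between EXP (-3) and INS (0)
        assert classify(ms, x)[0] == "INS"
        heavy_exp = {"EXP": 0.98, "INS": 0.01, "OTHER": 0.01}
        assert classify(ms, x, priors=heavy_exp)[0] == "EXP"
        assert classify_frames(ms, x[None, :], priors=heavy_exp)[0] == "EXP"

    def test_vectorized_frames(self, rng):
        ms = _toy_model_set()
        x = np.array([[-3.0], [0.1], [2.9], [-2.8]])
        assert list(classify_frames(ms, x)) == ["EXP", "INS", "OTHER", "EXP"]


class TestSerialization:
    def test_gmm_roundtrip_exact(self, tmp_path, rng):
        x = rng.standard_normal((200, 3))
        ms = ClassModelSet(models={c: gmm_fit(x, 4, seed=i)
                                   for i, c in enumerate(("EXP", "INS", "OTHER"))},
                           kind="GMM", train_meta={"feature_kind": "FFT_MFCC"})
        p = tmp_path / "m.json"
        ms.save(p)
        back = ClassModelSet.load(p)
        for c in ("EXP", "INS", "OTHER"):
            assert np.array_equal(back.models[c].means, ms.models[c].means)
            assert np.array_equal(back.models[c].variances, ms.models[c].variances)
            assert np.array_equal(back.models[c].weights, ms.models[c].weights)

    def test_hmm_roundtrip_scores_identically(self, tmp_path, rng):
        model, seqs = _toy_hmm(seed=21)
        ms = ClassModelSet(models={"EXP": model, "INS": model, "OTHER": model},
                           kind="HMM", train_meta={})
        p = tmp_path / "h.json"
        ms.save(p)
        back = ClassModelSet.load(p)
        seq = rng.standard_normal((10, 2))
        assert sequence_loglik(back.models["EXP"], seq) == pytest.approx(
            sequence_loglik(model, seq), abs=1e-12)
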