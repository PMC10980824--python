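"""HMM engine: closed-form single-state fit, parameter recovery on
generated data, Viterbi against exhaustive path enumeration, and the
likelihood-based selection score."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import restdyn as rd
from restdyn.hmm import HMMModel, model_score, viterbi_decode


def _random_model(rng, K, d=1):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    means = rng.standard_normal((K, d)) * 2
    covs = np.stack([np.eye(d) * rng.uniform(0.3, 2.0) for _ in range(K)])
    return HMMModel(
        K=K, startprob=pi, transmat=A, means=means, covars=covs,
        score=np.nan, restart_index=0,
    )


def _brute_force_path(model, X):
    """Enumerate all K^T paths; max joint log-probability, lexicographic ties."""
    T = X.shape[0]
    logB = np.stack(
        [
            multivariate_normal.logpdf(X, model.means[k], model.covars[k])
            for k in range(model.K)
        ],
        axis=1,
    ).reshape(T, model.K)
    with np.errstate(divide="ignore"):
        lpi, lA = np.log(model.startprob), np.log(model.transmat)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(model.K), repeat=T):
        lp = lpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += lA[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
    return np.asarray(best)


class TestFit:
    def test_single_state_closed_form(self, rng):
        X = rng.standard_normal((500, 3)) + [1.0, -2.0, 0.5]
        m = rd.fit_hmm(X, K=1, n_restarts=1, seed=0)
        np.testing.assert_allclose(m.means[0], X.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(m.transmat, [[1.0]])
        np.testing.assert_allclose(m.covars[0], np.cov(X.T, bias=True), atol=1e-4)

    def test_two_state_parameter_recovery(self):
        cfg = rd.SimulationConfig(
            n_subjects=1, n_sessions=1, n_nodes=2, n_states=2,
            samples_per_session=20_000, noise_sd=1.0, seed=21,
            transition_matrix=np.array([[0.95, 0.05], [0.05, 0.95]]),
            state_patterns=np.array([[5.0, 5.0], [-5.0, -5.0]]),
        )
        paths = rd.simulate_state_paths(cfg)
        ds = rd.simulate_envelopes(paths, cfg)
        X = ds.data[("sub001", "RS1")].T
        m = rd.fit_hmm(X, K=2, n_restarts=3, seed=0)
        perm = rd.match_states(cfg.state_patterns, m.means)
        for k in range(2):
            np.testing.assert_allclose(
                m.means[perm[k]], cfg.state_patterns[k], atol=0.1
            )
            assert abs(m.transmat[perm[k], perm[k]] - 0.95) < 0.02

    def test_more_restarts_never_worse(self, rng):
        X = np.concatenate(
            [rng.standard_normal((300, 2)) + 3, rng.standard_normal((300, 2)) - 3]
        )
        s1 = rd.fit_hmm(X, K=2, n_restarts=1, seed=5).score
        s10 = rd.fit_hmm(X, K=2, n_restarts=10, seed=5).score
        assert s10 <= s1 + 1e-9

    def test_seeded_fit_is_reproducible(self, rng):
        X = rng.standard_normal((400, 2))
        a = rd.fit_hmm(X, K=2, n_restarts=2, seed=9)
        b = rd.fit_hmm(X, K=2, n_restarts=2, seed=9)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.transmat, b.transmat)
        assert a.score == b.score

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            rd.fit_hmm(np.array([[np.inf, 1.0]]), K=1)


class TestViterbi:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(77)
        for trial in range(100):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(4, 11))
            model = _random_model(rng, K)
            X = rng.standard_normal((T, 1)) * 2
            decoded = viterbi_decode(model, X).path
            expected = _brute_force_path(model, X)
            np.testing.assert_array_equal(decoded, expected, err_msg=f"trial {trial}")

    def test_single_state_constant_path(self, rng):
        model = _random_model(rng, 1)
        seq = viterbi_decode(model, rng.standard_normal((20, 1)))
        assert np.all(seq.path == 0)

    def test_dominant_emissions_follow_pattern(self):
        K = 2
        model = HMMModel(
            K=K,
            startprob=np.array([0.5, 0.5]),
            transmat=np.full((K, K), 0.5),
            means=np.array([[-10.0], [10.0]]),
            covars=np.ones((K, 1, 1)),
            score=np.nan,
            restart_index=0,
        )
        pattern = np.array([0, 1] * 10)
        X = model.means[pattern]
        np.testing.assert_array_equal(viterbi_decode(model, X).path, pattern)

    def test_dimension_mismatch_rejected(self, rng):
        model = _random_model(rng, 2, d=3)
        with pytest.raises(ValueError):
            viterbi_decode(model, rng.standard_normal((10, 2)))

    def test_exclusivity_and_occupancy_sum(self, rng):
        model = _random_model(rng, 3)
        bounds = [("s", "RS1", 0, 50), ("s", "RS2", 50, 120)]
        seq = viterbi_decode(model, rng.standard_normal((120, 1)), boundaries=bounds)
        for path in seq.split().values():
            fo = np.bincount(path, minlength=3) / path.size
            assert fo.sum() == pytest.approx(1.0, abs=1e-12)


class TestModelScore:
    def test_true_model_beats_perturbed_on_large_data(self):
        cfg = rd.SimulationConfig(
            n_subjects=1, n_sessions=1, n_nodes=2, n_states=2,
            samples_per_session=20_000, noise_sd=1.0, seed=31,
            state_patterns=np.array([[2.0, 0.0], [0.0, 2.0]]),
        )
        ds, truth = rd.simulate_dataset(cfg)
        X = ds.data[("sub001", "RS1")].T
        true_model = HMMModel(
            K=2, startprob=cfg.initial_probs, transmat=cfg.transition_matrix,
            means=cfg.state_patterns, covars=np.stack([np.eye(2), np.eye(2)]),
            score=np.nan, restart_index=0,
        )
        pert = HMMModel(
            K=2, startprob=cfg.initial_probs, transmat=cfg.transition_matrix,
            means=cfg.state_patterns + 0.5, covars=true_model.covars * 1.8,
            score=np.nan, restart_index=0,
        )
        assert model_score(true_model, X) <= model_score(pert, X)

    def test_duplicated_data_doubles_score(self, rng):
        model = _random_model(rng, 2, d=2)
        X = rng.standard_normal((200, 2))
        single = model_score(model, X)
        bounds = [("a", "RS1", 0, 200), ("a", "RS2", 200, 400)]
        double = model_score(model, np.vstack([X, X]), boundaries=bounds)
        assert double == pytest.approx(2 * single, rel=1e-6)

    def test_label_permutation_invariance(self, rng):
        model = _random_model(rng, 3, d=2)
        X = rng.standard_normal((150, 2))
        perm = np.array([2, 0, 1])
        permuted = HMMModel(
            K=3,
            startprob=model.startprob[perm],
            transmat=model.transmat[np.ix_(perm, perm)],
            means=model.means[perm],
            covars=model.covars[perm],
            score=np.nan,
            restart_index=0,
        )
        assert model_score(permuted, X) == pytest.approx(model_score(model, X), rel=1e-12)

    def test_agrees_with_hmmlearn_forward(self, rng):
        from hmmlearn.hmm import GaussianHMM

        model = _random_model(rng, 2, d=2)
        X = rng.standard_normal((100, 2))
        h = GaussianHMM(n_components=2, covariance_type="full", init_params="")
        h.startprob_, h.transmat_ = model.startprob, model.transmat
        h.means_, h.covars_ = model.means, model.covars
        assert model_score(model, X) == pytest.approx(-h.score(X), rel=1e-10)


def test_match_states_recovers_permutation(rng):
    maps = rng.standard_normal((4, 10))
    perm = np.array([3, 1, 0, 2])
    result = rd.match_states(maps, maps[perm])
    # other[result[k]] must equal reference[k]; sign flips must not matter
    np.testing.assert_allclose(maps[perm][result], maps)
    flipped = maps[perm] * np.array([[-1], [1], [-1], [1]])
    np.testing.assert_array_equal(rd.match_states(maps, flipped), result)
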