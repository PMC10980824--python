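"""K-state Gaussian-observation hidden Markov model on envelope PCs.

Fitting uses expectation-maximisation (Baum-Welch) with multiple random
restarts, retaining the restart with the best model-selection score
(negative log-likelihood; lower is better — the maximum-likelihood
analogue of selecting the lowest variational free energy). Decoding uses
the Viterbi algorithm, yielding a temporally exclusive state path: exactly
one active state per sample. Recording boundaries reset the chain, so the
concatenated group fit treats every recording as an independent sequence.

State labels are arbitrary up to permutation; cross-run comparisons must
first match states (see :func:`match_states`, Hungarian assignment on
absolute cosine similarity of state maps or means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp


@dataclass
class HMMModel:
    """Fitted model parameters plus the selection score of the winning restart."""

    K: int
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray  # (K, d)
    covars: np.ndarray  # (K, d, d)
    score: float  # negative log-likelihood; lower is better
    restart_index: int
    covariance_type: str = "full"
    converged: bool = True

    def validate(self) -> None:
        assert abs(self.startprob.sum() - 1) < 1e-8
        assert np.allclose(self.transmat.sum(axis=1), 1, atol=1e-8)


@dataclass
class StateSequence:
    """Temporally exclusive decoded state path over concatenated samples."""

    path: np.ndarray  # int in 0..K-1
    K: int
    boundaries: list[tuple[str, str, int, int]] = field(default_factory=list)

    def split(self) -> dict[tuple[str, str], np.ndarray]:
        return {
            (subj, sess): self.path[start:end]
            for (subj, sess, start, end) in self.boundaries
        }


def _lengths(boundaries, n_samples: int) -> list[int]:
    if not boundaries:
        return [n_samples]
    return [end - start for (_, _, start, end) in boundaries]


def _log_gaussian(X: np.ndarray, means: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """Per-state multivariate normal log-density, shape (T, K)."""
    T, d = X.shape
    K = means.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        cov = covars[k]
        chol = np.linalg.cholesky(cov)
        dev = X - means[k]
        sol = np.linalg.solve(chol, dev.T)
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def fit_hmm(
    X: np.ndarray,
    K: int = 8,
    n_restarts: int = 10,
    seed: int = 0,
    boundaries=None,
    covariance_type: str = "full",
    rel_tol: float = 1e-6,
    max_iter: int = 500,
    self_prob_init: float = 0.8,
) -> HMMModel:
    """Fit a K-state Gaussian HMM by EM with ``n_restarts`` random inits.

    Each restart initialises means/covariances randomly from a seeded
    stream; the transition matrix starts sticky (diagonal
    ``self_prob_init``), reflecting that envelope states dwell for several
    samples — this steers EM away from degenerate fast-alternation optima.
    The restart with the lowest negative log-likelihood is retained.
    Convergence is an EM log-likelihood gain below ``rel_tol`` per sample
    (or ``max_iter`` iterations). Degenerate covariances are regularised
    by hmmlearn's diagonal loading (min_covar).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if K < 1 or n_restarts < 1:
        raise ValueError("K and n_restarts must be >= 1")
    lengths = _lengths(boundaries, X.shape[0])
    abs_tol = rel_tol * X.shape[0]
    root = np.random.SeedSequence(seed)
    best = None
    failures = []
    for r, child in enumerate(root.spawn(n_restarts)):
        rs = np.random.RandomState(int(child.generate_state(1)[0] % (2**31)))
        model = GaussianHMM(
            n_components=K,
            covariance_type=covariance_type,
            n_iter=max_iter,
            tol=abs_tol,
            random_state=rs,
            min_covar=1e-6,
            init_params="mc",
        )
        model.startprob_ = np.full(K, 1.0 / K)
        if K == 1:
            model.transmat_ = np.ones((1, 1))
        else:
            model.transmat_ = np.full((K, K), (1.0 - self_prob_init) / (K - 1))
            np.fill_diagonal(model.transmat_, self_prob_init)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X, lengths=lengths)
                ll = model.score(X, lengths=lengths)
            except (ValueError, np.linalg.LinAlgError) as exc:  # degenerate restart
                failures.append(exc)
                continue
        if best is None or -ll < best.score:
            # hmmlearn's covars_ property always materialises full matrices
            covars = np.asarray(model.covars_, dtype=float)
            best = HMMModel(
                K=K,
                startprob=model.startprob_.copy(),
                transmat=model.transmat_.copy(),
                means=model.means_.copy(),
                covars=covars.copy(),
                score=-ll,
                restart_index=r,
                covariance_type=covariance_type,
                converged=bool(model.monitor_.converged),
            )
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures[-1]!r}")
    return best


def viterbi_decode(model: HMMModel, X: np.ndarray, boundaries=None) -> StateSequence:
    """Maximum-probability state path (log-space Viterbi, per recording).

    Ties are broken toward the lower state index (argmax convention), so
    decoding is fully deterministic. Each recording segment restarts from
    the initial distribution.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("X dimensionality does not match the model")
    logB = _log_gaussian(X, model.means, model.covars)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.startprob)
        log_A = np.log(model.transmat)
    path = np.empty(X.shape[0], dtype=np.int64)
    bounds = boundaries or [("", "", 0, X.shape[0])]
    for (_, _, start, end) in bounds:
        T = end - start
        delta = log_pi + logB[start]
        back = np.empty((T, model.K), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, None] + log_A
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(model.K)] + logB[start + t]
        s = int(np.argmax(delta))
        seg = np.empty(T, dtype=np.int64)
        seg[-1] = s
        for t in range(T - 1, 0, -1):
            s = int(back[t, s])
            seg[t - 1] = s
        path[start:end] = seg
    return StateSequence(path=path, K=model.K, boundaries=list(boundaries or []))


def model_score(model: HMMModel, X: np.ndarray, boundaries=None) -> float:
    """Selection criterion: negative log-likelihood of X under the model.

    Computed with the forward algorithm in log space, restarting at every
    recording boundary; deterministic given (model, X). Lower is better.
    """
    X = np.asarray(X, dtype=float)
    logB = _log_gaussian(X, model.means, model.covars)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.startprob)
        log_A = np.log(model.transmat)
    total = 0.0
    bounds = boundaries or [("", "", 0, X.shape[0])]
    for (_, _, start, end) in bounds:
        alpha = log_pi + logB[start]
        for t in range(start + 1, end):
            alpha = logsumexp(alpha[:, None] + log_A, axis=0) + logB[t]
        total += logsumexp(alpha)
    return float(-total)


def match_states(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Hungarian state matching by maximal absolute cosine similarity.

    ``reference`` and ``other`` are (K, n) state descriptors (power maps or
    observation means). Returns ``perm`` such that ``other[perm[k]]``
    corresponds to ``reference[k]``.
    """
    ref = np.asarray(reference, dtype=float)
    oth = np.asarray(other, dtype=float)
    norm_r = np.linalg.norm(ref, axis=1, keepdims=True)
    norm_o = np.linalg.norm(oth, axis=1, keepdims=True)
    norm_r[norm_r == 0] = 1.0
    norm_o[norm_o == 0] = 1.0
    sim = np.abs((ref / norm_r) @ (oth / norm_o).T)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(ref.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm
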