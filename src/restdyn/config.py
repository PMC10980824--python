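"""Configuration objects for the simulation and analysis pipeline.

Defaults encode the study conditions the pipeline emulates: seven 5-min
eyes-open resting-state sessions (RS1..RS7) around a motor-learning task,
126-node source-space envelopes sampled at 40 Hz, an 8-state envelope HMM
with 10 restarts, network-based statistics at t > 3.5 with 5000
permutations, a 60 % state-network threshold and a Bonferroni family of 21.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: Resting-state session labels in recording order.
SESSION_LABELS = tuple(f"RS{i}" for i in range(1, 8))

#: Map of testing windows to their (pre, post) resting-state sessions.
#: T1 = boost (~30 min post-learning), T2 = silent (~4 h), T3 = next day.
WINDOW_SESSIONS = {
    "T1": ("RS2", "RS3"),
    "T2": ("RS4", "RS5"),
    "T3": ("RS6", "RS7"),
}

#: Narrow frequency bands (Hz) used for band-limited connectome variants.
BANDS = {
    "wide": (4.0, 30.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


def _default_transition_matrix(K: int, self_prob: float = 0.85) -> np.ndarray:
    """Sticky uniform transition matrix with diagonal ``self_prob``.

    self_prob = 0.85 at 40 Hz gives a mean state lifetime of
    1/(1-0.85) = 6.67 samples ~ 167 ms, inside the 100-200 ms range
    typical of transient envelope states.
    """
    if K == 1:
        return np.ones((1, 1))
    A = np.full((K, K), (1.0 - self_prob) / (K - 1))
    np.fill_diagonal(A, self_prob)
    return A


def _default_state_patterns(K: int, n_nodes: int, amplitude: float = 1.0) -> np.ndarray:
    """Block mean-power patterns: state k elevates its own node block.

    Nodes are split round-robin into K groups; state k adds ``amplitude``
    to its group and -amplitude/(K-1) elsewhere so patterns are zero-mean
    across states at every node.
    """
    M = np.full((K, n_nodes), -amplitude / max(K - 1, 1))
    for n in range(n_nodes):
        M[n % K, n] = amplitude
    if K == 1:
        M[:] = 0.0
    return M


@dataclass
class SimulationConfig:
    """Generative settings for Markov-switching envelope data.

    Parameters
    ----------
    n_subjects, n_sessions, n_nodes, n_states
        Dataset dimensions. Sessions mirror RS1..RS7.
    samples_per_session
        Samples per recording (T). 12000 = 5 min at 40 Hz.
    fs
        Envelope sampling rate in Hz.
    transition_matrix, initial_probs
        Markov-chain parameters (row-stochastic K x K, length-K simplex).
        ``None`` selects the sticky/uniform defaults.
    state_patterns
        K x n_nodes mean-power offsets added upon state activation.
    noise_sd
        Per-node Gaussian observation noise SD.
    baseline
        Constant envelope offset (removed downstream by demeaning).
    mixing
        Optional n_nodes x n_nodes linear mixing matrix emulating
        instantaneous spatial leakage. ``None`` = identity.
    coupling
        Optional list of ``(node_indices, sd, timescale_s)`` tuples, each
        adding a shared slow Gaussian component to the listed nodes,
        emulating supra-second inter-node amplitude coupling.
    seed
        Top-level seed; per-recording streams are derived deterministically.
    """

    n_subjects: int = 30
    n_sessions: int = 7
    n_nodes: int = 126
    n_states: int = 8
    samples_per_session: int = 12000
    fs: float = 40.0
    transition_matrix: np.ndarray | None = None
    initial_probs: np.ndarray | None = None
    state_patterns: np.ndarray | None = None
    noise_sd: float = 0.3
    baseline: float = 0.0
    mixing: np.ndarray | None = None
    coupling: list[tuple[Sequence[int], float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = _default_transition_matrix(self.n_states)
        if self.initial_probs is None:
            self.initial_probs = np.full(self.n_states, 1.0 / self.n_states)
        if self.state_patterns is None:
            self.state_patterns = _default_state_patterns(self.n_states, self.n_nodes)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.state_patterns = np.asarray(self.state_patterns, dtype=float)
        self.validate()

    def validate(self) -> None:
        K = self.n_states
        if K < 1:
            raise ValueError("n_states must be >= 1")
        if self.samples_per_session < 2:
            raise ValueError("samples_per_session must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        A = self.transition_matrix
        if A.shape != (K, K):
            raise ValueError(f"transition_matrix must be {K}x{K}, got {A.shape}")
        if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        pi = self.initial_probs
        if pi.shape != (K,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("initial_probs must be a length-K simplex vector")
        if self.state_patterns.shape != (K, self.n_nodes):
            raise ValueError("state_patterns must be n_states x n_nodes")
        if self.mixing is not None:
            mix = np.asarray(self.mixing, dtype=float)
            if mix.shape != (self.n_nodes, self.n_nodes):
                raise ValueError("mixing must be n_nodes x n_nodes")

    def recording_seed(self, subject: int, session: int) -> np.random.SeedSequence:
        """Deterministic per-recording seed stream.

        Uses ``SeedSequence(seed, spawn_key=(subject, session))`` so every
        (subject, session) pair has an independent, auditable stream and
        the whole dataset is reproducible from the single top-level seed.
        """
        return np.random.SeedSequence(self.seed, spawn_key=(subject, session))


@dataclass
class HMMConfig:
    """Envelope-HMM inference settings (8 states, 10 random restarts)."""

    n_states: int = 8
    n_restarts: int = 10
    covariance_type: str = "full"  # "diag" available
    rel_tol: float = 1e-6
    max_iter: int = 500


@dataclass
class NBSConfig:
    """Network-based statistics settings (t > 3.5, 5000 permutations)."""

    threshold: float = 3.5
    n_perm: int = 5000


@dataclass
class RunConfig:
    """Full pipeline configuration. Defaults are the printed study settings."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    nbs: NBSConfig = field(default_factory=NBSConfig)
    band: str = "wide"
    n_pca_components: int = 40
    state_network_fraction: float = 0.60
    bonferroni_factor: int = 21
    smooth_s: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("RunConfig requires an explicit seed")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; one of {sorted(BANDS)}")

    def hash(self) -> str:
        """Short stable digest of the full configuration."""

        def enc(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(type(obj))

        payload = json.dumps(
            {
                "simulation": asdict(self.simulation),
                "hmm": asdict(self.hmm),
                "nbs": asdict(self.nbs),
                "band": self.band,
                "n_pca_components": self.n_pca_components,
                "state_network_fraction": self.state_network_fraction,
                "bonferroni_factor": self.bonferroni_factor,
                "smooth_s": self.smooth_s,
                "seed": self.seed,
            },
            sort_keys=True,
            default=enc,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
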