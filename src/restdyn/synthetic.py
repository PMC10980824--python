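"""Synthetic inputs with known ground truth.

Every input the analysis needs can be generated here: Markov-switching
amplitude-envelope datasets (known state paths and spatial patterns, with
optional linear mixing emulating source leakage and optional slow shared
components emulating supra-second amplitude coupling), connectome sets with
planted edge effects for permutation-statistics power/FWER checks, and
finger-tapping keypress streams for the behaviour module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig, SESSION_LABELS

#: The fixed 5-element finger-tapping sequence (little-index-ring-middle-little).
FTT_SEQUENCE = (4, 1, 3, 2, 4)


@dataclass
class EnvelopeDataset:
    """Per subject x session node amplitude-envelope time series.

    ``data[(subject, session)]`` is an (n_nodes, T) float array. Session
    labels follow RS1..RS7; time lengths may differ per recording.
    """

    subjects: list[str]
    sessions: list[str]
    data: dict[tuple[str, str], np.ndarray]
    fs: float
    band: tuple[float, float] = (4.0, 30.0)

    @property
    def n_nodes(self) -> int:
        return next(iter(self.data.values())).shape[0]

    def recordings(self):
        """Iterate (subject, session, matrix) in subject-major order."""
        for subj in self.subjects:
            for sess in self.sessions:
                if (subj, sess) in self.data:
                    yield subj, sess, self.data[(subj, sess)]


@dataclass
class GroundTruth:
    """Generator-side truth used as oracle for recovery tests."""

    state_paths: dict[tuple[str, str], np.ndarray]
    config: SimulationConfig
    temporal_params: pd.DataFrame | None = None
    planted_edges: list[tuple[int, int]] = field(default_factory=list)
    effect_size: float = 0.0


def _subject_labels(n: int) -> list[str]:
    return [f"sub{i + 1:03d}" for i in range(n)]


def simulate_state_paths(cfg: SimulationConfig) -> dict[tuple[str, str], np.ndarray]:
    """Draw one Markov-chain state path per (subject, session).

    Paths are 0-based integer arrays of length ``cfg.samples_per_session``,
    sampled from (initial_probs, transition_matrix). Each recording uses an
    independent stream derived from ``cfg.seed`` via
    ``SeedSequence(seed, spawn_key=(subject_index, session_index))``.
    """
    cfg.validate()
    subjects = _subject_labels(cfg.n_subjects)
    sessions = list(SESSION_LABELS[: cfg.n_sessions])
    K = cfg.n_states
    # Pre-compute per-row CDFs once; inverse-CDF sampling keeps the loop cheap.
    cdf_A = np.cumsum(cfg.transition_matrix, axis=1)
    cdf_pi = np.cumsum(cfg.initial_probs)
    paths: dict[tuple[str, str], np.ndarray] = {}
    for si, subj in enumerate(subjects):
        for ti, sess in enumerate(sessions):
            rng = np.random.default_rng(cfg.recording_seed(si, ti))
            u = rng.random(cfg.samples_per_session)
            path = np.empty(cfg.samples_per_session, dtype=np.int64)
            path[0] = np.searchsorted(cdf_pi, u[0], side="right")
            for t in range(1, cfg.samples_per_session):
                path[t] = np.searchsorted(cdf_A[path[t - 1]], u[t], side="right")
            np.clip(path, 0, K - 1, out=path)
            paths[(subj, sess)] = path
    return paths


def _slow_component(rng: np.random.Generator, T: int, fs: float, timescale_s: float) -> np.ndarray:
    """Zero-mean unit-SD slow signal: white noise moving-averaged over timescale_s."""
    win = max(int(round(timescale_s * fs)), 1)
    x = rng.standard_normal(T + win - 1)
    sm = np.convolve(x, np.ones(win) / win, mode="valid")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def simulate_envelopes(
    paths: dict[tuple[str, str], np.ndarray], cfg: SimulationConfig
) -> EnvelopeDataset:
    """Generate envelopes ``baseline + M[state(t)] + slow coupling + noise``.

    The observation model is additive Gaussian on top of state mean-power
    patterns, matching the Gaussian observation model the HMM assumes. An
    optional mixing matrix is applied last (instantaneous linear leakage).
    Noise streams are derived from the same per-recording seeds as the
    paths (children of the recording stream), so the full dataset is
    reproducible from ``cfg.seed`` alone.
    """
    cfg.validate()
    subjects = _subject_labels(cfg.n_subjects)
    sessions = list(SESSION_LABELS[: cfg.n_sessions])
    data: dict[tuple[str, str], np.ndarray] = {}
    for si, subj in enumerate(subjects):
        for ti, sess in enumerate(sessions):
            key = (subj, sess)
            if key not in paths:
                raise ValueError(f"missing state path for {key}")
            path = np.asarray(paths[key])
            T = path.shape[0]
            if path.min() < 0 or path.max() >= cfg.n_states:
                raise ValueError("state path out of range for config")
            child = cfg.recording_seed(si, ti).spawn(1)[0]
            rng = np.random.default_rng(child)
            env = cfg.baseline + cfg.state_patterns[path].T  # (n_nodes, T)
            env = env + rng.standard_normal((cfg.n_nodes, T)) * cfg.noise_sd
            if cfg.coupling:
                for nodes, sd, timescale_s in cfg.coupling:
                    shared = _slow_component(rng, T, cfg.fs, timescale_s) * sd
                    env[np.asarray(nodes)] += shared
            if cfg.mixing is not None:
                env = np.asarray(cfg.mixing, dtype=float) @ env
            data[key] = env
    return EnvelopeDataset(subjects=subjects, sessions=sessions, data=data, fs=cfg.fs)


def simulate_dataset(cfg: SimulationConfig) -> tuple[EnvelopeDataset, GroundTruth]:
    """Convenience: paths + envelopes + ground-truth record in one call."""
    paths = simulate_state_paths(cfg)
    dataset = simulate_envelopes(paths, cfg)
    return dataset, GroundTruth(state_paths=paths, config=cfg)


# ---------------------------------------------------------------------------
# Connectome simulation with planted effects
# ---------------------------------------------------------------------------

def simulate_connectome_set(
    n_subjects: int,
    n_nodes: int,
    seed: int,
    base_level: float = 0.2,
    subject_sd: float = 0.15,
    n_conditions: int = 2,
) -> np.ndarray:
    """Simulate paired condition connectomes, shape (n_conditions, n_subjects, n, n).

    Every matrix is ``base + N(0, subject_sd)`` edgewise, symmetrized, with
    unit diagonal; conditions are exchangeable under the null. subject_sd
    = 0.15 reflects typical between-subject variability of envelope
    correlations.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, 1)
    out = np.empty((n_conditions, n_subjects, n_nodes, n_nodes))
    for c in range(n_conditions):
        for s in range(n_subjects):
            mat = np.eye(n_nodes)
            vals = np.clip(base_level + rng.standard_normal(iu[0].size) * subject_sd, -1, 1)
            mat[iu] = vals
            mat[(iu[1], iu[0])] = vals
            out[c, s] = mat
    return out


def plant_connectome_effect(
    base_matrices: np.ndarray,
    edges: list[tuple[int, int]],
    delta: float,
    group_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Increase the listed edges by ``delta`` for flagged matrices.

    ``base_matrices`` has shape (..., n, n); ``group_mask`` is a boolean
    array over the leading axes selecting which matrices receive the
    effect (default: all). Output is re-symmetrized and clipped to [-1, 1].
    """
    mats = np.array(base_matrices, dtype=float, copy=True)
    n = mats.shape[-1]
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise IndexError(f"edge ({i}, {j}) out of range for {n} nodes")
    flat = mats.reshape(-1, n, n)
    if group_mask is None:
        mask = np.ones(flat.shape[0], dtype=bool)
    else:
        mask = np.asarray(group_mask, dtype=bool).reshape(-1)
        if mask.size != flat.shape[0]:
            raise ValueError("group_mask does not match matrix count")
    for idx in np.nonzero(mask)[0]:
        for i, j in edges:
            flat[idx, i, j] += delta
            flat[idx, j, i] = flat[idx, i, j]
    np.clip(flat, -1.0, 1.0, out=flat)
    diag = np.arange(n)
    flat[:, diag, diag] = np.clip(np.diagonal(base_matrices.reshape(-1, n, n), axis1=1, axis2=2), -1, 1)
    return flat.reshape(mats.shape)


# ---------------------------------------------------------------------------
# Finger-tapping keypress simulation
# ---------------------------------------------------------------------------

def simulate_ftt_blocks(
    n_blocks: int = 26,
    mean_rate: float = 3.0,
    error_rate: float = 0.02,
    seed: int = 0,
    block_duration_s: float = 30.0,
    learning_gain: float = 0.0,
    learning_tau_blocks: float = 5.0,
) -> pd.DataFrame:
    """Simulate keypress streams for 30-s finger-tapping blocks.

    Correct presses follow the repeating 4-1-3-2-4 sequence; each press is
    independently corrupted (replaced by a different key in 1..4) with
    probability ``error_rate``. Inter-press intervals are exponential with
    mean ``1/rate_b``; with ``learning_gain`` > 0 the rate rises across
    blocks as ``mean_rate * (1 + gain * (1 - exp(-(b-1)/tau)))``,
    emulating the within-session learning curve.

    Returns a tidy frame with columns ``block`` (1-based), ``t_ms``
    (within-block time), ``key``.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be > 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = np.asarray(FTT_SEQUENCE)
    rows = []
    for b in range(1, n_blocks + 1):
        rate = mean_rate * (1.0 + learning_gain * (1.0 - np.exp(-(b - 1) / learning_tau_blocks)))
        t = 0.0
        pos = 0
        while True:
            t += rng.exponential(1.0 / rate)
            if t >= block_duration_s:
                break
            key = int(seq[pos % seq.size])
            if error_rate > 0 and rng.random() < error_rate:
                wrong = [k for k in (1, 2, 3, 4) if k != key]
                key = int(wrong[rng.integers(len(wrong))])
            rows.append((b, t * 1000.0, key))
            pos += 1
    return pd.DataFrame(rows, columns=["block", "t_ms", "key"]).astype(
        {"block": np.int64, "t_ms": float, "key": np.int64}
    )
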