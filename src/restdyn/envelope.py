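"""Envelope preprocessing: Hilbert amplitude, overlapping-window
downsampling, standardisation + concatenation, and pre-whitening PCA.

The target representation is the matrix a group-level envelope HMM
consumes: per-recording node envelopes are demeaned, scaled by a single
global standard deviation, temporally concatenated subject-major /
session-minor with explicit boundary records, then reduced to 40
pre-whitened principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from sklearn.decomposition import PCA

from .synthetic import EnvelopeDataset


@dataclass
class ConcatenatedEnvelope:
    """Concatenated standardized envelopes plus PCA projection.

    ``X`` is (samples, nodes) standardized data; ``Z`` is (samples,
    n_components) whitened PC scores; ``boundaries`` is an ordered list of
    (subject, session, start, end) half-open row ranges partitioning X.
    """

    X: np.ndarray
    boundaries: list[tuple[str, str, int, int]]
    fs: float
    Z: np.ndarray | None = None
    pca_basis: np.ndarray | None = None  # (n_components, nodes), unit rows
    pca_mean: np.ndarray | None = None
    pca_scale: np.ndarray | None = None  # per-component SDs used to whiten
    n_components: int | None = None

    @property
    def lengths(self) -> list[int]:
        return [end - start for (_, _, start, end) in self.boundaries]

    def split(self, M: np.ndarray | None = None) -> dict[tuple[str, str], np.ndarray]:
        """De-concatenate a (samples, ...) array back into recordings."""
        arr = self.X if M is None else M
        return {
            (subj, sess): arr[start:end]
            for (subj, sess, start, end) in self.boundaries
        }


def hilbert_envelope(signal: np.ndarray) -> np.ndarray:
    """Amplitude envelope: modulus of the analytic signal."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("signal must be 1-D with length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return np.abs(hilbert(x))


def moving_average_downsample(
    x: np.ndarray, fs: float, win_s: float = 0.100, step_s: float = 0.025
) -> tuple[np.ndarray, float]:
    """Overlapping moving-window average downsampler.

    Output sample m is the mean of x over the half-open window
    [m*step, m*step + win) seconds, so 100-ms windows sliding every 25 ms
    (75 % overlap) yield an effective output rate of 1/step = 40 Hz.
    Returns (downsampled signal, output rate in Hz). Works along the last
    axis for 2-D input.
    """
    if not (win_s >= step_s > 0):
        raise ValueError("need win_s >= step_s > 0")
    x = np.asarray(x, dtype=float)
    win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    if win < 1 or step < 1:
        raise ValueError("window/step shorter than one input sample")
    T = x.shape[-1]
    if T < win:
        raise ValueError("signal shorter than one window")
    n_out = (T - win) // step + 1
    # cumulative-sum windowed means; partial trailing window dropped
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    starts = np.arange(n_out) * step
    out = (c[..., starts + win] - c[..., starts]) / win
    return out, 1.0 / step_s


def standardize_concatenate(dataset: EnvelopeDataset) -> ConcatenatedEnvelope:
    """Demean each node per recording, scale by one global SD, concatenate.

    Channels are demeaned independently within each recording; the whole
    concatenated matrix is then divided by a single scalar standard
    deviation ("global variance" normalisation). Rows stack subject-major,
    session-minor, with half-open boundary records.
    """
    blocks = []
    boundaries: list[tuple[str, str, int, int]] = []
    start = 0
    for subj, sess, env in dataset.recordings():
        block = np.asarray(env, dtype=float).T  # (T, nodes)
        block = block - block.mean(axis=0, keepdims=True)
        blocks.append(block)
        boundaries.append((subj, sess, start, start + block.shape[0]))
        start += block.shape[0]
    if not blocks:
        raise ValueError("empty dataset")
    X = np.concatenate(blocks, axis=0)
    global_sd = X.std()
    if global_sd == 0:
        raise ValueError("zero global variance")
    X /= global_sd
    return ConcatenatedEnvelope(X=X, boundaries=boundaries, fs=dataset.fs)


def prewhiten_pca(concat: ConcatenatedEnvelope, n_components: int = 40) -> ConcatenatedEnvelope:
    """Project onto the top principal components, scaled to unit variance.

    Components with (near-)zero variance are dropped with a warning when
    the data rank is below ``n_components``. The basis, mean and
    per-component scales are stored for mapping state-space results back
    to node space.
    """
    X = concat.X
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    sd = scores.std(axis=0, ddof=0)
    keep = sd > 1e-10 * max(sd.max(), 1.0)
    if not np.all(keep):
        warnings.warn(
            f"data rank {int(keep.sum())} < requested {n_components} components; reducing"
        )
        scores, sd = scores[:, keep], sd[keep]
        basis = pca.components_[keep]
    else:
        basis = pca.components_
    concat.Z = scores / sd
    concat.pca_basis = basis
    concat.pca_mean = pca.mean_
    concat.pca_scale = sd
    concat.n_components = scores.shape[1]
    return concat


def pca_backproject(concat: ConcatenatedEnvelope, Z: np.ndarray | None = None) -> np.ndarray:
    """Map whitened PC scores back to node space (retained subspace only)."""
    if concat.pca_basis is None:
        raise ValueError("run prewhiten_pca first")
    scores = concat.Z if Z is None else Z
    return (scores * concat.pca_scale) @ concat.pca_basis + concat.pca_mean
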