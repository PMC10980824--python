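"""Amplitude-envelope functional connectomes.

Per subject/session/band we build a symmetric node x node matrix of slow
amplitude-envelope correlations (Pearson correlation between
moving-average-smoothed envelopes), a per-node power vector (signal
variance, controlling for power-induced connectivity effects) and a node
registry combining the 116-region AAL atlas with extra motor-learning
nodes (126 in the reference configuration). An optional pairwise
regression orthogonalization stage stands in for source-leakage
correction: before correlating a pair, the target signal is residualized
on the seed, removing instantaneous linear leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

REGISTRY_COLUMNS = ["id", "name", "mni_x", "mni_y", "mni_z", "source"]


@dataclass
class Connectome:
    """Symmetric envelope-correlation matrix + node power for one recording."""

    matrix: np.ndarray
    power: np.ndarray
    registry: pd.DataFrame | None = None
    subject: str = ""
    session: str = ""
    band: str = "wide"


def load_aal_table() -> pd.DataFrame:
    """The 116-region AAL atlas node table shipped with the package."""
    with resources.files("restdyn.data").joinpath("aal116_nodes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_motor_nodes() -> pd.DataFrame:
    """Synthetic 10-node motor-learning literature table (stand-in registry)."""
    with resources.files("restdyn.data").joinpath("motor_nodes_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def build_node_registry(aal_table: pd.DataFrame, extra_nodes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Concatenate atlas and extra nodes (atlas first) with uniqueness checks."""
    parts = [aal_table]
    if extra_nodes is not None and len(extra_nodes):
        parts.append(extra_nodes)
    registry = pd.concat(parts, ignore_index=True)
    for col in ("id", "name"):
        if col in registry and registry[col].duplicated().any():
            dup = registry[col][registry[col].duplicated()].iloc[0]
            raise ValueError(f"duplicate node {col}: {dup!r}")
    return registry


def default_registry() -> pd.DataFrame:
    """The 126-node reference registry (116 AAL + 10 motor-literature nodes)."""
    return build_node_registry(load_aal_table(), load_motor_nodes())


def _smooth(signals: np.ndarray, fs: float, smooth_s: float) -> np.ndarray:
    """Moving-average smooth along the last axis (slow-envelope timescale)."""
    win = max(int(round(smooth_s * fs)), 1)
    if win <= 1:
        return signals
    kernel = np.ones(win) / win
    return np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="valid"), -1, signals)


def orthogonalize(target: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Residualize ``target`` on ``seed`` (least squares, with intercept).

    Removes the instantaneous linear component of the seed from the
    target; inputs already orthogonal pass through unchanged. A constant
    seed is an error.
    """
    seed = np.asarray(seed, dtype=float)
    target = np.asarray(target, dtype=float)
    sc = seed - seed.mean()
    denom = np.dot(sc, sc)
    if denom == 0:
        raise ValueError("constant seed signal")
    tc = target - target.mean()
    beta = np.dot(tc, sc) / denom
    return tc - beta * sc


def envelope_correlation(
    node_signals: np.ndarray,
    fs: float,
    smooth_s: float = 1.0,
    orthogonalize_pairs: bool = False,
) -> np.ndarray:
    """Slow amplitude-envelope correlation matrix.

    Envelopes are moving-average smoothed over ``smooth_s`` seconds (the
    supra-second timescale of envelope connectivity), then Pearson
    correlated. With ``orthogonalize_pairs`` the correlation of each pair
    is the average over both residualization directions (target on seed),
    the generic stand-in for leakage correction. Zero-variance channels
    give NaN rows/columns; the diagonal is 1.
    """
    S = np.asarray(node_signals, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("need >= 2 node signals")
    Ssm = _smooth(S, fs, smooth_s)
    n = S.shape[0]
    sd = Ssm.std(axis=1)
    if not orthogonalize_pairs:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(Ssm)
        C[sd == 0, :] = np.nan
        C[:, sd == 0] = np.nan
    else:
        C = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                if sd[i] == 0 or sd[j] == 0:
                    continue
                rs = []
                for a, b in ((i, j), (j, i)):
                    resid = orthogonalize(Ssm[b], Ssm[a])
                    if resid.std() < 1e-12 * sd[a]:
                        rs.append(np.nan)  # perfectly collinear pair
                    else:
                        rs.append(np.corrcoef(Ssm[a], resid)[0, 1])
                C[i, j] = C[j, i] = np.nanmean(rs) if np.isfinite(rs).any() else np.nan
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def node_power(node_signals: np.ndarray) -> np.ndarray:
    """Per-node signal variance (power estimate)."""
    S = np.asarray(node_signals, dtype=float)
    if S.shape[-1] < 2:
        raise ValueError("need length >= 2")
    return S.var(axis=-1, ddof=1)


def build_connectome(
    node_signals: np.ndarray,
    fs: float,
    smooth_s: float = 1.0,
    registry: pd.DataFrame | None = None,
    orthogonalize_pairs: bool = False,
    subject: str = "",
    session: str = "",
    band: str = "wide",
) -> Connectome:
    """Assemble matrix + power vector (+ registry) for one recording."""
    return Connectome(
        matrix=envelope_correlation(node_signals, fs, smooth_s, orthogonalize_pairs),
        power=node_power(node_signals),
        registry=registry,
        subject=subject,
        session=session,
        band=band,
    )


def mean_connectivity_strength(matrix: np.ndarray, network_nodes) -> float:
    """Mean connectivity strength of a state network.

    Restrict the matrix to the network's nodes; per node, average its
    off-diagonal correlations within the network; return the mean of the
    node means. For a symmetric matrix this equals the grand mean of all
    off-diagonal entries of the restricted matrix.
    """
    nodes = np.asarray(list(network_nodes), dtype=np.int64)
    if nodes.size < 2:
        raise ValueError("state network needs >= 2 nodes")
    sub = np.asarray(matrix, dtype=float)[np.ix_(nodes, nodes)]
    m = sub.shape[0]
    off = ~np.eye(m, dtype=bool)
    node_means = np.array([sub[i, off[i]].mean() for i in range(m)])
    return float(node_means.mean())
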