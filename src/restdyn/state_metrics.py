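"""Per-state temporal parameters, state power maps and state networks.

From a decoded, temporally exclusive state path we compute, per state and
recording: FO (fractional occupancy — fraction of samples the state is
active), NO (number of occurrences — count of activation runs), MLT (mean
lifetime — mean activation-run duration, seconds) and MIL (mean interval
length — mean duration of inactive gaps strictly between two visits,
seconds). Unvisited states get NO = 0, FO = 0 and missing MLT/MIL; a state
occupying a whole recording has a missing MIL.

State power maps are node-wise partial correlations between a state's
activation indicator and the standardized node envelopes, controlling for
the other states' indicators (one state dropped as reference, since the K
indicators sum to one). The state network of a map is the node subset
where |map| reaches at least a fraction (default 60 %) of its maximum
absolute value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def run_lengths(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean vector: (run values, run lengths)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty(0, dtype=bool), np.empty(0, dtype=np.int64)
    change = np.nonzero(np.diff(mask))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [mask.size]])
    return mask[starts], ends - starts


def temporal_params(path: np.ndarray, fs: float, K: int | None = None) -> pd.DataFrame:
    """Temporal parameters of one recording's state path.

    Returns a frame indexed 0..K-1 with columns NO, FO, MLT_s, MIL_s.
    MIL counts only inactive runs bounded by visits on both sides.
    """
    path = np.asarray(path, dtype=np.int64)
    if path.size == 0:
        raise ValueError("empty state path")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if K is None:
        K = int(path.max()) + 1
    T = path.size
    rows = []
    for k in range(K):
        active = path == k
        vals, lens = run_lengths(active)
        act_lens = lens[vals]
        no = int(act_lens.size)
        fo = float(active.sum() / T)
        mlt = float(act_lens.mean() / fs) if no > 0 else np.nan
        if no >= 2:
            # inactive runs strictly between two activation runs: all
            # non-active runs except a leading and/or trailing one
            inact = lens[~vals]
            if not vals[0]:
                inact = inact[1:]
            if not vals[-1]:
                inact = inact[:-1]
            mil = float(inact.mean() / fs) if inact.size else np.nan
        else:
            mil = np.nan
        rows.append((k, no, fo, mlt, mil))
    return pd.DataFrame(rows, columns=["state", "NO", "FO", "MLT_s", "MIL_s"]).set_index("state")


def temporal_params_table(
    paths: dict[tuple[str, str], np.ndarray], fs: float, K: int
) -> pd.DataFrame:
    """Stack per-recording temporal parameters into one tidy table."""
    frames = []
    for (subj, sess), path in paths.items():
        tp = temporal_params(path, fs=fs, K=K).reset_index()
        tp.insert(0, "session", sess)
        tp.insert(0, "subject", subj)
        frames.append(tp)
    return pd.concat(frames, ignore_index=True)


def state_power_maps(
    path: np.ndarray, envelopes: np.ndarray, K: int | None = None
) -> np.ndarray:
    """Node-wise partial correlation between state indicators and envelopes.

    ``envelopes`` is (samples, nodes), aligned with ``path``. For state k
    the controls are the indicators of the other states minus one
    reference (the last state, or the first when k is the last), avoiding
    the exact collinearity of the full indicator set. Constant envelope
    channels yield NaN. Returns a (K, nodes) map matrix in [-1, 1].
    """
    path = np.asarray(path, dtype=np.int64)
    E = np.asarray(envelopes, dtype=float)
    if E.shape[0] != path.size:
        raise ValueError("path and envelopes must share the sample axis")
    if K is None:
        K = int(path.max()) + 1
    ind = np.stack([(path == k).astype(float) for k in range(K)], axis=1)
    maps = np.full((K, E.shape[1]), np.nan)
    for k in range(K):
        ref = K - 1 if k != K - 1 else 0
        ctrl_idx = [j for j in range(K) if j not in (k, ref)]
        x = ind[:, k]
        if x.std() == 0:
            continue  # state never (or always) active: map undefined
        if ctrl_idx:
            Zc = np.column_stack([np.ones(path.size), ind[:, ctrl_idx]])
            beta_E, *_ = np.linalg.lstsq(Zc, E, rcond=None)
            beta_x, *_ = np.linalg.lstsq(Zc, x, rcond=None)
            Er = E - Zc @ beta_E
            xr = x - Zc @ beta_x
        else:
            Er, xr = E, x
        xr = xr - xr.mean()
        Er = Er - Er.mean(axis=0, keepdims=True)
        sx = xr.std()
        sE = Er.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Er.T @ xr) / (path.size * sE * sx)
        r[sE == 0] = np.nan
        maps[k] = np.clip(r, -1.0, 1.0)
    return maps


def extract_state_network(power_map: np.ndarray, fraction: float = 0.60) -> np.ndarray:
    """Indices of nodes with |map| >= fraction * max |map|."""
    m = np.asarray(power_map, dtype=float)
    finite = np.isfinite(m)
    if not finite.any():
        raise ValueError("power map has no finite values")
    peak = np.nanmax(np.abs(m))
    if peak == 0:
        return np.nonzero(finite)[0]
    return np.nonzero(finite & (np.abs(m) >= fraction * peak))[0]
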