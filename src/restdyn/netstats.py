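"""Network-based statistics (NBS): permutation FWER over connected components.

Edge-wise statistics (paired t across subjects, or Pearson correlation
with a covariate) are thresholded (default t > 3.5); maximal connected
components of the suprathreshold graph are the inferential units, with
size = edge count ("extent"). Family-wise error is controlled by building
the permutation null of the *maximum* component size — sign-flipping
within-subject difference matrices for the paired design, reshuffling the
covariate across subjects for the correlation design — and

    p_fwer(component) = (1 + #{perm max-size >= observed size}) / (n_perm + 1).

Positive and negative tails are analysed separately (directional effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy import stats


@dataclass
class Component:
    """One suprathreshold connected component."""

    edges: list[tuple[int, int]]
    nodes: list[int]
    size: int  # edge count
    p_fwer: float = np.nan


@dataclass
class NBSResult:
    stat_matrix: np.ndarray
    threshold: float
    tail: str
    components: list[Component]
    null_max_size: np.ndarray
    n_perm: int
    seed: int

    @property
    def significant(self) -> list[Component]:
        return [c for c in self.components if c.p_fwer <= 0.05]

    def node_weights(self) -> dict[int, float]:
        """Node weight = sum of suprathreshold edge statistics incident to it."""
        w: dict[int, float] = {}
        for comp in self.components:
            for i, j in comp.edges:
                s = abs(self.stat_matrix[i, j])
                w[i] = w.get(i, 0.0) + s
                w[j] = w.get(j, 0.0) + s
        return w


def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, 1)


def _edge_vectors(matrices: np.ndarray) -> np.ndarray:
    """(n_subjects, n_edges) upper-triangle edge values."""
    mats = np.asarray(matrices, dtype=float)
    iu = _triu(mats.shape[-1])
    return mats[..., iu[0], iu[1]]


def _paired_t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """Vectorized paired t over the first axis; NaN for zero-variance edges."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def _vec_to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = _triu(n)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def edge_paired_t(matrices_a: np.ndarray, matrices_b: np.ndarray) -> np.ndarray:
    """Edge-wise paired t statistic of (A - B) across matched subjects."""
    A, B = np.asarray(matrices_a), np.asarray(matrices_b)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValueError("need matched subject stacks with >= 3 subjects")
    t = _paired_t_from_diffs(_edge_vectors(A) - _edge_vectors(B))
    return _vec_to_matrix(t, A.shape[-1])


def edge_correlation(matrices: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Edge-wise Pearson correlation with a subject covariate."""
    y = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("covariate must be finite")
    if y.std() == 0:
        raise ValueError("constant covariate")
    X = _edge_vectors(matrices)
    r = _corr_with_covariate(X, y)
    return _vec_to_matrix(r, np.asarray(matrices).shape[-1])


def _corr_with_covariate(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return r


def suprathreshold_components(
    stat_matrix: np.ndarray, threshold: float, tail: str = "greater"
) -> list[Component]:
    """Maximal connected components of the thresholded statistic graph.

    ``tail='greater'`` keeps edges with stat > threshold; ``'less'`` keeps
    stat < -threshold. NaN statistics are never suprathreshold.
    """
    S = np.asarray(stat_matrix, dtype=float)
    n = S.shape[0]
    iu = _triu(n)
    vals = S[iu]
    if tail == "greater":
        keep = vals > threshold
    elif tail == "less":
        keep = vals < -threshold
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    keep &= np.isfinite(vals)
    return _components_from_mask(keep, iu, n)


def _components_from_mask(keep: np.ndarray, iu, n: int) -> list[Component]:
    ki, kj = iu[0][keep], iu[1][keep]
    if ki.size == 0:
        return []
    graph = coo_matrix((np.ones(ki.size), (ki, kj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    comps: dict[int, Component] = {}
    for i, j in zip(ki, kj):
        lab = labels[i]
        comp = comps.setdefault(lab, Component(edges=[], nodes=[], size=0))
        comp.edges.append((int(i), int(j)))
    out = []
    for comp in comps.values():
        comp.nodes = sorted({v for e in comp.edges for v in e})
        comp.size = len(comp.edges)
        out.append(comp)
    out.sort(key=lambda c: -c.size)
    return out


def _max_component_size(keep: np.ndarray, iu, n: int) -> int:
    """Size (edge count) of the largest component; cheap paths for 0/1 edges."""
    cnt = int(keep.sum())
    if cnt <= 1:
        return cnt
    comps = _components_from_mask(keep, iu, n)
    return comps[0].size if comps else 0


def nbs_fwer(
    data,
    design: str,
    threshold: float = 3.5,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "greater",
    covariate: np.ndarray | None = None,
) -> NBSResult:
    """Full NBS analysis with permutation FWER control.

    Parameters
    ----------
    data
        Paired design: tuple ``(matrices_a, matrices_b)`` of matched
        (n_subjects, n, n) stacks. Correlation design: one (n_subjects,
        n, n) stack, plus ``covariate``.
    design
        ``'paired'`` or ``'correlation'``.
    threshold
        Statistic cutoff; for the correlation design the edge r values
        are converted to t statistics (t = r sqrt((n-2)/(1-r^2))) so the
        same cutoff scale applies.
    tail
        ``'greater'`` or ``'less'`` (one-sided, analysed separately).
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a coarse FWER estimate")
    rng = np.random.default_rng(seed)
    if design == "paired":
        A, B = data
        A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
        if A.shape != B.shape or A.shape[0] < 3:
            raise ValueError("paired design needs matched stacks with >= 3 subjects")
        n_sub, n = A.shape[0], A.shape[-1]
        diffs = _edge_vectors(A) - _edge_vectors(B)
        obs_stat = _paired_t_from_diffs(diffs)
        def perm_stats(n_draws: int) -> np.ndarray:
            signs = rng.integers(0, 2, size=(n_draws, n_sub)) * 2 - 1
            mean = (signs @ diffs) / n_sub
            ssq = (diffs**2).sum(axis=0)  # invariant under sign flips
            var = (ssq - n_sub * mean**2) / (n_sub - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = mean / np.sqrt(var / n_sub)
            t[:, np.isnan(obs_stat)] = np.nan
            return t
    elif design == "correlation":
        mats = np.asarray(data, dtype=float)
        if covariate is None:
            raise ValueError("correlation design requires a covariate")
        y = np.asarray(covariate, dtype=float)
        if y.std() == 0 or mats.shape[0] != y.size or y.size < 4:
            raise ValueError("degenerate correlation design")
        n_sub, n = mats.shape[0], mats.shape[-1]
        X = _edge_vectors(mats)
        dof = n_sub - 2
        def r_to_t(r: np.ndarray) -> np.ndarray:
            with np.errstate(invalid="ignore", divide="ignore"):
                return r * np.sqrt(dof / np.clip(1.0 - r**2, 1e-12, None))
        obs_stat = r_to_t(_corr_with_covariate(X, y))
        Xc = X - X.mean(axis=0)
        sx = np.sqrt((Xc**2).sum(axis=0))
        def perm_stats(n_draws: int) -> np.ndarray:
            idx = np.argsort(rng.random((n_draws, n_sub)), axis=1)
            Ypc = y[idx] - y.mean()  # (draws, n_sub), centering is perm-invariant
            syp = np.sqrt((Ypc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Ypc @ Xc) / (syp[:, None] * sx[None, :])
            r[:, sx == 0] = np.nan
            return r_to_t(r)
    else:
        raise ValueError("design must be 'paired' or 'correlation'")

    iu = _triu(n)
    sign = 1.0 if tail == "greater" else -1.0
    obs_components = suprathreshold_components(_vec_to_matrix(obs_stat, n), threshold, tail)

    null_max = np.zeros(n_perm, dtype=np.int64)
    chunk = 500
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        t = perm_stats(k)
        keep = (sign * t > threshold) & np.isfinite(t)
        for p in range(k):
            null_max[done + p] = _max_component_size(keep[p], iu, n)
        done += k
    for comp in obs_components:
        comp.p_fwer = float((1 + np.sum(null_max >= comp.size)) / (n_perm + 1))
    return NBSResult(
        stat_matrix=_vec_to_matrix(obs_stat, n),
        threshold=threshold,
        tail=tail,
        components=obs_components,
        null_max_size=null_max,
        n_perm=n_perm,
        seed=seed,
    )
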