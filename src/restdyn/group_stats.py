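"""Scalar group statistics for the session x induction x group design.

A split-plot (mixed-design) repeated-measures ANOVA with up to two
within-subject factors (session: boost / silent / next-day windows;
induction: pre vs post test) and one between-subject factor (Wake vs Nap
group), with Mauchly sphericity assessment and Greenhouse-Geisser
correction of within-subject effects. Post-hocs use paired Wilcoxon
signed-rank tests; brain-behaviour associations use Spearman rank
correlations with Fisher-z confidence intervals; the multiple-comparison
family is controlled by Bonferroni (factor 21 in the reference design:
K - 1 = 7 independent states x 3 independent temporal parameters).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Mixed-design ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(p: int) -> np.ndarray:
    """(p, p-1) orthonormal contrast basis (Helmert, normalised)."""
    H = np.zeros((p, p - 1))
    for j in range(1, p):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
        H[:, j - 1] /= np.linalg.norm(H[:, j - 1])
    return H


def _gg_epsilon_and_mauchly(scores: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser epsilon and Mauchly p for contrast scores.

    ``scores`` is (n_subjects, p) contrast scores (p = effect df);
    covariance is pooled within groups. Returns (epsilon, mauchly_p);
    mauchly_p = 1 when p == 1 (sphericity trivially holds).
    """
    n, p = scores.shape
    if p <= 1:
        return 1.0, 1.0
    resid = np.empty_like(scores)
    d_err = 0
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] = scores[sel] - scores[sel].mean(axis=0)
        d_err += sel.sum() - 1
    S = resid.T @ resid / d_err
    tr = np.trace(S)
    eps = tr**2 / (p * np.trace(S @ S)) if tr > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / p, 1.0))
    # Mauchly's test on the pooled contrast covariance
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0):
        return eps, 0.0  # singular covariance: maximal violation
    W = np.exp(np.sum(np.log(eig)) - p * np.log(tr / p))
    f = 1.0 - (2 * p**2 + p + 2) / (6.0 * p * d_err)
    chi2 = -f * d_err * np.log(W)
    df = p * (p + 1) // 2 - 1
    return eps, float(stats.chi2.sf(chi2, df))


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eps: float = 1.0
    p_gg: float = np.nan
    mauchly_p: float = np.nan


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: tuple[str, ...] = ("session", "induction"),
    between: str | None = "group",
    gg: str = "auto",
) -> pd.DataFrame:
    """Split-plot ANOVA: 1-2 within-subject factors, optional between factor.

    Expects a complete, balanced long table (one row per subject x within
    cell); an empty cell raises an error naming it. Group sizes may
    differ. With ``gg='auto'`` the Greenhouse-Geisser-corrected p is
    reported (``p_gg``) whenever Mauchly's test rejects sphericity at
    0.05; ``'always'``/``'never'`` force the choice.

    Returns a tidy frame with one row per effect (within mains and
    interactions, between main, and mixed interactions) carrying F,
    df1, df2, p, epsilon, Mauchly p, and the GG-corrected p.
    """
    df = table.copy()
    if between is None:
        df["_grp"] = "all"
        between = "_grp"
    levels = {w: sorted(df[w].unique()) for w in within}
    subjects = sorted(df[subject].unique())
    cells = list(itertools.product(*[levels[w] for w in within]))
    # cell means per subject (duplicate rows averaged), completeness check
    piv = df.groupby([subject, *within], observed=True)[dv].mean()
    data = np.empty((len(subjects), len(cells)))
    for si, s in enumerate(subjects):
        for ci, cell in enumerate(cells):
            key = (s, *cell)
            if key not in piv.index:
                raise ValueError(f"empty design cell: subject={s}, {dict(zip(within, cell))}")
            data[si, ci] = piv.loc[key]
    grp_of = df.groupby(subject, observed=True)[between].first()
    groups = np.asarray([grp_of[s] for s in subjects])
    glevels = sorted(set(groups))
    N, a = len(subjects), len(glevels)
    if min((groups == g).sum() for g in glevels) < 2:
        raise ValueError("need >= 2 subjects per group")
    shape = tuple(len(levels[w]) for w in within)
    Y = data.reshape((N,) + shape)  # (subjects, b[, c])

    def group_mean(arr: np.ndarray) -> dict:
        return {g: arr[groups == g].mean(axis=0) for g in glevels}

    n_g = {g: int((groups == g).sum()) for g in glevels}
    subj_mean = Y.reshape(N, -1).mean(axis=1)  # per-subject mean
    gmean_subj = group_mean(subj_mean)
    grand = subj_mean.mean()
    n_cells = int(np.prod(shape))

    out: list[AnovaEffect] = []
    # --- between-subject stratum ---
    ss_a = n_cells * sum(n_g[g] * (gmean_subj[g] - grand) ** 2 for g in glevels)
    ss_s = n_cells * sum(
        ((subj_mean[groups == g] - gmean_subj[g]) ** 2).sum() for g in glevels
    )
    df_s = N - a
    if a > 1:
        F = (ss_a / (a - 1)) / (ss_s / df_s)
        out.append(AnovaEffect(between, F, a - 1, df_s, float(stats.f.sf(F, a - 1, df_s))))

    # --- within-subject strata: every non-empty subset of within factors ---
    H = {w: _orthonormal_contrasts(len(levels[w])) for w in within}
    axis_of = {w: 1 + i for i, w in enumerate(within)}
    for r in range(1, len(within) + 1):
        for fac_set in itertools.combinations(within, r):
            # contrast scores: apply the factor contrasts along the involved
            # axes and average over the remaining within axes
            C = Y
            for w in within:
                ax = axis_of[w]
                if w in fac_set:
                    C = np.moveaxis(
                        np.tensordot(C, H[w], axes=([ax], [0])), -1, ax
                    )
                else:
                    C = C.mean(axis=ax, keepdims=True)
            scores = C.reshape(N, -1)  # (N, p), p = effect df
            p_eff = scores.shape[1]
            eps, mau_p = _gg_epsilon_and_mauchly(scores, groups)
            gmean_sc = group_mean(scores)
            wmean = sum(n_g[g] * gmean_sc[g] for g in glevels) / N
            resid = np.concatenate(
                [scores[groups == g] - gmean_sc[g] for g in glevels]
            )
            ss_err = (resid**2).sum()
            df_err = p_eff * (N - a)
            # main within effect (subject-weighted mean contrast vs 0)
            ss_w = N * (wmean**2).sum()
            # group x within interaction
            ss_int = sum(n_g[g] * ((gmean_sc[g] - wmean) ** 2).sum() for g in glevels)
            name = " x ".join(fac_set)
            for eff_name, ss, d1 in (
                (name, ss_w, p_eff),
                *(((f"{between} x {name}", ss_int, p_eff * (a - 1)),) if a > 1 else ()),
            ):
                ms_err = ss_err / df_err
                F = (ss / d1) / ms_err
                p_unc = float(stats.f.sf(F, d1, df_err))
                p_gg = float(stats.f.sf(F, d1 * eps, df_err * eps))
                out.append(
                    AnovaEffect(eff_name, F, d1, df_err, p_unc, eps, p_gg, mau_p)
                )

    res = pd.DataFrame([vars(e) for e in out])
    use_gg = {
        "auto": (res["mauchly_p"] < 0.05) & (res["eps"] < 1.0),
        "always": res["eps"] < 1.0,
        "never": pd.Series(False, index=res.index),
    }[gg]
    res["p_corrected"] = np.where(use_gg, res["p_gg"], res["p"])
    res["df1_corrected"] = np.where(use_gg, res["df1"] * res["eps"], res["df1"])
    res["df2_corrected"] = np.where(use_gg, res["df2"] * res["eps"], res["df2"])
    return res


def rm_anova(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Alias for :func:`mixed_anova` (repeated-measures design entry point)."""
    return mixed_anova(table, **kwargs)


# ---------------------------------------------------------------------------
# Correlations and post-hocs
# ---------------------------------------------------------------------------

def spearman_ci(x, y, alpha: float = 0.05) -> dict:
    """Spearman rho with Fisher-z confidence interval and two-sided p.

    rho uses average ranks (ties allowed); the CI is
    tanh(atanh(rho) +/- z_{1-alpha/2} / sqrt(n - 3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise ValueError("need >= 5 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")
    rho, p = stats.spearmanr(x, y)
    rho = float(np.clip(rho, -1.0, 1.0))
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return {
        "rho": rho,
        "ci_low": math.tanh(z - half),
        "ci_high": math.tanh(z + half),
        "p": float(p),
        "n": int(n),
    }


def bonferroni(p: float | np.ndarray, factor: int = 21) -> float | np.ndarray:
    """Bonferroni-adjusted p-value: min(1, p * factor)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must be in [0, 1]")
    out = np.minimum(1.0, p * factor)
    return float(out) if out.ndim == 0 else out


def bonferroni_factor(n_states: int = 8, n_params: int = 4) -> int:
    """Size of the correction family under the independence counting.

    Of K states only K - 1 are independent (one state's activation is
    determined by the others), and of the 4 temporal parameters only 3
    are (NO is determined by MLT, MIL and FO): (K - 1) x (n_params - 1).
    """
    return (n_states - 1) * (n_params - 1)


def wilcoxon_signed_rank(a, b) -> dict:
    """Paired Wilcoxon signed-rank test.

    W is the smaller signed-rank sum; exact p for n <= 25 (no ties/zeros),
    normal approximation with continuity correction otherwise. Zero
    differences are dropped; all-zero differences are flagged as
    undefined (NaN statistics) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    if nz.size < 5:
        if nz.size == 0:
            warnings.warn("all differences zero: Wilcoxon undefined")
            return {"W": np.nan, "p": np.nan, "n": 0}
        raise ValueError("need >= 5 nonzero paired differences")
    exact = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    res = stats.wilcoxon(
        nz,
        zero_method="wilcox",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    # W = rank sum of positive (a - b) differences, so swapping the inputs
    # yields the complementary statistic n(n+1)/2 - W
    ranks = stats.rankdata(np.abs(nz))
    W = float(ranks[nz > 0].sum())
    return {"W": W, "p": float(res.pvalue), "n": int(nz.size)}
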