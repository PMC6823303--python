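"""Within-subject factorial statistics.

Implements the fully repeated-measures ANOVA used throughout the analyses
(up to three within-subject factors, e.g. Locking x Type x Epoch), with the
Greenhouse-Geisser sphericity correction, partial eta-squared effect sizes,
uncorrected (LSD) pairwise follow-ups, and one-sample / paired t tests.

Each effect is tested against its own subject-by-effect interaction.  With
an orthonormal contrast matrix C for the effect and the n x m matrix Y of
cell scores, the contrast scores Z = Y C' give

    SS_effect = n * ||mean(Z)||^2,   SS_error = sum ||Z - mean(Z)||^2,
    F = (SS_effect / df1) / (SS_error / df2),  df1 = rank(C), df2 = df1*(n-1).

The Greenhouse-Geisser epsilon is the Box estimator applied to C S C' where
S is the sample covariance of the cell scores; it is clipped to
[1/df1, 1], and the corrected p value uses (eps*df1, eps*df2).  Following
common reporting practice the correction is applied only when the effect
has more than one numerator df and the estimated epsilon is below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t test of mean(values) against mu0."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        # a perfectly constant sample equal to mu0 is a null result (t=0);
        # a constant sample away from mu0 has no defined t statistic
        if x.mean() == mu0:
            return TTestResult(t=0.0, df=len(x) - 1, p=1.0, mean_diff=0.0)
        raise ValueError("zero variance with nonzero mean difference: "
                         "t statistic undefined")
    t = (x.mean() - mu0) / (sd / np.sqrt(len(x)))
    df = len(x) - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p),
                       mean_diff=float(x.mean() - mu0))


def paired_t(a, b) -> TTestResult:
    """Two-sided paired t test; identical to a one-sample t on a - b."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser (Box) epsilon from a k x k cell covariance matrix.

    Computed on the double-centered covariance; equals 1 under compound
    symmetry (sphericity) and is clipped to its theoretical range
    [1/(k-1), 1].
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least 2 levels")
    center = np.eye(k) - np.ones((k, k)) / k
    m = center @ cov @ center
    num = np.trace(m) ** 2
    den = (k - 1) * np.sum(m * m)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthonormal, sum zero)."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def _effect_contrast(factors: dict, effect: tuple) -> np.ndarray:
    """Orthonormal contrast for an effect in the full-cell space.

    Kronecker product over factors in declaration order: Helmert rows for
    factors in the effect, the normalised unit vector (mean) otherwise.
    """
    mats = []
    for name, levels in factors.items():
        k = len(levels)
        mats.append(_helmert(k) if name in effect
                    else np.ones((1, k)) / np.sqrt(k))
    c = mats[0]
    for m in mats[1:]:
        c = np.kron(c, m)
    return c


def _cell_matrix(data: pd.DataFrame, factors: dict, value: str) -> np.ndarray:
    """Pivot long data to the n_subjects x n_cells matrix (cells in
    factor-declaration order), validating completeness and balance."""
    names = list(factors)
    if len(names) == 1:
        grid = pd.Index(factors[names[0]], name=names[0])
    else:
        grid = pd.MultiIndex.from_product([factors[f] for f in names],
                                          names=names)
    wide = data.pivot_table(index="subject", columns=names, values=value,
                            aggfunc="mean", dropna=False)
    wide = wide.reindex(columns=grid)
    if wide.isna().any().any():
        i, j = np.argwhere(wide.isna().to_numpy())[0]
        cell = grid[j] if len(names) == 1 else tuple(grid[j])
        raise ValueError(
            f"missing cell for subject {wide.index[i]!r}, cell {cell!r}: "
            "the repeated-measures design must be complete and balanced"
        )
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects")
    return wide.to_numpy(dtype=float)


def rm_anova(data: pd.DataFrame, factors: dict, value: str = "value") -> pd.DataFrame:
    """Fully within-subject ANOVA for 1-3 factors.

    ``data`` is long format with a ``subject`` column, one column per factor
    and a value column; ``factors`` maps factor name to its ordered levels.
    Returns one row per effect (main effects and all interactions) with
    columns ``effect, F, df1, df2, epsilon, p, p_gg, eta_p2``.  ``p_gg``
    equals ``p`` where no correction applies and never falls below it.
    """
    if not 1 <= len(factors) <= 3:
        raise ValueError("rm_anova supports 1 to 3 within-subject factors")
    y = _cell_matrix(data, factors, value)
    n = y.shape[0]
    cov = np.cov(y, rowvar=False)
    cov = np.atleast_2d(cov)

    rows = []
    names = list(factors)
    for size in range(1, len(names) + 1):
        for effect in combinations(names, size):
            c = _effect_contrast(factors, effect)
            z = y @ c.T
            zbar = z.mean(axis=0)
            df1 = c.shape[0]
            df2 = df1 * (n - 1)
            ss_effect = n * float(zbar @ zbar)
            resid = z - zbar
            ss_error = float((resid * resid).sum())
            if ss_error <= 0:
                raise ValueError(
                    f"zero error variance for effect {'*'.join(effect)}: "
                    "F is undefined (constant data?)"
                )
            f = (ss_effect / df1) / (ss_error / df2)
            p = float(sps.f.sf(f, df1, df2))
            if df1 > 1:
                eps = gg_epsilon(c @ cov @ c.T)
            else:
                eps = 1.0
            if df1 > 1 and eps < 1.0 - 1e-9:
                p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
                p_gg = max(p_gg, p)
            else:
                p_gg = p
            rows.append({
                "effect": " * ".join(effect), "F": f, "df1": df1, "df2": df2,
                "epsilon": eps, "p": p, "p_gg": p_gg,
                "eta_p2": ss_effect / (ss_effect + ss_error),
            })
    return pd.DataFrame(rows)


def lsd_pairwise(data: pd.DataFrame, factor: str, levels,
                 value: str = "value") -> pd.DataFrame:
    """Fisher LSD follow-ups: uncorrected paired t tests for each level pair.

    ``data`` is long format; scores are first averaged within subject x
    level over any other factors, then each pair is compared with a paired
    t test with no multiplicity adjustment.
    """
    wide = data.pivot_table(index="subject", columns=factor, values=value,
                            aggfunc="mean", dropna=False)
    missing = [l for l in levels if l not in wide.columns]
    if missing:
        raise ValueError(f"levels absent from data: {missing}")
    wide = wide[list(levels)]
    if wide.isna().any().any():
        subj = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"missing cell for subject {subj!r}")
    rows = []
    for a, b in combinations(levels, 2):
        res = paired_t(wide[a], wide[b])
        rows.append({"level_a": a, "level_b": b, "mean_diff": res.mean_diff,
                     "t": res.t, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)


def anova_to_dict(table: pd.DataFrame) -> dict:
    """Serialisable form: effect name -> {F, df1, df2, epsilon, p, p_gg, eta_p2}."""
    return {
        r["effect"]: {k: (float(r[k]) if k != "effect" else r[k])
                      for k in ("F", "df1", "df2", "epsilon", "p", "p_gg",
                                "eta_p2")}
        for _, r in table.iterrows()
    }
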