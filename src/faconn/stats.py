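"""Statistical primitives: partial Pearson correlation with nuisance
covariates, Benjamini-Hochberg FDR, and the two group-comparison tests
(Fisher's exact and Wilcoxon rank-sum)."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized by ordinary least squares on
    [intercept, covariates]; r is the Pearson correlation of the
    residuals, and the two-tailed p comes from
    t = r * sqrt(df / (1 - r^2)) with df = n - 2 - n_covariates.

    Returns
    -------
    (r, p, df)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
        if z.shape[0] != n:
            raise ValueError("covariate matrix does not align with x")
    k = z.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > n_covariates + 3 (n={n}, covariates={k})")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("degenerate feature: zero residual variance")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        return r_clip, 0.0, df
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r_clip, p, df


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p sums the hypergeometric probabilities of every table
    with the observed margins whose probability does not exceed the
    observed table's (with a small relative slack for ties).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty margin in 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p.

    Exact when the pooled sample has at most 20 observations and no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
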