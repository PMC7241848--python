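"""Shared least-squares and likelihood-ratio machinery.

All models in the pipeline are ordinary linear models with homoscedastic
Gaussian residuals.  Likelihood-ratio statistics use the profiled Gaussian
log-likelihood, so LR = n * log(RSS_reduced / RSS_full), referred to a
chi-square with df equal to the rank difference of the two designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class OLSFit:
    """Joint least-squares fit with per-coefficient inference."""

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    tss: float
    n: int
    rank: int

    @property
    def df_resid(self) -> int:
        return self.n - self.rank

    @property
    def r2(self) -> float:
        if self.tss == 0:
            return 0.0
        return 1.0 - self.rss / self.tss

    @property
    def adj_r2(self) -> float:
        # rank includes the intercept column
        if self.tss == 0 or self.df_resid <= 0:
            return 0.0
        return 1.0 - (self.rss / self.df_resid) / (self.tss / (self.n - 1))


def ols_fit(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Fit y = X b + e by least squares; X must already contain an intercept.

    Standard errors use the unbiased residual-variance estimate.  A
    rank-deficient design raises ``np.linalg.LinAlgError`` naming the issue;
    callers that must tolerate aliased columns should drop them first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {p} columns)"
        )
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - rank
    if df <= 0:
        sigma2 = np.nan
    else:
        sigma2 = rss / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv), 0.0) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(t), df) if df > 0 else np.full(p, np.nan)
    return OLSFit(coef=coef, se=se, t=t, p=pvals, rss=rss, tss=tss, n=n, rank=rank)


def rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a possibly rank-deficient design."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def gaussian_lrt(
    X_full: np.ndarray, X_reduced: np.ndarray, y: np.ndarray
) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested Gaussian linear models.

    Returns (LR, df, p).  df is the rank difference, so aliased columns in
    either design do not inflate the reference distribution.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    rss_f, rank_f = rss_rank(X_full, y)
    rss_r, rank_r = rss_rank(X_reduced, y)
    df = rank_f - rank_r
    if df <= 0:
        return 0.0, 0, 1.0
    if rss_f <= 0:
        if rss_r <= max(1e-12 * n, np.finfo(float).tiny):
            # both models fit exactly: the extra terms add nothing
            return 0.0, df, 1.0
        # full model is saturated/noiseless; treat as infinitely significant
        return np.inf, df, 0.0
    lr = max(0.0, n * np.log(rss_r / rss_f))
    p = float(stats.chi2.sf(lr, df))
    return float(lr), df, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def adjusted_r2_from_rss(rss: float, tss: float, n: int, rank: int) -> float:
    if tss == 0 or n - rank <= 0:
        return 0.0
    return 1.0 - (rss / (n - rank)) / (tss / (n - 1))
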