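"""Phylogenetic comparative statistics.

PGLS regression under four trait-evolution models (BM, fixed-root OU,
Pagel's lambda, early burst), maximum-likelihood Pagel's-lambda
phylogenetic signal with a likelihood-ratio test, a phylogenetic paired
t-test, and Benjamini-Hochberg FDR adjustment within caller-declared
families.

The model parameter (lambda, alpha or r), where the model has one, is
estimated by bounded scalar ML wrapped around the analytic profile over
the regression coefficients and the Brownian rate: for any fixed
parameter value the GLS coefficients and sigma^2 have closed forms, so
only a one-dimensional search remains.  Five grid starts guard against
local optima.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .phylo import (ModelParams, PhyloCovariance, PhyloTree, _chol_with_jitter,
                    model_covariance)

logger = logging.getLogger(__name__)

_PARAM_BOUNDS = {"lambda": (0.0, 1.0), "OU_fixed_root": (-10.0, 10.0),
                 "EB": (-10.0, 1.0)}  # OU bound is on log(alpha)


@dataclass
class PglsFit:
    """A fitted PGLS regression."""

    model: str
    coef: dict[str, float]
    se: dict[str, float]
    tvals: dict[str, float]
    pvals: dict[str, float]
    param: float | None          # lambda | alpha | r (None for BM)
    sigma2: float
    loglik: float
    aic: float
    n: int
    p_bh: dict[str, float] | None = None

    @property
    def slope_names(self) -> list[str]:
        return [k for k in self.coef if k != "intercept"]


@dataclass
class SignalEstimate:
    """Pagel's-lambda phylogenetic signal with LRT against lambda = 0."""

    lam: float
    loglik: float
    loglik0: float
    pvalue: float
    n: int


@dataclass
class PairedTTest:
    mean_diff: float
    se: float
    tstat: float
    pvalue: float
    lam: float
    n: int


# ---------------------------------------------------------------- helpers

def align_tree_traits(tree: PhyloTree, *traits) -> tuple[PhyloCovariance, list[np.ndarray]]:
    """Intersect tree tips with trait labels; drop (and log) missing tips.

    Each trait may be a pandas Series (indexed by tip label), a dict, or a
    plain array already aligned to ``tree.tip_labels``.
    """
    labels = list(tree.tip_labels)
    series = []
    for t in traits:
        if isinstance(t, pd.Series):
            series.append(t)
        elif isinstance(t, dict):
            series.append(pd.Series(t))
        else:
            arr = np.asarray(t, dtype=float)
            if arr.shape[0] != len(labels):
                raise ValueError("array trait must have one value per tip")
            series.append(pd.Series(arr, index=labels))
    common = [lab for lab in labels
              if all(lab in s.index and np.isfinite(s[lab]) for s in series)]
    dropped = len(labels) - len(common)
    if dropped:
        logger.info("dropped %d tip(s) without complete trait data", dropped)
    if len(common) < 2:
        raise ValueError("fewer than 2 tips with complete trait data")
    cov = tree.covariance(common)
    return cov, [s.loc[common].to_numpy(dtype=float) for s in series]


def _gls_profile(V: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Closed-form GLS at fixed unit-rate covariance ``V``.

    Returns (beta, sigma2_ml, loglik, XtViX_inv, rss_w) where ``loglik``
    is the multivariate-normal log-likelihood at the profiled ML
    ``sigma2``.
    """
    n = len(y)
    L = _chol_with_jitter(V, "model covariance")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vi_X = linalg.cho_solve((L, True), X)
    Vi_y = linalg.cho_solve((L, True), y)
    XtViX = X.T @ Vi_X
    try:
        XtViX_inv = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular design matrix") from exc
    beta = XtViX_inv @ (X.T @ Vi_y)
    resid = y - X @ beta
    rss_w = float(resid @ linalg.cho_solve((L, True), resid))
    sigma2 = max(rss_w / n, 1e-300)
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return beta, sigma2, loglik, XtViX_inv, rss_w


def _unit_params(model: str, value: float | None) -> ModelParams:
    if model == "BM":
        return ModelParams("BM", 1.0)
    if model == "lambda":
        return ModelParams("lambda", 1.0, lam=value)
    if model == "OU_fixed_root":
        return ModelParams("OU_fixed_root", 1.0, alpha=math.exp(value))
    if model == "EB":
        return ModelParams("EB", 1.0, r=value)
    raise ValueError(f"unknown model {model!r}")


def _optimize_param(cov: PhyloCovariance, y: np.ndarray, X: np.ndarray,
                    model: str) -> tuple[float | None, float]:
    """ML over the scalar model parameter; returns (raw_param, loglik)."""
    if model == "BM":
        _, _, ll, _, _ = _gls_profile(model_covariance(cov, _unit_params("BM", None)), y, X)
        return None, ll

    def nll(v: float) -> float:
        V = model_covariance(cov, _unit_params(model, float(v)))
        try:
            return -_gls_profile(V, y, X)[2]
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return np.inf

    lo, hi = _PARAM_BOUNDS[model]
    grid = np.linspace(lo, hi, 5)
    vals = [nll(g) for g in grid]
    best = int(np.argmin(vals))
    blo = grid[max(best - 1, 0)]
    bhi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(nll, bounds=(blo, bhi), method="bounded",
                                   options={"xatol": 1e-7})
    cand = [(res.fun, float(res.x))] + [(v, float(g)) for v, g in zip(vals, grid)]
    fbest, xbest = min(cand)
    return xbest, -fbest


def _raw_to_param(model: str, raw: float | None) -> float | None:
    if raw is None:
        return None
    return math.exp(raw) if model == "OU_fixed_root" else raw


# ------------------------------------------------------------------- PGLS

def pgls(tree: PhyloTree, y, X, model: str = "BM",
         names: Sequence[str] | None = None) -> PglsFit:
    """PGLS regression of ``y`` on one or more predictors.

    ``y`` and each column of ``X`` may be pandas Series keyed by tip
    label (missing tips dropped with a logged count) or arrays aligned to
    the tree's tip order.  The model parameter, where the model has one,
    is estimated by ML jointly with the GLS coefficients; slope SEs come
    from the GLS covariance with the unbiased residual variance, t uses
    df = n - #coefficients, and AIC counts all free parameters
    (coefficients + sigma^2 + the model parameter if any).
    """
    if model not in _PARAM_BOUNDS and model != "BM":
        raise ValueError(f"unknown model {model!r}")
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        cov, aligned = align_tree_traits(tree, y, *[X[c] for c in cols])
        yv, xcols = aligned[0], aligned[1:]
    else:
        Xs = [X] if not isinstance(X, (list, tuple)) else list(X)
        cols = list(names) if names else [f"x{i+1}" for i in range(len(Xs))]
        cov, aligned = align_tree_traits(tree, y, *Xs)
        yv, xcols = aligned[0], aligned[1:]
    n = len(yv)
    Xmat = np.column_stack([np.ones(n)] + list(xcols))
    coef_names = ["intercept"] + cols
    p = Xmat.shape[1]
    if n <= (p - 1) + 2:
        raise ValueError(f"n = {n} too small for {p - 1} predictor(s)")
    if np.linalg.matrix_rank(Xmat) < p:
        raise np.linalg.LinAlgError("singular design matrix")

    raw, loglik = _optimize_param(cov, yv, Xmat, model)
    V = model_covariance(cov, _unit_params(model, raw))
    beta, sigma2_ml, loglik, XtViX_inv, rss_w = _gls_profile(V, yv, Xmat)
    sigma2_unbiased = rss_w / (n - p)
    se = np.sqrt(sigma2_unbiased * np.diag(XtViX_inv))
    tvals = beta / se
    df = n - p
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    k = p + 1 + (0 if model == "BM" else 1)
    return PglsFit(
        model=model,
        coef=dict(zip(coef_names, beta)),
        se=dict(zip(coef_names, se)),
        tvals=dict(zip(coef_names, tvals)),
        pvals=dict(zip(coef_names, np.clip(pvals, np.nextafter(0, 1), 1.0))),
        param=_raw_to_param(model, raw),
        sigma2=sigma2_ml,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        n=n,
    )


# -------------------------------------------------------------- signal

def pagel_lambda_signal(tree: PhyloTree, x) -> SignalEstimate:
    """ML Pagel's lambda with a chi-square(1) LRT against lambda = 0.

    The mean and rate are profiled out analytically at each lambda; the
    search is a 5-point grid refined by bounded scalar optimization.  On a
    star tree the likelihood is flat in lambda and lambda_hat is reported
    as 0 with a warning.
    """
    cov, (xv,) = align_tree_traits(tree, x)
    n = len(xv)
    if n < 4:
        raise ValueError("phylogenetic signal needs n >= 4")
    if np.ptp(xv) == 0:
        raise ValueError("degenerate trait: x is constant")
    Xmat = np.ones((n, 1))
    offdiag = cov.C - np.diag(np.diag(cov.C))
    star = not np.any(offdiag)
    if star:
        logger.warning("star tree: lambda likelihood is flat; reporting 0")
        _, _, ll0, _, _ = _gls_profile(
            model_covariance(cov, _unit_params("lambda", 0.0)), xv, Xmat)
        return SignalEstimate(0.0, ll0, ll0, 1.0, n)
    raw, loglik = _optimize_param(cov, xv, Xmat, "lambda")
    _, _, ll0, _, _ = _gls_profile(
        model_covariance(cov, _unit_params("lambda", 0.0)), xv, Xmat)
    lrt = max(2.0 * (loglik - ll0), 0.0)
    pval = float(sps.chi2.sf(lrt, df=1))
    return SignalEstimate(float(raw), loglik, ll0, max(pval, np.nextafter(0, 1)), n)


# -------------------------------------------------------- paired t-test

def phylo_paired_ttest(tree: PhyloTree, x1, x2, use_lrt: bool = False) -> PairedTTest:
    """Phylogenetic paired t-test on d = x1 - x2.

    ``d`` is modelled as Brownian with Pagel's lambda estimated by ML; the
    mean difference is its GLS estimate.  Default inference is a t-test
    with df = n - 2 (mean and variance estimated); ``use_lrt`` switches to
    a chi-square(1) likelihood-ratio test of mean zero.
    """
    cov, (a, b) = align_tree_traits(tree, x1, x2)
    d = a - b
    n = len(d)
    if np.ptp(d) == 0 and d[0] == 0.0:
        return PairedTTest(0.0, 0.0, 0.0, 1.0, 0.0, n)
    if np.ptp(d) == 0:
        raise ValueError("zero-variance difference")
    Xmat = np.ones((n, 1))
    raw, loglik = _optimize_param(cov, d, Xmat, "lambda")
    V = model_covariance(cov, _unit_params("lambda", raw))
    beta, _, _, XtViX_inv, rss_w = _gls_profile(V, d, Xmat)
    sigma2 = rss_w / (n - 1)
    se = math.sqrt(sigma2 * XtViX_inv[0, 0])
    tstat = float(beta[0] / se)
    if use_lrt:
        L = _chol_with_jitter(V, "model covariance")
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        rss0 = float(d @ linalg.cho_solve((L, True), d))
        s0 = rss0 / n
        ll0 = -0.5 * (n * math.log(2.0 * math.pi * s0) + logdet + n)
        pval = float(sps.chi2.sf(max(2.0 * (loglik - ll0), 0.0), df=1))
    else:
        pval = float(2.0 * sps.t.sf(abs(tstat), n - 2))
    return PairedTTest(float(beta[0]), se, tstat, pval, float(raw), n)


# ----------------------------------------------------------------- BH FDR

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within one family.

    Standard step-up (``adj_(k) = min_{j>=k} p_(j) m / j``, capped at 1);
    output order matches input order.  P values are never floored here;
    a printed-table floor such as 2.2e-16 enters only as an input literal
    when reproducing published tables.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_adjust_grouped(frame: pd.DataFrame, p_col: str, group_cols: Sequence[str],
                      out_col: str = "P_BH") -> pd.DataFrame:
    """BH adjustment applied independently within each declared family.

    The family structure used for the headline regressions groups the
    tests per (domain x temperature index) across the eight GC indexes
    (m = 8); other groupings are a caller decision, so the columns that
    define a family are explicit arguments.
    """
    frame = frame.copy()
    frame[out_col] = np.nan
    for _, idx in frame.groupby(list(group_cols)).groups.items():
        frame.loc[idx, out_col] = bh_adjust(frame.loc[idx, p_col].to_numpy())
    return frame
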