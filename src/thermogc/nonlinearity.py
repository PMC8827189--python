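"""Penalized-spline regression of GC content on growth temperature with a
genus random intercept, reporting effective degrees of freedom (edf).

The model is ``GC ~ b0 + s(Topt) + (1 | genus) + eps`` where ``s`` is a
cubic B-spline smooth (knots at quantiles, integrated-squared-second-
derivative penalty).  It is fitted in its mixed-model representation:
the penalty's null space (constant + linear) joins the fixed effects and
the penalized components become i.i.d. random effects, so the smoothing
parameter is a variance ratio selected by REML alongside the genus
random-intercept variance.  The edf of the smooth is the trace of its
block of the hat matrix; an edf of 1 indicates a linear relationship,
values of 8-10 (for a 10-dimensional basis) high nonlinearity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class GammFit:
    intercept: float
    edf: float                 # of the smooth, incl. its linear null space
    smooth_pvalue: float       # approximate Wald test of s(x) == 0
    sigma2: float              # residual variance
    genus_sd: float            # random-intercept standard deviation
    smooth_sd: float           # sd of the penalized spline coefficients
    lambda_smooth: float       # penalty weight sigma2 / tau_s^2
    reml: float
    basis_dim: int
    n: int
    grid_x: np.ndarray
    grid_fit: np.ndarray       # b0 + s(x) on grid_x

    def predict_smooth(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid_x, self.grid_fit)


# ------------------------------------------------------------- spline basis

def _bspline_basis(x: np.ndarray, knots: np.ndarray, basis_dim: int) -> np.ndarray:
    xc = np.clip(x, knots[3], knots[-4])
    B = interpolate.BSpline.design_matrix(xc, knots, 3).toarray()
    assert B.shape[1] == basis_dim
    return B


def _make_knots(x: np.ndarray, basis_dim: int) -> np.ndarray:
    n_interior = basis_dim - 4
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs)
    lo, hi = float(np.min(x)), float(np.max(x))
    interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _second_derivative_penalty(knots: np.ndarray, basis_dim: int) -> np.ndarray:
    """Exact integral of products of basis second derivatives.

    B'' of a cubic B-spline is piecewise linear, so 2-point Gauss-Legendre
    per inter-knot interval integrates the products exactly.
    """
    P = np.zeros((basis_dim, basis_dim))
    gauss_x = np.array([-1.0, 1.0]) / math.sqrt(3.0)
    uniq = np.unique(knots)
    for a, b in zip(uniq[:-1], uniq[1:]):
        if b <= a:
            continue
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts = mid + half * gauss_x
        D2 = np.column_stack([
            interpolate.BSpline(knots, np.eye(basis_dim)[j], 3)(pts, nu=2)
            for j in range(basis_dim)])
        P += half * (D2[0][:, None] * D2[0][None, :] + D2[1][:, None] * D2[1][None, :])
    return P


# ---------------------------------------------------------------- fitting

def fit_gamm(x, y, genus, basis_dim: int = 10,
             ratios: tuple[float, float] | None = None,
             grid_size: int = 100) -> GammFit:
    """Fit ``y ~ b0 + s(x) + (1|genus)`` by REML.

    ``ratios`` fixes (tau_s^2/sigma2, tau_g^2/sigma2) instead of selecting
    them by REML — useful for probing the penalty limit behaviour.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    genus = np.asarray(genus)
    n = len(y)
    if not (len(x) == len(genus) == n):
        raise ValueError("x, y and genus must have equal length")
    if n < 30:
        raise ValueError("fit needs n >= 30")
    if np.ptp(x) == 0:
        raise ValueError("all x identical")
    levels, gidx = np.unique(genus, return_inverse=True)
    G = len(levels)
    use_genus = G >= 2
    if not use_genus:
        logger.warning("single genus: fitting a plain penalized spline")

    knots = _make_knots(x, basis_dim)
    B = _bspline_basis(x, knots, basis_dim)
    P = _second_derivative_penalty(knots, basis_dim)
    # Mixed-model reparametrization: null space of P -> fixed, rest -> random.
    w, U = np.linalg.eigh(P)
    null_dim = int((w < w.max() * 1e-10).sum())
    if null_dim != 2:  # cubic second-derivative penalty has {1, x} null space
        null_dim = 2
    Upen, wpen = U[:, null_dim:], w[null_dim:]
    Z = B @ Upen / np.sqrt(wpen)          # n x (basis_dim - 2)
    X = np.column_stack([np.ones(n), (x - x.mean()) / max(x.std(), 1e-12)])
    A = np.zeros((n, G))
    A[np.arange(n), gidx] = 1.0

    q = Z.shape[1]
    # Low-rank REML: V = I + W D W' with W = [Z A], so every quantity in
    # the criterion reduces to (q + G)-dimensional algebra via Woodbury.
    W = np.column_stack([Z, A]) if use_genus else Z
    k = W.shape[1]
    WtW = W.T @ W
    WtX = W.T @ X
    Wty = W.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    p = X.shape[1]

    def reml_crit(theta: np.ndarray) -> float:
        r_s, r_g = np.exp(np.clip(theta, -30, 30))
        d = np.concatenate([np.full(q, r_s), np.full(G, r_g)])[:k]
        Dinv = 1.0 / np.maximum(d, 1e-300)
        try:
            B = np.linalg.inv(np.diag(Dinv) + WtW)
        except np.linalg.LinAlgError:
            return 1e10
        _, logdetV = np.linalg.slogdet(np.eye(k) + d[:, None] * WtW)
        XtViX = XtX - WtX.T @ B @ WtX
        XtViy = Xty - WtX.T @ B @ Wty
        ytViy = yty - float(Wty @ B @ Wty)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return 1e10
        rss = ytViy - float(beta @ XtViy)
        s2 = max(rss / (n - p), 1e-300)
        sign, ld2 = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e10
        return 0.5 * ((n - p) * math.log(s2) + logdetV + ld2 + (n - p))

    if ratios is not None:
        theta = np.log(np.maximum(ratios, 1e-24))
    else:
        grid_s = np.linspace(-18.0, 12.0, 16)
        grid_g = np.linspace(-8.0, 8.0, 9) if use_genus else np.array([-30.0])
        vals = [(reml_crit(np.array([a, b])), a, b) for a in grid_s for b in grid_g]
        _, a0, b0 = min(vals)
        res = optimize.minimize(reml_crit, np.array([a0, b0]), method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8,
                                         "maxfev": 400})
        theta = res.x
    r_s, r_g = np.exp(np.clip(theta, -30, 30))

    # Joint penalized solve for coefficients and the hat-matrix trace.
    blocks = [X, Z] + ([A] if use_genus else [])
    F = np.column_stack(blocks)
    pen = np.concatenate([np.zeros(X.shape[1]), np.full(q, 1.0 / r_s)]
                         + ([np.full(G, 1.0 / r_g)] if use_genus else []))
    FtF = F.T @ F
    Hinv = np.linalg.inv(FtF + np.diag(pen))
    coefs = Hinv @ (F.T @ y)
    fitted = F @ coefs
    resid = y - fitted
    edf_all = np.sum(Hinv * FtF.T, axis=1)          # diag of Hinv @ FtF
    smooth_cols = slice(1, 2 + q)                    # linear term + penalized part
    edf = float(edf_all[smooth_cols].sum())
    edf_total = float(edf_all.sum())
    sigma2 = float(resid @ resid) / max(n - edf_total, 1.0)
    genus_sd = math.sqrt(sigma2 * r_g) if use_genus else 0.0
    smooth_sd = math.sqrt(sigma2 * r_s)

    # Approximate Wald test of the whole smooth (linear + penalized parts),
    # using the Bayesian posterior covariance sigma2 * Hinv.
    cs = coefs[smooth_cols]
    Vs = sigma2 * Hinv[smooth_cols, smooth_cols]
    try:
        stat = float(cs @ np.linalg.solve(Vs, cs))
        pval = float(sps.chi2.sf(stat, df=max(edf, 1.0)))
    except np.linalg.LinAlgError:
        pval = math.nan

    gx = np.linspace(float(np.min(x)), float(np.max(x)), grid_size)
    Bg = _bspline_basis(gx, knots, basis_dim)
    Zg = Bg @ Upen / np.sqrt(wpen)
    Xg = np.column_stack([np.ones(grid_size), (gx - x.mean()) / max(x.std(), 1e-12)])
    grid_fit = Xg @ coefs[:2] + Zg @ coefs[2:2 + q]

    return GammFit(
        intercept=float(coefs[0]), edf=edf,
        smooth_pvalue=pval, sigma2=sigma2, genus_sd=genus_sd,
        smooth_sd=smooth_sd, lambda_smooth=1.0 / max(r_s, 1e-300),
        reml=-reml_crit(np.log([max(r_s, 1e-24), max(r_g, 1e-24)])),
        basis_dim=basis_dim, n=n, grid_x=gx, grid_fit=grid_fit,
    )
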