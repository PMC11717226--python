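"""Granger-Geweke deviance tests on a fitted VARX model.

For each target channel and each candidate source (every endogenous
channel's lag block, every exogenous channel's lag block), the full
model is compared against a reduced model with that block deleted.
The test statistic is the deviance

    D = T log(sigma2_reduced / sigma2_full),

twice the Gaussian log-likelihood ratio, chi-square distributed under
the null with degrees of freedom equal to the number of deleted
parameters.  The effect size is the generalized R-squared
``R^2 = 1 - exp(-D / T)``.

Ridge regularization biases the likelihoods; the de-biased deviance

    D = T' log(sigma2_r / sigma2_f) - b_r + b_f,
    b = diag(R_xe' R_xx^{-1} R_xe) / sigma2,

with the effective sample count ``T' = T - N``, restores the
chi-square calibration (b vanishes exactly for an ordinary
least-squares fit, where predictors and residuals are orthogonal).

Reduced models are solved from submatrices of the cached normal
equations, so the data are scanned exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

from .core_model import MultiSeries, VARXFilters
from .estimation import (FitConfig, NormalEquations, build_normal_equations,
                         residual_stats, ridge_solve, unpack_coefficients)

__all__ = [
    "GrangerResult",
    "deviance",
    "bias_correction",
    "debiased_deviance",
    "chi2_pvalue",
    "effect_size",
    "granger_analysis",
    "bh_fdr",
]

log = logging.getLogger(__name__)


def deviance(sigma2_reduced: np.ndarray, sigma2_full: np.ndarray,
             T: int) -> np.ndarray:
    """Plain deviance D = T log(sigma2_r / sigma2_f), elementwise."""
    sr = np.asarray(sigma2_reduced, dtype=float)
    sf = np.asarray(sigma2_full, dtype=float)
    if (sr <= 0).any() or (sf <= 0).any():
        raise ValueError("degenerate fit: residual variance must be positive")
    return T * np.log(sr / sf)


def bias_correction(R_xe: np.ndarray, R_xx: np.ndarray,
                    R_ee_diag: np.ndarray, T_used: int,
                    gamma: float = 0.0,
                    use_regularized_inverse: bool = False) -> np.ndarray:
    """Ridge likelihood bias b = diag(R_xe' R_xx^{-1} R_xe) / sigma2.

    ``diag(R_xe' R_xx^{-1} R_xe)`` is the excess residual sum of
    squares the shrunk estimate leaves over the least-squares optimum
    (a second-order expansion of the profiled Gaussian log-likelihood
    around it); dividing by ``sigma2 = R_ee / T_used`` expresses it on
    the deviance scale.  ``R_xx^{-1}`` is the raw (unregularized)
    inverse; set ``use_regularized_inverse`` to invert
    ``R_xx + gamma diag(R_xx)`` instead for sensitivity checks.  The
    result is nonnegative and exactly zero whenever R_xe = 0 (any OLS
    fit).
    """
    R_xe = np.asarray(R_xe, dtype=float)
    if not R_xe.any():
        return np.zeros(R_xe.shape[1])
    G = R_xx + gamma * np.diag(np.diag(R_xx)) if use_regularized_inverse else R_xx
    sol = scipy.linalg.solve(G, R_xe, assume_a="pos")
    quad = np.einsum("ni,ni->i", R_xe, sol)
    return np.maximum(quad, 0.0) * T_used / R_ee_diag


def debiased_deviance(sigma2_reduced, sigma2_full, b_reduced, b_full,
                      T_effective: int, clamp: bool = True) -> np.ndarray:
    """De-biased deviance D = T' log(sigma2_r / sigma2_f) - b_r + b_f.

    The corrected statistic can come out slightly negative; it is
    clamped to 0 (p = 1) before the chi-square lookup.
    """
    D = deviance(sigma2_reduced, sigma2_full, T_effective)
    D = D - np.asarray(b_reduced, dtype=float) + np.asarray(b_full, dtype=float)
    return np.maximum(D, 0.0) if clamp else D


def chi2_pvalue(D: np.ndarray, n_removed: int) -> np.ndarray:
    """p = 1 - F(D, n_removed) with F the chi-square CDF."""
    if n_removed <= 0:
        raise ValueError("n_removed must be a positive parameter count")
    return stats.chi2.sf(np.asarray(D, dtype=float), df=n_removed)


def effect_size(D: np.ndarray, T: int) -> np.ndarray:
    """Generalized R-squared, R^2 = 1 - exp(-D / T).

    The square root R of this quantity is the conventional effect size
    for connectivity graphs.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    return 1.0 - np.exp(-np.asarray(D, dtype=float) / T)


@dataclass
class GrangerResult:
    """Per-channel deviance tests of a VARX fit.

    Endogenous matrices are (d_y, d_y) indexed [target, source];
    exogenous matrices are (d_y, d_x).  Entries are NaN where a test
    could not be run (degenerate variable).
    """

    A_deviance: np.ndarray
    A_pval: np.ndarray
    A_R2: np.ndarray
    B_deviance: np.ndarray
    B_pval: np.ndarray
    B_R2: np.ndarray
    sigma2_full: np.ndarray
    bias_full: np.ndarray
    T_used: int
    T_effective: int
    N: int
    filters: VARXFilters
    config: FitConfig
    names_y: tuple = ()
    names_x: tuple = ()

    def edges(self, alpha: float | None = None):
        """Edge list (source, target, kind, R, R2, deviance, pval) as a
        DataFrame, optionally thresholded at ``alpha``."""
        import pandas as pd

        rows = []
        for kind, D, p, R2, src_names in (
                ("A", self.A_deviance, self.A_pval, self.A_R2, self.names_y),
                ("B", self.B_deviance, self.B_pval, self.B_R2, self.names_x)):
            for i, tgt in enumerate(self.names_y):
                for j, src in enumerate(src_names):
                    rows.append({"source": src, "target": tgt, "kind": kind,
                                 "R": float(np.sqrt(max(R2[i, j], 0.0))),
                                 "R2": float(R2[i, j]),
                                 "deviance": float(D[i, j]),
                                 "pval": float(p[i, j])})
        df = pd.DataFrame(rows)
        if alpha is not None:
            df = df[df["pval"] < alpha].reset_index(drop=True)
        return df


def _reduced_sigma2(ne: NormalEquations, keep: np.ndarray, gamma: float,
                    debias: bool, use_reg_inv: bool):
    """Fit the reduced model on a submatrix of the cached cross-products."""
    R_xx_r = ne.R_xx[np.ix_(keep, keep)]
    R_xy_r = ne.R_xy[keep, :]
    H_r = ridge_solve(R_xx_r, R_xy_r, gamma=gamma)
    sigma2_r, R_ee_r, R_xe_r = residual_stats(
        R_xx_r, H_r, R_xy=R_xy_r, R_yy_diag=ne.R_yy_diag, T_used=ne.T_used)
    b_r = (bias_correction(R_xe_r, R_xx_r, R_ee_r, ne.T_used, gamma=gamma,
                           use_regularized_inverse=use_reg_inv)
           if debias else np.zeros(ne.R_xy.shape[1]))
    return sigma2_r, b_r


def granger_analysis(data: MultiSeries, config: FitConfig,
                     use_regularized_inverse: bool = False) -> GrangerResult:
    """Fit the full VARX model once, then test every predictor block.

    Each endogenous source tests ``n_a`` parameters per target
    (including each channel's own history on the diagonal); each
    exogenous source tests ``n_b`` parameters (``n_basis`` when a basis
    is in use).  With ``gamma > 0`` the de-biased deviance at
    ``T' = T_used - N`` is used; at ``gamma = 0`` the plain deviance at
    ``T_used``.
    """
    ne = build_normal_equations(data, config)
    gamma, debias = config.gamma, config.debias
    if gamma == 0 and ne.T_used <= ne.N:
        raise ValueError(f"T_used={ne.T_used} must exceed N={ne.N} for an "
                         "unregularized fit")
    H_hat = ridge_solve(ne, gamma=gamma)
    sigma2_f, R_ee_f, R_xe_f = residual_stats(ne, H_hat)
    ok_target = sigma2_f > 0
    if not ok_target.any():
        raise ValueError("full model leaves zero residual variance on every "
                         "channel; deviance tests are undefined")
    if not ok_target.all():
        log.warning("channel(s) %s have zero residual variance; their tests "
                    "are skipped",
                    [n for n, ok in zip(ne.names_y, ok_target) if not ok])
        sigma2_f = np.where(ok_target, sigma2_f, 1.0)
    b_f = (bias_correction(R_xe_f, ne.R_xx, R_ee_f, ne.T_used, gamma=gamma,
                           use_regularized_inverse=use_regularized_inverse)
           if debias else np.zeros(ne.d_y))
    T_eff = ne.T_used - ne.N if debias else ne.T_used

    d_y, d_x = ne.d_y, ne.d_x
    A_D = np.full((d_y, d_y), np.nan)
    A_p = np.full((d_y, d_y), np.nan)
    A_R2 = np.full((d_y, d_y), np.nan)
    B_D = np.full((d_y, d_x), np.nan)
    B_p = np.full((d_y, d_x), np.nan)
    B_R2 = np.full((d_y, d_x), np.nan)

    diag = np.diag(ne.R_xx)
    all_cols = np.arange(ne.N)
    i_endo = i_exo = 0
    for blk in ne.index_map:
        j = i_endo if blk.kind == "endogenous" else i_exo
        if blk.kind == "endogenous":
            i_endo += 1
        else:
            i_exo += 1
        if not diag[blk.idx].any():
            log.warning("variable %r has zero variance after masking; "
                        "its tests are skipped", blk.name)
            continue
        try:
            keep = np.setdiff1d(all_cols, blk.idx)
            sigma2_r, b_r = _reduced_sigma2(ne, keep, gamma, debias,
                                            use_regularized_inverse)
            sigma2_r = np.where(ok_target, sigma2_r, 1.0)
            D = (debiased_deviance(sigma2_r, sigma2_f, b_r, b_f, T_eff)
                 if debias else deviance(sigma2_r, sigma2_f, T_eff))
            D = np.maximum(D, 0.0)
            p = chi2_pvalue(D, blk.n_lags)
            R2 = effect_size(D, T_eff)
            D[~ok_target] = np.nan
            p[~ok_target] = np.nan
            R2[~ok_target] = np.nan
        except Exception as exc:  # noqa: BLE001 -- per-test failure is recorded
            log.warning("test for %r failed: %s", blk.name, exc)
            continue
        if blk.kind == "endogenous":
            A_D[:, j], A_p[:, j], A_R2[:, j] = D, p, R2
        else:
            B_D[:, j], B_p[:, j], B_R2[:, j] = D, p, R2

    return GrangerResult(
        A_deviance=A_D, A_pval=A_p, A_R2=A_R2,
        B_deviance=B_D, B_pval=B_p, B_R2=B_R2,
        sigma2_full=sigma2_f, bias_full=b_f,
        T_used=ne.T_used, T_effective=T_eff, N=ne.N,
        filters=unpack_coefficients(H_hat, ne), config=config,
        names_y=tuple(ne.names_y), names_x=tuple(ne.names_x))


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in helper; the raw
    matrices are always emitted unadjusted).  NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = stats.false_discovery_control(p[mask].ravel(),
                                                  method="bh").reshape(-1)
    return out
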