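"""Least-squares identification of VARX filters.

The regression stacks, for every valid sample ``t``, the lagged
predictors ``phi(t) = [y(t-1)..y(t-n_a), x(t)..x(t-n_b+1)]`` into the
block-Toeplitz design matrix ``X`` and solves ``Y = X H + E``.  The
normal equations ``R_xx = X'X``, ``R_xy = X'Y`` are cached so that
reduced models (one predictor variable deleted) can be solved from
submatrices without rescanning the data.

A sample contributes only if its target and its entire lagged history
are finite and lie within one recording segment; missing values (NaN)
therefore knock out every sample whose predictor window touches them.

Ridge (Tikhonov) regularization uses the scale-equalizing penalty
``gamma * diag(R_xx)``, and long exogenous filters can be compressed
onto Gaussian lag bases, reducing ``n_b`` raw lags to ``n_basis``
coefficients per input channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.linalg

from .core_model import MultiSeries, VARXFilters

__all__ = [
    "FitConfig",
    "BasisSet",
    "Block",
    "NormalEquations",
    "EstimationError",
    "gaussian_basis",
    "build_design",
    "build_normal_equations",
    "ridge_solve",
    "residual_stats",
    "unpack_coefficients",
    "fit_varx",
    "cv_gamma",
]


class EstimationError(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Model orders and regularization for a VARX fit.

    ``n_a`` lags of every endogenous channel and ``n_b`` lags (0..n_b-1)
    of every exogenous channel enter the regression.  ``gamma`` scales
    the ridge penalty ``gamma * diag(R_xx)``; 0 gives ordinary least
    squares.  ``n_basis`` compresses each exogenous filter onto that
    many Gaussian lag bases.  ``bias_correction`` defaults to on
    whenever ``gamma > 0``.
    """

    n_a: int = 0
    n_b: int = 0
    gamma: float = 0.0
    n_basis: int | None = None
    bias_correction: bool | None = None

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("model orders must be nonnegative")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.n_basis is not None and self.n_basis > self.n_b:
            raise ValueError(f"n_basis={self.n_basis} exceeds n_b={self.n_b}")

    @property
    def debias(self) -> bool:
        return self.gamma > 0 if self.bias_correction is None else self.bias_correction


@dataclass
class BasisSet:
    """Gaussian lag bases for compressing exogenous filters.

    ``W`` has shape (n_b, n_basis); the full-lag filter is recovered as
    ``B(l) = sum_k W[l, k] Bc(k)`` where ``Bc`` holds the compressed
    coefficients.  Columns are unimodal bumps normalized to unit
    maximum.
    """

    W: np.ndarray
    centers: np.ndarray
    widths: np.ndarray

    @property
    def n_b(self) -> int:
        return self.W.shape[0]

    @property
    def n_basis(self) -> int:
        return self.W.shape[1]


def gaussian_basis(n_b: int, n_basis: int, width: float | None = None) -> BasisSet:
    """Build ``n_basis`` Gaussian bumps spanning lags 0..n_b-1.

    Centers are equally spaced including both endpoints; the standard
    deviation defaults to the center spacing with a floor of 0.5 lag so
    no column degenerates.  Pass ``width`` explicitly to override (e.g.
    a small width makes W approach the identity when n_basis = n_b).
    """
    if not (1 <= n_basis <= n_b):
        raise ValueError(f"need 1 <= n_basis <= n_b, got n_basis={n_basis}, n_b={n_b}")
    if n_basis == 1:
        centers = np.array([(n_b - 1) / 2.0])
        spacing = max((n_b - 1) / 2.0, 1.0)
    else:
        centers = np.linspace(0.0, n_b - 1.0, n_basis)
        spacing = centers[1] - centers[0]
    if width is None:
        width = max(spacing, 0.5)
    elif width <= 0:
        raise ValueError("width must be positive")
    lags = np.arange(n_b, dtype=float)
    W = np.exp(-0.5 * ((lags[:, None] - centers[None, :]) / width) ** 2)
    W /= W.max(axis=0, keepdims=True)
    assert (W.sum(axis=1) > 0).all(), "basis leaves uncovered lags"
    return BasisSet(W=W, centers=centers, widths=np.full(n_basis, float(width)))


class Block(NamedTuple):
    """One predictor variable's columns in the design matrix."""

    name: str
    kind: str               # "endogenous" | "exogenous"
    cols: tuple             # (start, stop) column range, half-open
    n_lags: int             # parameters removed when this block is dropped

    @property
    def idx(self) -> np.ndarray:
        return np.arange(*self.cols)


@dataclass
class NormalEquations:
    """Cached cross-products of the lagged regression.

    ``R_xx`` (N x N) and ``R_xy`` (N x d_y) are accumulated over the
    ``T_used`` samples with a complete, finite, within-segment history.
    ``index_map`` records which columns belong to which variable so
    reduced models can be carved out by deleting a block.
    """

    R_xx: np.ndarray
    R_xy: np.ndarray
    R_yy_diag: np.ndarray
    T_used: int
    index_map: tuple
    n_a: int
    n_b: int
    d_y: int
    d_x: int
    basis: BasisSet | None = None
    names_y: Sequence[str] = ()
    names_x: Sequence[str] = ()

    @property
    def N(self) -> int:
        return self.R_xx.shape[0]


def build_design(data: MultiSeries, n_a: int, n_b: int):
    """Materialize the lagged design matrix and validity mask.

    Returns ``(Phi, Yt, valid)`` where ``Phi`` is (T, N) with NaN where
    a lag is unavailable, ``Yt`` the target matrix, and ``valid`` marks
    samples whose whole predictor window and target are finite and lie
    inside one segment.
    """
    T, d_y, d_x = data.T, data.d_y, data.d_x
    N = d_y * n_a + d_x * n_b
    if N == 0:
        raise EstimationError("model has no predictors (n_a = n_b = 0)")
    Phi = np.full((T, N), np.nan)
    for j in range(d_y):
        for li in range(n_a):
            l = li + 1
            if l < T:
                Phi[l:, j * n_a + li] = data.Y[:T - l, j]
    off = d_y * n_a
    for j in range(d_x):
        for l in range(n_b):
            if l < T:
                Phi[l:, off + j * n_b + l] = data.X[:T - l, j]
    min_depth = max(n_a, n_b - 1, 0)
    valid = data.segment_of() >= min_depth
    valid &= np.isfinite(Phi).all(axis=1)
    valid &= np.isfinite(data.Y).all(axis=1)
    return Phi, data.Y, valid


def _index_map(data: MultiSeries, n_a: int, n_lags_x: int) -> tuple:
    blocks = []
    col = 0
    if n_a > 0:
        for name in data.names_y:
            blocks.append(Block(name, "endogenous", (col, col + n_a), n_a))
            col += n_a
    if n_lags_x > 0:
        for name in data.names_x:
            blocks.append(Block(name, "exogenous", (col, col + n_lags_x), n_lags_x))
            col += n_lags_x
    return tuple(blocks)


def build_normal_equations(data: MultiSeries, config: FitConfig,
                           basis: BasisSet | None = None) -> NormalEquations:
    """Accumulate R_xx, R_xy, R_yy over all valid samples.

    With a basis, the exogenous blocks are compressed immediately:
    R_xx -> M' R_xx M and R_xy -> M' R_xy, where M is block diagonal
    with the identity on endogenous columns and W on each exogenous
    channel's columns.
    """
    n_a, n_b = config.n_a, config.n_b
    if basis is None and config.n_basis is not None:
        basis = gaussian_basis(n_b, config.n_basis)
    for j, name in enumerate(data.names_y):
        if not np.isfinite(data.Y[:, j]).any():
            raise EstimationError(f"endogenous variable {name!r} has no finite samples")
    for j, name in enumerate(data.names_x):
        if n_b > 0 and not np.isfinite(data.X[:, j]).any():
            raise EstimationError(f"exogenous variable {name!r} has no finite samples")

    Phi, Y, valid = build_design(data, n_a, n_b)
    T_used = int(valid.sum())
    if T_used == 0:
        raise EstimationError("no valid samples: every predictor window is "
                              "incomplete (check n_a/n_b against segment "
                              "lengths and missing values)")
    Pv, Yv = Phi[valid], Y[valid]
    R_xx = Pv.T @ Pv
    R_xy = Pv.T @ Yv
    R_yy_diag = np.einsum("ti,ti->i", Yv, Yv)

    if basis is not None and data.d_x > 0 and n_b > 0:
        if basis.n_b != n_b:
            raise EstimationError(f"basis spans {basis.n_b} lags but n_b={n_b}")
        n_endo = data.d_y * n_a
        M = scipy.linalg.block_diag(np.eye(n_endo),
                                    *([basis.W] * data.d_x))
        R_xx = M.T @ R_xx @ M
        R_xy = M.T @ R_xy
        n_lags_x = basis.n_basis
    else:
        basis = None
        n_lags_x = n_b if data.d_x > 0 else 0

    return NormalEquations(
        R_xx=R_xx, R_xy=R_xy, R_yy_diag=R_yy_diag, T_used=T_used,
        index_map=_index_map(data, n_a, n_lags_x),
        n_a=n_a, n_b=n_b, d_y=data.d_y, d_x=data.d_x, basis=basis,
        names_y=tuple(data.names_y), names_x=tuple(data.names_x))


def _ridge_matrix(R_xx: np.ndarray, gamma: float) -> np.ndarray:
    if gamma == 0:
        return R_xx
    return R_xx + gamma * np.diag(np.diag(R_xx))


def ridge_solve(R_xx_or_ne, R_xy: np.ndarray | None = None,
                gamma: float = 0.0) -> np.ndarray:
    """Solve (R_xx + gamma diag(R_xx)) H = R_xy via Cholesky.

    Accepts either a :class:`NormalEquations` or the raw matrices.  On
    a singular system the solver falls back to a least-squares solution
    with a warning (at gamma = 0 this signals rank deficiency; a small
    positive gamma is the usual remedy).
    """
    if isinstance(R_xx_or_ne, NormalEquations):
        ne = R_xx_or_ne
        R_xx, R_xy = ne.R_xx, ne.R_xy
    else:
        R_xx = R_xx_or_ne
        if R_xy is None:
            raise ValueError("R_xy required when passing raw matrices")
    G = _ridge_matrix(R_xx, gamma)
    try:
        c, low = scipy.linalg.cho_factor(G, lower=True)
        return scipy.linalg.cho_solve((c, low), R_xy)
    except scipy.linalg.LinAlgError:
        warnings.warn("normal equations are singular"
                      + ("; consider gamma > 0" if gamma == 0 else "")
                      + " -- falling back to a minimum-norm least-squares solve",
                      RuntimeWarning, stacklevel=2)
        H, *_ = scipy.linalg.lstsq(G, R_xy)
        return H


def residual_stats(ne_or_Rxx, H_hat: np.ndarray,
                   R_xy: np.ndarray | None = None,
                   R_yy_diag: np.ndarray | None = None,
                   T_used: int | None = None):
    """Residual cross-products of a fitted model.

    Returns ``(sigma2, R_ee_diag, R_xe)`` with
    ``R_ee = H' R_xx H - 2 H' R_xy + R_yy`` evaluated per output,
    ``sigma2 = diag(R_ee) / T_used`` and ``R_xe = R_xy - R_xx H`` (the
    predictor-residual cross-product needed for the ridge bias
    correction; exactly zero for an OLS fit).
    """
    if isinstance(ne_or_Rxx, NormalEquations):
        ne = ne_or_Rxx
        R_xx, R_xy, R_yy_diag, T_used = ne.R_xx, ne.R_xy, ne.R_yy_diag, ne.T_used
    else:
        R_xx = ne_or_Rxx
        if R_xy is None or R_yy_diag is None or T_used is None:
            raise ValueError("R_xy, R_yy_diag and T_used required with raw matrices")
    RxxH = R_xx @ H_hat
    R_ee_diag = (np.einsum("ni,ni->i", H_hat, RxxH)
                 - 2.0 * np.einsum("ni,ni->i", H_hat, R_xy)
                 + R_yy_diag)
    tol = 1e-8 * max(R_yy_diag.max(), 1.0)
    if (R_ee_diag < -tol).any():
        raise EstimationError("negative residual variance: numerical failure")
    R_ee_diag = np.maximum(R_ee_diag, 0.0)
    sigma2 = R_ee_diag / T_used
    R_xe = R_xy - RxxH
    return sigma2, R_ee_diag, R_xe


def unpack_coefficients(H_hat: np.ndarray, ne: NormalEquations,
                        basis: BasisSet | None = None) -> VARXFilters:
    """Rearrange the (N, d_y) coefficient matrix into filter tensors.

    With a basis, the compressed exogenous coefficients are expanded
    back to the lag domain via ``B(l) = sum_k W[l, k] Bc(k)``.
    """
    basis = basis if basis is not None else ne.basis
    d_y, d_x, n_a, n_b = ne.d_y, ne.d_x, ne.n_a, ne.n_b
    A = np.zeros((n_a, d_y, d_y))
    B = np.zeros((n_b, d_y, d_x))
    endo = [b for b in ne.index_map if b.kind == "endogenous"]
    exo = [b for b in ne.index_map if b.kind == "exogenous"]
    for j, blk in enumerate(endo):
        A[:, :, j] = H_hat[slice(*blk.cols), :]       # lag-major rows -> (lag, target)
    for j, blk in enumerate(exo):
        coeffs = H_hat[slice(*blk.cols), :]           # (n_lags or n_basis, d_y)
        if basis is not None:
            coeffs = basis.W @ coeffs                 # expand to (n_b, d_y)
        B[:, :, j] = coeffs
    return VARXFilters(A=A, B=B, names_y=ne.names_y or None,
                       names_x=ne.names_x or None)


def fit_varx(data: MultiSeries, config: FitConfig,
             basis: BasisSet | None = None):
    """One-call fit: returns (filters, ne, H_hat, sigma2)."""
    ne = build_normal_equations(data, config, basis=basis)
    H_hat = ridge_solve(ne, gamma=config.gamma)
    sigma2, _, _ = residual_stats(ne, H_hat)
    return unpack_coefficients(H_hat, ne), ne, H_hat, sigma2


def cv_gamma(data: MultiSeries, config: FitConfig,
             gammas: Sequence[float], n_folds: int = 5, seed: int = 0):
    """Cross-validated mean squared prediction error per gamma.

    Contiguous chunks of valid samples are held out in turn; the model
    is fitted on the remainder and scored on the held-out chunk.  Never
    invoked automatically -- gamma stays a user choice.
    """
    Phi, Y, valid = build_design(data, config.n_a, config.n_b)
    idx = np.flatnonzero(valid)
    if len(idx) < n_folds:
        raise EstimationError("too few valid samples for cross-validation")
    folds = np.array_split(idx, n_folds)
    M = None
    if config.n_basis is not None:
        bs = gaussian_basis(config.n_b, config.n_basis)
        n_endo = data.d_y * config.n_a
        M = scipy.linalg.block_diag(np.eye(n_endo), *([bs.W] * data.d_x))
    scores = {}
    for gamma in gammas:
        mse = 0.0
        for hold in folds:
            train = np.setdiff1d(idx, hold)
            Pt, Ph = Phi[train], Phi[hold]
            if M is not None:
                Pt, Ph = Pt @ M, Ph @ M
            H = ridge_solve(Pt.T @ Pt, Pt.T @ Y[train], gamma=gamma)
            r = Y[hold] - Ph @ H
            mse += float(np.mean(r ** 2))
        scores[float(gamma)] = mse / n_folds
    return scores
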