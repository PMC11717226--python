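"""Model objects and simulators for VARX (vector autoregression with
exogenous input) systems.

The model predicts a vector of endogenous variables ``y(t)`` (dimension
``d_y``) from its own past and from lagged exogenous inputs ``x(t)``
(dimension ``d_x``)::

    y(t) = sum_{l=1..n_a} A(l) y(t-l) + sum_{l=0..n_b-1} B(l) x(t-l) + e(t)

``A`` holds the autoregressive (endogenous) filters, ``B`` the
moving-average (exogenous) filters, and ``e(t)`` is an unobserved white
innovation that drives the recurrent dynamic.  In the *equation-error*
model above the innovation enters the recursion; the alternative
*output-error* model runs the recursion noise-free on a hidden state
``z(t)`` and adds observation noise only at the output::

    z(t) = sum_l A(l) z(t-l) + sum_l B(l) x(t-l),    y(t) = z(t) + e(t)

Both generators are provided here; only the equation-error model has a
closed-form estimator (see :mod:`varxgranger.estimation`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VARXFilters",
    "MultiSeries",
    "ScenarioSpec",
    "InstabilityError",
    "simulate_varx",
    "simulate_output_error",
    "impulse_response",
    "spectral_radius",
]


class InstabilityError(RuntimeError):
    """Raised when a simulated recursion produces non-finite values."""

    def __init__(self, t: int):
        self.t = t
        super().__init__(f"recursion produced non-finite values at sample t={t}; "
                         "the AR filter is unstable")


@dataclass
class VARXFilters:
    """AR and MA filter tensors of a VARX model.

    Parameters
    ----------
    A : ndarray, shape (n_a, d_y, d_y)
        Autoregressive filters. ``A[l-1, i, j]`` is the weight of
        ``y_j(t-l)`` in the prediction of ``y_i(t)`` (row = target,
        column = source); lags run 1..n_a.
    B : ndarray, shape (n_b, d_y, d_x)
        Moving-average filters. ``B[l, i, j]`` is the weight of
        ``x_j(t-l)`` in the prediction of ``y_i(t)``; lags run 0..n_b-1.
    names_y, names_x : sequence of str, optional
        Variable names used when serializing.
    """

    A: np.ndarray
    B: np.ndarray
    names_y: Sequence[str] | None = None
    names_x: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError(f"A must have shape (n_a, d_y, d_y), got {self.A.shape}")
        if self.B.ndim != 3:
            raise ValueError(f"B must have shape (n_b, d_y, d_x), got {self.B.shape}")
        if self.A.shape[1] != self.B.shape[1] and self.A.size and self.B.size:
            raise ValueError("A and B disagree on d_y: "
                             f"{self.A.shape[1]} vs {self.B.shape[1]}")
        if not (np.isfinite(self.A).all() and np.isfinite(self.B).all()):
            raise ValueError("filter coefficients must be finite")

    @property
    def n_a(self) -> int:
        return self.A.shape[0]

    @property
    def n_b(self) -> int:
        return self.B.shape[0]

    @property
    def d_y(self) -> int:
        return self.A.shape[1] if self.A.size or self.A.shape[1] else self.B.shape[1]

    @property
    def d_x(self) -> int:
        return self.B.shape[2]

    def to_json(self) -> str:
        doc = {
            "n_a": self.n_a, "n_b": self.n_b,
            "d_y": self.d_y, "d_x": self.d_x,
            "A": self.A.tolist(), "B": self.B.tolist(),
            "names": {"y": list(self.names_y) if self.names_y else None,
                      "x": list(self.names_x) if self.names_x else None},
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VARXFilters":
        doc = json.loads(text)
        d_y, d_x = int(doc["d_y"]), int(doc["d_x"])
        A = np.asarray(doc["A"], dtype=float).reshape(int(doc["n_a"]), d_y, d_y)
        B = np.asarray(doc["B"], dtype=float).reshape(int(doc["n_b"]), d_y, d_x)
        names = doc.get("names") or {}
        return cls(A=A, B=B, names_y=names.get("y"), names_x=names.get("x"))


@dataclass
class MultiSeries:
    """A multivariate time series split into endogenous and exogenous parts.

    ``Y`` is the (T, d_y) endogenous matrix, ``X`` the (T, d_x) exogenous
    matrix (``d_x`` may be 0).  Missing samples are NaN.  ``segment_starts``
    marks the first index of each independent recording segment; lagged
    predictors never reach across a segment boundary.
    """

    Y: np.ndarray
    X: np.ndarray | None = None
    names_y: Sequence[str] | None = None
    names_x: Sequence[str] | None = None
    segment_starts: Sequence[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.ndim != 2:
            raise ValueError("Y must be a (T, d_y) matrix")
        if self.X is None:
            self.X = np.zeros((self.Y.shape[0], 0))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(f"Y has {self.Y.shape[0]} samples but X has {self.X.shape[0]}")
        starts = sorted(int(s) for s in self.segment_starts)
        if not starts or starts[0] != 0:
            raise ValueError("segment_starts must begin at index 0")
        if len(set(starts)) != len(starts):
            raise ValueError("segment_starts must be strictly increasing")
        if starts and starts[-1] >= self.T and self.T > 0:
            raise ValueError("segment start beyond end of series")
        self.segment_starts = starts
        if self.names_y is None:
            self.names_y = [f"y{i + 1}" for i in range(self.d_y)]
        if self.names_x is None:
            self.names_x = [f"x{i + 1}" for i in range(self.d_x)]

    @property
    def T(self) -> int:
        return self.Y.shape[0]

    @property
    def d_y(self) -> int:
        return self.Y.shape[1]

    @property
    def d_x(self) -> int:
        return self.X.shape[1]

    def segment_of(self) -> np.ndarray:
        """Per-sample depth into its own segment (0 at each segment start)."""
        depth = np.arange(self.T)
        for s in self.segment_starts:
            depth[s:] = np.arange(self.T - s)
        return depth


@dataclass
class ScenarioSpec:
    """Configuration of a causal-structure simulation.

    ``structure`` fixes the role of the conditioning variable ``x``:
    a common cause of both endogenous channels, a collider driven by
    them, or an unconnected (independent) variable.  In every structure
    the one-directional endogenous path y1 -> y2 is present with weight
    ``coupling_strength`` at lag 1.  ``noise_model`` selects
    equation-error generation (innovation inside the recursion) or
    output-error generation (noise-free hidden recursion plus
    observation noise).
    """

    structure: Literal["common_cause", "collider", "independent"] = "common_cause"
    noise_model: Literal["equation_error", "output_error"] = "equation_error"
    coupling_strength: float = 0.3
    include_x_in_model: bool = True
    n_a: int = 3
    n_b: int = 3
    T: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in ("common_cause", "collider", "independent"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.noise_model not in ("equation_error", "output_error"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _as_innovations(e, T: int, d_y: int, rng=None, sd: float = 1.0) -> np.ndarray:
    if e is None:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return rng.normal(scale=sd, size=(T, d_y))
    e = np.asarray(e, dtype=float)
    if e.shape != (T, d_y):
        raise ValueError(f"innovations must have shape ({T}, {d_y}), got {e.shape}")
    return e


def _ma_drive(filters: VARXFilters, x: np.ndarray | None, T: int) -> np.ndarray:
    """Convolve the exogenous input with B: sum_{l=0..n_b-1} B(l) x(t-l)."""
    drive = np.zeros((T, filters.d_y))
    if x is None or filters.d_x == 0 or filters.n_b == 0:
        return drive
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape != (T, filters.d_x):
        raise ValueError(f"x must have shape ({T}, {filters.d_x}), got {x.shape}")
    for j in range(filters.d_x):
        for i in range(filters.d_y):
            drive[:, i] += np.convolve(x[:, j], filters.B[:, i, j])[:T]
    return drive


def _run_recursion(filters: VARXFilters, drive: np.ndarray) -> np.ndarray:
    """Run y(t) = sum_l A(l) y(t-l) + drive(t) with zero pre-history."""
    T, d_y = drive.shape
    n_a = filters.n_a
    if n_a == 0:
        y = drive.copy()
        bad = ~np.isfinite(y).all(axis=1)
        if bad.any():
            raise InstabilityError(int(np.flatnonzero(bad)[0]))
        return y
    # companion-form weights acting on the flattened history
    # [y(t-1); y(t-2); ...; y(t-n_a)]
    A_flat = np.concatenate([filters.A[l] for l in range(n_a)], axis=1)
    y = np.empty((T, d_y))
    hist = np.zeros(d_y * n_a)
    for t in range(T):
        yt = A_flat @ hist + drive[t]
        if not np.all(np.isfinite(yt)):
            raise InstabilityError(t)
        y[t] = yt
        if n_a > 1:
            hist[d_y:] = hist[:-d_y]
        hist[:d_y] = yt
    return y


def simulate_varx(filters: VARXFilters, x: np.ndarray | None = None,
                  e: np.ndarray | None = None, T: int | None = None,
                  noise_sd: float = 1.0, rng=None) -> np.ndarray:
    """Simulate the equation-error VARX recursion.

    Pre-history samples (t < 0) are taken to be zero.  Supply either an
    explicit innovation matrix ``e`` (for exact reproducibility) or a
    length ``T`` with ``noise_sd``/``rng`` to draw i.i.d. Gaussian
    innovations.

    Returns the (T, d_y) endogenous series.  Raises
    :class:`InstabilityError` if an unstable AR filter drives the
    output non-finite.
    """
    if T is None:
        if e is not None:
            T = np.asarray(e).shape[0]
        elif x is not None:
            T = np.atleast_2d(np.asarray(x)).shape[0]
        else:
            raise ValueError("either T, x, or e must determine the length")
    e = _as_innovations(e, T, filters.d_y, rng=rng, sd=noise_sd)
    drive = _ma_drive(filters, x, T) + e
    return _run_recursion(filters, drive)


def simulate_output_error(filters: VARXFilters, x: np.ndarray | None = None,
                          noise: np.ndarray | None = None, T: int | None = None,
                          noise_sd: float = 1.0, rng=None,
                          return_hidden: bool = False):
    """Simulate the output-error model: a noise-free hidden recursion
    ``z(t)`` driven by the input, observed as ``y(t) = z(t) + e(t)``.

    Unlike :func:`simulate_varx`, the noise never enters the recursion.
    """
    if T is None:
        if noise is not None:
            T = np.asarray(noise).shape[0]
        elif x is not None:
            T = np.atleast_2d(np.asarray(x)).shape[0]
        else:
            raise ValueError("either T, x, or noise must determine the length")
    z = _run_recursion(filters, _ma_drive(filters, x, T))
    e = _as_innovations(noise, T, filters.d_y, rng=rng, sd=noise_sd)
    y = z + e
    return (y, z) if return_hidden else y


def impulse_response(filters: VARXFilters, horizon: int) -> np.ndarray:
    """Total system response H = (I - A)^{-1} B, shape (horizon, d_y, d_x).

    Computed in the time domain by passing a unit impulse through each
    input channel with the innovation set to zero.  An unstable AR
    filter yields a diverging (but still returned) truncated response
    with a warning.
    """
    import warnings

    if spectral_radius(filters) >= 1.0:
        warnings.warn("unstable AR filter: the impulse response diverges; "
                      "returning the truncated response",
                      RuntimeWarning, stacklevel=2)
    H = np.zeros((horizon, filters.d_y, filters.d_x))
    for j in range(filters.d_x):
        x_imp = np.zeros((horizon, filters.d_x))
        x_imp[0, j] = 1.0
        drive = _ma_drive(filters, x_imp, horizon)
        with np.errstate(over="ignore", invalid="ignore"):
            H[:, :, j] = _run_unchecked(filters, drive)
    return H


def _run_unchecked(filters: VARXFilters, drive: np.ndarray) -> np.ndarray:
    T, d_y = drive.shape
    n_a = filters.n_a
    if n_a == 0:
        return drive.copy()
    A_flat = np.concatenate([filters.A[l] for l in range(n_a)], axis=1)
    y = np.empty((T, d_y))
    hist = np.zeros(d_y * n_a)
    for t in range(T):
        y[t] = A_flat @ hist + drive[t]
        if n_a > 1:
            hist[d_y:] = hist[:-d_y]
        hist[:d_y] = y[t]
    return y


def spectral_radius(filters: VARXFilters) -> float:
    """Largest eigenvalue magnitude of the companion matrix of A.

    A value below 1 means the AR recursion is stable.  Returns 0 for a
    pure MA model (n_a = 0).
    """
    n_a, d_y = filters.n_a, filters.d_y
    if n_a == 0 or not filters.A.size:
        return 0.0
    n = d_y * n_a
    C = np.zeros((n, n))
    C[:d_y, :] = np.concatenate([filters.A[l] for l in range(n_a)], axis=1)
    if n_a > 1:
        C[d_y:, :-d_y] = np.eye(d_y * (n_a - 1))
    return float(np.max(np.abs(np.linalg.eigvals(C))))
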