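import numpy as np
import pytest

from varxgranger import MultiSeries, VARXFilters, simulate_varx


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def stable_filters():
    """A comfortably stable 2-output, 1-input system with 2 AR lags and
    3 MA lags."""
    A = np.zeros((2, 2, 2))
    A[:, 0, 0] = [0.4, 0.1]
    A[:, 1, 1] = [0.3, 0.1]
    A[0, 1, 0] = 0.25          # y1 -> y2
    B = np.zeros((3, 2, 1))
    B[:, 0, 0] = [1.0, 0.5, 0.2]
    B[:, 1, 0] = [0.3, -0.4, 0.1]
    return VARXFilters(A=A, B=B)


@pytest.fixture
def simulated_data(rng, stable_filters):
    """A seeded realization of the stable system, wrapped as MultiSeries."""
    T = 400
    x = rng.standard_normal((T, 1))
    y = simulate_varx(stable_filters, x=x, rng=rng)
    return MultiSeries(Y=y, X=x)


def naive_varx_recursion(A, B, x, e):
    """Independent sample-by-sample oracle for the VARX recursion,
    applying the lag sums term by term."""
    n_a, d_y, _ = A.shape
    n_b = B.shape[0]
    T = e.shape[0]
    y = np.zeros((T, d_y))
    for t in range(T):
        acc = e[t].copy()
        for l in range(1, n_a + 1):
            if t - l >= 0:
                acc += A[l - 1] @ y[t - l]
        for l in range(n_b):
            if t - l >= 0 and x is not None:
                acc += B[l] @ x[t - l]
        y[t] = acc
    return y
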