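# Demo: factoring a prolonged response into fast drive + recurrence

Sensory-driven neural recordings typically show a prolonged response
to each stimulus event. A pure moving-average model (the mTRF view)
must spend one coefficient per lag of that response. A VARX fit
instead factors it: a short exogenous filter `B` captures the fast
drive, and the recurrent filter `A` generates the long tail, with the
total response recovered as `H = (I − A)⁻¹ B`.

The snippet below builds a synthetic system of that shape — fast
2-lag input filters, slow recurrent dynamics — fits it both ways, and
compares the two total responses:

```python
import numpy as np
import varxgranger as vg

rng = np.random.default_rng(606)
A = np.zeros((2, 2, 2))
A[:, 0, 0] = [0.5, 0.2]           # slow recurrence
A[:, 1, 1] = [0.45, 0.25]
A[0, 1, 0] = 0.2
B = np.zeros((2, 2, 1))
B[:, 0, 0] = [1.0, 0.4]           # fast exogenous response
B[:, 1, 0] = [0.6, 0.2]
truth = vg.VARXFilters(A=A, B=B)

x = rng.standard_normal((100_000, 1))
y = vg.simulate_varx(truth, x=x, rng=rng)
data = vg.MultiSeries(Y=y, X=x)

varx_fit, *_ = vg.fit_varx(data, vg.FitConfig(n_a=2, n_b=2))     # 12 params
H_factored = vg.impulse_response(varx_fit, 30)

ma_fit, *_ = vg.fit_varx(data, vg.FitConfig(n_a=0, n_b=30))      # 60 params
H_direct = ma_fit.B                                              # mTRF view
```

The two estimates of the 30-lag total response agree to within 10% of
the peak (this is asserted, at exactly these settings, by
`tests/test_acceptance.py::test_factored_response_matches_direct_ma_estimate`),
while the VARX factorization uses a fifth of the parameters and
separates the short drive from the reverberation. For genuinely long
responses, combine a long `n_b` with `n_basis` Gaussian lag bases to
keep the parameter count down.
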