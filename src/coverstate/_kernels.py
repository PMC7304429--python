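"""Compiled inner loop for the ordinal-beta cell log-probabilities.

The sampler spends essentially all of its time evaluating, per panel cell,
``log [ I_xhi(a, b) - I_xlo(a, b) ]`` with the beta shapes derived from the
logit-scale linear predictor and the dispersion.  Going through the numpy
ufunc machinery costs an order of magnitude more than the underlying C
routine, so when numba is available the whole per-cell computation is JIT
compiled around scipy's own C ``betainc`` (resolved through
``scipy.special.cython_special``, hence numerically identical to the ufunc).
Without numba the vectorised numpy path in :mod:`coverstate._posterior` is
used instead; both routes produce the same log-probabilities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cell_logprobs_kernel", "HAVE_KERNEL"]

_UNIT_EPS = 1e-6      # mirrors beta_ordinal._clip_unit
_PROB_FLOOR = 1e-300

cell_logprobs_kernel = None
HAVE_KERNEL = False

try:  # pragma: no cover - exercised indirectly; fallback tested explicitly
    import ctypes

    from numba import njit
    from numba.extending import get_cython_function_address

    # __pyx_fuse_0 is the double specialisation of the fused signature
    _addr = get_cython_function_address(
        "scipy.special.cython_special", "__pyx_fuse_0betainc")
    _betainc_c = ctypes.CFUNCTYPE(
        ctypes.c_double, ctypes.c_double, ctypes.c_double, ctypes.c_double)(_addr)

    @njit(cache=False)
    def _kernel(psi, delta, x_hi, x_lo, out):  # (V,n), (V,), (n,), (n,), (V,n)
        V, n = psi.shape
        for v in range(V):
            d = delta[v]
            if d < _UNIT_EPS:
                d = _UNIT_EPS
            elif d > 1.0 - _UNIT_EPS:
                d = 1.0 - _UNIT_EPS
            phi = (1.0 - d) / d
            for i in range(n):
                mu = 1.0 / (1.0 + np.exp(-psi[v, i]))
                if mu < _UNIT_EPS:
                    mu = _UNIT_EPS
                elif mu > 1.0 - _UNIT_EPS:
                    mu = 1.0 - _UNIT_EPS
                a = mu * phi
                b = (1.0 - mu) * phi
                hi = 1.0 if x_hi[i] >= 1.0 else _betainc_c(a, b, x_hi[i])
                lo = 0.0 if x_lo[i] <= 0.0 else _betainc_c(a, b, x_lo[i])
                pr = hi - lo
                if pr < _PROB_FLOOR:
                    pr = _PROB_FLOOR
                elif pr > 1.0:
                    pr = 1.0
                out[v, i] = np.log(pr)

    # compile and sanity-check once at import
    _probe = np.empty((1, 1))
    _kernel(np.zeros((1, 1)), np.array([0.5]), np.array([0.75]), np.array([0.5]), _probe)
    from scipy.special import betainc as _betainc_ufunc

    _expected = np.log(_betainc_ufunc(0.5, 0.5, 0.75) - _betainc_ufunc(0.5, 0.5, 0.5))
    if abs(float(_probe[0, 0]) - float(_expected)) > 1e-12:
        raise RuntimeError("compiled betainc kernel disagrees with scipy")

    cell_logprobs_kernel = _kernel
    HAVE_KERNEL = True
except Exception:  # numba missing or ABI lookup failed: fall back to numpy
    cell_logprobs_kernel = None
    HAVE_KERNEL = False
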