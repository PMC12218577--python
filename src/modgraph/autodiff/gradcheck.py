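"""Central finite-difference gradient checking — the independent oracle
against which every autodiff backward pass is validated."""

from __future__ import annotations

from typing import Callable

import numpy as np

from .tensor import Tensor


def numerical_gradient(fn: Callable[[np.ndarray], float], x: np.ndarray,
                       step: float = 1e-3) -> np.ndarray:
    """Central finite differences of a scalar function at x."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    flat = x.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + step
        f_plus = fn(x)
        flat[i] = orig - step
        f_minus = fn(x)
        flat[i] = orig
        gflat[i] = (f_plus - f_minus) / (2 * step)
    return grad


def check_gradient(fn: Callable[[Tensor], Tensor], x: np.ndarray,
                   step: float = 1e-3, rtol: float = 1e-3,
                   atol: float = 1e-6) -> float:
    """Compare autodiff gradient of scalar-valued fn against finite differences.

    Returns the maximum elementwise discrepancy scaled by the gradient
    magnitude; raises AssertionError if outside tolerance.
    """
    xt = Tensor(np.asarray(x, dtype=np.float64).copy(), requires_grad=True)
    out = fn(xt)
    out.backward()
    analytic = xt.grad.copy()
    numeric = numerical_gradient(lambda a: float(fn(Tensor(a)).data), x, step=step)
    denom = np.maximum(np.abs(numeric), 1.0)
    err = float(np.max(np.abs(analytic - numeric) / denom))
    if not np.allclose(analytic, numeric, rtol=rtol, atol=max(atol, rtol)):
        raise AssertionError(f"gradient mismatch: max scaled error {err:.2e}")
    return err
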