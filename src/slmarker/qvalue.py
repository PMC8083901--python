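"""Storey q-values for false-discovery-rate estimation.

The q-value of a hypothesis is the minimum positive FDR at which it would be
called significant: q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted
p-values, where pi0 is the estimated proportion of true nulls. With pi0
forced to 1 this reduces exactly to Benjamini–Hochberg adjusted p-values.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


def storey_pi0(
    pvalues: np.ndarray,
    lambdas: np.ndarray = _LAMBDA_GRID,
    fixed_lambda: float | None = None,
) -> float:
    """Estimate the proportion of true null hypotheses.

    By default uses the Storey–Tibshirani smoother: pi0(λ) = #{p > λ} /
    (m (1 − λ)) over the λ grid, a natural cubic spline through those
    estimates, evaluated at the largest grid point. With ``fixed_lambda``
    the single-λ point estimate is returned instead. Either way the result
    is clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value vector")
    if fixed_lambda is not None:
        pi0 = np.mean(p > fixed_lambda) / (1 - fixed_lambda)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        pi0_l = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
        spline = CubicSpline(lambdas, pi0_l, bc_type="natural")
        pi0 = float(spline(lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0)) if pi0 <= 0 else float(min(pi0, 1.0))


def storey_qvalues(pvalues: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """q-values in the input order.

    ``pi0=None`` estimates pi0 with the smoother when at least 20 p-values
    are available, otherwise falls back to the fixed λ = 0.5 point estimate
    (the smoother is unstable on short vectors). ``pi0=1`` yields
    Benjamini–Hochberg adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p) if p.size >= 20 else storey_pi0(p, fixed_lambda=0.5)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up: running min from the largest p
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
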