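"""q-value estimation (Storey & Tibshirani-style FDR control).

pi0, the proportion of true nulls, is estimated on the lambda grid
{0, 0.05, ..., 0.95} and extrapolated to the grid maximum with a cubic
smoother; q-values are the step-up transform q(p_(i)) = min_{j>=i}
pi0 * m * p_(j) / j.  Forcing pi0 = 1 recovers Benjamini-Hochberg
adjusted p-values exactly.
"""

from __future__ import annotations

import numpy as np

_LAMBDAS = np.arange(0.0, 0.96, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray = _LAMBDAS) -> float:
    """Cubic-smoother extrapolation of pi0(lambda) at the largest lambda."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(pvalues, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """q-values for a vector of p-values.

    Parameters
    ----------
    pvalues : array-like in [0, 1]
    pi0 : float, optional
        Override the estimated null proportion (pi0=1 gives BH).

    Returns
    -------
    (qvalues, pi0) with q-values aligned to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * pi0 / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)
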