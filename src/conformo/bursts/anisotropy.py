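"""Steady-state burst anisotropy and the Perrin relation.

``r = (I_par - G * I_perp) / (I_par + 2 G * I_perp)`` per burst, and the
Perrin equation ``r(tau) = r0 / (1 + tau / theta)`` linking the
steady-state anisotropy of a molecule to its fluorescence lifetime
``tau`` and rotational correlation time ``theta`` (``r0`` is the
fundamental anisotropy, fixed at 0.4).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["burst_anisotropy", "perrin", "perrin_fit"]

R0_FUNDAMENTAL = 0.4


def burst_anisotropy(counts_parallel, counts_perpendicular, g_factor=1.0):
    """Steady-state anisotropy from polarized counts (NaN for empty bursts)."""
    ipar = np.asarray(counts_parallel, dtype=float)
    iperp = np.asarray(counts_perpendicular, dtype=float)
    if np.any(ipar < 0) or np.any(iperp < 0):
        raise ValueError("counts must be non-negative")
    if g_factor <= 0:
        raise ValueError("g_factor must be positive")
    denom = ipar + 2.0 * g_factor * iperp
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ipar - g_factor * iperp) / denom
    r = np.where(denom == 0, np.nan, r)
    return float(r) if np.ndim(counts_parallel) == 0 else r


def perrin(tau, theta, r0=R0_FUNDAMENTAL):
    """Perrin anisotropy ``r0 / (1 + tau/theta)``."""
    return r0 / (1.0 + np.asarray(tau, dtype=float) / theta)


def perrin_fit(r, tau, r0=R0_FUNDAMENTAL):
    """Least-squares rotational correlation time from (r, tau) pairs.

    Pairs with non-finite entries are dropped; at least 3 molecules are
    required.  Returns ``theta`` in the units of ``tau``.
    """
    r = np.asarray(r, dtype=float)
    tau = np.asarray(tau, dtype=float)
    ok = np.isfinite(r) & np.isfinite(tau)
    r, tau = r[ok], tau[ok]
    if r.size < 3:
        raise ValueError("perrin_fit requires at least 3 (r, tau) pairs")
    span = max(tau.max(), 1.0)

    def sse(theta):
        return float(np.sum((r - perrin(tau, theta, r0)) ** 2))

    res = minimize_scalar(sse, bounds=(1e-6, 1e4 * span), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)
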