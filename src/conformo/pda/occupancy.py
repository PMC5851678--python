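"""Occupancy-time distribution of a stationary two-state Markov chain.

For a chain with rates ``k12`` (state 1 -> 2) and ``k21`` (state 2 -> 1),
observed over a window of length ``T``, the cumulative time ``T1`` spent
in state 1 has two point masses and a continuous part.  With
``x = k12*t1``, ``y = k21*(T - t1)``, ``u = sqrt(x*y)`` and stationary
probabilities ``p1 = k21/(k12+k21)``, ``p2 = 1 - p1``:

``P(T1 = T) = p1 * exp(-k12*T)``          (never left state 1)
``P(T1 = 0) = p2 * exp(-k21*T)``          (never left state 2)
``f(t1) = exp(-(x+y)) * [ (p1*k12 + p2*k21) * I0(2u)
          + (p1*k12*k21*t1 + p2*k12*k21*(T-t1)) / u * I1(2u) ]``

derived by summing over the number of completed dwells (the Gamma-density
convolutions collapse onto modified Bessel functions).  The implementation
evaluates the Bessel terms in exponentially scaled form, so the density is
stable for arbitrarily fast exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ive

__all__ = ["OccupancyTimeDistribution", "occupancy_time_distribution"]


@dataclass
class OccupancyTimeDistribution:
    """Distribution of time-in-state-1 over a window of ``T`` ms."""

    k12: float
    k21: float
    T: float
    p_full: float   # P(T1 = T)
    p_zero: float   # P(T1 = 0)

    def density(self, t1):
        """Continuous density at ``t1`` in ms (0 outside ``(0, T)``)."""
        t1 = np.asarray(t1, dtype=float)
        k1, k2, T = self.k12, self.k21, self.T
        out = np.zeros_like(t1)
        if k1 == 0 and k2 == 0:
            return out
        inside = (t1 > 0) & (t1 < T)
        x = k1 * t1[inside]
        y = k2 * (T - t1[inside])
        u = np.sqrt(x * y)
        p1 = k2 / (k1 + k2)
        p2 = 1.0 - p1
        # e^{-(x+y)} I_n(2u) = ive(n, 2u) * e^{-(sqrt(x)-sqrt(y))^2}
        with np.errstate(over="ignore", invalid="ignore"):
            damp = np.exp(-(np.sqrt(x) - np.sqrt(y)) ** 2)
        i0 = ive(0, 2 * u)
        with np.errstate(invalid="ignore", divide="ignore"):
            i1_over_u = np.where(u > 0, ive(1, 2 * u) / np.maximum(u, 1e-300), 1.0)
        val = damp * ((p1 * k1 + p2 * k2) * i0
                      + (p1 * k1 * k2 * t1[inside]
                         + p2 * k1 * k2 * (T - t1[inside])) * i1_over_u)
        out[inside] = np.nan_to_num(val, nan=0.0, posinf=0.0)
        return out

    def nodes(self, n=129):
        """Quadrature nodes/weights for the continuous part.

        Returns ``(t1, w)`` with ``sum(w) = 1 - p_full - p_zero`` — the
        continuous weight is renormalized onto the nodes so the total
        distribution integrates to exactly 1.
        """
        mass_c = 1.0 - self.p_full - self.p_zero
        if mass_c <= 1e-12 or (self.k12 == 0 and self.k21 == 0):
            return np.empty(0), np.empty(0)
        coarse = np.linspace(0.0, self.T, 1025)[1:-1]
        with np.errstate(all="ignore"):
            f = np.nan_to_num(self.density(coarse), nan=0.0, posinf=0.0)
        fmax = f.max()
        if fmax <= 0 or not np.isfinite(fmax):
            # exchange so fast the density is narrower than the coarse
            # grid: all continuous mass sits at the stationary mean
            p1 = self.k21 / (self.k12 + self.k21)
            return np.array([p1 * self.T]), np.array([mass_c])
        support = np.flatnonzero(f > fmax * 1e-12)
        lo = coarse[max(support[0] - 1, 0)]
        hi = coarse[min(support[-1] + 1, coarse.size - 1)]
        t = np.linspace(lo, hi, n)
        w = self.density(t)
        # trapezoid weights
        dt = np.gradient(t)
        w = w * dt
        s = w.sum()
        if s <= 0:
            return np.empty(0), np.empty(0)
        return t, w * (mass_c / s)


def occupancy_time_distribution(k12, k21, T):
    """Distribution of the cumulative time in state 1 over ``[0, T]``.

    Rates in 1/ms, ``T`` in ms.  Both rates zero gives the degenerate
    two-point distribution at {0, T} with stationary weights 1/2 each
    (documented convention for a frozen chain).
    """
    if k12 < 0 or k21 < 0:
        raise ValueError("rates must be non-negative")
    if T <= 0:
        raise ValueError("window length must be positive")
    if k12 == 0 and k21 == 0:
        return OccupancyTimeDistribution(k12, k21, T, 0.5, 0.5)
    p1 = k21 / (k12 + k21)
    p2 = 1.0 - p1
    return OccupancyTimeDistribution(
        k12, k21, T,
        p_full=p1 * np.exp(-k12 * T),
        p_zero=p2 * np.exp(-k21 * T),
    )
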