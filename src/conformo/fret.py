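"""Förster-transfer relations shared across the package.

All distances are in Ångström and all efficiencies are unitless. The
Förster radius ``R0`` is treated as an input constant throughout; it is
never derived from spectra here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance_to_efficiency",
    "efficiency_to_distance",
    "apparent_acceptor_probability",
]


def distance_to_efficiency(R, R0):
    """Transfer efficiency ``E = 1 / (1 + (R/R0)^6)`` for a donor-acceptor pair.

    Parameters
    ----------
    R : float or array_like
        Donor-acceptor distance in Å. Must be >= 0.
    R0 : float
        Förster radius in Å. Must be > 0.

    Returns
    -------
    float or ndarray
        Efficiency in ``(0, 1]`` (``E = 1`` at ``R = 0``).
    """
    R = np.asarray(R, dtype=float)
    if R0 <= 0:
        raise ValueError(f"Förster radius must be positive, got R0={R0}")
    if np.any(R < 0):
        raise ValueError("distances must be non-negative")
    out = 1.0 / (1.0 + (R / R0) ** 6)
    return float(out) if out.ndim == 0 else out


def efficiency_to_distance(E, R0):
    """Inverse Förster relation ``R = R0 * (1/E - 1)^(1/6)``.

    ``E`` must lie in ``(0, 1]``; ``E = 1`` maps to ``R = 0``.
    """
    E = np.asarray(E, dtype=float)
    if R0 <= 0:
        raise ValueError(f"Förster radius must be positive, got R0={R0}")
    if np.any((E <= 0) | (E > 1)):
        raise ValueError("efficiencies must lie in (0, 1]")
    out = R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def apparent_acceptor_probability(E, gamma=1.0, beta=0.0):
    """Probability that a detected donor-excited fluorescence photon is red.

    This maps a true transfer efficiency to the *apparent* acceptor fraction
    seen by a photon-counting experiment with relative detection efficiency
    ``gamma`` (red vs. blue channel) and donor cross-talk ``beta`` (fraction
    of donor photons registered in the red channel).  It is the forward
    mapping used by photon distribution analysis, which models uncorrected
    proximity ratios:

    ``eps = (gamma*E + beta*(1-E)) / (gamma*E + beta*(1-E) + (1-E))``

    Background is handled separately (it is additive in counts, not a
    per-photon probability).
    """
    E = np.asarray(E, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    red = gamma * E + beta * (1.0 - E)
    out = red / (red + (1.0 - E))
    return float(out) if out.ndim == 0 else out
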