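"""Theoretical E versus donor-lifetime relations (FRET lines).

Molecules that are conformationally static on the millisecond time scale
fall on the *static* FRET line; systematic deviation toward longer
lifetimes at a given E indicates sub-millisecond exchange between states
and is diagnosed with a *dynamic* FRET line connecting the two exchanging
states.

With a distribution p(R) of donor-acceptor distances inside a burst
(here: a Gaussian of width ``linker_width`` around the state distance,
modelling fast dye-linker motion), the burst-averaged observables are

``E = 1 - <tau>_x / tau_D``            (intensity-based efficiency)
``tau_obs = <tau^2>_x / <tau>_x``      (fluorescence-weighted lifetime)

with ``tau(R) = tau_D (1 - E(R))`` and ``<.>_x`` the species average over
p(R).  For ``linker_width = 0`` the static line reduces to the ideal
``E = 1 - tau/tau_D``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..fret import distance_to_efficiency

__all__ = ["FretLine", "static_fret_line", "dynamic_fret_line"]


@dataclass
class FretLine:
    """Sampled E(tau) curve with its generating parameters."""

    kind: str
    tau: np.ndarray     # ns, observed (fluorescence-weighted) lifetime
    efficiency: np.ndarray
    donor_lifetime: float
    forster_radius: float | None = None
    linker_width: float | None = None
    endpoints: tuple | None = None

    def __call__(self, tau):
        """Interpolated E at observed lifetime ``tau`` (ns)."""
        order = np.argsort(self.tau)
        return np.interp(tau, self.tau[order], self.efficiency[order])


def static_fret_line(calib, linker_width=6.0, n_points=400, n_sigma=4.0):
    """Static FRET line for Gaussian dye-linker broadening.

    Parameters
    ----------
    calib : FretCalibration
        Supplies the donor-only lifetime and Förster radius.
    linker_width : float
        Width (sigma, Å) of the fast Gaussian distance jitter.
    """
    if linker_width < 0:
        raise ValueError("linker_width must be non-negative")
    tau_d = calib.donor_lifetime
    r0 = calib.forster_radius
    centers = np.linspace(0.05 * r0, 3.0 * r0, n_points)
    if linker_width == 0:
        eff = distance_to_efficiency(centers, r0)
        tau = tau_d * (1.0 - eff)
        return FretLine("static", tau, eff, tau_d, r0, linker_width)
    grid = np.linspace(-n_sigma, n_sigma, 81)
    w = np.exp(-0.5 * grid**2)
    w /= w.sum()
    eff_out = np.empty(n_points)
    tau_out = np.empty(n_points)
    for i, rc in enumerate(centers):
        r = np.maximum(rc + linker_width * grid, 1e-3)
        tau_r = tau_d * (1.0 - distance_to_efficiency(r, r0))
        m1 = np.sum(w * tau_r)
        m2 = np.sum(w * tau_r**2)
        eff_out[i] = 1.0 - m1 / tau_d
        tau_out[i] = m2 / m1
    return FretLine("static", tau_out, eff_out, tau_d, r0, linker_width)


def dynamic_fret_line(calib, tau1, tau2, n_points=200):
    """Dynamic FRET line between two exchanging states.

    ``tau1``/``tau2`` are the endpoint donor lifetimes (ns), usually
    hand-picked from the extreme static states.  The curve traces the
    burst-averaged (E, tau_obs) coordinates as the fractional occupancy
    moves from one state to the other:

    ``tau_obs = (x tau1^2 + (1-x) tau2^2) / (x tau1 + (1-x) tau2)``
    ``E = 1 - (x tau1 + (1-x) tau2) / tau_D``
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("endpoint lifetimes must be positive")
    tau_d = calib.donor_lifetime
    x = np.linspace(0.0, 1.0, n_points)
    m1 = x * tau1 + (1.0 - x) * tau2
    m2 = x * tau1**2 + (1.0 - x) * tau2**2
    return FretLine("dynamic", m2 / m1, 1.0 - m1 / tau_d, tau_d,
                    calib.forster_radius, None, (tau1, tau2))
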