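"""Temperature dependence of binding enthalpy and its surface-area origin.

Kirchhoff's relation ``d(dH)/dT = dCp`` makes the heat-capacity change on
binding the slope of ``dH(T_i)`` versus ``T_i``; ``dH`` is extrapolated
to the reference temperature ``Tr = 60 C`` where the empirical
Murphy-Freire parameterization links both quantities to the polar and
nonpolar solvent-accessible surface area buried on binding:

``dH_r(Tr) = a * dASA_p + b * dASA_n``
``dCp      = c * dASA_p + d * dASA_n``

with a = 31.4, b = -8.44 cal mol^-1 A^-2 and c = -0.26,
d = 0.45 cal mol^-1 K^-1 A^-2.  Buried area is negative in this sign
convention; residue-count equivalents divide by the average ASA of a
polar (56 A^2) or apolar (34 A^2) residue and are reported as
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KirchhoffFit", "AsaEstimate", "kirchhoff_fit",
           "asa_decomposition", "asa_forward", "residue_counts",
           "MURPHY_FREIRE"]

#: Empirical coefficients (a, b, c, d) at Tr = 60 C.
MURPHY_FREIRE = {"a": 31.4, "b": -8.44, "c": -0.26, "d": 0.45}

#: Reference temperature for the parameterization, K.
T_REFERENCE = 333.15

#: Average ASA of polar / apolar residues, A^2.
ASA_POLAR = 56.0
ASA_APOLAR = 34.0


@dataclass
class KirchhoffFit:
    """Linear ``dH(T)`` fit: slope ``dCp`` and intercept at ``Tr``."""

    temperatures: np.ndarray      # K
    delta_h: np.ndarray           # cal/mol
    delta_cp: float               # cal/mol/K
    delta_h_ref: float            # cal/mol at T_REFERENCE
    residual_sd: float

    def predict(self, T):
        return self.delta_h_ref + self.delta_cp * (np.asarray(T) - T_REFERENCE)


@dataclass
class AsaEstimate:
    """Polar/nonpolar buried-surface decomposition of (dHr, dCp)."""

    delta_asa_polar: float      # A^2, negative = buried
    delta_asa_nonpolar: float   # A^2
    delta_h_ref: float          # cal/mol
    delta_cp: float             # cal/mol/K


def kirchhoff_fit(temperatures, delta_h, celsius=False) -> KirchhoffFit:
    """Fit ``dH(T) = dH_r(Tr) + dCp (T - Tr)`` by linear regression.

    ``temperatures`` in K (or C with ``celsius=True``); ``delta_h`` in
    cal/mol.  At least 3 temperatures are required.
    """
    T = np.asarray(temperatures, dtype=float)
    if celsius:
        T = T + 273.15
    dh = np.asarray(delta_h, dtype=float)
    if T.size < 3:
        raise ValueError("Kirchhoff fit needs at least 3 temperatures")
    if T.size != dh.size:
        raise ValueError("temperature/enthalpy length mismatch")
    slope, intercept = np.polyfit(T - T_REFERENCE, dh, 1)
    resid = dh - (intercept + slope * (T - T_REFERENCE))
    return KirchhoffFit(T, dh, float(slope), float(intercept),
                        float(np.std(resid)))


def asa_forward(delta_asa_polar, delta_asa_nonpolar):
    """``(dH_r, dCp)`` from surface areas (the forward relations)."""
    c = MURPHY_FREIRE
    dhr = c["a"] * delta_asa_polar + c["b"] * delta_asa_nonpolar
    dcp = c["c"] * delta_asa_polar + c["d"] * delta_asa_nonpolar
    return dhr, dcp


def asa_decomposition(delta_h_ref, delta_cp) -> AsaEstimate:
    """Invert the 2x2 Murphy-Freire system for (dASA_p, dASA_n).

    ``delta_h_ref`` in cal/mol at 60 C, ``delta_cp`` in cal/mol/K.  The
    system is regular (a*d - b*c != 0 with the fixed coefficients), so
    the solution is unique.
    """
    co = MURPHY_FREIRE
    A = np.array([[co["a"], co["b"]], [co["c"], co["d"]]])
    sol = np.linalg.solve(A, [delta_h_ref, delta_cp])
    return AsaEstimate(float(sol[0]), float(sol[1]),
                       float(delta_h_ref), float(delta_cp))


def residue_counts(estimate: AsaEstimate):
    """``(n_polar, n_apolar)`` residue equivalents of the buried area.

    Magnitudes of ``dASA_p / 56`` and ``dASA_n / 34``.
    """
    return (abs(estimate.delta_asa_polar) / ASA_POLAR,
            abs(estimate.delta_asa_nonpolar) / ASA_APOLAR)
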