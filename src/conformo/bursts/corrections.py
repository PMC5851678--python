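"""Burst-count corrections: background, direct excitation, cross-talk, gamma.

The corrected FRET efficiency and stoichiometry of a burst follow the
standard two-color MFD formulas

``E = (F_BR - a*F_RR - b*F_BB) / (F_BR - a*F_RR - b*F_BB + g*F_BB)``

``S = (F_BR - a*F_RR - b*F_BB + g*F_BB)
     / (F_BR - a*F_RR - b*F_BB + g*F_BB + F_RR)``

with ``F_XY = S_XY - B_XY * duration`` the background-corrected counts,
``a`` (alpha) the direct-acceptor-excitation correction, ``b`` (beta) the
donor cross-talk and ``g`` (gamma) the relative detection efficiency of
the two spectral channels.  Out-of-range values are *not* clamped — shot
noise legitimately pushes E outside [0, 1]; undefined values (zero
denominator) are flagged instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CorrectionSet", "correct_and_score"]


@dataclass
class CorrectionSet:
    """Correction factors of one measurement.

    ``background_rates`` maps the signal classes ``BB``, ``BR``, ``RR`` to
    counts/s; ``g_factor`` is the polarization detection ratio used by the
    anisotropy computation.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0
    background_rates: dict = field(default_factory=dict)
    g_factor: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if any(v < 0 for v in self.background_rates.values()):
            raise ValueError("background rates must be non-negative")
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")

    def rate(self, key):
        return float(self.background_rates.get(key, 0.0))


def correct_and_score(s_bb, s_br, s_rr, duration, corrections: CorrectionSet):
    """Corrected counts, FRET efficiency and stoichiometry per burst.

    Parameters are arrays of raw per-class counts and burst durations in
    seconds.  Returns a dict with ``F_BB``, ``F_BR``, ``F_RR``, ``E``,
    ``S`` and a boolean ``undefined`` flag marking bursts whose E or S
    denominator vanished (their E/S are NaN and they should be excluded
    downstream).
    """
    s_bb = np.asarray(s_bb, dtype=float)
    s_br = np.asarray(s_br, dtype=float)
    s_rr = np.asarray(s_rr, dtype=float)
    duration = np.asarray(duration, dtype=float)

    f_bb = s_bb - corrections.rate("BB") * duration
    f_br = s_br - corrections.rate("BR") * duration
    f_rr = s_rr - corrections.rate("RR") * duration

    signal = f_br - corrections.alpha * f_rr - corrections.beta * f_bb
    denom_e = signal + corrections.gamma * f_bb
    denom_s = denom_e + f_rr
    undefined = (denom_e == 0) | (denom_s == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(undefined, np.nan, signal / denom_e)
        s = np.where(undefined, np.nan, denom_e / denom_s)
    return {"F_BB": f_bb, "F_BR": f_br, "F_RR": f_rr,
            "E": e, "S": s, "undefined": undefined}
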