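"""Stopped-flow association/dissociation kinetics.

Under pseudo-first-order conditions each mixing trace relaxes as a single
exponential with observed rate ``kobs = kon * [L] + koff``; the
association rate constant is the slope of ``kobs`` versus ligand
concentration.  The dissociation rate constant comes from a displacement
trace (excess unlabelled ligand), and the kinetic dissociation constant
is ``Kd = koff / kon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = ["KineticTrace", "RateConstants", "fit_single_exponential",
           "stopped_flow_analysis", "simulate_trace"]


@dataclass
class KineticTrace:
    """A fluorescence relaxation trace at one ligand concentration."""

    time: np.ndarray            # s
    signal: np.ndarray
    concentration: float = 0.0  # M

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size != self.signal.size:
            raise ValueError("time/signal length mismatch")
        if self.time.size < 10:
            raise ValueError("trace too short")


@dataclass
class RateConstants:
    """Result of a stopped-flow analysis."""

    kobs: np.ndarray            # s^-1 per concentration
    concentrations: np.ndarray  # M
    kon: float                  # M^-1 s^-1
    kon_intercept: float        # s^-1
    koff: float | None = None   # s^-1
    flags: list = field(default_factory=list)

    @property
    def kd_kinetic(self):
        """``koff / kon`` in M (None without a displacement trace)."""
        if self.koff is None or self.kon <= 0:
            return None
        return self.koff / self.kon


def simulate_trace(kobs, amplitude=1.0, offset=0.0, duration=None, n=500,
                   noise_sd=0.0, concentration=0.0, seed=0,
                   rising=False):
    """Synthetic single-exponential trace ``offset + A exp(-kobs t)``.

    ``rising=True`` gives the association-direction signal
    ``offset + A (1 - exp(-kobs t))``.
    """
    if kobs <= 0:
        raise ValueError("kobs must be positive")
    rng = np.random.default_rng(seed)
    duration = duration if duration is not None else 5.0 / kobs
    t = np.linspace(0.0, duration, n)
    decay = np.exp(-kobs * t)
    y = offset + amplitude * ((1.0 - decay) if rising else decay)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    return KineticTrace(t, y, concentration)


def fit_single_exponential(trace: KineticTrace):
    """Least-squares ``y = c + A exp(-k t)`` fit; returns ``(kobs, result)``.

    A poor-fit flag is attached when the residual sd exceeds 20% of the
    fitted amplitude.
    """
    t, y = trace.time, trace.signal
    span = y.max() - y.min()
    k0 = 1.0 / max(t[-1] / 3.0, 1e-9)
    p = lmfit.Parameters()
    p.add("k", value=k0, min=1e-6)
    p.add("amp", value=(y[0] - y[-1]) if abs(y[0] - y[-1]) > 0 else span)
    p.add("offset", value=y[-1])

    def resid(pars):
        return (pars["offset"] + pars["amp"] * np.exp(-pars["k"] * t)) - y

    res = lmfit.minimize(resid, p, method="leastsq")
    k = float(res.params["k"].value)
    flags = []
    amp = abs(float(res.params["amp"].value))
    if amp == 0 or np.std(res.residual) > 0.2 * amp:
        flags.append("poor single-exponential fit")
    return k, flags


def stopped_flow_analysis(traces, displacement_trace=None) -> RateConstants:
    """Full kon/koff analysis from pseudo-first-order traces.

    ``traces`` is a list of :class:`KineticTrace` at >= 3 ligand
    concentrations; ``displacement_trace`` (optional) yields ``koff``.
    """
    if len(traces) < 3:
        raise ValueError("kon fit needs traces at >= 3 concentrations")
    conc = np.array([tr.concentration for tr in traces], dtype=float)
    kobs = np.empty(conc.size)
    flags = []
    for i, tr in enumerate(traces):
        kobs[i], fl = fit_single_exponential(tr)
        flags += [f"trace {i} ({tr.concentration:.3g} M): {f}" for f in fl]
    order = np.argsort(conc)
    slope, intercept = np.polyfit(conc[order], kobs[order], 1)
    koff = None
    if displacement_trace is not None:
        koff, fl = fit_single_exponential(displacement_trace)
        flags += [f"displacement: {f}" for f in fl]
    return RateConstants(kobs=kobs, concentrations=conc, kon=float(slope),
                         kon_intercept=float(intercept), koff=koff,
                         flags=flags)
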