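"""One-site isothermal titration calorimetry: simulation and fitting.

The instrument injects titrant (syringe concentration ``X_s``) into a
perfusion cell of volume ``V0`` holding the macromolecule.  Injected
volume displaces cell content, so after injection ``i`` the total
concentrations follow the standard dilution bookkeeping

``M_i = M_0 * prod_j (1 - v_j / V0)``
``X_i = X_s * (1 - prod_j (1 - v_j / V0))``

The bound concentration comes from the single-site mass balance (the
positive root of the binding quadratic), the cumulative heat is
``Q_i = n * dH * V0 * [MX]_i`` and the measured differential heat per
injection corrects for the displaced volume:

``q_i = Q_i - Q_{i-1} + (v_i / V0) * (Q_i + Q_{i-1}) / 2``

Fitting estimates ``n``, ``Kd`` and ``dH`` by least squares; ``dG`` and
``-T dS`` follow from the Gibbs relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = ["Titration", "ThermoParams", "simulate_isotherm", "fit_isotherm",
           "gibbs_dissection", "GAS_CONSTANT"]

#: cal / (mol K)
GAS_CONSTANT = 1.9872


@dataclass
class ThermoParams:
    """Binding thermodynamics of a 1:1 interaction.

    ``delta_g``, ``delta_h`` and ``minus_t_delta_s`` are in kcal/mol;
    ``delta_s`` in cal/mol/K; ``delta_cp`` (optional) in cal/mol/K.
    The Gibbs identity ``dG = dH - T dS`` is enforced on construction.
    """

    kd: float
    temperature: float
    delta_h: float
    n_sites: float = 1.0
    delta_cp: float | None = None
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def delta_g(self):
        """kcal/mol, from ``dG = -RT ln(1/Kd)``."""
        return -GAS_CONSTANT * self.temperature * np.log(1.0 / self.kd) / 1000.0

    @property
    def minus_t_delta_s(self):
        """-T dS in kcal/mol, from ``dG = dH - T dS``."""
        return self.delta_g - self.delta_h

    @property
    def delta_s(self):
        """cal/mol/K."""
        return -(self.minus_t_delta_s * 1000.0) / self.temperature

    def check_identity(self, tol=1e-6):
        lhs = self.delta_g
        rhs = self.delta_h + self.minus_t_delta_s
        return abs(lhs - rhs) < tol


@dataclass
class Titration:
    """An ITC titration schedule, optionally carrying measured heats.

    Volumes in liters, concentrations in mol/L, temperature in K, heats
    in cal per injection (exothermic negative).
    """

    cell_volume: float = 200e-6
    injection_volumes: np.ndarray = None
    cell_concentration: float = 10e-6
    syringe_concentration: float = 200e-6
    temperature: float = 293.15
    heats: np.ndarray | None = None
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.injection_volumes is None:
            self.injection_volumes = np.full(20, 2e-6)
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.size != self.injection_volumes.size:
                raise ValueError("heats length must equal injections")

    @property
    def n_injections(self):
        return self.injection_volumes.size

    def concentrations(self):
        """Total (macromolecule, titrant) concentration after each injection."""
        dil = np.cumprod(1.0 - self.injection_volumes / self.cell_volume)
        m = self.cell_concentration * dil
        x = self.syringe_concentration * (1.0 - dil)
        return m, x

    @property
    def c_value(self):
        """Wiseman c of the *intended* fit; meaningful once Kd is known."""
        return None


def _bound_fraction_conc(m_tot, x_tot, kd, n):
    """Complex concentration [MX] from the quadratic mass balance."""
    sites = n * m_tot
    b = sites + x_tot + kd
    return 0.5 * (b - np.sqrt(np.maximum(b * b - 4.0 * sites * x_tot, 0.0)))


def _cumulative_heats(titration, kd, dh, n):
    m, x = titration.concentrations()
    mx = _bound_fraction_conc(m, x, kd, n)
    return dh * titration.cell_volume * mx  # cal


def _differential_heats(titration, kd, dh, n):
    q = _cumulative_heats(titration, kd, dh, n)
    qprev = np.concatenate([[0.0], q[:-1]])
    v = titration.injection_volumes
    return q - qprev + (v / titration.cell_volume) * 0.5 * (q + qprev)


def simulate_isotherm(params: ThermoParams, schedule: Titration, seed=0):
    """Synthesize per-injection heats for a one-site binding experiment.

    Gaussian noise of ``schedule.noise_sd`` (cal) is added per injection.
    A warning flag is attached when the syringe cannot reach ~2x molar
    equivalence (the isotherm would not approach saturation).
    """
    rng = np.random.default_rng(seed)
    q = _differential_heats(schedule, params.kd, params.delta_h * 1000.0,
                            params.n_sites)
    if schedule.noise_sd > 0:
        q = q + rng.normal(0.0, schedule.noise_sd, q.size)
    flags = []
    m, x = schedule.concentrations()
    if x[-1] < 1.5 * params.n_sites * m[-1]:
        flags.append("undersaturated: final molar ratio "
                     f"{x[-1] / (params.n_sites * m[-1]):.2f} < 1.5")
    out = Titration(
        cell_volume=schedule.cell_volume,
        injection_volumes=schedule.injection_volumes.copy(),
        cell_concentration=schedule.cell_concentration,
        syringe_concentration=schedule.syringe_concentration,
        temperature=schedule.temperature,
        heats=q,
        noise_sd=schedule.noise_sd,
    )
    return out, flags


def fit_isotherm(titration: Titration, fix_n=None) -> ThermoParams:
    """Least-squares one-site fit of an isotherm: ``n``, ``Kd``, ``dH``.

    ``dG`` and ``-T dS`` are derived through the Gibbs relations at the
    titration temperature.  Fits with a Wiseman c outside [1, 1000] are
    flagged low-confidence rather than rejected.
    """
    if titration.heats is None:
        raise ValueError("titration carries no measured heats")
    if titration.n_injections < 8:
        raise ValueError("need at least 8 injections to fit an isotherm")
    heats = titration.heats
    dh0 = heats[0] / (titration.cell_volume * titration.cell_concentration)

    p = lmfit.Parameters()
    p.add("log10_kd", value=np.log10(titration.cell_concentration / 10),
          min=-15, max=0)
    p.add("dh", value=dh0)
    if fix_n is None:
        p.add("n", value=1.0, min=0.1, max=10.0)
    else:
        p.add("n", value=fix_n, vary=False)

    def resid(pars):
        kd = 10.0 ** pars["log10_kd"].value
        return _differential_heats(titration, kd, pars["dh"].value,
                                   pars["n"].value) - heats

    res = lmfit.minimize(resid, p, method="leastsq")
    kd = float(10.0 ** res.params["log10_kd"].value)
    dh = float(res.params["dh"].value) / 1000.0  # kcal/mol
    n = float(res.params["n"].value)
    flags = []
    c = n * titration.cell_concentration / kd
    if not 1.0 <= c <= 5000.0:
        flags.append(f"low-confidence fit: Wiseman c = {c:.3g} outside [1, 5000]")
    stderr = {}
    if res.errorbars:
        stderr["kd"] = float(np.log(10) * kd
                             * res.params["log10_kd"].stderr)
        stderr["dh"] = float(res.params["dh"].stderr) / 1000.0
        if fix_n is None:
            stderr["n"] = float(res.params["n"].stderr)
    return ThermoParams(kd=kd, temperature=titration.temperature,
                        delta_h=dh, n_sites=n, stderr=stderr, flags=flags)


def gibbs_dissection(kd, delta_h, temperature):
    """``(dG, -T dS)`` in kcal/mol from ``Kd`` (M), ``dH`` (kcal/mol), T (K)."""
    if kd <= 0 or temperature <= 0:
        raise ValueError("Kd and temperature must be positive")
    dg = -GAS_CONSTANT * temperature * np.log(1.0 / kd) / 1000.0
    return dg, dg - delta_h
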