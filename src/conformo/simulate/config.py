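"""Configuration types for the photon-level diffusion simulator.

The defaults encode the in-silico validation conditions used throughout
this package: 2000 s of acquisition in a 5 um^3 box containing 10 freely
diffusing molecules (D = 1 um^2/s) observed through a 3D-Gaussian point
spread function with lateral waist 200 nm and axial waist 1000 nm, dye
linkers fluctuating over 5 Å, Gaussian distance distributions of width
5 Å, a 10 ms redraw period for the quasi-static distance of each
molecule, and alternating donor/acceptor excitation at 26.67 MHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["SimulationConfig", "StateModel", "FretCalibration"]


@dataclass
class SimulationConfig:
    """Physical and numerical parameters of a simulated acquisition.

    Parameters
    ----------
    duration : float
        Acquisition time in seconds (trajectory mode).
    box_volume : float
        Volume of the cubic periodic box in um^3.
    n_molecules : int
        Number of labelled molecules diffusing in the box.
    diffusion_coeff : float
        Diffusion coefficient D in um^2/s.
    psf_waist_lateral, psf_waist_axial : float
        1/e^2 waists of the Gaussian detection profile, in nm.
    peak_brightness : float
        Detected counts/s from a molecule at the focus, per excitation
        color (the donor-excitation and acceptor-excitation photon rates
        at focus are ``peak_brightness`` and
        ``peak_brightness * acceptor_brightness_ratio``).
    acceptor_brightness_ratio : float
        Acceptor-excitation brightness relative to donor excitation.
    background_rates : dict
        Counts/s per detection channel name (see ``conformo.photons.CHANNELS``).
    excitation_alternation_rate : float
        Laser alternation rate in MHz (metadata; gates are deterministic).
    interleave_delay : float
        Delay between the two laser pulses in ns (metadata).
    linker_fluctuation : float
        Standard deviation in Å of the fast per-photon Gaussian dye-position
        jitter.
    static_redraw_time : float
        Period in ms at which a molecule's quasi-static distance is redrawn
        from its state's Gaussian.
    mode : {"trajectory", "event"}
        ``trajectory`` integrates Brownian motion of all molecules in the
        periodic box; ``event`` simulates independent passages through the
        observation region only (identical per-photon physics, no dead time
        between bursts).
    n_bursts : int
        Number of molecule transits to generate in event mode.
    time_step : float
        Integration step in us (default 1 us, far below the diffusion time
        through the lateral waist, wr^2/4D = 10 us at the defaults).
    crosstalk, direct_excitation : float
        Per-photon misassignment probabilities: a donor photon is recorded
        in the red channel with probability ``crosstalk`` (beta pathway);
        each donor-excitation period additionally excites the acceptor
        directly at a rate ``direct_excitation * peak_brightness`` (alpha
        pathway).
    gamma : float
        Simulated relative detection efficiency of acceptor vs donor
        photons (acceptor photons after donor excitation are thinned by
        ``gamma`` when < 1).
    irf_width : float
        Optional Gaussian IRF width (sigma, ns) convolved onto microtimes.
    seed : int
        Seed for all randomness; identical config + seed gives identical
        output.
    """

    duration: float = 2000.0
    box_volume: float = 5.0
    n_molecules: int = 10
    diffusion_coeff: float = 1.0
    psf_waist_lateral: float = 200.0
    psf_waist_axial: float = 1000.0
    peak_brightness: float = 150e3
    acceptor_brightness_ratio: float = 0.6
    background_rates: dict = field(default_factory=dict)
    excitation_alternation_rate: float = 26.67
    interleave_delay: float = 18.0
    linker_fluctuation: float = 5.0
    static_redraw_time: float = 10.0
    mode: str = "trajectory"
    n_bursts: int = 1000
    time_step: float = 1.0
    crosstalk: float = 0.0
    direct_excitation: float = 0.0
    gamma: float = 1.0
    irf_width: float = 0.0
    seed: int = 0

    def __post_init__(self):
        positive = [
            ("duration", self.duration),
            ("box_volume", self.box_volume),
            ("diffusion_coeff", self.diffusion_coeff),
            ("psf_waist_lateral", self.psf_waist_lateral),
            ("psf_waist_axial", self.psf_waist_axial),
            ("static_redraw_time", self.static_redraw_time),
            ("time_step", self.time_step),
            ("excitation_alternation_rate", self.excitation_alternation_rate),
        ]
        for name, value in positive:
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.mode not in ("trajectory", "event"):
            raise ValueError(f"mode must be 'trajectory' or 'event', got {self.mode!r}")
        if self.mode == "event" and self.n_bursts <= 0:
            raise ValueError("event mode requires n_bursts >= 1")
        if self.peak_brightness < 0 or self.acceptor_brightness_ratio < 0:
            raise ValueError("brightness parameters must be non-negative")
        if any(v < 0 for v in self.background_rates.values()):
            raise ValueError("background rates must be non-negative")
        if self.linker_fluctuation < 0 or self.irf_width < 0:
            raise ValueError("widths must be non-negative")
        if not 0 <= self.crosstalk < 1 or self.direct_excitation < 0:
            raise ValueError("invalid photon misassignment probabilities")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def box_side(self):
        """Side of the cubic box in um."""
        return self.box_volume ** (1.0 / 3.0)

    def to_dict(self):
        return asdict(self)


@dataclass
class StateModel:
    """Conformational states of the labelled molecule.

    ``states`` lists the dynamic, interconverting states as
    ``(mean_distance_A, width_A)`` Gaussians; ``rate_matrix`` gives the
    interconversion rates in 1/ms (``rate_matrix[i, j]`` is the i -> j
    rate, diagonal ignored).  An optional third, non-interconverting state
    is occupied by a fraction ``static_state_fraction`` of molecules.
    """

    states: list
    rate_matrix: np.ndarray | None = None
    static_state: tuple | None = None
    static_state_fraction: float = 0.0

    def __post_init__(self):
        self.states = [(float(r), float(s)) for r, s in self.states]
        for r, s in self.states:
            if r <= 0:
                raise ValueError("state mean distances must be positive")
            if s < 0:
                raise ValueError("state widths must be non-negative")
        n = len(self.states)
        if self.rate_matrix is None:
            self.rate_matrix = np.zeros((n, n))
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        if self.rate_matrix.shape != (n, n):
            raise ValueError(
                f"rate_matrix shape {self.rate_matrix.shape} does not match "
                f"{n} states"
            )
        off = self.rate_matrix[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if self.static_state is not None:
            r, s = self.static_state
            if r <= 0 or s < 0:
                raise ValueError("invalid static state parameters")
        if not 0.0 <= self.static_state_fraction <= 1.0:
            raise ValueError("static_state_fraction must be in [0, 1]")
        if self.static_state_fraction > 0 and self.static_state is None:
            raise ValueError("static_state_fraction > 0 requires a static_state")

    @property
    def n_states(self):
        return len(self.states)


@dataclass
class FretCalibration:
    """Photophysical constants of the dye pair.

    ``kappa_squared``, ``donor_quantum_yield`` and ``acceptor_extinction``
    are carried as metadata only; the Förster radius is an input, not
    derived from them.
    """

    forster_radius: float = 53.0
    donor_lifetime: float = 3.8
    acceptor_lifetime: float = 1.0
    fundamental_anisotropy: float = 0.4
    rotational_correlation_time: float = 1.0
    kappa_squared: float = 2.0 / 3.0
    donor_quantum_yield: float = 0.62
    acceptor_extinction: float = 265e3

    def __post_init__(self):
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be positive")
        if self.donor_lifetime <= 0 or self.acceptor_lifetime <= 0:
            raise ValueError("lifetimes must be positive")
        if not 0.0 <= self.fundamental_anisotropy <= 0.4:
            raise ValueError("fundamental anisotropy must be in [0, 0.4]")
        if self.rotational_correlation_time <= 0:
            raise ValueError("rotational correlation time must be positive")

    def to_dict(self):
        return asdict(self)
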