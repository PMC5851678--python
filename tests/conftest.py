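"""Shared fixtures.

The expensive acceptance pipeline (event-mode simulation at full scale,
burst analysis, PDA global fit with confidence intervals) runs once per
session and is shared by several acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from conformo.simulate import (SimulationConfig, StateModel, FretCalibration,
                               simulate_photon_stream)
from conformo.bursts import analyze_bursts, CorrectionSet
from conformo.pda import (rebin_bursts, PdaModel, global_fit,
                          confidence_intervals)

# The two-state system used throughout: open/closed distances 62/41 Å,
# R0 = 53 Å, symmetric exchange at 1/ms, widths 8% of the distance.
R_CLOSED, R_OPEN = 41.0, 62.0
WIDTH_FRACTION = 0.08
GAMMA, BETA = 0.69, 0.01


def two_state_model(k12=1.0, k21=1.0):
    return StateModel(
        states=[(R_CLOSED, WIDTH_FRACTION * R_CLOSED),
                (R_OPEN, WIDTH_FRACTION * R_OPEN)],
        rate_matrix=[[0.0, k12], [k21, 0.0]],
    )


def simulate_dataset(n_bursts, k12, k21, seed, static_state=None,
                     static_fraction=0.0, label=""):
    """Event-mode simulation -> burst pipeline -> PDA dataset."""
    states = StateModel(
        states=[(R_CLOSED, WIDTH_FRACTION * R_CLOSED),
                (R_OPEN, WIDTH_FRACTION * R_OPEN)],
        rate_matrix=[[0.0, k12], [k21, 0.0]],
        static_state=static_state,
        static_state_fraction=static_fraction,
    )
    cfg = SimulationConfig(mode="event", n_bursts=n_bursts,
                           peak_brightness=1.5e5, seed=seed,
                           gamma=GAMMA, crosstalk=BETA)
    stream = simulate_photon_stream(cfg, states, FretCalibration())
    table, _ = analyze_bursts(stream, CorrectionSet(beta=BETA, gamma=GAMMA),
                              lifetimes=False, anisotropies=False)
    return rebin_bursts(table, gamma=GAMMA, beta=BETA, label=label)


@pytest.fixture(scope="session")
def full_scale_fit():
    """Full-scale two-state recovery: simulate, fit, profile CIs.

    Scale chosen so every bin duration carries >= 3000 accepted bins.
    """
    ds = simulate_dataset(n_bursts=2000, k12=1.0, k21=1.0, seed=101,
                          label="two-state 1/ms")
    model0 = PdaModel(R1=44.0, R2=58.0, R_static=0.0,
                      width_fraction=0.06, linker_width=5.0, kind="dynamic",
                      k12=[0.5], k21=[2.0], A3=[0.0])
    fit = global_fit([ds], model0, n_restarts=3, seed=7)
    cis = confidence_intervals(fit, [ds], seed=7)
    return {"dataset": ds, "fit": fit, "cis": cis,
            "truth": {"k12": 1.0, "k21": 1.0}}
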