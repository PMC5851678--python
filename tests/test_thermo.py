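"""Thermodynamics: ITC isotherms, Gibbs/Kirchhoff, ASA, stopped flow."""

import numpy as np
import pytest

from conformo.thermo import (Titration, ThermoParams, simulate_isotherm,
                             fit_isotherm, gibbs_dissection, kirchhoff_fit,
                             asa_forward, asa_decomposition, residue_counts,
                             simulate_trace, fit_single_exponential,
                             stopped_flow_analysis, KineticTrace,
                             GAS_CONSTANT)


# ----------------------------------------------------------------------
# Gibbs relations
# ----------------------------------------------------------------------

def test_unit_kd_gives_zero_free_energy():
    dg, _ = gibbs_dissection(1.0, -5.0, 298.15)
    assert dg == pytest.approx(0.0, abs=1e-12)


def test_nanomolar_affinity_free_energy():
    # Kd = 4.5 nM at 293.15 K
    dg, _ = gibbs_dissection(4.5e-9, -15.0, 293.15)
    expected = -GAS_CONSTANT * 293.15 * np.log(1 / 4.5e-9) / 1000.0
    assert dg == pytest.approx(expected, rel=1e-12)
    assert dg == pytest.approx(-11.19, abs=0.02)


def test_enthalpy_equal_to_free_energy_means_zero_entropy():
    dg, mtds = gibbs_dissection(1e-6, None or -GAS_CONSTANT * 298.15
                                * np.log(1e6) / 1000.0, 298.15)
    assert mtds == pytest.approx(0.0, abs=1e-9)


def test_thermo_params_identity_enforced():
    p = ThermoParams(kd=1e-8, temperature=293.15, delta_h=-20.0)
    assert p.check_identity()
    assert p.delta_g == pytest.approx(p.delta_h + p.minus_t_delta_s, abs=1e-9)


# ----------------------------------------------------------------------
# isotherm simulation / fitting
# ----------------------------------------------------------------------

def test_zero_enthalpy_zero_heats():
    p = ThermoParams(kd=1e-7, temperature=293.15, delta_h=0.0)
    sim, _ = simulate_isotherm(p, Titration(), seed=0)
    assert np.allclose(sim.heats, 0.0)


def test_total_heat_approaches_site_saturation():
    p = ThermoParams(kd=1e-9, temperature=293.15, delta_h=-12.0)
    sched = Titration(injection_volumes=np.full(40, 2e-6))
    sim, _ = simulate_isotherm(p, sched, seed=0)
    total = sim.heats.sum()
    # every macromolecule initially in the cell binds before being displaced,
    # so the integrated heat approaches dH x (initial moles of sites)
    expected = -12000.0 * 200e-6 * 10e-6
    assert total == pytest.approx(expected, rel=0.05)


def test_noiseless_round_trip_exact():
    p = ThermoParams(kd=2e-7, temperature=293.15, delta_h=-10.0)
    sim, flags = simulate_isotherm(p, Titration(), seed=1)
    assert flags == []
    fit = fit_isotherm(sim)
    assert fit.kd == pytest.approx(2e-7, rel=1e-6)
    assert fit.delta_h == pytest.approx(-10.0, rel=1e-6)
    assert fit.n_sites == pytest.approx(1.0, rel=1e-6)


def test_noisy_round_trip_recovery():
    """c ~ 50, 1% heat noise: Kd and dH recovered within 5% on average."""
    p = ThermoParams(kd=2e-7, temperature=293.15, delta_h=-10.0)
    clean, _ = simulate_isotherm(p, Titration(), seed=0)
    noise = 0.01 * np.abs(clean.heats).max()
    errs = []
    for seed in range(6):
        sim, _ = simulate_isotherm(p, Titration(noise_sd=noise), seed=seed)
        f = fit_isotherm(sim)
        errs.append((abs(f.kd / 2e-7 - 1), abs(f.delta_h / -10.0 - 1)))
        assert f.check_identity()
    mean_err = np.mean(errs, axis=0)
    assert mean_err[0] < 0.05 and mean_err[1] < 0.05


def test_fixed_vs_free_stoichiometry_agree():
    p = ThermoParams(kd=2e-7, temperature=293.15, delta_h=-10.0)
    clean, _ = simulate_isotherm(p, Titration(), seed=3)
    noise = 0.01 * np.abs(clean.heats).max()
    sim, _ = simulate_isotherm(p, Titration(noise_sd=noise), seed=3)
    free = fit_isotherm(sim)
    fixed = fit_isotherm(sim, fix_n=1.0)
    assert fixed.kd == pytest.approx(free.kd, rel=0.1)


def test_undersaturation_flagged():
    p = ThermoParams(kd=1e-7, temperature=293.15, delta_h=-10.0)
    sched = Titration(injection_volumes=np.full(8, 1e-6),
                      syringe_concentration=20e-6)
    _, flags = simulate_isotherm(p, sched, seed=0)
    assert any("undersaturated" in f for f in flags)


def test_too_few_injections_rejected():
    p = ThermoParams(kd=1e-7, temperature=293.15, delta_h=-10.0)
    sim, _ = simulate_isotherm(p, Titration(injection_volumes=np.full(5, 2e-6)),
                               seed=0)
    with pytest.raises(ValueError):
        fit_isotherm(sim)


# ----------------------------------------------------------------------
# Kirchhoff + ASA
# ----------------------------------------------------------------------

def test_constant_enthalpy_zero_heat_capacity():
    T = np.array([283.15, 293.15, 303.15, 308.15])
    kf = kirchhoff_fit(T, np.full(4, -5000.0))
    assert kf.delta_cp == pytest.approx(0.0, abs=1e-9)
    assert kf.delta_h_ref == pytest.approx(-5000.0)


def test_linear_series_recovered_exactly():
    T = np.array([283.15, 293.15, 298.15, 308.15])
    dh = -5000.0 + (-200.0) * (T - 333.15)
    kf = kirchhoff_fit(T, dh)
    assert kf.delta_cp == pytest.approx(-200.0, rel=1e-9)
    assert kf.delta_h_ref == pytest.approx(-5000.0, rel=1e-9)


def test_celsius_kelvin_slope_invariance():
    Tc = np.array([10.0, 20.0, 25.0, 35.0])
    dh = -3000.0 - 150.0 * Tc
    a = kirchhoff_fit(Tc + 273.15, dh)
    b = kirchhoff_fit(Tc, dh, celsius=True)
    assert a.delta_cp == pytest.approx(b.delta_cp, rel=1e-12)
    assert a.delta_h_ref == pytest.approx(b.delta_h_ref, rel=1e-12)


def test_kirchhoff_needs_three_points():
    with pytest.raises(ValueError):
        kirchhoff_fit([283.15, 293.15], [-1.0, -2.0])


def test_asa_forward_and_exact_inversion():
    dhr, dcp = asa_forward(-100.0, -200.0)
    assert dhr == pytest.approx(-1452.0)
    assert dcp == pytest.approx(-64.0)
    est = asa_decomposition(dhr, dcp)
    assert est.delta_asa_polar == pytest.approx(-100.0, abs=1e-9)
    assert est.delta_asa_nonpolar == pytest.approx(-200.0, abs=1e-9)


def test_asa_homogeneous_case():
    est = asa_decomposition(0.0, 0.0)
    assert (est.delta_asa_polar, est.delta_asa_nonpolar) == (0.0, 0.0)


def test_residue_count_conversion():
    est = asa_decomposition(*asa_forward(-560.0, -340.0))
    n_p, n_n = residue_counts(est)
    assert n_p == pytest.approx(10.0)
    assert n_n == pytest.approx(10.0)


def test_full_thermo_pipeline_round_trip():
    """Parameters -> isotherms at 4 temperatures -> fits -> Kirchhoff -> ASA."""
    dcp_true = -300.0       # cal/mol/K
    dhr_true = -20000.0     # cal/mol at 60 C
    temps = np.array([283.15, 291.15, 299.15, 308.15])
    fitted = []
    for i, T in enumerate(temps):
        dh_true = (dhr_true + dcp_true * (T - 333.15)) / 1000.0
        p = ThermoParams(kd=2e-7, temperature=T, delta_h=dh_true)
        clean, _ = simulate_isotherm(p, Titration(temperature=T), seed=10 + i)
        noise = 0.01 * np.abs(clean.heats).max()
        sim, _ = simulate_isotherm(
            p, Titration(temperature=T, noise_sd=noise), seed=10 + i)
        fitted.append(fit_isotherm(sim).delta_h * 1000.0)
    kf = kirchhoff_fit(temps, np.array(fitted))
    assert kf.delta_cp == pytest.approx(dcp_true, rel=0.10)
    assert kf.delta_h_ref == pytest.approx(dhr_true, rel=0.10)
    est = asa_decomposition(kf.delta_h_ref, kf.delta_cp)
    ref = asa_decomposition(dhr_true, dcp_true)
    assert est.delta_asa_polar == pytest.approx(ref.delta_asa_polar, rel=0.15)


# ----------------------------------------------------------------------
# stopped flow
# ----------------------------------------------------------------------

def test_single_exponential_recovery():
    tr = simulate_trace(kobs=3.0, amplitude=1.0, offset=0.2, noise_sd=0.01,
                        seed=0)
    k, flags = fit_single_exponential(tr)
    assert k == pytest.approx(3.0, rel=0.02)
    assert flags == []


def test_exact_line_gives_exact_kon():
    rc_traces = [simulate_trace(kobs=2.0e6 * c, concentration=c, seed=i)
                 for i, c in enumerate((5e-6, 10e-6, 15e-6))]
    rc = stopped_flow_analysis(rc_traces)
    assert rc.kon == pytest.approx(2.0e6, rel=1e-3)


def test_kd_from_rate_ratio():
    traces = [simulate_trace(kobs=2e6 * c + 0.2, concentration=c, seed=i)
              for i, c in enumerate((5e-6, 10e-6, 15e-6, 25e-6))]
    disp = simulate_trace(kobs=0.2, seed=9)
    rc = stopped_flow_analysis(traces, disp)
    assert rc.koff == pytest.approx(0.2, rel=0.01)
    assert rc.kd_kinetic == pytest.approx(1e-7, rel=0.02)


def test_kon_koff_unbiased_over_replicates():
    kons, koffs = [], []
    for seed in range(40):
        traces = [simulate_trace(kobs=2e6 * c + 0.2, concentration=c,
                                 noise_sd=0.02, seed=seed * 10 + i)
                  for i, c in enumerate((5e-6, 10e-6, 15e-6, 25e-6))]
        disp = simulate_trace(kobs=0.2, noise_sd=0.02, seed=seed * 10 + 7)
        rc = stopped_flow_analysis(traces, disp)
        kons.append(rc.kon)
        koffs.append(rc.koff)
    assert abs(np.mean(kons) / 2e6 - 1) < 0.02
    assert abs(np.mean(koffs) / 0.2 - 1) < 0.02


def test_needs_three_concentrations():
    traces = [simulate_trace(kobs=1.0, concentration=c) for c in (1e-6, 2e-6)]
    with pytest.raises(ValueError):
        stopped_flow_analysis(traces)
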