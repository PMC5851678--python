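"""Photon distribution analysis: rebinning, occupancy law, forward model."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom, kstest

from conformo.photons import PhotonStream
from conformo.bursts import sliding_window_burst_search
from conformo.pda import (PdaDataset, rebin_bursts, epr_histogram,
                          occupancy_time_distribution, PdaModel,
                          static_pda_histogram, dynamic_pda_histogram,
                          fast_exchange_histogram, sample_pda_bins,
                          default_epr_edges)
from conformo.simulate import sample_occupancy_times


# ----------------------------------------------------------------------
# rebinning
# ----------------------------------------------------------------------

def burst_stream(rate_hz, duration_s, seed=0, p_red=0.3, p_rr=0.3):
    """One dense photon cluster (a single burst after search)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0, duration_s, n))
    gates = (rng.random(n) < p_rr).astype(int)
    red = rng.random(n) < p_red
    ch = np.where(gates == 1, 2, np.where(red, 2, 0))
    return PhotonStream.from_float_times(t, np.zeros(n), ch, gates)


def test_bin_count_arithmetic():
    # a burst spanning exactly 1.0 ms at 0.5-ms binning -> 2 full bins
    t = np.linspace(0.0, 1.0e-3, 201)
    ps = PhotonStream.from_float_times(t, np.zeros(201), np.zeros(201),
                                       np.zeros(201))
    bt = sliding_window_burst_search(ps)
    assert len(bt) == 1
    ds = rebin_bursts(bt, bin_durations_ms=[0.5], min_photons=1,
                      max_photons=10**6, s_region=None)
    assert ds.n_bins(0.5) == 2


def test_low_count_bins_excluded():
    ps = burst_stream(4e4, 2e-3, seed=2)  # ~8 donor-gate photons per 0.2 ms
    bt = sliding_window_burst_search(ps, min_total=20)
    ds_all = rebin_bursts(bt, bin_durations_ms=[0.2], min_photons=1,
                          max_photons=10**6, s_region=None)
    with pytest.raises(ValueError, match="photon-count bounds"):
        rebin_bursts(bt, bin_durations_ms=[0.2], min_photons=20,
                     max_photons=250, s_region=None)
    assert ds_all.n_bins(0.2) >= 1


def test_rebin_photon_conservation():
    ps = burst_stream(3e5, 5e-3, seed=3)
    bt = sliding_window_burst_search(ps)
    ds = rebin_bursts(bt, bin_durations_ms=[1.0], min_photons=1,
                      max_photons=10**6, s_region=None)
    f, sa = ds.bins[1.0]
    dg = ps.gates == 0
    # retained bins cannot carry more photons than the burst owns
    assert f.sum() <= int(dg.sum())
    assert np.all(sa <= f)


def test_s_region_selection():
    ps = burst_stream(3e5, 5e-3, seed=4, p_rr=0.05)  # S ~ 0.95: donor-only-ish
    bt = sliding_window_burst_search(ps)
    with pytest.raises(ValueError, match="S region"):
        rebin_bursts(bt, bin_durations_ms=[1.0], min_photons=1,
                     max_photons=10**6, s_region=(0.3, 0.8))


# ----------------------------------------------------------------------
# occupancy-time distribution
# ----------------------------------------------------------------------

def test_no_switch_probability():
    d = occupancy_time_distribution(1.0, 1.0, 1.0)
    assert d.p_full == pytest.approx(0.5 * np.exp(-1.0), rel=1e-12)
    assert d.p_zero == pytest.approx(0.5 * np.exp(-1.0), rel=1e-12)


def test_frozen_chain_two_point():
    d = occupancy_time_distribution(0.0, 0.0, 1.0)
    assert (d.p_full, d.p_zero) == (0.5, 0.5)
    assert np.all(d.density(np.linspace(0.01, 0.99, 9)) == 0.0)


@pytest.mark.parametrize("k12,k21,T", [(1.0, 1.0, 1.0), (0.3, 1.2, 0.5),
                                       (10.0, 10.0, 1.0), (300.0, 300.0, 1.0)])
def test_occupancy_normalization_and_mean(k12, k21, T):
    d = occupancy_time_distribution(k12, k21, T)
    integral, _ = quad(d.density, 0, T, limit=300)
    assert integral + d.p_full + d.p_zero == pytest.approx(1.0, abs=1e-6)
    t, w = d.nodes(257)
    mean = float((t * w).sum() + d.p_full * T)
    assert mean == pytest.approx(k21 / (k12 + k21) * T, abs=2e-3 * T)


def test_occupancy_matches_gillespie():
    rng = np.random.default_rng(7)
    k12, k21, T = 0.8, 1.6, 1.0
    samples = sample_occupancy_times(k12, k21, T, 100_000, rng)
    d = occupancy_time_distribution(k12, k21, T)
    # point masses within Monte-Carlo error
    n = samples.size
    for mass, frac in ((d.p_full, (samples >= T - 1e-12).mean()),
                       (d.p_zero, (samples <= 1e-12).mean())):
        assert frac == pytest.approx(mass, abs=4 * np.sqrt(mass / n))
    # KS on the continuous part
    cont = samples[(samples > 1e-12) & (samples < T - 1e-12)]
    t, w = d.nodes(801)
    cdf = np.cumsum(w) / w.sum()
    ks = kstest(cont, lambda q: np.interp(q, t, cdf))
    assert ks.pvalue > 1e-3


def test_invalid_occupancy_inputs():
    with pytest.raises(ValueError):
        occupancy_time_distribution(-1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        occupancy_time_distribution(1.0, 1.0, 0.0)


# ----------------------------------------------------------------------
# forward model
# ----------------------------------------------------------------------

def plain_dataset(F, gamma=1.0, beta=0.0):
    return PdaDataset(bins={1.0: (F, np.zeros_like(F))}, gamma=gamma,
                      beta=beta)


def test_single_sharp_state_is_pure_binomial():
    """sigma = 0, no corrections: P(j) = C(F, j) eps^j (1-eps)^(F-j)."""
    F = np.full(1000, 40)
    ds = plain_dataset(F)
    R, R0 = 50.0, 53.0
    eps = 1.0 / (1.0 + (R / R0) ** 6)
    # one histogram bin centred on each possible acceptor count j/40
    edges = (np.arange(42) - 0.5) / 40.0
    h = static_pda_histogram([(R, 0.0, 1.0)], ds, 1.0, edges=edges,
                             forster_radius=R0)
    expected = 1000 * binom.pmf(np.arange(41), 40, eps)
    assert np.allclose(h, expected, atol=1e-6 * 1000 + 1e-9)


def test_histogram_mass_equals_bin_count():
    rng = np.random.default_rng(1)
    F = rng.integers(20, 100, 500)
    ds = plain_dataset(F, gamma=0.69, beta=0.01)
    h = static_pda_histogram([(45.0, 4.0, 0.3), (60.0, 5.0, 0.7)], ds, 1.0)
    assert h.sum() == pytest.approx(500, rel=1e-9)


def test_invalid_states_rejected():
    ds = plain_dataset(np.full(10, 30))
    with pytest.raises(ValueError):
        static_pda_histogram([(45.0, -1.0, 1.0)], ds, 1.0)
    with pytest.raises(ValueError):
        static_pda_histogram([(45.0, 1.0, 0.5)], ds, 1.0)  # areas != 1
    with pytest.raises(ValueError):
        static_pda_histogram([(45.0, 1.0, 1.0)], ds, 0.7)  # missing duration


def test_static_oracle_small():
    """Analytic static histogram vs direct Monte-Carlo at 1e5 bins."""
    rng = np.random.default_rng(11)
    F = rng.integers(20, 251, 100_000)
    ds = plain_dataset(F, gamma=0.69, beta=0.01)
    model = PdaModel(R1=41.0, R2=62.0, width_fraction=0.08, kind="static",
                     areas=[(0.4, 0.6, 0.0)])
    h = dynamic_pda_histogram(model, ds, 1.0)
    sa = sample_pda_bins(model, F, 1.0, ds, rng)
    obs = epr_histogram(F, sa, default_epr_edges())
    use = h >= 4
    chi2 = float(((obs[use] - h[use]) ** 2 / h[use]).sum() / use.sum())
    assert chi2 < 1.5


def test_dynamic_limits():
    rng = np.random.default_rng(12)
    F = rng.integers(20, 251, 20_000)
    ds = plain_dataset(F, gamma=0.69, beta=0.01)
    base = PdaModel(R1=41.0, R2=62.0, R_static=50.0, width_fraction=0.08,
                    kind="dynamic", k12=[1.0], k21=[1.0], A3=[0.2])
    # frozen limit equals the static mixture with stationary areas
    frozen = dynamic_pda_histogram(base.copy(k12=[0.0], k21=[0.0]), ds, 1.0)
    static = dynamic_pda_histogram(
        PdaModel(R1=41.0, R2=62.0, R_static=50.0, width_fraction=0.08,
                 kind="static", areas=[(0.4, 0.4, 0.2)]), ds, 1.0)
    assert np.abs(frozen - static).max() / frozen.sum() < 1e-3
    # fast-exchange limit collapses onto the time-averaged state
    fast = dynamic_pda_histogram(base.copy(k12=[4e3], k21=[4e3]), ds, 1.0)
    avg = fast_exchange_histogram(base, ds, 1.0)
    assert np.abs(fast - avg).max() / fast.sum() < 1e-3


def test_background_kernel_normalized():
    from conformo.pda import PdaKernel

    F = np.full(200, 50)
    kern = PdaKernel(F, 1.0, default_epr_edges(), background_donor=800.0,
                     background_acceptor=500.0)
    w = np.zeros(kern.eps_grid.size)
    w[80] = 1.0
    h = kern.expected(w)
    assert h.sum() == pytest.approx(200, rel=1e-4)


def test_dataset_validation():
    with pytest.raises(ValueError):
        PdaDataset(bins={1.0: (np.array([30]), np.array([31]))})
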