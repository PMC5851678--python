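"""Burst search, ALEX-2CDE filter, corrections, lifetimes, anisotropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conformo.photons import PhotonStream
from conformo.bursts import (sliding_window_burst_search, burst_region_mask,
                             alex_2cde, CorrectionSet, correct_and_score,
                             mle_lifetime, burst_anisotropy, perrin,
                             perrin_fit, static_fret_line, dynamic_fret_line,
                             multiparameter_histograms)
from conformo.simulate import FretCalibration


def stream_from_times(times, gates=None, channels=None):
    n = len(times)
    return PhotonStream.from_float_times(
        np.asarray(times, dtype=float),
        np.zeros(n), channels if channels is not None else np.zeros(n),
        gates if gates is not None else np.zeros(n))


def brute_force_regions(times, window, min_per_window):
    """O(n^2) reference for the sliding-window in-region flag."""
    t = np.asarray(times, dtype=float)
    out = np.zeros(t.size, dtype=bool)
    for i in range(t.size):
        lo, hi = t[i] - window / 2, t[i] + window / 2
        out[i] = np.sum((t >= lo) & (t < hi)) >= min_per_window
    return out


# ----------------------------------------------------------------------
# burst search
# ----------------------------------------------------------------------

def test_empty_stream_gives_empty_table():
    assert len(sliding_window_burst_search(stream_from_times([]))) == 0


def test_dense_run_is_single_burst():
    ps = stream_from_times(np.arange(100) * 1e-6)
    bt = sliding_window_burst_search(ps)
    assert len(bt) == 1
    assert bt.df["n_photons"].iloc[0] == 100


def test_sparse_photons_no_burst():
    # 200-us spacing -> 2.5 photons per 500-us window < 5
    ps = stream_from_times(np.arange(100) * 200e-6)
    assert len(sliding_window_burst_search(ps)) == 0


def test_unordered_stream_rejected():
    with pytest.raises(ValueError):
        burst_region_mask(np.array([1.0, 0.5]), 500e-6, 5)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_burst_search_equals_brute_force(seed):
    """Exact agreement with the O(n^2) window scan on random streams."""
    rng = np.random.default_rng(seed)
    # mixture of sparse background and dense burst-like clusters
    t = [rng.uniform(0, 0.05, 200)]
    for _ in range(rng.integers(1, 6)):
        t0 = rng.uniform(0, 0.05)
        t.append(t0 + rng.exponential(20e-6, rng.integers(20, 120)).cumsum())
    t = np.sort(np.concatenate(t))
    got = burst_region_mask(t, 500e-6, 5)
    ref = brute_force_regions(t, 500e-6, 5)
    assert np.array_equal(got, ref)


def test_burst_membership_matches_brute_force_10k():
    rng = np.random.default_rng(99)
    t = [rng.uniform(0, 0.3, 4000)]
    for k in range(40):
        t0 = rng.uniform(0, 0.3)
        t.append(t0 + rng.exponential(15e-6, 150).cumsum())
    t = np.sort(np.concatenate(t))
    assert t.size >= 10_000
    got = burst_region_mask(t, 500e-6, 5)
    ref = brute_force_regions(t, 500e-6, 5)
    assert np.array_equal(got, ref)


def test_e_s_invariant_under_time_rescaling():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0, 1e-3, 400))
    ch = rng.choice([0, 2], 400)
    g = np.zeros(400)
    cs = CorrectionSet(gamma=0.8)
    out = {}
    for scale in (1.0, 2.0):
        ps = stream_from_times(t * scale, g, ch)
        bt = sliding_window_burst_search(ps, window_us=500 * scale)
        bt.compute_corrections(cs)
        out[scale] = bt.df["E"].to_numpy()
    assert np.allclose(out[1.0], out[2.0])


# ----------------------------------------------------------------------
# ALEX-2CDE
# ----------------------------------------------------------------------

def test_alex2cde_alternating_is_well_mixed():
    n = 400
    t = np.arange(n) * 10e-6
    score = alex_2cde(t, np.arange(n) % 2, 100e-6)
    assert score < 5.0


def test_alex2cde_segregated_exceeds_threshold():
    n = 400
    t = np.arange(n) * 10e-6
    g = (np.arange(n) >= n // 2).astype(int)
    assert alex_2cde(t, g, 100e-6) > 12.0


def test_alex2cde_single_gate_maximal():
    t = np.arange(50) * 10e-6
    assert alex_2cde(t, np.zeros(50), 100e-6) == 100.0


def test_alex2cde_monotone_under_progressive_segregation():
    rng = np.random.default_rng(8)
    n = 600
    t = np.arange(n) * 10e-6
    g = rng.integers(0, 2, n)
    scores = []
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        gg = g.copy()
        m = int(frac * n)
        # push the acceptor-gate photons of the first m slots to the end
        head = gg[:m]
        gg2 = np.concatenate([np.zeros(int((head == 0).sum()), dtype=int),
                              gg[m:],
                              np.ones(int((head == 1).sum()), dtype=int)])
        scores.append(alex_2cde(t, gg2, 100e-6))
    assert all(b >= a - 1.0 for a, b in zip(scores, scores[1:]))
    assert scores[-1] > scores[0]


# ----------------------------------------------------------------------
# corrections
# ----------------------------------------------------------------------

def test_uncorrected_ratio():
    cs = CorrectionSet()
    out = correct_and_score([60], [40], [10], [0.0], cs)
    assert out["E"][0] == pytest.approx(0.4)


def test_full_correction_example():
    cs = CorrectionSet(alpha=0.05, beta=0.01, gamma=0.69)
    out = correct_and_score([100], [50], [80], [0.0], cs)
    assert out["E"][0] == pytest.approx(45 / 114, rel=1e-12)
    assert out["S"][0] == pytest.approx(114 / 194, rel=1e-12)


def test_donor_only_molecule():
    cs = CorrectionSet(alpha=0.05, beta=0.01, gamma=0.69)
    f_bb, f_rr = 200.0, 0.0
    f_br = 0.05 * f_rr + 0.01 * f_bb  # exactly the leak-through level
    out = correct_and_score([f_bb], [f_br], [f_rr], [0.0], cs)
    assert out["E"][0] == pytest.approx(0.0, abs=1e-12)
    assert out["S"][0] == pytest.approx(1.0, abs=1e-12)


def test_background_subtraction_and_undefined_flag():
    cs = CorrectionSet(background_rates={"BB": 100.0, "BR": 50.0, "RR": 10.0})
    out = correct_and_score([110], [55], [11], [0.1], cs)
    assert out["F_BB"][0] == pytest.approx(100.0)
    assert out["F_BR"][0] == pytest.approx(50.0)
    out2 = correct_and_score([0], [0], [0], [0.0], CorrectionSet())
    assert out2["undefined"][0] and np.isnan(out2["E"][0])


# ----------------------------------------------------------------------
# lifetime MLE
# ----------------------------------------------------------------------

def test_lifetime_mle_consistent():
    rng = np.random.default_rng(0)
    t = rng.exponential(3.8, 100_000) % 18.75
    assert mle_lifetime(t, 18.75) == pytest.approx(3.8, rel=0.01)


@pytest.mark.parametrize("tau", [0.5, 2.0, 5.0])
def test_lifetime_mle_small_bias(tau):
    rng = np.random.default_rng(1)
    est = [mle_lifetime(rng.exponential(tau, 10_000) % 18.75, 18.75)
           for _ in range(5)]
    assert np.mean(est) == pytest.approx(tau, rel=0.01)


def test_lifetime_boundary_and_min_photons():
    assert mle_lifetime(np.zeros(100) + 1e-6, 18.75) < 0.01
    assert np.isnan(mle_lifetime(np.ones(5), 18.75, min_photons=10))


def test_lifetime_with_background_fraction():
    rng = np.random.default_rng(2)
    n = 50_000
    t = np.concatenate([rng.exponential(2.0, int(0.8 * n)) % 18.75,
                        rng.uniform(0, 18.75, int(0.2 * n))])
    est = mle_lifetime(t, 18.75, background_fraction=0.2)
    assert est == pytest.approx(2.0, rel=0.03)


# ----------------------------------------------------------------------
# anisotropy
# ----------------------------------------------------------------------

def test_perrin_fixed_points():
    assert perrin(10.0, 10.0) == pytest.approx(0.2)
    assert perrin(0.0, 10.0) == pytest.approx(0.4)


def test_anisotropy_from_counts():
    assert burst_anisotropy(3.0, 1.0, 1.0) == pytest.approx((3 - 1) / (3 + 2))
    assert np.isnan(burst_anisotropy(0.0, 0.0))


def test_perrin_round_trip():
    rng = np.random.default_rng(4)
    tau = rng.uniform(0.5, 6.0, 100)
    r = perrin(tau, 10.0) * (1 + 0.02 * rng.standard_normal(100))
    assert perrin_fit(r, tau) == pytest.approx(10.0, rel=0.05)


def test_perrin_fit_needs_three_points():
    with pytest.raises(ValueError):
        perrin_fit([0.2, 0.3], [1.0, 2.0])


# ----------------------------------------------------------------------
# FRET lines
# ----------------------------------------------------------------------

def test_static_line_without_linker_is_ideal():
    cal = FretCalibration()
    line = static_fret_line(cal, linker_width=0.0)
    ideal = 1.0 - line.tau / cal.donor_lifetime
    assert np.allclose(line.efficiency, ideal, atol=1e-9)


def test_static_line_limits():
    cal = FretCalibration()
    line = static_fret_line(cal, linker_width=6.0)
    # tau -> tau_D as E -> 0 and tau -> 0 as E -> 1
    assert line.efficiency[np.argmax(line.tau)] < 0.05
    assert line.efficiency[np.argmin(line.tau)] > 0.93


def test_dynamic_line_through_endpoints():
    cal = FretCalibration()
    line = dynamic_fret_line(cal, 0.8, 3.0)
    assert line.tau[0] == pytest.approx(3.0)
    assert line.tau[-1] == pytest.approx(0.8)
    assert np.all(np.isfinite(line.efficiency))


def test_negative_linker_rejected():
    with pytest.raises(ValueError):
        static_fret_line(FretCalibration(), linker_width=-1.0)


# ----------------------------------------------------------------------
# histograms
# ----------------------------------------------------------------------

def test_histogram_conservation():
    import pandas as pd

    rng = np.random.default_rng(5)
    df = pd.DataFrame({"E": rng.uniform(0, 1, 500),
                       "S": rng.uniform(0, 1, 500),
                       "tau_DA": rng.uniform(0.1, 3.8, 500)})
    h = multiparameter_histograms(df)
    counts, _, _ = h["E_vs_tau"]
    assert counts.sum() == 500
    assert np.array_equal(counts.sum(axis=1), h["proj_tau"])
    assert np.array_equal(counts.sum(axis=0), h["proj_E_tau"])
    counts_es, _, _ = h["E_vs_S"]
    assert counts_es.sum() == 500
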