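"""Continuous-time Markov chain engine for conformational kinetics.

Rates are given in 1/ms, durations in seconds (the convention used by the
simulator), and paths are exact event-driven (Gillespie) realizations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "stationary_distribution",
    "simulate_ctmc_path",
    "state_at_times",
    "sample_occupancy_times",
]

MS = 1e-3  # seconds per millisecond


def _validate_rates(rate_matrix):
    Q = np.asarray(rate_matrix, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("rate matrix must be square")
    off = Q[~np.eye(Q.shape[0], dtype=bool)]
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be non-negative")
    return Q


def stationary_distribution(rate_matrix):
    """Stationary distribution of the chain with off-diagonal rates in 1/ms.

    Solves ``pi Q = 0`` with the generator built from the off-diagonal
    rates.  For a chain with absorbing or disconnected states the returned
    vector is a valid invariant distribution (computed by least squares on
    the augmented system).
    """
    K = _validate_rates(rate_matrix).copy()
    n = K.shape[0]
    np.fill_diagonal(K, 0.0)
    Q = K - np.diag(K.sum(axis=1))
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_ctmc_path(rate_matrix, duration, seed, initial_state=None):
    """Exact Gillespie path of the conformational chain over ``[0, duration]``.

    Parameters
    ----------
    rate_matrix : (n, n) array_like
        Off-diagonal interconversion rates in 1/ms (diagonal ignored).
    duration : float
        Path length in seconds.
    seed : int or numpy.random.Generator
        Randomness source.
    initial_state : int, optional
        Starting state; drawn from the stationary distribution when omitted.

    Returns
    -------
    states : ndarray of int
        Visited states, ``states[i]`` entered at ``entry_times[i]``.
    entry_times : ndarray of float
        Entry times in seconds, starting at 0.
    """
    K = _validate_rates(rate_matrix).copy()
    np.fill_diagonal(K, 0.0)
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = K.shape[0]
    exit_rates = K.sum(axis=1) / MS  # 1/s
    if initial_state is None:
        state = int(rng.choice(n, p=stationary_distribution(K)))
    else:
        state = int(initial_state)

    states = [state]
    times = [0.0]
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate == 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        p = K[state] / K[state].sum()
        state = int(rng.choice(n, p=p))
        states.append(state)
        times.append(t)
    return np.asarray(states, dtype=np.intp), np.asarray(times, dtype=float)


def state_at_times(states, entry_times, query_times):
    """State occupied at each of ``query_times`` (seconds) along a path."""
    idx = np.searchsorted(entry_times, query_times, side="right") - 1
    return states[np.clip(idx, 0, len(states) - 1)]


def sample_occupancy_times(k12, k21, T, n, rng):
    """Cumulative time spent in state 1 over windows of length ``T`` ms.

    Vectorized Gillespie sampler for the stationary two-state chain; used
    as the stochastic oracle for the analytic occupancy-time distribution.
    ``k12``/``k21`` are in 1/ms, ``T`` in ms.  Returns ``n`` samples in ms.
    """
    if k12 < 0 or k21 < 0:
        raise ValueError("rates must be non-negative")
    p1 = 0.5 if (k12 + k21) == 0 else k21 / (k12 + k21)
    state = (rng.random(n) >= p1).astype(np.int8)  # 0 == state 1
    remaining = np.full(n, float(T))
    t1 = np.zeros(n)
    rates = np.array([k12, k21])
    active = rates[state] > 0
    while np.any(active):
        idx = np.flatnonzero(active)
        r = rates[state[idx]]
        dwell = np.where(r > 0, rng.exponential(1.0, idx.size) / np.maximum(r, 1e-300), np.inf)
        used = np.minimum(dwell, remaining[idx])
        in1 = state[idx] == 0
        t1[idx[in1]] += used[in1]
        remaining[idx] -= used
        switched = dwell < remaining[idx] + used  # dwell ended inside window
        state[idx[switched]] ^= 1
        active[idx] = switched & (remaining[idx] > 0)
        active[idx[remaining[idx] <= 0]] = False
    # molecules that never moved spend the whole window in their initial state
    untouched = (rates[state] == 0) & (state == 0) & (remaining > 0)
    t1[untouched] += remaining[untouched]
    return t1
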