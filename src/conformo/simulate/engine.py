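"""Photon-level simulation of freely diffusing FRET-labelled molecules.

Two generation modes share identical per-photon physics:

``trajectory``
    Brownian motion of all molecules is integrated with a fixed time step
    in a cubic periodic box; the instantaneous detected rate of a molecule
    is ``peak_brightness`` times the 3D-Gaussian point-spread-function
    weight ``exp(-2x^2/wr^2 - 2y^2/wr^2 - 2z^2/wz^2)`` at its position.

``event``
    Only passages through the observation region (an ellipsoid of 2.5
    waists, where the PSF weight has decayed to ~4e-6) are simulated:
    molecules enter uniformly over the region surface — the diffusive flux
    from a uniform bath is uniform per unit area — random-walk with the
    same time step and emit photons with the same position-dependent rate
    until they exit.  This reproduces the burst-size and FRET-efficiency
    statistics of trajectory mode without spending time on the empty box.

Per photon: the conformational state comes from an exact continuous-time
Markov path; the instantaneous donor-acceptor distance is the state's
quasi-static Gaussian draw (re-drawn every ``static_redraw_time``) plus a
fast Gaussian linker jitter; donor photons draw microtimes from the
FRET-quenched exponential decay ``tau_D * (1 - E)``, sensitized acceptor
photons add the acceptor decay on top of the donor delay; polarization is
assigned from the time-dependent anisotropy ``r(t) = r0 exp(-t/theta)``;
uniform Poisson background is added per detection channel.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from ..photons import PhotonStream, CHANNELS
from .config import SimulationConfig, StateModel, FretCalibration
from .ctmc import MS, simulate_ctmc_path, state_at_times, stationary_distribution

__all__ = ["simulate_photon_stream"]

_EVENT_REGION_WAISTS = 1.5   # observation-region semi-axes in PSF waists
_EVENT_MAX_PASSAGE = 0.2     # s cap on a single passage
_EVENT_SPACING = _EVENT_MAX_PASSAGE + 20e-3  # passages can never overlap
_EVENT_MIN_PHOTONS = 50      # a passage with this many photons counts as a burst
_BLOCK = 256                 # random-walk steps advanced per vector op


# ----------------------------------------------------------------------
# conformational states and distances
# ----------------------------------------------------------------------

def _two_state_path(k12, k21, duration, rng):
    """Vectorized alternating-dwell Gillespie path for a two-state chain."""
    k = np.array([k12, k21], dtype=float)
    if k.sum() == 0:
        s0 = int(rng.random() >= 0.5)
        return np.array([s0]), np.array([0.0])
    p1 = k[1] / k.sum()
    s0 = int(rng.random() >= p1)
    if k[s0] == 0:
        return np.array([s0]), np.array([0.0])
    mean_rate = 0.5 * (k[0] + k[1]) / MS  # events per s
    states_list, times_list = [], []
    t_done, state = 0.0, s0
    while t_done < duration:
        n = int(max(64, (duration - t_done) * mean_rate * 1.3))
        seq = (state + np.arange(n)) % 2
        with np.errstate(divide="ignore"):
            dwell = rng.exponential(1.0, n) / np.where(k[seq] > 0, k[seq] / MS, np.inf)
        entry = t_done + np.concatenate(([0.0], np.cumsum(dwell[:-1])))
        keep = entry < duration
        states_list.append(seq[keep])
        times_list.append(entry[keep])
        t_done = entry[keep][-1] + dwell[keep][-1]
        state = (seq[keep][-1] + 1) % 2
        if not np.isfinite(t_done):
            break
    return np.concatenate(states_list), np.concatenate(times_list)


def _state_path(states: StateModel, duration, rng):
    n = states.n_states
    if n == 1:
        return np.array([0]), np.array([0.0])
    if n == 2:
        return _two_state_path(states.rate_matrix[0, 1], states.rate_matrix[1, 0],
                               duration, rng)
    return simulate_ctmc_path(states.rate_matrix, duration, rng)


def _photon_distances(times, states: StateModel, config: SimulationConfig,
                      rng, duration):
    """Instantaneous D-A distance for photons of a single molecule.

    Draws, in a fixed order so that results are reproducible: the static /
    dynamic assignment, the Markov path, the quasi-static Gaussian redraws
    per ``static_redraw_time`` slot, then the per-photon linker jitter.
    """
    t_redraw = config.static_redraw_time * MS
    n_slots = int(np.floor(duration / t_redraw)) + 1
    n_dyn = states.n_states
    is_static = rng.random() < states.static_state_fraction
    if is_static:
        path = (np.array([0]), np.array([0.0]))
    else:
        path = _state_path(states, duration, rng)
    z = rng.standard_normal((n_slots, n_dyn + 1))
    if times.size == 0:
        return np.empty(0)
    slots = np.minimum((times / t_redraw).astype(np.intp), n_slots - 1)
    if is_static:
        R0_, sig = states.static_state
        base = R0_ + sig * z[slots, n_dyn]
    else:
        s = state_at_times(*path, times)
        means = np.array([r for r, _ in states.states])
        widths = np.array([w for _, w in states.states])
        base = means[s] + widths[s] * z[slots, s]
    if config.linker_fluctuation > 0:
        base = base + config.linker_fluctuation * rng.standard_normal(times.size)
    return np.maximum(base, 1.0)  # dyes cannot overlap; floor far below R0


# ----------------------------------------------------------------------
# per-photon detection physics
# ----------------------------------------------------------------------

def _polarization(micro_ns, calib: FretCalibration, rng):
    """Parallel/perpendicular split from r(t) = r0 exp(-t/theta)."""
    r = calib.fundamental_anisotropy * np.exp(
        -micro_ns / calib.rotational_correlation_time)
    p_par = (1.0 + 2.0 * r) / (2.0 + r)
    return rng.random(micro_ns.size) < p_par


def _emit_donor_gate(times, distances, config: SimulationConfig,
                     calib: FretCalibration, rng):
    """Detection physics for donor-excitation-period photons.

    ``times`` are emission macrotimes of all excitation events that led to
    a detected photon (before gamma thinning); a fraction
    ``direct_excitation/(1+direct_excitation)`` of them are direct
    acceptor excitations.
    """
    n = times.size
    E = 1.0 / (1.0 + (distances / calib.forster_radius) ** 6)
    p_direct = config.direct_excitation / (1.0 + config.direct_excitation)
    direct = rng.random(n) < p_direct
    fret = (~direct) & (rng.random(n) < E)
    donor = ~direct & ~fret

    # relative detection efficiency of the red channel
    keep = np.ones(n, dtype=bool)
    if config.gamma < 1.0:
        keep[fret] = rng.random(fret.sum()) < config.gamma
    elif config.gamma > 1.0:
        keep[donor] = rng.random(donor.sum()) < 1.0 / config.gamma

    tau_da = calib.donor_lifetime * np.maximum(1.0 - E, 1e-6)
    micro = np.empty(n)
    micro[donor] = rng.exponential(tau_da[donor])
    micro[fret] = rng.exponential(tau_da[fret]) + rng.exponential(
        calib.acceptor_lifetime, fret.sum())
    micro[direct] = rng.exponential(calib.acceptor_lifetime, direct.sum())

    red = fret | direct
    if config.crosstalk > 0:
        xt = donor & (rng.random(n) < config.crosstalk)
        red = red | xt

    # anisotropy follows the emitting dye's own excited-state delay
    decay_delay = micro.copy()
    acc = fret | direct
    decay_delay[fret] = micro[fret] - tau_da[fret]  # acceptor component only
    np.clip(decay_delay, 0.0, None, out=decay_delay)
    par = _polarization(decay_delay, calib, rng)

    channel = np.where(red, np.where(par, CHANNELS["acceptor_parallel"],
                                     CHANNELS["acceptor_perpendicular"]),
                       np.where(par, CHANNELS["donor_parallel"],
                                CHANNELS["donor_perpendicular"]))
    if config.irf_width > 0:
        micro = micro + config.irf_width * rng.standard_normal(n)
    gate = np.zeros(n, dtype=np.uint8)
    return (times[keep], micro[keep], channel[keep].astype(np.uint8), gate[keep])


def _emit_acceptor_gate(times, calib: FretCalibration, config, rng):
    n = times.size
    micro = rng.exponential(calib.acceptor_lifetime, n)
    par = _polarization(micro, calib, rng)
    channel = np.where(par, CHANNELS["acceptor_parallel"],
                       CHANNELS["acceptor_perpendicular"]).astype(np.uint8)
    if config.irf_width > 0:
        micro = micro + config.irf_width * rng.standard_normal(n)
    return times, micro, channel, np.ones(n, dtype=np.uint8)


def _background(config: SimulationConfig, span, rng):
    times, micro, chan, gate = [], [], [], []
    window_ns = 18.75
    for name, rate in config.background_rates.items():
        if rate <= 0:
            continue
        code = CHANNELS[name]
        n = rng.poisson(rate * span)
        times.append(rng.uniform(0.0, span, n))
        micro.append(rng.uniform(0.0, window_ns, n))
        chan.append(np.full(n, code, dtype=np.uint8))
        if code in (0, 1):  # blue photons only exist in the donor period
            gate.append(np.zeros(n, dtype=np.uint8))
        else:               # red background falls in both periods equally
            gate.append((rng.random(n) < 0.5).astype(np.uint8))
    if not times:
        z = np.empty(0)
        return z, z, z.astype(np.uint8), z.astype(np.uint8)
    return (np.concatenate(times), np.concatenate(micro),
            np.concatenate(chan), np.concatenate(gate))


# ----------------------------------------------------------------------
# excitation-event sampling from PSF weights
# ----------------------------------------------------------------------

def _sample_photon_times(weights, t0, dt, rate, rng):
    """Poisson photon emission times from per-step PSF weights.

    ``weights`` has shape (n_steps, n_walkers); returns flat arrays of
    emission times and walker indices.
    """
    # thin to steps with non-negligible weight before the Poisson draw; the
    # discarded emission probability is < 1e-7 per step
    step_idx, walker_idx = np.nonzero(weights > 1e-7 / (rate * dt))
    lam = weights[step_idx, walker_idx] * (rate * dt)
    counts = rng.poisson(lam)
    emitted = counts > 0
    c = counts[emitted]
    rep_step = np.repeat(step_idx[emitted], c)
    rep_walker = np.repeat(walker_idx[emitted], c)
    t = t0 + (rep_step + rng.random(rep_step.size)) * dt
    return t, rep_walker


# ----------------------------------------------------------------------
# trajectory mode
# ----------------------------------------------------------------------

def _simulate_trajectory(config: SimulationConfig, states: StateModel,
                         calib: FretCalibration, rng):
    L = config.box_side
    dt = config.time_step * 1e-6
    n_steps_total = int(round(config.duration / dt))
    nm = config.n_molecules
    sigma_step = np.sqrt(2.0 * config.diffusion_coeff * dt)
    wr = config.psf_waist_lateral * 1e-3   # um
    wz = config.psf_waist_axial * 1e-3

    q_d = config.peak_brightness * (1.0 + config.direct_excitation)
    q_a = config.peak_brightness * config.acceptor_brightness_ratio

    pos = rng.uniform(-L / 2, L / 2, (nm, 3))
    chunk = max(1, int(2e6 / nm))  # keep chunk arrays near ~50 MB
    d_times, d_mol, a_times, a_mol = [], [], [], []
    done = 0
    while done < n_steps_total:
        n = min(chunk, n_steps_total - done)
        steps = rng.normal(0.0, sigma_step, (n, nm, 3))
        traj = pos[None] + np.cumsum(steps, axis=0)
        pos = traj[-1].copy()
        traj -= L * np.round(traj / L)  # periodic wrap, PSF at the origin
        pos -= L * np.round(pos / L)
        w = np.exp(-2.0 * (traj[..., 0] ** 2 + traj[..., 1] ** 2) / wr ** 2
                   - 2.0 * traj[..., 2] ** 2 / wz ** 2)
        t0 = done * dt
        if q_d > 0:
            t, m = _sample_photon_times(w, t0, dt, q_d, rng)
            d_times.append(t)
            d_mol.append(m)
        if q_a > 0:
            t, m = _sample_photon_times(w, t0, dt, q_a, rng)
            a_times.append(t)
            a_mol.append(m)
        done += n

    d_times = np.concatenate(d_times) if d_times else np.empty(0)
    d_mol = np.concatenate(d_mol) if d_mol else np.empty(0, dtype=np.intp)
    a_times = np.concatenate(a_times) if a_times else np.empty(0)

    # conformational state machinery per molecule, seeded independently
    distances = np.empty(d_times.size)
    for m in range(nm):
        sub = np.random.default_rng(np.random.SeedSequence(
            entropy=config.seed, spawn_key=(1, m)))
        mask = d_mol == m
        distances[mask] = _photon_distances(
            d_times[mask], states, config, sub, config.duration)

    parts = [_emit_donor_gate(d_times, distances, config, calib, rng),
             _emit_acceptor_gate(a_times, calib, config, rng),
             _background(config, config.duration, rng)]
    return parts


# ----------------------------------------------------------------------
# event mode
# ----------------------------------------------------------------------

def _ellipsoid_entries(n, a, c, rng):
    """Points uniform per unit area on the ellipsoid (a, a, c)."""
    out = np.empty((n, 3))
    got = 0
    m_max = a * max(a, c)
    while got < n:
        k = 2 * (n - got) + 16
        u = rng.normal(size=(k, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        dens = a * np.sqrt(c ** 2 * (u[:, 0] ** 2 + u[:, 1] ** 2)
                           + a ** 2 * u[:, 2] ** 2)
        keep = rng.random(k) < dens / m_max
        pts = u[keep] * np.array([a, a, c])
        take = min(pts.shape[0], n - got)
        out[got:got + take] = pts[:take]
        got += take
    return out


_MAX_WALKERS = 4096          # concurrent walkers (bounds block memory)


def _run_passages(n, first_id, config, rng, a, c):
    """Simulate ``n`` independent passages through the observation region.

    Returns flat arrays ``(d_times, d_pid, a_times, a_pid)`` of emission
    times (s, relative to each passage's entry) and global passage ids,
    plus the per-passage durations in steps.
    """
    if n > _MAX_WALKERS:
        parts = []
        done = 0
        while done < n:
            take = min(_MAX_WALKERS, n - done)
            parts.append(_run_passages(take, first_id + done, config, rng, a, c))
            done += take
        return tuple(np.concatenate([p[i] for p in parts]) for i in range(5))
    dt = config.time_step * 1e-6
    wr = config.psf_waist_lateral * 1e-3
    wz = config.psf_waist_axial * 1e-3
    sigma_step = np.sqrt(2.0 * config.diffusion_coeff * dt)
    max_steps = int(_EVENT_MAX_PASSAGE / dt)
    q_d = config.peak_brightness * (1.0 + config.direct_excitation)
    q_a = config.peak_brightness * config.acceptor_brightness_ratio

    pos = _ellipsoid_entries(n, a, c, rng) * (1.0 - 1e-9)
    steps_done = np.zeros(n, dtype=np.int64)
    exit_step = np.full(n, max_steps, dtype=np.int64)
    d_times, d_pid, a_times, a_pid = [], [], [], []
    active_pos = pos
    active_id = np.arange(n)
    while active_id.size:
        k = _BLOCK
        steps = rng.normal(0.0, sigma_step, (k, active_id.size, 3))
        traj = active_pos[None] + np.cumsum(steps, axis=0)
        outside = ((traj[..., 0] / a) ** 2 + (traj[..., 1] / a) ** 2
                   + (traj[..., 2] / c) ** 2) > 1.0
        exited_any = outside.any(axis=0)
        first_exit = np.where(exited_any, outside.argmax(axis=0), k)
        inside = np.arange(k)[:, None] < first_exit[None, :]
        w = np.where(inside,
                     np.exp(-2.0 * (traj[..., 0] ** 2 + traj[..., 1] ** 2)
                            / wr ** 2 - 2.0 * traj[..., 2] ** 2 / wz ** 2),
                     0.0)
        if q_d > 0:
            t, widx = _sample_photon_times(w, 0.0, dt, q_d, rng)
            d_times.append(t + steps_done[active_id[widx]] * dt)
            d_pid.append(active_id[widx] + first_id)
        if q_a > 0:
            t, widx = _sample_photon_times(w, 0.0, dt, q_a, rng)
            a_times.append(t + steps_done[active_id[widx]] * dt)
            a_pid.append(active_id[widx] + first_id)

        steps_done[active_id] += np.where(exited_any, first_exit, k)
        finished = exited_any | (steps_done[active_id] >= max_steps)
        exit_step[active_id[finished]] = steps_done[active_id[finished]]
        still = ~finished
        # continuing walkers never exited, so they sit at the block end
        active_pos = traj[k - 1, still, :]
        active_id = active_id[still]

    cat = lambda lst, dtype: (np.concatenate(lst) if lst
                              else np.empty(0, dtype=dtype))
    return (cat(d_times, float), cat(d_pid, np.intp),
            cat(a_times, float), cat(a_pid, np.intp), exit_step)


def _simulate_event(config: SimulationConfig, states: StateModel,
                    calib: FretCalibration, rng):
    """Event mode: accumulate passages until ``n_bursts`` of them carry at
    least ``_EVENT_MIN_PHOTONS`` detected photons, then lay the
    photon-bearing passages out on a common time axis with generous
    spacing so that passages can never overlap."""
    dt = config.time_step * 1e-6
    wr = config.psf_waist_lateral * 1e-3
    wz = config.psf_waist_axial * 1e-3
    a = _EVENT_REGION_WAISTS * wr
    c = _EVENT_REGION_WAISTS * wz

    target = config.n_bursts
    d_times, d_pid, a_times, a_pid, durations = [], [], [], [], []
    n_done = 0
    n_good = 0
    no_light = (config.peak_brightness == 0)
    max_total = max(1000 * target, 100000)
    batch = max(512, 2 * target)
    while True:
        dt_, dp_, at_, ap_, exit_step = _run_passages(
            batch, n_done, config, rng, a, c)
        d_times.append(dt_)
        d_pid.append(dp_)
        a_times.append(at_)
        a_pid.append(ap_)
        durations.append(exit_step * dt)
        n_done += batch
        counts = np.bincount(np.concatenate([dp_, ap_]) - (n_done - batch),
                             minlength=batch)
        n_good += int((counts >= _EVENT_MIN_PHOTONS).sum())
        if n_good >= target or n_done >= max_total or no_light:
            break
        yield_est = max(n_good / n_done, 1.0 / max_total)
        batch = int(min(max(512, 1.2 * (target - n_good) / yield_est),
                        max_total - n_done))
        if batch <= 0:
            break

    d_times = np.concatenate(d_times)
    d_pid = np.concatenate(d_pid)
    a_times = np.concatenate(a_times)
    a_pid = np.concatenate(a_pid)
    durations = np.concatenate(durations)

    # conformational physics per passage, lazily and reproducibly seeded
    distances = np.empty(d_times.size)
    order = np.argsort(d_pid, kind="stable")
    d_times = d_times[order]
    d_pid = d_pid[order]
    bounds = np.searchsorted(d_pid, np.arange(n_done + 1))
    for p in range(n_done):
        lo, hi = bounds[p], bounds[p + 1]
        if lo == hi:
            continue
        sub = np.random.default_rng(np.random.SeedSequence(
            entropy=config.seed, spawn_key=(2, p)))
        distances[lo:hi] = _photon_distances(
            d_times[lo:hi], states, config, sub, max(durations[p], dt))

    # only photon-bearing passages occupy a slot on the time axis
    occupied = np.union1d(np.unique(d_pid), np.unique(a_pid))
    slot = np.full(n_done, -1, dtype=np.int64)
    slot[occupied] = np.arange(occupied.size)
    d_times = d_times + slot[d_pid] * _EVENT_SPACING
    a_times = a_times + slot[a_pid] * _EVENT_SPACING
    span = max(occupied.size, 1) * _EVENT_SPACING

    parts = [_emit_donor_gate(d_times, distances, config, calib, rng),
             _emit_acceptor_gate(a_times, calib, config, rng),
             _background(config, span, rng)]
    return parts


# ----------------------------------------------------------------------

def _config_hash(config, states, calib):
    blob = json.dumps(
        {"config": config.to_dict(),
         "states": {"states": states.states,
                    "rates": states.rate_matrix.tolist(),
                    "static": states.static_state,
                    "static_fraction": states.static_state_fraction},
         "calib": calib.to_dict()},
        sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_photon_stream(config: SimulationConfig, states: StateModel,
                           calib: FretCalibration) -> PhotonStream:
    """Run the simulator and return a time-ordered :class:`PhotonStream`.

    Identical ``(config, states, calib)`` — including ``config.seed`` —
    produce bit-identical streams.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0,)))
    if config.mode == "trajectory":
        parts = _simulate_trajectory(config, states, calib, rng)
    else:
        parts = _simulate_event(config, states, calib, rng)

    times = np.concatenate([p[0] for p in parts])
    micro = np.concatenate([p[1] for p in parts])
    chan = np.concatenate([p[2] for p in parts]).astype(np.uint8)
    gate = np.concatenate([p[3] for p in parts]).astype(np.uint8)

    meta = {
        "generator": "conformo.simulate",
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": _config_hash(config, states, calib),
        "excitation_alternation_rate_MHz": config.excitation_alternation_rate,
        "interleave_delay_ns": config.interleave_delay,
    }
    return PhotonStream.from_float_times(times, micro, chan, gate, metadata=meta)
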