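"""Shot-noise-exact forward model for photon distribution analysis.

PDA predicts the proximity-ratio histogram of time-binned single-molecule
data.  A conformational state is a Gaussian distance distribution; a
distance maps to an *apparent* acceptor probability ``eps`` through the
Förster relation and the detection corrections (gamma, beta); the
acceptor count of a bin with ``F`` detected donor-excitation photons is
then binomially distributed, optionally convolved with Poisson background
counts in both detection channels.  Dynamic PDA additionally averages the
two exchanging states' ``eps`` over the occupancy-time distribution of a
two-state Markov chain within the bin.

The expensive shot-noise part depends only on the dataset (its empirical
photon-count distribution, background and corrections) — never on the
model parameters — so it is precomputed once as a kernel matrix
``M[eps_grid, histogram_bin]``.  Evaluating a model then reduces to
building a mixture weight vector over the ``eps`` grid and one matrix
product, which makes simplex fitting and profile-likelihood confidence
intervals cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from ..fret import distance_to_efficiency, apparent_acceptor_probability
from .dataset import PdaDataset
from .occupancy import occupancy_time_distribution

__all__ = [
    "PdaModel",
    "PdaKernel",
    "default_epr_edges",
    "static_pda_histogram",
    "dynamic_pda_histogram",
    "fast_exchange_histogram",
    "sample_pda_bins",
]

N_EPS = 201
_R_NODES = 21
_R_NODES_DYN = 25   # nodes per state in the dynamic triple integral (fitting)
_N_OCC_FIT = 97     # occupancy nodes during fitting
_N_OCC_EXACT = 257  # occupancy nodes for reference histograms


def default_epr_edges(n_bins=51):
    """Proximity-ratio histogram bin edges on [0, 1]."""
    return np.linspace(0.0, 1.0, n_bins + 1)


# ----------------------------------------------------------------------
# model parameters
# ----------------------------------------------------------------------

@dataclass
class PdaModel:
    """Three-state PDA model with global/per-dataset parameter linking.

    States 1 and 2 interconvert; state 3 is static.  ``R1``, ``R2``,
    ``R_static`` (Å) and the width fraction (``sigma_i = width_fraction *
    R_i``) are global over all datasets.  Per dataset: either the
    interconversion rates ``k12``/``k21`` in 1/ms plus the static-state
    area ``A3`` (``kind="dynamic"``), or the three state areas
    (``kind="static"``, rates ignored, frozen states).
    """

    R1: float
    R2: float
    R_static: float = 0.0
    width_fraction: float = 0.08
    forster_radius: float = 53.0
    linker_width: float = 0.0
    kind: str = "dynamic"
    k12: list = field(default_factory=list)       # per dataset, 1/ms
    k21: list = field(default_factory=list)
    A3: list = field(default_factory=list)        # per dataset
    areas: list = field(default_factory=list)     # per dataset (A1, A2, A3)

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0 or self.R_static < 0:
            raise ValueError("state distances must be positive")
        if not 0.0 < self.width_fraction < 1.0:
            raise ValueError("width_fraction must be in (0, 1)")
        if self.linker_width < 0:
            raise ValueError("linker_width must be non-negative")
        if self.kind not in ("dynamic", "static"):
            raise ValueError("kind must be 'dynamic' or 'static'")
        if self.kind == "dynamic":
            if any(k < 0 for k in list(self.k12) + list(self.k21)):
                raise ValueError("rates must be non-negative")
            if any(not 0 <= a <= 1 for a in self.A3):
                raise ValueError("A3 must be in [0, 1]")
        else:
            for a in self.areas:
                if len(a) != 3 or min(a) < -1e-12 or abs(sum(a) - 1) > 1e-6:
                    raise ValueError("areas must be 3 non-negative numbers "
                                     "summing to 1 per dataset")

    @property
    def n_datasets(self):
        return len(self.A3) if self.kind == "dynamic" else len(self.areas)

    def sigma(self, R):
        return self.width_fraction * R

    def copy(self, **kw):
        return replace(self, **kw)


# ----------------------------------------------------------------------
# shot-noise kernel
# ----------------------------------------------------------------------

def _poisson_weights(mean, tail=1e-6):
    """Truncated, renormalized Poisson pmf."""
    if mean <= 0:
        return np.array([1.0])
    kmax = 1
    while True:
        k = np.arange(kmax + 1)
        logp = k * np.log(mean) - mean - gammaln(k + 1)
        p = np.exp(logp)
        if 1.0 - p.sum() < tail or kmax > 200:
            return p / p.sum()
        kmax *= 2


class PdaKernel:
    """Precomputed mapping from an ``eps`` mixture to expected bin counts.

    Parameters
    ----------
    f_counts : array of int
        Donor-excitation photon count of every retained time bin.
    T_ms : float
        Bin duration in ms (used for the background means).
    edges : ndarray
        Proximity-ratio histogram edges.
    background_donor, background_acceptor : float
        Donor-gate background rates (counts/s) reaching the donor and
        acceptor channels.
    n_eps : int
        Resolution of the apparent-acceptor-probability grid.
    """

    def __init__(self, f_counts, T_ms, edges, background_donor=0.0,
                 background_acceptor=0.0, n_eps=None):
        f_counts = np.asarray(f_counts, dtype=np.int64)
        if f_counts.size == 0:
            raise ValueError("empty photon-count distribution")
        self.edges = np.asarray(edges, dtype=float)
        self.n_bins = self.edges.size - 1
        self.n_total = f_counts.size
        n_eps = N_EPS if n_eps is None else n_eps
        self.eps_grid = np.linspace(0.0, 1.0, n_eps)
        self.T_ms = T_ms

        bd = _poisson_weights(background_donor * T_ms * 1e-3)
        ba = _poisson_weights(background_acceptor * T_ms * 1e-3)
        p = np.clip(self.eps_grid, 1e-12, 1.0 - 1e-12)[:, None]
        logp, log1mp = np.log(p), np.log1p(-p)

        uniq, counts = np.unique(f_counts, return_counts=True)
        M = np.zeros((n_eps, self.n_bins))
        for F, nF in zip(uniq, counts):
            sa = np.arange(F + 1)
            prob = np.zeros((n_eps, F + 1))
            for ib, wb in enumerate(ba):
                for id_, wd in enumerate(bd):
                    nfl = F - ib - id_
                    if nfl < 0:
                        continue
                    k = np.arange(nfl + 1)
                    lg = (gammaln(nfl + 1) - gammaln(k + 1)
                          - gammaln(nfl - k + 1))
                    pm = np.exp(lg + k * logp + (nfl - k) * log1mp)
                    prob[:, ib:ib + nfl + 1] += (wb * wd) * pm
            # map acceptor counts to histogram bins; SA/F is increasing so
            # the bin index is sorted and reduceat applies
            bidx = np.minimum(np.searchsorted(self.edges, sa / F,
                                              side="right") - 1,
                              self.n_bins - 1)
            bidx = np.maximum(bidx, 0)
            starts = np.searchsorted(bidx, np.arange(self.n_bins), side="left")
            empty = starts == np.append(starts[1:], F + 1)
            red = np.add.reduceat(prob, np.minimum(starts, F), axis=1)
            # reduceat repeats values for empty segments; zero them out
            red[:, empty] = 0.0
            M += nF * red
        self.M = M

    def expected(self, eps_weights):
        """Expected histogram counts for a normalized eps mixture."""
        return eps_weights @ self.M


def _deposit(eps_values, weights, grid, out):
    """Linear-interpolation deposit of point masses onto the eps grid."""
    x = np.clip(np.asarray(eps_values, dtype=float).ravel(), 0.0, 1.0) \
        * (grid.size - 1)
    wt = np.asarray(weights, dtype=float).ravel()
    i0 = np.minimum(x.astype(np.intp), grid.size - 2)
    frac = x - i0
    out += np.bincount(i0, wt * (1.0 - frac), minlength=grid.size)
    out += np.bincount(i0 + 1, wt * frac, minlength=grid.size)


_EPS_CURVE_CACHE = {}


def _eps_curve(r0, gamma, beta, linker_width):
    """Monotone apparent-acceptor-probability curve eps(R), optionally
    smoothed over a Gaussian per-photon linker jitter.

    Fast dye-linker motion redraws the distance photon by photon, so each
    photon's acceptance probability is the jitter-averaged
    ``eps_eff(R) = E_delta[eps(R + delta)]``; because the jitter is
    independent per photon the bin counts stay exactly binomial in this
    smoothed probability.  Returns ``(r_ascending, eps_values)``.
    """
    key = (round(r0, 9), round(gamma, 9), round(beta, 9),
           round(linker_width, 9))
    if key not in _EPS_CURVE_CACHE:
        r = np.linspace(1e-3, 6.0 * r0, 8192)
        eps = apparent_acceptor_probability(
            distance_to_efficiency(r, r0), gamma, beta)
        if linker_width > 0:
            from scipy.ndimage import gaussian_filter1d

            dr = r[1] - r[0]
            eps = gaussian_filter1d(eps, linker_width / dr, mode="nearest")
        if len(_EPS_CURVE_CACHE) > 64:
            _EPS_CURVE_CACHE.clear()
        _EPS_CURVE_CACHE[key] = (r, eps)
    return _EPS_CURVE_CACHE[key]


_HERMEGAUSS_CACHE = {}


def _gauss_nodes(mean, sigma, n=_R_NODES):
    """Gauss-Hermite nodes/weights of a Gaussian distance distribution."""
    if sigma <= 0:
        return np.array([mean]), np.array([1.0])
    if n not in _HERMEGAUSS_CACHE:
        z, w = np.polynomial.hermite_e.hermegauss(n)
        _HERMEGAUSS_CACHE[n] = (z, w / w.sum())
    z, w = _HERMEGAUSS_CACHE[n]
    return np.maximum(mean + sigma * z, 1e-3), w


def _eps_of_R(R, model: PdaModel, dataset: PdaDataset):
    r_tab, eps_tab = _eps_curve(model.forster_radius, dataset.gamma,
                                dataset.beta, model.linker_width)
    return np.interp(np.asarray(R, dtype=float), r_tab, eps_tab)


def _deposit_gaussian_state(mean, sigma, grid, area, out, r0, gamma, beta,
                            linker_width=0.0):
    """Exact deposit of one Gaussian distance state onto the eps grid.

    ``eps(R)`` is strictly decreasing in R, so the mass of each eps-grid
    cell is a difference of Gaussian CDFs of the inverted cell edges — no
    quadrature nodes, hence no spike artefacts at large photon counts.
    """
    from scipy.special import ndtr

    r_asc, eps_vals = _eps_curve(r0, gamma, beta, linker_width)
    if sigma <= 0:
        eps = np.interp([max(mean, 1e-3)], r_asc, eps_vals)
        _deposit(np.asarray(eps), np.array([area]), grid, out)
        return
    # monotone table eps (ascending) <-> R (descending)
    eps_tab = eps_vals[::-1]
    r_tab = r_asc[::-1]
    cell_edges = np.concatenate([[0.0],
                                 0.5 * (grid[:-1] + grid[1:]),
                                 [1.0]])
    r_edges = np.interp(cell_edges, eps_tab, r_tab)
    # eps below the physical minimum maps to the table's largest R; treat
    # the lowest cell edge as R = +inf so tail mass is conserved
    z = (r_edges - mean) / sigma
    cdf = ndtr(z)
    cdf[0] = 1.0   # eps >= 0 corresponds to all of R < inf
    cdf[-1] = 0.0  # eps <= 1 corresponds to R > -inf (fold R<0 tail in)
    out += area * (cdf[:-1] - cdf[1:])


# ----------------------------------------------------------------------
# eps mixtures
# ----------------------------------------------------------------------

def _eps_weights_static(model, dataset, d, grid):
    w = np.zeros(grid.size)
    for (R, area) in zip((model.R1, model.R2, model.R_static),
                         model.areas[d]):
        if area <= 0:
            continue
        _deposit_gaussian_state(R, model.sigma(R), grid, area, w,
                                model.forster_radius, dataset.gamma,
                                dataset.beta, model.linker_width)
    return w


def _eps_weights_dynamic(model, dataset, d, T_ms, grid, n_occupancy=_N_OCC_FIT):
    w = np.zeros(grid.size)
    a3 = model.A3[d]
    if a3 > 0 and model.R_static > 0:
        _deposit_gaussian_state(model.R_static, model.sigma(model.R_static),
                                grid, a3, w, model.forster_radius,
                                dataset.gamma, dataset.beta,
                                model.linker_width)
    a_dyn = 1.0 - a3
    if a_dyn <= 0:
        return w
    r1, g1 = _gauss_nodes(model.R1, model.sigma(model.R1), _R_NODES_DYN)
    r2, g2 = _gauss_nodes(model.R2, model.sigma(model.R2), _R_NODES_DYN)
    e1 = _eps_of_R(r1, model, dataset)
    e2 = _eps_of_R(r2, model, dataset)
    occ = occupancy_time_distribution(model.k12[d], model.k21[d], T_ms)
    if occ.p_full > 0:
        _deposit_gaussian_state(model.R1, model.sigma(model.R1), grid,
                                a_dyn * occ.p_full, w, model.forster_radius,
                                dataset.gamma, dataset.beta,
                                model.linker_width)
    if occ.p_zero > 0:
        _deposit_gaussian_state(model.R2, model.sigma(model.R2), grid,
                                a_dyn * occ.p_zero, w, model.forster_radius,
                                dataset.gamma, dataset.beta,
                                model.linker_width)
    t1, wt = occ.nodes(n_occupancy)
    if t1.size:
        frac = (t1 / T_ms)[None, None, :]
        eps_bar = (e1[:, None, None] * frac
                   + e2[None, :, None] * (1.0 - frac))
        ww = (g1[:, None, None] * g2[None, :, None] * wt[None, None, :])
        _deposit(eps_bar.ravel(), a_dyn * ww.ravel(), grid, w)
    return w


def _eps_weights_fast_exchange(model, dataset, d, grid):
    """k -> infinity limit: each molecule shows the time-averaged eps."""
    w = np.zeros(grid.size)
    a3 = model.A3[d]
    if a3 > 0 and model.R_static > 0:
        r, g = _gauss_nodes(model.R_static, model.sigma(model.R_static))
        _deposit(_eps_of_R(r, model, dataset), a3 * g, grid, w)
    k12, k21 = model.k12[d], model.k21[d]
    p1 = 0.5 if k12 + k21 == 0 else k21 / (k12 + k21)
    r1, g1 = _gauss_nodes(model.R1, model.sigma(model.R1))
    r2, g2 = _gauss_nodes(model.R2, model.sigma(model.R2))
    e1 = _eps_of_R(r1, model, dataset)
    e2 = _eps_of_R(r2, model, dataset)
    eps_bar = p1 * e1[:, None] + (1.0 - p1) * e2[None, :]
    ww = g1[:, None] * g2[None, :]
    _deposit(eps_bar.ravel(), (1.0 - a3) * ww.ravel(), grid, w)
    return w


# ----------------------------------------------------------------------
# public forward operations
# ----------------------------------------------------------------------

def _kernel_for(dataset, T_ms, edges, n_eps=None):
    f, _ = dataset.bins[T_ms]
    return PdaKernel(f, T_ms, edges, dataset.background_donor,
                     dataset.background_acceptor, n_eps)


def static_pda_histogram(states, dataset: PdaDataset, T_ms, edges=None,
                         forster_radius=53.0):
    """Expected proximity-ratio histogram for frozen Gaussian states.

    ``states`` is a list of ``(R, sigma, area)`` with areas summing to 1;
    the photon-count distribution, corrections and background are taken
    from ``dataset`` at bin duration ``T_ms``.
    """
    areas = np.array([a for _, _, a in states], dtype=float)
    sig = [s for _, s, _ in states]
    if np.any(np.asarray(sig) < 0):
        raise ValueError("state widths must be non-negative")
    if abs(areas.sum() - 1.0) > 1e-6:
        raise ValueError("state areas must sum to 1")
    if T_ms not in dataset.bins:
        raise ValueError(f"dataset has no {T_ms}-ms bins")
    edges = default_epr_edges() if edges is None else edges
    if all(s == 0 for _, s, _ in states):
        # zero-width states are exact binomial mixtures; skip the eps grid
        return _delta_state_histogram(states, dataset, T_ms, edges,
                                      forster_radius)
    kern = _kernel_for(dataset, T_ms, edges)
    w = np.zeros(kern.eps_grid.size)
    for (R, s, a) in states:
        _deposit_gaussian_state(R, s, kern.eps_grid, a, w, forster_radius,
                                dataset.gamma, dataset.beta)
    return kern.expected(w)


def _delta_state_histogram(states, dataset, T_ms, edges, forster_radius):
    eps = np.array([apparent_acceptor_probability(
        distance_to_efficiency(np.array([R]), forster_radius),
        dataset.gamma, dataset.beta)[0] for R, _, _ in states])
    areas = np.array([a for _, _, a in states])
    f, _ = dataset.bins[T_ms]
    bd = _poisson_weights(dataset.background_donor * T_ms * 1e-3)
    ba = _poisson_weights(dataset.background_acceptor * T_ms * 1e-3)
    from scipy.stats import binom as _binom

    n_bins = edges.size - 1
    out = np.zeros(n_bins)
    uniq, counts = np.unique(np.asarray(f, dtype=np.int64),
                             return_counts=True)
    for F, nF in zip(uniq, counts):
        sa = np.arange(F + 1)
        prob = np.zeros(F + 1)
        for e, a in zip(eps, areas):
            for ib, wb in enumerate(ba):
                for id_, wd in enumerate(bd):
                    nfl = F - ib - id_
                    if nfl < 0:
                        continue
                    prob[ib:ib + nfl + 1] += (a * wb * wd) * _binom.pmf(
                        np.arange(nfl + 1), nfl, e)
        bidx = np.clip(np.searchsorted(edges, sa / F, side="right") - 1,
                       0, n_bins - 1)
        out += nF * np.bincount(bidx, prob, minlength=n_bins)
    return out


def dynamic_pda_histogram(model: PdaModel, dataset: PdaDataset, T_ms,
                          d=0, edges=None):
    """Expected histogram of the three-state dynamic model."""
    if T_ms not in dataset.bins:
        raise ValueError(f"dataset has no {T_ms}-ms bins")
    edges = default_epr_edges() if edges is None else edges
    kern = _kernel_for(dataset, T_ms, edges)
    if model.kind == "static":
        w = _eps_weights_static(model, dataset, d, kern.eps_grid)
    else:
        w = _eps_weights_dynamic(model, dataset, d, T_ms, kern.eps_grid,
                                 n_occupancy=_N_OCC_EXACT)
    return kern.expected(w)


def fast_exchange_histogram(model: PdaModel, dataset: PdaDataset, T_ms,
                            d=0, edges=None):
    """Analytic infinite-rate limit of the dynamic model."""
    edges = default_epr_edges() if edges is None else edges
    kern = _kernel_for(dataset, T_ms, edges)
    w = _eps_weights_fast_exchange(model, dataset, d, kern.eps_grid)
    return kern.expected(w)


# ----------------------------------------------------------------------
# Monte-Carlo sampler (stochastic oracle / data generator)
# ----------------------------------------------------------------------

def sample_pda_bins(model: PdaModel, f_counts, T_ms, dataset_like, rng, d=0):
    """Sample acceptor counts per bin by direct simulation.

    Per bin: static/dynamic assignment, Gaussian distance draws, exact
    Gillespie occupancy time, occupancy-weighted ``eps`` and a binomial
    acceptor count.  Background is not sampled (use background-free
    datasets as oracles).  Returns the ``SA`` array matching ``f_counts``.
    """
    from ..simulate.ctmc import sample_occupancy_times

    f = np.asarray(f_counts, dtype=np.int64)
    n = f.size
    eps = np.empty(n)
    if model.kind == "static":
        a1, a2, a3 = model.areas[d]
        choice = rng.choice(3, size=n, p=[a1, a2, a3])
        Rm = np.array([model.R1, model.R2, model.R_static])
        R = rng.normal(Rm[choice], model.sigma(Rm[choice]))
        eps = _eps_of_R(np.maximum(R, 1e-3), model, dataset_like)
    else:
        a3 = model.A3[d]
        is_static = rng.random(n) < a3
        R3 = rng.normal(model.R_static, model.sigma(model.R_static),
                        size=n)
        eps3 = _eps_of_R(np.maximum(R3, 1e-3), model, dataset_like)
        t1 = sample_occupancy_times(model.k12[d], model.k21[d], T_ms,
                                    n, rng)
        R1 = rng.normal(model.R1, model.sigma(model.R1), size=n)
        R2 = rng.normal(model.R2, model.sigma(model.R2), size=n)
        e1 = _eps_of_R(np.maximum(R1, 1e-3), model, dataset_like)
        e2 = _eps_of_R(np.maximum(R2, 1e-3), model, dataset_like)
        frac = t1 / T_ms
        eps_dyn = frac * e1 + (1.0 - frac) * e2
        eps = np.where(is_static, eps3, eps_dyn)
    return rng.binomial(f, np.clip(eps, 0.0, 1.0))
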