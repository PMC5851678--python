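"""Time-bin datasets for photon distribution analysis.

Accepted bursts are re-cut into consecutive bins of several durations
(0.2, 0.5, 0.75 and 1 ms by default; the trailing partial bin of each
burst is discarded).  Per bin the *donor-excitation* photon counts are
kept: ``F`` (all donor-gate photons) and the acceptor share ``SA``
(donor-gate, red channel), giving the uncorrected proximity ratio
``E_PR = SA / F``.  Bins outside the photon-count bounds (20..250 by
default) or outside the stoichiometry selection region — which removes
bins with complex acceptor photophysics and donor-/acceptor-only
molecules — are dropped.  Correction factors and background rates are
carried on the dataset and consumed inside the PDA forward model, never
applied to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PdaDataset", "rebin_bursts", "DEFAULT_BIN_DURATIONS"]

DEFAULT_BIN_DURATIONS = (0.2, 0.5, 0.75, 1.0)  # ms


@dataclass
class PdaDataset:
    """Binned proximity-ratio data of one sample.

    ``bins`` maps bin duration (ms) to an ``(F, SA)`` pair of integer
    arrays over the retained bins.  ``gamma``/``beta`` and the donor-gate
    background rates (counts/s reaching the donor and acceptor detection
    channels) parameterize the forward model.
    """

    label: str = ""
    bins: dict = field(default_factory=dict)
    burst_ids: dict = field(default_factory=dict)
    gamma: float = 1.0
    beta: float = 0.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    min_photons: int = 20
    max_photons: int = 250

    def __post_init__(self):
        for T, (f, sa) in self.bins.items():
            f = np.asarray(f, dtype=np.int64)
            sa = np.asarray(sa, dtype=np.int64)
            if f.size != sa.size:
                raise ValueError(f"F/SA length mismatch for T={T}")
            if np.any(sa > f) or np.any(sa < 0):
                raise ValueError("acceptor counts must be within [0, F]")
            self.bins[T] = (f, sa)
            if T in self.burst_ids and len(self.burst_ids[T]) != f.size:
                raise ValueError(f"burst_ids length mismatch for T={T}")

    @property
    def bin_durations(self):
        return sorted(self.bins)

    def n_bins(self, T):
        return self.bins[T][0].size

    def histogram(self, T, edges):
        """Observed proximity-ratio histogram for bin duration ``T`` ms."""
        f, sa = self.bins[T]
        return epr_histogram(f, sa, edges)

    def independent_subset(self, T):
        """One bin per burst for duration ``T`` (requires burst ids).

        Consecutive bins of a burst share the molecule's state path, so
        they are statistically dependent; this subset (the first retained
        bin of each burst) restores the independence that plain
        chi-square and runs tests assume.
        """
        if T not in self.burst_ids:
            raise ValueError("dataset carries no burst provenance")
        f, sa = self.bins[T]
        ids = np.asarray(self.burst_ids[T])
        _, first = np.unique(ids, return_index=True)
        return PdaDataset(label=f"{self.label} (1 bin/burst)",
                          bins={T: (f[first], sa[first])},
                          gamma=self.gamma, beta=self.beta,
                          background_donor=self.background_donor,
                          background_acceptor=self.background_acceptor,
                          min_photons=self.min_photons,
                          max_photons=self.max_photons)


def epr_histogram(f, sa, edges):
    """Histogram of proximity ratios ``sa/f`` over ``edges``.

    Uses the same left-inclusive ``searchsorted`` convention and the same
    floating-point division as the PDA forward kernel, so edge-exact
    ratios (e.g. ``sa/f`` landing precisely on a bin edge) land in the
    same bin on both sides of a comparison.
    """
    f = np.asarray(f)
    sa = np.asarray(sa)
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, sa / f, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    return np.bincount(idx, minlength=edges.size - 1)


def rebin_bursts(table, bin_durations_ms=DEFAULT_BIN_DURATIONS,
                 min_photons=20, max_photons=250, s_region=(0.3, 0.8),
                 gamma=1.0, beta=0.0, background_donor=0.0,
                 background_acceptor=0.0, label=""):
    """Cut bursts into fixed-duration bins and build a :class:`PdaDataset`.

    Parameters
    ----------
    table : BurstTable
        Bursts carrying photon-level data (post ALEX-2CDE filtering).
    bin_durations_ms : sequence of float
        Bin durations in ms; each duration yields its own histogram.
    min_photons, max_photons : int
        Donor-excitation photon-count bounds per retained bin.
    s_region : (float, float) or None
        Keep bins whose raw stoichiometry ``F / (F + RR)`` lies inside the
        closed interval; ``None`` disables the selection.
    gamma, beta, background_donor, background_acceptor :
        Correction parameters stored on the dataset for the forward model.

    Raises
    ------
    ValueError
        If no bin survives, naming the responsible filter.
    """
    stream = table.stream
    t = stream.times
    dg = stream.gates == 0
    red = stream.is_acceptor_channel()

    bins = {}
    burst_ids = {}
    for T_ms in bin_durations_ms:
        T = T_ms * 1e-3
        f_all, sa_all, rr_all, id_all = [], [], [], []
        n_cut = 0
        for i in range(len(table)):
            sl = table.photon_slice(i)
            tt = t[sl]
            rel = tt - tt[0]
            n_full = int(np.floor((rel[-1]) / T))
            if n_full < 1:
                continue
            idx = np.minimum((rel / T).astype(np.intp), n_full)
            inside = idx < n_full
            bidx = idx[inside]
            w_dg = dg[sl][inside]
            w_red = red[sl][inside]
            f = np.bincount(bidx[w_dg], minlength=n_full)
            sa = np.bincount(bidx[w_dg & w_red], minlength=n_full)
            rr = np.bincount(bidx[~w_dg & w_red], minlength=n_full)
            f_all.append(f)
            sa_all.append(sa)
            rr_all.append(rr)
            id_all.append(np.full(n_full, i, dtype=np.int64))
            n_cut += n_full
        if not f_all:
            raise ValueError(
                f"no bins of {T_ms} ms could be cut (bursts shorter than the "
                "bin duration)")
        f = np.concatenate(f_all)
        sa = np.concatenate(sa_all)
        rr = np.concatenate(rr_all)
        bid = np.concatenate(id_all)
        keep = (f >= min_photons) & (f <= max_photons)
        if s_region is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.where(f + rr > 0, f / (f + rr), np.nan)
            keep &= (s >= s_region[0]) & (s <= s_region[1])
        if not keep.any():
            raise ValueError(
                f"no {T_ms}-ms bin survived the photon-count bounds "
                f"[{min_photons}, {max_photons}] and S region {s_region}")
        bins[T_ms] = (f[keep], sa[keep])
        burst_ids[T_ms] = bid[keep]
    return PdaDataset(label=label, bins=bins, burst_ids=burst_ids,
                      gamma=gamma, beta=beta,
                      background_donor=background_donor,
                      background_acceptor=background_acceptor,
                      min_photons=min_photons, max_photons=max_photons)
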