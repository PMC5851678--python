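"""All-photon sliding-window burst search.

A photon is *in a burst region* iff at least ``min_per_window`` photons
(all detection channels and both excitation gates pooled) fall inside a
window of length ``window`` centred on it, the window taken as the
half-open interval ``[t - w/2, t + w/2)``.  Maximal runs of consecutive
in-region photons form candidate bursts; candidates with fewer than
``min_total`` photons are discarded.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sliding_window_burst_search", "burst_region_mask"]


def burst_region_mask(times, window, min_per_window):
    """Boolean in-burst-region flag per photon (times in s, window in s)."""
    t = np.asarray(times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("photon stream must be time-ordered")
    lo = np.searchsorted(t, t - window / 2.0, side="left")
    hi = np.searchsorted(t, t + window / 2.0, side="left")
    return (hi - lo) >= min_per_window


def sliding_window_burst_search(stream, window_us=500.0, min_per_window=5,
                                min_total=50):
    """Identify single-molecule bursts in a photon stream.

    Parameters
    ----------
    stream : PhotonStream
        Time-ordered photons (all channels/gates are pooled for the search).
    window_us : float
        Sliding window length in microseconds.
    min_per_window : int
        Minimum photons within the window centred on a photon for it to be
        part of a burst region.
    min_total : int
        Minimum photons for a candidate burst to be kept.

    Returns
    -------
    BurstTable
        Table of bursts with raw per-class counts (empty for an empty or
        burst-free stream).
    """
    from .table import BurstTable

    if window_us <= 0 or min_per_window <= 0 or min_total <= 0:
        raise ValueError("burst-search thresholds must be positive")
    t = stream.times
    if t.size == 0:
        return BurstTable.empty(stream)
    mask = burst_region_mask(t, window_us * 1e-6, min_per_window)
    if not mask.any():
        return BurstTable.empty(stream)
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        stops = np.concatenate([stops, [mask.size]])
    keep = (stops - starts) >= min_total
    return BurstTable(stream, starts[keep], stops[keep])
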