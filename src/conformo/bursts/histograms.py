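"""Multiparameter burst histograms (E vs lifetime, E vs stoichiometry)."""

from __future__ import annotations

import numpy as np

__all__ = ["multiparameter_histograms", "plot_multiparameter"]


def multiparameter_histograms(df, bins_e=41, bins_tau=41, bins_s=41,
                              e_range=(-0.1, 1.1), tau_range=None,
                              s_range=(-0.1, 1.1)):
    """2D histograms E vs tau_DA and E vs S with 1D projections.

    Bursts with NaN in a pair are excluded from that histogram only.
    Returns a dict of ``(counts, x_edges, y_edges)`` triples plus the 1D
    projections; the marginal sums of each 2D histogram equal the
    projections by construction.
    """
    e = df["E"].to_numpy(float)
    out = {}
    if "tau_DA" in df:
        tau = df["tau_DA"].to_numpy(float)
        ok = np.isfinite(e) & np.isfinite(tau)
        tr = tau_range or (0.0, max(1.0, np.nanmax(tau[ok]) if ok.any() else 1.0))
        h, xe, ye = np.histogram2d(tau[ok], e[ok], bins=(bins_tau, bins_e),
                                   range=(tr, e_range))
        out["E_vs_tau"] = (h, xe, ye)
        out["proj_tau"] = h.sum(axis=1)
        out["proj_E_tau"] = h.sum(axis=0)
    if "S" in df:
        s = df["S"].to_numpy(float)
        ok = np.isfinite(e) & np.isfinite(s)
        h, xe, ye = np.histogram2d(e[ok], s[ok], bins=(bins_e, bins_s),
                                   range=(e_range, s_range))
        out["E_vs_S"] = (h, xe, ye)
        out["proj_E_S"] = h.sum(axis=1)
        out["proj_S"] = h.sum(axis=0)
    return out


def plot_multiparameter(hists, z_offset=0.15, fret_line=None, ax=None):
    """Render the E-vs-lifetime histogram.

    ``z_offset`` applies a display floor at the given fraction of the
    maximum *only to the rendered image* — the histogram data are never
    modified.  Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    h, xe, ye = hists["E_vs_tau"]
    img = h.T.copy()
    if z_offset:
        img[img < z_offset * img.max()] = 0.0
    ax.pcolormesh(xe, ye, img, cmap="viridis")
    if fret_line is not None:
        ax.plot(fret_line.tau, fret_line.efficiency, "k-", lw=1)
    ax.set_xlabel(r"$\tau_{D(A)}$ (ns)")
    ax.set_ylabel("E")
    return ax
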