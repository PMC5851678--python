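"""Per-burst containers and the burst-wise analysis pipeline.

A :class:`BurstTable` references the parent photon stream and stores, for
each burst, the photon index range plus a growing :class:`pandas.DataFrame`
of burst-wise quantities.  Signal classes follow the two-color
nomenclature: ``BB`` blue-excited blue-detected (donor), ``BR``
blue-excited red-detected (FRET acceptor), ``RR`` red-excited red-detected
(direct acceptor); each is the sum of its two polarization channels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filters import alex_2cde
from .lifetime import mle_lifetime
from .anisotropy import burst_anisotropy

__all__ = ["BurstTable"]


class BurstTable:
    """Bursts of one photon stream.

    Attributes
    ----------
    stream : PhotonStream
    starts, stops : ndarray of int
        Photon index ranges ``[start, stop)`` per burst.
    df : pandas.DataFrame
        One row per burst; populated by :meth:`compute_counts` (always run)
        and the optional analysis steps.
    """

    def __init__(self, stream, starts, stops):
        self.stream = stream
        self.starts = np.asarray(starts, dtype=np.intp)
        self.stops = np.asarray(stops, dtype=np.intp)
        if self.starts.size != self.stops.size:
            raise ValueError("starts/stops length mismatch")
        self.df = pd.DataFrame(index=pd.RangeIndex(self.starts.size))
        self.compute_counts()

    @classmethod
    def empty(cls, stream):
        return cls(stream, np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp))

    def __len__(self):
        return self.starts.size

    # ------------------------------------------------------------------
    def photon_slice(self, i):
        """Indices of the photons of burst ``i``."""
        return slice(int(self.starts[i]), int(self.stops[i]))

    def _segment_sum(self, values):
        """Sum a per-photon array over each burst."""
        c = np.concatenate([[0], np.cumsum(values)])
        return c[self.stops] - c[self.starts]

    def compute_counts(self):
        s = self.stream
        t = s.times
        n = len(self)
        if n == 0:
            for col in ("start", "stop", "duration", "n_photons",
                        "S_BB", "S_BR", "S_RR",
                        "S_BB_par", "S_BB_perp", "S_BR_par", "S_BR_perp",
                        "S_RR_par", "S_RR_perp"):
                self.df[col] = np.empty(0)
            return self
        dg = s.gates == 0
        donor_ch = s.is_donor_channel()
        par = (s.channels == 0) | (s.channels == 2)
        self.df["start"] = t[self.starts]
        self.df["stop"] = t[self.stops - 1]
        self.df["duration"] = self.df["stop"] - self.df["start"]
        self.df["n_photons"] = self.stops - self.starts
        combos = {
            "S_BB": dg & donor_ch,
            "S_BR": dg & ~donor_ch,
            "S_RR": ~dg & ~donor_ch,
            "S_BB_par": dg & donor_ch & par,
            "S_BB_perp": dg & donor_ch & ~par,
            "S_BR_par": dg & ~donor_ch & par,
            "S_BR_perp": dg & ~donor_ch & ~par,
            "S_RR_par": ~dg & ~donor_ch & par,
            "S_RR_perp": ~dg & ~donor_ch & ~par,
        }
        for name, m in combos.items():
            self.df[name] = self._segment_sum(m.astype(np.int64)).astype(int)
        return self

    # ------------------------------------------------------------------
    def compute_alex_2cde(self, kde_time_constant_us=100.0):
        """ALEX-2CDE filter score per burst (low = well interleaved)."""
        t = self.stream.times
        g = self.stream.gates
        scores = np.empty(len(self))
        for i in range(len(self)):
            sl = self.photon_slice(i)
            scores[i] = alex_2cde(t[sl], g[sl],
                                  kde_time_constant_us * 1e-6)
        self.df["alex_2cde"] = scores
        return self

    def compute_corrections(self, corrections):
        """Background-corrected counts, FRET efficiency and stoichiometry."""
        from .corrections import correct_and_score

        out = correct_and_score(
            self.df["S_BB"].to_numpy(float),
            self.df["S_BR"].to_numpy(float),
            self.df["S_RR"].to_numpy(float),
            self.df["duration"].to_numpy(float),
            corrections,
        )
        for k, v in out.items():
            self.df[k] = v
        return self

    def compute_lifetimes(self, min_photons=10):
        """Burst-wise MLE donor and acceptor lifetimes (ns)."""
        s = self.stream
        micro = s.microtimes_ns
        window_ns = s.tcspc_range * 1e9
        dg = s.gates == 0
        donor_ch = s.is_donor_channel()
        tau_d = np.full(len(self), np.nan)
        tau_a = np.full(len(self), np.nan)
        for i in range(len(self)):
            sl = self.photon_slice(i)
            md = micro[sl][dg[sl] & donor_ch[sl]]
            ma = micro[sl][~dg[sl] & ~donor_ch[sl]]
            if md.size >= min_photons:
                tau_d[i] = mle_lifetime(md, window_ns, min_photons=min_photons)
            if ma.size >= min_photons:
                tau_a[i] = mle_lifetime(ma, window_ns, min_photons=min_photons)
        self.df["tau_DA"] = tau_d
        self.df["tau_A"] = tau_a
        return self

    def compute_anisotropies(self, g_factor=1.0):
        """Steady-state donor and acceptor anisotropy per burst."""
        self.df["r_D"] = burst_anisotropy(
            self.df["S_BB_par"].to_numpy(float),
            self.df["S_BB_perp"].to_numpy(float), g_factor)
        self.df["r_A"] = burst_anisotropy(
            self.df["S_RR_par"].to_numpy(float),
            self.df["S_RR_perp"].to_numpy(float), g_factor)
        return self

    # ------------------------------------------------------------------
    def select(self, mask):
        """New table restricted to bursts where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        out = BurstTable(self.stream, self.starts[mask], self.stops[mask])
        out.df = self.df.loc[mask].reset_index(drop=True)
        return out

    def filter_alex_2cde(self, max_score=12.0):
        if "alex_2cde" not in self.df:
            self.compute_alex_2cde()
        return self.select(self.df["alex_2cde"].to_numpy() < max_score)

    def burst_photon_times(self):
        """List of per-burst photon time arrays (s, absolute)."""
        t = self.stream.times
        return [t[self.photon_slice(i)] for i in range(len(self))]

    def to_csv(self, path):
        self.df.to_csv(path, index=False)
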