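"""Time-tagged photon records for real or simulated experiments.

A :class:`PhotonStream` is the format-neutral in-memory model of a
time-correlated single-photon counting acquisition with pulsed interleaved
excitation: macrotimes (integer clock ticks), microtimes (TCSPC bin
indices), a detection channel per photon and an excitation-period gate per
photon.  File IO lives in :mod:`conformo.simulate.photon_hdf5`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhotonStream", "CHANNELS", "GATES"]

#: Detection channel codes (spectral window x polarization).
CHANNELS = {
    "donor_parallel": 0,
    "donor_perpendicular": 1,
    "acceptor_parallel": 2,
    "acceptor_perpendicular": 3,
}

#: Excitation-period gate codes.
GATES = {"donor_excitation": 0, "acceptor_excitation": 1}

_DONOR_CHANNELS = (0, 1)
_ACCEPTOR_CHANNELS = (2, 3)


@dataclass
class PhotonStream:
    """Photon records sorted by macrotime.

    Attributes
    ----------
    timestamps : ndarray of int64
        Macrotimes in clock ticks, non-decreasing.
    timestamp_unit : float
        Seconds per clock tick.
    nanotimes : ndarray of uint16
        TCSPC bin index per photon, measured from the start of the photon's
        excitation gate.
    tcspc_unit : float
        Seconds per TCSPC bin.
    tcspc_range : float
        Length of one excitation gate in seconds (microtime < range).
    channels : ndarray of uint8
        Detection channel per photon (see :data:`CHANNELS`).
    gates : ndarray of uint8
        Excitation gate per photon (see :data:`GATES`).
    metadata : dict
        Provenance: resolved configuration, seed, or acquisition info.
    """

    timestamps: np.ndarray
    timestamp_unit: float
    nanotimes: np.ndarray
    tcspc_unit: float
    tcspc_range: float
    channels: np.ndarray
    gates: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.nanotimes = np.asarray(self.nanotimes, dtype=np.uint16)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        self.gates = np.asarray(self.gates, dtype=np.uint8)
        n = self.timestamps.size
        for name in ("nanotimes", "channels", "gates"):
            if getattr(self, name).size != n:
                raise ValueError(
                    f"{name} has {getattr(self, name).size} entries, expected {n}"
                )
        if self.timestamp_unit <= 0 or self.tcspc_unit <= 0 or self.tcspc_range <= 0:
            raise ValueError("time resolutions must be positive")
        if n and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("macrotimes must be non-decreasing")
        if np.any(self.channels > 3) or np.any(self.gates > 1):
            raise ValueError("undefined channel or gate code")
        max_bin = int(np.ceil(self.tcspc_range / self.tcspc_unit))
        if n and int(self.nanotimes.max()) >= max_bin:
            raise ValueError("microtime outside the excitation period")

    # ------------------------------------------------------------------
    def __len__(self):
        return self.timestamps.size

    @property
    def times(self):
        """Macrotimes in seconds (float64)."""
        return self.timestamps * self.timestamp_unit

    @property
    def microtimes_ns(self):
        """Microtimes in nanoseconds (float64)."""
        return self.nanotimes * (self.tcspc_unit * 1e9)

    @property
    def duration(self):
        """Span from first to last photon, in seconds (0 for < 2 photons)."""
        if len(self) < 2:
            return 0.0
        return float((self.timestamps[-1] - self.timestamps[0]) * self.timestamp_unit)

    def is_donor_channel(self):
        return np.isin(self.channels, _DONOR_CHANNELS)

    def is_acceptor_channel(self):
        return np.isin(self.channels, _ACCEPTOR_CHANNELS)

    def select(self, mask):
        """A new stream containing the photons where ``mask`` is True."""
        return PhotonStream(
            timestamps=self.timestamps[mask],
            timestamp_unit=self.timestamp_unit,
            nanotimes=self.nanotimes[mask],
            tcspc_unit=self.tcspc_unit,
            tcspc_range=self.tcspc_range,
            channels=self.channels[mask],
            gates=self.gates[mask],
            metadata=dict(self.metadata),
        )

    @classmethod
    def from_float_times(
        cls,
        times_s,
        microtimes_ns,
        channels,
        gates,
        timestamp_unit=12.5e-9,
        tcspc_unit=18.75e-9 / 4096,
        tcspc_range=18.75e-9,
        metadata=None,
        sort=True,
    ):
        """Quantize floating-point photon times into a stream.

        Microtimes are wrapped into the gate window, mirroring a TCSPC
        electronics roll-over; for an exponential decay the wrapped
        distribution on ``[0, range)`` is identical to the truncated one.
        """
        times_s = np.asarray(times_s, dtype=float)
        microtimes_ns = np.asarray(microtimes_ns, dtype=float)
        channels = np.asarray(channels)
        gates = np.asarray(gates)
        if sort and times_s.size:
            order = np.argsort(times_s, kind="stable")
            times_s = times_s[order]
            microtimes_ns = microtimes_ns[order]
            channels = channels[order]
            gates = gates[order]
        ts = np.round(times_s / timestamp_unit).astype(np.int64)
        range_ns = tcspc_range * 1e9
        micro = np.mod(microtimes_ns, range_ns)
        nano = np.floor(micro / (tcspc_unit * 1e9)).astype(np.uint16)
        return cls(
            timestamps=ts,
            timestamp_unit=timestamp_unit,
            nanotimes=nano,
            tcspc_unit=tcspc_unit,
            tcspc_range=tcspc_range,
            channels=channels.astype(np.uint8),
            gates=gates.astype(np.uint8),
            metadata=metadata or {},
        )
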