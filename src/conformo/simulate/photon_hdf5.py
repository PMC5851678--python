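"""Photon-HDF5-compatible file IO for photon streams.

The on-disk layout follows the Photon-HDF5 conventions: a ``photon_data``
group holding ``timestamps``, ``detectors`` and ``nanotimes`` arrays with
their ``*_specs`` metadata, plus ``setup`` and ``identity`` groups.  The
per-photon excitation gate, which Photon-HDF5 normally encodes implicitly
through nanotime ranges, is stored explicitly as
``photon_data/user/gates`` so that a round trip is lossless.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from ..photons import PhotonStream

__all__ = ["write_photon_stream", "read_photon_stream"]

_MANDATORY = [
    "photon_data/timestamps",
    "photon_data/detectors",
    "photon_data/nanotimes",
    "photon_data/user/gates",
    "photon_data/timestamps_specs/timestamps_unit",
    "photon_data/nanotimes_specs/tcspc_unit",
    "photon_data/nanotimes_specs/tcspc_range",
]


def write_photon_stream(stream: PhotonStream, path):
    """Write a stream to ``path`` (HDF5)."""
    with h5py.File(path, "w") as f:
        pd = f.create_group("photon_data")
        pd.create_dataset("timestamps", data=stream.timestamps)
        pd.create_dataset("detectors", data=stream.channels)
        pd.create_dataset("nanotimes", data=stream.nanotimes)
        specs = pd.create_group("timestamps_specs")
        specs.create_dataset("timestamps_unit", data=stream.timestamp_unit)
        nspecs = pd.create_group("nanotimes_specs")
        nspecs.create_dataset("tcspc_unit", data=stream.tcspc_unit)
        nspecs.create_dataset("tcspc_range", data=stream.tcspc_range)
        user = pd.create_group("user")
        user.create_dataset("gates", data=stream.gates)
        setup = f.create_group("setup")
        setup.create_dataset("num_spectral_ch", data=2)
        setup.create_dataset("num_polarization_ch", data=2)
        setup.create_dataset("lifetime", data=True)
        setup.create_dataset("modulated_excitation", data=True)
        ident = f.create_group("identity")
        ident.create_dataset("software", data="conformo")
        ident.create_dataset(
            "metadata_json", data=json.dumps(stream.metadata, default=str))


def read_photon_stream(path) -> PhotonStream:
    """Read a stream written by :func:`write_photon_stream`.

    Raises a descriptive :class:`ValueError` naming the first missing
    mandatory field.
    """
    with h5py.File(path, "r") as f:
        for field in _MANDATORY:
            if field not in f:
                raise ValueError(
                    f"not a valid photon file: missing mandatory field {field!r}")
        pd = f["photon_data"]
        metadata = {}
        if "identity/metadata_json" in f:
            raw = f["identity/metadata_json"][()]
            if isinstance(raw, bytes):
                raw = raw.decode()
            metadata = json.loads(raw)
        return PhotonStream(
            timestamps=pd["timestamps"][()].astype(np.int64),
            timestamp_unit=float(pd["timestamps_specs/timestamps_unit"][()]),
            nanotimes=pd["nanotimes"][()].astype(np.uint16),
            tcspc_unit=float(pd["nanotimes_specs/tcspc_unit"][()]),
            tcspc_range=float(pd["nanotimes_specs/tcspc_range"][()]),
            channels=pd["detectors"][()].astype(np.uint8),
            gates=pd["user/gates"][()].astype(np.uint8),
            metadata=metadata,
        )
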