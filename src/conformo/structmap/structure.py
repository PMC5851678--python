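"""Structure parsing and a compact text format for coordinate fixtures.

PDB files are read through biotite; alternate locations are resolved to
the highest occupancy, waters are excluded by default and hetero atoms
(ligands, ions) are kept only on request.  The compact ``.cst`` format is
a small line-oriented text serialization used for storing down-sampled
coordinate fixtures (one residue header per residue, one ``name x y z``
line per atom, 0.1 Å precision) — adequate for surface-area and
dye-accessibility geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = ["StructureModel", "parse_structure", "write_pdb",
           "write_compact", "read_compact"]


@dataclass
class StructureModel:
    """Parsed coordinates plus provenance.

    ``atoms`` is a biotite :class:`AtomArray`; ``source_id`` records the
    origin (e.g. a PDB code or file name).
    """

    atoms: struc.AtomArray
    source_id: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self):
        return self.atoms.array_length()

    def chains(self):
        return sorted(set(self.atoms.chain_id))

    def residue_ids(self, chain=None):
        a = self.atoms
        if chain is not None:
            a = a[a.chain_id == chain]
        return sorted(set(zip(a.chain_id, a.res_id.tolist())))

    def select(self, mask):
        return StructureModel(self.atoms[mask], self.source_id)

    def coords(self):
        return self.atoms.coord


def parse_structure(path, chains=None, include_hetero=False,
                    keep_waters=False, source_id=None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path : str or Path
        PDB text file.
    chains : sequence of str, optional
        Keep only these chain ids.
    include_hetero : bool
        Keep hetero atoms (ligands/ions); waters additionally require
        ``keep_waters``.
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    mask = np.ones(atoms.array_length(), dtype=bool)
    if not keep_waters:
        mask &= ~np.isin(atoms.res_name, ("HOH", "WAT", "DOD"))
    if not include_hetero:
        mask &= ~atoms.hetero
    if chains is not None:
        mask &= np.isin(atoms.chain_id, list(chains))
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise ValueError("no atoms left after filtering")
    return StructureModel(atoms, source_id or str(path))


def write_pdb(model: StructureModel, path):
    """Write the model as standard PDB text (via biotite)."""
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


def write_compact(model: StructureModel, path):
    """Serialize to the compact text format (0.1 Å precision)."""
    a = model.atoms
    starts = struc.get_residue_starts(a)
    with open(path, "w") as f:
        f.write(f"#cst 1 {model.source_id}\n")
        bounds = np.append(starts, a.array_length())
        for s, e in zip(bounds[:-1], bounds[1:]):
            f.write(f">{a.chain_id[s]} {a.res_id[s]} {a.res_name[s]}\n")
            for i in range(s, e):
                x, y, z = a.coord[i]
                f.write(f"{a.atom_name[i]} {x:.1f} {y:.1f} {z:.1f}\n")


def read_compact(path) -> StructureModel:
    """Read the compact text format back into a :class:`StructureModel`."""
    chain, resid, resname = "A", 0, "UNK"
    names, coords, chains, resids, resnames = [], [], [], [], []
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#cst"):
            raise ValueError(f"{path} is not a compact structure file")
        source = header.split(maxsplit=2)[2].strip() if len(
            header.split(maxsplit=2)) > 2 else ""
        for ln, line in enumerate(f, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                if len(parts) != 3:
                    raise ValueError(f"line {ln}: malformed residue header")
                chain, resid, resname = parts[0], int(parts[1]), parts[2]
            else:
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"line {ln}: malformed atom record")
                names.append(parts[0])
                coords.append([float(v) for v in parts[1:]])
                chains.append(chain)
                resids.append(resid)
                resnames.append(resname)
    n = len(names)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords)
    atoms.atom_name = np.asarray(names)
    atoms.chain_id = np.asarray(chains)
    atoms.res_id = np.asarray(resids, dtype=int)
    atoms.res_name = np.asarray(resnames)
    atoms.element = np.asarray([_element_from_name(nm) for nm in names])
    atoms.hetero = np.zeros(n, dtype=bool)
    return StructureModel(atoms, source)


def _element_from_name(name):
    for two in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        if name.upper().startswith(two) and len(name) > 1:
            return two.capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"
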