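"""Synthetic coordinate models for tests and demonstrations.

Everything here is *constructed* geometry — pseudo-protein models built
from idealized residues — not experimental coordinates.  They exercise
the surface-area and accessible-volume machinery with known ground truth
(analytic sphere areas, constructed burial, prescribed site separations).
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc

from .structure import StructureModel

__all__ = ["atoms_from_table", "single_atom", "buried_atom_cluster",
           "extended_tripeptide", "two_domain_model"]


def atoms_from_table(rows, source_id="synthetic"):
    """Build a model from ``(chain, res_id, res_name, atom_name, x, y, z)``."""
    n = len(rows)
    atoms = struc.AtomArray(n)
    atoms.coord = np.array([[r[4], r[5], r[6]] for r in rows], dtype=float)
    atoms.chain_id = np.array([r[0] for r in rows])
    atoms.res_id = np.array([r[1] for r in rows], dtype=int)
    atoms.res_name = np.array([r[2] for r in rows])
    atoms.atom_name = np.array([r[3] for r in rows])
    atoms.element = np.array([r[3][0] for r in rows])
    atoms.hetero = np.zeros(n, dtype=bool)
    return StructureModel(atoms, source_id)


def single_atom(element="C", source_id="synthetic single atom"):
    rows = [("A", 1, "ALA", element, 0.0, 0.0, 0.0)]
    return atoms_from_table(rows, source_id)


def buried_atom_cluster(shell_radius=4.0, n_shell=128,
                        source_id="synthetic burial fixture"):
    """A central atom enclosed by a dense spherical shell of atoms."""
    rows = [("A", 1, "ALA", "C", 0.0, 0.0, 0.0)]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_shell):
        z = 1.0 - 2.0 * (i + 0.5) / n_shell
        r = np.sqrt(1.0 - z * z)
        th = golden * i
        rows.append(("A", 2 + i, "ALA", "C",
                     shell_radius * r * np.cos(th),
                     shell_radius * r * np.sin(th),
                     shell_radius * z))
    return atoms_from_table(rows, source_id)


_BACKBONE = {  # idealized extended-strand offsets per residue, Å
    "N": (0.0, 0.0, 0.0),
    "CA": (1.2, 0.9, 0.0),
    "C": (2.4, 0.0, 0.0),
    "O": (2.4, -1.2, 0.3),
}


def extended_tripeptide(res_name="GLY", source_id="synthetic GXG strand"):
    """An extended (straight) Gly-X-Gly-like tripeptide."""
    rows = []
    for i in range(3):
        name = res_name if i == 1 else "GLY"
        for atom, (x, y, z) in _BACKBONE.items():
            rows.append(("A", i + 1, name, atom, x + 3.6 * i, y, z))
        if name != "GLY":
            x, y, z = _BACKBONE["CA"]
            rows.append(("A", i + 1, name, "CB", x + 3.6 * i, y + 1.5, z + 0.5))
    return atoms_from_table(rows, source_id)


def _compact_domain(center, n_res, res_id0, chain, rng, radius=9.0):
    """A compact blob of idealized ALA residues (synthetic domain)."""
    rows = []
    for i in range(n_res):
        while True:
            p = rng.uniform(-radius, radius, 3)
            if np.linalg.norm(p) <= radius:
                break
        base = np.asarray(center) + p
        for atom, off in _BACKBONE.items():
            rows.append((chain, res_id0 + i, "ALA", atom,
                         base[0] + off[0], base[1] + off[1], base[2] + off[2]))
        rows.append((chain, res_id0 + i, "ALA", "CB",
                     base[0] + 1.2, base[1] + 2.2, base[2] + 0.6))
    return rows


def two_domain_model(separation=30.0, n_res=60, seed=11,
                     site_a=1, site_b=None,
                     source_id="synthetic two-domain model"):
    """Two compact pseudo-domains with labelled sites on their far faces.

    ``separation`` sets the center-to-center distance along x; the two
    attachment sites (first residue of domain 1, placed at the outer face;
    ``site_b`` defaults to the first residue of domain 2) end up roughly
    ``separation + 18`` Å apart.  Varying ``separation`` mimics an
    open/closed domain rearrangement with a known distance change.
    """
    rng = np.random.default_rng(seed)
    rows = []
    # attachment residues at deterministic outer-face positions
    for atom, off in _BACKBONE.items():
        rows.append(("A", site_a, "CYS", atom,
                     -9.0 + off[0] - 3.0, off[1], off[2]))
    rows.append(("A", site_a, "CYS", "SG", -14.0, 1.4, 0.8))
    rows += _compact_domain((0.0, 0.0, 0.0), n_res, 2, "A", rng)
    site_b = site_b if site_b is not None else 100 + n_res + 2
    for atom, off in _BACKBONE.items():
        rows.append(("A", site_b, "CYS", atom,
                     separation + 9.0 + off[0] + 3.0, off[1], off[2]))
    rows.append(("A", site_b, "CYS", "SG", separation + 16.0, 1.4, 0.8))
    rows += _compact_domain((separation, 0.0, 0.0), n_res, 101, "A", rng)
    return atoms_from_table(rows, source_id)
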