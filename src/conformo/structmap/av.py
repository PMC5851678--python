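"""Accessible-volume dye modelling and FRET-averaged distances.

A dye tethered to a residue by a flexible linker can occupy any position
reachable from the attachment atom within the linker length, along a path
wide enough for the linker, without the dye sphere clashing into the
protein.  The single-radius accessible volume (AV1) computes this set by
a Dijkstra flood fill on a cubic grid: grid points are *path-free* when
their clearance to the nearest atom exceeds half the linker width,
*dye-free* when it exceeds the dye radius, and allowed when they are
dye-free and geodesically reachable from the attachment atom through
path-free space within the linker length.  All allowed positions carry
uniform weight.

The FRET-averaged inter-dye distance of a donor/acceptor AV pair is
``<R_DA>_E = R0 * (1/<E> - 1)^(1/6)`` with ``<E>`` the mean Förster
efficiency over dye position pairs — the distance a measured mean
efficiency is converted to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from biotite.structure.info import vdw_radius_single

from ..fret import distance_to_efficiency, efficiency_to_distance
from .structure import StructureModel

__all__ = ["DyeParameters", "AccessibleVolume", "DistancePrediction",
           "accessible_volume", "fret_averaged_distance",
           "ATTO488_MALEIMIDE", "ALEXA647_MALEIMIDE"]


@dataclass
class DyeParameters:
    """Geometric dye model: linker length/width and dye radius, in Å."""

    linker_length: float = 20.0
    linker_width: float = 4.5
    dye_radius: float = 3.5

    def __post_init__(self):
        if min(self.linker_length, self.linker_width, self.dye_radius) <= 0:
            raise ValueError("dye parameters must be positive")


#: Common maleimide dye geometries (assumed, not measured).
ATTO488_MALEIMIDE = DyeParameters(20.0, 4.5, 3.5)
ALEXA647_MALEIMIDE = DyeParameters(22.0, 4.5, 3.5)


@dataclass
class AccessibleVolume:
    """Allowed dye positions with uniform weights."""

    points: np.ndarray       # (n, 3) Å
    weights: np.ndarray      # (n,), sums to 1
    attachment: np.ndarray   # (3,)
    grid_spacing: float
    dye: DyeParameters

    @property
    def n_points(self):
        return self.points.shape[0]

    @property
    def volume(self):
        """Occupied volume in Å^3 (cells x spacing^3)."""
        return self.n_points * self.grid_spacing ** 3

    def mean_position(self):
        return self.points.mean(axis=0)


@dataclass
class DistancePrediction:
    """AV-pair distance summary."""

    mean_distance: float        # <R>
    fret_averaged: float        # <R_DA>_E
    mean_efficiency: float
    forster_radius: float
    n_pairs: int


def _atom_radii(atoms):
    radii = np.empty(atoms.array_length())
    for i, el in enumerate(atoms.element):
        r = vdw_radius_single(el.capitalize())
        radii[i] = 1.7 if r is None else r
    return radii


def _find_attachment(model, chain, res_id, atom_name):
    a = model.atoms
    mask = (a.chain_id == chain) & (a.res_id == res_id)
    if not mask.any():
        raise KeyError(f"residue {chain}:{res_id} not in structure")
    for name in ([atom_name] if atom_name else ["SG", "CB", "CA"]):
        m = mask & (a.atom_name == name)
        if m.any():
            return np.flatnonzero(m)[0]
    raise KeyError(f"no attachment atom for {chain}:{res_id}")


def accessible_volume(model: StructureModel, chain, res_id,
                      dye: DyeParameters = ATTO488_MALEIMIDE,
                      atom_name=None, grid_spacing=1.0,
                      exclude_attachment_residue=True) -> AccessibleVolume:
    """Grid flood-fill accessible volume of a dye at one residue.

    Parameters
    ----------
    model : StructureModel
    chain, res_id :
        Attachment residue; the attachment atom defaults to the first of
        SG, CB, CA present.
    exclude_attachment_residue : bool
        Ignore clashes with the attachment residue's own side chain (the
        native side chain is replaced by the dye).

    Raises
    ------
    ValueError
        When no grid point is accessible (site buried).
    """
    a = model.atoms
    idx = _find_attachment(model, chain, res_id, atom_name)
    origin = a.coord[idx]

    clash_mask = np.ones(a.array_length(), dtype=bool)
    clash_mask[idx] = False  # the linker must be free to leave its anchor
    if exclude_attachment_residue:
        clash_mask &= ~((a.chain_id == chain) & (a.res_id == res_id))
    atoms_xyz = a.coord[clash_mask]
    radii = _atom_radii(a[clash_mask])

    L = dye.linker_length
    n_side = int(np.floor(2 * L / grid_spacing)) + 1
    axis = origin[None, :] + grid_spacing * (
        np.arange(n_side) - n_side // 2)[:, None] * np.eye(3)[None, 0]
    g1 = grid_spacing * (np.arange(n_side) - n_side // 2)
    gx, gy, gz = np.meshgrid(g1, g1, g1, indexing="ij")
    pts = origin[None, :] + np.stack([gx.ravel(), gy.ravel(), gz.ravel()], 1)
    within = np.linalg.norm(pts - origin, axis=1) <= L
    pts = pts[within]

    # clearance to the nearest atom surface (vdW radius subtracted)
    if atoms_xyz.shape[0]:
        tree = cKDTree(atoms_xyz)
        k = min(12, atoms_xyz.shape[0])
        dist, nn = tree.query(pts, k=k, workers=-1)
        if k == 1:
            dist, nn = dist[:, None], nn[:, None]
        clearance = (dist - radii[nn]).min(axis=1)
    else:
        clearance = np.full(pts.shape[0], np.inf)

    path_free = clearance > dye.linker_width / 2.0
    dye_free = clearance > dye.dye_radius
    if not path_free.any():
        raise ValueError(f"site {chain}:{res_id} inaccessible "
                         "(no path-free space at the attachment)")

    # Dijkstra on the path-free subgrid, 26-connected
    free_idx = np.flatnonzero(path_free)
    coords = np.round((pts[free_idx] - origin) / grid_spacing).astype(np.int64)
    key = ((coords[:, 0] + n_side) * 4 * n_side ** 2
           + (coords[:, 1] + n_side) * 2 * n_side + (coords[:, 2] + n_side))
    lookup = dict(zip(key.tolist(), range(free_idx.size)))
    rows, cols, vals = [], [], []
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])
    for off in offsets:
        nk = ((coords[:, 0] + off[0] + n_side) * 4 * n_side ** 2
              + (coords[:, 1] + off[1] + n_side) * 2 * n_side
              + (coords[:, 2] + off[2] + n_side))
        tgt = np.array([lookup.get(v, -1) for v in nk.tolist()])
        ok = tgt >= 0
        rows.append(np.flatnonzero(ok))
        cols.append(tgt[ok])
        vals.append(np.full(ok.sum(), grid_spacing * np.linalg.norm(off)))
    graph = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(free_idx.size, free_idx.size)).tocsr()

    # source: the grid cell nearest the attachment atom
    d0 = np.linalg.norm(pts[free_idx] - origin, axis=1)
    src = int(np.argmin(d0))
    if d0[src] > 2.0 * grid_spacing + dye.linker_width:
        raise ValueError(f"site {chain}:{res_id} inaccessible "
                         "(attachment atom fully buried)")
    pathlen = dijkstra(graph, indices=src, min_only=True) + d0[src]

    allowed = (pathlen <= L) & dye_free[free_idx]
    points = pts[free_idx[allowed]]
    if points.shape[0] == 0:
        raise ValueError(f"site {chain}:{res_id} inaccessible "
                         "(no clash-free dye position within the linker)")
    w = np.full(points.shape[0], 1.0 / points.shape[0])
    return AccessibleVolume(points, w, origin, grid_spacing, dye)


def fret_averaged_distance(av_donor: AccessibleVolume,
                           av_acceptor: AccessibleVolume, forster_radius,
                           n_pairs=200000, seed=0) -> DistancePrediction:
    """Mean and FRET-averaged inter-dye distance of an AV pair.

    Subsamples ``n_pairs`` position pairs (seeded) unless the dense pair
    set is smaller, in which case all pairs are enumerated.
    """
    if forster_radius <= 0:
        raise ValueError("Förster radius must be positive")
    if av_donor.n_points == 0 or av_acceptor.n_points == 0:
        raise ValueError("empty accessible volume")
    nd, na = av_donor.n_points, av_acceptor.n_points
    if nd * na <= n_pairs:
        diff = av_donor.points[:, None, :] - av_acceptor.points[None, :, :]
        r = np.sqrt((diff ** 2).sum(axis=2)).ravel()
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, nd, n_pairs)
        j = rng.integers(0, na, n_pairs)
        r = np.linalg.norm(av_donor.points[i] - av_acceptor.points[j], axis=1)
    e = distance_to_efficiency(r, forster_radius)
    mean_e = float(e.mean())
    return DistancePrediction(
        mean_distance=float(r.mean()),
        fret_averaged=float(efficiency_to_distance(mean_e, forster_radius)),
        mean_efficiency=mean_e,
        forster_radius=forster_radius,
        n_pairs=r.size,
    )
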