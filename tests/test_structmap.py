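"""Structure parsing, SASA, exposure classes, accessible volumes."""

import numpy as np
import pytest

from conformo.structmap import (parse_structure, write_compact, read_compact,
                                sasa, classify_exposure, buried_surface,
                                accessible_volume, fret_averaged_distance,
                                DyeParameters, ATTO488_MALEIMIDE,
                                ALEXA647_MALEIMIDE)
from conformo.structmap.synthetic import (single_atom, buried_atom_cluster,
                                          extended_tripeptide,
                                          two_domain_model, atoms_from_table)


PDB_FIXTURE = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
ATOM      4  O   ALA A   1      13.603   7.306  -5.735  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.542   6.180  -4.092  1.00  0.00           C
ATOM      6  N   GLY A   2      12.561   7.903  -3.824  1.00  0.00           N
ATOM      7  CA  GLY A   2      13.513   8.962  -3.502  1.00  0.00           C
ATOM      8  C   GLY A   2      13.107  10.306  -4.084  1.00  0.00           C
ATOM      9  O   GLY A   2      11.965  10.501  -4.505  1.00  0.00           O
ATOM     10  CA ASER B   3      15.000  10.000  -3.000  0.60  0.00           C
ATOM     11  CA BSER B   3      15.200  10.100  -3.100  0.40  0.00           C
HETATM   12  O   HOH A   4      20.000  20.000  20.000  1.00  0.00           O
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    p = tmp_path / "fixture.pdb"
    p.write_text(PDB_FIXTURE)
    return p


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------

def test_parse_counts_and_water_exclusion(pdb_file):
    m = parse_structure(pdb_file)
    # 9 protein atoms + 1 altloc-resolved SER CA; water dropped
    assert m.n_atoms == 10


def test_chain_filter(pdb_file):
    m = parse_structure(pdb_file, chains=["A"])
    assert set(m.atoms.chain_id) == {"A"}
    assert m.n_atoms == 9


def test_altloc_resolved_to_highest_occupancy(pdb_file):
    m = parse_structure(pdb_file, chains=["B"])
    assert m.n_atoms == 1
    assert m.atoms.coord[0, 0] == pytest.approx(15.0)


def test_malformed_file_raises(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text("ATOM   garbage line that is not a PDB record\n")
    with pytest.raises(ValueError):
        parse_structure(bad)


def test_compact_round_trip(tmp_path, pdb_file):
    m = parse_structure(pdb_file)
    path = tmp_path / "m.cst"
    write_compact(m, path)
    back = read_compact(path)
    assert back.n_atoms == m.n_atoms
    assert np.allclose(back.coords(), m.coords(), atol=0.051)
    assert list(back.atoms.res_name) == list(m.atoms.res_name)


# ----------------------------------------------------------------------
# SASA
# ----------------------------------------------------------------------

def test_single_atom_matches_analytic_sphere():
    m = single_atom()
    r = sasa(m, point_number=960, vdw_radii="Single")
    analytic = 4 * np.pi * (1.7 + 1.4) ** 2
    assert r.total == pytest.approx(analytic, rel=0.01)


def test_enclosed_atom_has_zero_sasa():
    m = buried_atom_cluster()
    r = sasa(m)
    assert r.atom_sasa[0] == pytest.approx(0.0, abs=1e-9)


def test_sasa_point_count_convergence():
    m = two_domain_model(separation=20.0, n_res=25)
    prev = sasa(m, point_number=960).total
    dense = sasa(m, point_number=3840).total
    assert abs(prev - dense) / dense < 0.005


def test_central_residue_of_extended_strand_is_exposed():
    m = extended_tripeptide("GLY")
    r = sasa(m)
    cls = classify_exposure(r, [("A", 2)])
    assert cls[("A", 2)]["class"] == "exposed"
    assert 50.0 < cls[("A", 2)]["rel_acc"] <= 160.0


def test_threshold_rule():
    m = extended_tripeptide("GLY")
    r = sasa(m)
    r.residues.loc[r.residues.res_id == 2, "rel_acc"] = 5.0
    assert classify_exposure(r, [("A", 2)])[("A", 2)]["class"] == "buried"
    r.residues.loc[r.residues.res_id == 2, "rel_acc"] = 18.0
    assert (classify_exposure(r, [("A", 2)])[("A", 2)]["class"]
            == "partially exposed")


def test_unknown_site_lists_valid_ids():
    r = sasa(extended_tripeptide("GLY"))
    with pytest.raises(KeyError, match="valid ids"):
        classify_exposure(r, [("A", 99)])


def test_buried_surface_identity_and_antisymmetry():
    a = two_domain_model(separation=14.0, n_res=40)
    b = two_domain_model(separation=40.0, n_res=40)
    zero, _ = buried_surface(a, a)
    assert zero == pytest.approx(0.0, abs=1e-9)
    d_ab, _ = buried_surface(b, a)   # open minus closed
    d_ba, _ = buried_surface(a, b)
    assert d_ab == pytest.approx(-d_ba, rel=1e-12)
    assert d_ab > 100.0  # contact at 14 A separation buries real surface


def test_sasa_against_independent_implementation(tmp_path):
    """Cross-check biotite Shrake-Rupley against Biopython's on a fixture."""
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    from conformo.structmap import write_pdb

    m = two_domain_model(separation=20.0, n_res=25)
    pdb = tmp_path / "cross.pdb"
    write_pdb(m, pdb)

    ours = sasa(parse_structure(pdb), point_number=960, vdw_radii="Single")
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("x", str(pdb))
    ShrakeRupley(probe_radius=1.4, n_points=960).compute(struct, level="S")
    theirs = struct.sasa
    assert ours.total == pytest.approx(theirs, rel=0.05)


# ----------------------------------------------------------------------
# accessible volumes
# ----------------------------------------------------------------------

def test_av_of_free_site_bounded_by_linker_sphere():
    # a single tiny anchor far from everything: AV fits in the linker sphere
    rows = [("A", 1, "CYS", "SG", 0.0, 0.0, 0.0)]
    m = atoms_from_table(rows)
    av = accessible_volume(m, "A", 1, DyeParameters(12.0, 4.5, 3.5),
                           grid_spacing=1.0,
                           exclude_attachment_residue=False)
    sphere = 4.0 / 3.0 * np.pi * 12.0 ** 3
    assert 0.5 * sphere < av.volume <= 1.05 * sphere
    # every point within the linker length
    d = np.linalg.norm(av.points - av.attachment, axis=1)
    assert d.max() <= 12.0 + 1e-9


def test_av_wall_strictly_reduces_volume():
    rows = [("A", 1, "CYS", "SG", 0.0, 0.0, 0.0)]
    free = accessible_volume(atoms_from_table(rows), "A", 1,
                             DyeParameters(10.0, 4.5, 3.5),
                             exclude_attachment_residue=False)
    wall = [("A", 2 + i * 30 + j, "ALA", "C", 4.0, -15.0 + i,
             -15.0 + j) for i in range(30) for j in range(30)]
    blocked = accessible_volume(atoms_from_table(rows + wall), "A", 1,
                                DyeParameters(10.0, 4.5, 3.5),
                                exclude_attachment_residue=False)
    assert blocked.volume < free.volume


def test_av_buried_site_raises():
    m = buried_atom_cluster(shell_radius=3.0, n_shell=400)
    with pytest.raises((ValueError, KeyError)):
        accessible_volume(m, "A", 1, DyeParameters(10.0, 4.5, 3.5),
                          atom_name="C", exclude_attachment_residue=False)


def test_degenerate_clouds_give_forster_radius():
    a = type("AV", (), {})
    av1 = _point_cloud([[0.0, 0.0, 0.0]])
    av2 = _point_cloud([[53.0, 0.0, 0.0]])
    pred = fret_averaged_distance(av1, av2, 53.0)
    assert pred.fret_averaged == pytest.approx(53.0, rel=1e-9)
    assert pred.mean_distance == pytest.approx(53.0, rel=1e-9)


def _point_cloud(points):
    from conformo.structmap.av import AccessibleVolume

    pts = np.asarray(points, dtype=float)
    return AccessibleVolume(pts, np.full(len(pts), 1.0 / len(pts)),
                            pts[0], 1.0, ATTO488_MALEIMIDE)


def test_subsampled_pair_average_matches_dense():
    rng = np.random.default_rng(3)
    av1 = _point_cloud(rng.normal(0, 4, (300, 3)))
    av2 = _point_cloud(rng.normal((50, 0, 0), 4, (300, 3)))
    dense = fret_averaged_distance(av1, av2, 53.0, n_pairs=10**9)
    sub = fret_averaged_distance(av1, av2, 53.0, n_pairs=80_000, seed=1)
    assert sub.fret_averaged == pytest.approx(dense.fret_averaged, abs=0.2)


def test_av_rigid_motion_invariance():
    m = two_domain_model(separation=24.0, n_res=30)
    av_d = accessible_volume(m, "A", 1)
    av_a = accessible_volume(m, "A", 132, dye=ALEXA647_MALEIMIDE)
    base = fret_averaged_distance(av_d, av_a, 53.0, seed=2)

    # rotate + translate all coordinates rigidly
    th = 0.7
    Rz = np.array([[np.cos(th), -np.sin(th), 0],
                   [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    m2 = two_domain_model(separation=24.0, n_res=30)
    m2.atoms.coord = m2.atoms.coord @ Rz.T + np.array([5.0, -3.0, 7.0])
    av_d2 = accessible_volume(m2, "A", 1)
    av_a2 = accessible_volume(m2, "A", 132, dye=ALEXA647_MALEIMIDE)
    moved = fret_averaged_distance(av_d2, av_a2, 53.0, seed=2)
    assert moved.fret_averaged == pytest.approx(base.fret_averaged, abs=0.8)


def test_av_grid_convergence():
    m = two_domain_model(separation=24.0, n_res=30)
    preds = []
    for spacing in (1.6, 0.8):
        av_d = accessible_volume(m, "A", 1, grid_spacing=spacing)
        av_a = accessible_volume(m, "A", 132, dye=ALEXA647_MALEIMIDE,
                                 grid_spacing=spacing)
        preds.append(fret_averaged_distance(av_d, av_a, 53.0, seed=0)
                     .fret_averaged)
    assert abs(preds[1] - preds[0]) < 0.5


def test_open_vs_closed_separation_ordering():
    """Larger domain separation gives a larger FRET-averaged distance."""
    out = {}
    for name, sep in (("open", 44.0), ("closed", 23.0)):
        m = two_domain_model(separation=sep)
        av_d = accessible_volume(m, "A", 1)
        av_a = accessible_volume(m, "A", 162, dye=ALEXA647_MALEIMIDE)
        out[name] = fret_averaged_distance(av_d, av_a, 53.0).fret_averaged
    assert out["open"] - out["closed"] > 10.0
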