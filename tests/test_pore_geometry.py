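"""Pore axis, radius profiles, rotamers, and the gate permeation rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gatekin.pore_geometry import (
    AtomRecord,
    Structure,
    TRP_ROTAMER_TABLE,
    dihedral,
    facing_distance,
    gate_aperture,
    make_toy_pore,
    min_constriction,
    permeation_feasibility,
    pore_axis,
    radius_profile,
    read_pdb,
    set_symmetric_rotamer,
    write_pdb,
)

Z_AXIS = np.array([0.0, 0.0, 1.0])


def brute_force_radius(structure, z, lateral=2.0, step=0.01):
    """Independent fine-grid oracle for the probe radius at one z."""
    coords = structure.coords
    vdw = structure.vdw
    g = np.arange(-lateral, lateral + step / 2, step)
    gx, gy = np.meshgrid(g, g)
    pts = np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)], axis=1)
    d = np.linalg.norm(coords[None] - pts[:, None], axis=2) - vdw[None]
    return max(float(d.min(axis=1).max()), 0.0)


def strip_symmetry(s):
    return Structure(s.atoms)


class TestReadWritePdb:
    def test_two_atom_toy(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(
            "ATOM      1  C1  TOY A   1       1.000   2.000   3.000  1.00  0.00"
            "           C  \n"
            "ATOM      2  N1  TOY A   1       4.000   5.000   6.000  1.00  0.00"
            "           N  \n"
            "END\n"
        )
        s = read_pdb(p)
        assert len(s.atoms) == 2
        assert np.allclose(s.atoms[0].xyz, [1, 2, 3])
        assert s.atoms[0].vdw_radius == 1.70  # Bondi carbon
        assert s.atoms[1].vdw_radius == 1.55  # Bondi nitrogen

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA ATOY A   1       0.000   0.000   0.000  0.40  0.00"
            "           C  \n"
            "ATOM      2  CA BTOY A   1       9.000   9.000   9.000  0.60  0.00"
            "           C  \n"
            "END\n"
        )
        s = read_pdb(p)
        assert len(s.atoms) == 1
        assert np.allclose(s.atoms[0].xyz, [9, 9, 9])

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_pdb("/nonexistent/structure.pdb")

    def test_roundtrip_precision(self, tmp_path, ring_structure):
        p = tmp_path / "ring.pdb"
        write_pdb(ring_structure, p)
        back = read_pdb(p)
        assert np.abs(back.coords - ring_structure.coords).max() <= 1e-3

    def test_unknown_element_fallback_warns(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(
            "ATOM      1  X1  TOY A   1       0.000   0.000   0.000  1.00  0.00"
            "           X  \n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="unknown element"):
            s = read_pdb(p)
        assert s.atoms[0].vdw_radius == 1.70


class TestPoreAxis:
    def test_ring_axis_is_z(self, ring_structure):
        point, u = pore_axis(strip_symmetry(ring_structure))
        assert np.allclose(point, 0.0, atol=1e-8)
        assert abs(abs(np.dot(u, Z_AXIS)) - 1.0) < 1e-6

    def test_translation_equivariance(self, ring_structure):
        shift = np.array([10.0, 0.0, 0.0])
        moved = strip_symmetry(ring_structure).with_coords(
            ring_structure.coords + shift
        )
        point, u = pore_axis(moved)
        assert np.allclose(point, shift, atol=1e-8)
        assert abs(abs(np.dot(u, Z_AXIS)) - 1.0) < 1e-6

    def test_stacked_rings_axis(self):
        cyl = make_toy_pore("cylinder", n_rings=2, z_spacing=4.0)
        point, u = pore_axis(strip_symmetry(cyl))
        assert abs(abs(np.dot(u, Z_AXIS)) - 1.0) < 1e-6

    def test_too_few_atoms(self):
        atoms = tuple(
            AtomRecord(i, "C1", "TOY", 1, "A", np.array([float(i), 0, 0]), "C", 1.7)
            for i in range(2)
        )
        with pytest.raises(ValueError):
            pore_axis(Structure(atoms))


class TestRadiusProfile:
    def test_ring_waist_analytic(self, ring_structure):
        prof = radius_profile(ring_structure, z_range=(-0.5, 0.5), z_step=0.25)
        _, r, d = min_constriction(prof)
        assert r == pytest.approx(5.0 - 1.7, abs=0.01)
        assert d == pytest.approx(2 * r)

    def test_matches_brute_force_oracle(self, ring_structure):
        prof = radius_profile(ring_structure, z_range=(-1.0, 1.0), z_step=0.5)
        for z, r in zip(prof.z, prof.radius):
            assert abs(r - brute_force_radius(ring_structure, z)) < 0.05

    def test_cylinder_constant_profile(self):
        cyl = make_toy_pore("cylinder", n_rings=7, z_spacing=1.0)
        prof = radius_profile(cyl, z_range=(-2.0, 2.0), z_step=1.0)
        # sampled on ring planes: identical geometry at each z
        assert np.ptp(prof.radius) < 1e-3

    def test_hourglass_waist_location(self):
        hg = make_toy_pore("hourglass", waist_radius=3.0, ring_radius=5.0)
        prof = radius_profile(hg, z_range=(-5.0, 5.0), z_step=0.5)
        z, r, _ = min_constriction(prof)
        assert z == pytest.approx(0.0, abs=0.5)
        assert r == pytest.approx(3.0 - 1.7, abs=0.05)

    def test_vdw_inflation_monotonicity(self):
        a = make_toy_pore("ring", vdw=1.70)
        b = make_toy_pore("ring", vdw=2.00)
        pa = radius_profile(a, z_range=(0.0, 0.1), z_step=0.25)
        pb = radius_profile(b, z_range=(0.0, 0.1), z_step=0.25)
        assert pa.radius[0] - pb.radius[0] == pytest.approx(0.30, abs=0.02)

    def test_rigid_motion_invariance(self, ring_structure):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        moved = strip_symmetry(ring_structure).with_coords(
            ring_structure.coords @ R.T + t
        )
        p0 = radius_profile(ring_structure, z_range=(-0.5, 0.5), z_step=0.25)
        p1 = radius_profile(moved, z_range=(-0.5, 0.5), z_step=0.25)
        assert np.allclose(p0.radius, p1.radius, atol=0.02)

    def test_open_region_flagged(self, ring_structure):
        prof = radius_profile(
            ring_structure, z_range=(40.0, 41.0), z_step=0.5, lateral_bound=5.0
        )
        assert prof.open_flags.all()
        assert np.allclose(prof.radius, 5.0)


class TestMinConstriction:
    def test_window_and_ties(self):
        from gatekin.pore_geometry import PoreProfile

        prof = PoreProfile(
            z=np.array([0.0, 1.0, 2.0, 3.0]),
            radius=np.array([2.0, 1.0, 1.0, 3.0]),
            axis_point=np.zeros(3),
            axis_direction=Z_AXIS,
        )
        z, r, d = min_constriction(prof)
        assert (z, r) == (1.0, 1.0)  # tie broken toward smallest z
        z2, r2, _ = min_constriction(prof, z_window=(2.5, 3.5))
        assert (z2, r2) == (3.0, 3.0)
        with pytest.raises(ValueError):
            min_constriction(prof, z_window=(10.0, 11.0))


class TestRotamers:
    def test_identity_set(self, tetramer_gate):
        chi1, chi2 = TRP_ROTAMER_TABLE["facing"]
        out = set_symmetric_rotamer(tetramer_gate, 583, list("ABCD"), chi1, chi2)
        assert np.abs(out.coords - tetramer_gate.coords).max() < 1e-6

    def test_target_dihedrals_reached(self, tetramer_gate):
        out = set_symmetric_rotamer(tetramer_gate, 583, list("ABCD"), -60.0, 75.0)
        for ch in "ABCD":
            idx = {
                out.atoms[i].name: i for i in out.select(chain=ch, resnum=583)
            }
            c = out.coords
            chi1 = dihedral(c[idx["N"]], c[idx["CA"]], c[idx["CB"]], c[idx["CG"]])
            chi2 = dihedral(c[idx["CA"]], c[idx["CB"]], c[idx["CG"]], c[idx["CD1"]])
            assert chi1 == pytest.approx(-60.0, abs=1e-6)
            assert chi2 == pytest.approx(75.0, abs=1e-6)

    def test_bond_lengths_preserved(self, tetramer_gate):
        out = set_symmetric_rotamer(tetramer_gate, 583, list("ABCD"), 60.0, 90.0)
        for s in (tetramer_gate, out):
            idx = {s.atoms[i].name: i for i in s.select(chain="A", resnum=583)}
            c = s.coords
            for a, b in [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1")]:
                d = np.linalg.norm(c[idx[a]] - c[idx[b]])
                i2 = {
                    tetramer_gate.atoms[i].name: i
                    for i in tetramer_gate.select(chain="A", resnum=583)
                }
                d0 = np.linalg.norm(
                    tetramer_gate.coords[i2[a]] - tetramer_gate.coords[i2[b]]
                )
                assert d == pytest.approx(d0, abs=1e-9)

    def test_c4_symmetry_preserved(self, tetramer_gate):
        out = set_symmetric_rotamer(tetramer_gate, 583, list("ABCD"), -60.0, 90.0)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        A = out.coords[out.select(chain="A")]
        B = out.coords[out.select(chain="B")]
        assert np.abs(A @ rot.T - B).max() < 1e-9

    def test_missing_atom_named(self, tetramer_gate):
        with pytest.raises(ValueError, match="residue 999"):
            set_symmetric_rotamer(tetramer_gate, 999, ["A"], 180.0, 90.0)


class TestFacingDistance:
    def test_constructed_pair(self):
        atoms = tuple(
            AtomRecord(i + 1, "CG", "TRP", 583, ch, xyz, "C", 1.7)
            for i, (ch, xyz) in enumerate(
                [("A", np.array([1.55, 0.0, 0.0])), ("B", np.array([-1.55, 0.0, 0.0]))]
            )
        )
        assert facing_distance(Structure(atoms), 583) == pytest.approx(3.1)

    def test_tetramer_diagonals_equal(self, tetramer_gate):
        s = tetramer_gate
        # symmetric tetramer: both diagonal pairs give the same distance
        coordsA = s.coords[[i for i in s.select(chain="A", resnum=583)
                            if s.atoms[i].name in ("CG", "CD1", "NE1")]]
        coordsC = s.coords[[i for i in s.select(chain="C", resnum=583)
                            if s.atoms[i].name in ("CG", "CD1", "NE1")]]
        coordsB = s.coords[[i for i in s.select(chain="B", resnum=583)
                            if s.atoms[i].name in ("CG", "CD1", "NE1")]]
        coordsD = s.coords[[i for i in s.select(chain="D", resnum=583)
                            if s.atoms[i].name in ("CG", "CD1", "NE1")]]
        dac = np.linalg.norm(coordsA[:, None] - coordsC[None], axis=2).min()
        dbd = np.linalg.norm(coordsB[:, None] - coordsD[None], axis=2).min()
        assert dac == pytest.approx(dbd, abs=1e-9)

    def test_matches_exhaustive_pair_scan(self, tetramer_gate):
        s = tetramer_gate
        side = ("CG", "CD1", "NE1")
        chains = s.chains
        pairs = [(chains[0], chains[2]), (chains[1], chains[3])]
        best = np.inf
        for ca, cb in pairs:
            A = s.coords[[i for i in s.select(chain=ca, resnum=583)
                          if s.atoms[i].name in side]]
            B = s.coords[[i for i in s.select(chain=cb, resnum=583)
                          if s.atoms[i].name in side]]
            for a in A:
                for b in B:
                    best = min(best, float(np.linalg.norm(a - b)))
        assert facing_distance(s, 583) == pytest.approx(best, abs=1e-12)

    def test_single_chain_rejected(self):
        atoms = (AtomRecord(1, "CG", "TRP", 583, "A", np.zeros(3), "C", 1.7),)
        with pytest.raises(ValueError):
            facing_distance(Structure(atoms), 583, chains=["A"])


class TestGateRule:
    def test_calibrated_mapping(self):
        # 3.1 A facing distance -> 0.8 A passage with the default r_eff
        assert gate_aperture(3.1) == pytest.approx(0.8)

    def test_zero_r_eff_identity(self):
        assert gate_aperture(4.2, r_eff=0.0) == 4.2

    def test_clamped_at_zero(self):
        assert gate_aperture(2.3, r_eff=1.15) == 0.0

    def test_blocked_for_facing_gate(self):
        assert permeation_feasibility(0.8, 0.99) == "blocked"

    def test_boundary_counts_permeable(self):
        assert permeation_feasibility(0.99, 0.99) == "permeable"

    @given(
        d1=st.floats(0.0, 20.0),
        d2=st.floats(0.0, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_aperture_monotone_in_distance(self, d1, d2):
        if d1 <= d2:
            assert gate_aperture(d1) <= gate_aperture(d2)
        apertures = sorted([gate_aperture(d1), gate_aperture(d2)])
        verdicts = [permeation_feasibility(a) for a in apertures]
        # feasibility is monotone: once permeable, stays permeable
        assert not (verdicts[0] == "permeable" and verdicts[1] == "blocked")


class TestTetramerGateFixture:
    def test_facing_distance_is_target(self, tetramer_gate):
        assert facing_distance(tetramer_gate, 583) == pytest.approx(3.1, abs=1e-6)

    def test_rotamer_sweep_strictly_ordered(self, tetramer_gate):
        # facing < down < up in constriction radius on this fixture
        radii = {}
        for name, (chi1, chi2) in TRP_ROTAMER_TABLE.items():
            s = set_symmetric_rotamer(tetramer_gate, 583, list("ABCD"), chi1, chi2)
            prof = radius_profile(
                s, axis=(np.zeros(3), Z_AXIS), z_range=(-4.0, 4.0), z_step=0.5
            )
            radii[name] = min_constriction(prof)[1]
        assert radii["facing"] < radii["down"] < radii["up"]

    def test_facing_blocked_widened_permeable(self, tetramer_gate):
        d_facing = facing_distance(tetramer_gate, 583)
        assert permeation_feasibility(gate_aperture(d_facing)) == "blocked"
        for name in ("up", "down"):
            chi1, chi2 = TRP_ROTAMER_TABLE[name]
            s = set_symmetric_rotamer(tetramer_gate, 583, list("ABCD"), chi1, chi2)
            d = facing_distance(s, 583)
            assert permeation_feasibility(gate_aperture(d)) == "permeable"
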