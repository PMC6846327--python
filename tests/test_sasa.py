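"""Accessible-surface computation against closed forms and cross-checks.

The sampled areas are compared with analytic results (isolated sphere,
two-sphere spherical caps), with Bio.PDB's independent implementation, and
with the algorithm's own convergence and invariance properties.
"""

import copy
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from varstab.sasa import (
    MAX_ASA_TIEN,
    RsaProfile,
    SasaError,
    delta_rsa,
    is_buried,
    restrict_to_chain,
    rsa_profile,
    shrake_rupley,
)
from varstab.structures import read_pdb
from varstab.simulate import generate_toy_structure

from conftest import atoms_structure, single_atom_structure

PROBE = 1.4


def sphere_area(r):
    return 4.0 * math.pi * (r + PROBE) ** 2


def two_sphere_exposed_areas(r1, r2, d):
    """Closed-form exposed areas of two intersecting solvent-expanded spheres.

    The spherical cap of sphere 1 hidden inside sphere 2 has height
    h1 = R1 - (d² + R1² - R2²) / (2d) and area 2π R1 h1.
    """
    R1, R2 = r1 + PROBE, r2 + PROBE
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return (4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * h1,
            4 * math.pi * R2 ** 2 - 2 * math.pi * R2 * h2)


class TestShrakeRupley:
    def test_isolated_atom_matches_sphere_area(self):
        s = single_atom_structure(radius=1.70)
        result = shrake_rupley(s)
        area = result.per_residue[("A", 1)]
        assert area == pytest.approx(sphere_area(1.70), rel=0.01)
        # an isolated sphere is sampled exactly: every point is exposed
        assert area == pytest.approx(sphere_area(1.70), rel=1e-12)

    def test_distant_atoms_do_not_occlude(self):
        s = atoms_structure([(0, 0, 0), (100, 0, 0)])
        result = shrake_rupley(s)
        for pos in (1, 2):
            assert result.per_residue[("A", pos)] == pytest.approx(
                sphere_area(1.70), rel=1e-12)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5])
    def test_two_sphere_cap_closed_form(self, d):
        s = atoms_structure([(0, 0, 0), (d, 0, 0)])
        result = shrake_rupley(s)
        expect1, expect2 = two_sphere_exposed_areas(1.70, 1.70, d)
        assert result.per_residue[("A", 1)] == pytest.approx(expect1, rel=0.01)
        assert result.per_residue[("A", 2)] == pytest.approx(expect2, rel=0.01)

    def test_unequal_radii_cap_closed_form(self):
        s = atoms_structure([(0, 0, 0)], radius=1.70)
        # append a second, smaller atom by building a fresh structure
        from varstab.structures import Atom, ProteinStructure, Residue
        small = Residue(seq_number=2, aa="A", atoms=[
            Atom(name="N", element="N", coords=np.array([2.5, 0.0, 0.0]),
                 radius=1.55)])
        s = ProteinStructure("two", {"A": [s.chains["A"][0], small]})
        result = shrake_rupley(s)
        e1, e2 = two_sphere_exposed_areas(1.70, 1.55, 2.5)
        assert result.per_residue[("A", 1)] == pytest.approx(e1, rel=0.01)
        assert result.per_residue[("A", 2)] == pytest.approx(e2, rel=0.01)

    def test_total_invariant_under_rigid_motion(self, toy_helix):
        base = shrake_rupley(toy_helix).total()
        rng = np.random.default_rng(2)
        moved = copy.deepcopy(toy_helix)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        for _, _, atom in moved.iter_atoms():
            atom.coords = R @ atom.coords + t
        assert shrake_rupley(moved).total() == pytest.approx(base, rel=1e-6)

    def test_occlusion_is_monotone_in_atoms(self):
        # adding an atom can only remove exposed sample points (fixed frame)
        rng = np.random.default_rng(3)
        coords = list(rng.uniform(0, 6, (6, 3)))
        before = shrake_rupley(atoms_structure(coords), orient=False)
        coords.append(rng.uniform(0, 6, 3))
        after = shrake_rupley(atoms_structure(coords), orient=False)
        for pos in range(1, 7):
            assert after.per_residue[("A", pos)] <= \
                before.per_residue[("A", pos)] + 1e-12

    def test_quadrature_converges(self, toy_helix):
        coarse = shrake_rupley(toy_helix, n_points=960)
        fine = shrake_rupley(toy_helix, n_points=3840)
        for key, area in coarse.per_residue.items():
            assert area == pytest.approx(fine.per_residue[key],
                                         rel=0.01, abs=0.5)

    def test_per_residue_sums_per_atom(self, toy_complex):
        result = shrake_rupley(toy_complex)
        for (cid, pos), area in result.per_residue.items():
            parts = [v for (c, p, _), v in result.per_atom.items()
                     if (c, p) == (cid, pos)]
            assert area == pytest.approx(sum(parts), abs=1e-9)

    def test_matches_biopython_reference(self, toy_helix):
        # independent implementation on the same algorithmic definition
        bio = pytest.importorskip("Bio.PDB.SASA")
        from Bio.PDB import PDBParser
        import io
        from varstab.structures import write_pdb

        parser = PDBParser(QUIET=True)
        bio_structure = parser.get_structure("t", io.StringIO(write_pdb(toy_helix)))
        sr = bio.ShrakeRupley(probe_radius=PROBE, n_points=960,
                              radii_dict={"C": 1.70})
        sr.compute(bio_structure, level="R")
        ours = shrake_rupley(toy_helix, orient=False)
        for res in bio_structure.get_residues():
            mine = ours.per_residue[("A", res.id[1])]
            assert mine == pytest.approx(res.sasa, rel=0.02, abs=1.0)

    def test_too_few_points_rejected(self, toy_helix):
        with pytest.raises(SasaError):
            shrake_rupley(toy_helix, n_points=8)


class TestRsaProfile:
    def test_normalisation_arithmetic(self):
        # mean ASA across structures, then divide by the residue maximum
        s = single_atom_structure()
        prof = rsa_profile([(s, _fake_result({("A", 1): 64.5}, {("A", 1): "A"})),
                            (s, _fake_result({("A", 1): 64.5}, {("A", 1): "A"}))])
        assert prof.rsa[1] == pytest.approx(64.5 / MAX_ASA_TIEN["A"])
        assert prof.n_structures[1] == 2

    def test_mean_then_normalize(self):
        s = single_atom_structure()
        prof = rsa_profile([
            (s, _fake_result({("A", 1): 80.0}, {("A", 1): "W"})),
            (s, _fake_result({("A", 1): 120.0}, {("A", 1): "W"})),
        ])
        assert prof.mean_asa[1] == pytest.approx(100.0)
        assert prof.rsa[1] == pytest.approx(100.0 / MAX_ASA_TIEN["W"])

    def test_buried_core_of_dense_cluster(self):
        # a carbon caged by close neighbours on all sides is inaccessible
        shell = []
        for dx in (-2.2, 2.2):
            for dy in (-2.2, 2.2):
                for dz in (-2.2, 2.2):
                    shell.append((dx, dy, dz))
        shell += [(3.1, 0, 0), (-3.1, 0, 0), (0, 3.1, 0), (0, -3.1, 0),
                  (0, 0, 3.1), (0, 0, -3.1)]
        s = atoms_structure([(0.0, 0.0, 0.0)] + shell)
        result = shrake_rupley(s, n_points=3840)
        center_asa = result.per_residue[("A", 1)]
        rsa = center_asa / MAX_ASA_TIEN["A"]
        assert rsa < 0.02

    def test_unknown_residue_type_rejected(self):
        s = single_atom_structure()
        with pytest.raises(SasaError):
            rsa_profile([(s, _fake_result({("A", 1): 10.0}, {("A", 1): "X"}))])

    def test_tsv_roundtrip(self, tmp_path, toy_helix):
        prof = rsa_profile([(toy_helix, shrake_rupley(toy_helix))])
        path = tmp_path / "rsa.tsv"
        prof.to_tsv(str(path))
        again = RsaProfile.from_tsv(str(path))
        for pos, value in prof.rsa.items():
            assert again.rsa[pos] == pytest.approx(value, rel=1e-4)


def _fake_result(per_residue, residue_aa):
    from varstab.sasa import SasaResult
    return SasaResult(per_atom={}, per_residue=dict(per_residue),
                      residue_aa=dict(residue_aa), probe_radius=PROBE,
                      n_sphere_points=960)


class TestBurial:
    @pytest.mark.parametrize("rsa, buried", [
        (0.0, True), (0.19, True), (0.199999, True),
        (0.2, False), (0.5, False), (1.3, False),
    ])
    def test_strict_threshold(self, rsa, buried):
        assert is_buried(rsa) is buried

    def test_negative_rsa_rejected(self):
        with pytest.raises(SasaError):
            is_buried(-0.1)


class TestDeltaRsa:
    def test_identical_profiles_give_zero(self, toy_helix):
        prof = rsa_profile([(toy_helix, shrake_rupley(toy_helix))])
        d = delta_rsa(prof, prof)
        assert all(v == 0.0 for v in d.values())

    def test_interface_fixture(self):
        """Binding a second chain occludes contact residues, nothing grows."""
        pdb_complex = generate_toy_structure(20, ("A", "B"), seed=7)
        s_complex = read_pdb(pdb_complex, "cx")
        s_iso = s_complex.chain("A")
        # sample the complex whole so chain B occludes, then restrict to A;
        # fixed frame so the isolated chain sees the identical sample grid
        res_complex = restrict_to_chain(
            shrake_rupley(s_complex, orient=False), "A")
        res_iso = shrake_rupley(s_iso, orient=False)
        prof_complex = rsa_profile([(s_complex, res_complex)])
        prof_iso = rsa_profile([(s_iso, res_iso)])
        d = delta_rsa(prof_complex, prof_iso)
        assert min(d.values()) < -0.05          # genuine interface burial
        assert max(d.values()) <= 1e-12         # occlusion only
        # residues pointing away from the partner are essentially unchanged
        assert sum(1 for v in d.values() if abs(v) < 0.01) >= 3
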