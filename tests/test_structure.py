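import numpy as np
import pytest

from betapharm.errors import DomainError, MatchingError, SelectionError
from betapharm.structure import (
    AtomRecord,
    StructureModel,
    atom_distance,
    bfactor_delta,
    calpha_rmsd,
    dihedral,
    normalized_bfactors,
    read_structure,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00 20.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 20.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 20.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60 30.00           C
ATOM      3  CA  ALA A   2       3.000   4.000   0.000  1.00 10.00           C
END
"""


def _atom(chain, resnum, name, xyz, b=20.0, element=None, resname="ALA"):
    return AtomRecord(chain_id=chain, residue_number=resnum, insertion_code="",
                      residue_name=resname, atom_name=name, altloc="",
                      occupancy=1.0, element=element or name[0],
                      xyz=tuple(float(v) for v in xyz), b_factor=b)


def _model(atoms):
    return StructureModel(atoms=atoms, source="in-memory")


def _transformed(model, R=None, shift=(0.0, 0.0, 0.0)):
    R = np.eye(3) if R is None else R
    shift = np.asarray(shift)
    atoms = [
        AtomRecord(chain_id=a.chain_id, residue_number=a.residue_number,
                   insertion_code=a.insertion_code, residue_name=a.residue_name,
                   atom_name=a.atom_name, altloc=a.altloc, occupancy=a.occupancy,
                   element=a.element, xyz=tuple(R @ np.asarray(a.xyz) + shift),
                   b_factor=a.b_factor)
        for a in model.atoms
    ]
    return _model(atoms)


def _rot(deg, axis=(0.0, 0.0, 1.0)):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    r = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(r) * K + (1 - np.cos(r)) * (K @ K)


class TestReadStructure:
    def test_minimal_pdb_parses_three_atoms(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        m = read_structure(p)
        assert len(m.atoms) == 3
        ca = m.resolve(("A", 1, "CA"))
        assert ca.xyz == pytest.approx((1.5, 0.0, 0.0))
        assert ca.b_factor == 20.0

    def test_altloc_resolution_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        m = read_structure(p)
        assert len(m.atoms) == 2
        kept = m.resolve(("A", 1, "CA"))
        assert kept.occupancy == pytest.approx(0.6)  # the B conformer wins
        assert kept.xyz[0] == pytest.approx(9.0)

    def test_mmcif_gives_identical_model(self, tmp_path):
        import gemmi

        pdb = tmp_path / "mini.pdb"
        pdb.write_text(MINIMAL_PDB)
        st = gemmi.read_structure(str(pdb))
        st.setup_entities()
        cif = tmp_path / "mini.cif"
        st.make_mmcif_document().write_file(str(cif))
        m1 = read_structure(pdb)
        m2 = read_structure(cif)
        assert len(m1.atoms) == len(m2.atoms)
        for a, b in zip(m1.atoms, m2.atoms):
            assert a.xyz == pytest.approx(b.xyz)
            assert a.b_factor == pytest.approx(b.b_factor)
            assert (a.chain_id, a.residue_number, a.atom_name) == \
                   (b.chain_id, b.residue_number, b.atom_name)


class TestAtomDistance:
    def test_pythagorean_triplet(self):
        m = _model([_atom("A", 1, "CA", (0, 0, 0)),
                    _atom("A", 2, "CA", (3, 4, 0))])
        assert atom_distance(m, ("A", 1, "CA"), ("A", 2, "CA")) == 5.0

    def test_identical_selector_gives_zero(self):
        m = _model([_atom("A", 1, "CA", (1, 2, 3))])
        assert atom_distance(m, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0

    def test_unresolved_selector_raises(self):
        m = _model([_atom("A", 1, "CA", (0, 0, 0))])
        with pytest.raises(SelectionError, match="residue=99"):
            atom_distance(m, ("A", 1, "CA"), ("A", 99, "CZ"))

    def test_rigid_transform_invariance(self):
        m = _model([_atom("A", 1, "CA", (0, 0, 0)),
                    _atom("A", 2, "CA", (3, 4, 0))])
        m2 = _transformed(m, _rot(63.0, (1, 1, 0)), (5, -2, 7))
        d1 = atom_distance(m, ("A", 1, "CA"), ("A", 2, "CA"))
        d2 = atom_distance(m2, ("A", 1, "CA"), ("A", 2, "CA"))
        assert d1 == pytest.approx(d2, abs=1e-9)


def _helix_model(n=12, b=None):
    atoms = []
    for i in range(n):
        theta = np.radians(100.0 * i)
        ca = (2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i)
        atoms.append(_atom("A", i + 1, "CA", ca,
                           b=(b[i] if b is not None else 20.0)))
    return _model(atoms)


class TestCalphaRmsd:
    def test_self_comparison_is_zero(self):
        m = _helix_model()
        rmsd, n = calpha_rmsd(m, m)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert n == 12

    def test_rigid_copy_superposes_exactly(self):
        m = _helix_model()
        m2 = _transformed(m, _rot(35.0, (1, 2, 3)), (10, -4, 2))
        rmsd, _ = calpha_rmsd(m, m2)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_and_transform_invariance(self):
        rng = np.random.default_rng(0)
        m = _helix_model()
        jittered = _model([
            _atom(a.chain_id, a.residue_number, a.atom_name,
                  np.asarray(a.xyz) + rng.normal(0, 0.3, 3))
            for a in m.atoms
        ])
        r_ab, _ = calpha_rmsd(m, jittered)
        r_ba, _ = calpha_rmsd(jittered, m)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        moved = _transformed(jittered, _rot(120.0, (0, 1, 1)), (3, 3, 3))
        r_moved, _ = calpha_rmsd(m, moved)
        assert r_moved == pytest.approx(r_ab, abs=1e-9)

    def test_reflection_guard(self):
        """A mirrored structure must not superpose to zero via an improper rotation."""
        m = _helix_model()
        mirrored = _model([
            _atom(a.chain_id, a.residue_number, a.atom_name,
                  (a.xyz[0], a.xyz[1], -a.xyz[2]))
            for a in m.atoms
        ])
        rmsd, _ = calpha_rmsd(m, mirrored)
        assert rmsd > 0.5

    def test_too_few_matches_raises(self):
        m1 = _helix_model(3)
        m2 = _model([_atom("A", 50, "CA", (0, 0, 0)),
                     _atom("A", 51, "CA", (3, 0, 0)),
                     _atom("A", 52, "CA", (6, 0, 0))])
        with pytest.raises(MatchingError):
            calpha_rmsd(m1, m2)


class TestNormalizedBFactors:
    def test_uniform_bfactors_normalize_to_one(self):
        prof = normalized_bfactors(_helix_model(b=[30.0] * 12))
        assert all(nb == pytest.approx(1.0) for *_x, nb in prof.entries)

    def test_scale_invariance(self):
        b = np.linspace(10, 50, 12)
        p1 = normalized_bfactors(_helix_model(b=b))
        p2 = normalized_bfactors(_helix_model(b=2.0 * b))
        for (*_a, n1), (*_b, n2) in zip(p1.entries, p2.entries):
            assert n1 == pytest.approx(n2, rel=1e-12)

    def test_two_residue_hand_arithmetic(self):
        # equal atom counts, B = 20 and 40 -> overall 30 -> 0.6667 / 1.3333
        m = _model([_atom("A", 1, "N", (0, 0, 0), b=20.0),
                    _atom("A", 1, "CA", (1, 0, 0), b=20.0),
                    _atom("A", 2, "N", (2, 0, 0), b=40.0),
                    _atom("A", 2, "CA", (3, 0, 0), b=40.0)])
        prof = normalized_bfactors(m)
        normalized = prof.normalized()
        assert normalized[("A", 1)] == pytest.approx(2.0 / 3.0, abs=1e-4)
        assert normalized[("A", 2)] == pytest.approx(4.0 / 3.0, abs=1e-4)

    def test_hydrogens_excluded_from_statistics(self):
        m = _model([_atom("A", 1, "CA", (0, 0, 0), b=20.0),
                    _atom("A", 1, "H", (0.5, 0, 0), b=99.0, element="H"),
                    _atom("A", 2, "CA", (3, 0, 0), b=40.0)])
        prof = normalized_bfactors(m)
        assert prof.overall_b == pytest.approx(30.0)

    def test_atom_weighted_mean_is_exactly_one(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(5, 80, 12)
        prof = normalized_bfactors(_helix_model(b=b))
        weights = prof.n_atoms_per_residue
        total = sum(weights.values())
        mean = sum(weights[(c, r)] * nb for c, r, _n, _mb, nb in prof.entries) / total
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_empty_selection_raises(self):
        with pytest.raises(SelectionError):
            normalized_bfactors(_helix_model(), chain_id="Z")


class TestBFactorDelta:
    def test_self_delta_all_zero_unchanged(self):
        prof = normalized_bfactors(_helix_model(b=np.linspace(10, 50, 12)))
        deltas = bfactor_delta(prof, prof)
        assert all(d == 0.0 and cls == "unchanged" for _c, _r, d, cls in deltas)

    def test_uniform_shift_same_sign_everywhere(self):
        b = np.linspace(10, 50, 12)
        pa = normalized_bfactors(_helix_model(b=b))
        # same normalized profile shifted: construct directly
        from betapharm.structure import ResidueBFactorProfile

        pb = ResidueBFactorProfile(
            entries=[(c, r, n, mb, nb - 0.05) for c, r, n, mb, nb in pa.entries],
            overall_b=pa.overall_b, n_atoms_per_residue=pa.n_atoms_per_residue)
        deltas = bfactor_delta(pa, pb)
        assert all(cls == "increased" for *_x, cls in deltas)
        vals = [d for _c, _r, d, _cls in deltas]
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_residue_sets_raise(self):
        pa = normalized_bfactors(_helix_model(4))
        pb = normalized_bfactors(_model(
            [_atom("B", 100 + i, "CA", (i * 3.0, 0, 0)) for i in range(4)]))
        with pytest.raises(MatchingError):
            bfactor_delta(pa, pb)


class TestDihedral:
    def _four(self, last):
        return _model([_atom("A", 1, "C1", (0, 1, 0), element="C"),
                       _atom("A", 1, "C2", (0, 0, 0), element="C"),
                       _atom("A", 1, "C3", (1, 0, 0), element="C"),
                       _atom("A", 1, "C4", last, element="C")])

    SELS = (("A", 1, "C1"), ("A", 1, "C2"), ("A", 1, "C3"), ("A", 1, "C4"))

    def test_planar_cis_is_zero(self):
        m = self._four((1, 1, 0))
        assert dihedral(m, *self.SELS) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        m = self._four((1, -1, 0))
        assert abs(dihedral(m, *self.SELS)) == pytest.approx(180.0, abs=1e-9)

    def test_mirror_image_flips_sign(self):
        m = self._four((1, 0.5, 0.8))
        ang = dihedral(m, *self.SELS)
        mirrored = self._four((1, 0.5, -0.8))
        mirrored = _model([
            _atom(a.chain_id, 1, a.atom_name,
                  (a.xyz[0], a.xyz[1], -a.xyz[2]), element="C")
            for a in self._four((1, 0.5, 0.8)).atoms
        ])
        assert dihedral(mirrored, *self.SELS) == pytest.approx(-ang, abs=1e-9)

    def test_rigid_transform_invariance(self):
        m = self._four((1, 0.5, 0.8))
        ang = dihedral(m, *self.SELS)
        moved = _transformed(m, _rot(77.0, (2, 1, 5)), (1, 2, 3))
        assert dihedral(moved, *self.SELS) == pytest.approx(ang, abs=1e-9)

    def test_collinear_atoms_undefined(self):
        m = _model([_atom("A", 1, "C1", (0, 0, 0), element="C"),
                    _atom("A", 1, "C2", (1, 0, 0), element="C"),
                    _atom("A", 1, "C3", (2, 0, 0), element="C"),
                    _atom("A", 1, "C4", (3, 1, 0), element="C")])
        with pytest.raises(DomainError, match="collinear"):
            dihedral(m, *self.SELS)
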