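"""Distances, torsions, H-bond detection, and turn flags on constructed
geometries; the torsion implementation is cross-checked against RDKit's."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem import rdMolTransforms

from alphaturn import (
    HBondCriteria,
    detect_hbonds,
    dihedral,
    flag_turns,
    measure_distance,
    virtual_torsions,
)
from alphaturn.geometry import GeometryError, bond_angle, kabsch_rmsd

coord = st.floats(min_value=-10, max_value=10, allow_nan=False)
point = st.tuples(coord, coord, coord).map(np.array)


def _rdkit_dihedral(p0, p1, p2, p3):
    """Independent oracle: RDKit's dihedral on a dummy 4-atom conformer."""
    mol = Chem.RWMol()
    for _ in range(4):
        mol.AddAtom(Chem.Atom(6))
    conf = Chem.Conformer(4)
    for i, p in enumerate((p0, p1, p2, p3)):
        conf.SetAtomPosition(i, [float(x) for x in p])
    m = mol.GetMol()
    m.AddConformer(conf)
    return rdMolTransforms.GetDihedralDeg(m.GetConformer(), 0, 1, 2, 3)


class TestPrimitives:
    def test_distance_identity_and_boundary(self):
        pts = np.array([[0.0, 0.0, 0.0], [7.0, 0.0, 0.0]])
        assert measure_distance(pts, 0, 0) == 0.0
        assert measure_distance(pts, 0, 1) == 7.0  # probe needs strictly < 7

    def test_invalid_atom_id(self):
        with pytest.raises(GeometryError):
            measure_distance(np.zeros((2, 3)), 0, 5)

    @given(point, point, point, point)
    @settings(max_examples=200, deadline=None)
    def test_dihedral_matches_rdkit(self, p0, p1, p2, p3):
        # reject degenerate (collinear / coincident) frames
        for a, b in [(p0, p1), (p1, p2), (p2, p3)]:
            if np.linalg.norm(a - b) < 1e-3:
                return
        if (
            np.linalg.norm(np.cross(p0 - p1, p2 - p1)) < 1e-3
            or np.linalg.norm(np.cross(p1 - p2, p3 - p2)) < 1e-3
        ):
            return
        ours = dihedral(p0, p1, p2, p3)
        oracle = _rdkit_dihedral(p0, p1, p2, p3)
        diff = abs((ours - oracle + 180) % 360 - 180)
        assert diff < 1e-6

    def test_planar_zigzag_torsions(self):
        pts = np.array(
            [[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0], [4, 0, 0]], dtype=float
        )
        assert abs(dihedral(*pts[:4])) == pytest.approx(180.0)

    def test_bond_angle_right(self):
        assert bond_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_kabsch_rmsd_of_rotated_copy_is_zero(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(12, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        q = p @ rot.T + np.array([1.0, -2.0, 3.0])
        assert kabsch_rmsd(p, q) < 1e-10


class TestDetectHbonds:
    def test_inverse_gamma_gives_single_seven_ring(self, inverse_gamma, criteria):
        g, conf, roles = inverse_gamma
        contacts = detect_hbonds(conf, g, criteria, roles)
        assert len(contacts) == 1
        hb = contacts[0]
        assert hb.ring_size == 7 and hb.label == "5→3"
        # the reported contact satisfies the criteria exactly as stated
        assert hb.distance <= criteria.max_ha_distance
        assert hb.angle >= criteria.min_dha_angle

    def test_helix_gives_thirteen_ring(self, helix, criteria):
        g, conf, roles = helix
        contacts = detect_hbonds(conf, g, criteria, roles)
        assert any(hb.ring_size == 13 and hb.label == "5→1" for hb in contacts)

    def test_extended_chain_has_none(self, extended, criteria):
        g, conf, roles = extended
        assert detect_hbonds(conf, g, criteria, roles) == []

    def test_heavy_atom_mode(self, helix):
        g, conf, roles = helix
        crit = HBondCriteria(mode="heavy")
        contacts = detect_hbonds(conf, g, crit, roles)
        assert any(hb.ring_size == 13 for hb in contacts)
        assert all(hb.angle is None for hb in contacts)

    def test_bad_criteria_rejected(self):
        with pytest.raises(GeometryError):
            HBondCriteria(max_ha_distance=-1)
        with pytest.raises(GeometryError):
            HBondCriteria(min_dha_angle=270)


class TestVirtualTorsions:
    def test_round_trip_on_helix(self, helix):
        g, conf, roles = helix
        tors = virtual_torsions(conf, roles)
        for k in (2, 3, 4):
            phi, psi = tors[k]
            assert phi == pytest.approx(-63.0, abs=0.5)
            assert psi == pytest.approx(-42.0, abs=0.5)

    def test_terminal_residues_partial(self, helix):
        _g, conf, roles = helix
        tors = virtual_torsions(conf, roles)
        assert tors[1][0] is None  # no preceding C' for phi(1)
        assert tors[5][1] is None  # no following N for psi(5)


class TestFlagTurns:
    def test_helix_flags(self, helix, criteria):
        g, conf, roles = helix
        fl = flag_turns(conf, g, criteria, roles)
        assert fl.has_hbond_b and not fl.has_hbond_a
        assert fl.dalpha < 7.0 and fl.dalpha_probe_pass
        assert 5.5 <= fl.dalpha <= 7.0  # canonical CA(i)-CA(i+4) range

    def test_gamma_flags(self, inverse_gamma, criteria):
        g, conf, roles = inverse_gamma
        fl = flag_turns(conf, g, criteria, roles)
        assert fl.has_hbond_a and not fl.has_hbond_b

    def test_extended_flags(self, extended, criteria):
        g, conf, roles = extended
        fl = flag_turns(conf, g, criteria, roles)
        assert not fl.has_hbond_a and not fl.has_hbond_b
        assert fl.dalpha > 7.0 and not fl.dalpha_probe_pass

    def test_dalpha_invariant_under_rigid_motion(self, helix, criteria):
        g, conf, roles = helix
        fl0 = flag_turns(conf, g, criteria, roles)
        rng = np.random.default_rng(42)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = conf.coords @ q.T + np.array([5.0, -3.0, 11.0])
        fl1 = flag_turns(moved, g, criteria, roles)
        assert fl1.dalpha == pytest.approx(fl0.dalpha, abs=1e-9)
        assert fl1.has_hbond_b == fl0.has_hbond_b
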