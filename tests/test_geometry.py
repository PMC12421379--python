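"""Geometry primitives against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4kit import geometry
from g4kit.geometry import (
    DegenerateGeometryError,
    classify_glycosidic,
    dihedral,
    ls_plane,
    normalize_angle,
    pucker_from_nus,
    sugar_pucker,
    superpose_rmsd,
)

from conftest import random_rotation


def oracle_dihedral(p1, p2, p3, p4) -> float:
    """Two-plane definition: signed angle between the (p1,p2,p3) and
    (p2,p3,p4) planes about the p2->p3 axis, coded independently."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


def oracle_plane_normal(points) -> np.ndarray:
    """Covariance eigen-decomposition oracle for the least-squares plane."""
    pts = np.asarray(points, float)
    cov = np.cov((pts - pts.mean(0)).T)
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, 0]


def oracle_quaternion_rmsd(ref, mov) -> float:
    """Horn's closed-form quaternion superposition (independent of Kabsch)."""
    ref = np.asarray(ref, float) - np.mean(ref, axis=0)
    mov = np.asarray(mov, float) - np.mean(mov, axis=0)
    M = mov.T @ ref
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e = float(np.sum(ref**2) + np.sum(mov**2) - 2.0 * lam)
    return math.sqrt(max(e, 0.0) / len(ref))


class TestDihedral:
    def test_cis_is_zero(self):
        p = [np.array(v, float) for v in [(1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)]]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        p = [np.array(v, float) for v in [(1, 1, 0), (0, 1, 0), (0, 0, 0), (-1, 0, 0)]]
        assert abs(dihedral(*p)) == pytest.approx(180.0, abs=1e-12)

    def test_agrees_with_two_plane_oracle(self):
        rng = np.random.default_rng(7)
        n = 0
        while n < 1000:
            pts = rng.uniform(-5, 5, size=(4, 3))
            if min(np.linalg.norm(np.diff(pts, axis=0), axis=1)) < 0.5:
                continue
            try:
                got = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            want = oracle_dihedral(*pts)
            assert abs(normalize_angle(got - want)) < 1e-9
            n += 1

    def test_collinear_axis_raises(self):
        a = np.array([0.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            dihedral(a, np.array([1.0, 0, 0]), np.array([2.0, 0, 0]), np.array([3.0, 0, 0]))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_invariance_and_reversal(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-4, 4, size=(4, 3))
        if min(np.linalg.norm(np.diff(pts, axis=0), axis=1)) < 0.5:
            return
        try:
            base = dihedral(*pts)
        except DegenerateGeometryError:
            return
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, size=3)
        moved = [R @ p + t for p in pts]
        assert dihedral(*moved) == pytest.approx(base, abs=1e-8)
        # reversing the point order preserves the torsion value
        assert dihedral(*pts[::-1]) == pytest.approx(base, abs=1e-9)


class TestPlane:
    def test_exactly_coplanar(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert ls_plane(pts).rms_dev == pytest.approx(0.0, abs=1e-12)

    def test_jitter_bound(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, size=(20, 3))
        h = 0.2
        pts[:, 2] = rng.uniform(-h, h, size=20)
        assert ls_plane(pts).rms_dev <= h

    def test_normal_matches_eigen_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            pts = rng.normal(size=(8, 3)) * [3.0, 2.0, 0.4]
            got = ls_plane(pts).normal
            want = oracle_plane_normal(pts)
            assert min(np.linalg.norm(got - want), np.linalg.norm(got + want)) < 1e-9

    def test_collinear_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            ls_plane(pts)


class TestSuperpose:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        assert superpose_rmsd(pts, pts)[2] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        R = random_rotation(rng)
        moved = (R @ pts.T).T + [3.0, -2.0, 7.0]
        assert superpose_rmsd(pts, moved)[2] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom(self):
        rng = np.random.default_rng(2)
        n = 16
        pts = rng.normal(size=(n, 3)) * 4
        moved = pts.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        _, _, rmsd = superpose_rmsd(pts, moved)
        # after refitting, the residual is slightly below sqrt(1/n)
        assert rmsd <= math.sqrt(1.0 / n) + 1e-9
        assert rmsd > 0.5 * math.sqrt(1.0 / n)
        assert rmsd == pytest.approx(oracle_quaternion_rmsd(pts, moved), abs=1e-9)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            ref = rng.normal(size=(8, 3)) * 3
            mov = ref + rng.normal(size=(8, 3)) * 0.5
            assert superpose_rmsd(ref, mov)[2] == pytest.approx(
                oracle_quaternion_rmsd(ref, mov), abs=1e-9
            )

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(9, 3))
        b = a + rng.normal(size=(9, 3)) * 0.3
        assert superpose_rmsd(a, b)[2] == pytest.approx(superpose_rmsd(b, a)[2], abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestPucker:
    def test_stated_nu_set_is_c2_endo(self):
        # closed-form evaluation of the pseudorotation relation for this set:
        # tan P = ((1.5+37.2)-(22.1-25.0)) / (2*(-35.0)*(sin36+sin72))
        nus = (-25.0, 37.2, -35.0, 22.1, 1.5)
        num = (nus[4] + nus[1]) - (nus[3] + nus[0])
        den = 2.0 * nus[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
        expected_p = math.degrees(math.atan(num / den)) + 180.0
        phase, amp, cls = pucker_from_nus(nus)
        assert phase == pytest.approx(expected_p, abs=1e-9)
        assert 144.0 <= phase < 180.0
        assert cls == "C2'-endo"
        assert amp > 30.0

    def test_max_nu2_symmetric_is_c3_endo(self):
        # nu_j = numax * cos((j - 2) * 144) is the P = 0 limit: nu2 at its
        # maximum with symmetric flanking torsions -> C3'-endo
        numax = 37.0
        nus = [numax * math.cos(math.radians(144.0 * (j - 2))) for j in range(5)]
        phase, amp, cls = pucker_from_nus(nus)
        assert phase == pytest.approx(0.0, abs=1e-6) or phase == pytest.approx(360.0, abs=1e-6)
        assert amp == pytest.approx(numax, abs=1e-6)
        assert cls == "C3'-endo"

    def test_flat_ring_degenerate(self):
        phase, amp, cls = pucker_from_nus((0.0, 0.0, 0.0, 0.0, 0.0))
        assert phase is None and amp == 0.0 and cls is None

    def test_rigid_motion_invariance(self, ideal_dg_residue):
        phase0, amp0, cls0 = sugar_pucker(ideal_dg_residue)
        assert phase0 is not None and amp0 > 0 and cls0 in geometry.PUCKER_BINS
        rng = np.random.default_rng(21)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)
        for a in ideal_dg_residue.atoms:
            a.pos = R @ a.pos + t
        phase1, amp1, cls1 = sugar_pucker(ideal_dg_residue)
        assert phase1 == pytest.approx(phase0, abs=1e-8)
        assert amp1 == pytest.approx(amp0, abs=1e-8)
        assert cls1 == cls0


class TestGlycosidic:
    @pytest.mark.parametrize(
        "chi,expected",
        [(60.0, "syn"), (-120.0, "anti"), (90.0, "syn"), (-90.0, "anti"), (180.0, "anti")],
    )
    def test_boundary_convention(self, chi, expected):
        assert classify_glycosidic(chi) == expected


class TestBackboneTorsions:
    def test_single_residue_chain_boundaries(self, ideal_dg_residue):
        profiles = geometry.backbone_torsions([ideal_dg_residue])
        p = profiles[0]
        assert p.alpha is None and p.epsilon is None and p.zeta is None
        assert p.delta is not None
        assert p.chi is not None
        assert p.glycosidic in ("syn", "anti")

    def test_torsion_roundtrip_through_forward_kinematics(self):
        from g4kit.synthetic_data import backbone_from_torsions

        targets = [
            dict(alpha=-62.0, beta=176.0, gamma=54.0, delta=128.0, epsilon=-178.0, zeta=-95.0),
            dict(alpha=-70.0, beta=170.0, gamma=60.0, delta=140.0, epsilon=-170.0, zeta=-90.0),
            dict(alpha=150.0, beta=-160.0, gamma=45.0, delta=85.0, epsilon=-150.0, zeta=70.0),
        ]
        model = backbone_from_torsions(targets)
        profiles = geometry.backbone_torsions(list(model.chains["A"]))
        for i, p in enumerate(profiles):
            for name in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"):
                got = getattr(p, name)
                if got is None:
                    continue
                assert abs(normalize_angle(got - targets[i][name])) < 0.5

    def test_torsion_table_columns(self, ideal_dg_residue):
        table = geometry.torsion_table(geometry.backbone_torsions([ideal_dg_residue]))
        assert list(table.columns)[:3] == ["chain_id", "seq_num", "res_name"]
        assert len(table) == 1
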