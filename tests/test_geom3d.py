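"""Geometry: pair detection, trajectories, SVD line fits, bend angles,
and Kabsch superposition against a quaternion oracle."""

import numpy as np
import pytest

from locsig import geom3d, synth
from locsig.geom3d import (
    AxisTrajectory,
    bend_angle,
    detect_base_pairs,
    fit_line_svd,
    helical_trajectory,
    kabsch_superpose,
    load_trajectory,
)
from locsig.io import Atom, Structure3D


def rigid_transform(structure: Structure3D, rot: np.ndarray, trans: np.ndarray) -> Structure3D:
    atoms = [
        Atom(a.chain, a.resnum, a.resname, a.name, *(rot @ a.pos + trans))
        for a in structure.atoms
    ]
    return Structure3D(atoms=atoms, chain_types=dict(structure.chain_types))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def quaternion_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: optimal-RMSD via the Horn quaternion method."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = ((a0**2).sum() + (b0**2).sum())
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / len(a)))


class TestDetectBasePairs:
    def test_ideal_helix_exact_recovery(self):
        """All programmed pairs recovered with no extras on a noiseless
        generated duplex."""
        st, truth = synth.build_kinked_helix(synth.HelixSpec(seed=2))
        pt = detect_base_pairs(st, "A")
        assert sorted(pt.pairs) == truth["pairs"]

    def test_kinked_helix_exact_recovery(self):
        st, truth = synth.build_kinked_helix(synth.HelixSpec(kink_deg=26.0, seed=3))
        pt = detect_base_pairs(st, "A")
        assert sorted(pt.pairs) == truth["pairs"]

    def test_distant_residues_not_paired(self):
        atoms = []
        for resnum, x in ((1, 0.0), (8, 50.0)):
            for name, dx in (("C1'", 0.0), ("N1", 1.4), ("C2", 2.0), ("N3", 2.8),
                             ("C4", 3.4), ("C5", 3.0), ("C6", 2.0)):
                atoms.append(Atom("A", resnum, "U", name, x + dx, 0.1 * dx, 0.0))
        st = Structure3D(atoms=atoms, chain_types={"A": "RNA"})
        assert detect_base_pairs(st, "A").pairs == ()

    def test_non_rna_chain_rejected(self):
        st = Structure3D(
            atoms=[Atom("B", 1, "ALA", "CA", 0, 0, 0)], chain_types={"B": "protein"}
        )
        with pytest.raises(ValueError, match="not classified as RNA"):
            detect_base_pairs(st, "B")


class TestTrajectory:
    def test_straight_helix_collinear(self):
        st, truth = synth.build_kinked_helix(synth.HelixSpec(kink_deg=0.0, seed=4))
        traj = helical_trajectory(st, truth["pairs"], "A")
        fit = fit_line_svd(traj.points)
        dists = np.linalg.norm(
            (traj.points - fit.centroid)
            - np.outer((traj.points - fit.centroid) @ fit.direction, fit.direction),
            axis=1,
        )
        assert dists.max() < 0.8

    def test_rigid_equivariance(self):
        st, truth = synth.build_kinked_helix(synth.HelixSpec(kink_deg=19.0, seed=5))
        rng = np.random.default_rng(5)
        rot, trans = random_rotation(rng), rng.normal(size=3) * 30
        st2 = rigid_transform(st, rot, trans)
        t1 = helical_trajectory(st, truth["pairs"], "A")
        t2 = helical_trajectory(st2, truth["pairs"], "A")
        assert np.allclose(t2.points, t1.points @ rot.T + trans, atol=1e-6)

    def test_imported_passthrough(self, tmp_path):
        pts = np.arange(30, dtype=float).reshape(10, 3) * 7.0  # spacing > 6 Å
        p = tmp_path / "traj.tsv"
        p.write_text(
            "index\tx\ty\tz\n"
            + "\n".join(f"{i}\t{x}\t{y}\t{z}" for i, (x, y, z) in enumerate(pts))
        )
        traj = load_trajectory(p)
        assert traj.source == "imported"
        assert np.allclose(traj.points, pts)  # spacing invariant not applied

    def test_computed_spacing_invariant(self):
        with pytest.raises(ValueError, match="spacing"):
            AxisTrajectory(points=np.array([[0, 0, 0], [0, 0, 10.0]]), source="computed")


class TestFitLineSvd:
    def test_collinear_closed_form(self):
        pts = np.array([[0, 0, 0], [1, 2, 2], [2, 4, 4], [3, 6, 6]], dtype=float)
        fit = fit_line_svd(pts)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.direction, np.array([1, 2, 2]) / 3.0)

    def test_two_points(self):
        fit = fit_line_svd(np.array([[0.0, 0, 0], [0, 3, 4]]))
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.direction, [0, 0.6, 0.8])

    def test_noisy_direction_within_5_degrees(self):
        rng = np.random.default_rng(7)
        truth = np.array([0.0, 0.0, 1.0])
        pts = np.outer(np.arange(10) * 2.8, truth) + rng.normal(0, 0.3, (10, 3))
        fit = fit_line_svd(pts)
        ang = np.degrees(np.arccos(abs(fit.direction @ truth)))
        assert ang < 5.0

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_line_svd(np.ones((5, 3)))

    def test_minimizes_perpendicular_rss(self):
        """No random candidate line out of 10^4 beats the SVD fit."""
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 3)) + np.outer(np.arange(12), [1.0, 0.5, -0.3])
        fit = fit_line_svd(pts)

        def rss(centroid, direction):
            c = pts - centroid
            return ((c**2).sum(axis=1) - (c @ direction) ** 2).sum()

        best = rss(fit.centroid, fit.direction)
        dirs = rng.normal(size=(10_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for d in dirs:
            assert rss(pts.mean(axis=0), d) >= best - 1e-9


class TestBendAngle:
    def test_straight_limit(self):
        st, truth = synth.build_kinked_helix(synth.HelixSpec(kink_deg=0.0, seed=8))
        traj = helical_trajectory(st, truth["pairs"], "A")
        for split in (4, 7, 10):
            res = bend_angle(traj, (0, split - 1), (split, len(traj) - 1))
            assert res.angle_deg < 2.0

    @pytest.mark.parametrize("kink", [10.0, 19.0, 26.0, 45.0])
    def test_programmed_kink_recovered(self, kink):
        st, truth = synth.build_kinked_helix(
            synth.HelixSpec(kink_deg=kink, noise_sigma=0.3, seed=int(kink))
        )
        traj = helical_trajectory(st, truth["pairs"], "A")
        res = bend_angle(traj, truth["lower_traj_range"], truth["upper_traj_range"])
        assert res.angle_deg == pytest.approx(kink, abs=2.0)

    def test_orientation_convention_stable_under_reversal(self):
        """Reversing the point order within one range leaves the angle
        unchanged because directions are re-oriented base -> loop."""
        st, truth = synth.build_kinked_helix(synth.HelixSpec(kink_deg=26.0, seed=9))
        traj = helical_trajectory(st, truth["pairs"], "A")
        res = bend_angle(traj, truth["lower_traj_range"], truth["upper_traj_range"])
        lo = truth["lower_traj_range"]
        flipped = np.concatenate(
            [traj.points[lo[0] : lo[1] + 1][::-1], traj.points[lo[1] + 1 :]]
        )
        res2 = bend_angle(
            AxisTrajectory(points=flipped, source="imported"),
            truth["lower_traj_range"],
            truth["upper_traj_range"],
        )
        assert res2.angle_deg == pytest.approx(res.angle_deg, abs=1e-6)

    def test_rigid_invariance(self):
        st, truth = synth.build_kinked_helix(synth.HelixSpec(kink_deg=26.0, seed=10))
        rng = np.random.default_rng(10)
        st2 = rigid_transform(st, random_rotation(rng), rng.normal(size=3) * 20)
        t1 = helical_trajectory(st, truth["pairs"], "A")
        t2 = helical_trajectory(st2, truth["pairs"], "A")
        r1 = bend_angle(t1, truth["lower_traj_range"], truth["upper_traj_range"])
        r2 = bend_angle(t2, truth["lower_traj_range"], truth["upper_traj_range"])
        assert abs(r1.angle_deg - r2.angle_deg) < 1e-6

    def test_scale_invariance(self):
        st, truth = synth.build_kinked_helix(synth.HelixSpec(kink_deg=19.0, seed=11))
        traj = helical_trajectory(st, truth["pairs"], "A")
        scaled = AxisTrajectory(points=traj.points * 1.7, source="imported")
        r1 = bend_angle(traj, truth["lower_traj_range"], truth["upper_traj_range"])
        r2 = bend_angle(scaled, truth["lower_traj_range"], truth["upper_traj_range"])
        assert abs(r1.angle_deg - r2.angle_deg) < 1e-9

    def test_overlapping_ranges_rejected(self):
        st, truth = synth.build_kinked_helix(synth.HelixSpec(seed=12))
        traj = helical_trajectory(st, truth["pairs"], "A")
        with pytest.raises(ValueError, match="overlap"):
            bend_angle(traj, (0, 8), (5, 14))


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_exact_recovery_of_applied_transform(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(15, 3))
        rot_true = random_rotation(rng)
        trans_true = rng.normal(size=3) * 10
        b = (a - trans_true) @ rot_true  # so that rot @ b + trans == a
        rot, trans, rmsd = kabsch_superpose(a, b)
        assert rmsd < 1e-9
        assert np.allclose(rot, rot_true, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_degenerate_rank_warned(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="rank"):
            kabsch_superpose(line, line)
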