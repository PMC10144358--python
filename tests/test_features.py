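"""Geometric feature oracles: plane normals, dihedrals, C2-CSM, SDF, scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import medoidspec as ms
from medoidspec import synthetic as syn
from medoidspec.features import _body_frame
from medoidspec.trajectory import AtomSelection, Frame, Trajectory


def rigid_motion(coords, seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(2**31)))
    return rot.apply(np.array(coords)) + rng.uniform(-5, 5, size=3)


class TestPlaneNormal:
    def test_planar_counterclockwise_points_give_plus_z(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0.5, 0.5, 0]])
        assert np.allclose(ms.plane_normal(pts), [0, 0, 1], atol=1e-12)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        with pytest.raises(ValueError, match="degenerate"):
            ms.plane_normal(pts)

    def test_matches_svd_smallest_singular_vector(self, rng):
        # 20 noisy points near a random plane vs the raw SVD solution
        basis = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        pts = rng.normal(size=(20, 2)) @ basis[:, :2].T + 0.01 * rng.normal(size=(20, 3))
        n = ms.plane_normal(pts)
        _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
        oracle = vt[-1]
        assert min(np.abs(n - oracle).max(), np.abs(n + oracle).max()) < 1e-8
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)


def _dimer_traj(acceptor_rot=None, shift=(0.0, 0.0, 3.4), seed=0, n_frames=1):
    """Single synthetic dimer frame built directly from the rigid templates."""
    from medoidspec.synthetic import _ACCEPTOR_TEMPLATE, _DONOR_TEMPLATE

    acc = _ACCEPTOR_TEMPLATE if acceptor_rot is None else acceptor_rot.apply(_ACCEPTOR_TEMPLATE)
    coords = np.vstack([_DONOR_TEMPLATE, acc + np.asarray(shift)])
    frames = [Frame(index=i, symbols=("C",) * 10 + ("C", "C", "N", "N", "N", "N"),
                    coords=coords) for i in range(n_frames)]
    return Trajectory(frames=frames)


SEL_A = AtomSelection("donor", syn.DIMER_DONOR_INDICES)
SEL_B = AtomSelection("acceptor", syn.DIMER_ACCEPTOR_INDICES)


class TestPlanePairFeatures:
    def test_parallel_planes_theta_zero_and_flagged(self):
        traj = _dimer_traj()
        (pf,) = ms.plane_pair_features(traj, SEL_A, SEL_B, syn.DIMER_LOCAL_FRAME)
        assert pf.theta_r == pytest.approx(0.0, abs=1e-6)
        assert pf.degenerate_axis
        assert np.allclose(pf.n_r, 0.0)

    def test_ninety_degree_rotation_about_x(self):
        rot = Rotation.from_euler("x", 90, degrees=True)
        traj = _dimer_traj(acceptor_rot=rot, shift=(0, 0, 4.0))
        (pf,) = ms.plane_pair_features(traj, SEL_A, SEL_B, syn.DIMER_LOCAL_FRAME)
        assert pf.theta_r == pytest.approx(90.0, abs=1e-8)
        assert np.abs(np.abs(pf.n_r) - [1, 0, 0]).max() < 1e-8

    def test_rigid_motion_invariance(self):
        rot = Rotation.from_euler("zyx", [25, 40, -15], degrees=True)
        traj = _dimer_traj(acceptor_rot=rot, shift=(1.0, -0.5, 3.5))
        (ref,) = ms.plane_pair_features(traj, SEL_A, SEL_B, syn.DIMER_LOCAL_FRAME)
        for seed in range(5):
            moved = Trajectory(
                frames=[Frame(index=0, symbols=traj.symbols,
                              coords=rigid_motion(traj[0].coords, seed))]
            )
            (pf,) = ms.plane_pair_features(moved, SEL_A, SEL_B, syn.DIMER_LOCAL_FRAME)
            assert pf.theta_r == pytest.approx(ref.theta_r, abs=1e-8)
            assert np.abs(pf.n_r - ref.n_r).max() < 1e-8
            assert np.abs(pf.r_rel - ref.r_rel).max() < 1e-8

    def test_theta_within_range_on_generated_ensemble(self, dimer_run):
        theta = dimer_run["raw"]["theta_r"]
        assert (theta >= 0).all() and (theta <= 180).all()


class TestDihedral:
    def test_cis_is_zero_trans_is_180(self):
        p1, p2, p3 = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        assert ms.dihedral(p1, p2, p3, [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)
        assert ms.dihedral(p1, p2, p3, [1, -1, 0]) == pytest.approx(180.0, abs=1e-12)

    def test_collinear_triple_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ms.dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_matches_atan2_formula_and_mdanalysis_magnitude(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(25):
            pts = rng.normal(size=(4, 3)) * 2.0
            got = ms.dihedral(*pts)
            # independent textbook route: project the outer bonds off the axis,
            # then take the signed angle between the projections
            b1 = pts[2] - pts[1]
            b1 /= np.linalg.norm(b1)
            u = (pts[0] - pts[1]) - np.dot(pts[0] - pts[1], b1) * b1
            w = (pts[3] - pts[2]) - np.dot(pts[3] - pts[2], b1) * b1
            oracle = math.degrees(math.atan2(np.dot(np.cross(u, w), b1), np.dot(u, w)))
            assert abs((got - oracle + 180) % 360 - 180) < 1e-9
            # MDAnalysis agrees including the sign (float32 internals => 1e-3 deg)
            mda = math.degrees(float(calc_dihedrals(pts[0], pts[1], pts[2], pts[3])))
            assert abs((got - mda + 180) % 360 - 180) < 1e-3


class TestEncodePeriodic:
    @pytest.mark.parametrize("phi,expected", [(0, (1, 0)), (90, (0, 1)), (180, (-1, 0))])
    def test_cardinal_angles(self, phi, expected):
        c, s = ms.encode_periodic(phi)
        assert c == pytest.approx(expected[0], abs=1e-12)
        assert s == pytest.approx(expected[1], abs=1e-12)

    def test_plus_minus_180_encode_identically(self):
        assert ms.encode_periodic(-180) == pytest.approx(ms.encode_periodic(180))

    @given(st.floats(min_value=-720, max_value=720, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_output_on_unit_circle(self, phi):
        c, s = ms.encode_periodic(phi)
        assert abs(c * c + s * s - 1.0) < 1e-12


class TestC2CSM:
    def test_exactly_symmetric_structure_is_zero(self):
        spec = syn.C2GeneratorSpec()
        assert ms.c2_csm(spec.template, None, spec.permutation) < 1e-8

    def test_rigid_motion_invariance(self):
        spec = syn.C2GeneratorSpec(seed=1)
        (coords,) = syn.make_c2_series(spec, [0.3])
        ref = ms.c2_csm(coords, None, spec.permutation)
        assert ref > 0.01
        for seed in range(5):
            assert ms.c2_csm(rigid_motion(coords, seed), None, spec.permutation) == pytest.approx(
                ref, abs=1e-8
            )

    def test_matches_rotation_search_oracle(self):
        # single displaced atom: compare with brute-force search over rotations
        spec = syn.C2GeneratorSpec()
        coords = np.asarray(spec.template, dtype=float).copy()
        coords[0] += [0.3, -0.2, 0.1]
        got = ms.c2_csm(coords, None, spec.permutation)

        x = coords - coords.mean(axis=0)
        y = x[list(spec.permutation)]

        def rmsd_of(rotvec):
            r = Rotation.from_rotvec(rotvec)
            return np.sqrt(((r.apply(y) - x) ** 2).sum() / len(x))

        best = np.inf
        for rv in Rotation.random(300, random_state=0).as_rotvec():
            res = minimize(rmsd_of, rv, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12})
            best = min(best, res.fun)
        assert got == pytest.approx(best, abs=1e-4)

    def test_invalid_permutations_rejected(self):
        spec = syn.C2GeneratorSpec()
        with pytest.raises(ValueError, match="involution"):
            ms.c2_csm(spec.template, None, (1, 2, 3, 4, 5, 6, 7, 0))
        frame = Frame(index=0, symbols=("C", "N"), coords=np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(ValueError, match="maps"):
            ms.c2_csm(frame, None, (1, 0))


class TestStandardize:
    def test_column_contract(self, rng):
        df = pd.DataFrame(rng.normal(loc=3, scale=5, size=(40, 4)), columns=list("abcd"))
        std, params = ms.standardize(df)
        assert np.abs(std.mean(axis=0)).max() < 1e-10
        assert np.abs(std.std(axis=0, ddof=0) - 1).max() < 1e-10
        assert params.dropped == []

    def test_zero_variance_column_dropped_and_recorded(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "const": np.full(30, 2.5)})
        std, params = ms.standardize(df)
        assert list(std.columns) == ["a"]
        assert params.dropped == ["const"]

    def test_idempotence(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 3)))
        once, _ = ms.standardize(df)
        twice, _ = ms.standardize(once)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12

    def test_inverse_transform_recovers_input(self, rng):
        df = pd.DataFrame(rng.normal(loc=-2, scale=3, size=(20, 3)), columns=list("xyz"))
        scaler = ms.FeatureStandardizer().fit(df)
        back = scaler.inverse_transform(scaler.transform(df))
        assert np.abs(back.to_numpy() - df.to_numpy()).max() < 1e-10


class TestSDF:
    def test_static_trajectory_single_occupied_bin(self):
        traj = _dimer_traj(n_frames=8)
        grid = ms.sdf(traj, syn.DIMER_LOCAL_FRAME, SEL_B, bin_width=0.5)
        assert grid.n_binned == 8
        assert (grid.counts > 0).sum() == 1
        assert grid.counts.max() == 8

    def test_counts_conserved_on_ensemble(self, small_dimer):
        traj = small_dimer["traj"]
        grid = ms.sdf(traj, syn.DIMER_LOCAL_FRAME, SEL_B, bin_width=1.0)
        assert grid.n_binned == len(traj)
        assert grid.density().sum() == pytest.approx(1.0)

    def test_planted_bimodal_displacement_recovered(self):
        # two clusters far apart laterally -> two well-separated occupied regions
        spec = syn.DimerGeneratorSpec(
            n_frames=80, n_clusters=2, seed=5,
            base_rotations=[(5.0, [1, 0, 0]), (5.0, [0, 1, 0])],
            base_displacements=[[-3.0, 0.0, 3.4], [3.0, 0.0, 3.4]],
        )
        traj, labels = syn.make_dimer_trajectory(spec)
        grid = ms.sdf(traj, syn.DIMER_LOCAL_FRAME, SEL_B, bin_width=1.5)
        occupied = np.argwhere(grid.counts > 0)
        # occupied x-bins split into two groups separated by an empty gap
        xs = sorted(set(occupied[:, 0]))
        gaps = np.diff(xs)
        assert gaps.max() >= 2

    def test_collinear_local_frame_rejected(self):
        traj = _dimer_traj()
        with pytest.raises(ValueError, match="[Cc]ollinear"):
            ms.sdf(traj, (0, 2, 7), SEL_B, bin_width=0.5)


def test_body_frame_is_orthonormal():
    rng = np.random.default_rng(0)
    for _ in range(10):
        pts = rng.normal(size=(3, 3))
        r = _body_frame(*pts)
        assert np.abs(r @ r.T - np.eye(3)).max() < 1e-12
        assert np.linalg.det(r) == pytest.approx(1.0)
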