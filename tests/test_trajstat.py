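"""Trajectory statistics: superposition, Rg, RMSF, occupancy, clustering, torsions."""

import numpy as np
import pytest

from phytoscreen.trajstat import (
    AtomRecord,
    HBondSpec,
    Trajectory,
    TrajectoryError,
    gromos_cluster,
    hbond_occupancy,
    kabsch_rotation,
    moving_average,
    radius_of_gyration,
    read_trajectory,
    rmsd_superpose,
    rmsf,
    torsion_series,
)
from phytoscreen.synthdata import (
    HBondSeriesSpec,
    TrajectorySpec,
    gen_hbond_distances,
    gen_trajectory,
)


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _toy_traj(coords, dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    atoms = [AtomRecord(f"A{i}", "MOL", 1, 12.0) for i in range(n)]
    return Trajectory(coords, atoms, np.arange(len(coords)) * dt)


class TestReadTrajectory:
    PDB_FRAME = (
        "ATOM      1  N   ALA A   1      10.000  20.000  35.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.000  21.000  30.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1      12.500  22.000  31.000  1.00  0.00           C\n"
    )

    def _write_pdb(self, tmp_path, n_models=2, drop_last_atom_in=None):
        text = []
        for m in range(1, n_models + 1):
            text.append(f"MODEL     {m}\n")
            frame = self.PDB_FRAME
            if drop_last_atom_in == m:
                frame = "".join(frame.splitlines(keepends=True)[:-1])
            text.append(frame)
            text.append("ENDMDL\n")
        text.append("END\n")
        path = tmp_path / "toy.pdb"
        path.write_text("".join(text))
        return path

    def test_two_model_pdb(self, tmp_path):
        t = read_trajectory(self._write_pdb(tmp_path))
        assert t.n_frames == 2 and t.n_atoms == 3
        assert t.atoms[1].name == "CA" and t.atoms[1].resid == 1

    def test_angstrom_to_nm(self, tmp_path):
        t = read_trajectory(self._write_pdb(tmp_path))
        assert t.coordinates[0, 0, 2] == pytest.approx(3.5)  # 35 Å → 3.5 nm

    def test_model_atom_count_mismatch(self, tmp_path):
        path = self._write_pdb(tmp_path, n_models=3, drop_last_atom_in=2)
        with pytest.raises(TrajectoryError, match="model 2"):
            read_trajectory(path)

    def test_xyz_requires_sidecar(self, tmp_path):
        xyz = tmp_path / "toy.xyz"
        xyz.write_text("2\nframe\nC 0.0 0.0 0.0\nC 1.5 0.0 0.0\n")
        with pytest.raises(TrajectoryError, match="sidecar"):
            read_trajectory(xyz)

    def test_xyz_with_sidecar(self, tmp_path):
        xyz = tmp_path / "toy.xyz"
        xyz.write_text("2\nframe\nC 0.0 0.0 0.0\nC 1.5 0.0 0.0\n")
        meta = tmp_path / "toy_atoms.csv"
        meta.write_text("name,resname,resid,mass\nC1,LIG,1,12.011\nC2,LIG,1,12.011\n")
        t = read_trajectory(xyz, sidecar=meta)
        assert t.n_atoms == 2
        assert t.coordinates[0, 1, 0] == pytest.approx(0.15)
        assert t.atoms[0].mass == pytest.approx(12.011)

    def test_selection_language(self):
        atoms = [AtomRecord("CA", "ALA", i + 1, 12.0) for i in range(10)]
        atoms[4] = AtomRecord("CB", "GLY", 5, 12.0)
        t = Trajectory(np.zeros((1, 10, 3)), atoms, np.array([0.0]))
        assert list(t.select("resid 2-4")) == [1, 2, 3]
        assert list(t.select("name CB")) == [4]
        assert list(t.select("resid 1-6 and name CA")) == [0, 1, 2, 3, 5]
        assert list(t.select("resname GLY")) == [4]
        assert len(t.select(None)) == 10


class TestRmsdSuperpose:
    def test_identical_frames(self, rng):
        x = rng.standard_normal((10, 3))
        r, _ = rmsd_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        x = rng.standard_normal((10, 3))
        moved = x @ _random_rotation(rng).T + np.array([1.0, -2.0, 0.5])
        r, sup = rmsd_superpose(x, moved)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert sup == pytest.approx(x, abs=1e-8)

    def test_symmetry(self, rng):
        a = rng.standard_normal((8, 3))
        b = a + rng.normal(0, 0.1, (8, 3))
        assert rmsd_superpose(a, b)[0] == pytest.approx(rmsd_superpose(b, a)[0], abs=1e-10)

    def test_matches_quaternion_grid_oracle(self, rng):
        """Brute-force search over rotations on two 4-point configurations."""
        p = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 0.9]])
        q = p + rng.normal(0, 0.15, p.shape)
        best = np.inf
        grid_rng = np.random.default_rng(0)
        pc = p - p.mean(0)
        qc = q - q.mean(0)
        for _ in range(200_000):
            rot = _random_rotation(grid_rng)
            r = np.sqrt(((qc @ rot.T - pc) ** 2).sum(axis=1).mean())
            best = min(best, r)
        exact, _ = rmsd_superpose(p, q)
        assert exact <= best + 1e-12
        assert exact == pytest.approx(best, abs=1e-3)

    def test_mass_weighting_changes_fit(self, rng):
        a = rng.standard_normal((6, 3))
        b = a + rng.normal(0, 0.2, a.shape)
        masses = np.array([100.0, 1, 1, 1, 1, 1])
        r_w, _ = rmsd_superpose(a, b, masses=masses)
        r_u, _ = rmsd_superpose(a, b)
        assert r_w != pytest.approx(r_u, abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(TrajectoryError, match="3"):
            rmsd_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_kabsch_proper_rotation(self, rng):
        p = rng.standard_normal((5, 3))
        q = rng.standard_normal((5, 3))
        rot = kabsch_rotation(p - p.mean(0), q - q.mean(0))
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(frame, np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_coincident_atoms(self):
        frame = np.zeros((5, 3))
        assert radius_of_gyration(frame, np.ones(5)) == 0.0

    def test_homogeneous_scaling(self, rng):
        frame = rng.standard_normal((12, 3))
        m = rng.uniform(1, 16, 12)
        assert radius_of_gyration(3.0 * frame, m) == pytest.approx(
            3.0 * radius_of_gyration(frame, m), abs=1e-12)

    def test_zero_mass_error(self):
        with pytest.raises(TrajectoryError):
            radius_of_gyration(np.zeros((2, 3)), np.zeros(2))


class TestRmsf:
    def test_static_trajectory_zero(self):
        traj = gen_trajectory(TrajectorySpec(n_atoms=8, n_frames=20, jitter_sigma=0.0), seed=1)
        assert rmsf(traj) == pytest.approx(np.zeros(8), abs=1e-12)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        """Per-axis σ jitter gives RMSF = σ√3 (fit disabled, known scaffold)."""
        sigma = 0.02
        traj = gen_trajectory(
            TrajectorySpec(n_atoms=30, n_frames=10_000, jitter_sigma=sigma), seed=2)
        values = rmsf(traj, fit=False)
        assert values == pytest.approx(np.full(30, sigma * np.sqrt(3)), rel=0.03)

    def test_heterogeneous_sigma_ordering(self):
        sigmas = np.array([0.005, 0.02, 0.05, 0.1])
        traj = gen_trajectory(
            TrajectorySpec(n_atoms=4, n_frames=4000, jitter_sigma=tuple(sigmas)), seed=3)
        values = rmsf(traj, fit=False)
        assert list(np.argsort(values)) == [0, 1, 2, 3]

    def test_empty_window_error(self):
        traj = gen_trajectory(TrajectorySpec(n_atoms=5, n_frames=10), seed=1)
        with pytest.raises(TrajectoryError):
            rmsf(traj, window=(8, 8))


class TestHbondOccupancy:
    def test_constructed_series(self):
        """393 of 1000 frames below cutoff by construction → 39.30%."""
        d = np.full(1000, 0.45)
        d[:393] = 0.25
        coords = np.zeros((1000, 2, 3))
        coords[:, 1, 0] = d
        traj = _toy_traj(coords)
        res = hbond_occupancy(traj, [HBondSpec(0, 1, cutoff=0.30)])
        assert res[0].occupancy_percent == 39.30

    def test_zero_cutoff(self):
        traj = gen_trajectory(TrajectorySpec(n_atoms=4, n_frames=50), seed=5)
        res = hbond_occupancy(traj, [HBondSpec(0, 1, cutoff=0.0)])
        assert res[0].occupancy_percent == 0.0

    def test_telegraph_series_occupancy(self):
        traj, _ = gen_hbond_distances(HBondSeriesSpec(p=0.4, n_frames=10_000), seed=6)
        res = hbond_occupancy(traj, [HBondSpec(0, 1, cutoff=0.30)])
        assert res[0].occupancy_percent == pytest.approx(40.0, abs=2.0)

    def test_occupancy_bounds_and_distance_series(self):
        traj, d = gen_hbond_distances(HBondSeriesSpec(p=0.7, n_frames=500), seed=7)
        res = hbond_occupancy(traj, [HBondSpec(0, 1)])
        assert 0.0 <= res[0].occupancy_percent <= 100.0
        assert res[0].distances == pytest.approx(d, abs=1e-12)

    def test_spec_validation(self):
        with pytest.raises(TrajectoryError):
            HBondSpec(2, 2)


class TestGromosCluster:
    def test_identical_frames_single_cluster(self):
        traj = _toy_traj(np.repeat(np.random.default_rng(0).standard_normal((1, 5, 3)), 10, axis=0))
        res = gromos_cluster(traj, cutoff=0.1)
        assert len(res.clusters) == 1
        assert res.representatives[0] == 0  # lowest index on ties

    def test_two_planted_basins(self):
        traj = gen_trajectory(TrajectorySpec(
            n_atoms=20, n_frames=100, jitter_sigma=0.03 / np.sqrt(3),
            n_basins=2, basin_separation=0.5), seed=8)
        res = gromos_cluster(traj, cutoff=0.1)
        assert len(res.clusters) == 2
        # frames alternate between basins; memberships must match parity
        for cluster in res.clusters:
            assert len({f % 2 for f in cluster}) == 1
        assert sum(len(c) for c in res.clusters) == traj.n_frames

    def test_cutoff_limits(self):
        traj = gen_trajectory(TrajectorySpec(n_atoms=10, n_frames=15, jitter_sigma=0.05), seed=9)
        assert len(gromos_cluster(traj, cutoff=1e6).clusters) == 1
        assert len(gromos_cluster(traj, cutoff=1e-12).clusters) == traj.n_frames

    def test_representative_is_medoid(self):
        traj = gen_trajectory(TrajectorySpec(n_atoms=10, n_frames=30, jitter_sigma=0.02), seed=10)
        from phytoscreen.trajstat import pairwise_rmsd_matrix

        res = gromos_cluster(traj, cutoff=1e6)
        m, _ = pairwise_rmsd_matrix(traj)
        members = res.clusters[0]
        sums = m[np.ix_(members, members)].sum(axis=1)
        assert res.representatives[0] == members[int(np.argmin(sums))]


class TestTorsion:
    def _chain(self, phi_deg):
        """4-atom chain with dihedral phi about the central bond."""
        phi = np.radians(phi_deg)
        return np.array([[
            [1.0, 1.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0],
            [np.cos(phi), 0.0, np.sin(phi)],
        ]])

    def test_trans_planar(self):
        traj = _toy_traj(self._chain(180.0))
        assert torsion_series(traj, (0, 1, 2, 3))[0] == pytest.approx(180.0, abs=1e-8)

    def test_cis_planar(self):
        traj = _toy_traj(self._chain(0.0))
        assert torsion_series(traj, (0, 1, 2, 3))[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("angle", [30.0, 60.0, 120.0, -45.0, -170.0])
    def test_constructed_angles(self, angle):
        traj = _toy_traj(self._chain(angle))
        got = torsion_series(traj, (0, 1, 2, 3))[0]
        assert abs(got) == pytest.approx(abs(angle), abs=1e-8)

    def test_mirror_negates(self, rng):
        coords = rng.standard_normal((1, 4, 3))
        mirrored = coords.copy()
        mirrored[..., 0] *= -1
        a = torsion_series(_toy_traj(coords), (0, 1, 2, 3))[0]
        b = torsion_series(_toy_traj(mirrored), (0, 1, 2, 3))[0]
        if abs(a) != pytest.approx(180.0, abs=1e-9):
            assert b == pytest.approx(-a, abs=1e-8)

    def test_colinear_gives_nan_with_warning(self):
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = [0, 1, 2, 3]  # all on the x-axis
        with pytest.warns(UserWarning, match="colinear"):
            out = torsion_series(_toy_traj(coords), (0, 1, 2, 3))
        assert np.isnan(out[0])

    def test_distinct_indices_required(self):
        traj = _toy_traj(np.zeros((1, 4, 3)))
        with pytest.raises(TrajectoryError):
            torsion_series(traj, (0, 1, 1, 3))

    def test_range_convention(self, rng):
        traj = _toy_traj(rng.standard_normal((50, 4, 3)))
        out = torsion_series(traj, (0, 1, 2, 3))
        assert ((out > -180.0) & (out <= 180.0)).all()


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = np.full(100, 2.5)
        assert moving_average(s, 21) == pytest.approx(s)

    def test_window_one_identity(self, rng):
        s = rng.standard_normal(50)
        assert moving_average(s, 1) == pytest.approx(s)

    def test_linear_ramp_interior_unchanged(self):
        s = np.arange(100, dtype=float)
        out = moving_average(s, 21)
        assert out[10:-10] == pytest.approx(s[10:-10])

    def test_edges_truncated_mean(self):
        s = np.arange(10, dtype=float)
        out = moving_average(s, 5)
        assert out[0] == pytest.approx(np.mean(s[:3]))  # only 3 frames available

    def test_validation(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), 4)
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), 21)
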