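"""Superposition, RMSD/RMSF/Rg/SASA and summaries against closed forms,
brute-force oracles and independent solvers."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from exomd.domain import Structure, Trajectory
from exomd.synthetic import TrajSimConfig, generate_trajectory
from exomd.trajectory import (
    AtomSelection,
    kabsch_superpose,
    rg_series,
    rmsd_series,
    rmsf_per_residue,
    sasa_structure,
    select_all,
    select_backbone,
    sphere_points,
    summarize_series,
    superpose_to_mean,
)

from .oracles import align_vectors_rmsd, brute_force_min_rmsd


def _structure(coords, names=None, masses=None, radii=None, residues=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Structure(
        names or ["CA"] * n,
        residues if residues is not None else range(1, n + 1),
        masses if masses is not None else [12.0] * n,
        radii if radii is not None else [0.17] * n,
        coords,
    )


def _rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestKabsch:
    def test_identical_frames(self, rng):
        x = rng.normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self, rng):
        x = rng.normal(size=(5, 3))
        moved = x @ _rot_z(np.pi / 2).T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd = kabsch_superpose(moved, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rotation_is_proper(self, rng):
        # a near-reflected pair must still yield det +1
        x = rng.normal(size=(4, 3))
        y = x.copy()
        y[:, 2] *= -1.0
        rot, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_search_on_4_atom_toys(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 3))
        y = rng.normal(size=(4, 3))
        _, _, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(brute_force_min_rmsd(x, y), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 7, 3))
        assert kabsch_superpose(x, y)[2] == pytest.approx(kabsch_superpose(y, x)[2], abs=1e-12)

    def test_invariant_under_rigid_motion_of_either_frame(self, rng):
        x, y = rng.normal(size=(2, 8, 3))
        base = kabsch_superpose(x, y)[2]
        rot = _rot_z(0.7)
        assert kabsch_superpose(x @ rot.T + 5.0, y)[2] == pytest.approx(base, abs=1e-10)
        assert kabsch_superpose(x, y @ rot.T - 2.0)[2] == pytest.approx(base, abs=1e-10)

    def test_too_few_atoms_rejected(self, rng):
        x = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="3 selected atoms"):
            kabsch_superpose(x, x)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(4, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self):
        _, traj = generate_trajectory(TrajSimConfig(mode="static", n_particles=10, n_frames=5))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_pure_rigid_rotation_is_zero(self, rng):
        ref = rng.normal(size=(8, 3))
        frames = np.array([ref @ _rot_z(a).T + a for a in np.linspace(0, 3, 6)])
        traj = Trajectory(frames, frame_time=1.0)
        np.testing.assert_allclose(rmsd_series(traj, reference=ref), 0.0, atol=1e-10)

    def test_matches_independent_solver_per_frame(self):
        _, traj = generate_trajectory(
            TrajSimConfig(mode="harmonic", n_particles=12, n_frames=20, seed=5)
        )
        ours = rmsd_series(traj)
        expected = [align_vectors_rmsd(f, traj.coords[0]) for f in traj.coords]
        np.testing.assert_allclose(ours, expected, atol=1e-7)

    def test_harmonic_mean_rmsd_tracks_planted_amplitude(self):
        # isotropic per-atom RMSF sigma -> RMSD fluctuation about a rigid
        # reference of the same magnitude (superposition removes little for
        # spatially uncorrelated noise)
        sigma = 0.12
        n = 30
        cfg = TrajSimConfig(
            mode="harmonic", n_particles=n, n_frames=800, amplitudes=(sigma,) * n, seed=9
        )
        _, traj = generate_trajectory(cfg)
        mean_rmsd = rmsd_series(traj).mean()
        # reference frame itself is noisy: expected displacement ~ sigma*sqrt(2)
        assert mean_rmsd == pytest.approx(sigma * np.sqrt(2.0), rel=0.10)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        structure, traj = generate_trajectory(
            TrajSimConfig(mode="static", n_particles=6, n_frames=4)
        )
        rmsf = rmsf_per_residue(traj, structure)
        np.testing.assert_allclose(rmsf.values, 0.0, atol=1e-12)

    def test_two_point_alternation_closed_form(self):
        # one atom alternating +/- d along x, superposition disabled
        d = 0.25
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0], [1.0, 1.0, 1.0]])
        frames = np.array([base.copy() for _ in range(10)])
        frames[::2, 0, 0] += d
        frames[1::2, 0, 0] -= d
        traj = Trajectory(frames, frame_time=1.0)
        structure = _structure(base)
        rmsf = rmsf_per_residue(traj, structure, fit=False)
        assert rmsf.loc[1] == pytest.approx(d, abs=1e-12)
        np.testing.assert_allclose(rmsf.loc[2:].values, 0.0, atol=1e-12)

    def test_planted_amplitude_recovery_at_2000_frames(self):
        rng = np.random.default_rng(77)
        n = 40
        amplitudes = tuple(rng.uniform(0.03, 0.3, size=n))
        cfg = TrajSimConfig(
            mode="harmonic", n_particles=n, n_frames=2000, amplitudes=amplitudes, seed=13
        )
        structure, traj = generate_trajectory(cfg)
        rmsf = rmsf_per_residue(traj, structure)
        rho = spearmanr(rmsf.values, amplitudes).statistic
        assert rho > 0.9

    def test_hinge_domain_fluctuates_above_background(self):
        cfg = TrajSimConfig(
            mode="hinge", n_particles=30, n_frames=1500, seed=21,
            hinge_residues=tuple(range(25, 31)),
        )
        structure, traj = generate_trajectory(cfg)
        rmsf = rmsf_per_residue(traj, structure)
        hinge = rmsf.loc[25:].mean()
        background = rmsf.loc[:24].median()
        assert hinge > 3.0 * background

    def test_cut_leaving_too_few_frames_rejected(self):
        structure, traj = generate_trajectory(
            TrajSimConfig(mode="harmonic", n_particles=5, n_frames=10, frame_time=1.0)
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            rmsf_per_residue(traj, structure, cut=9.5)


class TestRg:
    def test_two_equal_masses(self):
        d = 0.8
        coords = np.array([[[0.0, 0, 0], [d, 0, 0]]])
        structure = _structure(coords[0], masses=[5.0, 5.0])
        traj = Trajectory(coords)
        assert rg_series(traj, structure)[0] == pytest.approx(d / 2)

    def test_square_of_equal_masses(self):
        a = 1.2
        coords = np.array([[[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]]], dtype=float)
        structure = _structure(coords[0])
        traj = Trajectory(coords)
        assert rg_series(traj, structure)[0] == pytest.approx(a / np.sqrt(2))

    @pytest.mark.parametrize("k", [0.5, 2.0, 3.7])
    def test_homogeneity_under_scaling(self, k, rng):
        coords = rng.normal(size=(1, 9, 3))
        structure = _structure(coords[0])
        base = rg_series(Trajectory(coords), structure)[0]
        scaled = rg_series(Trajectory(coords * k), structure)[0]
        assert scaled == pytest.approx(k * base)

    def test_mass_weighting_shifts_rg(self):
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])
        structure = _structure(coords[0], masses=[1.0, 3.0])
        weighted = rg_series(Trajectory(coords), structure, mass_weighted=True)[0]
        unweighted = rg_series(Trajectory(coords), structure, mass_weighted=False)[0]
        assert weighted == pytest.approx(np.sqrt(3) / 4)
        assert unweighted == pytest.approx(0.5)

    def test_zero_mass_rejected(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 1, 0] = 1.0
        coords[0, 2, 1] = 1.0
        structure = _structure(coords[0], masses=[0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="mass"):
            rg_series(Trajectory(coords), structure)

    def test_rg_of_mean_structure_below_mean_rg(self):
        structure, traj = generate_trajectory(
            TrajSimConfig(mode="harmonic", n_particles=20, n_frames=100, seed=3)
        )
        fitted, mean = superpose_to_mean(traj.coords)
        mean_structure_rg = rg_series(Trajectory(mean[None]), structure)[0]
        frame_rg = rg_series(Trajectory(fitted), structure).mean()
        assert mean_structure_rg <= frame_rg + 1e-12


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        structure = _structure(np.zeros((1, 3)), radii=[0.15])
        total, per = sasa_structure(structure, probe=0.14)
        exact = 4 * np.pi * 0.29**2
        assert total == pytest.approx(exact, rel=0.02)
        assert per[0] == total

    def test_disjoint_spheres_are_additive(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        structure = _structure(coords, radii=[0.15, 0.15])
        total, _ = sasa_structure(structure, probe=0.14)
        single, _ = sasa_structure(_structure(np.zeros((1, 3)), radii=[0.15]), probe=0.14)
        assert total == pytest.approx(2 * single, rel=1e-12)

    def test_caged_atom_fully_buried(self):
        # centre atom enclosed by 26 lattice neighbours at tight spacing
        offsets = [
            np.array([i, j, k], dtype=float)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        spacing = 0.18
        coords = np.vstack([[0.0, 0.0, 0.0], spacing * np.array(offsets)])
        structure = _structure(coords, radii=[0.17] * 27)
        _, per = sasa_structure(structure, probe=0.14)
        assert per[0] == 0.0

    def test_point_count_floor(self):
        structure = _structure(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="32"):
            sasa_structure(structure, n_points=16)

    def test_convergence_with_point_count(self, rng):
        coords = rng.uniform(-0.5, 0.5, size=(20, 3))
        structure = _structure(coords, radii=[0.16] * 20)
        coarse, _ = sasa_structure(structure, n_points=960)
        fine, _ = sasa_structure(structure, n_points=3840)
        assert abs(coarse - fine) / fine < 0.01

    def test_matches_independent_shrake_rupley(self, rng):
        # biotite's Shrake-Rupley with identical radii/probe as cross-check
        import biotite.structure as struc

        coords_nm = rng.uniform(-0.4, 0.4, size=(15, 3))
        radius_nm = 0.17
        structure = _structure(coords_nm, radii=[radius_nm] * 15)
        ours, _ = sasa_structure(structure, probe=0.14, n_points=1000)

        atoms = struc.AtomArray(15)
        atoms.coord = coords_nm * 10.0  # nm -> Angstrom
        atoms.atom_name = np.array(["CA"] * 15, dtype="U6")
        atoms.res_id = np.arange(1, 16)
        atoms.res_name = np.array(["GLY"] * 15, dtype="U5")
        atoms.chain_id = np.array(["A"] * 15, dtype="U4")
        atoms.element = np.array(["C"] * 15, dtype="U2")
        theirs_a2 = struc.sasa(
            atoms, probe_radius=1.4, vdw_radii=np.full(15, radius_nm * 10.0), point_number=1000
        ).sum()
        assert ours == pytest.approx(theirs_a2 / 100.0, rel=0.02)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestSummarize:
    def test_simple_series(self):
        s = summarize_series([1.0, 2.0, 3.0], frame_time=1.0, cut=0.0)
        assert (s.mean, s.sd, s.n_frames_used) == (2.0, 1.0, 3)

    def test_cut_uses_tail_frames_only(self, rng):
        values = rng.normal(size=10)
        s = summarize_series(values, frame_time=1.0, cut=5.0)
        tail = values[5:]
        assert s.n_frames_used == 5
        assert s.mean == pytest.approx(tail.mean())
        assert s.sd == pytest.approx(tail.std(ddof=1))

    def test_constant_series_sd_zero(self):
        assert summarize_series([4.2] * 6, frame_time=0.5).sd == 0.0

    def test_insufficient_frames_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            summarize_series([1.0, 2.0], frame_time=1.0, cut=1.5)


class TestSelections:
    def test_backbone_selection(self):
        structure = _structure(
            np.zeros((4, 3)), names=["N", "CA", "CB", "O"], residues=[1, 1, 1, 1]
        )
        sel = select_backbone(structure)
        assert list(sel.indices) == [0, 1, 3]

    def test_empty_selection_rejected(self):
        structure = _structure(np.zeros((2, 3)), names=["CB", "CG"], residues=[1, 1])
        with pytest.raises(ValueError, match="backbone"):
            select_backbone(structure)
        assert len(select_all(structure)) == 2
        with pytest.raises(ValueError):
            AtomSelection(np.array([], dtype=int))
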