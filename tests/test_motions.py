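"""Collective-motion machinery: PCA spectra and reconstruction, motion-matrix
correlations and rigid-body invariance, eigenvector projections, RMSF/B-factor
conversion and locally-fitted RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allodyn.constants import KB
from allodyn.core import Topology, TrajectoryEnsemble
from allodyn.motions import (
    local_rmsd,
    motion_correlation,
    motion_matrix,
    motion_matrix_from_mode,
    pca,
    pca_structures,
    project,
    project_ensemble,
    reconstruct,
    rmsf,
    rmsf_and_bfactor,
)

T = 300.0


def single_chain_traj(frames):
    n = frames.shape[1]
    topo = Topology(
        serials=np.arange(1, n + 1), names=["CA"] * n,
        resids=np.arange(1, n + 1), resnames=["GLY"] * n,
        chains=["A"] * n, masses=np.full(n, 110.0),
        hetero=np.zeros(n, dtype=bool),
    )
    return TrajectoryEnsemble(topology=topo, replicas=[frames], label="t")


class TestPCA:
    def test_single_axis_displacement_dominates(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 3))
        amp = rng.normal(size=200)
        mode = np.zeros((5, 3))
        mode[2, 0] = 1.0
        frames = base[None] + amp[:, None, None] * mode[None]
        frames += rng.normal(scale=1e-4, size=frames.shape)
        traj = single_chain_traj(frames)
        eig = pca(traj, selection="ca", superpose=False)
        assert eig.eigenvalues[0] / eig.eigenvalues.sum() > 0.99

    def test_orthonormal_eigenvectors(self, dimer_traj):
        eig = pca(dimer_traj, selection="ca")
        g = eig.eigenvectors @ eig.eigenvectors.T
        np.testing.assert_allclose(g, np.eye(len(g)), atol=1e-8)
        assert np.all(np.diff(eig.eigenvalues) <= 1e-12)

    def test_known_covariance_eigenvalues(self):
        # planar 2-mode Gaussian displacements of one atom among anchors
        rng = np.random.default_rng(1)
        n = 20_000
        lam_true = np.array([4e-4, 1e-4])
        disp = rng.normal(size=(n, 2)) * np.sqrt(lam_true)
        frames = np.zeros((n, 4, 3))
        # far-apart static anchors pin rotation/translation
        frames[:] = np.array(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [5, 5, 5]], dtype=float
        )
        frames[:, 3, 0] += disp[:, 0]
        frames[:, 3, 1] += disp[:, 1]
        traj = single_chain_traj(frames)
        eig = pca(traj, selection="ca", superpose=False)
        se = lam_true * np.sqrt(2 / n)
        assert abs(eig.eigenvalues[0] - lam_true[0]) < 3 * se[0] + 1e-7
        assert abs(eig.eigenvalues[1] - lam_true[1]) < 3 * se[1] + 1e-7

    def test_reconstruction_from_all_modes(self, dimer_traj):
        eig = pca(dimer_traj, selection="ca")
        idx = dimer_traj.topology.select("ca")
        from allodyn.geometry import iterative_mean_structure

        coords, mean = iterative_mean_structure(
            dimer_traj.concatenated()[:20, idx]
        )
        pr = np.stack([
            project(coords, eig, mode=k, fit=False)
            for k in range(eig.n_modes)
        ], axis=1)
        rebuilt = reconstruct(eig, pr)
        np.testing.assert_allclose(rebuilt, coords, atol=1e-8)


class TestMotionMatrix:
    def test_identical_conformations_zero(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3))
        assert np.allclose(motion_matrix(a, a).matrix, 0.0)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.1, size=a.shape)
        r = Rotation.from_euler("xyz", [0.5, 1.0, -0.7]).as_matrix()
        m1 = motion_matrix(a, b)
        m2 = motion_matrix(a @ r.T + 5.0, b)
        np.testing.assert_allclose(m1.matrix, m2.matrix, atol=1e-10)

    def test_three_residue_stretch_hand_computed(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        b = np.array([[0, 0, 0], [1.5, 0, 0], [3, 0, 0]], dtype=float)
        m = motion_matrix(a, b).matrix
        expected = np.array([
            [0.0, -0.5, -1.0],
            [-0.5, 0.0, -0.5],
            [-1.0, -0.5, 0.0],
        ])
        np.testing.assert_allclose(m, expected)

    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=0.2, size=a.shape)
        m = motion_matrix(a, b)
        neg = motion_matrix(b, a)
        assert motion_correlation(m, m) == pytest.approx(1.0)
        assert motion_correlation(m, neg) == pytest.approx(-1.0)

    def test_independent_matrices_uncorrelated(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(5):
            a, b, c, d = rng.normal(size=(4, 50, 3))
            rs.append(abs(motion_correlation(motion_matrix(a, b),
                                             motion_matrix(c, d))))
        assert np.median(rs) < 0.1

    def test_zero_variance_rejected(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        m0 = motion_matrix(a, a)
        m1 = motion_matrix(a, a + 0.1)
        with pytest.raises(ValueError, match="zero-variance"):
            motion_correlation(m0, m1)

    def test_mode_derived_matrix_matches_displaced_structures(self, dimer_traj):
        eig = pca(dimer_traj, selection="ca")
        m = motion_matrix_from_mode(eig, mode=0)
        amp = np.sqrt(eig.eigenvalues[0])
        v = eig.eigenvectors[0].reshape(-1, 3)
        direct = motion_matrix(eig.mean + amp * v, eig.mean - amp * v)
        np.testing.assert_allclose(m.matrix, direct.matrix)


class TestProjection:
    def test_mean_structure_projects_to_zero(self, dimer_traj):
        eig = pca(dimer_traj, selection="ca")
        assert project(eig.mean, eig, mode=0)[0] == pytest.approx(0.0, abs=1e-10)

    def test_displaced_frame_projects_to_amplitude(self, dimer_traj):
        eig = pca(dimer_traj, selection="ca")
        c = 0.37
        frame = eig.mean + c * eig.eigenvectors[0].reshape(-1, 3)
        assert project(frame, eig, mode=0)[0] == pytest.approx(c, abs=1e-8)

    def test_two_state_ensemble_separates_bimodally(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(12, 3)) * 2
        shift = np.zeros((12, 3))
        shift[6:, 2] = 0.8
        frames = []
        for i in range(400):
            s = base + (shift if i % 2 else 0) + rng.normal(
                scale=0.02, size=base.shape)
            frames.append(s)
        traj = single_chain_traj(np.array(frames))
        eig = pca(traj, selection="ca")
        p = project_ensemble(traj, eig, mode=0)
        gap = (p[::2].mean() + p[1::2].mean()) / 2
        assert np.all(np.sign(p[::2] - gap) == np.sign(p[0] - gap))
        assert np.all(np.sign(p[1::2] - gap) != np.sign(p[0] - gap))

    def test_selection_mismatch_rejected(self, dimer_traj):
        eig = pca(dimer_traj, selection="ca")
        with pytest.raises(ValueError, match="selection"):
            project(np.zeros((3, 3)), eig)


class TestRMSF:
    def test_bfactor_closed_form(self):
        # 1 Å RMSF -> B = 8 pi^2 / 3 = 26.32 Å^2
        from allodyn.constants import BFACTOR_PREFACTOR

        assert BFACTOR_PREFACTOR == pytest.approx(26.3189, abs=1e-3)

    def test_frozen_atoms_zero_rmsf(self):
        frames = np.tile(np.random.default_rng(7).normal(size=(5, 3)), (50, 1, 1))
        traj = single_chain_traj(frames)
        assert np.allclose(rmsf(traj, "ca"), 0.0, atol=1e-10)

    def test_enm_rmsf_matches_analytic_covariance(self, dimer):
        from allodyn.synthetic import EnsembleSpec, sample_ensemble

        n = 40_000
        traj = sample_ensemble(dimer, EnsembleSpec(1, n, T, "gaussian", 19))
        r = rmsf(traj, "ca")
        hinv = np.linalg.pinv(dimer.hessian(), rcond=1e-10)
        diag = np.diag(hinv).reshape(-1, 3).sum(axis=1)
        expected = np.sqrt(KB * T * diag) * 10.0
        # superposition slightly reduces apparent fluctuation; allow a few %
        np.testing.assert_allclose(r, expected, rtol=0.08)

    def test_correlation_with_provided_bfactors(self, dimer_traj):
        out = rmsf_and_bfactor(dimer_traj, "ca",
                               experimental_b=np.arange(24, dtype=float))
        assert "correlation" in out and -1 <= out["correlation"] <= 1
        out2 = rmsf_and_bfactor(dimer_traj, "ca",
                                experimental_b=out["bfactor_A2"])
        assert out2["correlation"] == pytest.approx(1.0)


class TestLocalRMSD:
    def test_reference_replicated_gives_zero(self, dimer):
        frames = np.tile(dimer.positions, (10, 1, 1))
        traj = TrajectoryEnsemble(topology=dimer.topology(), replicas=[frames])
        r = local_rmsd(traj, "A:3", reference=dimer.positions)
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_comoving_target_ignores_global_motion(self, dimer):
        rng = np.random.default_rng(8)
        frames = []
        for _ in range(20):
            rot = Rotation.from_rotvec(rng.normal(scale=0.5, size=3)).as_matrix()
            frames.append(dimer.positions @ rot.T + rng.normal(scale=2.0, size=3))
        traj = TrajectoryEnsemble(topology=dimer.topology(),
                                  replicas=[np.array(frames)])
        r = local_rmsd(traj, "A:3", reference=dimer.positions)
        np.testing.assert_allclose(r, 0.0, atol=1e-8)

    def test_planted_flip_is_bimodal(self, dimer):
        frames = np.tile(dimer.positions, (40, 1, 1))
        topo = dimer.topology()
        t_atom = topo.atoms_of_residue(topo.residue_index("A", 3))[0]
        frames[::2, t_atom] += np.array([0.0, 0.0, 0.3])  # flip half the frames
        traj = TrajectoryEnsemble(topology=topo, replicas=[frames])
        r = local_rmsd(traj, "A:3", reference=dimer.positions)
        assert np.allclose(r[1::2], 0.0, atol=1e-8)
        assert np.all(r[::2] > 2.0)  # ~3 Å displacement

    def test_empty_neighbourhood_rejected(self, dimer):
        frames = np.tile(dimer.positions, (3, 1, 1))
        traj = TrajectoryEnsemble(topology=dimer.topology(), replicas=[frames])
        with pytest.raises(ValueError, match="neighbourhood"):
            local_rmsd(traj, "A:3", reference=dimer.positions, fit_cutoff_A=0.01)


def test_structure_set_pca_recovers_dominant_mode():
    rng = np.random.default_rng(9)
    base = rng.normal(size=(15, 3)) * 2
    mode = np.zeros((15, 3))
    mode[5:10, 1] = 1.0
    mode /= np.linalg.norm(mode)
    structs = np.array([base + a * mode for a in
                        np.linspace(-0.5, 0.5, 11)])
    eig = pca_structures(structs, superpose=False)
    v = eig.eigenvectors[0].reshape(-1, 3)
    overlap = abs(np.sum(v * mode))
    assert overlap > 0.99
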