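"""Collective-motion analysis: PCA, motion matrices, projections, RMSF.

PCA diagonalises the covariance of superposed Cartesian coordinates over a
selection (main-chain atoms by convention); eigenvectors describe collective
motions and eigenvalues (nm²) their amplitudes.  Motions are compared in
internal coordinates through **motion matrices** — differences of two
Cα–Cα distance matrices — whose Pearson correlation over unique
off-diagonal entries is fitting-free and rigid-body invariant.  Ensembles
and external structure sets can be projected onto any eigenvector for
state-separation plots; RMSF per residue converts to crystallographic
B-factors via B = (8π²/3)·RMSF².
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import BFACTOR_PREFACTOR
from .core import TrajectoryEnsemble
from .geometry import iterative_mean_structure, kabsch_rotation, superpose


@dataclass
class EigenSystem:
    """PCA result over an atom selection.

    ``eigenvectors[k]`` is a unit (n_sel·3,) vector; ``eigenvalues`` (nm²)
    descend.  ``mean`` is the (n_sel, 3) structure the ensemble was fitted
    to; projections of any conformation are taken about it.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray  # (n_modes, n_sel*3)
    eigenvalues: np.ndarray
    selection: str

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class MotionMatrix:
    """Residue×residue matrix of Cα–Cα distance differences (nm)."""

    matrix: np.ndarray
    residue_labels: list[str] | None = None


def pca(
    traj: TrajectoryEnsemble, selection: str = "mainchain",
    n_modes: int | None = None, superpose: bool = True,
) -> EigenSystem:
    """Principal component analysis of the coordinate covariance.

    Frames are superposed to their iterated mean on the selection (skip with
    ``superpose=False`` for pre-aligned data).  The sign of each eigenvector
    is fixed so its largest-magnitude component is positive, making mode
    directions deterministic.
    """
    idx = traj.topology.select(selection)
    coords = traj.concatenated()[:, idx]
    if coords.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    if superpose:
        coords, mean = iterative_mean_structure(coords)
    else:
        mean = coords.mean(axis=0)
    flat = (coords - mean).reshape(coords.shape[0], -1)
    cov = np.cov(flat, rowvar=False)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0.0, None), vec[:, order]
    if n_modes is not None:
        if n_modes > len(lam):
            warn(f"only {len(lam)} modes available, truncating request")
            n_modes = len(lam)
        lam, vec = lam[:n_modes], vec[:, :n_modes]
    vec = vec.T
    flips = np.sign(vec[np.arange(len(vec)), np.argmax(np.abs(vec), axis=1)])
    vec = vec * flips[:, None]
    return EigenSystem(
        mean=mean, eigenvectors=vec, eigenvalues=lam, selection=selection
    )


def pca_structures(
    structures: np.ndarray, selection_label: str = "ca", superpose: bool = True
) -> EigenSystem:
    """PCA of a small structure set (e.g. crystal structures), equal weights.

    ``structures`` is (n_structures, n_atoms, 3); the set is superposed to
    its iterated mean first (unless already aligned).
    """
    structures = np.asarray(structures, float)
    if superpose:
        coords, mean = iterative_mean_structure(structures)
    else:
        coords, mean = structures, structures.mean(axis=0)
    flat = (coords - mean).reshape(coords.shape[0], -1)
    cov = np.cov(flat, rowvar=False)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0.0, None), vec[:, order].T
    flips = np.sign(vec[np.arange(len(vec)), np.argmax(np.abs(vec), axis=1)])
    return EigenSystem(
        mean=mean, eigenvectors=vec * flips[:, None], eigenvalues=lam,
        selection=selection_label,
    )


def project(
    frames: np.ndarray, eig: EigenSystem, mode: int = 0, fit: bool = True
) -> np.ndarray:
    """Project conformations onto one eigenvector.

    ``frames`` is (n_frames, n_sel, 3) over the same selection as ``eig``;
    each frame is superposed to the eigen-system's mean first (disable with
    ``fit=False`` for pre-fitted coordinates).  Returns the per-frame scalar
    displacement along the mode (nm).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1] * 3 != eig.eigenvectors.shape[1]:
        raise ValueError("selection size does not match the eigen-system")
    if fit:
        frames = superpose(frames, eig.mean)
    disp = (frames - eig.mean).reshape(frames.shape[0], -1)
    return disp @ eig.eigenvectors[mode]


def project_ensemble(
    traj: TrajectoryEnsemble, eig: EigenSystem, mode: int = 0
) -> np.ndarray:
    idx = traj.topology.select(eig.selection)
    return project(traj.concatenated()[:, idx], eig, mode)


def reconstruct(eig: EigenSystem, projections: np.ndarray) -> np.ndarray:
    """Rebuild centred coordinates from per-mode projections (inverse of
    projecting onto all modes)."""
    flat = np.asarray(projections) @ eig.eigenvectors
    return flat.reshape(-1, eig.mean.shape[0], 3) + eig.mean


def motion_matrix(conf_a: np.ndarray, conf_b: np.ndarray,
                  residue_labels: list[str] | None = None) -> MotionMatrix:
    """M = D(a) − D(b) with D the Cα–Cα distance matrix of a conformation.

    Purely internal coordinates — rigid-body placement of either
    conformation cancels exactly.
    """
    conf_a = np.asarray(conf_a, float)
    conf_b = np.asarray(conf_b, float)
    if conf_a.shape != conf_b.shape:
        raise ValueError("conformations have different atom counts")
    m = squareform(pdist(conf_a)) - squareform(pdist(conf_b))
    return MotionMatrix(matrix=m, residue_labels=residue_labels)


def motion_matrix_from_mode(
    eig: EigenSystem, mode: int = 0, amplitude: float | None = None
) -> MotionMatrix:
    """Motion matrix of mean ± amplitude·eigenvector displacements.

    Default amplitude is one standard deviation along the mode
    (√eigenvalue).
    """
    if amplitude is None:
        amplitude = float(np.sqrt(eig.eigenvalues[mode]))
    v = eig.eigenvectors[mode].reshape(-1, 3)
    return motion_matrix(eig.mean + amplitude * v, eig.mean - amplitude * v)


def motion_correlation(m1: MotionMatrix, m2: MotionMatrix) -> float:
    """Pearson correlation of two motion matrices over unique off-diagonal
    entries; raises on zero-variance (featureless) input."""
    a, b = m1.matrix, m2.matrix
    if a.shape != b.shape:
        raise ValueError("motion matrices have different shapes")
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance motion matrix: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def rmsf(traj: TrajectoryEnsemble, selection: str = "ca") -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) after superposition."""
    idx = traj.topology.select(selection)
    coords, mean = iterative_mean_structure(traj.concatenated()[:, idx])
    msf = np.mean(np.sum((coords - mean) ** 2, axis=-1), axis=0)
    return np.sqrt(msf) * 10.0  # nm -> Å


def rmsf_and_bfactor(
    traj: TrajectoryEnsemble,
    selection: str = "ca",
    experimental_b: np.ndarray | None = None,
) -> dict:
    """RMSF (Å), derived B-factors (Ų) and, when an experimental B column
    is supplied, their Pearson correlation."""
    r = rmsf(traj, selection)
    b = BFACTOR_PREFACTOR * r**2
    out = {"rmsf_A": r, "bfactor_A2": b}
    if experimental_b is not None:
        experimental_b = np.asarray(experimental_b, float)
        if len(experimental_b) != len(b):
            raise ValueError("experimental B column length mismatch")
        out["correlation"] = float(np.corrcoef(b, experimental_b)[0, 1])
    return out


def domain_rotation_angle(
    struct_a: np.ndarray,
    struct_b: np.ndarray,
    domain_indices: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> float:
    """Rigid-body rotation (degrees) of a domain between two structures.

    ``struct_b`` is first superposed onto ``struct_a`` using ``fit_indices``
    (everything outside the domain by default, i.e. the stationary core);
    the least-squares rotation of the domain atoms is then extracted and its
    angle returned, the standard read-out for hinge motions of a sub-domain.
    """
    struct_a = np.asarray(struct_a, float)
    struct_b = np.asarray(struct_b, float)
    if fit_indices is None:
        fit_indices = np.setdiff1d(np.arange(len(struct_a)), domain_indices)
    b = superpose(struct_b[None], struct_a, fit_indices=fit_indices)[0]
    da = struct_a[domain_indices] - struct_a[domain_indices].mean(axis=0)
    db = b[domain_indices] - b[domain_indices].mean(axis=0)
    rot = kabsch_rotation(db, da)
    cos = (np.trace(rot) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def local_rmsd(
    traj: TrajectoryEnsemble,
    target_residue: str,
    reference: np.ndarray,
    fit_cutoff_A: float = 6.0,
) -> np.ndarray:
    """Per-frame RMSD (Å) of one residue after fitting on its neighbourhood.

    Frames are fitted on all atoms within ``fit_cutoff_A`` of the target
    residue in the ``reference`` structure (the target itself excluded), so
    the number measures local rearrangement, not global motion.  The
    reference should be the average structure over all states being
    compared.
    """
    topo = traj.topology
    chain, resid = target_residue.split(":")
    t_atoms = topo.atoms_of_residue(topo.residue_index(chain, int(resid)))
    cutoff_nm = fit_cutoff_A / 10.0
    d = np.linalg.norm(
        reference[:, None, :] - reference[None, t_atoms, :], axis=-1
    ).min(axis=1)
    neigh = np.flatnonzero((d <= cutoff_nm) & ~np.isin(np.arange(topo.n_atoms),
                                                       t_atoms))
    if len(neigh) < 3:
        raise ValueError(
            f"no usable neighbourhood within {fit_cutoff_A} Å of {target_residue}"
        )
    coords = traj.concatenated()
    fitted = superpose(coords, reference, fit_indices=neigh)
    diff = fitted[:, t_atoms] - reference[t_atoms]
    return np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1)) * 10.0
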