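"""Rigid-body superposition and internal-coordinate geometry helpers."""

from __future__ import annotations

import numpy as np


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rotation matrices aligning centred ``mobile`` onto
    centred ``reference``.

    Both arrays are (..., n, 3) and are assumed already centred.  Returns
    rotation matrices R of shape (..., 3, 3) such that mobile @ R ≈ reference,
    with proper rotations enforced (det = +1).
    """
    h = np.swapaxes(mobile, -2, -1) @ reference
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    # flip the smallest singular direction where a reflection was found
    d = np.ones(h.shape[:-2] + (3,))
    d[..., -1] = np.sign(det)
    return (u * d[..., None, :]) @ vt


def superpose(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame onto ``reference`` by a least-squares fit.

    Parameters
    ----------
    frames
        (n_frames, n_atoms, 3) coordinates.
    reference
        (n_atoms, 3) reference structure.
    fit_indices
        Atom indices used for the fit; the transform is applied to all atoms.
    """
    frames = np.asarray(frames, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(frames.shape[1])
    ref_fit = reference[fit_indices]
    ref_cen = ref_fit.mean(axis=0)
    mob_cen = frames[:, fit_indices].mean(axis=1, keepdims=True)
    rot = kabsch_rotation(frames[:, fit_indices] - mob_cen, ref_fit - ref_cen)
    return (frames - mob_cen) @ rot + ref_cen


def iterative_mean_structure(
    frames: np.ndarray,
    fit_indices: np.ndarray | None = None,
    n_iter: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames to their own mean, iterating the mean.

    Returns ``(superposed_frames, mean_structure)``.  Two or three rounds are
    enough for the small rigid-body spreads typical of equilibrium ensembles.
    """
    ref = frames[0]
    out = frames
    for _ in range(n_iter):
        out = superpose(frames, ref, fit_indices)
        ref = out.mean(axis=0)
    return out, ref


def dihedral_angles(
    coords: np.ndarray,
    quads: np.ndarray,
) -> np.ndarray:
    """Dihedral angles (radians, in (−π, π]) for atom quadruples.

    ``coords`` is (n_frames, n_atoms, 3); ``quads`` is (D, 4) atom indices.
    Returns (n_frames, D).
    """
    p0 = coords[:, quads[:, 0]]
    p1 = coords[:, quads[:, 1]]
    p2 = coords[:, quads[:, 2]]
    p3 = coords[:, quads[:, 3]]
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.arctan2(y, x)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two (n, 3) structures (no fitting)."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))
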