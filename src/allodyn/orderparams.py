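"""NMR-style order parameters from trajectories.

Methyl-axis S² measures the rotational restriction of a bond vector: 1 for a
rigid vector, 0 for isotropic disorder.  Per time window of length
``window_ps`` (default 3 ns, the windowing convention of methyl-axis
back-calculations) the second moments of the normalised vector are combined
as

    S² = 3/2·[⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²] − 1/2,

then averaged over windows and replicas.  Dihedral order parameters use
circular moments, S = ⟨cos χ⟩² + ⟨sin χ⟩², per dihedral over the whole
(concatenated) ensemble, averaged per residue.

Differences are reported as S_before − S_after, so a **positive** difference
is a flexibility gain after the perturbation (e.g. ligand binding) and a
negative one a flexibility loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrajectoryEnsemble
from .geometry import dihedral_angles, iterative_mean_structure


@dataclass
class OrderParameterProfile:
    """Per-vector or per-residue order parameters for one state."""

    names: list[str]
    values: np.ndarray
    kind: str  # "methyl_axis" | "dihedral"
    window_ps: float | None = None
    per_window: np.ndarray | None = None  # (n_windows_total, K)
    state: str = "state"


def s2_from_vectors(vectors: np.ndarray) -> np.ndarray | float:
    """Generalized order parameter of unit-vector series.

    ``vectors`` is (n_frames, 3) or (n_frames, K, 3); vectors are normalised
    internally.  Returns a scalar or a length-K array.
    """
    v = np.asarray(vectors, dtype=float)
    single = v.ndim == 2
    if single:
        v = v[:, None, :]
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    s2 = 1.5 * (
        np.mean(x * x, axis=0) ** 2
        + np.mean(y * y, axis=0) ** 2
        + np.mean(z * z, axis=0) ** 2
        + 2 * np.mean(x * y, axis=0) ** 2
        + 2 * np.mean(x * z, axis=0) ** 2
        + 2 * np.mean(y * z, axis=0) ** 2
    ) - 0.5
    return float(s2[0]) if single else s2


def methyl_axis_s2(
    traj: TrajectoryEnsemble,
    window_ps: float = 3000.0,
    superpose: bool = True,
) -> OrderParameterProfile:
    """Windowed S² for every axis vector defined on the trajectory topology.

    Frames of each replica are superposed to their mean structure first so
    global tumbling does not leak into the order parameter.  Each replica is
    cut into non-overlapping windows of ``window_ps``; the reported value is
    the mean over all windows of all replicas.
    """
    topo = traj.topology
    if topo.axis_pairs is None or len(topo.axis_pairs) == 0:
        raise ValueError("topology defines no axis vectors")
    n_win_frames = int(round(window_ps / traj.frame_spacing_ps))
    if n_win_frames < 1:
        raise ValueError("window shorter than the frame spacing")
    tail, head = topo.axis_pairs[:, 0], topo.axis_pairs[:, 1]
    fit_idx = topo.select("full")
    per_window = []
    for rep in traj.replicas:
        if n_win_frames > rep.shape[0]:
            raise ValueError(
                f"window of {n_win_frames} frames longer than replica "
                f"({rep.shape[0]} frames)"
            )
        coords = rep
        if superpose:
            coords, _ = iterative_mean_structure(rep, fit_idx, n_iter=2)
        vec = coords[:, head] - coords[:, tail]
        n_windows = coords.shape[0] // n_win_frames
        for w in range(n_windows):
            per_window.append(
                s2_from_vectors(vec[w * n_win_frames:(w + 1) * n_win_frames])
            )
    per_window = np.asarray(per_window)
    labels = topo.residue_labels()
    names = [labels[topo.atom_residue[t]] for t in tail]
    return OrderParameterProfile(
        names=names,
        values=per_window.mean(axis=0),
        kind="methyl_axis",
        window_ps=n_win_frames * traj.frame_spacing_ps,
        per_window=per_window,
        state=traj.label,
    )


def dihedral_order_parameter(angles: np.ndarray) -> np.ndarray | float:
    """Circular-moment order parameter S = ⟨cos χ⟩² + ⟨sin χ⟩².

    1 for a frozen dihedral, → 0 for a uniformly rotating one.  ``angles``
    in radians, shape (n_frames,) or (n_frames, D).
    """
    c = np.mean(np.cos(angles), axis=0)
    s = np.mean(np.sin(angles), axis=0)
    out = c**2 + s**2
    return float(out) if np.ndim(out) == 0 else out


def dihedral_order_parameters(
    traj: TrajectoryEnsemble,
    dihedral_names: tuple[str, ...] = ("phi", "psi", "chi"),
) -> OrderParameterProfile:
    """Per-residue dihedral order parameters over the concatenated ensemble.

    Each residue's value is the mean S over its defined dihedrals (φ, ψ and
    the side-chain stand-in χ where present); dihedrals are internal
    coordinates, so no superposition is involved.  Residues with no defined
    dihedral (chain termini) are skipped.
    """
    topo = traj.topology
    coords = traj.concatenated()
    per_res_sum = np.zeros(topo.n_residues)
    per_res_n = np.zeros(topo.n_residues, dtype=int)
    found = False
    for name in dihedral_names:
        quads = topo.dihedrals.get(name)
        if quads is None or len(quads) == 0:
            continue
        found = True
        angles = dihedral_angles(coords, quads[:, :4])
        s = dihedral_order_parameter(angles)
        np.add.at(per_res_sum, quads[:, 4], np.atleast_1d(s))
        np.add.at(per_res_n, quads[:, 4], 1)
    if not found:
        raise ValueError(
            f"topology defines none of the dihedral sets {dihedral_names}"
        )
    defined = per_res_n > 0
    labels = topo.residue_labels()
    return OrderParameterProfile(
        names=[lab for lab, d in zip(labels, defined) if d],
        values=per_res_sum[defined] / per_res_n[defined],
        kind="dihedral",
        state=traj.label,
    )


def order_parameter_difference(
    before: OrderParameterProfile, after: OrderParameterProfile
) -> OrderParameterProfile:
    """Δ = S_before − S_after (positive = flexibility gain after)."""
    if before.kind != after.kind:
        raise ValueError("profiles are of different kinds")
    if before.names != after.names:
        raise ValueError("profiles cover different vectors/residues")
    return OrderParameterProfile(
        names=list(before.names),
        values=before.values - after.values,
        kind=f"delta_{before.kind}",
        window_ps=before.window_ps,
        state=f"{before.state}-{after.state}",
    )
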