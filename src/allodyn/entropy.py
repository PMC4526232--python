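"""Configurational entropy estimators.

Two estimators of the vibrational entropy of a fluctuating molecule, both
resting on the harmonic approximation but inferring the mode spectrum from
different observables:

* **QH (quasi-harmonic)** — eigen-decompose the covariance of mass-weighted
  coordinates; a mode of covariance eigenvalue λ corresponds to
  ω = √(kB·T/λ).
* **FC (force covariance)** — eigen-decompose the covariance of mass-weighted
  atomic forces f_i/√m_i; a mode of eigenvalue μ corresponds to
  ω = √(μ/(kB·T)), since ⟨f²⟩ = m·ω²·kB·T for a harmonic oscillator.

Both feed the recovered frequencies into the quantum harmonic-oscillator
entropy.  For an exactly harmonic (Gaussian) ensemble the two agree in the
infinite-sampling limit; on anharmonic, multimodal landscapes the coordinate
covariance inflates (QH overestimates entropy strongly) while forces track
the local curvature, so FC degrades more gracefully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import HBAR, KB, KCAL_PER_KJ
from .core import PairForceSeries, Topology, TrajectoryEnsemble
from .geometry import iterative_mean_structure

#: Relative floor under which covariance eigenvalues are treated as the
#: rigid-body / numerical null space and dropped.
EIGENVALUE_FLOOR = 1e-10


def s_qho(omega: np.ndarray | float, temperature: float) -> np.ndarray | float:
    """Quantum harmonic-oscillator entropy per mode, kJ·mol⁻¹·K⁻¹.

    s(ω) = kB·[ x/(eˣ−1) − ln(1−e⁻ˣ) ] with x = ħω/(kB·T).  Decreasing in ω;
    → 0 as ω → ∞ and diverges logarithmically as ω → 0.
    """
    x = HBAR * np.asarray(omega, dtype=float) / (KB * temperature)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        s = KB * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
    s = np.where(x > 0, s, np.inf)
    return float(s) if np.ndim(omega) == 0 else s


@dataclass
class EntropyResult:
    """Mode spectrum and total entropy of one state.

    ``omegas`` are mode angular frequencies in rad·ps⁻¹ (ascending);
    ``total_S`` is in kJ·mol⁻¹·K⁻¹.
    """

    omegas: np.ndarray
    mode_entropies: np.ndarray
    total_S: float
    temperature: float
    selection: str
    estimator: str
    n_dropped: int = 0

    def minus_TS_kcal(self) -> float:
        """−T·S in kcal·mol⁻¹ at the result's temperature."""
        return -self.temperature * self.total_S * KCAL_PER_KJ


def entropy_from_frequencies(
    omegas: np.ndarray,
    temperature: float,
    selection: str = "all",
    estimator: str = "modes",
    n_dropped: int = 0,
) -> EntropyResult:
    omegas = np.sort(np.asarray(omegas, dtype=float))
    per_mode = s_qho(omegas, temperature)
    return EntropyResult(
        omegas=omegas,
        mode_entropies=per_mode,
        total_S=float(np.sum(per_mode)),
        temperature=temperature,
        selection=selection,
        estimator=estimator,
        n_dropped=n_dropped,
    )


def _spectrum(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    """Eigenvalues above the relative floor, plus the count dropped."""
    lam = np.linalg.eigvalsh(matrix)
    floor = EIGENVALUE_FLOOR * lam.max()
    kept = lam[lam > floor]
    return kept, len(lam) - len(kept)


def qh_frequencies_from_covariance(
    cov_mw: np.ndarray, temperature: float
) -> tuple[np.ndarray, int]:
    """Mode frequencies from a mass-weighted coordinate covariance (amu·nm²)."""
    lam, dropped = _spectrum(cov_mw)
    return np.sqrt(KB * temperature / lam)[::-1], dropped


def fc_frequencies_from_covariance(
    cov_f_mw: np.ndarray, temperature: float
) -> tuple[np.ndarray, int]:
    """Mode frequencies from a mass-weighted force covariance."""
    mu, dropped = _spectrum(cov_f_mw)
    return np.sqrt(mu / (KB * temperature)), dropped


def quasi_harmonic_entropy(
    traj: TrajectoryEnsemble,
    selection: str = "full",
    temperature: float = 300.0,
    superpose: bool = True,
) -> EntropyResult:
    """QH entropy of an ensemble over a named atom selection.

    Frames are least-squares superposed to the selection's (iterated) mean
    structure before the covariance is formed, so rigid-body variance is
    removed coherently with the analysed atoms.  Covariance eigenvalues in
    the resulting ~6-dimensional null space fall under the spectral floor and
    are dropped; their entropy contribution vanishes anyway (ω → ∞).
    """
    topo = traj.topology
    idx = topo.select(selection)
    coords = traj.concatenated()[:, idx]
    n_frames = coords.shape[0]
    if n_frames < 3 * len(idx):
        warnings.warn(
            f"only {n_frames} frames for {len(idx)} atoms; the quasi-harmonic "
            "covariance may be poorly conditioned",
            stacklevel=2,
        )
    if superpose:
        coords, _ = iterative_mean_structure(coords)
    w = np.sqrt(topo.masses[idx])
    flat = (coords * w[None, :, None]).reshape(n_frames, -1)
    cov = np.cov(flat, rowvar=False)
    omegas, dropped = qh_frequencies_from_covariance(cov, temperature)
    return entropy_from_frequencies(omegas, temperature, selection, "QH", dropped)


def rigid_basis_mw(masses: np.ndarray,
                   positions: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal mass-weighted rigid-body directions, (3n, k).

    Translations always; infinitesimal rotations about the centre of
    geometry when ``positions`` are supplied.  These span the null space of
    any mass-weighted Hessian's rigid modes.
    """
    n = len(masses)
    sqm = np.sqrt(np.repeat(masses, 3))
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        vecs.append(t.reshape(-1))
    if positions is not None:
        cen = positions - positions.mean(axis=0)
        for ax in np.eye(3):
            vecs.append(np.cross(cen, ax).reshape(-1))
    r = np.array(vecs).T * sqm[:, None]
    q, _ = np.linalg.qr(r)
    return q


def force_covariance_entropy(
    forces: PairForceSeries | list[PairForceSeries] | np.ndarray,
    topology: Topology,
    selection: str = "full",
    temperature: float = 300.0,
    remove_rigid: bool = True,
    reference: np.ndarray | None = None,
) -> EntropyResult:
    """FC entropy from per-atom total forces.

    ``forces`` may be a (n_frames, n_atoms, 3) array of atomic forces, a
    :class:`PairForceSeries`, or a list of them (replicas); pair forces are
    summed per atom first.  No superposition is needed: a rigid rotation of
    all frames rotates the force covariance without changing its spectrum.

    With ``remove_rigid`` (the force-space analogue of superposing
    coordinates before QH) the selection's rigid-body force components are
    projected out before the covariance: net force always, net torque when a
    ``reference`` structure for the selection (or full topology) is given.
    Without this, a sub-selection of a larger system retains weak restoring
    forces along its own rigid directions — ultra-soft spurious modes that
    make entropy differences across binding states incomparable.
    """
    if isinstance(forces, PairForceSeries):
        forces = [forces]
    if isinstance(forces, list):
        forces = np.concatenate(
            [f.atomic_forces(topology.n_atoms) for f in forces], axis=0
        )
    idx = topology.select(selection)
    f = forces[:, idx] / np.sqrt(topology.masses[idx])[None, :, None]
    flat = f.reshape(f.shape[0], -1)
    if remove_rigid:
        pos = None
        if reference is not None:
            pos = reference[idx] if len(reference) == topology.n_atoms \
                else np.asarray(reference)
        q = rigid_basis_mw(topology.masses[idx], pos)
        flat = flat - (flat @ q) @ q.T
    cov = np.cov(flat, rowvar=False)
    if np.any(np.diag(cov) <= 0):
        warnings.warn("zero-variance force components dropped", stacklevel=2)
    omegas, dropped = fc_frequencies_from_covariance(cov, temperature)
    return entropy_from_frequencies(omegas, temperature, selection, "FC", dropped)


def entropy_difference(
    result_a: EntropyResult, result_b: EntropyResult
) -> float:
    """Binding-style entropy change −T·ΔS = −T·(S_b − S_a) in kcal·mol⁻¹.

    Positive values are entropic penalties (state *b* is stiffer / lower
    entropy than state *a*).  Estimator, selection and temperature must match.
    """
    if result_a.estimator != result_b.estimator:
        raise ValueError(
            f"estimator mismatch: {result_a.estimator} vs {result_b.estimator}"
        )
    if result_a.selection != result_b.selection:
        raise ValueError(
            f"selection mismatch: {result_a.selection} vs {result_b.selection}"
        )
    if result_a.temperature != result_b.temperature:
        raise ValueError("temperature mismatch")
    t = result_a.temperature
    return -t * (result_b.total_S - result_a.total_S) * KCAL_PER_KJ


def entropy_difference_bootstrap(
    traj_a: TrajectoryEnsemble,
    traj_b: TrajectoryEnsemble,
    estimator: str = "QH",
    selection: str = "full",
    temperature: float = 300.0,
    forces_a: list[PairForceSeries] | None = None,
    forces_b: list[PairForceSeries] | None = None,
    n_boot: int = 20,
    seed: int = 0,
) -> dict:
    """−TΔS with a replica-bootstrap uncertainty band.

    Replicas are resampled with replacement within each state; the band is
    the 2.5–97.5 percentile range over ``n_boot`` resamples.
    """

    def one(ta: TrajectoryEnsemble, tb: TrajectoryEnsemble,
            fa: list | None, fb: list | None) -> float:
        if estimator.upper() == "QH":
            ra = quasi_harmonic_entropy(ta, selection, temperature)
            rb = quasi_harmonic_entropy(tb, selection, temperature)
        elif estimator.upper() == "FC":
            ra = force_covariance_entropy(fa, ta.topology, selection, temperature)
            rb = force_covariance_entropy(fb, tb.topology, selection, temperature)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        return entropy_difference(ra, rb)

    point = one(traj_a, traj_b, forces_a, forces_b)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        ia = rng.integers(0, traj_a.n_replicas, traj_a.n_replicas)
        ib = rng.integers(0, traj_b.n_replicas, traj_b.n_replicas)
        ta = traj_a.with_replicas([traj_a.replicas[i] for i in ia])
        tb = traj_b.with_replicas([traj_b.replicas[i] for i in ib])
        fa = [forces_a[i] for i in ia] if forces_a is not None else None
        fb = [forces_b[i] for i in ib] if forces_b is not None else None
        draws.append(one(ta, tb, fa, fb))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "minus_T_delta_S_kcal": point,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "estimator": estimator.upper(),
        "selection": selection,
        "temperature_K": temperature,
    }
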