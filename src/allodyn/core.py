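"""Core in-memory containers shared by all analysis stages.

A :class:`Topology` maps atoms to residues and protomers (chains) and carries
masses plus the selection groups downstream analyses need (main-chain atoms,
methyl-axis vector definitions, dihedral quadruples).  A
:class:`TrajectoryEnsemble` holds the replicate coordinate series of one
liganded state.  A :class:`PairForceSeries` holds per-frame atom-pairwise
force vectors.

Residues are identified externally by protomer-qualified labels like
``"A:12"``; the second protomer of a homodimer is thus distinguished the way
NMR papers prime residue numbers (12 vs 12').
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MAINCHAIN_NAMES = ("N", "CA", "C", "O")


@dataclass
class Topology:
    """Atoms → residues → protomers mapping with masses and selection groups.

    Parameters
    ----------
    serials
        1-based atom serial numbers, unique.
    names
        Atom names (PDB convention: CA, N, C, O, ...).
    resids
        Residue numbers, per atom.
    resnames
        Residue names, per atom.
    chains
        Chain / protomer identifier, per atom.
    masses
        Atomic (or pseudo-atom) masses in amu, strictly positive.
    hetero
        True for ligand / heteroatom records.
    axis_pairs
        (K, 2) atom *indices* defining symmetry-axis vectors (tail, head),
        the stand-in for terminal C–CH3 bonds.
    dihedrals
        Mapping of dihedral name (e.g. ``"phi"``) to an (D, 5) int array:
        four atom indices followed by the residue index the angle belongs to.
    """

    serials: np.ndarray
    names: list[str]
    resids: np.ndarray
    resnames: list[str]
    chains: list[str]
    masses: np.ndarray
    hetero: np.ndarray
    axis_pairs: np.ndarray | None = None
    dihedrals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.serials = np.asarray(self.serials, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        if len(np.unique(self.serials)) != len(self.serials):
            raise ValueError("atom serials must be unique")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        # residue bookkeeping: order of first appearance
        keys = list(zip(self.chains, self.resids.tolist()))
        seen: dict[tuple[str, int], int] = {}
        atom_res = np.empty(len(keys), dtype=int)
        for a, key in enumerate(keys):
            if key not in seen:
                seen[key] = len(seen)
            atom_res[a] = seen[key]
        self._residue_keys = list(seen)
        self.atom_residue = atom_res  #: residue index per atom

    # ------------------------------------------------------------------ #
    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    @property
    def n_residues(self) -> int:
        return len(self._residue_keys)

    def residue_labels(self) -> list[str]:
        """Protomer-qualified labels, e.g. ``['A:1', 'A:2', 'B:1']``."""
        return [f"{c}:{r}" for c, r in self._residue_keys]

    def residue_chain(self) -> list[str]:
        return [c for c, _ in self._residue_keys]

    def residue_resid(self) -> np.ndarray:
        return np.array([r for _, r in self._residue_keys], dtype=int)

    def residue_hetero(self) -> np.ndarray:
        """True for residues made entirely of hetero atoms (ligands)."""
        out = np.ones(self.n_residues, dtype=bool)
        np.logical_and.at(out, self.atom_residue, self.hetero)
        return out

    def residue_index(self, chain: str, resid: int) -> int:
        try:
            return self._residue_keys.index((chain, int(resid)))
        except ValueError:
            raise KeyError(f"no residue {chain}:{resid} in topology") from None

    def atoms_of_residue(self, index: int) -> np.ndarray:
        return np.flatnonzero(self.atom_residue == index)

    def serial_to_index(self) -> dict[int, int]:
        return {int(s): i for i, s in enumerate(self.serials)}

    def select(self, selection: str) -> np.ndarray:
        """Atom indices for a named selection.

        ``"full"``: all non-hetero atoms; ``"mainchain"``: N/CA/C/O of
        non-hetero residues; ``"ca"``: CA only; ``"all"``: every atom
        including ligands.
        """
        if selection == "all":
            return np.arange(self.n_atoms)
        if selection == "full":
            return np.flatnonzero(~self.hetero)
        if selection == "mainchain":
            mask = np.array([n in MAINCHAIN_NAMES for n in self.names])
            return np.flatnonzero(mask & ~self.hetero)
        if selection == "ca":
            mask = np.array([n == "CA" for n in self.names])
            return np.flatnonzero(mask & ~self.hetero)
        raise ValueError(f"unknown selection {selection!r}")


@dataclass
class TrajectoryEnsemble:
    """Replicate coordinate series for one liganded state.

    ``replicas`` is a list of (n_frames, n_atoms, 3) arrays in nm, all sharing
    ``topology``; ``frame_spacing_ps`` is constant within a replica.
    """

    topology: Topology
    replicas: list[np.ndarray]
    frame_spacing_ps: float = 20.0
    label: str = "state"

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("ensemble needs at least one replica")
        for r in self.replicas:
            if r.ndim != 3 or r.shape[1] != self.topology.n_atoms or r.shape[2] != 3:
                raise ValueError(
                    "replica shape must be (n_frames, n_atoms, 3) matching topology"
                )

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_frames_total(self) -> int:
        return sum(r.shape[0] for r in self.replicas)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.replicas, axis=0)

    def with_replicas(self, replicas: list[np.ndarray]) -> "TrajectoryEnsemble":
        return replace(self, replicas=replicas)


@dataclass
class PairForceSeries:
    """Per-frame atom-pairwise force vectors.

    ``pairs`` holds 0-based atom index pairs with i < j, stored once;
    ``forces[t, p]`` is the force (kJ·mol⁻¹·nm⁻¹) exerted *on atom i by atom
    j* of pair p at frame t.  Newton's third law (F_ji = −F_ij) is implicit.
    """

    pairs: np.ndarray
    forces: np.ndarray
    times_ps: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.forces = np.asarray(self.forces, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        if self.forces.shape[:2] != (len(self.times_ps), len(self.pairs)):
            raise ValueError("forces must be shaped (n_frames, n_pairs, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.times_ps)

    def atomic_forces(self, n_atoms: int) -> np.ndarray:
        """Sum pair forces into per-atom total forces, (n_frames, n_atoms, 3)."""
        out = np.zeros((self.n_frames, n_atoms, 3))
        np.add.at(out, (slice(None), self.pairs[:, 0]), self.forces)
        np.subtract.at(out, (slice(None), self.pairs[:, 1]), self.forces)
        return out
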