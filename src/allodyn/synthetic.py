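"""Synthetic elastic-network dimer models with analytic ground truth.

The generator builds a C2-symmetric two-protomer elastic network model (ENM):
pseudo-atoms on a jittered lattice, Hookean springs between all pairs within
a contact cutoff, and optionally

* a **ligand** node attached by springs to a binding pocket (the stand-in for
  effector binding as a local stiffness perturbation), and
* a **planted pathway** — a designated chain of springs whose stiffness
  differs between two states, emulating an inter-protomer allosteric route
  whose recovery downstream analyses can be scored against.

Because fluctuations are stationary Gaussians with covariance kB·T·H⁺ (H the
spring Hessian), the configurational entropy, per-bond force statistics and
per-node variances are all known in closed form, which makes every downstream
estimator testable without external trajectories.

Units: nm, amu, kJ·mol⁻¹, ps (see :mod:`allodyn.constants`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse.csgraph as csgraph
from scipy.sparse import csr_matrix

from .constants import KB
from .core import PairForceSeries, Topology, TrajectoryEnsemble
from .entropy import EntropyResult, entropy_from_frequencies

_SITE_NAMES = ("N", "CA", "C", "CB")
_SITE_MASSES = {"N": 15.0, "CA": 13.0, "C": 28.0, "CB": 54.0}
_SITE_OFFSETS = {
    "N": np.array([-0.125, 0.045, 0.0]),
    "CA": np.zeros(3),
    "C": np.array([0.125, 0.045, 0.0]),
    "CB": np.array([0.0, -0.10, 0.11]),
}
_ONE_SITE_MASS = 110.0  # mean amino-acid residue mass, amu
_LIGAND_MASS = 329.0  # cAMP-like, amu


@dataclass
class PathwaySpec:
    """A designated set of residue-residue contacts with stiffness deltas.

    ``edges`` lists ``((chain_u, resid_u), (chain_v, resid_v))`` pairs;
    ``delta_k`` (kJ·mol⁻¹·nm⁻²) is added to every spring joining the two
    residues when the pathway is applied.
    """

    edges: list[tuple[tuple[str, int], tuple[str, int]]]
    delta_k: float


@dataclass
class EnsembleSpec:
    """Sampling protocol for one state.

    ``sampler`` is ``"gaussian"`` (frames i.i.d. from the exact ENM
    covariance — entropy ground truth is exact) or ``"langevin"`` (per-mode
    Ornstein-Uhlenbeck with correlation time 1/ω — for analyses that need
    time correlation, e.g. windowed order parameters).
    """

    n_replicas: int = 1
    n_frames: int = 1000
    temperature: float = 300.0
    sampler: str = "gaussian"
    seed: int = 0
    frame_spacing_ps: float = 20.0

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.sampler not in ("gaussian", "langevin"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class ToyModel:
    """An elastic-network model with known Hessian and planted ground truth."""

    positions: np.ndarray  # (N, 3) equilibrium coordinates, nm
    masses: np.ndarray  # (N,) amu
    names: list[str]
    resids: np.ndarray
    resnames: list[str]
    chains: list[str]
    hetero: np.ndarray  # ligand flag per node
    springs: np.ndarray  # (M, 2) node index pairs, i < j
    stiffness: np.ndarray  # (M,) kJ·mol⁻¹·nm⁻²
    eq_length: np.ndarray  # (M,) nm
    pathway_springs: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    pathway_delta_k: float = 0.0
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    label: str = "model"

    def __post_init__(self) -> None:
        self.springs = np.asarray(self.springs, dtype=int).reshape(-1, 2)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        if np.any(self.springs[:, 0] >= self.springs[:, 1]):
            raise ValueError("springs must be stored once with i < j")
        pairs = {tuple(p) for p in self.springs}
        if len(pairs) != len(self.springs):
            raise ValueError("duplicate springs")
        if np.any(self.stiffness <= 0):
            raise ValueError("spring stiffnesses must be positive")

    # ------------------------------------------------------------------ #
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def pathway_edges(self) -> np.ndarray:
        """Node-index pairs of the planted pathway springs (ground truth)."""
        return self.springs[self.pathway_springs]

    def pathway_residue_pairs(self) -> set[tuple[str, str]]:
        """Planted pathway as unordered residue-label pairs (``'A:3'``)."""
        topo = self.topology()
        labels = topo.residue_labels()
        out = set()
        for i, j in self.pathway_edges:
            u, v = labels[topo.atom_residue[i]], labels[topo.atom_residue[j]]
            if u != v:
                out.add((min(u, v), max(u, v)))
        return out

    def with_pathway_applied(self, label: str | None = None) -> "ToyModel":
        """The alternate state: pathway springs stiffened by ``delta_k``."""
        k = self.stiffness.copy()
        k[self.pathway_springs] += self.pathway_delta_k
        if np.any(k <= 0):
            raise ValueError("pathway delta_k would make a stiffness non-positive")
        return replace(self, stiffness=k, label=label or f"{self.label}+pathway")

    def topology(self) -> Topology:
        axis_pairs, dihedrals = _selection_groups(self)
        return Topology(
            serials=np.arange(1, self.n_atoms + 1),
            names=list(self.names),
            resids=self.resids,
            resnames=list(self.resnames),
            chains=list(self.chains),
            masses=self.masses,
            hetero=self.hetero,
            axis_pairs=axis_pairs,
            dihedrals=dihedrals,
        )

    # ------------------------------------------------------------------ #
    def hessian(self) -> np.ndarray:
        """(3N, 3N) second-derivative matrix of the spring potential.

        Equilibrium lengths equal the build geometry's distances (a relaxed
        network), so each spring contributes k·d̂d̂ᵀ on its pair block.
        """
        n = self.n_atoms
        h = np.zeros((3 * n, 3 * n))
        d = self.positions[self.springs[:, 0]] - self.positions[self.springs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dhat = d / r[:, None]
        blocks = self.stiffness[:, None, None] * dhat[:, :, None] * dhat[:, None, :]
        # springs strained at build geometry also pick up the tangential term
        strain = 1.0 - self.eq_length / r
        eye = np.eye(3)
        blocks += (self.stiffness * strain)[:, None, None] * (
            eye[None] - dhat[:, :, None] * dhat[:, None, :]
        )
        for (i, j), b in zip(self.springs, blocks):
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            h[si, si] += b
            h[sj, sj] += b
            h[si, sj] -= b
            h[sj, si] -= b
        return h

    def mass_weighted_hessian(self) -> np.ndarray:
        w = 1.0 / np.sqrt(np.repeat(self.masses, 3))
        return self.hessian() * w[:, None] * w[None, :]

    def mode_spectrum(self) -> np.ndarray:
        """Vibrational frequencies ω (rad·ps⁻¹) of the internal modes.

        Rigid-body (and, for degenerate geometries such as collinear pairs,
        additional null) modes are identified by a relative spectral floor
        and excluded; a generic connected 3-D model has exactly six.
        """
        lam = np.linalg.eigvalsh(self.mass_weighted_hessian())
        lam = lam[lam > 1e-9 * lam.max()]
        return np.sqrt(lam)


# ---------------------------------------------------------------------- #
# builders


def _selection_groups(model: "ToyModel") -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Methyl-axis stand-in vectors and backbone dihedral quadruples."""
    topo_res: dict[tuple[str, int], dict[str, int]] = {}
    for a, (c, r, nm, het) in enumerate(
        zip(model.chains, model.resids.tolist(), model.names, model.hetero)
    ):
        if het:
            continue
        topo_res.setdefault((c, r), {})[nm] = a
    axis, phi, psi, chi = [], [], [], []
    keys = list(topo_res)
    res_index = {k: i for i, k in enumerate(dict.fromkeys(
        zip(model.chains, model.resids.tolist())))}
    for idx, key in enumerate(keys):
        atoms = topo_res[key]
        if "CB" in atoms and "CA" in atoms:
            axis.append((atoms["CA"], atoms["CB"]))
            if "N" in atoms and "C" in atoms:
                chi.append((atoms["N"], atoms["CA"], atoms["C"], atoms["CB"],
                            res_index[key]))
        elif len(atoms) == 1 and idx + 1 < len(keys):
            nxt = topo_res[keys[idx + 1]]
            if keys[idx + 1][0] == key[0] and len(nxt) == 1:
                axis.append((next(iter(atoms.values())), next(iter(nxt.values()))))
        if "N" in atoms and "CA" in atoms and "C" in atoms:
            if idx > 0 and keys[idx - 1][0] == key[0]:
                prev = topo_res[keys[idx - 1]]
                if "C" in prev:
                    phi.append((prev["C"], atoms["N"], atoms["CA"], atoms["C"],
                                res_index[key]))
            if idx + 1 < len(keys) and keys[idx + 1][0] == key[0]:
                nxt = topo_res[keys[idx + 1]]
                if "N" in nxt:
                    psi.append((atoms["N"], atoms["CA"], atoms["C"], nxt["N"],
                                res_index[key]))
    dihedrals = {}
    for name, quads in (("phi", phi), ("psi", psi), ("chi", chi)):
        if quads:
            dihedrals[name] = np.array(quads, dtype=int)
    axis_arr = np.array(axis, dtype=int) if axis else None
    return axis_arr, dihedrals


def _protomer_sites(n_res: int, spacing: float, rng: np.random.Generator,
                    sites_per_residue: int) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Residue centres on a jittered compact lattice, expanded to sites."""
    side = int(np.ceil(n_res ** (1 / 3)))
    grid = np.array(
        [(x, y, z) for x in range(side) for y in range(side) for z in range(side)],
        dtype=float,
    )[:n_res]
    centres = grid * spacing
    centres += rng.normal(scale=0.05 * spacing, size=centres.shape)
    centres -= centres.mean(axis=0)
    if sites_per_residue == 1:
        names = ["CA"] * n_res
        return centres, names, np.arange(1, n_res + 1)
    pos, names, resids = [], [], []
    for i, c in enumerate(centres):
        for nm in _SITE_NAMES:
            pos.append(c + _SITE_OFFSETS[nm])
            names.append(nm)
            resids.append(i + 1)
    return np.asarray(pos), names, np.asarray(resids)


def build_enm_dimer(
    n_res_per_protomer: int,
    contact_cutoff: float = 1.2,
    k_default: float = 500.0,
    pathway_spec: PathwaySpec | None = None,
    seed: int = 0,
    sites_per_residue: int = 1,
    spacing: float = 0.55,
    interface_gap: float = 0.6,
) -> ToyModel:
    """Build a C2-symmetric elastic-network homodimer.

    Protomer A is a jittered compact lattice of pseudo-residues; protomer B
    is its image under a two-fold rotation about the z axis, so the dimer has
    exact C2 symmetry.  Springs of stiffness ``k_default`` join every node
    pair within ``contact_cutoff`` (nm), intra- and inter-protomer alike.
    ``pathway_spec`` marks a subset of residue contacts whose springs are to
    be stiffened by ``delta_k`` in the perturbed state (see
    :meth:`ToyModel.with_pathway_applied`); the marked springs are recorded
    on the model as ground truth.
    """
    if n_res_per_protomer < 4:
        raise ValueError("need at least 4 residues per protomer")
    if sites_per_residue not in (1, 4):
        raise ValueError("sites_per_residue must be 1 or 4")
    rng = np.random.default_rng(seed)
    pos_a, names_a, resids_a = _protomer_sites(
        n_res_per_protomer, spacing, rng, sites_per_residue
    )
    # protomer A sits at x > 0 with its inner face at x = +gap/2
    pos_a[:, 0] -= pos_a[:, 0].min() - interface_gap / 2
    # C2 rotation about the z axis: (x, y, z) -> (-x, -y, z)
    pos_b = pos_a * np.array([-1.0, -1.0, 1.0])
    positions = np.vstack([pos_a, pos_b])
    names = names_a + names_a
    resids = np.concatenate([resids_a, resids_a])
    chains = ["A"] * len(pos_a) + ["B"] * len(pos_b)
    if sites_per_residue == 1:
        masses = np.full(len(positions), _ONE_SITE_MASS)
    else:
        masses = np.array([_SITE_MASSES[n] for n in names])
    n = len(positions)
    diff = positions[:, None] - positions[None, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    within = dist[iu, ju] <= contact_cutoff
    springs = np.column_stack([iu[within], ju[within]])
    eq = dist[springs[:, 0], springs[:, 1]]
    _check_connected(n, springs, chains, resids)
    model = ToyModel(
        positions=positions,
        masses=masses,
        names=names,
        resids=resids,
        resnames=["GLY"] * n,
        chains=chains,
        hetero=np.zeros(n, dtype=bool),
        springs=springs,
        stiffness=np.full(len(springs), float(k_default)),
        eq_length=eq,
        label="apo",
    )
    if pathway_spec is not None:
        model = mark_pathway(model, pathway_spec)
    return model


def _check_connected(n: int, springs: np.ndarray, chains: list[str],
                     resids: np.ndarray) -> None:
    adj = csr_matrix(
        (np.ones(len(springs)), (springs[:, 0], springs[:, 1])), shape=(n, n)
    )
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        main = np.bincount(labels).argmax()
        isolated = [
            f"{chains[i]}:{resids[i]}" for i in np.flatnonzero(labels != main)
        ]
        raise ValueError(
            "contact network is disconnected; isolated nodes: "
            + ", ".join(sorted(set(isolated)))
        )


def mark_pathway(model: ToyModel, spec: PathwaySpec) -> ToyModel:
    """Record ``spec``'s residue contacts as the model's planted pathway."""
    topo = model.topology()
    res_of = topo.atom_residue
    wanted = set()
    for (cu, ru), (cv, rv) in spec.edges:
        wanted.add(frozenset((topo.residue_index(cu, ru), topo.residue_index(cv, rv))))
    hit = [
        m
        for m, (i, j) in enumerate(model.springs)
        if frozenset((res_of[i], res_of[j])) in wanted
    ]
    covered = {
        frozenset((res_of[i], res_of[j])) for i, j in model.springs[hit]
    }
    missing = wanted - covered
    if missing:
        labels = topo.residue_labels()
        pretty = ["-".join(sorted(labels[i] for i in m)) for m in missing]
        raise ValueError(
            "pathway edges have no spring within the contact cutoff: "
            + ", ".join(sorted(pretty))
        )
    return replace(
        model,
        pathway_springs=np.asarray(hit, dtype=int),
        pathway_delta_k=spec.delta_k,
    )


def shortest_interprotomer_pathway(
    model: ToyModel,
    start: tuple[str, int],
    end: tuple[str, int],
    delta_k: float,
) -> PathwaySpec:
    """A pathway along the shortest residue-contact chain from ``start`` to
    ``end`` (typically a residue of protomer A to one of protomer B)."""
    import networkx as nx

    topo = model.topology()
    g = nx.Graph()
    res_of = topo.atom_residue
    for i, j in model.springs:
        u, v = int(res_of[i]), int(res_of[j])
        if u != v:
            g.add_edge(u, v)
    path = nx.shortest_path(
        g, topo.residue_index(*start), topo.residue_index(*end)
    )
    chains = topo.residue_chain()
    resids = topo.residue_resid()
    edges = [
        ((chains[u], int(resids[u])), (chains[v], int(resids[v])))
        for u, v in zip(path[:-1], path[1:])
    ]
    return PathwaySpec(edges=edges, delta_k=delta_k)


def add_ligand(
    model: ToyModel,
    pocket_residues: list[tuple[str, int]],
    k_ligand: float,
    mass: float = _LIGAND_MASS,
    label: str | None = None,
) -> ToyModel:
    """Attach a ligand pseudo-atom to a binding pocket by springs.

    The ligand node sits at the pocket centroid, nudged away from the model's
    centre of geometry, and is joined to one node of each pocket residue (the
    CA site).  The input model is left unmodified.
    """
    if k_ligand <= 0:
        raise ValueError("k_ligand must be positive")
    if not pocket_residues:
        raise ValueError("pocket_residues must not be empty")
    topo = model.topology()
    anchor_atoms = []
    for chain, resid in pocket_residues:
        atoms = topo.atoms_of_residue(topo.residue_index(chain, resid))
        ca = [a for a in atoms if topo.names[a] == "CA"]
        anchor_atoms.append(ca[0] if ca else atoms[0])
    anchors = np.array(anchor_atoms, dtype=int)
    centroid = model.positions[anchors].mean(axis=0)
    outward = centroid - model.positions.mean(axis=0)
    nrm = np.linalg.norm(outward)
    lig_pos = centroid + (outward / nrm * 0.25 if nrm > 1e-9 else np.array([0, 0, 0.25]))
    n = model.n_atoms
    new_springs = np.array([[a, n] for a in sorted(set(anchors.tolist()))])
    eq_new = np.linalg.norm(model.positions[new_springs[:, 0]] - lig_pos, axis=1)
    n_lig = int(np.sum(model.hetero))
    return replace(
        model,
        positions=np.vstack([model.positions, lig_pos]),
        masses=np.append(model.masses, mass),
        names=list(model.names) + ["L"],
        resids=np.append(model.resids, 900 + n_lig + 1),
        resnames=list(model.resnames) + ["LIG"],
        chains=list(model.chains) + [model.chains[anchors[0]]],
        hetero=np.append(model.hetero, True),
        springs=np.vstack([model.springs, new_springs]),
        stiffness=np.append(model.stiffness, np.full(len(new_springs), k_ligand)),
        eq_length=np.append(model.eq_length, eq_new),
        label=label or f"{model.label}+lig",
    )


# ---------------------------------------------------------------------- #
# sampling and exact observables


def _replica_rng(seed: int, replica: int) -> np.random.Generator:
    """Counter-based (Philox) stream: replica r is bitwise identical no
    matter how many replicas are drawn."""
    return np.random.Generator(
        np.random.Philox(key=np.uint64(seed), counter=[0, 0, np.uint64(replica), 0])
    )


def sample_ensemble(model: ToyModel, spec: EnsembleSpec) -> TrajectoryEnsemble:
    """Draw an ensemble of fluctuation trajectories from the model.

    Frames have exact covariance kB·T·H⁺ about the equilibrium coordinates
    (rigid-body modes carry zero variance).  The ``langevin`` sampler keeps
    the same stationary covariance but gives each mode an exponential time
    correlation with τ = 1/ω.
    """
    hmw = model.mass_weighted_hessian()
    lam, vec = np.linalg.eigh(hmw)
    keep = lam > 1e-9 * lam.max()
    lam, vec = lam[keep], vec[:, keep]
    if len(lam) == 0:
        raise ValueError("model Hessian has no internal modes")
    omega = np.sqrt(lam)
    sigma = np.sqrt(KB * spec.temperature / lam)  # modal std dev
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(model.masses, 3))
    x0 = model.positions.reshape(-1)
    replicas = []
    for rep in range(spec.n_replicas):
        rng = _replica_rng(spec.seed, rep)
        if spec.sampler == "gaussian":
            q = rng.standard_normal((spec.n_frames, len(lam))) * sigma
        else:
            rho = np.exp(-spec.frame_spacing_ps * omega)  # dt / tau, tau = 1/omega
            q = np.empty((spec.n_frames, len(lam)))
            q[0] = rng.standard_normal(len(lam)) * sigma
            innov = np.sqrt(1.0 - rho**2) * sigma
            for t in range(1, spec.n_frames):
                q[t] = rho * q[t - 1] + innov * rng.standard_normal(len(lam))
        disp = (q @ vec.T) * inv_sqrt_m
        replicas.append((x0 + disp).reshape(spec.n_frames, model.n_atoms, 3))
    return TrajectoryEnsemble(
        topology=model.topology(),
        replicas=replicas,
        frame_spacing_ps=spec.frame_spacing_ps,
        label=model.label,
    )


def analytic_entropy(
    model: ToyModel,
    temperature: float = 300.0,
    selection: str = "all",
    estimator: str = "modes",
) -> EntropyResult:
    """Exact entropy of the model under the harmonic (quantum HO) treatment.

    ``estimator='modes'`` sums the quantum harmonic-oscillator entropy over
    the 3N−6 internal modes of the mass-weighted Hessian (requires
    ``selection='all'``).  ``'qh'`` and ``'fc'`` give the infinite-sampling
    limits of the corresponding estimator restricted to an atom selection:
    QH sees the marginal coordinate covariance kB·T·(H⁺)_sel, FC the force
    covariance kB·T·H_sel; for the full selection all three coincide.
    """
    if estimator == "modes":
        if selection != "all":
            raise ValueError("'modes' entropy is defined for the full model")
        return entropy_from_frequencies(
            model.mode_spectrum(), temperature, selection, "analytic", 6
        )
    topo = model.topology()
    idx = topo.select(selection)
    dof = (3 * idx[:, None] + np.arange(3)[None, :]).reshape(-1)
    sqm = np.sqrt(np.repeat(model.masses[idx], 3))
    if estimator == "qh":
        hinv = np.linalg.pinv(model.hessian(), rcond=1e-10)
        cov = KB * temperature * hinv[np.ix_(dof, dof)]
        cov_mw = cov * sqm[:, None] * sqm[None, :]
        # the QH estimator superposes frames on the selection, removing its
        # rigid-body variance; mirror that by projecting out the selection's
        # six rigid directions (mass-weighted) before taking the spectrum
        from .entropy import rigid_basis_mw

        q = rigid_basis_mw(model.masses[idx], model.positions[idx])
        proj = np.eye(len(dof)) - q @ q.T
        cov_mw = proj @ cov_mw @ proj
        lam = np.linalg.eigvalsh(cov_mw)
        lam = lam[lam > 1e-10 * lam.max()]
        omegas = np.sqrt(KB * temperature / lam)
        return entropy_from_frequencies(omegas, temperature, selection, "QH-limit")
    if estimator == "fc":
        from .entropy import rigid_basis_mw

        hmw = model.mass_weighted_hessian()
        block = hmw[np.ix_(dof, dof)]
        # remove the selection's rigid directions, mirroring the estimator
        q = rigid_basis_mw(model.masses[idx], model.positions[idx])
        proj = np.eye(len(dof)) - q @ q.T
        mu = np.linalg.eigvalsh(proj @ block @ proj)
        mu = mu[mu > 1e-10 * mu.max()]
        return entropy_from_frequencies(
            np.sqrt(mu), temperature, selection, "FC-limit"
        )
    raise ValueError(f"unknown estimator {estimator!r}")


def pairwise_forces_from_model(
    model: ToyModel,
    traj: TrajectoryEnsemble,
    include_nonbonded: bool = False,
    linearize: bool = False,
) -> list[PairForceSeries]:
    """Per-frame pairwise forces on every spring, one series per replica.

    The force stored for pair (i, j) is the force on i exerted by j:
    −k·(r−r₀)·d̂ with d = x_i − x_j.  With ``linearize`` the force is the
    first-order expansion about the equilibrium geometry,
    −k·(d̂₀·(d−d₀))·d̂₀, which is exactly the force field of the harmonic
    model the Gaussian sampler draws from — use it when an estimator is to
    be compared against the analytic harmonic oracle; the default exact
    force retains the geometric anharmonicity of finite-length springs.
    With ``include_nonbonded`` and per-atom charge/LJ parameters on the
    model, Coulomb and Lennard-Jones pair forces between non-bonded pairs
    are added as separate records.
    """
    if traj.topology.n_atoms != model.n_atoms:
        raise ValueError("trajectory topology does not match the model")
    pairs = model.springs
    if include_nonbonded:
        if model.charges is None or model.lj_sigma is None:
            raise ValueError("model carries no non-bonded parameters")
        bonded = {tuple(p) for p in model.springs}
        iu, ju = np.triu_indices(model.n_atoms, k=1)
        nb = np.array([
            (i, j) for i, j in zip(iu, ju) if (i, j) not in bonded
        ])
        pairs = np.vstack([model.springs, nb])
    out = []
    for rep in traj.replicas:
        n_frames = rep.shape[0]
        d = rep[:, pairs[:, 0]] - rep[:, pairs[:, 1]]
        r = np.linalg.norm(d, axis=-1)
        forces = np.zeros_like(d)
        m = len(model.springs)
        if linearize:
            d0 = (model.positions[model.springs[:, 0]]
                  - model.positions[model.springs[:, 1]])
            dhat0 = d0 / np.linalg.norm(d0, axis=-1, keepdims=True)
            proj = np.einsum("fmk,mk->fm", d[:, :m] - d0[None], dhat0)
            forces[:, :m] = -(model.stiffness * proj)[..., None] * dhat0[None]
        else:
            forces[:, :m] = (
                -(model.stiffness * (r[:, :m] - model.eq_length)
                  / r[:, :m])[..., None] * d[:, :m]
            )
        if include_nonbonded and len(pairs) > m:
            from .constants import COULOMB_KE

            qi = model.charges[pairs[m:, 0]]
            qj = model.charges[pairs[m:, 1]]
            sig = 0.5 * (model.lj_sigma[pairs[m:, 0]] + model.lj_sigma[pairs[m:, 1]])
            eps = np.sqrt(
                model.lj_epsilon[pairs[m:, 0]] * model.lj_epsilon[pairs[m:, 1]]
            )
            rr = r[:, m:]
            sr6 = (sig / rr) ** 6
            # magnitude of dV/dr, applied along d̂ (positive = repulsive)
            mag = (
                24 * eps * (2 * sr6**2 - sr6) / rr + COULOMB_KE * qi * qj / rr**2
            )
            forces[:, m:] = (mag / rr)[..., None] * d[:, m:]
        times = np.arange(n_frames) * traj.frame_spacing_ps
        out.append(
            PairForceSeries(
                pairs=pairs,
                forces=forces,
                times_ps=times,
                provenance={
                    "bonded": True,
                    "nonbonded": bool(include_nonbonded),
                    "model": model.label,
                },
            )
        )
    return out


def generate_axis_vectors(
    s2_target: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Unit-vector series whose methyl-axis order parameter is ``s2_target``.

    Wobble-in-a-cone sampling about the z axis: for cone semi-angle θ₀ the
    order parameter is S = cosθ₀(1+cosθ₀)/2 and S² is its square, so the cone
    angle is chosen from the positive root of c² + c − 2√(s2_target) = 0.
    """
    if not 0.0 <= s2_target <= 1.0:
        raise ValueError("s2_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    c0 = (-1.0 + np.sqrt(1.0 + 8.0 * np.sqrt(s2_target))) / 2.0
    if s2_target >= 1.0:
        return np.tile(np.array([0.0, 0.0, 1.0]), (n_frames, 1))
    if s2_target == 0.0:
        cos_t = rng.uniform(-1.0, 1.0, n_frames)  # isotropic on the sphere
    else:
        cos_t = rng.uniform(c0, 1.0, n_frames)
    phi = rng.uniform(0.0, 2 * np.pi, n_frames)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t]
    )
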