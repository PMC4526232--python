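"""Force distribution analysis (FDA) on residue pairwise forces.

The residue-pair force between residues u and v at one frame is the norm of
the *vector sum* of all atom-pairwise forces between atoms of u and atoms of
v — summing vectors before taking the magnitude, so opposing atomic forces
cancel.  Time- and replica-averaged tables of these scalars are compared
between liganded states; thresholding the absolute differences yields
connected "force networks" that trace allosteric signal propagation, and the
per-residue row sums ("punctual stress") provide a convergence diagnostic on
symmetric homodimers.

All forces are reported in pN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .constants import PN_PER_KJ_MOL_NM
from .core import PairForceSeries, Topology


@dataclass
class FramePairForces:
    """Per-frame residue-pair force values for one replica.

    ``values`` is (n_frames, Q) of scalars (pN) or (n_frames, Q, 3) of summed
    force vectors, for pairs listed in ``pair_index`` (residue indices,
    u < v, intra-residue pairs excluded).
    """

    pair_index: np.ndarray
    values: np.ndarray
    residue_labels: list[str]


@dataclass
class ResiduePairForceTable:
    """Time- and replica-averaged residue-pair forces ⟨F_uv⟩ (pN ≥ 0)."""

    pair_index: np.ndarray
    mean: np.ndarray
    per_replica: np.ndarray  # (n_replicas, Q)
    residue_labels: list[str]
    n_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = np.lexsort((self.pair_index[:, 1], self.pair_index[:, 0]))
        self.pair_index = self.pair_index[order]
        self.mean = np.asarray(self.mean)[order]
        self.per_replica = np.asarray(self.per_replica)[:, order]

    def as_dict(self) -> dict[tuple[str, str], float]:
        lab = self.residue_labels
        return {
            (lab[u], lab[v]): float(m)
            for (u, v), m in zip(self.pair_index, self.mean)
        }

    def without_hetero(self, topology: Topology) -> "ResiduePairForceTable":
        """Drop pairs touching ligand pseudo-residues and the residues
        themselves, so states with and without ligands become comparable."""
        het = topology.residue_hetero()
        keep_res = np.flatnonzero(~het)
        remap = -np.ones(len(het), dtype=int)
        remap[keep_res] = np.arange(len(keep_res))
        keep = ~(het[self.pair_index[:, 0]] | het[self.pair_index[:, 1]])
        return ResiduePairForceTable(
            pair_index=remap[self.pair_index[keep]],
            mean=self.mean[keep],
            per_replica=self.per_replica[:, keep],
            residue_labels=[self.residue_labels[i] for i in keep_res],
            n_frames=self.n_frames,
        )


@dataclass
class DeltaForceTable:
    """Signed differences ΔF_uv = ⟨F_uv⟩_B − ⟨F_uv⟩_A (pN)."""

    pair_index: np.ndarray
    delta: np.ndarray
    residue_labels: list[str]


@dataclass
class ForceNetwork:
    """Thresholded force-difference graph.

    ``components`` are residue-label lists ordered by size (residue count),
    ties broken by summed |ΔF| then by lexicographically smallest member;
    every retained edge satisfies |ΔF| ≥ cutoff.
    """

    edges: list[tuple[str, str, float]]
    cutoff: float
    components: list[list[str]]
    component_of: dict[str, int]

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for u, v, d in self.edges:
            g.add_edge(u, v, delta_f=d)
        return g

    def largest(self) -> list[str]:
        return self.components[0] if self.components else []


@dataclass
class StressProfile:
    """Punctual stress S_u = Σ_v ⟨F_uv⟩ per residue (pN)."""

    residue_labels: list[str]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.residue_labels, map(float, self.values)))


# ---------------------------------------------------------------------- #


def residue_pair_forces(
    series: PairForceSeries,
    topology: Topology,
    reduce: str = "norm",
) -> FramePairForces:
    """Collapse atom-pairwise forces to residue-pair values per frame.

    ``reduce='norm'`` (default) returns the per-frame norm of the summed
    vector, in pN; ``'vector'`` returns the summed vectors themselves (for
    the average-then-norm alternative convention).
    """
    res_of = topology.atom_residue
    ru = res_of[series.pairs[:, 0]]
    rv = res_of[series.pairs[:, 1]]
    inter = ru != rv
    lo = np.minimum(ru, rv)[inter]
    hi = np.maximum(ru, rv)[inter]
    # sign convention: record the vector acting on the lower residue index
    sign = np.where(ru[inter] <= rv[inter], 1.0, -1.0)
    keys = lo.astype(np.int64) * topology.n_residues + hi
    uniq, inv = np.unique(keys, return_inverse=True)
    q = len(uniq)
    n_frames = series.n_frames
    sums = np.zeros((n_frames, q, 3))
    contrib = series.forces[:, inter] * sign[None, :, None]
    np.add.at(sums, (slice(None), inv), contrib)
    pair_index = np.column_stack([uniq // topology.n_residues,
                                  uniq % topology.n_residues])
    if reduce == "vector":
        values = sums * PN_PER_KJ_MOL_NM
    elif reduce == "norm":
        values = np.linalg.norm(sums, axis=-1) * PN_PER_KJ_MOL_NM
    else:
        raise ValueError(f"unknown reduce {reduce!r}")
    return FramePairForces(
        pair_index=pair_index,
        values=values,
        residue_labels=topology.residue_labels(),
    )


def average_table(replicas: list[FramePairForces]) -> ResiduePairForceTable:
    """Average per-frame values over time, then unweighted over replicas.

    Scalar input follows the default convention (norm per frame, then
    average); vector input is averaged first and the norm taken afterwards,
    the sign-cancelling alternative.  Replicas must share one residue set.
    """
    if not replicas:
        raise ValueError("need at least one replica")
    labels = replicas[0].residue_labels
    for r in replicas[1:]:
        if r.residue_labels != labels:
            raise ValueError("replicas come from different topologies")
    keys = [
        {tuple(p) for p in r.pair_index} for r in replicas
    ]
    all_pairs = sorted(set().union(*keys))
    index = {p: i for i, p in enumerate(all_pairs)}
    q = len(all_pairs)
    per_rep = np.zeros((len(replicas), q))
    n_frames = []
    for k, rep in enumerate(replicas):
        cols = np.array([index[tuple(p)] for p in rep.pair_index])
        if rep.values.ndim == 3:
            per_rep[k, cols] = np.linalg.norm(rep.values.mean(axis=0), axis=-1)
        else:
            per_rep[k, cols] = rep.values.mean(axis=0)
        n_frames.append(rep.values.shape[0])
    return ResiduePairForceTable(
        pair_index=np.array(all_pairs, dtype=int),
        mean=per_rep.mean(axis=0),
        per_replica=per_rep,
        residue_labels=labels,
        n_frames=n_frames,
    )


def force_difference(
    table_a: ResiduePairForceTable, table_b: ResiduePairForceTable
) -> DeltaForceTable:
    """ΔF_uv = ⟨F_uv⟩_B − ⟨F_uv⟩_A; pairs absent from one state count as 0."""
    if table_a.residue_labels != table_b.residue_labels:
        raise ValueError("residue sets differ between the two tables")
    da = table_a.as_dict()
    db = table_b.as_dict()
    labels = table_a.residue_labels
    pos = {lab: i for i, lab in enumerate(labels)}
    pairs = sorted(set(da) | set(db))
    delta = np.array([db.get(p, 0.0) - da.get(p, 0.0) for p in pairs])
    idx = np.array([[pos[u], pos[v]] for u, v in pairs], dtype=int)
    return DeltaForceTable(pair_index=idx, delta=delta, residue_labels=labels)


def threshold_network(
    delta_table: DeltaForceTable, cutoff: float, keep: str = "all"
) -> ForceNetwork:
    """Connected graph of force differences with |ΔF| ≥ cutoff (pN).

    ``keep='largest'`` retains only the component with the most residues
    (the convention used for reporting allosteric networks).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels = delta_table.residue_labels
    mask = np.abs(delta_table.delta) >= cutoff
    g = nx.Graph()
    for (u, v), d in zip(delta_table.pair_index[mask], delta_table.delta[mask]):
        g.add_edge(labels[u], labels[v], delta_f=float(d))
    comps = [
        sorted(c)
        for c in nx.connected_components(g)
    ]

    def comp_key(c: list[str]) -> tuple:
        weight = sum(
            abs(g[u][v]["delta_f"]) for u, v in itertools.combinations(c, 2)
            if g.has_edge(u, v)
        )
        return (-len(c), -weight, c[0])

    comps.sort(key=comp_key)
    if keep == "largest":
        comps = comps[:1]
        keep_nodes = set(comps[0]) if comps else set()
    elif keep == "all":
        keep_nodes = set(g.nodes)
    else:
        raise ValueError(f"unknown keep mode {keep!r}")
    component_of = {}
    for ci, c in enumerate(comps):
        for node in c:
            component_of[node] = ci
    edges = [
        (u, v, float(d["delta_f"]))
        for u, v, d in g.edges(data=True)
        if u in keep_nodes and v in keep_nodes
    ]
    edges.sort(key=lambda e: (component_of[e[0]], e[0], e[1]))
    return ForceNetwork(
        edges=edges, cutoff=cutoff, components=comps, component_of=component_of
    )


def punctual_stress(table: ResiduePairForceTable) -> StressProfile:
    """Row sums of the mean pair-force table: S_u = Σ_v ⟨F_uv⟩."""
    values = _stress_from_means(table.pair_index, table.mean,
                                len(table.residue_labels))
    return StressProfile(residue_labels=table.residue_labels, values=values)


def _stress_from_means(pair_index: np.ndarray, means: np.ndarray,
                       n_residues: int) -> np.ndarray:
    out = np.zeros(n_residues)
    np.add.at(out, pair_index[:, 0], means)
    np.add.at(out, pair_index[:, 1], means)
    return out


def _protomer_partition(table: ResiduePairForceTable,
                        topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Indices of C2-mirrored residues in the two protomers, aligned by
    residue id."""
    chains = np.array(topology.residue_chain())
    resids = topology.residue_resid()
    het = topology.residue_hetero()
    label_pos = {lab: i for i, lab in enumerate(table.residue_labels)}
    all_labels = topology.residue_labels()
    prot = sorted(set(chains[~het]))
    if len(prot) != 2:
        raise ValueError(f"expected a two-protomer system, found chains {prot}")
    sides = []
    for p in prot:
        rows = np.flatnonzero((chains == p) & ~het)
        rows = rows[np.argsort(resids[rows])]
        sides.append(np.array([label_pos[all_labels[r]] for r in rows]))
    if len(sides[0]) != len(sides[1]):
        raise ValueError("protomers have different residue counts")
    return sides[0], sides[1]


def convergence_curve(
    table: ResiduePairForceTable,
    topology: Topology,
    k_max: int | None = None,
    max_subsets: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Protomer stress asymmetry as a function of replica subset size.

    For each subset size k, over all (or at most ``max_subsets`` randomly
    sampled) k-subsets of replicas: average the per-replica tables, compute
    punctual stress, and take the mean absolute difference between
    C2-mirrored residues of the two protomers.  On a symmetric dimer the
    curve decays toward zero as sampling accumulates.

    Returns ``(k_values, mean_abs_difference_pN)``.
    """
    n_rep = table.per_replica.shape[0]
    if n_rep < 2:
        raise ValueError("convergence diagnostic needs at least 2 replicas")
    if k_max is None:
        k_max = n_rep
    if k_max > n_rep:
        raise ValueError(f"k_max={k_max} exceeds replica count {n_rep}")
    ia, ib = _protomer_partition(table, topology)
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    out = np.zeros(len(ks))
    n_res = len(table.residue_labels)
    for pos, k in enumerate(ks):
        from math import comb

        if comb(n_rep, k) <= max_subsets:
            subsets = list(itertools.combinations(range(n_rep), k))
        else:
            subsets = [
                tuple(rng.choice(n_rep, size=k, replace=False))
                for _ in range(max_subsets)
            ]
        diffs = []
        for sub in subsets:
            means = table.per_replica[list(sub)].mean(axis=0)
            stress = _stress_from_means(table.pair_index, means, n_res)
            diffs.append(np.mean(np.abs(stress[ia] - stress[ib])))
        out[pos] = float(np.mean(diffs))
    return ks, out
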