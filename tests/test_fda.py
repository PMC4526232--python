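"""FDA semantics: vector-sum-then-norm pair forces, averaging conventions,
thresholded networks against a brute-force oracle, punctual stress
identities and the protomer-symmetry convergence diagnostic."""

import numpy as np
import pytest

from allodyn.constants import PN_PER_KJ_MOL_NM
from allodyn.core import PairForceSeries, Topology
from allodyn.fda import (
    FramePairForces,
    ResiduePairForceTable,
    average_table,
    convergence_curve,
    force_difference,
    punctual_stress,
    residue_pair_forces,
    threshold_network,
)
from allodyn.synthetic import EnsembleSpec, pairwise_forces_from_model, sample_ensemble


def toy_topology(n_atoms_per_res, chains=None):
    """n residues with given atom counts, single chain unless specified."""
    names, resids, ch = [], [], []
    for r, n in enumerate(n_atoms_per_res):
        for a in range(n):
            names.append(f"X{a}")
            resids.append(r + 1)
            ch.append(chains[r] if chains else "A")
    n_tot = len(names)
    return Topology(
        serials=np.arange(1, n_tot + 1),
        names=names,
        resids=np.array(resids),
        resnames=["GLY"] * n_tot,
        chains=ch,
        masses=np.ones(n_tot) * 10.0,
        hetero=np.zeros(n_tot, dtype=bool),
    )


def series_from_records(n_atoms, frames):
    """frames: list of dict {(i, j): vec}."""
    pairs = sorted(set().union(*[set(f) for f in frames]))
    forces = np.zeros((len(frames), len(pairs), 3))
    for t, rec in enumerate(frames):
        for p, v in rec.items():
            forces[t, pairs.index(p)] = v
    return PairForceSeries(
        pairs=np.array(pairs), forces=forces,
        times_ps=np.arange(len(frames), dtype=float),
    )


def brute_force_pair_table(series, topology):
    """Triple-loop reference: per frame, per residue pair, sum vectors."""
    res_of = topology.atom_residue
    n_res = topology.n_residues
    out = {}
    for t in range(series.n_frames):
        sums = {}
        for (i, j), vec in zip(series.pairs, series.forces[t]):
            u, v = res_of[i], res_of[j]
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            sign = 1.0 if u <= v else -1.0
            sums[key] = sums.get(key, np.zeros(3)) + sign * vec
        for key, vec in sums.items():
            out.setdefault(key, []).append(np.linalg.norm(vec))
    return {k: np.mean(v) * PN_PER_KJ_MOL_NM for k, v in out.items()}


class TestResiduePairForces:
    def test_single_atom_pair_gives_magnitude(self):
        topo = toy_topology([1, 1])
        f = 2.5
        s = series_from_records(2, [{(0, 1): (0, 0, f)}, {(0, 1): (0, 0, -f)}])
        fp = residue_pair_forces(s, topo)
        np.testing.assert_allclose(fp.values, f * PN_PER_KJ_MOL_NM)

    def test_opposite_vectors_cancel(self):
        topo = toy_topology([2, 2])
        f = np.array([1.0, -2.0, 0.5])
        s = series_from_records(4, [{(0, 2): tuple(f), (1, 3): tuple(-f)}])
        fp = residue_pair_forces(s, topo)
        np.testing.assert_allclose(fp.values, 0.0, atol=1e-12)

    def test_intra_residue_pairs_excluded(self):
        topo = toy_topology([2, 1])
        s = series_from_records(3, [{(0, 1): (1, 0, 0), (0, 2): (0, 1, 0)}])
        fp = residue_pair_forces(s, topo)
        assert len(fp.pair_index) == 1

    def test_matches_brute_force_on_random_toy(self):
        rng = np.random.default_rng(42)
        topo = toy_topology([2, 1, 3, 2, 2])
        n_atoms = topo.n_atoms
        iu, ju = np.triu_indices(n_atoms, k=1)
        frames = []
        for _ in range(6):
            rec = {}
            for i, j in zip(iu, ju):
                if rng.random() < 0.6:
                    rec[(int(i), int(j))] = tuple(rng.normal(size=3))
            frames.append(rec)
        s = series_from_records(n_atoms, frames)
        table = average_table([residue_pair_forces(s, topo)])
        oracle = brute_force_pair_table(s, topo)
        computed = table.as_dict()
        labels = topo.residue_labels()
        for (u, v), val in oracle.items():
            assert computed[(labels[u], labels[v])] == pytest.approx(val)

    def test_equivariance_under_residue_relabeling(self):
        # the same atomic forces with residues renumbered give a
        # consistently renamed table
        topo1 = toy_topology([1, 1, 1])
        topo2 = Topology(
            serials=topo1.serials, names=list(topo1.names),
            resids=np.array([7, 3, 5]), resnames=list(topo1.resnames),
            chains=list(topo1.chains), masses=topo1.masses,
            hetero=topo1.hetero,
        )
        s = series_from_records(
            3, [{(0, 1): (1, 0, 0), (1, 2): (0, 2, 0), (0, 2): (0, 0, 3)}]
        )
        t1 = average_table([residue_pair_forces(s, topo1)]).as_dict()
        t2 = average_table([residue_pair_forces(s, topo2)]).as_dict()
        rename = {"A:1": "A:7", "A:2": "A:3", "A:3": "A:5"}
        t2_sym = {frozenset(k): v for k, v in t2.items()}
        for (u, v), val in t1.items():
            assert t2_sym[frozenset((rename[u], rename[v]))] == pytest.approx(val)


class TestAveraging:
    def test_constant_scalar(self):
        topo = toy_topology([1, 1])
        s = series_from_records(5, [{(0, 1): (0, 0, 1.0)}] * 5)
        table = average_table([residue_pair_forces(s, topo)])
        np.testing.assert_allclose(table.mean, PN_PER_KJ_MOL_NM)

    def test_equilibrium_harmonic_pair_mean_positive(self, dimer, dimer_traj,
                                                     dimer_forces):
        # pairwise force magnitudes do not average to zero at equilibrium
        topo = dimer_traj.topology
        table = average_table(
            [residue_pair_forces(f, topo) for f in dimer_forces]
        )
        assert np.all(table.mean > 0)

    def test_unweighted_replica_average(self):
        topo = toy_topology([1, 1])
        rep_a = series_from_records(2, [{(0, 1): (0, 0, 1.0)}] * 2)
        rep_b = series_from_records(6, [{(0, 1): (0, 0, 3.0)}] * 6)
        table = average_table([
            residue_pair_forces(rep_a, topo),
            residue_pair_forces(rep_b, topo),
        ])
        np.testing.assert_allclose(table.mean, 2.0 * PN_PER_KJ_MOL_NM)

    def test_vector_mean_convention_cancels_signs(self):
        topo = toy_topology([1, 1])
        s = series_from_records(
            2, [{(0, 1): (0, 0, 1.0)}, {(0, 1): (0, 0, -1.0)}]
        )
        scalar = average_table([residue_pair_forces(s, topo)])
        vector = average_table([residue_pair_forces(s, topo, reduce="vector")])
        assert scalar.mean[0] == pytest.approx(PN_PER_KJ_MOL_NM)
        assert vector.mean[0] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_topologies_rejected(self):
        t1 = toy_topology([1, 1])
        t2 = toy_topology([1, 1, 1])
        s1 = series_from_records(2, [{(0, 1): (1, 0, 0)}] * 2)
        with pytest.raises(ValueError, match="topolog"):
            average_table([
                residue_pair_forces(s1, t1), residue_pair_forces(s1, t2),
            ])


def make_table(labels, entries, n_rep=1):
    pos = {lab: i for i, lab in enumerate(labels)}
    idx = np.array([[pos[u], pos[v]] for u, v in entries])
    vals = np.array(list(entries.values()), dtype=float)
    return ResiduePairForceTable(
        pair_index=idx, mean=vals,
        per_replica=np.tile(vals, (n_rep, 1)), residue_labels=list(labels),
    )


class TestDifferencesAndNetworks:
    def test_identical_tables_give_zero(self):
        t = make_table(["A:1", "A:2"], {("A:1", "A:2"): 10.0})
        d = force_difference(t, t)
        np.testing.assert_allclose(d.delta, 0.0)

    def test_pair_only_in_b(self):
        labels = ["A:1", "A:2", "A:3"]
        ta = make_table(labels, {("A:1", "A:2"): 5.0})
        tb = make_table(labels, {("A:1", "A:2"): 5.0, ("A:2", "A:3"): 60.0})
        d = force_difference(ta, tb)
        assert dict(zip(map(tuple, d.pair_index), d.delta))[(1, 2)] == 60.0

    def test_antisymmetry(self):
        labels = ["A:1", "A:2"]
        ta = make_table(labels, {("A:1", "A:2"): 5.0})
        tb = make_table(labels, {("A:1", "A:2"): 8.0})
        assert force_difference(ta, tb).delta[0] == -force_difference(tb, ta).delta[0]

    def test_residue_set_mismatch_rejected(self):
        ta = make_table(["A:1", "A:2"], {("A:1", "A:2"): 5.0})
        tb = make_table(["A:1", "A:3"], {("A:1", "A:3"): 5.0})
        with pytest.raises(ValueError, match="residue sets"):
            force_difference(ta, tb)

    def test_cutoff_above_max_gives_empty_network(self):
        ta = make_table(["A:1", "A:2"], {("A:1", "A:2"): 5.0})
        tb = make_table(["A:1", "A:2"], {("A:1", "A:2"): 25.0})
        net = threshold_network(force_difference(ta, tb), cutoff=50.0)
        assert net.edges == [] and net.components == []

    def test_planted_chain_recovered_exactly(self):
        labels = [f"A:{i}" for i in range(1, 7)]
        base = {("A:1", "A:2"): 10.0, ("A:3", "A:5"): 20.0,
                ("A:2", "A:4"): 30.0}
        chain = {("A:1", "A:3"): 60.0, ("A:3", "A:4"): 70.0,
                 ("A:4", "A:6"): 65.0}
        ta = make_table(labels, {**{k: 0.0 for k in base}, **{k: 0.0 for k in chain}})
        tb = make_table(labels, {**base, **chain})
        net = threshold_network(force_difference(ta, tb), cutoff=50.0,
                                keep="largest")
        got = {tuple(sorted((u, v))) for u, v, _ in net.edges}
        assert got == set(chain)
        assert net.largest() == ["A:1", "A:3", "A:4", "A:6"]

    def test_cutoff_monotonicity(self, dimer, dimer_traj, dimer_forces):
        topo = dimer_traj.topology
        reps = [residue_pair_forces(f, topo) for f in dimer_forces]
        ta = average_table(reps[:1])
        tb = average_table(reps[1:])
        delta = force_difference(ta, tb)
        e40 = {(u, v) for u, v, _ in threshold_network(delta, 40.0).edges}
        e50 = {(u, v) for u, v, _ in threshold_network(delta, 50.0).edges}
        assert e50 <= e40

    def test_component_ordering_deterministic(self):
        labels = [f"A:{i}" for i in range(1, 8)]
        entries = {("A:1", "A:2"): 60.0, ("A:3", "A:4"): 80.0,
                   ("A:5", "A:6"): 60.0}
        ta = make_table(labels, {k: 0.0 for k in entries})
        tb = make_table(labels, entries)
        net = threshold_network(force_difference(ta, tb), cutoff=50.0)
        # equal sizes: strongest component first, then lexicographic
        assert net.components == [["A:3", "A:4"], ["A:1", "A:2"], ["A:5", "A:6"]]


class TestStress:
    def test_single_pair(self):
        t = make_table(["A:1", "A:2"], {("A:1", "A:2"): 10.0})
        s = punctual_stress(t)
        np.testing.assert_allclose(s.values, [10.0, 10.0])

    def test_star_center_sums_arms(self):
        labels = ["A:1", "A:2", "A:3", "A:4"]
        t = make_table(labels, {("A:1", "A:2"): 1.0, ("A:1", "A:3"): 2.0,
                                ("A:1", "A:4"): 3.0})
        assert punctual_stress(t).as_dict()["A:1"] == pytest.approx(6.0)

    def test_double_counting_identity(self, dimer, dimer_traj, dimer_forces):
        topo = dimer_traj.topology
        table = average_table(
            [residue_pair_forces(f, topo) for f in dimer_forces]
        )
        s = punctual_stress(table)
        assert np.sum(s.values) == pytest.approx(2 * np.sum(table.mean))


class TestConvergence:
    def test_identical_replicas_flat_zero(self, dimer):
        topo = dimer.topology()
        labels = topo.residue_labels()
        t = make_table(labels, {(labels[0], labels[-1]): 5.0}, n_rep=4)
        ks, curve = convergence_curve(t, topo)
        np.testing.assert_allclose(curve, curve[0])

    def test_k1_matches_definition(self, dimer, dimer_traj, dimer_forces):
        topo = dimer_traj.topology
        table = average_table(
            [residue_pair_forces(f, topo) for f in dimer_forces]
        )
        ks, curve = convergence_curve(table, topo)
        # recompute k=1 by hand
        from allodyn.fda import _protomer_partition, _stress_from_means

        ia, ib = _protomer_partition(table, topo)
        per = []
        for r in range(table.per_replica.shape[0]):
            stress = _stress_from_means(
                table.pair_index, table.per_replica[r], len(table.residue_labels)
            )
            per.append(np.mean(np.abs(stress[ia] - stress[ib])))
        assert curve[0] == pytest.approx(np.mean(per))

    def test_asymmetry_shrinks_with_replicas(self, dimer):
        # seed-averaged trend on the symmetric dimer
        deltas = []
        for seed in range(4):
            spec = EnsembleSpec(n_replicas=6, n_frames=150, seed=100 + seed)
            traj = sample_ensemble(dimer, spec)
            forces = pairwise_forces_from_model(dimer, traj)
            topo = traj.topology
            table = average_table(
                [residue_pair_forces(f, topo) for f in forces]
            )
            ks, curve = convergence_curve(table, topo, seed=seed)
            deltas.append(curve)
        mean_curve = np.mean(deltas, axis=0)
        assert mean_curve[-1] < mean_curve[0]
        # non-increasing within noise: allow tiny upticks
        assert np.all(np.diff(mean_curve) < 0.05 * mean_curve[0])

    def test_k_exceeding_replicas_rejected(self, dimer):
        topo = dimer.topology()
        labels = topo.residue_labels()
        t = make_table(labels, {(labels[0], labels[-1]): 5.0}, n_rep=3)
        with pytest.raises(ValueError, match="exceeds"):
            convergence_curve(t, topo, k_max=5)

    def test_c2_stress_symmetry(self, dimer, dimer_traj, dimer_forces):
        # punctual stress per protomer should agree within sampling error
        topo = dimer_traj.topology
        table = average_table(
            [residue_pair_forces(f, topo) for f in dimer_forces]
        )
        s = punctual_stress(table)
        half = len(s.values) // 2
        a, b = s.values[:half], s.values[half:]
        rel = abs(a.mean() - b.mean()) / a.mean()
        assert rel < 0.05
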