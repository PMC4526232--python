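"""End-to-end pipeline: generate (or load) → forces → networks → entropy →
order parameters → motions → distance metrics, driven by one YAML config.

The demo configuration builds a synthetic C2 dimer in three liganded states
(apo, one ligand, two ligands), mirroring the apo/cap1/cap2 convention of
effector-binding studies, and writes per-stage TSV/YAML outputs plus a
manifest carrying the config hash and all seeds, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .core import TrajectoryEnsemble
from .entropy import (
    entropy_difference,
    force_covariance_entropy,
    quasi_harmonic_entropy,
)
from .fda import (
    average_table,
    convergence_curve,
    force_difference,
    punctual_stress,
    residue_pair_forces,
    threshold_network,
)
from .metrics import classify_by_inflections, minimal_distance
from .motions import pca, project_ensemble
from .orderparams import (
    methyl_axis_s2,
    order_parameter_difference,
)
from .synthetic import (
    EnsembleSpec,
    add_ligand,
    build_enm_dimer,
    pairwise_forces_from_model,
    sample_ensemble,
    shortest_interprotomer_pathway,
    mark_pathway,
)

log = logging.getLogger("allodyn.pipeline")


DEMO_CONFIG = {
    "output_dir": "allodyn_demo_run",
    "seed": 7,
    "temperature_K": 300.0,
    "synthetic": {
        "n_res_per_protomer": 12,
        "contact_cutoff_nm": 1.2,
        "k_default_kJ_per_mol_nm2": 500.0,
        "sites_per_residue": 1,
        "pocket_a_resids": [1, 2, 3, 4],
        "pocket_b_resids": [1, 2, 3, 4],
        "k_ligand_kJ_per_mol_nm2": 800.0,
        "pathway": {
            "start": ["A", 5],
            "end": ["B", 5],
            "delta_k_kJ_per_mol_nm2": 2500.0,
        },
        "pathway_second": {
            "start": ["A", 9],
            "end": ["B", 9],
            "delta_k_kJ_per_mol_nm2": 2500.0,
        },
    },
    "ensemble": {
        "n_replicas": 9,
        "n_frames": 300,
        "frame_spacing_ps": 20.0,
        "sampler": "gaussian",
    },
    "analysis": {
        "cutoffs_pN": [40.0, 50.0],
        "entropy_selections": ["full"],
        "order_window_ps": 1000.0,
        "n_pca_modes": 5,
        "mindist_pair": ["A:5", "B:5"],
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; see :data:`DEMO_CONFIG` for shape."""

    output_dir: str
    seed: int
    temperature_K: float
    synthetic: dict | None = None
    states: dict | None = None  # label -> {pdb, trajectories, forces}
    ensemble: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = aio.read_yaml(path)
        cfg = cls(
            output_dir=raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            temperature_K=float(raw.get("temperature_K", 300.0)),
            synthetic=raw.get("synthetic"),
            states=raw.get("states"),
            ensemble=raw.get("ensemble", {}),
            analysis=raw.get("analysis", {}),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if (self.synthetic is None) == (self.states is None):
            raise ValueError(
                "config must declare exactly one of 'synthetic' or 'states'"
            )
        if self.states is not None:
            for label, paths in self.states.items():
                for key in ("pdb", "trajectories", "forces"):
                    entries = paths.get(key)
                    if entries is None:
                        raise ValueError(f"state {label}: missing '{key}'")
                    for p in np.atleast_1d(entries):
                        if not Path(p).exists():
                            raise ValueError(
                                f"state {label}: path does not exist: {p}"
                            )


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{v:.10g}" if isinstance(v, float) else str(v) for v in row
            ) + "\n")


def _build_synthetic_states(cfg: RunConfig) -> dict:
    s = cfg.synthetic
    apo = build_enm_dimer(
        n_res_per_protomer=int(s["n_res_per_protomer"]),
        contact_cutoff=float(s.get("contact_cutoff_nm", 1.2)),
        k_default=float(s.get("k_default_kJ_per_mol_nm2", 500.0)),
        seed=cfg.seed,
        sites_per_residue=int(s.get("sites_per_residue", 1)),
    )
    n_res = int(s["n_res_per_protomer"])

    def _endpoint(entry) -> tuple[str, int]:
        # clamp to the protomer size so one demo config scales down cleanly
        return entry[0], min(int(entry[1]), n_res)

    pw = s.get("pathway")
    if pw is not None:
        spec = shortest_interprotomer_pathway(
            apo, _endpoint(pw["start"]), _endpoint(pw["end"]),
            float(pw["delta_k_kJ_per_mol_nm2"]),
        )
        apo = mark_pathway(apo, spec)
    k_lig = float(s.get("k_ligand_kJ_per_mol_nm2", 800.0))
    pocket_a = [("A", int(r)) for r in s.get("pocket_a_resids", [1, 2, 3, 4])]
    pocket_b = [("B", int(r)) for r in s.get("pocket_b_resids", [1, 2, 3, 4])]
    # each binding event stiffens its own planted inter-protomer chain, so
    # both transitions produce a detectable force-difference network
    cap1 = add_ligand(apo.with_pathway_applied("cap1-core"), pocket_a, k_lig,
                      label="cap1")
    pw2 = s.get("pathway_second")
    cap2_core = cap1
    if pw2 is not None:
        spec2 = shortest_interprotomer_pathway(
            cap1, _endpoint(pw2["start"]), _endpoint(pw2["end"]),
            float(pw2["delta_k_kJ_per_mol_nm2"]),
        )
        cap2_core = mark_pathway(cap1, spec2).with_pathway_applied("cap2-core")
    cap2 = add_ligand(cap2_core, pocket_b, k_lig, label="cap2")
    apo.label = "apo"
    return {"apo": apo, "cap1": cap1, "cap2": cap2}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``output_dir``.

    Returns a dict of in-memory results keyed by stage.  Any stage failure
    aborts with the stage name attached.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    temperature = config.temperature_K
    an = config.analysis
    report: dict = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------ #
        stage = "generate"
        ens_cfg = config.ensemble
        spec = EnsembleSpec(
            n_replicas=int(ens_cfg.get("n_replicas", 9)),
            n_frames=int(ens_cfg.get("n_frames", 300)),
            temperature=temperature,
            sampler=ens_cfg.get("sampler", "gaussian"),
            seed=config.seed,
            frame_spacing_ps=float(ens_cfg.get("frame_spacing_ps", 20.0)),
        )
        if config.synthetic is not None:
            models = _build_synthetic_states(config)
            ensembles, forces, forces_lin = {}, {}, {}
            for label, model in models.items():
                traj = sample_ensemble(model, spec)
                ensembles[label] = traj
                forces[label] = pairwise_forces_from_model(model, traj)
                # harmonic-consistent forces for the FC entropy estimator
                forces_lin[label] = pairwise_forces_from_model(
                    model, traj, linearize=True)
                aio.write_pdb(model.topology(), model.positions,
                              str(out / f"{label}.pdb"))
                aio.write_yaml(aio.model_sidecar(model),
                               str(out / f"{label}.groundtruth.yaml"))
            report["models"] = models
        else:
            ensembles, forces = _load_states(config)
            forces_lin = forces
        report["ensembles"] = ensembles
        state_labels = list(ensembles)

        # ------------------------------------------------------------ #
        stage = "forces"
        tables = {}
        for label in state_labels:
            topo = ensembles[label].topology
            reps = [residue_pair_forces(f, topo) for f in forces[label]]
            tables[label] = average_table(reps).without_hetero(topo)
        report["tables"] = tables

        stage = "networks"
        cutoffs = [float(c) for c in an.get("cutoffs_pN", [40.0, 50.0])]
        networks = {}
        for a, b in zip(state_labels[:-1], state_labels[1:]):
            delta = force_difference(tables[a], tables[b])
            for cutoff in cutoffs:
                net = threshold_network(delta, cutoff)
                key = f"{b}-{a}@{cutoff:g}pN"
                networks[key] = net
                aio.write_network(
                    net, str(out / f"network_{b}-{a}_{cutoff:g}pN.tsv"),
                    pml_path=str(out / f"network_{b}-{a}_{cutoff:g}pN.pml"),
                    pdb_path=f"{a}.pdb",
                )
        report["networks"] = networks

        stage = "stress"
        stress, curves = {}, {}
        for label in state_labels:
            sp = punctual_stress(tables[label])
            stress[label] = sp
            _write_tsv(out / f"stress_{label}.tsv", ["residue", "stress_pN"],
                       list(zip(sp.residue_labels, map(float, sp.values))))
            topo = ensembles[label].topology
            ks, diffs = convergence_curve(tables[label], topo,
                                          seed=config.seed)
            curves[label] = (ks, diffs)
            _write_tsv(out / f"convergence_{label}.tsv",
                       ["n_replicas", "mean_protomer_stress_diff_pN"],
                       list(zip(ks.tolist(), map(float, diffs))))
        report["stress"] = stress
        report["convergence"] = curves

        # ------------------------------------------------------------ #
        stage = "entropy"
        selections = an.get("entropy_selections", ["full"])
        entropy_rows = []
        entropy_results: dict = {}
        for sel in selections:
            for label in state_labels:
                qh = quasi_harmonic_entropy(ensembles[label], sel, temperature)
                fc = force_covariance_entropy(
                    forces_lin[label], ensembles[label].topology, sel,
                    temperature,
                    reference=ensembles[label].concatenated().mean(axis=0),
                )
                entropy_results[(sel, label)] = {"QH": qh, "FC": fc}
            for a, b in zip(state_labels[:-1], state_labels[1:]):
                for est in ("QH", "FC"):
                    d = entropy_difference(
                        entropy_results[(sel, a)][est],
                        entropy_results[(sel, b)][est],
                    )
                    entropy_rows.append((f"{b}-{a}", est, sel, float(d)))
        _write_tsv(out / "entropy_differences.tsv",
                   ["transition", "estimator", "selection",
                    "minus_T_delta_S_kcal_mol"],
                   entropy_rows)
        report["entropy"] = entropy_rows

        # ------------------------------------------------------------ #
        stage = "order_parameters"
        window = float(an.get("order_window_ps", 1000.0))
        profiles = {}
        first_topo = ensembles[state_labels[0]].topology
        if first_topo.axis_pairs is None or len(first_topo.axis_pairs) == 0:
            log.info("no axis vectors on topology; skipping order parameters")
            state_labels_op = []
        else:
            state_labels_op = state_labels
        for label in state_labels_op:
            profiles[label] = methyl_axis_s2(ensembles[label], window_ps=window)
            _write_tsv(out / f"s2_axis_{label}.tsv", ["vector", "S2"],
                       list(zip(profiles[label].names,
                                map(float, profiles[label].values))))
        for a, b in zip(state_labels_op[:-1], state_labels_op[1:]):
            diff = order_parameter_difference(profiles[a], profiles[b])
            _write_tsv(out / f"s2_axis_diff_{b}-{a}.tsv",
                       ["vector", "delta_S2"],
                       list(zip(diff.names, map(float, diff.values))))
        report["order_parameters"] = profiles

        # ------------------------------------------------------------ #
        stage = "motions"
        ref_label = state_labels[-1]
        eig = pca(ensembles[ref_label], selection="mainchain",
                  n_modes=int(an.get("n_pca_modes", 5)))
        proj_rows = []
        for label in state_labels:
            p = project_ensemble(ensembles[label], eig, mode=0)
            proj_rows.extend((label, i, float(v)) for i, v in enumerate(p))
        _write_tsv(out / "projection_mode1.tsv",
                   ["state", "frame", "projection_nm"], proj_rows)
        report["pca"] = eig

        # ------------------------------------------------------------ #
        stage = "metrics"
        pair = an.get("mindist_pair")
        if pair:
            ra, rb = pair
            series = {
                label: minimal_distance(ensembles[label], ra, rb, "all")
                for label in state_labels
            }
            cls = classify_by_inflections(series[state_labels[-1]], series)
            aio.write_yaml(
                {
                    "pair": list(pair),
                    "inflection_points_A": list(cls.inflection_points),
                    "fractions": cls.fractions,
                },
                str(out / "mindist_classification.yaml"),
            )
            report["classification"] = cls

        # ------------------------------------------------------------ #
        stage = "manifest"
        cfg_dict = {
            "output_dir": config.output_dir,
            "seed": config.seed,
            "temperature_K": config.temperature_K,
            "synthetic": config.synthetic,
            "states": config.states,
            "ensemble": config.ensemble,
            "analysis": config.analysis,
        }
        blob = yaml.safe_dump(cfg_dict, sort_keys=True).encode()
        manifest = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": config.seed,
            "package": "allodyn",
            "version": _version(),
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        aio.write_yaml(manifest, str(out / "manifest.yaml"))
        report["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return report


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("allodyn")
    except Exception:
        return "unknown"


def _load_states(config: RunConfig) -> tuple[dict, dict]:
    """Load path-based states: PDB topology + text trajectories + forces."""
    ensembles, forces = {}, {}
    for label, paths in config.states.items():
        structure = aio.read_pdb(paths["pdb"])
        reps = []
        spacing = None
        for tp in np.atleast_1d(paths["trajectories"]):
            coords, times = aio.read_trajectory(str(tp))
            reps.append(coords)
            if len(times) > 1:
                spacing = float(times[1] - times[0])
        ensembles[label] = TrajectoryEnsemble(
            topology=structure.topology,
            replicas=reps,
            frame_spacing_ps=spacing or 20.0,
            label=label,
        )
        forces[label] = [
            aio.read_pairforce_file(str(fp), structure.topology)
            for fp in np.atleast_1d(paths["forces"])
        ]
    return ensembles, forces
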