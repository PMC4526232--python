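"""Readers and writers: PDB structures, plain-text trajectories, pairwise
force records, network edge lists and YAML sidecars.

Format contracts
----------------
* **PDB** — read/write through biotite; chains become protomers, HETATM
  groups become ligand pseudo-residues, insertion codes are preserved.
  Atom serials are 1-based on disk; all in-memory indices are 0-based, and
  the parser is the only place the two meet.
* **Trajectory text format** — ``natoms N`` header, then repeated blocks
  ``frame <t_ps>`` followed by N lines ``x y z`` in nm.  ``#`` starts a
  comment.
* **Pairwise-force text format** — repeated blocks ``frame <t_ps>`` followed
  by lines ``<serial_i> <serial_j> <fx> <fy> <fz>`` (1-based serials,
  kJ·mol⁻¹·nm⁻¹, whitespace-separated, ``#`` comments, serial_i < serial_j,
  frame times strictly increasing).  Forces are stored as vectors because
  residue-pair reduction sums vectors before taking the norm.
* **Network TSV** — columns ``residue_u  residue_v  deltaF_pN
  component_id`` with protomer-qualified residue labels; the cutoff is
  recorded in a ``#`` header.  A PyMOL script drawing the edges on a
  structure can be written alongside.

All writers round-trip losslessly with their readers (floats are written
with 17 significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .core import PairForceSeries, Topology
from .fda import ForceNetwork

_F = "%.17g"  # lossless float formatting for round-trips


# ---------------------------------------------------------------------- #
# PDB

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
}


@dataclass
class PDBStructure:
    """A parsed structure: topology, coordinates (nm) and B-factors (Ų)."""

    topology: Topology
    coords_nm: np.ndarray
    b_factors: np.ndarray


def _element_mass(element: str, name: str) -> float:
    el = element.strip().upper()
    if not el:
        el = name.strip()[:1].upper()
    return _ELEMENT_MASSES.get(el, 12.011)


def read_pdb(path: str) -> PDBStructure:
    """Parse ATOM/HETATM records into a topology and coordinates.

    Chains become protomers; 1-based serials are retained on the topology.
    Duplicate serials or blank chain identifiers raise with the offending
    line numbers; a file with only HETATM records raises ``no polymer
    atoms``.
    """
    import biotite.structure.io.pdb as pdb

    with open(path) as fh:
        lines = fh.readlines()
    seen: dict[int, int] = {}
    has_polymer = False
    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if rec == "ATOM":
            has_polymer = True
        serial = int(line[6:11])
        if serial in seen:
            raise ValueError(
                f"{path}: duplicate atom serial {serial} "
                f"(lines {seen[serial]} and {ln})"
            )
        seen[serial] = ln
        if not line[21].strip():
            raise ValueError(f"{path}: missing chain id at line {ln}")
    if not has_polymer:
        raise ValueError(f"{path}: no polymer atoms (only HETATM records)")
    pf = pdb.PDBFile.read(path)
    arr = pf.get_structure(model=1, extra_fields=["atom_id", "b_factor"])
    icodes = [str(c) for c in arr.ins_code]
    topo = Topology(
        serials=np.asarray(arr.atom_id, dtype=int),
        names=[str(n) for n in arr.atom_name],
        resids=np.asarray(arr.res_id, dtype=int),
        resnames=[str(n) for n in arr.res_name],
        chains=[str(c) for c in arr.chain_id],
        masses=np.array(
            [_element_mass(e, n) for e, n in zip(arr.element, arr.atom_name)]
        ),
        hetero=np.asarray(arr.hetero, dtype=bool),
    )
    topo.icodes = icodes  # preserved verbatim
    return PDBStructure(
        topology=topo,
        coords_nm=np.asarray(arr.coord, dtype=float) / 10.0,
        b_factors=np.asarray(arr.b_factor, dtype=float),
    )


def write_pdb(
    topology: Topology,
    coords_nm: np.ndarray,
    path: str,
    b_factors: np.ndarray | None = None,
) -> None:
    """Write one model; pseudo-atoms go out as CA records, ligands as HETATM."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=float) * 10.0
    arr.chain_id = np.array(topology.chains)
    arr.res_id = topology.resids
    arr.res_name = np.array(topology.resnames)
    arr.atom_name = np.array(topology.names)
    arr.hetero = topology.hetero
    arr.element = np.array(
        [n.strip()[:1].upper() if n.strip() else "C" for n in topology.names]
    )
    arr.set_annotation("atom_id", topology.serials)
    arr.set_annotation(
        "b_factor",
        np.zeros(n) if b_factors is None else np.asarray(b_factors, float),
    )
    pf = pdb.PDBFile()
    pf.set_structure(arr)
    pf.write(path)


# ---------------------------------------------------------------------- #
# trajectory text format


def write_trajectory(path: str, coords: np.ndarray, times_ps: np.ndarray,
                     comment: str | None = None) -> None:
    """Write one replica's (n_frames, n_atoms, 3) coordinates in nm."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"natoms {coords.shape[1]}\n")
        for t, frame in zip(times_ps, coords):
            fh.write(f"frame {_F % t}\n")
            for x, y, z in frame:
                fh.write(f"{_F % x} {_F % y} {_F % z}\n")


def read_trajectory(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a trajectory text file; returns ``(coords, times_ps)``."""
    natoms = None
    frames: list[list[list[float]]] = []
    times: list[float] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "natoms":
                natoms = int(parts[1])
            elif parts[0] == "frame":
                times.append(float(parts[1]))
                frames.append([])
            else:
                if not frames:
                    raise ValueError(f"{path}:{ln}: coordinates before any frame")
                frames[-1].append([float(v) for v in parts[:3]])
    if natoms is None:
        raise ValueError(f"{path}: missing natoms header")
    for i, f in enumerate(frames):
        if len(f) != natoms:
            raise ValueError(
                f"{path}: frame {i} has {len(f)} atoms, expected {natoms}"
            )
    return np.array(frames, dtype=float), np.array(times, dtype=float)


# ---------------------------------------------------------------------- #
# pairwise-force text format


def write_pairforce_file(
    path: str, series: PairForceSeries, topology: Topology,
    comment: str | None = None,
) -> None:
    """Write per-frame pair force vectors with 1-based atom serials."""
    serials = topology.serials
    si = serials[series.pairs[:, 0]]
    sj = serials[series.pairs[:, 1]]
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for t, frame in zip(series.times_ps, series.forces):
            fh.write(f"frame {_F % t}\n")
            for a, b, (fx, fy, fz) in zip(si, sj, frame):
                fh.write(f"{a} {b} {_F % fx} {_F % fy} {_F % fz}\n")


def read_pairforce_file(path: str, topology: Topology) -> PairForceSeries:
    """Read a pairwise-force file, validating serials against the topology.

    Frames may list different pair subsets; absent pairs are zero-filled so
    the in-memory series is rectangular.
    """
    s2i = topology.serial_to_index()
    times: list[float] = []
    frames: list[dict[tuple[int, int], tuple[float, float, float]]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "frame":
                t = float(parts[1])
                if times and t <= times[-1]:
                    raise ValueError(
                        f"{path}:{ln}: non-monotone frame time {t}"
                    )
                times.append(t)
                frames.append({})
                continue
            if not frames:
                raise ValueError(f"{path}:{ln}: record before any frame header")
            si, sj = int(parts[0]), int(parts[1])
            if sj <= si:
                raise ValueError(
                    f"{path}:{ln}: require serial_i < serial_j, got {si} {sj}"
                )
            for s in (si, sj):
                if s not in s2i:
                    raise ValueError(f"{path}:{ln}: unknown atom serial {s}")
            frames[-1][(s2i[si], s2i[sj])] = (
                float(parts[2]), float(parts[3]), float(parts[4])
            )
    if not frames:
        raise ValueError(f"{path}: no frames")
    pairs = sorted(set().union(*frames))
    index = {p: i for i, p in enumerate(pairs)}
    forces = np.zeros((len(frames), len(pairs), 3))
    for t, rec in enumerate(frames):
        for p, vec in rec.items():
            forces[t, index[p]] = vec
    return PairForceSeries(
        pairs=np.array(pairs, dtype=int),
        forces=forces,
        times_ps=np.array(times),
        provenance={"source": path},
    )


# ---------------------------------------------------------------------- #
# network edge lists


def write_network(network: ForceNetwork, path: str,
                  pml_path: str | None = None,
                  pdb_path: str | None = None) -> None:
    """Write a force network as TSV (plus an optional PyMOL edge script).

    The TSV has one row per edge: protomer-qualified residue labels, the
    signed ΔF in pN, and the id of the connected component the edge belongs
    to.  An empty network yields a header-only file.
    """
    with open(path, "w") as fh:
        fh.write(f"# force difference network, cutoff_pN\t{_F % network.cutoff}\n")
        fh.write("residue_u\tresidue_v\tdeltaF_pN\tcomponent_id\n")
        for u, v, d in network.edges:
            fh.write(f"{u}\t{v}\t{_F % d}\t{network.component_of[u]}\n")
    if pml_path is not None:
        with open(pml_path, "w") as fh:
            if pdb_path:
                fh.write(f"load {pdb_path}, mol\n")
            fh.write("set dash_radius, 0.12\nset dash_gap, 0\n")
            for k, (u, v, _) in enumerate(network.edges):
                cu, ru = u.split(":")
                cv, rv = v.split(":")
                fh.write(
                    f"distance edge{k}, mol and chain {cu} and resi {ru} and "
                    f"name CA, mol and chain {cv} and resi {rv} and name CA\n"
                )
            fh.write("hide labels\ncolor marine, edge*\n")


def read_network(path: str) -> ForceNetwork:
    """Read a network TSV back; inverse of :func:`write_network`."""
    cutoff = 0.0
    edges: list[tuple[str, str, float]] = []
    component_of: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#"):
                if "cutoff_pN" in raw:
                    cutoff = float(raw.rsplit("\t", 1)[1])
                continue
            parts = raw.rstrip("\n").split("\t")
            if parts[0] == "residue_u":
                continue
            u, v, d, cid = parts
            edges.append((u, v, float(d)))
            component_of[u] = int(cid)
            component_of[v] = int(cid)
    n_comp = max(component_of.values()) + 1 if component_of else 0
    comps: list[list[str]] = [[] for _ in range(n_comp)]
    for node, cid in sorted(component_of.items()):
        comps[cid].append(node)
    return ForceNetwork(
        edges=edges, cutoff=cutoff, components=comps, component_of=component_of
    )


# ---------------------------------------------------------------------- #
# YAML sidecars


def write_yaml(data: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def model_sidecar(model) -> dict:
    """Ground-truth key-value record for a synthetic model (YAML-ready)."""
    return {
        "synthetic": True,
        "label": model.label,
        "n_atoms": int(model.n_atoms),
        "n_springs": int(len(model.springs)),
        "pathway_delta_k": float(model.pathway_delta_k),
        "pathway_residue_pairs": sorted(
            ["-".join(p) for p in model.pathway_residue_pairs()]
        ),
        "ligand_nodes": [int(i) for i in np.flatnonzero(model.hetero)],
    }
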