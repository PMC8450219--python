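"""File formats: network JSON, target CSVs, VTK polylines, YAML config.

The network container is versioned JSON — diff-able, round-trip
lossless, and trivially parsed by other tools.  Deformed meshes export
as legacy-ASCII VTK polydata (one polyline per fiber) with displacement
magnitude as point data and axial force as cell data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanics import BeamMesh, MechanicalState, element_axial_force
from .network import NetworkGraph, TargetDistributions

NETWORK_FORMAT_VERSION = 1


class NetworkFormatError(ValueError):
    """Raised on malformed or unsupported network files."""


def write_network(net: NetworkGraph, path) -> None:
    """Write a network to versioned JSON (lossless round trip)."""
    doc = {
        "format": "fibernet-network",
        "version": NETWORK_FORMAT_VERSION,
        "box_lengths": net.box_lengths.tolist(),
        "fiber_diameter": net.fiber_diameter,
        "nodes": net.nodes.tolist(),
        "segments": [
            {"nodes": [int(a), int(b)], "shift": [int(s) for s in sh]}
            for (a, b), sh in zip(net.segments, net.shifts)
        ],
        "metadata": _jsonable(net.provenance),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_network(path) -> NetworkGraph:
    """Read a network JSON file, validating schema and invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise NetworkFormatError(f"not valid JSON: {e}") from e
    if not isinstance(doc, dict) or doc.get("format") != "fibernet-network":
        raise NetworkFormatError("missing or wrong 'format' field")
    if "version" not in doc:
        raise NetworkFormatError("missing mandatory 'version' field")
    if doc["version"] != NETWORK_FORMAT_VERSION:
        raise NetworkFormatError(f"unsupported network format version {doc['version']}")
    for key in ("box_lengths", "nodes", "segments", "fiber_diameter"):
        if key not in doc:
            raise NetworkFormatError(f"missing field '{key}'")
    segs, shifts = [], []
    for i, seg in enumerate(doc["segments"]):
        try:
            a, b = seg["nodes"]
            sh = seg["shift"]
            if len(sh) != 3:
                raise ValueError
            segs.append((int(a), int(b)))
            shifts.append([int(s) for s in sh])
        except (KeyError, TypeError, ValueError) as e:
            raise NetworkFormatError(f"segment {i}: malformed nodes/shift") from e
    net = NetworkGraph(
        np.asarray(doc["box_lengths"], float),
        np.asarray(doc["nodes"], float),
        np.asarray(segs, int).reshape(-1, 2),
        np.asarray(shifts, int).reshape(-1, 3),
        float(doc["fiber_diameter"]),
        provenance=doc.get("metadata", {}),
    )
    try:
        net.validate()
    except ValueError as e:
        raise NetworkFormatError(str(e)) from e
    return net


# ---------------------------------------------------------------------------
# target distributions as CSV
# ---------------------------------------------------------------------------


def write_targets(targets: TargetDistributions, directory) -> None:
    """Write the three target distributions as CSV (bin_left, bin_right, density)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, edges, hist in (
        ("valency", targets.valency_edges, targets.valency_pmf),
        ("length", targets.length_edges, targets.length_hist),
        ("cosine", targets.cosine_edges, targets.cosine_hist),
    ):
        widths = np.diff(edges)
        pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "density": hist / widths}
        ).to_csv(directory / f"{name}.csv", index=False)


def read_targets(directory, weights=(1.0, 1.0, 1.0)) -> TargetDistributions:
    """Read target distribution CSVs written by :func:`write_targets`."""
    directory = Path(directory)
    data = {}
    for name in ("valency", "length", "cosine"):
        f = directory / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing target file {f}")
        df = pd.read_csv(f)
        for col in ("bin_left", "bin_right", "density"):
            if col not in df.columns:
                raise NetworkFormatError(f"{f}: missing column '{col}'")
        edges = np.append(df["bin_left"].to_numpy(), df["bin_right"].to_numpy()[-1])
        mass = df["density"].to_numpy() * np.diff(edges)
        mass = mass / mass.sum()
        data[name] = (edges, mass)
    return TargetDistributions(
        data["valency"][0], data["valency"][1],
        data["length"][0], data["length"][1],
        data["cosine"][0], data["cosine"][1],
        np.asarray(weights, float),
    )


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------


def export_vtk(mesh: BeamMesh, state: MechanicalState, path) -> None:
    """Legacy-ASCII VTK polydata export of the deformed fiber network.

    One polyline per network fiber (cross-link elements excluded);
    point data = displacement magnitude (μm), cell data = mean axial
    force of the fiber's elements (pN).  Node positions are the deformed
    unwrapped chains, so fibers render as connected curves.
    """
    if state.u.shape[0] != mesh.n_nodes:
        raise ValueError("state does not match mesh")
    lines = []
    points = []
    disp = []
    forces = []
    Lcur = mesh.box_lengths * state.stretch
    fiber_elements: dict[int, list[int]] = {}
    for e in range(mesh.n_elements):
        s = mesh.element_segment[e]
        if s >= 0 and mesh.alive[e]:
            fiber_elements.setdefault(int(s), []).append(e)

    for s, chain in enumerate(mesh.segment_chains):
        start = len(points)
        # unwrap the chain: walk elements, adding shift translations
        x = mesh.X[chain[0]] + state.u[chain[0]]
        points.append(x)
        disp.append(np.linalg.norm(state.u[chain[0]]))
        eids = fiber_elements.get(s, [])
        for k, e in enumerate(eids):
            j = mesh.conn[e, 1]
            x = mesh.X[j] + state.u[j] + mesh.shift[e] * Lcur + (points[start + k] - (mesh.X[mesh.conn[e, 0]] + state.u[mesh.conn[e, 0]]))
            points.append(x)
            disp.append(np.linalg.norm(state.u[j]))
        lines.append(list(range(start, len(points))))
        if eids:
            forces.append(float(np.mean(element_axial_force(mesh, state, np.array(eids)))))
        else:
            forces.append(0.0)

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("fibernet deformed fiber network\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(points)} float\n")
        for p in points:
            f.write("%.6f %.6f %.6f\n" % tuple(p))
        size = sum(len(l) + 1 for l in lines)
        f.write(f"LINES {len(lines)} {size}\n")
        for l in lines:
            f.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        f.write(f"POINT_DATA {len(points)}\n")
        f.write("SCALARS displacement float 1\nLOOKUP_TABLE default\n")
        for d in disp:
            f.write("%.6f\n" % d)
        f.write(f"CELL_DATA {len(lines)}\n")
        f.write("SCALARS axial_force float 1\nLOOKUP_TABLE default\n")
        for q in forces:
            f.write("%.6f\n" % q)


def read_vtk_polylines(path):
    """Minimal independent parser for the legacy VTK polyline files.

    Returns ``(points, lines, point_data, cell_data)``; used to verify
    that exported files are structurally sound.
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)
    header = [next(it), next(it), next(it), next(it)]
    if "vtk" not in header[0] or header[2].strip() != "ASCII":
        raise ValueError("not an ASCII legacy VTK file")
    if header[3].strip() != "DATASET POLYDATA":
        raise ValueError("not a POLYDATA dataset")
    tok = next(it).split()
    assert tok[0] == "POINTS"
    n_pts = int(tok[1])
    points = np.array([[float(x) for x in next(it).split()] for _ in range(n_pts)])
    tok = next(it).split()
    assert tok[0] == "LINES"
    n_lines = int(tok[1])
    lines = []
    for _ in range(n_lines):
        vals = [int(x) for x in next(it).split()]
        if vals[0] != len(vals) - 1:
            raise ValueError("inconsistent polyline length")
        lines.append(vals[1:])
    tok = next(it).split()
    assert tok[0] == "POINT_DATA" and int(tok[1]) == n_pts
    next(it), next(it)
    point_data = np.array([float(next(it)) for _ in range(n_pts)])
    tok = next(it).split()
    assert tok[0] == "CELL_DATA" and int(tok[1]) == n_lines
    next(it), next(it)
    cell_data = np.array([float(next(it)) for _ in range(n_lines)])
    return points, lines, point_data, cell_data
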