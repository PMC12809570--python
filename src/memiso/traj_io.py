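"""Structure/trajectory input and tabular metric output.

Structures (PDB, GRO) and trajectories (DCD, XTC) are parsed with
MDAnalysis and converted into the package's annotated :class:`Trajectory`
container; metric tables are written as CSV (one row per record, units in
the header) or schema-versioned JSON.  Coordinates are never unwrapped at
read time - unwrapping is an explicit geometry operation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import LipidSpec, Trajectory, annotate_topology

__all__ = [
    "MetricSeries",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_metrics",
    "read_metrics",
]

METRICS_JSON_SCHEMA = "memiso.metrics/1"

#: default sampling interval when the trajectory format stores no usable
#: time information (ns); matches a 10 ps coordinate-write interval
DEFAULT_DT_NS = 0.010


@dataclass
class MetricSeries:
    """A per-frame scalar metric time series for one replicate."""

    name: str
    unit: str
    times: np.ndarray
    values: np.ndarray
    replicate_id: str = "rep0"
    condition: str = "other"  # cis | trans | other

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite metric values")

    def mean(self) -> float:
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                f"{self.name} ({self.unit})": self.values,
                "replicate_id": self.replicate_id,
                "condition": self.condition,
            }
        )


def _universe(*paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*[str(p) for p in paths])


def _check_box(dim, path) -> np.ndarray:
    if dim is None:
        raise ValueError(f"{path}: no box record in file")
    box = np.asarray(dim[:3], dtype=float)
    if np.any(box <= 0) or not np.all(np.isfinite(box)):
        raise ValueError(f"{path}: degenerate box {box.tolist()}")
    return box


def read_structure(path, specs: Mapping[str, LipidSpec], **annotate_kwargs) -> Trajectory:
    """Read a PDB/GRO structure into a single-frame annotated Trajectory.
    Atom order is preserved; the file must carry a valid box record."""
    u = _universe(path)
    box = _check_box(u.dimensions, path)
    topo = annotate_topology(
        [a.name for a in u.atoms],
        [a.resid for a in u.atoms],
        [a.resname for a in u.atoms],
        specs,
        **annotate_kwargs,
    )
    coords = np.asarray(u.atoms.positions, dtype=float)[None, :, :]
    return Trajectory(topo, coords, box[None, :], np.array([0.0]))


def read_trajectory(
    structure_path,
    traj_path,
    specs: Mapping[str, LipidSpec],
    stride: int = 1,
    dt_ns: float | None = None,
    replicate_id: str = "rep0",
    condition: str = "other",
    **annotate_kwargs,
) -> Trajectory:
    """Read a trajectory (DCD/XTC) against its structure file.

    ``dt_ns`` sets the frame interval of the *stored* trajectory; frame
    times are synthesized as ``frame_index * dt_ns`` because DCD time
    handling is dialect-dependent.  Pass ``dt_ns=None`` to use the reader's
    own time stamps (ps, converted to ns) when the format provides them.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    base = _universe(structure_path)
    u = _universe(structure_path, traj_path)
    if len(u.atoms) != len(base.atoms):
        raise ValueError(
            f"atom-count mismatch: structure has {len(base.atoms)} atoms, "
            f"trajectory has {len(u.atoms)}"
        )
    topo = annotate_topology(
        [a.name for a in u.atoms],
        [a.resid for a in u.atoms],
        [a.resname for a in u.atoms],
        specs,
        **annotate_kwargs,
    )
    coords, boxes, times = [], [], []
    for i, ts in enumerate(u.trajectory):
        if i % stride:
            continue
        coords.append(np.asarray(ts.positions, dtype=np.float32).copy())
        boxes.append(_check_box(ts.dimensions, traj_path))
        times.append(ts.time / 1000.0 if dt_ns is None else i * dt_ns)
    return Trajectory(
        topo,
        np.asarray(coords),
        np.asarray(boxes),
        np.asarray(times, dtype=float),
        replicate_id=replicate_id,
        condition=condition,
    )


def _as_mda_universe(trajectory: Trajectory):
    import MDAnalysis as mda

    topo = trajectory.topology
    u = mda.Universe.empty(
        topo.n_atoms,
        n_residues=topo.n_residues,
        atom_resindex=topo.residue_index,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(topo.names))
    u.add_TopologyAttr("resnames", list(topo.residue_names))
    u.add_TopologyAttr("resids", [int(topo.resids[topo.residue_atoms(r)[0]]) for r in range(topo.n_residues)])
    u.atoms.positions = np.asarray(trajectory.coords[0], dtype=np.float32)
    u.dimensions = [*trajectory.boxes[0], 90.0, 90.0, 90.0]
    return u


def write_structure(trajectory: Trajectory, path, frame: int = 0) -> None:
    """Write one frame as PDB or GRO (format from the file extension)."""
    import MDAnalysis as mda

    u = _as_mda_universe(trajectory)
    u.atoms.positions = np.asarray(trajectory.coords[frame], dtype=np.float32)
    u.dimensions = [*trajectory.boxes[frame], 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), trajectory.n_atoms) as w:
            w.write(u.atoms)


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write all frames as DCD or XTC (format from the file extension)."""
    import MDAnalysis as mda

    u = _as_mda_universe(trajectory)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), trajectory.n_atoms) as w:
            for f in range(trajectory.n_frames):
                u.atoms.positions = np.asarray(trajectory.coords[f], dtype=np.float32)
                u.dimensions = [*trajectory.boxes[f], 90.0, 90.0, 90.0]
                w.write(u.atoms)


# -- metric tables ---------------------------------------------------------

def _series_frame(series: Sequence[MetricSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        rows.append(
            pd.DataFrame(
                {
                    "metric": s.name,
                    "unit": s.unit,
                    "time_ns": s.times,
                    "value": s.values,
                    "replicate_id": s.replicate_id,
                    "condition": s.condition,
                }
            )
        )
    cols = ["metric", "unit", "time_ns", "value", "replicate_id", "condition"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)[cols]


def write_metrics(data, path, fmt: str | None = None) -> Path:
    """Write metric data deterministically.

    ``data`` may be a MetricSeries, a sequence of them, a DataFrame, or (for
    JSON) any JSON-serializable mapping.  CSV output carries name and unit
    columns; JSON output is schema-versioned and key-sorted so two writes of
    the same data are byte-identical.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if isinstance(data, MetricSeries):
        data = [data]
    if fmt == "csv":
        if isinstance(data, pd.DataFrame):
            df = data
        else:
            df = _series_frame(list(data))
        df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
    elif fmt == "json":
        if isinstance(data, pd.DataFrame):
            payload = data.to_dict(orient="list")
        elif isinstance(data, list) and all(isinstance(s, MetricSeries) for s in data):
            payload = {
                s.name: {
                    "unit": s.unit,
                    "times_ns": s.times.tolist(),
                    "values": s.values.tolist(),
                    "replicate_id": s.replicate_id,
                    "condition": s.condition,
                }
                for s in data
            }
        else:
            payload = data
        doc = {"schema": METRICS_JSON_SCHEMA, "data": payload}
        path.write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")
    else:
        raise ValueError(f"unsupported metrics format: {fmt!r}")
    return path


def read_metrics(path, fmt: str | None = None):
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        doc = json.loads(path.read_text())
        if doc.get("schema") != METRICS_JSON_SCHEMA:
            raise ValueError(f"{path}: unknown metrics schema {doc.get('schema')!r}")
        return doc["data"]
    raise ValueError(f"unsupported metrics format: {fmt!r}")
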