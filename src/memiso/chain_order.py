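"""Acyl-chain order parameter S_CH.

S_CH = <(3 cos^2 theta - 1) / 2> with theta the angle between a C-H bond
vector and the bilayer normal (fixed to +z).  S_CH is 1 for bonds along the
normal, -0.5 for bonds in the membrane plane and 0 for isotropic
orientations; deuterium NMR conventionally reports |S_CD| of the same
quantity.  The average runs over the hydrogens of each carbon, all residues
of the selected lipid type and all frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Trajectory
from .traj_io import MetricSeries

__all__ = ["OrderProfile", "sch", "sch_samples", "order_timeseries", "p2"]


def p2(cos_theta) -> np.ndarray:
    """Second Legendre polynomial (3 x^2 - 1)/2."""
    c = np.asarray(cos_theta, dtype=float)
    return 0.5 * (3.0 * c * c - 1.0)


@dataclass
class OrderProfile:
    """Per-carbon order parameter profile for one lipid type / tail."""

    residue_name: str
    tail_index: int
    carbons: np.ndarray  # chain-local carbon positions
    s_ch: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        bad = (self.s_ch < -0.5 - 1e-9) | (self.s_ch > 1.0 + 1e-9)
        if np.any(bad):
            raise ValueError("S_CH outside [-0.5, 1]")

    def tail_mean(self) -> float:
        return float(np.average(self.s_ch, weights=self.n_samples))


def _pair_selection(topo, residue_name, tail_index):
    mask = np.ones(len(topo.ch_carbon), dtype=bool)
    if residue_name is not None:
        mask &= topo.ch_resname == residue_name
    if tail_index is not None:
        mask &= topo.ch_tail == tail_index
    return np.nonzero(mask)[0]


def sch_samples(trajectory: Trajectory, pair_indices: np.ndarray, frames=slice(None)) -> np.ndarray:
    """P2(cos theta) per (frame, selected C-H pair), shape (F, P)."""
    topo = trajectory.topology
    ci = topo.ch_carbon[pair_indices]
    hi = topo.ch_hydrogen[pair_indices]
    v = np.asarray(trajectory.coords[frames][:, hi, :], dtype=float) - np.asarray(
        trajectory.coords[frames][:, ci, :], dtype=float
    )
    norm = np.linalg.norm(v, axis=2)
    if np.any(norm < 1e-10):
        raise ValueError("degenerate C-H vector")
    return p2(v[:, :, 2] / norm)


def sch(
    trajectory: Trajectory,
    residue_name: str | None = None,
    tail_index: int | None = None,
) -> OrderProfile:
    """Per-carbon S_CH profile for one lipid type (and optionally one tail),
    averaged over hydrogens, residues and frames."""
    topo = trajectory.topology
    pairs = _pair_selection(topo, residue_name, tail_index)
    if len(pairs) == 0:
        raise ValueError(
            f"no C-H pairs for residue {residue_name!r} tail {tail_index!r} "
            "(hydrogens missing from the lipid definition?)"
        )
    vals = sch_samples(trajectory, pairs)  # (F, P)
    positions = topo.ch_position[pairs]
    carbons = np.unique(positions)
    s = np.empty(len(carbons))
    n = np.empty(len(carbons), dtype=int)
    for k, pos in enumerate(carbons):
        col = positions == pos
        s[k] = vals[:, col].mean()
        n[k] = vals[:, col].size
    return OrderProfile(
        residue_name=residue_name if residue_name is not None else "all",
        tail_index=tail_index if tail_index is not None else -1,
        carbons=carbons,
        s_ch=s,
        n_samples=n,
    )


def order_timeseries(
    trajectory: Trajectory,
    window: int,
    residue_name: str | None = None,
    tail_index: int | None = None,
) -> MetricSeries:
    """Windowed tail-mean S_CH versus time (window in frames), exposing
    order drift such as a phase change."""
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    if window > trajectory.n_frames:
        raise ValueError(
            f"window ({window} frames) longer than trajectory ({trajectory.n_frames})"
        )
    pairs = _pair_selection(trajectory.topology, residue_name, tail_index)
    if len(pairs) == 0:
        raise ValueError("no C-H pairs selected")
    vals = sch_samples(trajectory, pairs).mean(axis=1)  # per-frame tail mean
    n_win = trajectory.n_frames // window
    times = np.empty(n_win)
    means = np.empty(n_win)
    for w in range(n_win):
        sl = slice(w * window, (w + 1) * window)
        times[w] = trajectory.times[sl].mean()
        means[w] = vals[sl].mean()
    return MetricSeries(
        name="tail_mean_S_CH",
        unit="dimensionless",
        times=times,
        values=means,
        replicate_id=trajectory.replicate_id,
        condition=trajectory.condition,
    )
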