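"""Lateral diffusion from mean squared displacement.

Lipid motion is measured in the membrane plane only (n = 2 degrees of
freedom): MSD(t) = <|r_xy(t) - r_xy(0)|^2> over residue heavy-atom
centroids, and D = MSD(T) / (2 n T) with T the analysis-window duration
(the literal endpoint estimator; a least-squares fit through the origin is
offered as an alternative mode).  Trajectories are divided into
non-overlapping chunks, each restarting its reference position, and the
standard error of D combines the spread over chunk x replicate samples.

Unit conversion: 1 A^2/ns = 1e-7 cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Trajectory
from .geometry import residue_centroids, unwrap_xy

__all__ = [
    "A2_PER_NS_TO_CM2_PER_S",
    "MsdCurve",
    "DiffusionEstimate",
    "centroid_tracks",
    "drift_correct",
    "chunk_tracks",
    "msd",
    "msd_curves",
    "diffusion_coefficient",
]

A2_PER_NS_TO_CM2_PER_S = 1e-7


@dataclass
class MsdCurve:
    """MSD versus lag time for one lipid type in one chunk."""

    lag_ns: np.ndarray
    msd: np.ndarray  # A^2
    residue_name: str = "all"
    chunk_id: int = 0
    replicate_id: str = "rep0"
    n_residues: int = 0

    def __post_init__(self) -> None:
        self.lag_ns = np.asarray(self.lag_ns, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.msd.shape != self.lag_ns.shape:
            raise ValueError("lag/msd length mismatch")
        if abs(self.msd[0]) > 1e-9:
            raise ValueError("MSD at zero lag must be 0")
        if np.any(self.msd < -1e-9):
            raise ValueError("negative MSD")

    @property
    def duration_ns(self) -> float:
        return float(self.lag_ns[-1])


@dataclass
class DiffusionEstimate:
    residue_name: str
    d_a2_per_ns: float
    d_cm2_per_s: float
    standard_error_a2_per_ns: float
    n_samples: int
    per_sample_d: np.ndarray

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one chunk sample")

    @property
    def standard_error_cm2_per_s(self) -> float:
        return self.standard_error_a2_per_ns * A2_PER_NS_TO_CM2_PER_S


def centroid_tracks(trajectory: Trajectory, unwrap: bool = True) -> np.ndarray:
    """Unwrapped xy centroid tracks of lipid residues, shape (F, R, 2)
    (NaN columns for non-lipid residues)."""
    tracks = residue_centroids(trajectory)
    if unwrap and trajectory.n_frames > 1:
        lipid = trajectory.topology.residue_is_lipid
        tracks[:, lipid, :] = unwrap_xy(tracks[:, lipid, :], trajectory.boxes)
    return tracks


def drift_correct(tracks: np.ndarray, leaflets: np.ndarray) -> np.ndarray:
    """Remove per-leaflet collective drift: subtract each frame's centroid
    of lipid centroids, leaflet by leaflet."""
    out = np.array(tracks, dtype=float, copy=True)
    for leaf in ("upper", "lower"):
        cols = np.nonzero(leaflets == leaf)[0]
        if len(cols) == 0:
            continue
        mean = np.nanmean(out[:, cols, :], axis=1, keepdims=True)
        out[:, cols, :] -= mean
    return out


def chunk_tracks(tracks: np.ndarray, times: np.ndarray, chunk_ns: float):
    """Split tracks into non-overlapping windows of ``chunk_ns``; each chunk
    restarts its own reference position.  Yields (chunk_id, track_slice,
    time_slice); a trailing remainder shorter than chunk_ns is dropped."""
    if chunk_ns <= 0:
        raise ValueError("chunk duration must be positive")
    t0 = times[0]
    total = times[-1] - t0
    n_chunks = max(int(np.floor(total / chunk_ns + 1e-9)), 0)
    if n_chunks == 0:
        raise ValueError(f"trajectory ({total:.3g} ns) shorter than one chunk ({chunk_ns} ns)")
    for c in range(n_chunks):
        lo = t0 + c * chunk_ns
        hi = lo + chunk_ns
        sel = np.nonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))[0]
        if len(sel) >= 2:
            yield c, tracks[sel], times[sel]


def msd(tracks: np.ndarray, times: np.ndarray, multi_origin: bool = False) -> np.ndarray:
    """MSD(t) of xy tracks (F, R, 2) relative to the first frame, averaged
    over residues.  ``multi_origin=True`` additionally averages over all
    time origins at each lag (lower variance; not the default, which is the
    literal single-origin definition)."""
    tracks = np.asarray(tracks, dtype=float)
    if tracks.ndim != 3 or tracks.shape[0] < 2:
        raise ValueError("need (F>=2, R, 2) tracks")
    if not multi_origin:
        disp = tracks - tracks[:1]
        return np.nanmean(np.sum(disp * disp, axis=2), axis=1)
    F = tracks.shape[0]
    out = np.zeros(F)
    for lag in range(1, F):
        d = tracks[lag:] - tracks[:-lag]
        out[lag] = np.nanmean(np.sum(d * d, axis=2))
    return out


def msd_curves(
    trajectory: Trajectory,
    residue_name: str | None = None,
    chunk_ns: float = 200.0,
    drift_correction: bool = True,
    multi_origin: bool = False,
    tracks: np.ndarray | None = None,
) -> list[MsdCurve]:
    """Per-chunk MSD curves for one lipid type (or all lipids pooled).

    ``tracks`` may carry precomputed (and already drift-corrected, if
    requested) unwrapped centroid tracks to avoid recomputation when
    several lipid types are analysed from the same trajectory.
    """
    topo = trajectory.topology
    from .geometry import assign_leaflets

    if not np.any(topo.leaflets != ""):
        assign_leaflets(trajectory.frame(0), topo)
    if tracks is None:
        tracks = centroid_tracks(trajectory)
        if drift_correction:
            tracks = drift_correct(tracks, topo.leaflets)
    if residue_name is None:
        cols = topo.lipid_residue_indices()
        label = "all"
    else:
        cols = np.nonzero(topo.residue_is_lipid & (topo.residue_names == residue_name))[0]
        label = residue_name
    if len(cols) == 0:
        raise ValueError(f"no lipid residues of type {residue_name!r}")
    curves = []
    for cid, tr, tt in chunk_tracks(tracks[:, cols, :], trajectory.times, chunk_ns):
        curves.append(
            MsdCurve(
                lag_ns=tt - tt[0],
                msd=msd(tr, tt, multi_origin=multi_origin),
                residue_name=label,
                chunk_id=cid,
                replicate_id=trajectory.replicate_id,
                n_residues=len(cols),
            )
        )
    return curves


def _d_endpoint(curve: MsdCurve, n_dims: int) -> float:
    T = curve.duration_ns
    if T <= 0:
        raise ValueError("zero chunk duration")
    return float(curve.msd[-1] / (2.0 * n_dims * T))


def _d_fit(curve: MsdCurve, n_dims: int) -> float:
    # least squares through the origin: slope = sum(t*msd)/sum(t^2)
    t = curve.lag_ns
    denom = float(np.dot(t, t))
    if denom <= 0:
        raise ValueError("zero chunk duration")
    slope = float(np.dot(t, curve.msd) / denom)
    return slope / (2.0 * n_dims)


def diffusion_coefficient(
    curves: list[MsdCurve], n_dims: int = 2, mode: str = "endpoint"
) -> DiffusionEstimate:
    """Diffusion coefficient from chunked MSD curves.

    Each chunk contributes one sample D_c (endpoint estimator
    MSD(T)/(2 n T) by default, or a least-squares-through-origin fit);
    the estimate is the unweighted mean over chunk x replicate samples and
    the standard error is sd / sqrt(n_samples).
    """
    if not curves:
        raise ValueError("no MSD curves")
    est = {"endpoint": _d_endpoint, "fit": _d_fit}[mode]
    ds = np.array([est(c, n_dims) for c in curves])
    d_mean = float(ds.mean())
    se = float(ds.std(ddof=1) / np.sqrt(len(ds))) if len(ds) > 1 else 0.0
    names = {c.residue_name for c in curves}
    return DiffusionEstimate(
        residue_name=names.pop() if len(names) == 1 else "mixed",
        d_a2_per_ns=d_mean,
        d_cm2_per_s=d_mean * A2_PER_NS_TO_CM2_PER_S,
        standard_error_a2_per_ns=se,
        n_samples=len(ds),
        per_sample_d=ds,
    )
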