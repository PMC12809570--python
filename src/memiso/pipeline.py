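"""End-to-end orchestration: run every metric over a paired cis/trans
replicate set (synthetic or loaded from files) and aggregate a comparison
report.

Aggregation policy: each replicate contributes its own mean with equal
weight; condition values are unweighted means over replicate means.  The
diffusion standard error instead pools chunk x replicate samples, and the
surface-fraction ratio is computed on pooled per-atom samples.  The report
is fully deterministic for a given config (seeds included) and carries a
config hash as provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .chain_order import sch_samples
from .core_model import Trajectory, default_lipid_specs
from .lateral_diffusion import (
    centroid_tracks,
    diffusion_coefficient,
    drift_correct,
    msd_curves,
)
from .structure_metrics import (
    area_per_lipid,
    double_bond_depths,
    kink_angles,
    phosphate_depths,
    surface_fraction,
)
from .synthetic import default_spec, paired_condition_set
from .traj_io import read_trajectory, write_metrics

__all__ = [
    "AnalysisParams",
    "PipelineConfig",
    "ComparisonReport",
    "run_pipeline",
    "ratio_statistic",
    "rebuild_report",
]

ALL_METRICS = ("thickness", "volume", "apl", "kink", "order", "zdist", "surface", "diffusion")


@dataclass(frozen=True)
class AnalysisParams:
    surface_cutoff: float = 5.0  # A from the phosphate plane
    plane_offsets: tuple[float, float] = (-18.0, 18.0)
    grid_max_spacing: float = 1.0
    apl_stride: int = 25  # frames between grid partitions
    kink_stride: int = 5
    chunk_ns: float | None = None  # None: trajectory duration / 5
    drift_correction: bool = True
    msd_multi_origin: bool = False
    diffusion_mode: str = "endpoint"
    zdist_bin_width: float = 0.5
    zdist_range: tuple[float, float] = (-10.0, 30.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Either a synthetic paired set (``synthetic``) or explicit trajectory
    files (``inputs``: mappings with structure, trajectory, condition,
    replicate_id and optional dt_ns/stride keys)."""

    synthetic: dict | None = None
    inputs: tuple[dict, ...] | None = None
    metrics: tuple[str, ...] = ALL_METRICS
    params: AnalysisParams = field(default_factory=AnalysisParams)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'synthetic' or 'inputs'")
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # output location is not analysis-relevant
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            p = dict(d["params"])
            for k in ("plane_offsets", "zdist_range"):
                if k in p:
                    p[k] = tuple(p[k])
            d["params"] = AnalysisParams(**p)
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        if d.get("inputs") is not None:
            d["inputs"] = tuple(d["inputs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ComparisonReport:
    """Aggregated cis-vs-trans comparison.

    ``metrics``: metric name -> per-condition mean/sd/per-replicate values
    plus difference and percent difference (both denominators, since either
    condition can serve as the reference); ``diffusion``: per lipid type and
    condition; ``surface_ratio``: pooled cis/trans fraction ratio.
    """

    metrics: dict[str, Any]
    diffusion: dict[str, Any]
    surface_ratio: dict[str, Any]
    replicates: dict[str, Any]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "diffusion": self.diffusion,
            "surface_ratio": self.surface_ratio,
            "replicates": self.replicates,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(_jsonify(self.to_dict()), sort_keys=True, indent=1)


def _jsonify(x):
    if isinstance(x, dict):
        return {str(k): _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def ratio_statistic(cis_fraction: float, trans_fraction: float) -> dict:
    """Cis/trans surface-fraction ratio; a zero trans fraction is flagged
    infinite rather than raising."""
    if trans_fraction == 0.0:
        return {"ratio": float("inf"), "infinite": True}
    return {"ratio": float(cis_fraction / trans_fraction), "infinite": False}


# -- per-replicate analysis ------------------------------------------------

def _thickness_series(traj: Trajectory) -> np.ndarray:
    topo = traj.topology
    up = topo.is_phosphate & topo.leaflet_mask("upper")
    lo = topo.is_phosphate & topo.leaflet_mask("lower")
    if not up.any() or not lo.any():
        raise ValueError("empty leaflet")
    z = traj.coords[:, :, 2]
    return np.asarray(z[:, up], dtype=float).mean(axis=1) - np.asarray(
        z[:, lo], dtype=float
    ).mean(axis=1)


def analyse_replicate(traj: Trajectory, metrics, params: AnalysisParams) -> dict:
    """All requested per-replicate metric summaries for one trajectory."""
    from .geometry import assign_leaflets

    topo = traj.topology
    if not np.any(topo.leaflets != ""):
        assign_leaflets(traj.frame(0), topo)
    out: dict[str, Any] = {
        "replicate_id": traj.replicate_id,
        "condition": traj.condition,
        "n_frames": traj.n_frames,
        "duration_ns": float(traj.times[-1] - traj.times[0]),
    }
    if "thickness" in metrics or "volume" in metrics:
        th = _thickness_series(traj)
        out["thickness_mean"] = float(th.mean())
        out["thickness_series"] = th
        if "volume" in metrics:
            vol = traj.boxes[:, 0] * traj.boxes[:, 1] * th
            out["volume_mean"] = float(vol.mean())
            out["volume_series"] = vol
    if "apl" in metrics:
        areas: dict[str, list[float]] = {}
        apl_rows = []
        for i in range(0, traj.n_frames, params.apl_stride):
            res = area_per_lipid(
                traj.frame(i),
                topo,
                grid_max_spacing=params.grid_max_spacing,
                plane_offsets=params.plane_offsets,
            )
            for rn, a in res.per_type.items():
                areas.setdefault(rn, []).append(a)
            for plane, d in res.per_plane.items():
                for rn, (nc, nl, a) in d.items():
                    apl_rows.append((traj.times[i], plane, rn, nc, nl, a))
        out["apl"] = {rn: float(np.mean(v)) for rn, v in areas.items()}
        out["apl_rows"] = apl_rows
    if "kink" in metrics:
        ka = kink_angles(traj, stride=params.kink_stride)
        out["kink"] = {f"{rn}:{t}": float(v.mean()) for (rn, t), v in ka.items()}
        out["kink_mean"] = float(np.mean(np.concatenate(list(ka.values()))))
    if "order" in metrics:
        vals = sch_samples(traj, np.arange(len(topo.ch_carbon)))
        per_pair = vals.mean(axis=0)
        out["order_mean"] = float(per_pair.mean())
        df = pd.DataFrame(
            {
                "lipid": topo.ch_resname,
                "tail": topo.ch_tail,
                "carbon": topo.ch_position,
                "s": per_pair,
            }
        )
        prof = df.groupby(["lipid", "tail", "carbon"], sort=True).agg(
            S_CH=("s", "mean"), n=("s", "size")
        )
        prof["n"] *= traj.n_frames
        out["order_profile"] = prof.reset_index()
    if "zdist" in metrics or "surface" in metrics:
        db = double_bond_depths(traj)
        if "surface" in metrics:
            out["surface_fraction"] = surface_fraction(db, cutoff=params.surface_cutoff)
            out["surface_hits"] = int(np.count_nonzero(db <= params.surface_cutoff))
            out["surface_n"] = int(db.size)
        if "zdist" in metrics:
            lo, hi = params.zdist_range
            bins = np.arange(lo, hi + params.zdist_bin_width / 2, params.zdist_bin_width)
            ph = phosphate_depths(traj)
            out["zdist"] = {
                "bins": bins,
                "double_bond": np.histogram(db, bins=bins)[0] / db.size,
                "phosphate": np.histogram(ph, bins=bins)[0] / ph.size,
            }
    if "diffusion" in metrics:
        chunk = params.chunk_ns
        if chunk is None:
            chunk = (traj.times[-1] - traj.times[0]) / 5.0
        tracks = centroid_tracks(traj)
        if params.drift_correction:
            tracks = drift_correct(tracks, topo.leaflets)
        per_type: dict[str, list] = {}
        lipid_types = list(dict.fromkeys(topo.residue_names[topo.lipid_residue_indices()]))
        for rn in lipid_types + [None]:
            curves = msd_curves(
                traj,
                residue_name=rn,
                chunk_ns=chunk,
                multi_origin=params.msd_multi_origin,
                tracks=tracks,
            )
            per_type[rn if rn is not None else "all"] = curves
        out["msd_curves"] = per_type
        out["chunk_ns"] = float(chunk)
    return out


# -- aggregation -----------------------------------------------------------

def _condition_block(values: dict[str, list[float]]) -> dict:
    block = {}
    for cond, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        block[cond] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "per_replicate": arr.tolist(),
        }
    if "cis" in block and "trans" in block:
        c, t = block["cis"]["mean"], block["trans"]["mean"]
        block["difference_cis_minus_trans"] = c - t
        block["percent_difference_vs_trans"] = 100.0 * (c - t) / t if t else float("nan")
        block["percent_difference_vs_cis"] = 100.0 * (c - t) / c if c else float("nan")
    return block


def _collect(reps: list[dict], key: str) -> dict[str, list[float]]:
    vals: dict[str, list[float]] = {}
    for r in reps:
        if key in r:
            vals.setdefault(r["condition"], []).append(r[key])
    return vals


def aggregate_report(reps: list[dict], config: PipelineConfig, seeds: dict) -> ComparisonReport:
    metrics: dict[str, Any] = {}
    for key, label in (
        ("thickness_mean", "thickness_A"),
        ("volume_mean", "volume_A3"),
        ("kink_mean", "kink_angle_deg"),
        ("order_mean", "tail_mean_S_CH"),
        ("surface_fraction", "surface_fraction"),
    ):
        vals = _collect(reps, key)
        if vals:
            metrics[label] = _condition_block(vals)
    # per-type area per lipid
    apl_types: dict[str, dict[str, list[float]]] = {}
    for r in reps:
        for rn, a in r.get("apl", {}).items():
            apl_types.setdefault(rn, {}).setdefault(r["condition"], []).append(a)
    if apl_types:
        metrics["area_per_lipid_A2"] = {rn: _condition_block(v) for rn, v in apl_types.items()}
    # per-site kink angles
    kink_types: dict[str, dict[str, list[float]]] = {}
    for r in reps:
        for site, a in r.get("kink", {}).items():
            kink_types.setdefault(site, {}).setdefault(r["condition"], []).append(a)
    if kink_types:
        metrics["kink_angle_by_tail_deg"] = {k: _condition_block(v) for k, v in kink_types.items()}

    # diffusion: pool chunk x replicate samples per type and condition
    diffusion: dict[str, Any] = {}
    curves_by: dict[tuple[str, str], list] = {}
    for r in reps:
        for rn, curves in r.get("msd_curves", {}).items():
            curves_by.setdefault((rn, r["condition"]), []).extend(curves)
    for (rn, cond), curves in sorted(curves_by.items()):
        est = diffusion_coefficient(curves, n_dims=2, mode=config.params.diffusion_mode)
        diffusion.setdefault(rn, {})[cond] = {
            "D_A2_per_ns": est.d_a2_per_ns,
            "D_cm2_per_s": est.d_cm2_per_s,
            "se_A2_per_ns": est.standard_error_a2_per_ns,
            "n_samples": est.n_samples,
        }

    # pooled surface-fraction ratio
    surface_ratio: dict[str, Any] = {}
    pooled = {}
    for cond in ("cis", "trans"):
        hits = sum(r["surface_hits"] for r in reps if r["condition"] == cond and "surface_hits" in r)
        n = sum(r["surface_n"] for r in reps if r["condition"] == cond and "surface_n" in r)
        if n:
            pooled[cond] = hits / n
    if "cis" in pooled and "trans" in pooled:
        surface_ratio = ratio_statistic(pooled["cis"], pooled["trans"])
        surface_ratio["cis_fraction"] = pooled["cis"]
        surface_ratio["trans_fraction"] = pooled["trans"]

    rep_summaries = {
        r["replicate_id"]: {
            k: _jsonify(v)
            for k, v in r.items()
            if k
            not in (
                "thickness_series",
                "volume_series",
                "msd_curves",
                "order_profile",
                "zdist",
                "apl_rows",
            )
        }
        for r in reps
    }
    provenance = {
        "config": _jsonify(config.to_dict()),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "package_version": __version__,
    }
    return ComparisonReport(
        metrics=_jsonify(metrics),
        diffusion=_jsonify(diffusion),
        surface_ratio=_jsonify(surface_ratio),
        replicates=rep_summaries,
        provenance=provenance,
    )


# -- entry points ----------------------------------------------------------

def _iter_trajectories(config: PipelineConfig):
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        seed = int(syn.pop("seed"))
        n_rep = int(syn.pop("n_replicates", 5))
        cis_over = syn.pop("cis", {})
        trans_over = syn.pop("trans", {})
        common = syn.pop("common", {})
        spec_cis = default_spec("cis", seed=seed, **{**common, **cis_over})
        spec_trans = default_spec("trans", seed=seed + 1, **{**common, **trans_over})
        handles = paired_condition_set(spec_cis, spec_trans, n_replicates=n_rep)
        seeds = {h.replicate_id: h.spec.seed for h in handles}
        for h in handles:
            traj, _ = h.load()
            yield traj, seeds
    else:
        specs = default_lipid_specs()
        seeds: dict = {}
        for inp in config.inputs:
            traj = read_trajectory(
                inp["structure"],
                inp["trajectory"],
                specs,
                stride=int(inp.get("stride", 1)),
                dt_ns=inp.get("dt_ns"),
                replicate_id=inp.get("replicate_id", Path(inp["trajectory"]).stem),
                condition=inp.get("condition", "other"),
            )
            yield traj, seeds


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Run every requested metric on every replicate and aggregate.

    Replicates are generated (or read) and analysed one at a time so only a
    single trajectory is ever held in memory.  A stage failure aborts with
    the replicate identity attached; on failure with an output directory, a
    failure marker is flushed next to any partial outputs.
    """
    reps: list[dict] = []
    seeds: dict = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        for traj, seeds in _iter_trajectories(config):
            try:
                reps.append(analyse_replicate(traj, config.metrics, config.params))
            except Exception as exc:
                raise RuntimeError(
                    f"analysis failed for replicate {traj.replicate_id!r} "
                    f"({traj.condition}): {exc}"
                ) from exc
        report = aggregate_report(reps, config, seeds)
    except Exception:
        if out_dir:
            (out_dir / "FAILED").write_text("pipeline aborted; partial outputs only\n")
        raise
    if out_dir:
        _write_outputs(reps, report, out_dir)
    return report


def _write_outputs(reps: list[dict], report: ComparisonReport, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    per_rep = {r["replicate_id"]: {k: _jsonify(v) for k, v in r.items()
                                   if k not in ("msd_curves", "order_profile")}
               for r in reps}
    (out_dir / "replicate_metrics.json").write_text(
        json.dumps(per_rep, sort_keys=True, indent=1) + "\n"
    )
    frames = []
    for r in reps:
        if "thickness_series" in r:
            frames.append(
                pd.DataFrame(
                    {
                        "replicate_id": r["replicate_id"],
                        "condition": r["condition"],
                        "thickness_A": r["thickness_series"],
                        "volume_A3": r.get("volume_series"),
                    }
                )
            )
    if frames:
        write_metrics(pd.concat(frames, ignore_index=True), out_dir / "thickness_volume.csv")
    apl_rows = [
        (r["replicate_id"], r["condition"], *row)
        for r in reps
        for row in r.get("apl_rows", [])
    ]
    if apl_rows:
        write_metrics(
            pd.DataFrame(
                apl_rows,
                columns=["replicate_id", "condition", "time_ns", "plane_A",
                         "lipid", "n_cells", "n_lipids", "area_A2"],
            ),
            out_dir / "area_per_lipid.csv",
        )
    profs = []
    for r in reps:
        if "order_profile" in r:
            p = r["order_profile"].copy()
            p.insert(0, "condition", r["condition"])
            p.insert(0, "replicate_id", r["replicate_id"])
            profs.append(p)
    if profs:
        write_metrics(pd.concat(profs, ignore_index=True), out_dir / "order_parameter.csv")
    msd_rows = []
    for r in reps:
        for rn, curves in r.get("msd_curves", {}).items():
            for c in curves:
                for lag, v in zip(c.lag_ns, c.msd):
                    msd_rows.append((r["replicate_id"], r["condition"], rn, c.chunk_id, lag, v))
    if msd_rows:
        write_metrics(
            pd.DataFrame(
                msd_rows,
                columns=["replicate_id", "condition", "lipid", "chunk", "lag_ns", "msd_A2"],
            ),
            out_dir / "msd.csv",
        )
    zrows = []
    for r in reps:
        zd = r.get("zdist")
        if zd:
            centers = 0.5 * (zd["bins"][:-1] + zd["bins"][1:])
            for cls in ("double_bond", "phosphate"):
                for c, v in zip(centers, zd[cls]):
                    zrows.append((r["replicate_id"], r["condition"], cls, c, v))
    if zrows:
        write_metrics(
            pd.DataFrame(
                zrows,
                columns=["replicate_id", "condition", "atom_class", "depth_A", "probability"],
            ),
            out_dir / "zdistribution.csv",
        )


def rebuild_report(out_dir, config: PipelineConfig) -> dict:
    """Re-aggregate the scalar metric blocks from saved per-replicate files
    (no hidden state beyond what was written)."""
    per_rep = json.loads((Path(out_dir) / "replicate_metrics.json").read_text())
    reps = list(per_rep.values())
    report = aggregate_report(
        [{k: v for k, v in r.items()} for r in reps], config, seeds={}
    )
    return report.metrics
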