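"""Core geometry: torsions, cis/trans classification, the isomerization
operator, leaflet assignment and periodic-image handling.

Boxes are orthorhombic; x and y are treated periodically (minimum image),
z non-periodically (the bilayer is centred and never crosses the z face).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Frame, Topology, Trajectory, UnsaturationSite

__all__ = [
    "dihedral_angle",
    "classify_site",
    "classify_all",
    "isomerize_site",
    "isomerize_all",
    "assign_leaflets",
    "min_image_xy",
    "wrap_xy",
    "unwrap_xy",
    "residue_centroids",
]

#: |dihedral| below this is cis, at or above is trans (90 deg is the
#: symmetry point between the two wells; boundary goes to trans)
CIS_TRANS_THRESHOLD_DEG = 90.0


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    0 deg is the cis (eclipsed) geometry, +/-180 deg is trans.  Raises on
    degenerate input (coincident consecutive points or collinear p1,p2,p3 /
    p2,p3,p4, where the torsion is undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-10:
        raise ValueError("degenerate dihedral: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 * nb2 or np.linalg.norm(n2) < 1e-9 * nb2:
        raise ValueError("degenerate dihedral: collinear atoms")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def classify_site(frame: Frame, site: UnsaturationSite) -> str:
    """Classify one double bond as ``"cis"`` or ``"trans"`` from its torsion."""
    i1, i2, i3, i4 = site.dihedral_atom_indices
    ang = dihedral_angle(
        frame.positions[i1], frame.positions[i2], frame.positions[i3], frame.positions[i4]
    )
    return "cis" if abs(ang) < CIS_TRANS_THRESHOLD_DEG else "trans"


def classify_all(frame: Frame, topology: Topology) -> list[str]:
    return [classify_site(frame, s) for s in topology.sites]


def _distal_set(topology: Topology, site: UnsaturationSite) -> list[int]:
    """Atoms on the chain-terminus side of the C(i)=C(i+1) bond, found by
    walking the intra-residue bond graph from C(i+1) without crossing the
    double bond.  Raises if the walk reaches back to C(i) (a ring)."""
    c_prox, c_dist = site.bond_carbon_indices
    seen = {c_dist}
    stack = [c_dist]
    while stack:
        a = stack.pop()
        for b in topology.bonds.get(a, []):
            if a == c_dist and b == c_prox:
                continue  # the double bond itself
            if b == c_prox:
                raise ValueError(
                    f"distal set of site {site.residue_name}/{site.residue_index} "
                    "reaches back to the proximal carbon (cycle)"
                )
            if b not in seen:
                seen.add(b)
                stack.append(b)
    seen.discard(c_dist)
    return [c_dist] + sorted(seen)


def isomerize_site(frame: Frame, site: UnsaturationSite, topology: Topology) -> Frame:
    """Flip one double bond cis<->trans by rotating every atom distal to the
    C(i)=C(i+1) axis (toward the chain terminus) by 180 degrees about the
    axis through the two bond carbons.

    A 180-degree rotation about the unit axis u is the exact involution
    R = 2 u u^T - I; all non-distal atoms are untouched, so the operation is
    an isometry on the distal set and applying it twice restores the input.
    """
    c_prox, c_dist = site.bond_carbon_indices
    distal = _distal_set(topology, site)
    out = frame.copy()
    p_prox = frame.positions[c_prox]
    p_dist = frame.positions[c_dist]
    axis = p_dist - p_prox
    norm = np.linalg.norm(axis)
    if norm < 1e-10:
        raise ValueError("degenerate double bond: coincident carbons")
    u = axis / norm
    rel = frame.positions[distal] - p_prox
    out.positions[distal] = p_prox + 2.0 * np.outer(rel @ u, u) - rel
    return out


@dataclass
class IsomerizationReport:
    n_sites: int
    n_flipped: int
    flipped_sites: list[UnsaturationSite]
    final_states: list[str]


def isomerize_all(
    frame: Frame,
    topology: Topology,
    target: str = "invert",
    sites: list[UnsaturationSite] | None = None,
) -> tuple[Frame, IsomerizationReport]:
    """Drive every (selected) double bond to ``target`` in {cis, trans} or
    invert each site's current state.  Sites sharing a tail are processed
    from the chain end inward so distal sets nest cleanly.  Verifies that
    every site classifies as its target state afterwards."""
    if target not in ("cis", "trans", "invert"):
        raise ValueError(f"target must be cis/trans/invert, got {target!r}")
    chosen = topology.sites if sites is None else sites
    order = sorted(range(len(chosen)), key=lambda i: -chosen[i].position)
    out = frame.copy()
    flipped: list[UnsaturationSite] = []
    for i in order:
        site = chosen[i]
        state = classify_site(out, site)
        want = ({"cis": "trans", "trans": "cis"}[state]) if target == "invert" else target
        if state != want:
            out = isomerize_site(out, site, topology)
            if classify_site(out, site) != want:
                raise RuntimeError(
                    f"site {site.residue_name} residue {site.residue_index} tail "
                    f"{site.tail_index} failed to reach {want}"
                )
            flipped.append(site)
    final = [classify_site(out, s) for s in chosen]
    return out, IsomerizationReport(len(chosen), len(flipped), flipped, final)


# -- leaflets --------------------------------------------------------------

def phosphate_centroid_z(frame: Frame, topology: Topology) -> np.ndarray:
    """Per-residue mean z of phosphate-group atoms (NaN for non-lipids)."""
    z = frame.positions[:, 2]
    mask = topology.is_phosphate
    num = np.bincount(
        topology.residue_index[mask], weights=z[mask], minlength=topology.n_residues
    )
    den = np.bincount(topology.residue_index[mask], minlength=topology.n_residues)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def assign_leaflets(
    frame: Frame,
    topology: Topology,
    midplane_epsilon: float = 5.0,
    store: bool = True,
) -> np.ndarray:
    """Assign each lipid residue to the upper or lower leaflet by the sign of
    its phosphate-centroid z relative to the global phosphate mean.

    Residues whose phosphate centroid lies within ``midplane_epsilon`` of the
    midplane are resolved by tail direction instead (phosphates sit above
    the tail carbons in the upper leaflet).  Returns the per-residue label
    array ("upper"/"lower", "" for non-lipids) and stores it on the topology
    unless ``store=False``.
    """
    pc = phosphate_centroid_z(frame, topology)
    lipid = topology.residue_is_lipid
    if np.count_nonzero(lipid) < 2:
        raise ValueError("need at least 2 lipid residues to assign leaflets")
    mid = np.nanmean(pc[lipid])
    labels = np.full(topology.n_residues, "", dtype=object)
    z = frame.positions[:, 2]
    tc = topology.is_tail_carbon
    for r in np.nonzero(lipid)[0]:
        d = pc[r] - mid
        if abs(d) >= midplane_epsilon:
            labels[r] = "upper" if d > 0 else "lower"
        else:
            # ambiguous: compare phosphate height to the tail-carbon centroid
            atoms = topology.residue_atoms(r)
            tails = atoms[tc[atoms]]
            tail_z = z[tails].mean() if len(tails) else mid
            labels[r] = "upper" if pc[r] > tail_z else "lower"
    if store:
        topology.leaflets = labels
    return labels


# -- periodicity -----------------------------------------------------------

def min_image_xy(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention applied to the x and y components of a
    displacement array (..., 2 or 3)."""
    out = np.array(delta, dtype=float, copy=True)
    for k in (0, 1):
        out[..., k] -= box[k] * np.round(out[..., k] / box[k])
    return out


def wrap_xy(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap x, y into [0, L)."""
    out = np.array(positions, dtype=float, copy=True)
    for k in (0, 1):
        out[..., k] -= box[k] * np.floor(out[..., k] / box[k])
    return out


def unwrap_xy(tracks: np.ndarray, boxes: np.ndarray, warn_threshold: float = 0.5):
    """Remove periodic jumps from wrapped xy tracks.

    ``tracks`` has shape (F, R, 2) (per-frame residue centroids), ``boxes``
    (F, 2) or (F, 3).  Consecutive displacements are mapped to their minimum
    image and re-accumulated, so the returned tracks are continuous.  Any
    post-unwrap step still exceeding ``warn_threshold`` of the box indicates
    undersampled motion (aliasing); those steps are reported.
    """
    tracks = np.asarray(tracks, dtype=float)
    boxes = np.asarray(boxes, dtype=float)[:, :2]
    if tracks.ndim != 3 or tracks.shape[2] != 2:
        raise ValueError("tracks must have shape (F, R, 2)")
    disp = np.diff(tracks, axis=0)
    disp -= boxes[1:, None, :] * np.round(disp / boxes[1:, None, :])
    out = np.concatenate([tracks[:1], tracks[:1] + np.cumsum(disp, axis=0)], axis=0)
    aliased = np.abs(disp) >= warn_threshold * boxes[1:, None, :]
    n_alias = int(aliased.sum())
    if n_alias:
        import warnings

        warnings.warn(f"unwrap_xy: {n_alias} steps exceed {warn_threshold} box (aliasing?)")
    return out


def residue_centroids(
    trajectory: Trajectory, heavy_only: bool = True, lipid_only: bool = True
) -> np.ndarray:
    """Per-frame xy centroids of each residue, shape (F, n_residues, 2).

    Robust to wrapped coordinates: each residue's atoms are brought to the
    minimum image of its first atom before averaging, then the centroid is
    wrapped back into the box.  Residues with no selected atoms yield NaN.
    """
    topo = trajectory.topology
    mask = topo.is_heavy if heavy_only else np.ones(topo.n_atoms, dtype=bool)
    if lipid_only:
        mask = mask & topo.is_lipid
    F = trajectory.n_frames
    out = np.full((F, topo.n_residues, 2), np.nan)
    ridx = topo.residue_index[mask]
    order = np.argsort(ridx, kind="stable")
    sel = np.nonzero(mask)[0][order]
    ridx = ridx[order]
    counts = np.bincount(ridx, minlength=topo.n_residues)
    firsts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    have = counts > 0
    first_atom = np.full(topo.n_residues, -1, dtype=int)
    first_atom[have] = sel[firsts[have]]
    for f in range(F):
        xy = np.asarray(trajectory.coords[f][:, :2], dtype=float)
        box = trajectory.boxes[f][:2]
        ref = xy[first_atom[ridx]]
        rel = xy[sel] - ref
        rel -= box * np.round(rel / box)
        cx = np.bincount(ridx, weights=ref[:, 0] + rel[:, 0], minlength=topo.n_residues)
        cy = np.bincount(ridx, weights=ref[:, 1] + rel[:, 1], minlength=topo.n_residues)
        cent = np.stack([cx, cy], axis=1)
        cent[have] /= counts[have, None]
        out[f] = np.where(have[:, None], cent, np.nan)
        out[f, have] = wrap_xy(out[f, have], box)
    return out
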