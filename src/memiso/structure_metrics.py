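"""Frame-wise structural metrics of a bilayer patch.

All metrics are defined relative to the phosphate groups: thickness is the
mean phosphate-to-phosphate distance between leaflets, membrane volume is
the in-plane box area times the thickness, and depth measurements use the
per-leaflet, per-frame mean z of the phosphate phosphorus atoms as the
reference ("phosphate plane").  Area per lipid partitions a dense planar
grid among lipid residues by nearest heavy atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_model import Frame, Topology, Trajectory
from .geometry import assign_leaflets

__all__ = [
    "thickness",
    "membrane_volume",
    "area_per_lipid",
    "AreaPerLipidResult",
    "kink_angle",
    "kink_angles",
    "double_bond_depths",
    "phosphate_depths",
    "double_bond_zdist",
    "ZDistribution",
    "surface_fraction",
]


def _ensure_leaflets(frame_or_traj, topology: Topology) -> None:
    if not np.any(topology.leaflets != ""):
        frame = frame_or_traj if isinstance(frame_or_traj, Frame) else frame_or_traj.frame(0)
        assign_leaflets(frame, topology)


def thickness(frame: Frame, topology: Topology) -> float:
    """Phosphate-to-phosphate bilayer thickness (Angstrom): mean z of the
    upper leaflet's phosphate-group atoms minus the lower leaflet's."""
    _ensure_leaflets(frame, topology)
    z = frame.positions[:, 2]
    up = topology.is_phosphate & topology.leaflet_mask("upper")
    lo = topology.is_phosphate & topology.leaflet_mask("lower")
    if not up.any() or not lo.any():
        raise ValueError("empty leaflet: cannot compute thickness")
    return float(z[up].mean() - z[lo].mean())


def membrane_volume(frame: Frame, topology: Topology) -> float:
    """Membrane volume (Angstrom^3) = Lx * Ly * thickness."""
    return float(frame.box[0] * frame.box[1] * thickness(frame, topology))


@dataclass
class AreaPerLipidResult:
    """Grid-partition area per lipid for one frame.

    ``per_type``: residue name -> mean area per lipid (A^2) averaged over
    both grid planes (absent types omitted, never reported as zero);
    ``per_plane``: per plane offset, residue name -> (n_cells, n_lipids,
    area per lipid); ``cell_area`` and ``spacing`` describe the realized
    grid; ``cells_per_residue``: per plane, residue index -> cell count.
    """

    per_type: dict[str, float]
    per_plane: dict[float, dict[str, tuple[int, int, float]]]
    cell_area: float
    spacing: tuple[float, float]
    n_cells: tuple[int, int]
    box_area: float
    cells_per_residue: dict[float, np.ndarray] = field(default_factory=dict)

    def total_assigned_area(self, plane: float) -> float:
        return sum(n * self.cell_area for n, _, _ in self.per_plane[plane].values())


def _grid_points(box: np.ndarray, max_spacing: float) -> tuple[np.ndarray, float, float, int, int]:
    nx = int(np.ceil(box[0] / max_spacing))
    ny = int(np.ceil(box[1] / max_spacing))
    dx, dy = box[0] / nx, box[1] / ny
    gx = (np.arange(nx) + 0.5) * dx
    gy = (np.arange(ny) + 0.5) * dy
    pts = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    return pts, dx, dy, nx, ny


def area_per_lipid(
    frame: Frame,
    topology: Topology,
    grid_max_spacing: float = 1.0,
    plane_offsets: tuple[float, float] = (-18.0, 18.0),
    use_3d: bool = True,
) -> AreaPerLipidResult:
    """Area per lipid by nearest-residue grid partition.

    The xy plane is covered by a grid of ceil(L/s) x ceil(L/s) cells
    (realized spacing <= ``grid_max_spacing``); the grid is laid out at each
    ``plane_offsets`` z (measured from the midplane between the two
    phosphate planes) and every grid point is assigned to the lipid residue
    of that side's leaflet with the nearest heavy atom (3D distance with xy
    minimum image by default; ``use_3d=False`` restricts to xy distance).
    Per-type area = assigned cells x cell area / number of lipids of that
    type in the leaflet.
    """
    _ensure_leaflets(frame, topology)
    box = frame.box
    z = frame.positions[:, 2]
    plane_z = {}
    for leaf in ("upper", "lower"):
        m = topology.is_phosphate & topology.leaflet_mask(leaf)
        if not m.any():
            raise ValueError(f"empty {leaf} leaflet")
        plane_z[leaf] = z[m].mean()
    midplane = 0.5 * (plane_z["upper"] + plane_z["lower"])

    pts2d, dx, dy, nx, ny = _grid_points(box, grid_max_spacing)
    cell_area = dx * dy

    per_plane: dict[float, dict[str, tuple[int, int, float]]] = {}
    cells_per_residue: dict[float, np.ndarray] = {}
    type_areas: dict[str, list[float]] = {}
    for offset in plane_offsets:
        leaf = "upper" if offset > 0 else "lower"
        sel = np.nonzero(topology.is_heavy & topology.leaflet_mask(leaf))[0]
        if len(sel) == 0:
            raise ValueError(f"no heavy atoms in {leaf} leaflet")
        atoms = np.asarray(frame.positions[sel], dtype=float)
        # tile atoms over the 8 xy neighbour images so the KD-tree query is
        # minimum-image correct
        shifts = np.array(
            [(i * box[0], j * box[1]) for i in (-1, 0, 1) for j in (-1, 0, 1)]
        )
        tiled = np.repeat(atoms[None, :, :], len(shifts), axis=0)
        tiled[:, :, 0] += shifts[:, 0:1]
        tiled[:, :, 1] += shifts[:, 1:2]
        tiled = tiled.reshape(-1, 3)
        owner = np.tile(sel, len(shifts))

        if use_3d:
            query = np.column_stack([pts2d, np.full(len(pts2d), midplane + offset)])
            tree = cKDTree(tiled)
        else:
            query = pts2d
            tree = cKDTree(tiled[:, :2])
        _, nearest = tree.query(query, workers=-1)
        res_of_cell = topology.residue_index[owner[nearest]]

        counts = np.bincount(res_of_cell, minlength=topology.n_residues)
        cells_per_residue[offset] = counts
        leaf_res = np.nonzero((topology.leaflets == leaf) & topology.residue_is_lipid)[0]
        plane_result: dict[str, tuple[int, int, float]] = {}
        for resname in dict.fromkeys(topology.residue_names[leaf_res]):
            res_of_type = leaf_res[topology.residue_names[leaf_res] == resname]
            n_cells = int(counts[res_of_type].sum())
            n_lip = len(res_of_type)
            area = n_cells * cell_area / n_lip
            plane_result[resname] = (n_cells, n_lip, area)
            type_areas.setdefault(resname, []).append(area)
        per_plane[offset] = plane_result

    per_type = {k: float(np.mean(v)) for k, v in type_areas.items()}
    return AreaPerLipidResult(
        per_type=per_type,
        per_plane=per_plane,
        cell_area=cell_area,
        spacing=(dx, dy),
        n_cells=(nx, ny),
        box_area=float(box[0] * box[1]),
        cells_per_residue=cells_per_residue,
    )


def kink_angle(frame: Frame, topology: Topology, residue_index: int, tail_index: int) -> float:
    """Interior angle (degrees) at a tail's unsaturation kink, between the
    vectors from the kink carbon to the tail's carbonyl carbon and to its
    terminal carbon.  180 deg is a straight chain; the kink carbon is the
    chain-proximal carbon of the tail's first double bond.  Raises for
    saturated tails."""
    for site in topology.sites:
        if site.residue_index == residue_index and site.tail_index == tail_index:
            kink = frame.positions[site.dihedral_atom_indices[1]]
            v1 = frame.positions[site.carbonyl_index] - kink
            v2 = frame.positions[site.terminal_index] - kink
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    raise ValueError(f"residue {residue_index} tail {tail_index} has no unsaturation (no kink)")


def kink_angles(trajectory: Trajectory, stride: int = 1):
    """Kink angles for every unsaturation site over strided frames.

    Returns a dict (residue_name, tail_index) -> 1D array of angles pooled
    over sites and frames, computed vectorized.
    """
    topo = trajectory.topology
    if not topo.sites:
        raise ValueError("no unsaturation sites in topology")
    kink_idx = np.array([s.dihedral_atom_indices[1] for s in topo.sites])
    carb_idx = np.array([s.carbonyl_index for s in topo.sites])
    term_idx = np.array([s.terminal_index for s in topo.sites])
    keys = [(s.residue_name, s.tail_index) for s in topo.sites]
    out: dict[tuple[str, int], list[np.ndarray]] = {}
    coords = trajectory.coords[::stride]
    k = np.asarray(coords[:, kink_idx, :], dtype=float)
    v1 = np.asarray(coords[:, carb_idx, :], dtype=float) - k
    v2 = np.asarray(coords[:, term_idx, :], dtype=float) - k
    c = np.einsum("fsk,fsk->fs", v1, v2) / (
        np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2)
    )
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    for j, key in enumerate(keys):
        out.setdefault(key, []).append(ang[:, j])
    return {k2: np.concatenate(v) for k2, v in out.items()}


# -- depth distributions ---------------------------------------------------

def _leaflet_plane_z(trajectory: Trajectory) -> dict[str, np.ndarray]:
    """Per-frame reference-plane z for each leaflet: mean z of that
    leaflet's phosphorus atoms (P only, not the phosphate oxygens)."""
    topo = trajectory.topology
    _ensure_leaflets(trajectory, topo)
    planes = {}
    for leaf in ("upper", "lower"):
        m = topo.is_phosphorus & topo.leaflet_mask(leaf)
        if not m.any():
            raise ValueError(f"no phosphorus atoms in {leaf} leaflet")
        planes[leaf] = np.asarray(trajectory.coords[:, m, 2], dtype=float).mean(axis=1)
    return planes


def _signed_depths(trajectory: Trajectory, atom_mask: np.ndarray) -> np.ndarray:
    """Signed distance of selected atoms to their leaflet's phosphate plane,
    pooled over frames and leaflets.  d > 0 means buried toward the
    midplane, d < 0 past the plane into the water."""
    topo = trajectory.topology
    planes = _leaflet_plane_z(trajectory)
    chunks = []
    for leaf, sign in (("upper", +1.0), ("lower", -1.0)):
        m = atom_mask & topo.leaflet_mask(leaf)
        if not m.any():
            continue
        z = np.asarray(trajectory.coords[:, m, 2], dtype=float)
        d = sign * (planes[leaf][:, None] - z)
        chunks.append(d.ravel())
    if not chunks:
        raise ValueError("empty atom selection for depth measurement")
    return np.concatenate(chunks)


def double_bond_depths(trajectory: Trajectory) -> np.ndarray:
    """Per-atom signed depths of all double-bond carbons (pooled)."""
    return _signed_depths(trajectory, trajectory.topology.is_double_bond_carbon)


def phosphate_depths(trajectory: Trajectory) -> np.ndarray:
    """Signed depths of the phosphorus and phosphate-oxygen atoms relative
    to the P-only plane (by construction roughly centred at zero)."""
    return _signed_depths(trajectory, trajectory.topology.is_phosphate)


@dataclass
class ZDistribution:
    """Relative-probability histogram of signed depths to the phosphate
    plane; ``densities`` maps an atom class to bin masses summing to 1."""

    bin_edges: np.ndarray
    densities: dict[str, np.ndarray]
    n_samples: dict[str, int]

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")


DEFAULT_ZDIST_BINS = np.arange(-10.0, 30.0 + 0.25, 0.5)


def double_bond_zdist(trajectory: Trajectory, bins: np.ndarray | None = None) -> ZDistribution:
    """Depth histograms of double-bond carbons and of phosphate (P + O)
    atoms relative to the per-frame, per-leaflet phosphate plane."""
    bins = DEFAULT_ZDIST_BINS if bins is None else np.asarray(bins, dtype=float)
    densities = {}
    n_samples = {}
    for name, samples in (
        ("double_bond", double_bond_depths(trajectory)),
        ("phosphate", phosphate_depths(trajectory)),
    ):
        hist, _ = np.histogram(samples, bins=bins)
        total = hist.sum()
        if total == 0:
            raise ValueError(f"no {name} samples fall inside the histogram range")
        densities[name] = hist / total
        n_samples[name] = int(len(samples))
    return ZDistribution(bin_edges=bins, densities=densities, n_samples=n_samples)


def surface_fraction(samples: np.ndarray, cutoff: float = 5.0, headgroup_side_only: bool = True):
    """Fraction of depth samples within ``cutoff`` of the phosphate plane.

    With ``headgroup_side_only`` (default) a sample counts when d <= cutoff,
    i.e. anywhere on the headgroup side of the cutoff including past the
    plane into water; the alternative counts |d| <= cutoff only.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no depth samples")
    if headgroup_side_only:
        hits = samples <= cutoff
    else:
        hits = np.abs(samples) <= cutoff
    return float(np.count_nonzero(hits) / samples.size)
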