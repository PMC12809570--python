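"""Seeded synthetic bilayer generator with closed-form ground truth.

The generator emulates the statistical structure of an all-atom bilayer
patch (two leaflets, the default 50-lipid-per-leaflet PE/PG/cardiolipin
composition) at bead resolution: every lipid is a headgroup bead set with
named phosphate atoms plus ideal-geometry acyl chains with explicit
hydrogens, the double-bond dihedral built at 0 deg (cis) or 180 deg
(trans).  Dynamics are not integrated from forces; each observable is
driven by its own stochastic law so that every analysis operation has a
known expectation:

* lateral motion: per-residue rigid 2D Brownian steps with per-type D, so
  the MSD slope is 4D;
* bilayer thickness: phosphate planes at +/- thickness/2 with per-frame
  Gaussian jitter, so the mean thickness is exact;
* chain order: C-H vectors resampled every frame from a tilt law (fixed
  polar angle theta0 or a discrete mixture), so S_CH = sum w P2(cos theta);
* double-bond depth: a bulk Gaussian about each site's as-built depth (or a
  global mean) mixed with rare surface excursions uniform in a band below
  the phosphate plane, switched by a two-state Markov chain whose
  stationary excursion probability is exact, so the surface fraction has a
  closed form.

All randomness flows from one mandatory seed through independent spawned
streams (one per residue, per site, and per purpose), so a given spec is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_model import (
    LipidSpec,
    MembraneComposition,
    TailSpec,
    Topology,
    Trajectory,
    annotate_topology,
    default_composition,
    instantiate_composition,
)
from .chain_order import p2

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "build_membrane",
    "simulate_trajectory",
    "paired_condition_set",
    "ReplicateHandle",
    "brownian_tracks",
]

BOND_CC = 1.53
BOND_CDC = 1.33  # C=C
BOND_CH = 1.09
ANGLE_CCC = 111.0
MIN_AREA_PER_LIPID = 55.0  # A^2; below this the box is declared overfilled


# -- internal-coordinate chain building ------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float,
          dihedral_deg: float) -> np.ndarray:
    """Place atom d from the three previous atoms, the b-c-d bond angle and
    the a-b-c-d torsion (natural extension reference frame)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    d2 = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_chain(tail: TailSpec, condition: str) -> np.ndarray:
    """Ideal-geometry carbon chain descending -z: all torsions trans except
    each unsaturation torsion, set to 0 (cis) or 180 (trans).  Returns
    (n_carbons, 3) with carbon 1 at the origin."""
    n = tail.n_carbons
    unsat_pos = {u.position for u in tail.unsaturations}
    beta = math.radians((180.0 - ANGLE_CCC) / 2.0)
    s, c = math.sin(beta), math.cos(beta)
    xyz = np.zeros((n, 3))
    xyz[1] = xyz[0] + BOND_CC * np.array([0.0, s, -c])
    if n > 2:
        bond = BOND_CDC if 2 in unsat_pos else BOND_CC
        xyz[2] = xyz[1] + bond * np.array([0.0, -s, -c])
    for k in range(3, n):
        # 0-based index k is chain position k+1; the bond being laid down
        # joins positions k and k+1, the torsion spans positions k-2..k+1
        bond = BOND_CDC if k in unsat_pos else BOND_CC
        if (k - 1) in unsat_pos:
            tor = 0.0 if condition == "cis" else 180.0
        else:
            tor = 180.0
        xyz[k] = _nerf(xyz[k - 3], xyz[k - 2], xyz[k - 1], bond, ANGLE_CCC, tor)
    return xyz


def _head_template(spec: LipidSpec) -> dict[str, np.ndarray]:
    """Headgroup bead offsets (relative to the phosphate-group centroid at
    the origin); phosphate oxygens average to the phosphorus z so the group
    centroid sits on the phosphate plane."""
    o_offsets = np.array(
        [(1.2, 0.0, 0.85), (-1.2, 0.0, 0.85), (0.0, 1.2, -0.85), (0.0, -1.2, -0.85)]
    )
    out: dict[str, np.ndarray] = {}
    phos = list(spec.phosphate_atoms)
    n_groups = sum(1 for a in phos if a.startswith("P"))
    p_x = [-3.0, 3.0] if n_groups == 2 else [0.0]
    gi = -1
    oi = 0
    for a in phos:
        if a.startswith("P"):
            gi += 1
            oi = 0
            out[a] = np.array([p_x[gi], 0.0, 0.0])
        else:
            out[a] = np.array([p_x[gi], 0.0, 0.0]) + o_offsets[oi % 4]
            oi += 1
    others = [a for a in spec.head_atoms if a not in out]
    for k, a in enumerate(others):
        out[a] = np.array([0.6 * ((-1) ** k), 0.8 * (k % 3 - 1), 1.4 + 0.9 * (k // 3)])
    return out


def _lipid_template(spec: LipidSpec, condition: str) -> tuple[np.ndarray, dict]:
    """Template coordinates for one upper-leaflet lipid, atoms in
    spec.atom_names() order, phosphate-group centroid at the origin and
    tails descending -z.  Also returns per-tail kink angles (degrees) and
    per-site as-built depths (A below the phosphate plane)."""
    head = _head_template(spec)
    coords: dict[str, np.ndarray] = dict(head)
    n_tails = len(spec.tails)
    x_offsets = np.linspace(-1.8 * (n_tails - 1) / 2.0, 1.8 * (n_tails - 1) / 2.0, n_tails)
    kinks: dict[int, float] = {}
    depths: dict[int, float] = {}
    for t_idx, tail in enumerate(spec.tails):
        chain = _build_chain(tail, condition)
        origin = np.array([x_offsets[t_idx], 0.6, -2.2])
        chain = chain + origin
        for name, xyz in zip(tail.carbons, chain):
            coords[name] = xyz
        h_by_carbon = dict(tail.ch_pairs)
        for cname in tail.carbons:
            for h in h_by_carbon.get(cname, ()):
                coords[h] = coords[cname] + np.array([BOND_CH, 0.0, 0.0])
        if tail.unsaturations:
            u = tail.unsaturations[0]
            kink = chain[u.position - 1]
            v1 = chain[0] - kink
            v2 = chain[-1] - kink
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            kinks[t_idx] = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            for u in tail.unsaturations:
                zpair = 0.5 * (chain[u.position - 1][2] + chain[u.position][2])
                depths[(t_idx, u.position)] = float(-zpair)  # plane is at z=0
    order = spec.atom_names()
    arr = np.array([coords[a] for a in order])
    return arr, {"kinks": kinks, "depths": depths}


# -- specification and ground truth ----------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of one synthetic bilayer trajectory."""

    seed: int
    condition: str = "cis"  # cis | trans
    composition: MembraneComposition | None = None
    box: tuple[float, float, float] = (55.0, 55.0, 80.0)
    thickness_mean: float = 38.0  # A, phosphate plane to phosphate plane
    thickness_sigma: float = 1.0  # A, per-frame per-residue phosphate z jitter
    diffusion: dict = field(default_factory=lambda: {"default": 0.65, "PVCL2": 0.30})  # A^2/ns
    tilt: tuple[tuple[float, float], ...] = ((65.0, 1.0),)  # (theta_deg, weight)
    depth_mu: float | None = None  # None: centre on each site's as-built depth
    depth_sigma: float = 2.0  # A
    surface_prob: float = 0.008  # stationary excursion probability p_s
    surface_band: tuple[float, float] = (0.0, 5.0)  # excursion depth range (A)
    persistence_frames: int = 5  # mean dwell of the excursion state
    n_frames: int = 500
    dt_ns: float = 0.2
    lattice_jitter: float = 0.15  # fraction of lattice spacing
    replicate_id: str = "rep0"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.condition not in ("cis", "trans"):
            raise ValueError("condition must be cis or trans")
        if not (0.0 <= self.surface_prob <= 1.0):
            raise ValueError("surface_prob must be in [0, 1]")
        if self.depth_sigma < 0 or self.thickness_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if any(d < 0 for d in self.diffusion.values()):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.dt_ns <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        w = sum(w for _, w in self.tilt)
        if w <= 0:
            raise ValueError("tilt weights must sum to > 0")

    def get_composition(self) -> MembraneComposition:
        return self.composition if self.composition is not None else default_composition()

    def d_of(self, resname: str) -> float:
        return float(self.diffusion.get(resname, self.diffusion.get("default", 0.0)))


@dataclass
class GroundTruth:
    """The spec echoed plus the closed-form expectations every analysis
    operation should recover."""

    spec: SyntheticSpec
    leaflets: np.ndarray  # per-residue labels
    expected_thickness: float
    expected_sch: float
    expected_diffusion: dict[str, float]  # resname -> D (A^2/ns)
    site_built_depths: np.ndarray  # per unsaturation site, A
    kink_angles: dict[tuple[str, int], float]  # (resname, tail) -> deg

    def expected_msd_slope(self, resname: str = "default") -> float:
        return 4.0 * self.spec.d_of(resname)

    def expected_surface_fraction(self, cutoff: float = 5.0) -> float:
        """p_s * (band fraction below cutoff) + (1 - p_s) * Phi over the
        bulk Gaussian, averaged over sites when the depth law is centred on
        as-built depths."""
        from scipy.stats import norm

        s = self.spec
        b0, b1 = s.surface_band
        band = float(np.clip((cutoff - b0) / (b1 - b0), 0.0, 1.0)) if b1 > b0 else 1.0
        if s.depth_mu is not None:
            mus = np.array([s.depth_mu])
        else:
            mus = self.site_built_depths
        if s.depth_sigma == 0:
            bulk = float(np.mean(mus <= cutoff))
        else:
            bulk = float(np.mean(norm.cdf((cutoff - mus) / s.depth_sigma)))
        return s.surface_prob * band + (1.0 - s.surface_prob) * bulk


def expected_sch_of_tilt(tilt) -> float:
    thetas = np.array([t for t, _ in tilt])
    weights = np.array([w for _, w in tilt], dtype=float)
    weights = weights / weights.sum()
    return float(np.sum(weights * p2(np.cos(np.radians(thetas)))))


def default_spec(condition: str, seed: int, **overrides) -> SyntheticSpec:
    """Study-condition defaults per membrane state: the trans bilayer is
    thicker, more ordered, deeper-buried and slower than the cis one."""
    presets = {
        "cis": dict(
            thickness_mean=38.0,
            diffusion={"default": 0.65, "PVCL2": 0.30},
            tilt=((65.0, 1.0),),
            surface_prob=0.008,
        ),
        "trans": dict(
            thickness_mean=40.0,
            diffusion={"default": 0.525, "PVCL2": 0.24},
            tilt=((75.0, 1.0),),
            surface_prob=0.0015,
        ),
    }
    kwargs = dict(presets[condition])
    kwargs.update(overrides)
    return SyntheticSpec(seed=seed, condition=condition, **kwargs)


# -- generator internals ---------------------------------------------------

def _streams(spec: SyntheticSpec):
    root = np.random.SeedSequence(spec.seed)
    names = ["placement", "azimuth", "build_h", "dynamics", "depth", "traj_h", "jitter"]
    children = root.spawn(len(names))
    return dict(zip(names, children))


def _sample_tilt_unit_vectors(rng: np.random.Generator, tilt, n: int) -> np.ndarray:
    thetas = np.array([t for t, _ in tilt])
    weights = np.array([w for _, w in tilt], dtype=float)
    weights /= weights.sum()
    comp = rng.choice(len(thetas), size=n, p=weights)
    theta = np.radians(thetas[comp])
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    zsign = rng.choice([-1.0, 1.0], size=n)
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), zsign * np.cos(theta)])


def _resample_hydrogens(positions: np.ndarray, topo: Topology, rng, tilt) -> None:
    n = len(topo.ch_carbon)
    u = _sample_tilt_unit_vectors(rng, tilt, n)
    positions[topo.ch_hydrogen] = positions[topo.ch_carbon] + BOND_CH * u


def _rot_z(psi: float) -> np.ndarray:
    c, s = math.cos(psi), math.sin(psi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_membrane(spec: SyntheticSpec, _head_jitter: bool = True):
    """Build the bilayer structure: two leaflets of lipids on jittered
    lattices with phosphate planes at +/- thickness/2, each lipid a rigid
    template rotated to a random azimuth.  Deterministic for a given seed.
    Returns (single-frame Trajectory, GroundTruth)."""
    comp = spec.get_composition()
    n_leaf = comp.lipids_per_leaflet
    if n_leaf < 1:
        raise ValueError("empty composition")
    box = np.asarray(spec.box, dtype=float)
    if box[0] * box[1] / n_leaf < MIN_AREA_PER_LIPID:
        raise ValueError(
            f"overfilled box: {box[0] * box[1] / n_leaf:.1f} A^2/lipid < {MIN_AREA_PER_LIPID}"
        )

    streams = _streams(spec)
    rng_place = np.random.default_rng(streams["placement"])
    rng_azim = np.random.default_rng(streams["azimuth"])
    rng_h = np.random.default_rng(streams["build_h"])
    rng_jit = np.random.default_rng(streams["jitter"])

    names, resids, resnames, leaflets = instantiate_composition(comp)
    specs = comp.specs()
    topo = annotate_topology(names, resids, resnames, specs)
    leaflets = np.array(leaflets, dtype=object)
    topo.leaflets = leaflets

    templates = {rn: _lipid_template(specs[rn], spec.condition) for rn in specs}

    # jittered square lattice per leaflet, shuffled so types are mixed
    n_side = int(np.ceil(np.sqrt(n_leaf)))
    sx, sy = box[0] / n_side, box[1] / n_side
    grid = np.array(
        [((i + 0.5) * sx, (j + 0.5) * sy) for i in range(n_side) for j in range(n_side)]
    )

    positions = np.zeros((topo.n_atoms, 3))
    half = spec.thickness_mean / 2.0
    kink_angles: dict[tuple[str, int], float] = {}
    site_depths = []
    res_by_leaflet = {
        leaf: [r for r in range(topo.n_residues) if leaflets[r] == leaf]
        for leaf in ("upper", "lower")
    }
    for leaf, zsign in (("upper", 1.0), ("lower", -1.0)):
        rs = res_by_leaflet[leaf]
        sites_xy = grid[rng_place.permutation(len(grid))[: len(rs)]]
        sites_xy = sites_xy + rng_place.uniform(
            -spec.lattice_jitter, spec.lattice_jitter, size=sites_xy.shape
        ) * np.array([sx, sy])
        for r, xy in zip(rs, sites_xy):
            rn = topo.residue_names[r]
            template, meta = templates[rn]
            xyz = template.copy()
            if zsign < 0:
                xyz[:, 2] *= -1.0
            xyz = xyz @ _rot_z(rng_azim.uniform(0.0, 2.0 * np.pi)).T
            zjit = rng_jit.normal(0.0, spec.thickness_sigma) if _head_jitter else 0.0
            xyz += np.array([xy[0], xy[1], zsign * half + zjit])
            positions[topo.residue_atoms(r)] = xyz
            for t_idx, ang in meta["kinks"].items():
                kink_angles[(rn, t_idx)] = ang
    # as-built site depths, in topology site order (template depths are
    # invariant under the rigid placement, so read them off the templates)
    for s in topo.sites:
        _, meta = templates[s.residue_name]
        site_depths.append(meta["depths"][(s.tail_index, s.position)])

    _resample_hydrogens(positions, topo, rng_h, spec.tilt)

    traj = Trajectory(
        topo,
        positions[None, :, :],
        box[None, :],
        np.array([0.0]),
        replicate_id=spec.replicate_id,
        condition=spec.condition,
    )
    truth = GroundTruth(
        spec=spec,
        leaflets=leaflets,
        expected_thickness=spec.thickness_mean,
        expected_sch=expected_sch_of_tilt(spec.tilt),
        expected_diffusion={rn: spec.d_of(rn) for rn in specs},
        site_built_depths=np.array(site_depths),
        kink_angles=kink_angles,
    )
    return traj, truth


def simulate_trajectory(spec: SyntheticSpec):
    """Generate a full trajectory from the built membrane.

    Per frame: rigid per-residue lateral Brownian steps, fresh phosphate
    z jitter, double-bond depth redrawn from the two-state mixture (the
    four dihedral carbons and their hydrogens translate rigidly in z, so
    the cis/trans state is preserved), C-H vectors redrawn from the tilt
    law, and every residue wrapped into the box as a whole.
    """
    built, truth = build_membrane(spec, _head_jitter=False)
    topo = built.topology
    base = np.asarray(built.coords[0], dtype=float)
    box = np.asarray(spec.box, dtype=float)
    F = spec.n_frames
    streams = _streams(spec)

    # per-residue Brownian displacements (counter-based child stream each)
    lipid_res = topo.lipid_residue_indices()
    disp = np.zeros((F, topo.n_residues, 2))
    dyn_children = streams["dynamics"].spawn(topo.n_residues)
    for r in lipid_res:
        d = spec.d_of(topo.residue_names[r])
        rng = np.random.default_rng(dyn_children[r])
        steps = rng.normal(0.0, math.sqrt(2.0 * d * spec.dt_ns), size=(F - 1, 2))
        disp[1:, r] = np.cumsum(steps, axis=0)

    # per-frame phosphate-group z jitter, fresh each frame
    rng_jit = np.random.default_rng(streams["jitter"])
    head_jitter = rng_jit.normal(0.0, spec.thickness_sigma, size=(F, topo.n_residues))

    # two-state depth chains per site
    sites = topo.sites
    S = len(sites)
    depth_children = streams["depth"].spawn(max(S, 1))
    p_s = spec.surface_prob
    stay_surf = 1.0 - 1.0 / max(spec.persistence_frames, 1)
    leave_bulk = (
        (1.0 - stay_surf) * p_s / (1.0 - p_s) if p_s < 1.0 else 1.0
    )  # stationary prob of the surface state is exactly p_s
    depths = np.zeros((F, S))
    b0, b1 = spec.surface_band
    for j, site in enumerate(sites):
        rng = np.random.default_rng(depth_children[j])
        mu = spec.depth_mu if spec.depth_mu is not None else truth.site_built_depths[j]
        state = rng.random() < p_s
        for f in range(F):
            if state:
                depths[f, j] = rng.uniform(b0, b1)
                state = rng.random() < stay_surf
            else:
                depths[f, j] = rng.normal(mu, spec.depth_sigma)
                state = rng.random() < leave_bulk

    # site atom groups: 4 dihedral carbons + their hydrogens (rigid z shift)
    groups = [
        list(s.dihedral_atom_indices)
        + [h for c in s.dihedral_atom_indices for h in topo.hydrogens_of(c)]
        for s in sites
    ]
    bond_pairs = np.array([s.bond_carbon_indices for s in sites], dtype=int).reshape(S, 2)
    site_leaf_sign = np.array(
        [1.0 if topo.leaflets[s.residue_index] == "upper" else -1.0 for s in sites]
    )

    is_head = ~(topo.is_tail_carbon | topo.is_hydrogen) & topo.is_lipid
    rng_h = np.random.default_rng(streams["traj_h"])
    atom_res = topo.residue_index
    p_up = topo.is_phosphorus & topo.leaflet_mask("upper")
    p_lo = topo.is_phosphorus & topo.leaflet_mask("lower")

    coords = np.empty((F, topo.n_atoms, 3), dtype=np.float32)
    heavy_lipid = topo.is_heavy
    for f in range(F):
        pos = base.copy()
        pos[:, :2] += disp[f, atom_res]
        pos[is_head, 2] += head_jitter[f, atom_res[is_head]]
        if S:
            plane_up = pos[p_up, 2].mean()
            plane_lo = pos[p_lo, 2].mean()
            planes = np.where(site_leaf_sign > 0, plane_up, plane_lo)
            target = planes - site_leaf_sign * depths[f]
            current = pos[bond_pairs, 2].mean(axis=1)
            dz = target - current
            for j, grp in enumerate(groups):
                pos[grp, 2] += dz[j]
        _resample_hydrogens(pos, topo, rng_h, spec.tilt)
        # wrap each residue as a whole by its heavy-atom centroid
        cx = np.bincount(atom_res[heavy_lipid], weights=pos[heavy_lipid, 0],
                         minlength=topo.n_residues)
        cy = np.bincount(atom_res[heavy_lipid], weights=pos[heavy_lipid, 1],
                         minlength=topo.n_residues)
        cnt = np.bincount(atom_res[heavy_lipid], minlength=topo.n_residues)
        ok = cnt > 0
        cent = np.zeros((topo.n_residues, 2))
        cent[ok, 0] = cx[ok] / cnt[ok]
        cent[ok, 1] = cy[ok] / cnt[ok]
        shift = -np.floor(cent / box[:2]) * box[:2]
        shift[~ok] = 0.0
        pos[:, :2] += shift[atom_res]
        coords[f] = pos
    times = np.arange(F) * spec.dt_ns
    traj = Trajectory(
        topo, coords, np.tile(box, (F, 1)), times,
        replicate_id=spec.replicate_id, condition=spec.condition,
    )
    return traj, truth


# -- replicate sets --------------------------------------------------------

@dataclass(frozen=True)
class ReplicateHandle:
    """A labeled, seeded replicate; ``load()`` generates its trajectory."""

    condition: str
    replicate_id: str
    spec: SyntheticSpec

    def load(self):
        return simulate_trajectory(self.spec)


def paired_condition_set(
    spec_cis: SyntheticSpec, spec_trans: SyntheticSpec, n_replicates: int = 5
) -> list[ReplicateHandle]:
    """Build the paired cis/trans replicate set: ``n_replicates`` seeded
    trajectories per condition, seeds derived independently from each
    spec's base seed."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    handles = []
    all_seeds = []
    for spec in (spec_cis, spec_trans):
        seeds = np.random.SeedSequence(spec.seed).generate_state(n_replicates) % (2**31)
        for r, s in enumerate(seeds):
            rid = f"{spec.condition}-rep{r}"
            handles.append(
                ReplicateHandle(
                    condition=spec.condition,
                    replicate_id=rid,
                    spec=replace(spec, seed=int(s), replicate_id=rid),
                )
            )
            all_seeds.append(int(s))
    if len(set(all_seeds)) != len(all_seeds):
        raise ValueError("duplicate seeds across replicates")
    return handles


def brownian_tracks(
    d: float, n_particles: int, n_steps: int, dt_ns: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bare 2D Brownian tracks (n_steps+1, n_particles, 2) with known D and
    their times; the minimal oracle substrate for MSD/diffusion recovery."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(2.0 * d * dt_ns), size=(n_steps, n_particles, 2))
    tracks = np.concatenate(
        [np.zeros((1, n_particles, 2)), np.cumsum(steps, axis=0)], axis=0
    )
    return tracks, np.arange(n_steps + 1) * dt_ns
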