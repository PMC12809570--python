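"""Domain types shared by the whole pipeline.

The package analyses two-leaflet phospholipid patches (the default
composition models a *Pseudomonas putida* inner membrane: PE, PG and
cardiolipin species with palmitoyl/palmitoleoyl/oleoyl tails).  Atom roles
(phosphate group, tail carbons, double-bond carbons, C-H pairs) are not
inferred from chemistry but resolved from a shipped, editable
lipid-definition table keyed by residue name, following CHARMM36-style atom
naming.

Units: coordinates are Angstrom, times nanoseconds, throughout the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Unsaturation",
    "TailSpec",
    "LipidSpec",
    "MembraneComposition",
    "Frame",
    "Topology",
    "Trajectory",
    "UnsaturationSite",
    "load_lipid_definitions",
    "default_lipid_specs",
    "default_composition",
    "annotate_topology",
]

#: residue names silently tagged as non-lipid instead of raising
DEFAULT_SOLVENT_RESNAMES = frozenset(
    {"SOL", "TIP3", "TIP3P", "WAT", "HOH", "SPC", "CLA", "SOD", "POT", "CAL", "NA", "CL", "K"}
)


@dataclass(frozen=True)
class Unsaturation:
    """One C=C double bond in an acyl tail.

    ``position`` is the chain-local index of the first double-bond carbon
    (e.g. 9 for a d9 bond between carbons 9 and 10); ``dihedral_atoms`` are
    the four atom names C(i-1), C(i), C(i+1), C(i+2) whose torsion defines
    the cis/trans state.
    """

    position: int
    dihedral_atoms: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.dihedral_atoms) != 4 or len(set(self.dihedral_atoms)) != 4:
            raise ValueError("unsaturation needs 4 distinct dihedral atom names")


@dataclass(frozen=True)
class TailSpec:
    """One acyl tail: an ordered carbon chain with optional double bonds."""

    carbons: tuple[str, ...]
    unsaturations: tuple[Unsaturation, ...] = ()
    ch_pairs: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.carbons)
        if n < 2:
            raise ValueError("a tail needs at least 2 carbons")
        for u in self.unsaturations:
            # dihedral needs carbons position-1 .. position+2 inside the chain
            if not (2 <= u.position <= n - 2):
                raise ValueError(
                    f"unsaturation position {u.position} not interior to a {n}-carbon tail"
                )
            expected = self.carbons[u.position - 2 : u.position + 2]
            if tuple(u.dihedral_atoms) != tuple(expected):
                raise ValueError(
                    f"dihedral atoms {u.dihedral_atoms} do not match chain carbons {expected}"
                )
        carbon_set = set(self.carbons)
        for carbon, hydrogens in self.ch_pairs:
            if carbon not in carbon_set:
                raise ValueError(f"ch_pair carbon {carbon} not in tail")
            if not hydrogens:
                raise ValueError(f"ch_pair for {carbon} lists no hydrogens")

    @property
    def n_carbons(self) -> int:
        return len(self.carbons)

    @property
    def carbonyl_carbon(self) -> str:
        return self.carbons[0]

    @property
    def terminal_carbon(self) -> str:
        return self.carbons[-1]

    @property
    def descriptor(self) -> str:
        """Tail shorthand like ``16:1``."""
        return f"{self.n_carbons}:{len(self.unsaturations)}"


@dataclass(frozen=True)
class LipidSpec:
    """Role annotation for one lipid residue type."""

    residue_name: str
    headgroup_class: str  # PE | PG | CL
    tails: tuple[TailSpec, ...]
    phosphate_atoms: tuple[str, ...]
    head_atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.tails:
            raise ValueError(f"{self.residue_name}: at least one tail required")
        if not self.phosphate_atoms:
            raise ValueError(f"{self.residue_name}: phosphate_atoms must be non-empty")
        if self.headgroup_class not in ("PE", "PG", "CL"):
            raise ValueError(f"{self.residue_name}: unknown headgroup class {self.headgroup_class}")

    @property
    def carbonyl_carbons(self) -> tuple[str, ...]:
        return tuple(t.carbonyl_carbon for t in self.tails)

    @property
    def terminal_carbons(self) -> tuple[str, ...]:
        return tuple(t.terminal_carbon for t in self.tails)

    @property
    def n_unsaturations(self) -> int:
        return sum(len(t.unsaturations) for t in self.tails)

    def atom_names(self) -> list[str]:
        """Full ordered atom list for one residue instance (head first, then
        each tail's carbons with their hydrogens interleaved)."""
        names = list(self.head_atoms)
        for tail in self.tails:
            h_by_carbon = dict(tail.ch_pairs)
            for c in tail.carbons:
                names.append(c)
                names.extend(h_by_carbon.get(c, ()))
        return names


@dataclass(frozen=True)
class MembraneComposition:
    """Per-leaflet lipid counts; the bilayer doubles these over two leaflets."""

    entries: tuple[tuple[LipidSpec, int], ...]

    def __post_init__(self) -> None:
        for spec, count in self.entries:
            if count < 0:
                raise ValueError(f"negative count for {spec.residue_name}")

    @property
    def lipids_per_leaflet(self) -> int:
        return sum(c for _, c in self.entries)

    @property
    def total_lipids(self) -> int:
        return 2 * self.lipids_per_leaflet

    def counts(self) -> dict[str, int]:
        return {spec.residue_name: count for spec, count in self.entries}

    def specs(self) -> dict[str, LipidSpec]:
        return {spec.residue_name: spec for spec, _ in self.entries}


@dataclass
class Frame:
    """One trajectory frame: positions (N, 3) in Angstrom plus an
    orthorhombic box (Lx, Ly, Lz) and a time stamp in ns."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.box.copy(), self.time)


@dataclass(frozen=True)
class UnsaturationSite:
    """One double bond instance in one residue of a resolved topology."""

    residue_index: int
    residue_name: str
    tail_index: int
    position: int
    dihedral_atom_indices: tuple[int, int, int, int]
    carbonyl_index: int
    terminal_index: int
    state: str = "unknown"  # cis | trans | unknown

    def __post_init__(self) -> None:
        if len(set(self.dihedral_atom_indices)) != 4:
            raise ValueError("dihedral atom indices must be distinct")

    @property
    def bond_carbon_indices(self) -> tuple[int, int]:
        return self.dihedral_atom_indices[1], self.dihedral_atom_indices[2]

    def with_state(self, state: str) -> "UnsaturationSite":
        return replace(self, state=state)


class Topology:
    """Resolved atom-level annotation of a membrane system.

    Built by :func:`annotate_topology`; holds per-atom role masks, the
    per-residue leaflet assignment slot, every unsaturation site, the C-H
    pair table, and an intra-residue bond list sufficient for the
    isomerization operator (chain bonds plus C-H bonds).
    """

    def __init__(
        self,
        names: np.ndarray,
        resids: np.ndarray,
        resnames: np.ndarray,
        residue_index: np.ndarray,
        residue_names: np.ndarray,
        specs: Mapping[str, LipidSpec],
    ) -> None:
        self.names = names
        self.resids = resids
        self.resnames = resnames
        self.residue_index = residue_index
        self.residue_names = residue_names
        self.specs = dict(specs)

        n_atoms = len(names)
        self.n_atoms = n_atoms
        self.n_residues = len(residue_names)
        self.residue_is_lipid = np.array([rn in specs for rn in residue_names])

        self.is_lipid = self.residue_is_lipid[residue_index]
        self.is_hydrogen = np.array([n.startswith("H") for n in names]) & self.is_lipid
        self.is_heavy = self.is_lipid & ~self.is_hydrogen
        self.is_phosphate = np.zeros(n_atoms, dtype=bool)
        self.is_phosphorus = np.zeros(n_atoms, dtype=bool)
        self.is_tail_carbon = np.zeros(n_atoms, dtype=bool)
        self.is_double_bond_carbon = np.zeros(n_atoms, dtype=bool)

        self.sites: list[UnsaturationSite] = []
        self.bonds: dict[int, list[int]] = {}
        # flat C-H pair table (one row per pair) with grouping labels
        ch_c: list[int] = []
        ch_h: list[int] = []
        ch_res: list[int] = []
        ch_resname: list[str] = []
        ch_tail: list[int] = []
        ch_pos: list[int] = []

        # index atoms of each residue by name
        for r in range(self.n_residues):
            rn = residue_names[r]
            if rn not in specs:
                continue
            atom_idx = np.nonzero(residue_index == r)[0]
            by_name = {names[i]: i for i in atom_idx}
            spec = specs[rn]

            def need(atom: str) -> int:
                try:
                    return by_name[atom]
                except KeyError:
                    raise KeyError(
                        f"residue {rn} (resid {resids[atom_idx[0]]}): missing role atom {atom!r}"
                    ) from None

            for a in spec.phosphate_atoms:
                i = need(a)
                self.is_phosphate[i] = True
                if names[i].startswith("P"):
                    self.is_phosphorus[i] = True
            for t_idx, tail in enumerate(spec.tails):
                carbon_idx = [need(c) for c in tail.carbons]
                self.is_tail_carbon[carbon_idx] = True
                for a, b in zip(carbon_idx[:-1], carbon_idx[1:]):
                    self.bonds.setdefault(a, []).append(b)
                    self.bonds.setdefault(b, []).append(a)
                pos_of = {c: k + 1 for k, c in enumerate(tail.carbons)}
                for carbon, hydrogens in tail.ch_pairs:
                    ci = need(carbon)
                    for h in hydrogens:
                        hi = need(h)
                        self.bonds.setdefault(ci, []).append(hi)
                        self.bonds.setdefault(hi, []).append(ci)
                        ch_c.append(ci)
                        ch_h.append(hi)
                        ch_res.append(r)
                        ch_resname.append(rn)
                        ch_tail.append(t_idx)
                        ch_pos.append(pos_of[carbon])
                for u in tail.unsaturations:
                    d_idx = tuple(need(a) for a in u.dihedral_atoms)
                    self.is_double_bond_carbon[d_idx[1]] = True
                    self.is_double_bond_carbon[d_idx[2]] = True
                    self.sites.append(
                        UnsaturationSite(
                            residue_index=r,
                            residue_name=rn,
                            tail_index=t_idx,
                            position=u.position,
                            dihedral_atom_indices=d_idx,
                            carbonyl_index=need(tail.carbonyl_carbon),
                            terminal_index=need(tail.terminal_carbon),
                        )
                    )

        self.ch_carbon = np.array(ch_c, dtype=int)
        self.ch_hydrogen = np.array(ch_h, dtype=int)
        self.ch_residue = np.array(ch_res, dtype=int)
        self.ch_resname = np.array(ch_resname, dtype=object)
        self.ch_tail = np.array(ch_tail, dtype=int)
        self.ch_position = np.array(ch_pos, dtype=int)

        #: per-residue leaflet label ("upper"/"lower"/""), filled by
        #: geometry.assign_leaflets or by the synthetic generator
        self.leaflets: np.ndarray = np.full(self.n_residues, "", dtype=object)

    # -- convenience selections -------------------------------------------
    def lipid_residue_indices(self) -> np.ndarray:
        return np.nonzero(self.residue_is_lipid)[0]

    def residue_atoms(self, r: int) -> np.ndarray:
        return np.nonzero(self.residue_index == r)[0]

    def leaflet_mask(self, leaflet: str) -> np.ndarray:
        """Per-atom mask for atoms belonging to residues of one leaflet."""
        res_mask = self.leaflets == leaflet
        return res_mask[self.residue_index] & self.is_lipid

    def hydrogens_of(self, atom_index: int) -> list[int]:
        return [j for j in self.bonds.get(atom_index, []) if self.is_hydrogen[j]]


@dataclass
class Trajectory:
    """An annotated trajectory: stacked coordinates plus per-frame boxes.

    ``coords`` has shape (n_frames, n_atoms, 3); ``boxes`` (n_frames, 3);
    ``times`` (n_frames,) in ns, strictly increasing.
    """

    topology: Topology
    coords: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    replicate_id: str = "rep0"
    condition: str = "other"  # cis | trans | other

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if len(self.boxes) != len(self.coords) or len(self.times) != len(self.coords):
            raise ValueError("boxes/times length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        # always a copy: frames are freely mutable without touching the stack
        return Frame(np.array(self.coords[i], dtype=float), self.boxes[i].copy(), self.times[i])

    def frames(self) -> Iterable[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


# -- lipid-definition table -----------------------------------------------

def _tail_from_dict(d: Mapping) -> TailSpec:
    unsats = tuple(
        Unsaturation(int(u["position"]), tuple(u["dihedral"])) for u in d.get("unsaturations", [])
    )
    ch = tuple((c, tuple(hs)) for c, hs in d.get("ch_pairs", {}).items())
    return TailSpec(carbons=tuple(d["carbons"]), unsaturations=unsats, ch_pairs=ch)


def load_lipid_definitions(path=None) -> dict[str, LipidSpec]:
    """Load the lipid-definition table (shipped default or a user file)."""
    if path is None:
        ref = importlib.resources.files("memiso").joinpath("data/lipids.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = {}
    for resname, d in raw.items():
        specs[resname] = LipidSpec(
            residue_name=resname,
            headgroup_class=d["headgroup_class"],
            tails=tuple(_tail_from_dict(t) for t in d["tails"]),
            phosphate_atoms=tuple(d["phosphate_atoms"]),
            head_atoms=tuple(d.get("head_atoms", ())),
        )
    return specs


def default_lipid_specs() -> dict[str, LipidSpec]:
    return load_lipid_definitions()


#: per-leaflet counts of the default membrane model
DEFAULT_COUNTS = (("PYPE", 10), ("POPE", 7), ("YOPE", 14), ("PYPG", 11), ("POPG", 6), ("PVCL2", 2))


def default_composition(specs: Mapping[str, LipidSpec] | None = None) -> MembraneComposition:
    """The default per-leaflet composition of the bacterial membrane model:
    10 PYPE, 7 POPE, 14 YOPE, 11 PYPG, 6 POPG, 2 cardiolipin (50 per
    leaflet, 100 lipids over the bilayer)."""
    if specs is None:
        specs = default_lipid_specs()
    return MembraneComposition(tuple((specs[name], n) for name, n in DEFAULT_COUNTS))


# -- topology annotation ---------------------------------------------------

def annotate_topology(
    names: Sequence[str],
    resids: Sequence[int],
    resnames: Sequence[str],
    specs: Mapping[str, LipidSpec],
    solvent_resnames: Iterable[str] = DEFAULT_SOLVENT_RESNAMES,
) -> Topology:
    """Resolve a raw (name, resid, resname) atom table against lipid specs.

    Every residue whose name matches a spec is annotated atom-by-atom
    (phosphate / tail carbon / double-bond member / hydrogen).  Residues in
    ``solvent_resnames`` are tagged non-lipid; any other unmatched residue
    name raises.
    """
    names = np.asarray(names, dtype=object)
    resids = np.asarray(resids, dtype=int)
    resnames = np.asarray(resnames, dtype=object)
    if not (len(names) == len(resids) == len(resnames)):
        raise ValueError("names/resids/resnames length mismatch")
    if len(names) == 0:
        raise ValueError("empty topology")

    # contiguous residue segmentation on (resid, resname) change
    change = np.ones(len(names), dtype=bool)
    change[1:] = (resids[1:] != resids[:-1]) | (resnames[1:] != resnames[:-1])
    residue_index = np.cumsum(change) - 1
    starts = np.nonzero(change)[0]
    residue_names = resnames[starts]

    solvent = set(solvent_resnames)
    unknown = sorted({rn for rn in residue_names if rn not in specs and rn not in solvent})
    if unknown:
        raise KeyError(f"unknown lipid residue name(s) with no spec: {', '.join(unknown)}")

    return Topology(names, resids, resnames, residue_index, residue_names, specs)


def instantiate_composition(
    composition: MembraneComposition, leaflets: Sequence[str] = ("upper", "lower")
) -> tuple[list[str], list[int], list[str], list[str]]:
    """Expand a composition into flat per-atom (names, resids, resnames) plus
    a per-residue leaflet label list, ordered leaflet-major."""
    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    res_leaflets: list[str] = []
    resid = 0
    for leaflet in leaflets:
        for spec, count in composition.entries:
            for _ in range(count):
                resid += 1
                atoms = spec.atom_names()
                names.extend(atoms)
                resids.extend([resid] * len(atoms))
                resnames.extend([spec.residue_name] * len(atoms))
                res_leaflets.append(leaflet)
    return names, resids, resnames, res_leaflets
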