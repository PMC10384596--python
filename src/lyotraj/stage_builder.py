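"""Five-stage freeze-drying system construction.

The lyophilization pipeline prepares a protein system through five
consecutive stages, each consuming the final configuration of the previous
one:

RT   room temperature: the protein is solvated in a cubic box with a 15 A
     protein-to-face margin, excipients and counterions are added.
F    freezing: the box faces are covered with hexagonal (Ih) ice slabs.
1D   primary drying: bulk water further than 3 A from the protein is removed
     (sublimation) and the system is placed in a large vacuum box (50 A
     margin).
2D   secondary drying: only residual waters that coincide with crystal-water
     positions of the reference X-ray structure are retained (desorption).
REC  reconstitution: the dried system is re-solvated in a fresh 15 A box.

A separate coarse-grained (CG) preparation replicates a monomer on a
2x2x2 grid at 85 A centre-of-mass spacing with a 7.5 A box margin; it feeds
the protein-protein interaction statistics.

All geometry lives in :class:`StageConfig`; concentrations follow either a
molar (mM) or a mass-fraction (% w/w, excipient over excipient + water)
specification, and the system is neutralised with Na+ or Cl- counterions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_io import (
    Atom,
    SimulationBox,
    StructureModel,
    CHAIN_ALPHABET,
    STAGES,
)

logger = logging.getLogger("lyotraj")

AVOGADRO = 6.02214076e23  # 1/mol
WATER_MOLAR_MASS = 18.015  # g/mol

# Ice Ih lattice constants (hexagonal cell, 4 molecules per unit cell)
ICE_A = 4.497  # A
ICE_C = 7.322  # A
# O-H bond length and H-O-H angle of the rigid water geometry used for ice
OH_BOND = 0.9572  # A
HOH_ANGLE = np.deg2rad(104.52)


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class StageConfig:
    """Geometric parameters of one pipeline stage.

    Defaults implement the standard protocol: box margins of 15 A for the
    solvated RT/REC stages, 7.5 A for the CG multimer stage and 50 A for the
    vacuum drying stages; a 3 A water-stripping cutoff for primary drying;
    a 1.5 A crystal-water match cutoff for secondary drying; a 2.4 A clash
    cutoff wherever new molecules are inserted; a 2x2x2 CG replication grid
    at 85 A spacing; a 4 A inter-monomer contact cutoff and a 25% heatmap
    retention filter.
    """

    stage: str = "RT"
    box_margin: float = 15.0
    strip_cutoff: float = 3.0
    residual_match_cutoff: float = 1.5
    clash_cutoff: float = 2.4
    cg_grid: tuple[int, int, int] = (2, 2, 2)
    cg_spacing: float = 85.0
    heatmap_filter: float = 0.25
    contact_cutoff: float = 4.0
    water_grid_spacing: float = 3.1
    ice_thickness: float = 15.0

    #: stage-specific default margins
    DEFAULT_MARGINS = {"RT": 15.0, "REC": 15.0, "CG": 7.5, "1D": 50.0, "2D": 50.0,
                       "F": 15.0}

    def __post_init__(self) -> None:
        if self.stage not in STAGES + ("CG",):
            raise ValueError(f"unknown stage {self.stage!r}")
        for name in ("box_margin", "strip_cutoff", "residual_match_cutoff",
                     "clash_cutoff", "cg_spacing", "contact_cutoff",
                     "water_grid_spacing", "ice_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.heatmap_filter < 1:
            raise ValueError("heatmap_filter must lie in (0, 1)")

    @classmethod
    def for_stage(cls, stage: str, **overrides) -> "StageConfig":
        margin = overrides.pop("box_margin", cls.DEFAULT_MARGINS[stage])
        return cls(stage=stage, box_margin=margin, **overrides)


@dataclass
class ExcipientSpec:
    """An excipient species: arginine (net charge +1), tranexamic acid or
    sucrose (both neutral), or a custom molecule.

    Exactly one concentration mode is set: ``conc_mM`` (millimolar) or
    ``mass_fraction`` (% w/w as a fraction, excipient over excipient+water).
    """

    name: str
    molar_mass: float
    net_charge: int
    conc_mM: float | None = None
    mass_fraction: float | None = None

    #: built-in species
    KNOWN = {
        "ARG": (174.20, +1),
        "TXA": (157.21, 0),
        "SUC": (342.30, 0),
    }

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if (self.conc_mM is None) == (self.mass_fraction is None):
            raise ValueError("exactly one of conc_mM / mass_fraction must be set")

    @classmethod
    def of(cls, name: str, conc_mM: float | None = None,
           mass_fraction: float | None = None) -> "ExcipientSpec":
        mm, q = cls.KNOWN[name.upper()]
        return cls(name=name.upper(), molar_mass=mm, net_charge=q,
                   conc_mM=conc_mM, mass_fraction=mass_fraction)


@dataclass
class IonInventory:
    """Counterion bookkeeping; a neutralised system never mixes Na+ and Cl-."""

    n_na: int = 0
    n_cl: int = 0

    def __post_init__(self) -> None:
        if self.n_na < 0 or self.n_cl < 0:
            raise ValueError("ion counts must be non-negative")
        if self.n_na > 0 and self.n_cl > 0:
            raise ValueError("counterion inventory must not mix Na+ and Cl-")

    @property
    def net_charge(self) -> int:
        return self.n_na - self.n_cl


# ---------------------------------------------------------------------------
# Box definition and monomer replication
# ---------------------------------------------------------------------------


def define_box(model: StructureModel, margin: float, cubic: bool = True) -> SimulationBox:
    """Define a simulation box around the protein with the given
    protein-to-face margin.

    The minimum distance from any protein atom to the nearest box face
    equals ``margin``.  With ``cubic=True`` all sides equal the maximum axis
    extent plus twice the margin and the protein is centred.
    """
    prot = model.select(role="protein")
    if not prot:
        raise ValueError("model has no protein atoms")
    xyz = model.coords[prot]
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    extent = hi - lo
    center = (lo + hi) / 2
    if cubic:
        side = float(extent.max()) + 2 * margin
        lengths = np.full(3, side)
    else:
        lengths = extent + 2 * margin
    origin = center - lengths / 2
    return SimulationBox(lengths=lengths, origin=origin)


def min_distance_to_faces(model: StructureModel, box: SimulationBox,
                          role: str = "protein") -> float:
    """Smallest distance from any atom of the given role to a box face."""
    idx = model.select(role=role)
    xyz = model.coords[idx]
    lo = xyz - box.origin
    hi = (box.origin + box.lengths) - xyz
    return float(min(lo.min(), hi.min()))


def replicate_monomers(monomer: StructureModel, grid: tuple[int, int, int] = (2, 2, 2),
                       spacing: float = 85.0) -> StructureModel:
    """Replicate a single-chain monomer on a regular grid.

    Produces ``nx*ny*nz`` rigid copies with distinct chain ids whose centres
    of mass are ``spacing`` apart along each occupied axis; internal geometry
    is preserved exactly.
    """
    chains = monomer.chain_ids
    if len(chains) != 1:
        raise ValueError(f"monomer must be single-chain, got chains {chains}")
    if any(g < 1 for g in grid):
        raise ValueError("grid dimensions must be >= 1")
    n_copies = int(np.prod(grid))
    if n_copies > len(CHAIN_ALPHABET):
        raise ValueError("chain-id alphabet exhausted")
    atoms: list[Atom] = []
    k = 0
    for ix in range(grid[0]):
        for iy in range(grid[1]):
            for iz in range(grid[2]):
                shift = np.array([ix, iy, iz], dtype=float) * spacing
                cid = CHAIN_ALPHABET[k]
                k += 1
                for a in monomer.atoms:
                    atoms.append(replace(a, chain_id=cid, coords=a.coords + shift))
    return StructureModel(atoms, box=monomer.box)


# ---------------------------------------------------------------------------
# Excipient counting and neutralisation
# ---------------------------------------------------------------------------


def count_excipients_molar(box: SimulationBox, conc_mM: float) -> int:
    """Number of excipient molecules for a molar concentration in this box:
    round(C * V * N_A) with C in mol/L and V the box volume in litres."""
    if conc_mM < 0:
        raise ValueError("concentration must be non-negative")
    n = conc_mM * 1e-3 * box.volume_litres * AVOGADRO
    return int(round(n))


def count_excipients_ww(n_waters: int, spec: ExcipientSpec, fraction: float,
                        water_molar_mass: float = WATER_MOLAR_MASS) -> int:
    """Number of excipient molecules for a mass-fraction (% w/w) loading.

    The basis is excipient mass over (excipient + water) mass:
    N = round( f/(1-f) * n_waters * M_water / M_excipient ).
    """
    if not 0 <= fraction < 1:
        raise ValueError("mass fraction must lie in [0, 1)")
    n = fraction / (1.0 - fraction) * n_waters * water_molar_mass / spec.molar_mass
    return int(round(n))


def neutralize(solute_net_charge: int | float) -> IonInventory:
    """Counterions required to neutralise the solute (protein + excipients):
    a positive total charge is balanced with Cl-, a negative one with Na+."""
    if float(solute_net_charge) != int(solute_net_charge):
        raise ValueError("solute net charge must be an integer number of e")
    q = int(solute_net_charge)
    if q > 0:
        return IonInventory(n_cl=q)
    if q < 0:
        return IonInventory(n_na=-q)
    return IonInventory()


# ---------------------------------------------------------------------------
# Ice construction
# ---------------------------------------------------------------------------

# Fractional oxygen positions of the wurtzite-type oxygen sublattice of ice Ih
# (hexagonal cell, 4 molecules per cell, internal parameter u = 3/8).
_ICE_FRAC = np.array([
    [1 / 3, 2 / 3, 0.0],
    [1 / 3, 2 / 3, 3 / 8],
    [2 / 3, 1 / 3, 1 / 2],
    [2 / 3, 1 / 3, 7 / 8],
])

# Hexagonal lattice vectors
_ICE_CELL = np.array([
    [ICE_A, 0.0, 0.0],
    [-ICE_A / 2, ICE_A * np.sqrt(3) / 2, 0.0],
    [0.0, 0.0, ICE_C],
])


def _water_hydrogens(oxygen: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Two hydrogens at ideal intramolecular geometry, random orientation."""
    # random orthonormal pair
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = rng.normal(size=3)
    v -= u * (u @ v)
    v /= np.linalg.norm(v)
    half = HOH_ANGLE / 2
    h1 = oxygen + OH_BOND * (np.cos(half) * u + np.sin(half) * v)
    h2 = oxygen + OH_BOND * (np.cos(half) * u - np.sin(half) * v)
    return [h1, h2]


def build_ice_block(nx: int, ny: int, nz: int, seed: int = 0) -> StructureModel:
    """Build an ice-Ih block of nx x ny x nz hexagonal unit cells.

    Oxygens sit on the wurtzite lattice (a = 4.497 A, c = 7.322 A, four
    molecules per cell, nearest O-O distance ~2.75 A); hydrogens are placed
    at ideal rigid-water geometry with randomised orientations (proton
    disorder without Bernal-Fowler ring constraints).
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("unit-cell counts must be >= 1")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    res = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                cell_origin = ix * _ICE_CELL[0] + iy * _ICE_CELL[1] + iz * _ICE_CELL[2]
                for frac in _ICE_FRAC:
                    o = cell_origin + frac @ _ICE_CELL
                    res += 1
                    atoms.append(Atom("O", "OW", res, "ICE", "i", o, role="ice"))
                    for hn, h in enumerate(_water_hydrogens(o, rng), start=1):
                        atoms.append(Atom("H", f"HW{hn}", res, "ICE", "i", h, role="ice"))
    return StructureModel(atoms)


def place_ice_blocks(system: StructureModel, thickness: float | None = None,
                     clash_cutoff: float = 2.4, seed: int = 0) -> StructureModel:
    """Cover the box surfaces with three hexagonal ice slabs (one per axis,
    on the +x, +y and +z faces) to induce freezing.

    Ice molecules whose oxygen falls within ``clash_cutoff`` of any existing
    atom, or inside a previously placed slab's region, are deleted (a
    deterministic stand-in for relaxing bad contacts by minimisation).
    """
    if system.box is None:
        raise ValueError("system must carry a box to place ice on its faces")
    box = system.box
    thickness = thickness if thickness is not None else 15.0
    existing = system.coords
    tree = cKDTree(existing) if len(existing) else None

    new_atoms = [replace(a, coords=a.coords.copy()) for a in system.atoms]
    occupied_regions: list[tuple[np.ndarray, np.ndarray]] = []
    res_offset = max((a.residue_index for a in system.atoms if a.chain_id == "i"),
                     default=0)

    for axis in range(3):
        # slab region: spans the full face, sits outside the positive face
        lo = box.origin.copy()
        hi = box.origin + box.lengths
        lo[axis] = hi[axis]
        hi[axis] = hi[axis] + thickness
        # build an ice block big enough to cover the slab, then clip
        span = hi - lo
        n1 = int(np.ceil(span[0] / ICE_A)) + 2
        n2 = int(np.ceil(span[1] / (ICE_A * np.sqrt(3) / 2))) + 2
        n3 = int(np.ceil(span[2] / ICE_C)) + 1
        block = build_ice_block(n1, n2, n3, seed=seed + axis)
        # shift block so its bounding box min sits at the slab origin
        xyz = block.coords
        xyz = xyz - xyz.min(axis=0) + lo
        block.coords = xyz
        kept: list[Atom] = []
        for cid, ridx, atom_idx in block.residues():
            o = block.atoms[atom_idx[0]].coords  # oxygen placed first
            if np.any(o < lo) or np.any(o >= hi):
                continue
            if tree is not None and tree.query(o)[0] < clash_cutoff:
                continue
            if any(np.all(o >= rlo) and np.all(o < rhi)
                   for rlo, rhi in occupied_regions):
                continue
            res_offset += 1
            for ai in atom_idx:
                kept.append(replace(block.atoms[ai], residue_index=res_offset,
                                    chain_id="i",
                                    coords=block.atoms[ai].coords.copy()))
        occupied_regions.append((lo, hi))
        new_atoms.extend(kept)

    out = StructureModel(new_atoms, box=SimulationBox(
        lengths=box.lengths + thickness, origin=box.origin))
    return out


# ---------------------------------------------------------------------------
# Water stripping, residual selection, re-solvation
# ---------------------------------------------------------------------------


def _water_residue_keep(system: StructureModel, keep_fn) -> StructureModel:
    """Keep whole water residues whose oxygen satisfies keep_fn; all other
    roles pass through untouched."""
    keep_idx: list[int] = []
    for cid, ridx, atom_idx in system.residues():
        role = system.atoms[atom_idx[0]].role
        if role not in ("water", "ice"):
            keep_idx.extend(atom_idx)
            continue
        oxy = [i for i in atom_idx if system.atoms[i].element.upper() == "O"]
        o_coord = system.atoms[oxy[0]].coords if oxy else system.atoms[atom_idx[0]].coords
        if keep_fn(o_coord):
            keep_idx.extend(atom_idx)
    return system.subset(keep_idx)


def strip_bulk_water(system: StructureModel, cutoff: float = 3.0) -> StructureModel:
    """Remove bulk water to mimic primary-drying sublimation.

    A water molecule is retained iff its oxygen lies within ``cutoff`` of any
    protein atom (boundary inclusive); non-water atoms are untouched.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot = system.select(role="protein")
    if not prot:
        raise ValueError("system contains no protein")
    tree = cKDTree(system.coords[prot])
    return _water_residue_keep(system, lambda o: tree.query(o)[0] <= cutoff)


def select_residual_waters(system: StructureModel,
                           crystal_waters: np.ndarray | Sequence[Sequence[float]],
                           match_cutoff: float = 1.5) -> StructureModel:
    """Retain only residual waters that sit where crystal waters sit.

    A water survives secondary drying iff its oxygen lies within
    ``match_cutoff`` of any crystal-water position (given in the protein
    frame; superpose the system onto the reference protein first).
    """
    cw = np.asarray(crystal_waters, dtype=float).reshape(-1, 3)
    if cw.shape[0] == 0:
        logger.warning("empty crystal-water list: removing all waters")
        return _water_residue_keep(system, lambda o: False)
    tree = cKDTree(cw)
    return _water_residue_keep(system, lambda o: tree.query(o)[0] <= match_cutoff)


def resolvate(system: StructureModel, margin: float = 15.0,
              grid_spacing: float = 3.1, clash_cutoff: float = 2.4,
              seed: int = 0) -> StructureModel:
    """Re-solvate the system in a fresh cubic box for reconstitution.

    Waters (oxygen-only placeholders at grid sites) are placed on a cubic
    grid of the given spacing; sites within ``clash_cutoff`` of any existing
    atom are skipped.  With no protein present the existing box is reused.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if system.select(role="protein"):
        box = define_box(system, margin=margin, cubic=True)
    elif system.box is not None:
        box = system.box
    else:
        raise ValueError("system has neither protein nor a box")
    solute = [i for i, a in enumerate(system.atoms) if a.role != "water"]
    tree = cKDTree(system.coords[solute]) if solute else None
    rng = np.random.default_rng(seed)

    n_sites = np.floor(box.lengths / grid_spacing).astype(int)
    atoms = [replace(a, coords=a.coords.copy()) for a in system.atoms]
    res = max((a.residue_index for a in atoms if a.chain_id == "w"), default=0)
    for ix in range(n_sites[0]):
        for iy in range(n_sites[1]):
            for iz in range(n_sites[2]):
                site = box.origin + (np.array([ix, iy, iz]) + 0.5) * grid_spacing
                if tree is not None and tree.query(site)[0] < clash_cutoff:
                    continue
                res += 1
                atoms.append(Atom("O", "OW", res, "HOH", "w", site, role="water"))
    return StructureModel(atoms, box=box)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Stage-labelled snapshots produced by the end-to-end preparation."""

    stages: list[str]
    systems: list[StructureModel]

    def system(self, stage: str) -> StructureModel:
        return self.systems[self.stages.index(stage)]


def run_pipeline(protein: StructureModel,
                 crystal_waters: np.ndarray | None = None,
                 configs: dict[str, StageConfig] | None = None,
                 seed: int = 0) -> PipelineResult:
    """Run the full RT -> F -> 1D -> 2D -> REC preparation, each stage
    consuming the previous stage's output.

    ``protein`` may already carry waters (e.g. a solvated fixture); RT then
    only (re)defines the box.  ``crystal_waters`` are the reference oxygen
    positions used to select residual waters in secondary drying (defaults to
    no crystal waters, i.e. full desorption).
    """
    cfg = {s: StageConfig.for_stage(s) for s in STAGES}
    if configs:
        cfg.update(configs)

    stages: list[str] = []
    systems: list[StructureModel] = []

    # RT: cubic box at 15 A margin (solvation state comes with the input)
    rt = protein.copy()
    rt.box = define_box(rt, margin=cfg["RT"].box_margin, cubic=True)
    stages.append("RT"); systems.append(rt)

    # F: cover box faces with ice slabs
    frozen = place_ice_blocks(rt, thickness=cfg["F"].ice_thickness,
                              clash_cutoff=cfg["F"].clash_cutoff, seed=seed)
    stages.append("F"); systems.append(frozen)

    # 1D: strip bulk water, large vacuum box
    dried1 = strip_bulk_water(frozen, cutoff=cfg["1D"].strip_cutoff)
    dried1 = dried1.subset([i for i, a in enumerate(dried1.atoms) if a.role != "ice"])
    dried1.box = define_box(dried1, margin=cfg["1D"].box_margin, cubic=True)
    stages.append("1D"); systems.append(dried1)

    # 2D: keep only residual (crystal-like) waters
    cw = np.zeros((0, 3)) if crystal_waters is None else np.asarray(crystal_waters)
    dried2 = select_residual_waters(dried1, cw,
                                    match_cutoff=cfg["2D"].residual_match_cutoff)
    dried2.box = define_box(dried2, margin=cfg["2D"].box_margin, cubic=True)
    stages.append("2D"); systems.append(dried2)

    # REC: re-solvate in a fresh 15 A box
    rec = resolvate(dried2, margin=cfg["REC"].box_margin,
                    grid_spacing=cfg["REC"].water_grid_spacing,
                    clash_cutoff=cfg["REC"].clash_cutoff, seed=seed)
    stages.append("REC"); systems.append(rec)

    return PipelineResult(stages=stages, systems=systems)
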