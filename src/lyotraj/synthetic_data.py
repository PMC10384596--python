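"""Synthetic fixtures for exercising the freeze-drying pipeline without
molecular-dynamics runs.

Everything here is deterministic under a fixed seed and ships its ground
truth: ideal secondary-structure fragments (helix and extended strand from
ideal backbone torsions; an antiparallel hairpin built from explicit
hydrogen-bond-registered coordinates), solvated systems with waters at
controlled distances from the protein, multi-monomer trajectories with
scripted approach/contact events and known contact counts, and excipient
populations carrying the formulation charge logic (arginine +1, tranexamic
acid and sucrose neutral).

Fixture monomers are small (a handful of residues); they emulate the shape
of the problem, never the chemistry of a real therapeutic protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import Atom, SimulationBox, StructureModel, TrajectorySegment
from .stage_builder import ExcipientSpec, replicate_monomers

# ---------------------------------------------------------------------------
# Ideal backbone geometry
# ---------------------------------------------------------------------------

# Engh-Huber-style backbone parameters (A / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A-B-C."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _torsion_backbone(n_residues: int, phi: float, psi: float,
                      omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates from uniform ideal torsions."""
    res: list[dict[str, np.ndarray]] = []
    N = np.zeros(3)
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for _ in range(1, n_residues):
        prev = res[-1]
        Nn = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        CAn = _place(prev["CA"], prev["C"], Nn, _B_N_CA, _A_C_N_CA, omega)
        Cn = _place(prev["C"], Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
        prev["O"] = _place(Nn, prev["CA"], prev["C"], _B_C_O, _A_CA_C_O, 180.0)
        res.append({"N": Nn, "CA": CAn, "C": Cn})
    last = res[-1]
    # terminal carbonyl oxygen: trans to the last N-CA bond
    last["O"] = _place(last["N"], last["CA"], last["C"], _B_C_O, _A_CA_C_O, 0.0)
    return res


def _hairpin_backbone(n_residues: int) -> list[dict[str, np.ndarray]]:
    """Two antiparallel strands in exact mutual hydrogen-bond register,
    joined by a two-residue turn.

    Built from explicit coordinates: paired residues donate and accept
    simultaneously (N-H...O=C at ~1.97 A H...O, 2.97 A N...O), which is the
    mutual pattern the Kabsch-Sander antiparallel bridge test detects.
    """
    n_turn = 2
    ns = (n_residues - n_turn) // 2
    if ns < 1:
        raise ValueError("hairpin needs at least 4 residues")
    d = 4.2  # inter-strand N...C distance
    step = 3.5
    res: list[dict[str, np.ndarray]] = []
    # strand A along +x at y = 0
    for i in range(ns):
        x = step * i
        res.append({
            "N": np.array([x, 0.0, 0.0]),
            "H": np.array([x, -1.0, 0.0]),
            "CA": np.array([x + 1.1, 0.4, 0.8]),
            "C": np.array([x + 2.2, 0.0, 0.0]),
            "O": np.array([x + 2.2, -1.23, 0.0]),
        })
    # turn: arc beyond the strand ends
    x_end = step * (ns - 1) + 2.2
    extra = n_residues - 2 * ns - n_turn  # 0 or, for odd counts, 1 extra turn residue
    turn_count = n_turn + extra
    for k in range(turn_count):
        t = (k + 1) / (turn_count + 1)
        cx = x_end + 3.0 * np.sin(np.pi * t)
        cy = -d * t
        res.append({
            "N": np.array([cx, cy, 0.5]),
            "CA": np.array([cx + 0.9, cy + 0.4, 1.2]),
            "C": np.array([cx + 0.4, cy - 0.6, 0.2]),
            "O": np.array([cx + 0.4, cy - 0.6, 1.4]),
        })
    # strand B antiparallel at y = -d, running -x
    for m in range(ns):
        nx = x_end - step * m
        res.append({
            "N": np.array([nx, -d, 0.0]),
            "H": np.array([nx, -d + 1.0, 0.0]),
            "CA": np.array([nx - 1.1, -d - 0.4, 0.8]),
            "C": np.array([nx - 2.2, -d, 0.0]),
            "O": np.array([nx - 2.2, -d + 1.23, 0.0]),
        })
    return res


def make_ideal_fragment(kind: str, n_residues: int,
                        sequence: Sequence[str] | None = None) -> StructureModel:
    """Build an ideal secondary-structure fragment.

    ``kind``: 'helix' (phi = -57, psi = -47), 'extended' (phi = -139,
    psi = 135) or 'hairpin' (two antiparallel hydrogen-bond-registered
    strands with a turn).  ``sequence`` gives 3-letter residue names
    (defaults to poly-alanine).
    """
    if n_residues < 4:
        raise ValueError("fragments need at least 4 residues")
    if kind == "helix":
        bb = _torsion_backbone(n_residues, HELIX_PHI, HELIX_PSI)
    elif kind == "extended":
        bb = _torsion_backbone(n_residues, STRAND_PHI, STRAND_PSI)
    elif kind == "hairpin":
        bb = _hairpin_backbone(n_residues)
    else:
        raise ValueError(f"unknown fragment kind {kind!r}")
    seq = list(sequence) if sequence is not None else ["ALA"] * len(bb)
    if len(seq) != len(bb):
        raise ValueError("sequence length must match residue count")
    atoms: list[Atom] = []
    for ridx, (entry, rname) in enumerate(zip(bb, seq), start=1):
        for name in ("N", "CA", "C", "O", "H"):
            if name not in entry:
                continue
            element = name[0]
            atoms.append(Atom(element=element, name=name, residue_index=ridx,
                              residue_name=rname, chain_id="A",
                              coords=entry[name], role="protein"))
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Solvated fixtures
# ---------------------------------------------------------------------------


def make_solvated_fixture(protein: StructureModel,
                          shell_spec: Sequence[tuple[float, int]],
                          seed: int = 0,
                          tolerance: float = 0.05,
                          max_tries: int = 2000) -> StructureModel:
    """Surround a protein with waters at controlled minimum distances.

    For every (distance, n_waters) shell, exactly ``n_waters`` water oxygens
    are placed so each one's minimum distance to any protein atom equals the
    stated distance to within ``tolerance``; placement is deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    prot_idx = protein.select(role="protein")
    if not prot_idx:
        raise ValueError("fixture needs protein atoms")
    pxyz = protein.coords[prot_idx]
    atoms = [a for a in protein.atoms]
    placed: list[np.ndarray] = []
    res = 0
    for dist, n_waters in shell_spec:
        if dist <= 0:
            raise ValueError("shell distances must be positive")
        count = 0
        tries = 0
        while count < n_waters:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {n_waters} waters at {dist} A "
                    f"(placed {count})")
            anchor = pxyz[rng.integers(len(pxyz))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            site = anchor + dist * u
            dmin = float(np.linalg.norm(pxyz - site, axis=1).min())
            if abs(dmin - dist) > tolerance:
                continue
            if placed and min(float(np.linalg.norm(p - site)) for p in placed) < 2.0:
                continue
            placed.append(site)
            res += 1
            atoms.append(Atom("O", "OW", res, "HOH", "W", site, role="water"))
            count += 1
    return StructureModel(atoms, box=protein.box)


# ---------------------------------------------------------------------------
# Scripted aggregation trajectories
# ---------------------------------------------------------------------------


def make_cg_monomer(n_residues: int = 3, spacing: float = 6.0) -> StructureModel:
    """A linear bead monomer (one pseudo-atom per residue) for
    coarse-grained-like aggregation fixtures; intra-monomer bead spacing is
    wide enough that only the leading residue of an approaching monomer can
    enter a 4 A contact."""
    atoms = [Atom("C", "BB", i + 1, "GLY", "A",
                  np.array([i * spacing, 0.0, 0.0]), role="protein")
             for i in range(n_residues)]
    return StructureModel(atoms)


@dataclass
class AggregationScript:
    """Scripted contact events for a multi-monomer trajectory.

    ``schedule`` entries are ((first_frame, last_frame), (monomer_i,
    monomer_j), distance): during the inclusive frame range the scheduled
    monomer pair is translated so its closest inter-monomer atom distance
    equals ``distance``.  Every scheduled distance must differ from
    ``contact_cutoff`` by at least ``margin`` so the ground truth is
    unambiguous.
    """

    n_monomers: int
    n_frames: int
    schedule: list[tuple[tuple[int, int], tuple[int, int], float]]
    seed: int = 0
    contact_cutoff: float = 4.0
    margin: float = 0.5

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for (f0, f1), (a, b), dist in self.schedule:
            if not (0 <= f0 <= f1 < self.n_frames):
                raise ValueError(f"frame range ({f0}, {f1}) out of bounds")
            if a == b or not (0 <= a < self.n_monomers and 0 <= b < self.n_monomers):
                raise ValueError(f"invalid monomer pair ({a}, {b})")
            if abs(dist - self.contact_cutoff) < self.margin:
                raise ValueError(
                    f"scheduled distance {dist} within {self.margin} A of the "
                    f"contact cutoff {self.contact_cutoff}: ground truth ambiguous")
            key = tuple(sorted((a, b)))
            for (g0, g1) in seen.get(key, []):
                if f0 <= g1 and g0 <= f1:
                    raise ValueError(f"overlapping schedule entries for pair {key}")
            seen.setdefault(key, []).append((f0, f1))


def _approach(base: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
              target: float) -> np.ndarray:
    """Translate monomer b rigidly so the closest a-b atom distance equals
    ``target`` (iterating along the closest-pair direction)."""
    xyz = base.copy()
    for _ in range(50):
        d = np.linalg.norm(xyz[idx_a][:, None, :] - xyz[idx_b][None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        dmin = d[i, j]
        if abs(dmin - target) < 1e-9:
            break
        u = xyz[idx_a[i]] - xyz[idx_b[j]]
        u /= np.linalg.norm(u)
        xyz[idx_b] = xyz[idx_b] + (dmin - target) * u
    return xyz


def make_aggregation_trajectory(monomer: StructureModel, script: AggregationScript,
                                grid_spacing: float = 85.0,
                                ) -> tuple[TrajectorySegment, list[int]]:
    """Build a multi-monomer trajectory with scripted contact events.

    Monomers start on the standard centre-of-mass grid (85 A spacing) and
    scheduled pairs are rigidly translated into (or held out of) contact.
    Returns the trajectory plus the per-frame ground-truth count of residue
    pairs within the contact cutoff, recomputed by direct all-pairs
    enumeration.
    """
    n = script.n_monomers
    g = int(np.ceil(n ** (1 / 3)))
    grid = (g, g, int(np.ceil(n / g ** 2)))
    while np.prod(grid) < n:
        grid = (grid[0], grid[1], grid[2] + 1)
    system = replicate_monomers(monomer, grid=grid, spacing=grid_spacing)
    chains = system.chain_ids[:n]
    system = system.subset([i for i, a in enumerate(system.atoms)
                            if a.chain_id in chains])
    base = system.coords
    chain_atoms = {c: np.asarray(system.select(chain_id=c)) for c in chains}

    frames = np.repeat(base[None, :, :], script.n_frames, axis=0)
    for (f0, f1), (a, b), dist in script.schedule:
        ia, ib = chain_atoms[chains[a]], chain_atoms[chains[b]]
        # re-place monomer b collinearly beyond monomer a's +x extent so the
        # subsequent approach produces a single head-on closest pair
        start = base.copy()
        com_a = start[ia].mean(axis=0)
        com_b = start[ib].mean(axis=0)
        span = (np.ptp(start[ia], axis=0).max() + np.ptp(start[ib], axis=0).max())
        start[ib] += (com_a + np.array([span + 30.0, 0.0, 0.0])) - com_b
        moved = _approach(start, ia, ib, dist)
        for f in range(f0, f1 + 1):
            frames[f, ib] = moved[ib]

    # ground truth: brute-force residue-pair counting per frame
    residues = system.residues()
    ground_truth: list[int] = []
    for f in range(script.n_frames):
        xyz = frames[f]
        count = 0
        for p in range(len(residues)):
            cp, rp, ip = residues[p]
            for q in range(p + 1, len(residues)):
                cq, rq, iq = residues[q]
                if cp == cq:
                    continue
                dmin = np.linalg.norm(
                    xyz[ip][:, None, :] - xyz[iq][None, :, :], axis=2).min()
                if dmin < script.contact_cutoff:
                    count += 1
        ground_truth.append(count)

    seg = TrajectorySegment(stage="RT", model=system, frames=frames)
    return seg, ground_truth


# ---------------------------------------------------------------------------
# Excipient populations
# ---------------------------------------------------------------------------


@dataclass
class ExcipientPopulation:
    """A placed excipient population and its total formal charge."""

    model: StructureModel
    spec: ExcipientSpec
    n: int

    @property
    def net_charge(self) -> int:
        return self.n * self.spec.net_charge


def make_excipient_population(spec: ExcipientSpec, n: int,
                              grid_spacing: float = 8.0,
                              origin: np.ndarray | None = None,
                              ) -> ExcipientPopulation:
    """Place ``n`` single-residue excipient molecules (one bead each) on a
    non-clashing cubic grid."""
    if n < 0:
        raise ValueError("n must be non-negative")
    o = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    atoms: list[Atom] = []
    side = max(1, int(np.ceil(n ** (1 / 3))))
    k = 0
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                if k >= n:
                    break
                k += 1
                pos = o + np.array([ix, iy, iz], dtype=float) * grid_spacing
                atoms.append(Atom("C", spec.name[:2].upper() or "EX", k,
                                  spec.name[:3].upper(), "E", pos,
                                  role="excipient"))
    return ExcipientPopulation(model=StructureModel(atoms), spec=spec, n=n)
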