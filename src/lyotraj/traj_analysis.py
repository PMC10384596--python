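"""Scalar structural observables along the freeze-drying pipeline.

Implements the observables used to monitor protein structure through the
RT -> F -> 1D -> 2D -> REC stages: least-squares (Kabsch) superposition and
RMSD time courses against the starting structure, mass-weighted radius of
gyration, Shrake-Rupley solvent-accessible surface area and the
non-polar/total SASA ratio (hydrophobic exposure), beta-sheet content from
Kabsch-Sander backbone hydrogen-bond energies, geometric intramolecular
hydrogen-bond counts, and the kringle-2/catalytic domain-separation distance
whose collapse and recovery is the pipeline's central structural readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_io import STAGES, StructureModel, TrajectorySegment

# ---------------------------------------------------------------------------
# Series container
# ---------------------------------------------------------------------------


@dataclass
class StageSeries:
    """A stage-labelled observable time series (times in ns)."""

    observable: str
    times: np.ndarray
    values: np.ndarray
    stages: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.times) == len(self.values) == len(self.stages)):
            raise ValueError("times, values and stages must have equal length")
        order = [STAGES.index(s) for s in self.stages]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("stage labels must appear in pipeline order")

    def __len__(self) -> int:
        return len(self.times)

    @staticmethod
    def concatenate(parts: Sequence["StageSeries"]) -> "StageSeries":
        if not parts:
            raise ValueError("nothing to concatenate")
        name = parts[0].observable
        times = np.concatenate([p.times for p in parts])
        values = np.concatenate([p.values for p in parts])
        stages = [s for p in parts for s in p.stages]
        return StageSeries(name, times, values, stages)


@dataclass
class DomainDefinition:
    """Residue index ranges (inclusive) of the kringle-2 and catalytic
    domains and the connecting linker."""

    kringle2: tuple[int, int]
    catalytic: tuple[int, int]
    linker: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ranges = [self.kringle2, self.catalytic]
        if self.linker is not None:
            ranges.append(self.linker)
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"empty range ({lo}, {hi})")
        spans = sorted(ranges)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo <= a_hi:
                raise ValueError("domain ranges must be disjoint")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


def superpose(mobile: np.ndarray, reference: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``
    (Kabsch algorithm).

    Returns (rotation R, translation t, rmsd) such that ``mobile @ R.T + t``
    minimises the RMSD to ``reference`` over all proper rigid motions;
    det(R) = +1.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError(f"coordinate sets incongruent: {mob.shape} vs {ref.shape}")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    P = mob - mc
    Q = ref - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_timecourse(segments: TrajectorySegment | Sequence[TrajectorySegment],
                    selection: Sequence[int] | None = None) -> StageSeries:
    """Per-frame superposed RMSD against the starting structure.

    The reference is the first frame of the first segment; the default
    selection is the C-alpha atoms (all atoms if none are named CA).
    """
    if isinstance(segments, TrajectorySegment):
        segments = [segments]
    if not segments or all(s.n_frames == 0 for s in segments):
        raise ValueError("empty trajectory")
    model = segments[0].model
    if selection is None:
        selection = [i for i, a in enumerate(model.atoms)
                     if a.role == "protein" and a.name.strip() == "CA"]
        if not selection:
            selection = [i for i, a in enumerate(model.atoms) if a.role == "protein"]
        if not selection:
            selection = list(range(len(model)))
    sel = np.asarray(selection, dtype=int)
    ref = segments[0].frames[0][sel]
    times, values, stages = [], [], []
    t0 = 0.0
    for seg in segments:
        for k in range(seg.n_frames):
            _, _, r = superpose(seg.frames[k][sel], ref)
            times.append(t0 + k * seg.time_per_frame)
            values.append(r)
            stages.append(seg.stage)
        t0 = times[-1] + seg.time_per_frame if times else 0.0
    return StageSeries("rmsd", np.array(times), np.array(values), stages)


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance of atoms from their centre of mass (A)."""
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    if xyz.shape[0] == 0:
        raise ValueError("need at least one atom")
    if masses is None:
        masses = np.ones(xyz.shape[0])
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    com = np.average(xyz, axis=0, weights=m)
    d2 = np.sum((xyz - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

#: van der Waals radii (A) used for SASA; probe radius defaults to 1.4 A.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "NA": 2.27, "CL": 1.75, "K": 2.75, "MG": 1.73, "CA": 2.31,
    "FE": 1.95,
}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(model: StructureModel, probe_radius: float = DEFAULT_PROBE_RADIUS,
         n_sphere_points: int = DEFAULT_SPHERE_POINTS,
         radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) by Shrake-Rupley.

    Each atom is covered with ``n_sphere_points`` test points on a sphere of
    radius r_vdw + probe; points not buried inside any neighbouring sphere
    contribute area.  Accuracy improves with the number of points.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    xyz = model.coords
    n = len(model)
    r = np.empty(n)
    for i, a in enumerate(model.atoms):
        el = a.element.upper()
        if el not in table:
            raise ValueError(f"no van der Waals radius configured for element {el!r}")
        r[i] = table[el] + probe_radius
    pts = _sphere_points(n_sphere_points)
    tree = cKDTree(xyz)
    rmax = r.max()
    areas = np.zeros(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(xyz[i], r[i] + rmax) if j != i]
        test = xyz[i] + r[i] * pts
        if neigh:
            nx = xyz[neigh]
            nr = r[np.asarray(neigh)]
            d2 = np.sum((test[:, None, :] - nx[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nr ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r[i] ** 2 * frac
    return areas


#: Non-polar elements; hydrogens inherit the class of their heavy atom.
_NONPOLAR_ELEMENTS = frozenset({"C", "S"})


def _heavy_neighbor_element(model: StructureModel, i: int) -> str:
    """Element of the closest heavy atom in the same residue (for H atoms)."""
    a = model.atoms[i]
    best, best_d = None, np.inf
    for j, b in enumerate(model.atoms):
        if j == i or b.element.upper() == "H":
            continue
        if (b.chain_id, b.residue_index) != (a.chain_id, a.residue_index):
            continue
        d = float(np.linalg.norm(b.coords - a.coords))
        if d < best_d:
            best, best_d = b.element.upper(), d
    return best or "C"


def nonpolar_sasa_ratio(model: StructureModel, areas: np.ndarray) -> float:
    """Fraction of the total SASA contributed by non-polar atoms (C, S;
    hydrogens classified with their bonded heavy atom)."""
    areas = np.asarray(areas, dtype=float)
    if areas.shape[0] != len(model):
        raise ValueError("areas must be computed on the same model")
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("total SASA is zero")
    nonpolar = 0.0
    for i, a in enumerate(model.atoms):
        el = a.element.upper()
        if el == "H":
            el = _heavy_neighbor_element(model, i)
        if el in _NONPOLAR_ELEMENTS:
            nonpolar += areas[i]
    return nonpolar / total


# ---------------------------------------------------------------------------
# Backbone geometry helpers
# ---------------------------------------------------------------------------


def _backbone_table(model: StructureModel) -> list[dict]:
    """Per-residue backbone atoms (N, CA, C, O and H if present) for protein
    residues, in chain order."""
    out = []
    for cid, ridx, atom_idx in model.residues():
        if model.atoms[atom_idx[0]].role != "protein":
            continue
        entry: dict = {"chain": cid, "resid": ridx}
        for i in atom_idx:
            nm = model.atoms[i].name.strip().upper()
            if nm in ("N", "CA", "C", "O", "H", "HN"):
                entry.setdefault("H" if nm in ("H", "HN") else nm,
                                 model.atoms[i].coords)
        out.append(entry)
    return out


def _amide_hydrogen(prev_c: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Reconstruct the amide hydrogen: 1.0 A from N, opposite the bisector of
    the C(prev)-N and CA-N directions (planar sp2 nitrogen)."""
    u = prev_c - n
    u /= np.linalg.norm(u)
    v = ca - n
    v /= np.linalg.norm(v)
    b = u + v
    nb = np.linalg.norm(b)
    if nb < 1e-8:
        w = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(u, [0.0, 1.0, 0.0])
        b = w
        nb = np.linalg.norm(b)
    return n - b / nb


# ---------------------------------------------------------------------------
# Beta-sheet content (Kabsch-Sander)
# ---------------------------------------------------------------------------

_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol * A, electrostatic H-bond model
KS_ENERGY_CUTOFF = -0.5  # kcal/mol


def _ks_hbond_energy(donor: dict, acceptor: dict) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy (kcal/mol) for the
    donor residue's N-H and the acceptor residue's C=O."""
    N, H = donor["N"], donor["H"]
    C, O = acceptor["C"], acceptor["O"]
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0
    return _KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(bb: list[dict]) -> np.ndarray:
    """hb[i, j] True if residue i's N-H donates to residue j's C=O with
    Kabsch-Sander energy below the cutoff."""
    n = len(bb)
    # reconstruct missing amide hydrogens where geometry allows
    for k in range(n):
        e = bb[k]
        if "H" in e or "N" not in e or "CA" not in e:
            continue
        if k > 0 and bb[k - 1]["chain"] == e["chain"] \
                and bb[k - 1].get("resid", -10) == e["resid"] - 1 \
                and "C" in bb[k - 1]:
            e["H"] = _amide_hydrogen(bb[k - 1]["C"], e["N"], e["CA"])
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        di = bb[i]
        if "H" not in di or "N" not in di:
            continue
        for j in range(n):
            if i == j:
                continue
            aj = bb[j]
            if "C" not in aj or "O" not in aj:
                continue
            # exclude adjacent residues in the same chain
            if di["chain"] == aj["chain"] and abs(di["resid"] - aj["resid"]) < 2:
                continue
            if _ks_hbond_energy(di, aj) < KS_ENERGY_CUTOFF:
                hb[i, j] = True
    return hb


def beta_sheet_content(model: StructureModel) -> float:
    """Fraction of protein residues participating in beta bridges/ladders.

    Backbone hydrogen bonds are detected with the Kabsch-Sander electrostatic
    energy (bond if E < -0.5 kcal/mol, amide H reconstructed from geometry if
    absent); residues paired by the parallel or antiparallel bridge patterns
    are counted as beta.
    """
    bb = _backbone_table(model)
    n = len(bb)
    if n < 3:
        return 0.0
    hb = _hbond_matrix(bb)
    is_beta = np.zeros(n, dtype=bool)

    def sep_ok(i: int, j: int) -> bool:
        if bb[i]["chain"] != bb[j]["chain"]:
            return True
        return abs(bb[i]["resid"] - bb[j]["resid"]) >= 3

    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if i == j or not sep_ok(i, j):
                continue
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            antiparallel = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or antiparallel:
                is_beta[i] = True
                is_beta[j] = True
    return float(is_beta.sum()) / n


# ---------------------------------------------------------------------------
# Geometric hydrogen-bond count
# ---------------------------------------------------------------------------

HBOND_DISTANCE_CUTOFF = 3.5  # A, donor-acceptor heavy-atom distance
HBOND_ANGLE_CUTOFF = 30.0  # deg, deviation of D-H...A from linearity


def hbond_count(model: StructureModel,
                donors: Sequence[tuple[int, int]] | None = None,
                acceptors: Sequence[int] | None = None,
                d_cutoff: float = HBOND_DISTANCE_CUTOFF,
                angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> int:
    """Count intramolecular (intra-protein) hydrogen bonds.

    A bond is counted for a donor heavy atom D (N or O with an attached or
    reconstructable H) and an acceptor A (N or O) when the D-A distance is
    <= ``d_cutoff`` and the D-H...A angle deviates from linearity by at most
    ``angle_cutoff`` degrees.  ``donors`` is a list of (heavy, hydrogen) atom
    index pairs and ``acceptors`` a list of atom indices; both are derived
    from the structure when omitted.
    """
    xyz = model.coords
    protein = set(model.select(role="protein"))
    if donors is None:
        donors = []
        # attach each H to its nearest heavy N/O within bonding distance
        h_idx = [i for i in protein if model.atoms[i].element.upper() == "H"]
        heavy = [i for i in protein if model.atoms[i].element.upper() in ("N", "O")]
        if heavy:
            tree = cKDTree(xyz[heavy])
            for h in h_idx:
                d, k = tree.query(xyz[h])
                if d <= 1.25:
                    donors.append((heavy[k], h))
    if acceptors is None:
        acceptors = [i for i in protein if model.atoms[i].element.upper() in ("N", "O")]
    count = 0
    cosmin = np.cos(np.deg2rad(180.0 - angle_cutoff))
    for dheavy, dh in donors:
        for a in acceptors:
            if a == dheavy or a == dh:
                continue
            # skip acceptors in the same residue as the donor
            if (model.atoms[a].chain_id, model.atoms[a].residue_index) == \
               (model.atoms[dheavy].chain_id, model.atoms[dheavy].residue_index):
                continue
            if np.linalg.norm(xyz[a] - xyz[dheavy]) > d_cutoff:
                continue
            u = xyz[dh] - xyz[dheavy]
            v = xyz[a] - xyz[dh]
            cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            # D-H...A angle at H: 180 deg is linear
            if -cosang <= cosmin:
                count += 1
    return count


# ---------------------------------------------------------------------------
# Domain separation
# ---------------------------------------------------------------------------


def domain_separation(model: StructureModel, domains: DomainDefinition,
                      chain_id: str | None = None) -> tuple[float, float]:
    """Distance between the kringle-2 and catalytic domain centres of mass
    and the minimum inter-domain atom distance (both in A)."""
    def indices(rng: tuple[int, int]) -> list[int]:
        lo, hi = rng
        return [i for i, a in enumerate(model.atoms)
                if a.role == "protein" and lo <= a.residue_index <= hi
                and (chain_id is None or a.chain_id == chain_id)]

    ia = indices(domains.kringle2)
    ib = indices(domains.catalytic)
    if not ia or not ib:
        raise ValueError("domain ranges select no atoms")
    xyz = model.coords
    com_a = np.average(xyz[ia], axis=0, weights=model.masses[ia])
    com_b = np.average(xyz[ib], axis=0, weights=model.masses[ib])
    com_dist = float(np.linalg.norm(com_a - com_b))
    d = np.linalg.norm(xyz[ia][:, None, :] - xyz[ib][None, :, :], axis=2)
    return com_dist, float(d.min())


# ---------------------------------------------------------------------------
# Per-stage observable courses
# ---------------------------------------------------------------------------


def observable_timecourse(segments: Sequence[TrajectorySegment], observable: str,
                          **kwargs) -> StageSeries:
    """Evaluate a per-frame scalar observable ('rg', 'sasa_ratio', 'beta',
    'hbonds') across concatenated stage segments."""
    times, values, stages = [], [], []
    t0 = 0.0
    for seg in segments:
        prot = seg.model.select(role="protein")
        for k in range(seg.n_frames):
            m = seg.frame_model(k)
            if observable == "rg":
                v = radius_of_gyration(m.coords[prot], m.masses[prot])
            elif observable == "sasa_ratio":
                pm = m.subset(prot)
                v = nonpolar_sasa_ratio(pm, sasa(pm, **kwargs))
            elif observable == "beta":
                v = beta_sheet_content(m)
            elif observable == "hbonds":
                v = float(hbond_count(m, **kwargs))
            else:
                raise ValueError(f"unknown observable {observable!r}")
            times.append(t0 + k * seg.time_per_frame)
            values.append(v)
            stages.append(seg.stage)
        if times:
            t0 = times[-1] + seg.time_per_frame
    return StageSeries(observable, np.array(times), np.array(values), stages)
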