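"""Aggregation-prone residue (APR) scoring and difference maps.

The score is a transparent, structure-based aggregation-propensity proxy:
exposure-weighted hydrophobicity with spatial smoothing.  For residue i,

    score_i = sum over residues j with d(CA_i, CA_j) <= R of
              w(d_ij) * h_j * rsa_j

where h_j is a per-residue-type aggregation propensity (a normalised
hydrophobicity scale), rsa_j the residue's relative solvent accessibility,
and w(d) = 1 - d/R a linear distance decay over the neighbourhood radius R
(10 A by default).  Higher score = more aggregation-prone; a residue buried
together with its whole neighbourhood (rsa = 0 throughout) scores 0.  The
score makes no claim of numeric equivalence with any external
aggregation-propensity program.

Difference maps subtract one condition's profile from another element-wise;
the operand order is recorded in the result so the sign convention (positive
difference = first operand more prone) is always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import StructureModel
from .traj_analysis import sasa

DEFAULT_NEIGHBORHOOD_RADIUS = 10.0  # A

#: Kyte-Doolittle hydropathy rescaled to [0, 1] (GLY-referenced aggregation
#: propensity weight; ILE most prone, ARG least).
_KD = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
_kd_min = min(_KD.values())
_kd_max = max(_KD.values())
DEFAULT_PROPENSITY_SCALE = {k: (v - _kd_min) / (_kd_max - _kd_min)
                            for k, v in _KD.items()}

#: Maximum residue accessibilities (A^2) for relative SASA (Tien et al.
#: theoretical values).
MAX_RESIDUE_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class APRProfile:
    """Per-residue aggregation-propensity scores for one condition."""

    scores: np.ndarray
    residue_indices: list[int]
    residue_names: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("APR scores must be finite")
        if len(self.scores) != len(self.residue_indices):
            raise ValueError("one score per residue required")


@dataclass
class APRRegion:
    """A labelled aggregation-prone region, e.g. APR B spanning Met35-Val41."""

    label: str
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError("empty residue range")


@dataclass
class APRDifference:
    """Element-wise profile difference ``a - b`` with explicit operand order."""

    differences: np.ndarray
    residue_indices: list[int]
    minuend: str
    subtrahend: str

    def flag(self, magnitude: float) -> dict[int, str]:
        """Residues whose |difference| exceeds ``magnitude``: positive
        difference means the minuend condition is more aggregation-prone
        ('destabilized'), negative means less ('stabilized')."""
        out: dict[int, str] = {}
        for ridx, d in zip(self.residue_indices, self.differences):
            if d > magnitude:
                out[ridx] = "destabilized"
            elif d < -magnitude:
                out[ridx] = "stabilized"
        return out


def _relative_sasa(model: StructureModel, per_atom: np.ndarray,
                   residues: list[tuple[str, int, list[int]]]) -> np.ndarray:
    rsa = np.zeros(len(residues))
    for k, (cid, ridx, atom_idx) in enumerate(residues):
        name = model.atoms[atom_idx[0]].residue_name.upper()
        ref = MAX_RESIDUE_SASA.get(name, 200.0)
        rsa[k] = min(1.0, float(per_atom[atom_idx].sum()) / ref)
    return rsa


def apr_score(model: StructureModel,
              propensity_scale: dict[str, float] | None = None,
              neighborhood_radius: float = DEFAULT_NEIGHBORHOOD_RADIUS,
              condition: str = "",
              per_atom_sasa: np.ndarray | None = None,
              rsa: np.ndarray | None = None,
              sasa_kwargs: dict | None = None) -> APRProfile:
    """Per-residue aggregation-propensity profile of a protein structure.

    ``rsa`` (per-residue relative accessibility in [0, 1]) may be supplied
    directly for synthetic fixtures; otherwise it is derived from a
    Shrake-Rupley SASA computation on the model.
    """
    scale = propensity_scale or DEFAULT_PROPENSITY_SCALE
    prot = model.select(role="protein")
    pmodel = model.subset(prot)
    residues = pmodel.residues()
    if not residues:
        raise ValueError("model has no protein residues")
    names = [pmodel.atoms[idx[0]].residue_name.upper() for _, _, idx in residues]
    missing = {n for n in names if n not in scale}
    if missing:
        raise ValueError(f"propensity scale missing residue types: {sorted(missing)}")

    if rsa is None:
        per_atom = per_atom_sasa
        if per_atom is None:
            per_atom = sasa(pmodel, **(sasa_kwargs or {}))
        rsa = _relative_sasa(pmodel, np.asarray(per_atom, dtype=float), residues)
    rsa = np.asarray(rsa, dtype=float)
    if rsa.shape[0] != len(residues):
        raise ValueError("rsa must have one entry per residue")

    # residue anchor points: CA if present, else residue centroid
    anchors = np.zeros((len(residues), 3))
    for k, (cid, ridx, atom_idx) in enumerate(residues):
        ca = [i for i in atom_idx if pmodel.atoms[i].name.strip().upper() == "CA"]
        pts = pmodel.coords[ca if ca else atom_idx]
        anchors[k] = pts.mean(axis=0)

    h = np.array([scale[n] for n in names])
    R = neighborhood_radius
    d = np.linalg.norm(anchors[:, None, :] - anchors[None, :, :], axis=2)
    w = np.where(d <= R, 1.0 - d / R, 0.0)
    scores = w @ (h * rsa)
    return APRProfile(scores=scores,
                      residue_indices=[r[1] for r in residues],
                      residue_names=names, condition=condition)


def apr_difference(profile_a: APRProfile, profile_b: APRProfile) -> APRDifference:
    """Element-wise difference ``a - b`` between two congruent profiles."""
    if profile_a.residue_indices != profile_b.residue_indices:
        raise ValueError("profiles cover different residue sets")
    return APRDifference(differences=profile_a.scores - profile_b.scores,
                         residue_indices=list(profile_a.residue_indices),
                         minuend=profile_a.condition,
                         subtrahend=profile_b.condition)


def region_summary(diff: APRDifference, regions: list[APRRegion]) -> dict[str, float]:
    """Mean difference over each labelled region's residues."""
    out: dict[str, float] = {}
    idx = np.asarray(diff.residue_indices)
    for region in regions:
        lo, hi = region.residue_range
        mask = (idx >= lo) & (idx <= hi)
        if not mask.any():
            raise ValueError(f"region {region.label} selects no residues")
        out[region.label] = float(diff.differences[mask].mean())
    return out
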