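"""Inter-monomer contact statistics for coarse-grained aggregation runs.

A protein-protein interaction (PPI) is a residue pair on two different
monomers whose minimum atom-atom distance is strictly below the contact
cutoff (4 A by default).  Contacts are counted once per unordered residue
pair per frame and summed over frames; totals are normalised to the
condition with the weakest observed PPIs, so the non-aggregating reference
formulation maps to 1.0 and an aggregating one to its fold excess.  Pair
counts feed thresholded heatmaps (cells below 25% of the strongest pair of
the reference condition are removed), a monomer contact graph yields
oligomer-size distributions, and per-residue excipient contact occupancy
quantifies protein-excipient binding (e.g. Lys40-arginine).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_io import SimulationBox, StructureModel, TrajectorySegment

logger = logging.getLogger("lyotraj")

DEFAULT_CONTACT_CUTOFF = 4.0  # A, strict inequality
DEFAULT_HEATMAP_FILTER = 0.25


@dataclass(frozen=True)
class ContactRecord:
    """One inter-monomer residue-pair contact in one frame; chains are stored
    in sorted order so each unordered pair is recorded once."""

    chain_a: str
    chain_b: str
    residue_a: int
    residue_b: int
    frame: int = 0

    def __post_init__(self) -> None:
        if self.chain_a == self.chain_b:
            raise ValueError("contacts are inter-monomer only")
        if self.chain_a > self.chain_b:
            object.__setattr__(self, "chain_a", self.chain_b)
            object.__setattr__(self, "chain_b", self.chain_a)
            ra, rb = self.residue_a, self.residue_b
            object.__setattr__(self, "residue_a", rb)
            object.__setattr__(self, "residue_b", ra)


@dataclass
class PPIHeatmap:
    """Residue x residue contact-count matrix after reference thresholding."""

    matrix: np.ndarray
    residue_labels: list[int]
    reference_max: int
    filter_fraction: float

    def __post_init__(self) -> None:
        nz = self.matrix[self.matrix > 0]
        if nz.size and np.any(nz < self.filter_fraction * self.reference_max):
            raise ValueError("heatmap contains cells below the filter threshold")


def _minimum_image(delta: np.ndarray, box: SimulationBox) -> np.ndarray:
    L = box.lengths
    return delta - L * np.round(delta / L)


def _pairwise_min_dist(xa: np.ndarray, xb: np.ndarray,
                       box: SimulationBox | None) -> float:
    d = xa[:, None, :] - xb[None, :, :]
    if box is not None:
        d = _minimum_image(d, box)
    return float(np.sqrt(np.sum(d * d, axis=2)).min())


def inter_monomer_contacts(model: StructureModel,
                           coords: np.ndarray | None = None,
                           cutoff: float = DEFAULT_CONTACT_CUTOFF,
                           frame: int = 0,
                           chains: Sequence[str] | None = None,
                           ) -> set[ContactRecord]:
    """Residue pairs on different chains with minimum atom-atom distance
    strictly below ``cutoff``.

    The minimum-image convention applies when the model carries a box; each
    unordered residue pair is recorded once per frame.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
    box = model.box
    chain_ids = chains if chains is not None else model.chain_ids
    protein_chains = [c for c in chain_ids
                      if any(model.atoms[i].role == "protein"
                             for i in model.select(chain_id=c))]
    if len(protein_chains) < 2:
        logger.warning("fewer than two protein chains: no inter-monomer contacts")
        return set()

    # per-chain atom indices and per-atom residue ids
    per_chain: dict[str, np.ndarray] = {}
    residue_of: dict[str, np.ndarray] = {}
    for c in protein_chains:
        idx = [i for i in model.select(chain_id=c) if model.atoms[i].role == "protein"]
        per_chain[c] = np.asarray(idx, dtype=int)
        residue_of[c] = np.asarray([model.atoms[i].residue_index for i in idx])

    out: set[ContactRecord] = set()
    wrapped = xyz.copy()
    if box is not None:
        # kd-tree periodic mode needs coordinates in [0, L)
        wrapped = np.mod(xyz - box.origin, box.lengths)
    for ci in range(len(protein_chains)):
        for cj in range(ci + 1, len(protein_chains)):
            ca, cb = protein_chains[ci], protein_chains[cj]
            ia, ib = per_chain[ca], per_chain[cb]
            if box is not None:
                tree_a = cKDTree(wrapped[ia], boxsize=box.lengths)
                tree_b = cKDTree(wrapped[ib], boxsize=box.lengths)
            else:
                tree_a = cKDTree(xyz[ia])
                tree_b = cKDTree(xyz[ib])
            pairs = tree_a.query_ball_tree(tree_b, cutoff)
            for k, hits in enumerate(pairs):
                for m in hits:
                    pa = wrapped[ia[k]] if box is not None else xyz[ia[k]]
                    pb = wrapped[ib[m]] if box is not None else xyz[ib[m]]
                    delta = pa - pb
                    if box is not None:
                        delta = _minimum_image(delta, box)
                    if float(np.linalg.norm(delta)) < cutoff:
                        out.add(ContactRecord(ca, cb, int(residue_of[ca][k]),
                                              int(residue_of[cb][m]), frame))
    return out


def ppi_count(traj: TrajectorySegment, cutoff: float = DEFAULT_CONTACT_CUTOFF,
              unique_pairs: bool = False) -> int:
    """Total number of PPIs in a trajectory: contact records summed over
    frames (or, with ``unique_pairs``, distinct residue pairs over the whole
    trajectory)."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if len(traj.model.chain_ids) < 2:
        raise ValueError("ppi_count needs a multi-chain trajectory")
    all_records: list[ContactRecord] = []
    for k in range(traj.n_frames):
        all_records.extend(inter_monomer_contacts(traj.model, coords=traj.frames[k],
                                                  cutoff=cutoff, frame=k))
    if unique_pairs:
        return len({(r.chain_a, r.chain_b, r.residue_a, r.residue_b)
                    for r in all_records})
    return len(all_records)


def normalize_ppi(counts: Mapping[str, float]) -> dict[str, float]:
    """Normalise per-condition PPI counts to the weakest (smallest positive)
    condition, which maps to exactly 1.0."""
    positives = [v for v in counts.values() if v > 0]
    if not positives:
        raise ValueError("all conditions have zero PPIs; nothing to normalise")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    ref = min(positives)
    return {k: v / ref for k, v in counts.items()}


def contact_heatmap(records: Iterable[ContactRecord],
                    reference_records: Iterable[ContactRecord],
                    filter_fraction: float = DEFAULT_HEATMAP_FILTER,
                    n_residues: int | None = None) -> PPIHeatmap:
    """Residue-pair contact-count matrix thresholded against a reference
    condition.

    ``reference_max`` is the count of the strongest interacting residue pair
    of the reference (non-aggregating) condition; cells whose count falls
    strictly below ``filter_fraction * reference_max`` are zeroed (cells
    exactly at the threshold are retained).
    """
    ref = list(reference_records)
    if not ref:
        raise ValueError("reference record set must be non-empty")
    recs = list(records)

    def pair_counts(rs: list[ContactRecord]) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for r in rs:
            key = tuple(sorted((r.residue_a, r.residue_b)))
            out[key] = out.get(key, 0) + 1
        return out

    ref_counts = pair_counts(ref)
    reference_max = max(ref_counts.values())
    counts = pair_counts(recs)
    residues = sorted({r for pair in counts for r in pair}
                      | {r for pair in ref_counts for r in pair})
    if n_residues is not None:
        residues = list(range(1, n_residues + 1))
    index = {r: i for i, r in enumerate(residues)}
    mat = np.zeros((len(residues), len(residues)), dtype=float)
    thresh = filter_fraction * reference_max
    for (ra, rb), c in counts.items():
        if c < thresh:
            continue
        i, j = index[ra], index[rb]
        mat[i, j] = c
        mat[j, i] = c
    return PPIHeatmap(matrix=mat, residue_labels=residues,
                      reference_max=reference_max, filter_fraction=filter_fraction)


def oligomer_size_distribution(records: Iterable[ContactRecord],
                               monomers: Sequence[str]) -> list[int]:
    """Cluster sizes of the monomer contact graph (connected components of
    the graph whose nodes are monomers and edges are any inter-monomer
    contact); sizes sum to the number of monomers."""
    monomers = list(monomers)
    index = {c: i for i, c in enumerate(monomers)}
    rows, cols = [], []
    for r in records:
        if r.chain_a not in index or r.chain_b not in index:
            raise ValueError(f"contact references unknown chain: {r}")
        rows.append(index[r.chain_a])
        cols.append(index[r.chain_b])
    n = len(monomers)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return sorted((int(s) for s in sizes), reverse=True)


def excipient_contact_occupancy(traj: TrajectorySegment,
                                residue: tuple[str, int],
                                partner_role: str = "excipient",
                                cutoff: float = DEFAULT_CONTACT_CUTOFF,
                                partner_resname: str | None = None) -> float:
    """Fraction of frames in which any partner-role atom lies within
    ``cutoff`` of any atom of the given (chain, residue_index) residue."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chain, ridx = residue
    res_idx = [i for i, a in enumerate(traj.model.atoms)
               if a.chain_id == chain and a.residue_index == ridx]
    if not res_idx:
        raise ValueError(f"residue {residue} not found")
    partner_idx = [i for i, a in enumerate(traj.model.atoms)
                   if a.role == partner_role
                   and (partner_resname is None
                        or a.residue_name.upper() == partner_resname.upper())]
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if not partner_idx:
        return 0.0
    box = traj.model.box
    hits = 0
    for k in range(traj.n_frames):
        xyz = traj.frames[k]
        if _pairwise_min_dist(xyz[res_idx], xyz[partner_idx], box) <= cutoff:
            hits += 1
    return hits / traj.n_frames
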