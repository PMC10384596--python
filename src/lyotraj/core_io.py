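"""Structure and trajectory data model with PDB/XYZ input/output.

The pipeline operates on plain atom lists rather than a topology graph: every
stage-preparation rule and every observable used here is geometric, so an atom
record needs only its identity (element, name, residue, chain), its Cartesian
coordinates in Angstroms and a *role* label that classifies it as protein,
water, excipient, ion or ice.  The role labels drive stage construction (water
stripping touches only waters, ice placement only adds ice, neutralisation
only counts charged species) and the contact statistics (excipient-occupancy
needs to find excipient atoms).

Only a narrow, well-defined PDB dialect is supported: ATOM/HETATM, TER,
MODEL/ENDMDL for multi-frame files, and CRYST1 for orthorhombic boxes.
Coordinates are serialized at PDB precision (3 decimals).
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lyotraj")

# ---------------------------------------------------------------------------
# Constants shared across the package
# ---------------------------------------------------------------------------

#: Pipeline stages in execution order: room temperature, freezing, primary
#: drying, secondary drying, reconstitution.
STAGES = ("RT", "F", "1D", "2D", "REC")

ROLES = frozenset({"protein", "water", "excipient", "ion", "ice"})

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP", "H2O"})

#: Residue names recognised as monoatomic ions.
ION_RESNAMES = frozenset({"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "CA2"})

#: Default residue names treated as excipients when flagged by configuration.
#: Free arginine shares the three-letter code of the amino acid; it is told
#: apart from protein arginine by being on its own (non-protein) chain, so
#: excipient classification applies only to single-residue HETATM entries or
#: names listed here that are not part of a polymer chain.
EXCIPIENT_RESNAMES = frozenset({"TXA", "SUC"})

#: Chain identifier alphabet of the PDB dialect (62 symbols).
CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits

#: Atomic masses (u) for the elements this pipeline encounters.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "FE": 55.845, "SE": 78.971,
}


class ParseError(ValueError):
    """Raised when a structure file violates the supported dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """A single atom record.

    ``residue_index`` is 1-based per chain (PDB convention); ``coords`` is a
    3-vector in Angstroms; ``role`` is one of :data:`ROLES`.
    """

    element: str
    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    role: str = "protein"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)


@dataclass
class SimulationBox:
    """Orthorhombic simulation box: edge lengths and origin, both in Angstroms."""

    lengths: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.lengths.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("box lengths and origin must be 3-vectors")
        if not np.all(self.lengths > 0):
            raise ValueError("box lengths must be positive")

    @property
    def is_cubic(self) -> bool:
        return bool(np.allclose(self.lengths, self.lengths[0]))

    @property
    def volume_A3(self) -> float:
        """Box volume in cubic Angstroms."""
        return float(np.prod(self.lengths))

    @property
    def volume_litres(self) -> float:
        # 1 A^3 = 1e-27 L
        return self.volume_A3 * 1e-27


class StructureModel:
    """An ordered collection of atoms with an optional simulation box.

    Atoms belonging to one residue (same ``chain_id`` and ``residue_index``)
    must be contiguous in the atom order; chains partition the system into
    monomers and solvent groups.
    """

    def __init__(self, atoms: Sequence[Atom], box: SimulationBox | None = None):
        self.atoms: list[Atom] = list(atoms)
        self.box = box
        self._check_residue_contiguity()

    def _check_residue_contiguity(self) -> None:
        seen: set[tuple[str, int]] = set()
        prev: tuple[str, int] | None = None
        for a in self.atoms:
            key = (a.chain_id, a.residue_index)
            if key != prev:
                if key in seen:
                    raise ValueError(f"residue {key} is not contiguous in atom order")
                seen.add(key)
                prev = key

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, row in zip(self.atoms, xyz):
            a.coords = row.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if not out or out[-1] != a.chain_id:
                if a.chain_id in out:
                    continue
                out.append(a.chain_id)
        # preserve first-appearance order, unique
        seen: set[str] = set()
        ordered = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.add(a.chain_id)
                ordered.append(a.chain_id)
        return ordered

    def select(self, role: str | None = None, chain_id: str | None = None) -> list[int]:
        """Indices of atoms matching the given role and/or chain."""
        idx = []
        for i, a in enumerate(self.atoms):
            if role is not None and a.role != role:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            idx.append(i)
        return idx

    def subset(self, indices: Iterable[int]) -> "StructureModel":
        atoms = [replace(self.atoms[i], coords=self.atoms[i].coords.copy())
                 for i in indices]
        return StructureModel(atoms, box=self.box)

    def residue_count(self, chain_id: str | None = None) -> int:
        keys = {(a.chain_id, a.residue_index) for a in self.atoms
                if chain_id is None or a.chain_id == chain_id}
        return len(keys)

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, list[int]]]:
        """Residues as (chain_id, residue_index, atom indices), in atom order."""
        out: list[tuple[str, int, list[int]]] = []
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = (a.chain_id, a.residue_index)
            if out and (out[-1][0], out[-1][1]) == key:
                out[-1][2].append(i)
            else:
                out.append((a.chain_id, a.residue_index, [i]))
        return out

    def water_oxygen_indices(self) -> list[int]:
        """One identifiable oxygen atom index per water molecule."""
        out = []
        seen: set[tuple[str, int]] = set()
        for i, a in enumerate(self.atoms):
            if a.role in ("water", "ice") and a.element.upper() == "O":
                key = (a.chain_id, a.residue_index)
                if key not in seen:
                    seen.add(key)
                    out.append(i)
        return out

    def center_of_mass(self, indices: Iterable[int] | None = None) -> np.ndarray:
        if indices is None:
            xyz, m = self.coords, self.masses
        else:
            idx = list(indices)
            xyz = self.coords[idx]
            m = self.masses[idx]
        return np.average(xyz, axis=0, weights=m)

    def copy(self) -> "StructureModel":
        return self.subset(range(len(self.atoms)))


@dataclass
class TrajectorySegment:
    """Frames of coordinates congruent with a StructureModel, tagged with an
    FD stage label (one of :data:`STAGES`)."""

    stage: str
    model: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    time_per_frame: float = 1.0  # ns

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.model):
            raise ValueError(
                f"frames shape {self.frames.shape} incongruent with model of "
                f"{len(self.model)} atoms")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        m = self.model.copy()
        m.coords = self.frames[i]
        return m


def check_stage_order(segments: Sequence[TrajectorySegment]) -> None:
    """Concatenated segments must follow the RT -> F -> 1D -> 2D -> REC order."""
    order = [STAGES.index(s.stage) for s in segments]
    if any(b < a for a, b in zip(order, order[1:])):
        raise ValueError(f"stage labels out of pipeline order: {[s.stage for s in segments]}")


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------


def assign_role(residue_name: str, het: bool = False,
                excipient_resnames: frozenset[str] | set[str] = EXCIPIENT_RESNAMES,
                ) -> str:
    """Classify an atom by residue name.

    HOH/WAT-style names map to water, known ion names to ion, configured
    excipient names to excipient, and everything else to protein.  ICE is an
    internal name used for ice-lattice waters.
    """
    rn = residue_name.strip().upper()
    if rn == "ICE":
        return "ice"
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    if rn in excipient_resnames:
        return "excipient"
    return "protein"


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split())


def _guess_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise ParseError("empty atom name")
    rn = residue_name.strip().upper()
    if rn in ION_RESNAMES:
        return rn.rstrip("+-0123456789")
    # PDB convention: element is encoded in columns 13-14; names like "CA "
    # in a protein residue are carbon-alpha, two-letter elements are rare here
    if name[0].isdigit():
        name = name[1:]
    if rn in _STANDARD_AA or rn in WATER_RESNAMES:
        return name[0].upper()
    if len(name) >= 2 and name[:2].upper() in ATOMIC_MASSES and name[:2].isalpha():
        # e.g. CL, NA in hetero groups
        if name[:2].upper() in ("NA", "CL", "MG", "FE", "SE"):
            return name[:2].upper()
    return name[0].upper()


def _parse_pdb(path: Path, excipient_resnames: frozenset[str] | set[str],
               ) -> tuple[list[list[Atom]], SimulationBox | None]:
    models: list[list[Atom]] = []
    current: list[Atom] = []
    box: SimulationBox | None = None
    in_model = False
    unknown_resnames: set[str] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "CRYST1":
                try:
                    lengths = [float(raw[6:15]), float(raw[15:24]), float(raw[24:33])]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed CRYST1 record") from exc
                box = SimulationBox(lengths=lengths)
            elif rec == "MODEL":
                if current and not in_model:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    name = raw[12:16].strip()
                    resname = raw[17:20].strip()
                    chain = raw[21].strip() or "A"
                    resseq = int(raw[22:26])
                    x = float(raw[30:38])
                    y = float(raw[38:46])
                    z = float(raw[46:54])
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed {rec} record: {raw.rstrip()!r}"
                    ) from exc
                element = raw[76:78].strip() or _guess_element(name, resname)
                role = assign_role(resname, het=(rec == "HETATM"),
                                   excipient_resnames=excipient_resnames)
                if role == "protein" and resname.upper() not in _STANDARD_AA \
                        and resname.upper() not in ("ICE",):
                    unknown_resnames.add(resname)
                current.append(Atom(element=element, name=name,
                                    residue_index=resseq, residue_name=resname,
                                    chain_id=chain, coords=np.array([x, y, z]),
                                    role=role))
            # TER / REMARK / anything else: ignored

    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"{path}: no atoms found")
    if unknown_resnames:
        logger.warning("unknown residue names %s assigned role 'protein'",
                       sorted(unknown_resnames))
    return models, box


def _parse_xyz(path: Path) -> list[list[Atom]]:
    models: list[list[Atom]] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0:
            pass
        frame: list[Atom] = []
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}:{i + 1}: truncated XYZ frame")
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: malformed XYZ atom line")
            el = parts[0]
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 3 + j}: malformed XYZ coordinates") from exc
            frame.append(Atom(element=el, name=el, residue_index=j + 1,
                              residue_name="UNK", chain_id="A",
                              coords=np.array(xyz), role="protein"))
        models.append(frame)
        i += 2 + n
    if not models:
        raise ParseError(f"{path}: empty XYZ file")
    return models


def read_structure(path: str | Path, format: str | None = None,
                   excipient_resnames: Iterable[str] = EXCIPIENT_RESNAMES,
                   ) -> StructureModel:
    """Read a structure file into a :class:`StructureModel`.

    Roles are assigned from residue names (HOH/WAT -> water, NA+/CL- -> ion,
    configured names -> excipient, everything else -> protein; unknown
    residue names default to protein with a logged warning).  For multi-model
    files only the first model is returned; use :func:`read_trajectory` for
    all frames.
    """
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb")
    if fmt == "pdb":
        models, box = _parse_pdb(path, frozenset(r.upper() for r in excipient_resnames))
        return StructureModel(models[0], box=box)
    elif fmt == "xyz":
        models = _parse_xyz(path)
        return StructureModel(models[0], box=None)
    raise ValueError(f"unknown format {fmt!r}")


def read_trajectory(path: str | Path, stage: str = "RT", format: str | None = None,
                    time_per_frame: float = 1.0,
                    excipient_resnames: Iterable[str] = EXCIPIENT_RESNAMES,
                    ) -> TrajectorySegment:
    """Read a multi-model PDB (or multi-frame XYZ) as a trajectory segment."""
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb")
    if fmt == "pdb":
        models, box = _parse_pdb(path, frozenset(r.upper() for r in excipient_resnames))
    else:
        models, box = _parse_xyz(path), None
    ref = StructureModel(models[0], box=box)
    frames = np.array([[a.coords for a in m] for m in models], dtype=float)
    if any(len(m) != len(ref) for m in models):
        raise ParseError(f"{path}: frames have differing atom counts")
    return TrajectorySegment(stage=stage, model=ref, frames=frames,
                             time_per_frame=time_per_frame)


def _format_pdb_atom(serial: int, a: Atom) -> str:
    name = a.name
    # PDB alignment rule: 1-3 character names start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    else:
        name = name[:4]
    record = "HETATM" if a.role in ("water", "ion", "excipient", "ice") else "ATOM  "
    resname = a.residue_name[:3]
    x, y, z = a.coords
    return (f"{record}{serial % 100000:5d} {name} {resname:>3s} {a.chain_id}"
            f"{a.residue_index % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element.upper():>2s}")


def write_structure(model: StructureModel | TrajectorySegment, path: str | Path,
                    format: str = "pdb") -> None:
    """Write a structure (or trajectory segment, as multi-model PDB) to disk.

    Chain ids and residue numbering are preserved; a CRYST1 record is emitted
    when the model carries a box.  The PDB dialect supports at most 62 chains.
    """
    path = Path(path)
    if isinstance(model, TrajectorySegment):
        frames = model.frames
        base = model.model
    else:
        frames = None
        base = model
    if not base.atoms:
        raise ValueError("cannot write an empty model")
    if format == "pdb":
        if len(base.chain_ids) > len(CHAIN_ALPHABET):
            raise ValueError(
                f"PDB dialect supports at most {len(CHAIN_ALPHABET)} chains, "
                f"got {len(base.chain_ids)}")
        lines: list[str] = []
        if base.box is not None:
            lx, ly, lz = base.box.lengths
            lines.append(f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                         f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1")

        def emit_frame(coords: np.ndarray | None) -> None:
            serial = 0
            prev_chain = None
            for i, a in enumerate(base.atoms):
                if prev_chain is not None and a.chain_id != prev_chain:
                    lines.append("TER")
                prev_chain = a.chain_id
                serial += 1
                if coords is not None:
                    a = replace(a, coords=coords[i])
                lines.append(_format_pdb_atom(serial, a))
            lines.append("TER")

        if frames is None:
            emit_frame(None)
        else:
            for k in range(frames.shape[0]):
                lines.append(f"MODEL     {k + 1:4d}")
                emit_frame(frames[k])
                lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif format == "xyz":
        blocks = []
        frame_list = [base.coords] if frames is None else list(frames)
        for xyz in frame_list:
            rows = [str(len(base.atoms)), "generated by lyotraj"]
            for a, r in zip(base.atoms, xyz):
                rows.append(f"{a.element:<2s} {r[0]:12.6f} {r[1]:12.6f} {r[2]:12.6f}")
            blocks.append("\n".join(rows))
        path.write_text("\n".join(blocks) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Time-series export
# ---------------------------------------------------------------------------


def export_timeseries(series: "StageSeries", path: str | Path, sep: str = "\t") -> None:
    """Write a stage-labelled observable series as delimited text with columns
    ``time_ns``, ``stage``, ``value``; stage boundaries are recoverable from
    the stage column."""
    times = np.asarray(series.times, dtype=float)
    values = np.asarray(series.values, dtype=float)
    stages = list(series.stages)
    if times.size == 0:
        raise ValueError("cannot export an empty series")
    if not (len(times) == len(values) == len(stages)):
        raise ValueError("time, value and stage vectors must have equal length")
    df = pd.DataFrame({"time_ns": times, "stage": stages, "value": values})
    df.to_csv(path, sep=sep, index=False)


def read_timeseries(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    expected = {"time_ns", "stage", "value"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {expected - set(df.columns)}")
    return df
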