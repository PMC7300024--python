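"""Structure and multi-frame ensemble I/O, named selections, backbone dihedrals.

The on-disk formats are fixed-column PDB (multi-frame as MODEL/ENDMDL blocks)
and a YAML/JSON selection config mapping group names to inclusive 1-based
residue ranges, ``{group: [{chain, first, last}]}``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from .errors import (
    EmptySelectionError,
    PDBFormatError,
    PDBParseError,
    StructureError,
    UnknownSelectionError,
)

#: residue names recognized as water (PDB and GROMOS conventions)
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT"})

#: atom name identifying lipid head-group phosphates
LIPID_P_NAME = "P"

#: group names with fixed meaning in selection configs
RESERVED_GROUPS = frozenset(
    {f"TMH{i}" for i in range(1, 13)}
    | {f"ICH{i}" for i in range(1, 5)}
    | {"NBD1", "NBD2", "LINKER", "WATER", "LIPID_P"}
)

_TWO_LETTER_ELEMENTS = frozenset(
    {"CL", "BR", "NA", "MG", "FE", "ZN", "MN", "CU", "SE", "SI"}
)


def _infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS:
        return two.capitalize()
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One topology atom; coordinates live on :class:`Frame`."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite position for atom serial {self.serial}")


@dataclass
class Frame:
    """Coordinates (Å) for one snapshot; optional orthorhombic box and time (ps)."""

    positions: np.ndarray
    box: np.ndarray | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an N×3 array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must hold 3 orthorhombic edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Shared topology plus an ordered list of frames."""

    topology: list[AtomRecord]
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Trajectory requires at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise StructureError(
                    f"frame {i} has {fr.n_atoms} atoms, topology has {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def subset_frames(self, start: int | None = None, stop: int | None = None) -> "Trajectory":
        sub = self.frames[slice(start, stop)]
        if not sub:
            raise ValueError("frame subset is empty")
        return Trajectory(self.topology, list(sub))


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclass
class SelectionConfig:
    """Named residue-range groups: ``{name: [(chain, first, last), ...]}``."""

    groups: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ranges in self.groups.items():
            if not ranges:
                raise ValueError(f"group {name!r} is empty")
            for chain, first, last in ranges:
                if first > last:
                    raise ValueError(
                        f"group {name!r}: range {first}-{last} is inverted"
                    )

    @classmethod
    def from_dict(cls, raw: dict) -> "SelectionConfig":
        groups: dict[str, list[tuple[str, int, int]]] = {}
        for name, entries in raw.items():
            groups[name] = [
                (str(e["chain"]), int(e["first"]), int(e["last"])) for e in entries
            ]
        return cls(groups)

    def to_dict(self) -> dict:
        return {
            name: [{"chain": c, "first": f, "last": l} for c, f, l in ranges]
            for name, ranges in self.groups.items()
        }

    @classmethod
    def load(cls, path: str | Path) -> "SelectionConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(raw)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def select(
    trajectory: Trajectory,
    selection: str | tuple[str, int, int],
    config: SelectionConfig | None = None,
) -> np.ndarray:
    """Resolve a named group or ``(chain, first, last)`` range to atom indices.

    Returns sorted, de-duplicated 0-based indices into the topology.
    """
    if isinstance(selection, str):
        if config is None or selection not in config.groups:
            raise UnknownSelectionError(f"unknown selection group {selection!r}")
        ranges = config.groups[selection]
    else:
        ranges = [selection]

    hits: set[int] = set()
    for chain, first, last in ranges:
        for i, atom in enumerate(trajectory.topology):
            if atom.chain_id == chain and first <= atom.residue_seq <= last:
                hits.add(i)
    if not hits:
        raise EmptySelectionError(f"selection {selection!r} matched no atoms")
    return np.array(sorted(hits), dtype=int)


def iter_residues(
    topology: Sequence[AtomRecord],
) -> Iterator[tuple[tuple[str, int, str], list[int]]]:
    """Yield ``((chain, resseq, resname), atom_indices)`` in topology order."""
    key: tuple[str, int, str] | None = None
    idxs: list[int] = []
    for i, atom in enumerate(topology):
        k = (atom.chain_id, atom.residue_seq, atom.residue_name)
        if k != key:
            if key is not None:
                yield key, idxs
            key, idxs = k, []
        idxs.append(i)
    if key is not None:
        yield key, idxs


def water_oxygen_indices(
    topology: Sequence[AtomRecord],
    water_resnames: Iterable[str] = WATER_RESNAMES,
) -> np.ndarray:
    """Indices of water oxygen atoms (element O in a recognized water residue)."""
    names = frozenset(water_resnames)
    return np.array(
        [
            i
            for i, a in enumerate(topology)
            if a.residue_name in names and a.element == "O"
        ],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a :class:`Trajectory`."""
    topology: list[AtomRecord] = []
    frames: list[Frame] = []
    coords: list[list[float]] = []
    box: np.ndarray | None = None
    first_model_done = False
    n_expected: int | None = None

    def flush(line_no: int) -> None:
        nonlocal first_model_done, n_expected, coords
        if not coords:
            return
        if n_expected is None:
            n_expected = len(coords)
        elif len(coords) != n_expected:
            raise StructureError(
                f"MODEL ending near line {line_no} has {len(coords)} atoms, "
                f"expected {n_expected}"
            )
        frames.append(Frame(np.array(coords, dtype=float), box=box))
        first_model_done = True
        coords = []

    line_no = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                    alpha, beta, gamma = (
                        float(line[33:40]),
                        float(line[40:47]),
                        float(line[47:54]),
                    )
                except ValueError as exc:
                    raise PDBParseError(f"bad CRYST1 record: {exc}", line_no) from exc
                if not all(abs(ang - 90.0) < 1e-3 for ang in (alpha, beta, gamma)):
                    raise StructureError(
                        f"line {line_no}: triclinic box unsupported "
                        f"(angles {alpha}, {beta}, {gamma})"
                    )
                box = np.array([a, b, c])
            elif record == "MODEL ":
                if coords:
                    flush(line_no)
            elif record == "ENDMDL":
                flush(line_no)
            elif record in ("ATOM  ", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    serial = int(line[6:11])
                    resseq = int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(f"malformed coordinate field: {exc}", line_no) from exc
                if not first_model_done:
                    atom_name = line[12:16].strip()
                    element = line[76:78].strip() if len(line) >= 78 else ""
                    if not element:
                        element = _infer_element(atom_name)
                    else:
                        element = element.capitalize() if len(element) > 1 else element.upper()
                    topology.append(
                        AtomRecord(
                            serial=serial,
                            atom_name=atom_name,
                            element=element,
                            residue_name=line[17:20].strip(),
                            residue_seq=resseq,
                            chain_id=line[21].strip() or "A",
                            position=(x, y, z),
                        )
                    )
                coords.append([x, y, z])
        flush(line_no)  # trailing frame without ENDMDL

    if not frames:
        raise StructureError(f"no coordinates found in {path}")
    return Trajectory(topology, frames)


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as fixed-column PDB; multiple frames → MODEL blocks."""
    multi = trajectory.n_frames > 1
    lines: list[str] = []
    box = trajectory.frames[0].box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for imodel, frame in enumerate(trajectory.frames, start=1):
        if np.any(np.abs(frame.positions) >= 1e4):
            raise PDBFormatError(
                f"frame {imodel - 1}: coordinate magnitude ≥ 10^4 Å cannot be "
                "written in fixed columns"
            )
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        for atom, pos in zip(trajectory.topology, frame.positions):
            name = atom.atom_name
            if len(name) < 4 and len(atom.element) == 1:
                name = f" {name}"
            rec = "HETATM" if atom.residue_name in WATER_RESNAMES else "ATOM  "
            lines.append(
                f"{rec}{atom.serial % 100000:5d} {name:<4s}{atom.residue_name:>4s}"
                f"{atom.chain_id:>2s}{atom.residue_seq % 10000:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# backbone dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (−180, 180]."""
    b0 = -(p1 - p0)
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


#: default rectangular Ramachandran regions (phi_lo, phi_hi, psi_lo, psi_hi)
DEFAULT_FAVORED = (
    (-100.0, -30.0, -80.0, -5.0),   # right-handed helix
    (-180.0, -80.0, 90.0, 180.0),   # extended strand
)
DEFAULT_ALLOWED = (
    (-180.0, 0.0, -120.0, 60.0),
    (-180.0, -45.0, 60.0, 180.0),
    (-180.0, -45.0, -180.0, -120.0),
    (30.0, 100.0, -20.0, 90.0),     # left-handed helix
)


def _in_rect(phi: float, psi: float, rect: tuple[float, float, float, float]) -> bool:
    lo_f, hi_f, lo_p, hi_p = rect
    return lo_f <= phi <= hi_f and lo_p <= psi <= hi_p


def classify_dihedral(
    phi: float | None,
    psi: float | None,
    favored: Sequence[tuple[float, float, float, float]] = DEFAULT_FAVORED,
    allowed: Sequence[tuple[float, float, float, float]] = DEFAULT_ALLOWED,
) -> str:
    """Classify (phi, psi) as favored / allowed / outlier by rectangular regions.

    Terminal residues (missing phi or psi) classify as ``terminal``.
    """
    if phi is None or psi is None:
        return "terminal"
    if any(_in_rect(phi, psi, r) for r in favored):
        return "favored"
    if any(_in_rect(phi, psi, r) for r in allowed):
        return "allowed"
    return "outlier"


def backbone_dihedrals(
    frame: Frame,
    topology: Sequence[AtomRecord],
) -> list[dict]:
    """Per-residue phi/psi angles (degrees) for one frame.

    Returns a list of dicts with keys ``chain, residue_seq, residue_name, phi,
    psi, region``; phi of the first and psi of the last residue are ``None``.
    Residues missing any of N/CA/C are skipped with a warning.
    """
    residues = []
    for (chain, resseq, resname), idxs in iter_residues(topology):
        if resname in WATER_RESNAMES:
            continue
        atoms = {topology[i].atom_name: i for i in idxs}
        if not {"N", "CA", "C"} <= atoms.keys():
            warnings.warn(
                f"residue {chain}/{resname}{resseq} lacks backbone atoms; skipped"
            )
            continue
        residues.append((chain, resseq, resname, atoms))

    pos = frame.positions
    out: list[dict] = []
    for k, (chain, resseq, resname, atoms) in enumerate(residues):
        prev_ = residues[k - 1] if k > 0 else None
        next_ = residues[k + 1] if k + 1 < len(residues) else None
        # consecutive in chain and numbering, else treat as chain break
        if prev_ is not None and not (prev_[0] == chain and prev_[1] == resseq - 1):
            prev_ = None
        if next_ is not None and not (next_[0] == chain and next_[1] == resseq + 1):
            next_ = None
        phi = psi = None
        if prev_ is not None:
            phi = dihedral_angle(
                pos[prev_[3]["C"]], pos[atoms["N"]], pos[atoms["CA"]], pos[atoms["C"]]
            )
        if next_ is not None:
            psi = dihedral_angle(
                pos[atoms["N"]], pos[atoms["CA"]], pos[atoms["C"]], pos[next_[3]["N"]]
            )
        out.append(
            {
                "chain": chain,
                "residue_seq": resseq,
                "residue_name": resname,
                "phi": phi,
                "psi": psi,
                "region": classify_dihedral(phi, psi),
            }
        )
    return out
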