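"""Probe-grid binding-pocket detection, lining-atom/polarity characterization,
and docking-pose-to-site assignment.

Pocket detection places a probe sphere on every grid point of a search box
that (a) clashes with no protein heavy atom (distance ≥ probe + vdW radius)
and (b) is buried — a protein surface hit within a ray length along at least
``burial_min`` of the six axis directions. Probes are clustered by
26-neighborhood connectivity; pocket volume is ``n_probes × spacing³``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import AtomRecord

#: Bondi van der Waals radii, Å
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "H": 1.2}
VDW_DEFAULT = 1.7
PROBE_RADIUS = 1.4

RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PRO"}),
    "aromatic": frozenset({"PHE", "TYR", "TRP"}),
    "polar": frozenset({"SER", "THR", "ASN", "GLN", "CYS", "GLY", "HIS"}),
    "charged": frozenset({"ASP", "GLU", "LYS", "ARG"}),
}

_POLAR_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass
class SearchBox:
    """Axis-aligned box: center plus full edge lengths (Å)."""

    center: np.ndarray
    extents: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.extents = np.asarray(self.extents, dtype=float)
        if np.any(self.extents <= 0):
            raise ValueError("extents must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.extents / 2

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.extents / 2


@dataclass
class Pocket:
    """Connected probe cluster with volume and lining characterization."""

    probe_centers: np.ndarray
    grid_spacing: float
    volume: float
    lining_atoms: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    polarity: float | None = None
    residue_classes: dict[str, float] = field(default_factory=dict)

    @property
    def n_probes(self) -> int:
        return len(self.probe_centers)


def detect_pockets(
    positions: np.ndarray,
    elements: Sequence[str],
    search_box: SearchBox,
    grid_spacing: float = 0.8,
    burial_min: int = 5,
    probe_radius: float = PROBE_RADIUS,
    ray_length: float = 8.0,
    vdw_radii: Mapping[str, float] = VDW_RADII,
) -> list[Pocket]:
    """Detect pockets on a grid inside ``search_box``; sorted by volume desc.

    A direction counts as buried when some heavy atom lies within ``vdw`` of
    the axis ray with its surface reachable within ``ray_length`` along the
    ray (the along-axis distance to the atom *surface*,
    ``t − vdw ≤ ray_length``, is used so shells just beyond the nominal ray
    length still occlude).
    """
    heavy = np.array([i for i, e in enumerate(elements) if e != "H"], dtype=int)
    pos = np.asarray(positions, dtype=float)[heavy]
    radii = np.array([vdw_radii.get(elements[i], VDW_DEFAULT) for i in heavy])
    max_r = float(radii.max()) if len(radii) else VDW_DEFAULT

    nx, ny, nz = (
        max(1, int(np.floor(e / grid_spacing)) + 1) for e in search_box.extents
    )
    gx = search_box.lo[0] + np.arange(nx) * grid_spacing
    gy = search_box.lo[1] + np.arange(ny) * grid_spacing
    gz = search_box.lo[2] + np.arange(nz) * grid_spacing
    grid = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)

    if len(pos) == 0:
        return []
    tree = cKDTree(pos)

    # clash-free: no heavy atom with distance < probe + vdW(atom)
    clash_free = np.ones(len(grid), dtype=bool)
    neighbor_lists = tree.query_ball_point(grid, probe_radius + max_r)
    for gi, neigh in enumerate(neighbor_lists):
        for ai in neigh:
            if np.linalg.norm(grid[gi] - pos[ai]) < probe_radius + radii[ai]:
                clash_free[gi] = False
                break

    # burial along the 6 axis rays
    dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    occluded = np.zeros(len(grid), dtype=bool)
    candidates = np.nonzero(clash_free)[0]
    search_r = ray_length + 2 * max_r
    for gi in candidates:
        neigh = tree.query_ball_point(grid[gi], search_r)
        if not neigh:
            continue
        rel = pos[neigh] - grid[gi]
        r_n = radii[neigh]
        n_buried = 0
        for d in dirs:
            t = rel @ d
            perp2 = np.einsum("ij,ij->i", rel, rel) - t**2
            hit = (t > 0) & (t - r_n <= ray_length) & (perp2 <= r_n**2)
            if np.any(hit):
                n_buried += 1
        if n_buried >= burial_min:
            occluded[gi] = True

    keep = clash_free & occluded
    if not np.any(keep):
        return []

    # 26-connectivity clustering on the grid lattice
    lattice = keep.reshape(nx, ny, nz)
    labels, n_labels = ndimage.label(lattice, structure=np.ones((3, 3, 3), dtype=int))
    flat_labels = labels.reshape(-1)
    pockets = []
    for lab in range(1, n_labels + 1):
        members = grid[flat_labels == lab]
        pockets.append(
            Pocket(
                probe_centers=members,
                grid_spacing=grid_spacing,
                volume=len(members) * grid_spacing**3,
            )
        )
    pockets.sort(key=lambda p: -p.volume)
    return pockets


def lining_atoms(
    pocket: Pocket,
    positions: np.ndarray,
    elements: Sequence[str],
    r_line: float = 5.0,
) -> np.ndarray:
    """Protein heavy atoms within ``r_line`` of any probe center (sorted, unique)."""
    heavy = np.array([i for i, e in enumerate(elements) if e != "H"], dtype=int)
    if len(heavy) == 0 or pocket.n_probes == 0:
        return np.array([], dtype=int)
    tree = cKDTree(np.asarray(positions, dtype=float)[heavy])
    hits: set[int] = set()
    for neigh in tree.query_ball_point(pocket.probe_centers, r_line):
        hits.update(int(heavy[j]) for j in neigh)
    return np.array(sorted(hits), dtype=int)


def pocket_polarity(lining_elements: Sequence[str]) -> float | None:
    """(N+O+S) / (N+O+S+C) over lining atoms; ``None`` when undefined."""
    polar = carbon = 0
    for e in lining_elements:
        if e in _POLAR_ELEMENTS:
            polar += 1
        elif e == "C":
            carbon += 1
        else:
            warnings.warn(f"element {e!r} ignored in polarity calculation")
    denom = polar + carbon
    if denom == 0:
        return None
    return polar / denom


def classify_residue(residue_name: str) -> str | None:
    for cls, members in RESIDUE_CLASSES.items():
        if residue_name in members:
            return cls
    return None


def residue_class_distribution(
    lining: np.ndarray,
    topology: Sequence[AtomRecord],
) -> dict[str, float]:
    """Percentage of distinct lining residues per class (sums to 100)."""
    residues = {
        (topology[i].chain_id, topology[i].residue_seq, topology[i].residue_name)
        for i in np.asarray(lining, dtype=int)
    }
    counts = {cls: 0 for cls in RESIDUE_CLASSES}
    total = 0
    for _, _, resname in residues:
        cls = classify_residue(resname)
        if cls is None:
            warnings.warn(f"residue {resname!r} has no class; ignored")
            continue
        counts[cls] += 1
        total += 1
    if total == 0:
        return {}
    return {cls: 100.0 * n / total for cls, n in counts.items()}


def relative_change(reference_pct: float, variant_pct: float) -> float:
    """(variant − reference) / reference × 100, the report convention."""
    if reference_pct == 0:
        raise ValueError("reference percentage is zero")
    return (variant_pct - reference_pct) / reference_pct * 100.0


def characterize_pocket(
    pocket: Pocket,
    positions: np.ndarray,
    topology: Sequence[AtomRecord],
    r_line: float = 5.0,
) -> Pocket:
    """Fill lining atoms, polarity and residue-class distribution in place."""
    elements = [a.element for a in topology]
    lin = lining_atoms(pocket, positions, elements, r_line)
    pocket.lining_atoms = lin
    pocket.polarity = pocket_polarity([elements[i] for i in lin])
    pocket.residue_classes = residue_class_distribution(lin, topology)
    return pocket


# ---------------------------------------------------------------------------
# docking poses and site assignment
# ---------------------------------------------------------------------------

@dataclass
class DockPose:
    """One ranked ligand pose; rank 1 is the best (lowest) score."""

    ligand_id: str
    rank: int
    score: float
    heavy_atom_positions: np.ndarray

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be ≥ 1")
        self.heavy_atom_positions = np.asarray(self.heavy_atom_positions, dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.heavy_atom_positions.mean(axis=0)


@dataclass
class SiteAssignment:
    ligand_id: str
    rank: int
    site: str            # site name or "outside"
    distance: float      # Å to the assigned (or nearest) site center
    tied: bool = False


def assign_pose(
    pose: DockPose,
    site_centers: Mapping[str, Sequence[float]],
    cutoff: float = 10.0,
) -> SiteAssignment:
    """Nearest site by centroid distance; beyond ``cutoff`` → ``outside``.

    Ties within 10⁻⁶ Å break lexicographically on the site name and are
    flagged.
    """
    if not site_centers:
        raise ValueError("need at least one site center")
    centroid = pose.centroid
    dists = {
        name: float(np.linalg.norm(centroid - np.asarray(c, dtype=float)))
        for name, c in site_centers.items()
    }
    best = min(dists.values())
    tied_names = sorted(name for name, d in dists.items() if d - best < 1e-6)
    site = tied_names[0]
    tied = len(tied_names) > 1
    if best > cutoff:
        return SiteAssignment(pose.ligand_id, pose.rank, "outside", best, tied)
    return SiteAssignment(pose.ligand_id, pose.rank, site, dists[site], tied)


def save_pose_set(
    poses: Sequence[DockPose],
    pdb_path,
    tsv_path,
) -> None:
    """Persist poses as a multi-MODEL PDB plus a TSV score table.

    MODEL *k* holds the coordinates of TSV row *k* (columns ``ligand_id``,
    ``rank``, ``score_kcal_mol``). All poses must share an atom count.
    """
    from .structure_io import AtomRecord, Frame, Trajectory, write_pdb

    counts = {p.heavy_atom_positions.shape[0] for p in poses}
    if len(counts) != 1:
        raise ValueError("all poses must have the same heavy-atom count")
    n = counts.pop()
    topology = [
        AtomRecord(
            serial=i + 1,
            atom_name=f"C{i + 1}",
            element="C",
            residue_name="LIG",
            residue_seq=1,
            chain_id="L",
            position=tuple(poses[0].heavy_atom_positions[i]),
        )
        for i in range(n)
    ]
    frames = [Frame(p.heavy_atom_positions) for p in poses]
    write_pdb(Trajectory(topology, frames), pdb_path)
    table = pd.DataFrame(
        {
            "ligand_id": [p.ligand_id for p in poses],
            "rank": [p.rank for p in poses],
            "score_kcal_mol": [p.score for p in poses],
        }
    )
    table.to_csv(tsv_path, sep="\t", index=False)


def load_pose_set(pdb_path, tsv_path) -> list[DockPose]:
    """Inverse of :func:`save_pose_set`."""
    from .structure_io import read_pdb

    traj = read_pdb(pdb_path)
    table = pd.read_csv(tsv_path, sep="\t")
    if len(table) != traj.n_frames:
        raise ValueError(
            f"score table has {len(table)} rows but PDB has {traj.n_frames} MODELs"
        )
    return [
        DockPose(
            ligand_id=str(row.ligand_id),
            rank=int(row.rank),
            score=float(row.score_kcal_mol),
            heavy_atom_positions=traj.frames[k].positions,
        )
        for k, row in enumerate(table.itertuples())
    ]


def site_table(
    poses: Sequence[DockPose],
    site_centers: Mapping[str, Sequence[float]],
    cutoff: float = 10.0,
) -> pd.DataFrame:
    """Per-ligand best (minimum) score per site; NaN where no pose assigned.

    Ligands whose poses all fall outside every site appear with all-NaN rows
    (the 'unbound' readout).
    """
    sites = sorted(site_centers)
    best: dict[str, dict[str, float]] = {}
    for pose in poses:
        best.setdefault(pose.ligand_id, {})
        assignment = assign_pose(pose, site_centers, cutoff)
        if assignment.site == "outside":
            continue
        cur = best[pose.ligand_id].get(assignment.site)
        if cur is None or pose.score < cur:
            best[pose.ligand_id][assignment.site] = pose.score
    rows = []
    for ligand in sorted(best):
        row = {"ligand_id": ligand}
        for s in sites:
            row[s] = best[ligand].get(s, float("nan"))
        row["unbound"] = all(np.isnan(row[s]) for s in sites)
        rows.append(row)
    return pd.DataFrame(rows)
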