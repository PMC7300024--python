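"""Water-occupancy cavity volumetrics.

The central cavity of a transmembrane helix bundle is modeled as the
intersection of a membrane slab (along the average bundle axis) with the 2D
convex hull of the helix CA xy-projections, shrunk inward by a margin. The
cavity volume of a frame is ``n_cavity_waters × v_water`` — exactly linear in
the water count by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from .errors import InsufficientDataError
from .structure_io import (
    AtomRecord,
    Frame,
    SelectionConfig,
    Trajectory,
    select,
    water_oxygen_indices,
)

#: default per-water volume, Å³ (bulk molecular volume of water near 303 K)
V_WATER_DEFAULT = 30.0

AVOGADRO = 0.602214076  # 10^24 / mol, i.e. molecules per cm³·(g/mol) scale


def water_volume_from_density(density_g_cm3: float = 0.996, molar_mass: float = 18.015) -> float:
    """Per-molecule volume (Å³) of bulk water at the given density."""
    return molar_mass / (density_g_cm3 * AVOGADRO)


@dataclass
class CavityRegion:
    """Slab ∩ shrunk convex polygon; coordinates in the bundle-aligned frame."""

    z_lo: float
    z_hi: float
    hull_xy: np.ndarray  # (M, 2) hull vertices, counter-clockwise
    shrink_margin: float = 1.5
    #: rotation applied to world coordinates before testing (bundle axis → z)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if not self.z_lo < self.z_hi:
            raise ValueError("z_lo must be < z_hi")
        self.hull_xy = np.asarray(self.hull_xy, dtype=float)
        if self.hull_xy.shape[0] < 3:
            raise ValueError("hull needs ≥ 3 vertices")

    def shrunk_polygon(self) -> Polygon:
        poly = Polygon(self.hull_xy)
        if self.shrink_margin:
            poly = poly.buffer(-self.shrink_margin, join_style="mitre")
        if poly.is_empty:
            raise ValueError("shrink margin collapses the hull to nothing")
        return poly

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: strict interior of the shrunk region (world coords)."""
        pts = np.asarray(points, dtype=float) @ self.rotation.T
        in_slab = (pts[:, 2] >= self.z_lo) & (pts[:, 2] <= self.z_hi)
        poly = self.shrunk_polygon()
        mask = np.zeros(len(pts), dtype=bool)
        for i in np.nonzero(in_slab)[0]:
            # shapely contains() is strict: boundary points are excluded
            mask[i] = poly.contains(Point(pts[i, 0], pts[i, 1]))
        return mask


def rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the given unit vector onto +z."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def membrane_slab(
    frame: Frame,
    lipid_p_indices: Sequence[int] | None = None,
    explicit_bounds: tuple[float, float] | None = None,
    min_per_leaflet: int = 10,
) -> tuple[float, float]:
    """Slab bounds along z from lipid phosphate z-coordinates, or pass-through.

    Leaflets are split at the joint median; each bound is the mean z of one
    leaflet's phosphates.
    """
    if explicit_bounds is not None:
        z_lo, z_hi = explicit_bounds
        if not z_lo < z_hi:
            raise ValueError("explicit bounds must satisfy z_lo < z_hi")
        return float(z_lo), float(z_hi)
    if lipid_p_indices is None or len(lipid_p_indices) == 0:
        raise InsufficientDataError("need lipid phosphates or explicit bounds")
    z = frame.positions[np.asarray(lipid_p_indices, dtype=int), 2]
    mid = float(np.median(z))
    lower, upper = z[z <= mid], z[z > mid]
    if len(lower) < min_per_leaflet or len(upper) < min_per_leaflet:
        raise InsufficientDataError(
            f"fewer than {min_per_leaflet} phosphates in a leaflet"
        )
    return float(lower.mean()), float(upper.mean())


def cavity_region(
    frame: Frame,
    topology: Sequence[AtomRecord],
    helix_selections: dict[str, np.ndarray],
    z_bounds: tuple[float, float] | None = None,
    shrink_margin: float = 1.5,
    slab_fraction: float = 0.8,
    align: bool = True,
) -> CavityRegion:
    """Build the cavity region for one frame from the helix CA atoms.

    The frame is internally rotated so the bundle average axis lies along z
    (orientation independence); the hull is the convex hull of helix CA
    xy-projections. Without explicit ``z_bounds`` the slab is the central
    ``slab_fraction`` of the helix CA z-extent.
    """
    from .helix_bundle import fit_axis  # local import avoids a cycle

    ca_idx: list[int] = []
    axes = []
    for name, idx in helix_selections.items():
        idx = np.asarray(idx, dtype=int)
        ca = [i for i in idx if topology[i].atom_name == "CA"]
        if len(ca) >= 4:
            axes.append(fit_axis(frame.positions[ca]).direction)
        ca_idx.extend(ca)
    if len(ca_idx) < 3:
        raise InsufficientDataError("too few helix CA atoms to build a hull")

    if align and axes:
        mean_axis = np.mean(axes, axis=0)
        rot = rotation_to_z(mean_axis)
    else:
        rot = np.eye(3)

    ca = frame.positions[np.array(sorted(set(ca_idx)), dtype=int)] @ rot.T
    hull = ConvexHull(ca[:, :2])
    hull_xy = ca[hull.vertices, :2]

    if z_bounds is None:
        z_min, z_max = float(ca[:, 2].min()), float(ca[:, 2].max())
        half_trim = (1.0 - slab_fraction) * (z_max - z_min) / 2.0
        z_bounds = (z_min + half_trim, z_max - half_trim)

    return CavityRegion(
        z_lo=z_bounds[0],
        z_hi=z_bounds[1],
        hull_xy=hull_xy,
        shrink_margin=shrink_margin,
        rotation=rot,
    )


def waters_in_cavity(
    frame: Frame,
    topology: Sequence[AtomRecord],
    region: CavityRegion,
) -> np.ndarray:
    """Indices of water oxygens inside the cavity region (may be empty)."""
    ow = water_oxygen_indices(topology)
    if len(ow) == 0:
        return ow
    mask = region.contains(frame.positions[ow])
    return ow[mask]


def dbp_volume(
    frame: Frame,
    topology: Sequence[AtomRecord],
    region: CavityRegion,
    v_water: float = V_WATER_DEFAULT,
) -> float:
    """Cavity volume = (number of cavity waters) × v_water, exactly."""
    if v_water <= 0:
        raise ValueError("v_water must be positive")
    return len(waters_in_cavity(frame, topology, region)) * v_water


@dataclass
class VolumeDistribution:
    """Normalized histogram of per-frame cavity volumes."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_frames: int
    volumes: np.ndarray
    mean: float
    sd: float
    mode: float

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if self.n_frames > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def volume_distribution(
    trajectory: Trajectory,
    region: CavityRegion | Callable[[Frame], CavityRegion],
    bin_width: float = 30.0,
    v_water: float = V_WATER_DEFAULT,
) -> VolumeDistribution:
    """Distribution of cavity volumes over frames.

    ``region`` may be a fixed :class:`CavityRegion` or a per-frame builder
    (frame-adaptive hull).
    """
    vols = []
    for fr in trajectory.frames:
        reg = region(fr) if callable(region) else region
        vols.append(dbp_volume(fr, trajectory.topology, reg, v_water=v_water))
    volumes = np.array(vols)
    lo = np.floor(volumes.min() / bin_width) * bin_width
    n_bins = int(np.floor((volumes.max() - lo) / bin_width)) + 1
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, edges = np.histogram(volumes, bins=edges)
    probs = counts / counts.sum()
    mode_bin = int(np.argmax(counts))
    return VolumeDistribution(
        bin_edges=edges,
        probabilities=probs,
        n_frames=len(volumes),
        volumes=volumes,
        mean=float(volumes.mean()),
        sd=float(volumes.std(ddof=1)) if len(volumes) > 1 else 0.0,
        mode=float((edges[mode_bin] + edges[mode_bin + 1]) / 2),
    )


def helix_selection_map(
    trajectory: Trajectory, config: SelectionConfig, prefix: str = "TMH"
) -> dict[str, np.ndarray]:
    """Resolve all config groups named ``<prefix>N`` to atom index arrays."""
    out = {}
    for name in config.groups:
        if name.startswith(prefix) and name[len(prefix):].isdigit():
            out[name] = select(trajectory, name, config)
    return out
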