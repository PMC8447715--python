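"""Compactness metrics: SASA, van der Waals / envelope volumes, packing.

SASA uses the Shrake-Rupley rolling-probe algorithm with a deterministic
golden-section spiral point set, so results are exactly reproducible for a
given point count. Volumes are computed by grid integration: the van der
Waals volume is the grid measure of the union of vdW spheres; the total
(solvent-excluded envelope) volume is obtained by inflating every sphere by
the probe radius and then eroding the occupied grid by a probe-radius ball.
Packing density is the ratio of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .structure_io import StructureModel

__all__ = [
    "VDW_RADII",
    "CompactnessMetrics",
    "sphere_points",
    "compute_sasa",
    "compute_volumes",
    "compactness_metrics",
]

#: Bondi van der Waals radii (Angstrom); configurable per call.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4
MAX_GRID_CELLS = 10**8


@dataclass
class CompactnessMetrics:
    """Per-structure compactness record (Angstrom-based units)."""

    sasa: float  # A^2
    vdw_volume: float  # A^3
    total_volume: float  # A^3

    @property
    def packing_density(self) -> float:
        return self.vdw_volume / self.total_volume

    @property
    def surface_to_volume(self) -> float:
        return self.sasa / self.total_volume


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.clip(1 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _heavy_atoms(
    model: StructureModel, radii: dict[str, float], default_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    coords, rs = [], []
    unknown: set[str] = set()
    for atom in model.atoms():
        if atom.element == "H":
            continue
        r = radii.get(atom.element)
        if r is None:
            unknown.add(atom.element)
            r = default_radius
        coords.append(atom.coord)
        rs.append(r)
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: using default radius {default_radius} A",
            stacklevel=3,
        )
    if not coords:
        raise ValueError("no heavy atoms in model")
    return np.asarray(coords), np.asarray(rs)


def compute_sasa(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
    radii: dict[str, float] = VDW_RADII,
    default_radius: float = DEFAULT_RADIUS,
) -> float:
    """Shrake-Rupley solvent-accessible surface area over heavy atoms (A^2)."""
    coords, rs = _heavy_atoms(model, radii, default_radius)
    pts = sphere_points(n_points)
    expanded = rs + probe
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    area = 0.0
    for i in range(len(coords)):
        surface = coords[i] + expanded[i] * pts
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neighbours:
            nb_coords = coords[neighbours]
            nb_r = expanded[neighbours]
            d2 = ((surface[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        area += 4 * np.pi * expanded[i] ** 2 * n_acc / n_points
    return float(area)


def _occupancy_grid(
    coords: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing: float,
) -> np.ndarray:
    """Boolean grid of cells whose centre lies inside any sphere."""
    grid = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r - origin) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [origin[k] + spacing * np.arange(lo[k], hi[k]) for k in range(3)]
        dx2 = (ax[0] - c[0]) ** 2
        dy2 = (ax[1] - c[1]) ** 2
        dz2 = (ax[2] - c[2]) ** 2
        inside = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside
    return grid


def _ball_element(radius: float, spacing: float) -> np.ndarray:
    # half-cell compensation centres the rasterized ball's boundary on the
    # true radius; without it the eroded volume converges only linearly
    r_eff = radius + 0.5 * spacing
    n = int(np.floor(r_eff / spacing))
    ax = spacing * np.arange(-n, n + 1)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return d2 <= r_eff * r_eff


def compute_volumes(
    model: StructureModel,
    grid_spacing: float = 0.5,
    probe: float = PROBE_RADIUS,
    radii: dict[str, float] = VDW_RADII,
    default_radius: float = DEFAULT_RADIUS,
) -> tuple[float, float]:
    """Grid-integrated (vdw_volume, total_volume) in A^3.

    ``total_volume`` is the solvent-excluded envelope: the union of
    probe-inflated spheres eroded by a probe-radius ball. Both estimates
    converge to the analytic values as the spacing shrinks.
    """
    coords, rs = _heavy_atoms(model, radii, default_radius)
    margin = rs.max() + probe + 2 * grid_spacing
    origin = coords.min(axis=0) - margin
    top = coords.max(axis=0) + margin
    shape = tuple(np.ceil((top - origin) / grid_spacing).astype(int) + 1)
    n_cells = int(np.prod(shape))
    if n_cells > MAX_GRID_CELLS:
        raise ValueError(
            f"grid of {n_cells} cells exceeds {MAX_GRID_CELLS}; use a coarser grid_spacing"
        )
    cell_volume = grid_spacing**3

    vdw_grid = _occupancy_grid(coords, rs, origin, shape, grid_spacing)
    vdw_volume = float(vdw_grid.sum() * cell_volume)

    sas_grid = _occupancy_grid(coords, rs + probe, origin, shape, grid_spacing)
    ses_grid = binary_erosion(sas_grid, structure=_ball_element(probe, grid_spacing))
    # the envelope always contains the vdW union; enforce on the grid too
    ses_grid |= vdw_grid
    total_volume = float(ses_grid.sum() * cell_volume)
    return vdw_volume, total_volume


def compactness_metrics(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
    grid_spacing: float = 0.5,
    radii: dict[str, float] = VDW_RADII,
) -> CompactnessMetrics:
    """Assemble SASA, volumes, packing density and surface/volume ratio."""
    sasa = compute_sasa(model, probe=probe, n_points=n_points, radii=radii)
    vdw, total = compute_volumes(model, grid_spacing=grid_spacing, probe=probe, radii=radii)
    return CompactnessMetrics(sasa=sasa, vdw_volume=vdw, total_volume=total)
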