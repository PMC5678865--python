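"""Lattice geometry: the cubic grid, the embedded blood vessel, and cell seeding.

The tissue is a cube of 10-um voxels; each voxel holds at most one cell.
A blood vessel, when present, is a k x k voxel column spanning the full
grid along one axis, surrounded by a one-voxel-thick lining shell where
endothelial scavenger cells sit.  Secreting cells (fibroblast-like) and
tissue scavenger (CXCR7+) cells are placed uniformly at random, or
confined to cubic clusters for the two-cluster source/sink experiments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import UM3_TO_L

__all__ = [
    "CellType",
    "Grid",
    "VesselSpec",
    "CellPlacement",
    "ClusterSpec",
    "ConfigurationError",
    "CapacityError",
    "build_grid",
    "place_vessel",
    "seed_cells_random",
    "seed_cluster",
    "placements_to_frame",
    "frame_to_placements",
]


class ConfigurationError(ValueError):
    """Raised for geometrically unrealizable configuration values."""


class CapacityError(ValueError):
    """Raised when more cells are requested than admissible voxels exist."""


class CellType(str, enum.Enum):
    SECRETING = "secreting"
    CXCR7_TISSUE = "cxcr7_tissue"
    CXCR7_ENDOTHELIAL = "cxcr7_endothelial"


@dataclass(frozen=True)
class Grid:
    """Cubic lattice of cubic voxels.

    Attributes
    ----------
    side_length : float
        Edge length of the simulated tissue cube (um).
    voxel_size : float
        Edge length of one voxel (um); also the nominal cell diameter.
    dims : tuple of int
        Voxels per axis.
    voxel_volume_l : float
        Volume of one voxel in litres (10 um -> 1e-12 L = 1 pL).
    """

    side_length: float
    voxel_size: float
    dims: tuple[int, int, int]
    voxel_volume_l: float

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def volume_mm3(self) -> float:
        """Total domain volume in mm^3."""
        return (self.side_length * 1e-3) ** 3

    def voxel_center_um(self, voxel: tuple[int, int, int]) -> tuple[float, ...]:
        return tuple((i + 0.5) * self.voxel_size for i in voxel)


@dataclass(frozen=True)
class VesselSpec:
    """A straight vessel column and its one-voxel lining shell.

    ``vessel_voxels`` are the blood-filled lattice sites (no tissue, no
    cells); ``lining_voxels`` is the shell of tissue voxels laterally
    adjacent (faces and cross-sectional diagonals) to the vessel on every
    layer along the vessel axis.
    """

    cross_section_area: float  # um^2
    axis: int
    block_width: int  # k of the k x k cross-section
    vessel_voxels: frozenset[tuple[int, int, int]]
    lining_voxels: frozenset[tuple[int, int, int]]

    def vessel_mask(self, dims: tuple[int, int, int]) -> np.ndarray:
        mask = np.zeros(dims, dtype=bool)
        for v in self.vessel_voxels:
            mask[v] = True
        return mask

    def lining_mask(self, dims: tuple[int, int, int]) -> np.ndarray:
        mask = np.zeros(dims, dtype=bool)
        for v in self.lining_voxels:
            mask[v] = True
        return mask


@dataclass(frozen=True)
class CellPlacement:
    cell_type: CellType
    voxel: tuple[int, int, int]


@dataclass(frozen=True)
class ClusterSpec:
    """A cubic confinement region for one cell cluster.

    ``extent`` defaults to six cell diameters (60 um), the confinement
    cube used in the two-cluster experiments; ``center`` is the geometric
    center of the cube in um along each axis.
    """

    center_um: tuple[float, float, float]
    extent_um: float = 60.0
    n_cells: int = 100

    def voxel_block(self, grid: Grid) -> list[tuple[int, int, int]]:
        """Enumerate the voxels of the confinement cube."""
        n = int(round(self.extent_um / grid.voxel_size))
        if not np.isclose(n * grid.voxel_size, self.extent_um):
            raise ConfigurationError(
                f"cluster extent {self.extent_um} um is not a whole number of voxels"
            )
        starts = []
        for c in self.center_um:
            lo = (c - self.extent_um / 2.0) / grid.voxel_size
            i0 = int(round(lo))
            if not np.isclose(i0, lo):
                raise ConfigurationError(
                    f"cluster centered at {self.center_um} um is not voxel-aligned"
                )
            starts.append(i0)
        for s, d in zip(starts, grid.dims):
            if s < 0 or s + n > d:
                raise ConfigurationError("cluster cube extends outside the grid")
        return [
            (i, j, k)
            for i in range(starts[0], starts[0] + n)
            for j in range(starts[1], starts[1] + n)
            for k in range(starts[2], starts[2] + n)
        ]


def build_grid(side_length: float, voxel_size: float = 10.0) -> Grid:
    """Build the cubic lattice.

    Parameters are in um; ``side_length`` must be a positive integer
    multiple of ``voxel_size``.
    """
    if side_length <= 0 or voxel_size <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    n = side_length / voxel_size
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"side_length {side_length} is not a multiple of voxel_size {voxel_size}"
        )
    n = int(round(n))
    return Grid(
        side_length=float(side_length),
        voxel_size=float(voxel_size),
        dims=(n, n, n),
        voxel_volume_l=voxel_size**3 * UM3_TO_L,
    )


def place_vessel(grid: Grid, cross_section_area: float = 400.0, axis: int = 2) -> VesselSpec:
    """Embed a straight vessel spanning the grid along ``axis``.

    The cross-section must be realizable as a k x k voxel block
    (400 um^2 with 10-um voxels -> 2 x 2).  The block is centered on the
    grid; an off-center remainder is floored toward the origin.  The
    lining shell is the (k+2)^2 - k^2 ring of tissue voxels around the
    cross-section on every layer, including diagonal neighbors
    (12 voxels per layer for k = 2).
    """
    if axis not in (0, 1, 2):
        raise ConfigurationError(f"axis must be 0, 1 or 2, got {axis}")
    k_f = np.sqrt(cross_section_area) / grid.voxel_size
    k = int(round(k_f))
    if k < 1 or abs(k - k_f) > 1e-9:
        raise ConfigurationError(
            f"cross-section {cross_section_area} um^2 is not a k x k voxel block"
        )
    lateral = [a for a in (0, 1, 2) if a != axis]
    starts = {}
    for a in lateral:
        d = grid.dims[a]
        if k + 2 > d:
            raise ConfigurationError("vessel (with lining) does not fit in the grid")
        starts[a] = (d - k) // 2

    vessel = set()
    lining = set()
    n_axis = grid.dims[axis]
    a0, a1 = lateral
    lo0, lo1 = starts[a0], starts[a1]
    for layer in range(n_axis):
        for d0 in range(-1, k + 1):
            for d1 in range(-1, k + 1):
                i0, i1 = lo0 + d0, lo1 + d1
                if not (0 <= i0 < grid.dims[a0] and 0 <= i1 < grid.dims[a1]):
                    continue
                idx = [0, 0, 0]
                idx[axis] = layer
                idx[a0] = i0
                idx[a1] = i1
                inside = 0 <= d0 < k and 0 <= d1 < k
                (vessel if inside else lining).add(tuple(idx))
    return VesselSpec(
        cross_section_area=float(cross_section_area),
        axis=axis,
        block_width=k,
        vessel_voxels=frozenset(vessel),
        lining_voxels=frozenset(lining),
    )


def _admissible(
    grid: Grid,
    vessel: VesselSpec | None,
    cell_type: CellType,
    occupied: set[tuple[int, int, int]],
) -> list[tuple[int, int, int]]:
    if cell_type is CellType.CXCR7_ENDOTHELIAL:
        if vessel is None:
            raise ConfigurationError("endothelial cells require a vessel")
        pool = set(vessel.lining_voxels)
    else:
        pool = {
            (i, j, k)
            for i in range(grid.dims[0])
            for j in range(grid.dims[1])
            for k in range(grid.dims[2])
        }
        if vessel is not None:
            pool -= set(vessel.vessel_voxels)
    pool -= set(occupied)
    return sorted(pool)


def seed_cells_random(
    grid: Grid,
    vessel: VesselSpec | None,
    cell_type: CellType,
    n: int,
    seed: int | np.random.Generator,
    occupied: set[tuple[int, int, int]] | None = None,
) -> list[CellPlacement]:
    """Place ``n`` cells uniformly at random on admissible empty voxels.

    Admissible means: outside the vessel, not already occupied, and (for
    endothelial scavengers) restricted to the lining shell.  Sampling is
    without replacement and reproducible for a fixed seed.
    """
    occupied = occupied or set()
    pool = _admissible(grid, vessel, cell_type, occupied)
    if n > len(pool):
        raise CapacityError(f"requested {n} cells but only {len(pool)} admissible voxels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return [CellPlacement(cell_type, pool[i]) for i in sorted(chosen)]


def seed_cluster(
    grid: Grid,
    spec: ClusterSpec,
    cell_type: CellType,
    seed: int | np.random.Generator,
    occupied: set[tuple[int, int, int]] | None = None,
) -> list[CellPlacement]:
    """Place ``spec.n_cells`` cells at random voxels within a cluster cube."""
    occupied = occupied or set()
    block = [v for v in spec.voxel_block(grid) if v not in occupied]
    if spec.n_cells > len(block):
        raise CapacityError(
            f"cluster holds at most {len(block)} cells, requested {spec.n_cells}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(block), size=spec.n_cells, replace=False)
    return [CellPlacement(cell_type, block[i]) for i in sorted(chosen)]


def placements_to_frame(placements: list[CellPlacement]) -> pd.DataFrame:
    """Tabulate placements: one row per cell with columns type, i, j, k."""
    return pd.DataFrame(
        [(p.cell_type.value, *p.voxel) for p in placements],
        columns=["type", "i", "j", "k"],
    )


def frame_to_placements(frame: pd.DataFrame) -> list[CellPlacement]:
    return [
        CellPlacement(CellType(row.type), (int(row.i), int(row.j), int(row.k)))
        for row in frame.itertuples(index=False)
    ]
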