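"""Gradient metrics, steady-state detection, and unit conversions.

Gradient convention: a gradient value is the difference of mean total
(free + ECM-bound) concentration between two voxel sets divided by the
distance separating them, in nM/um.  For blood-referenced metrics the
sign is positive when the tissue concentration exceeds the blood
(gradient points into the tissue) and negative when the blood exceeds
the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Grid, VesselSpec
from .transport import GridState
from .units import nM_to_molecules

__all__ = [
    "GradientRecord",
    "compute_gradient",
    "detect_steady_state",
    "molecules_across_cell",
    "lining_distance_map",
    "shell_voxels",
]


@dataclass(frozen=True)
class GradientRecord:
    """One sample of a named gradient metric."""

    time: float  # h
    name: str  # cell_derived | blood_tissue | endothelial_tissue
    magnitude: float  # |nM/um|
    sign: int  # +1 tissue-high, -1 blood-high, 0 exactly zero

    @property
    def value(self) -> float:
        return self.sign * self.magnitude

    @classmethod
    def from_value(cls, time: float, name: str, value: float) -> "GradientRecord":
        sign = 0 if value == 0 else (1 if value > 0 else -1)
        return cls(time=time, name=name, magnitude=abs(value), sign=sign)


def compute_gradient(
    state: GridState,
    voxels_a,
    voxels_b,
    distance: float,
) -> float:
    """(mean total concentration over A - mean over B) / distance, nM/um.

    ``voxels_a``/``voxels_b`` are iterables of voxel index triples or
    index-array tuples.  Antisymmetric under swapping A and B.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    total = state.free + state.bound

    def mean_over(voxels) -> float:
        if isinstance(voxels, tuple) and len(voxels) == 3 and isinstance(voxels[0], np.ndarray):
            vals = total[voxels]
        else:
            voxels = list(voxels)
            if not voxels:
                raise ValueError("voxel set must be non-empty")
            idx = np.array(voxels, dtype=np.intp)
            vals = total[idx[:, 0], idx[:, 1], idx[:, 2]]
        if vals.size == 0:
            raise ValueError("voxel set must be non-empty")
        return float(vals.mean())

    return (mean_over(voxels_a) - mean_over(voxels_b)) / distance


def detect_steady_state(
    times: np.ndarray,
    values: np.ndarray,
    threshold: float,
    window: float = 300.0,
) -> float | None:
    """First time the trailing-window excursion of a series falls below threshold.

    ``times`` (s) must be uniformly sampled and increasing; ``window``
    is in seconds (default 5 min).  Returns the detection time or None
    if the history never settles (or is shorter than one window).
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    for i in range(times.size):
        lo = times[i] - window
        if lo < times[0] - 1e-9:
            continue
        in_win = (times >= lo - 1e-9) & (times <= times[i] + 1e-9)
        w = values[in_win]
        if w.max() - w.min() < threshold:
            return float(times[i])
    return None


def molecules_across_cell(
    gradient: float,
    cell_diameter: float = 10.0,
    volume_l: float = 1e-12,
) -> float:
    """Molecule-count difference a cell experiences across its diameter.

    gradient (nM/um) * diameter (um) gives the concentration difference,
    converted to molecules in the reference compartment volume.  The
    canonical migration-threshold gradient of 0.002 nM/um across a 10-um
    cell in a 1-pL compartment comes out near 12 molecules.
    """
    if gradient < 0 or cell_diameter < 0 or volume_l < 0:
        raise ValueError("inputs must be non-negative")
    return nM_to_molecules(gradient * cell_diameter, volume_l)


def lining_distance_map(grid: Grid, vessel: VesselSpec) -> np.ndarray:
    """Chebyshev distance (um) of every voxel from the vessel surface.

    The lining shell is at 10 um (first tissue compartments next to the
    vasculature); vessel voxels get -1.
    """
    dist = np.full(grid.dims, -1.0)
    vmask = vessel.vessel_mask(grid.dims)
    lateral = [a for a in range(3) if a != vessel.axis]
    # vessel cross-section bounding box in the lateral plane
    vs = np.argwhere(vmask)
    lo = {a: vs[:, a].min() for a in lateral}
    hi = {a: vs[:, a].max() for a in lateral}
    it = np.ndindex(grid.dims)
    for v in it:
        if vmask[v]:
            continue
        d = 0
        for a in lateral:
            if v[a] < lo[a]:
                d = max(d, lo[a] - v[a])
            elif v[a] > hi[a]:
                d = max(d, v[a] - hi[a])
        dist[v] = d * grid.voxel_size
    return dist


def shell_voxels(grid: Grid, vessel: VesselSpec, distance_um: float) -> tuple[np.ndarray, ...]:
    """Index arrays of the tissue shell at a given distance from the vessel."""
    dist = lining_distance_map(grid, vessel)
    mask = np.isclose(dist, distance_um)
    if not mask.any():
        raise ValueError(f"no voxels at distance {distance_um} um from the vessel")
    return np.nonzero(mask)
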