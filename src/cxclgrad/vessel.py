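"""Circadian forcing and transvascular chemokine exchange.

Blood CXCL12 and the cellular secretion rate both follow a cosinusoidal
daily rhythm

    X(t) = (X_max - X_min)/2 * cos(2 pi f (t - (t_start - t_max)))
         + (X_max + X_min)/2

with f = 1/24 h^-1 and a default 2-fold peak-to-trough ratio
(X_max = 2 X_min).  Both forcings share the same phase, which is what
keeps the blood-tissue gradient from reversing over a day.

The vessel exchanges chemokine with the surrounding lining compartments
through a mass-transfer boundary condition dn/dt = p A (C_blood -
C_endo): blood is an infinite, spatially uniform reservoir; each lining
compartment exchanges through its vessel-facing face(s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import Grid, VesselSpec
from .transport import GridState

__all__ = [
    "CircadianParams",
    "ExchangeParams",
    "circadian_value",
    "vessel_exchange",
    "VesselBoundary",
    "apply_vessel_bc",
]


@dataclass(frozen=True)
class CircadianParams:
    """Cosinusoidal daily forcing of one quantity.

    X_max, X_min : peak and trough of the forced quantity (nM for blood
        concentration, molecules/cell/s for the secretion rate).
    frequency : 1/h, default 1/24.
    t_start : clock time (h) at which the simulation begins.
    t_max : clock time (h) of the forcing maximum.  Human default is
        9 am expressed as circadian hour 12 (CT 12 = 9 am); the
        nocturnal-mouse convention is obtained by shifting t_max 12 h.
    phase_convention : "printed" uses the phase term t - (t_start -
        t_max) exactly as written above; "natural" uses t - t_max,
        which places the maximum at clock time t_max.  Both are exposed
        because the printed form is ambiguous about the sign of the
        offset.
    """

    X_max: float
    X_min: float
    frequency: float = 1.0 / 24.0
    t_start: float = 0.0
    t_max: float = 12.0
    phase_convention: Literal["printed", "natural"] = "printed"

    def __post_init__(self):
        if not (self.X_max >= self.X_min >= 0):
            raise ValueError("require X_max >= X_min >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @classmethod
    def twofold(cls, mean: float, **kwargs) -> "CircadianParams":
        """Forcing with the default 2-fold daily swing around ``mean``."""
        return cls(X_max=4.0 * mean / 3.0, X_min=2.0 * mean / 3.0, **kwargs)


def circadian_value(t: float | np.ndarray, params: CircadianParams) -> float | np.ndarray:
    """Evaluate the forcing at clock time t (hours; may exceed 24).

    With the "printed" phase convention the maximum falls at clock time
    t_start - t_max (mod period); with "natural" it falls at t_max.
    The two coincide for the defaults (t_start = 0, t_max = 12, 24-h
    period).
    """
    if params.phase_convention == "printed":
        offset = params.t_start - params.t_max
    else:
        offset = params.t_max
    arg = 2.0 * np.pi * params.frequency * (t - offset)
    return (params.X_max - params.X_min) / 2.0 * np.cos(arg) + (params.X_max + params.X_min) / 2.0


def vessel_exchange(
    C_blood: float,
    C_endo: float | np.ndarray,
    p: float,
    A: float | np.ndarray,
    dt: float,
) -> float | np.ndarray:
    """Moles of chemokine crossing the vessel wall in one step.

    n = p A (C_blood - C_endo) dt, positive into the tissue.  p in um/s,
    A in um^2, concentrations in nM; returns mol.
    """
    # nM = 1e-9 mol/L = 1e-24 mol/um^3
    return p * A * (C_blood - np.asarray(C_endo, dtype=np.float64)) * 1e-24 * dt


@dataclass(frozen=True)
class ExchangeParams:
    """Transvascular mass-transfer parameters.

    permeability : vascular permeability to the chemokine (um/s).
    The exchange area per lining compartment is its vessel-facing face
    area (voxel_size^2 per exposed face); corner compartments that only
    touch the vessel diagonally have zero face area and do not
    exchange.
    """

    permeability: float = 0.1

    def __post_init__(self):
        if self.permeability < 0:
            raise ValueError("permeability must be non-negative")


class VesselBoundary:
    """Precomputed exchange geometry for one vessel placement."""

    def __init__(self, grid: Grid, vessel: VesselSpec, params: ExchangeParams):
        self.grid = grid
        self.vessel = vessel
        self.params = params
        vmask = vessel.vessel_mask(grid.dims)
        face_area = grid.voxel_size**2
        idx, areas = [], []
        for v in sorted(vessel.lining_voxels):
            n_faces = 0
            for a in range(3):
                for d in (-1, 1):
                    nb = list(v)
                    nb[a] += d
                    if 0 <= nb[a] < grid.dims[a] and vmask[tuple(nb)]:
                        n_faces += 1
            if n_faces:
                idx.append(v)
                areas.append(n_faces * face_area)
        self.exchange_voxels = tuple(np.array([v[a] for v in idx]) for a in range(3))
        self.exchange_area = np.array(areas, dtype=np.float64)  # um^2 per compartment
        # concentration change per (nM driving force * s): p A / V
        self.rate_per_s = params.permeability * self.exchange_area / (
            grid.voxel_volume_l / 1e-15  # voxel volume in um^3
        )

    def apply(self, state: GridState, C_blood: float, dt: float) -> float:
        """Exchange with the blood over dt; returns net nM*voxel delivered.

        Only the free pool exchanges (ECM-bound chemokine is immobilized
        in the matrix).  Blood is an infinite reservoir: tissue fluxes
        do not alter C_blood.
        """
        c = state.free[self.exchange_voxels]
        # exact relaxation toward C_blood: stable and sign-correct at any dt
        delta = (C_blood - c) * (1.0 - np.exp(-self.rate_per_s * dt))
        state.free[self.exchange_voxels] = c + delta
        return float(delta.sum())


def apply_vessel_bc(
    state: GridState,
    grid: Grid,
    vessel: VesselSpec,
    exch: ExchangeParams,
    C_blood: float,
    dt: float,
    boundary: VesselBoundary | None = None,
) -> GridState:
    """One-shot transvascular exchange (see VesselBoundary for the fast path)."""
    bc = boundary if boundary is not None else VesselBoundary(grid, vessel, exch)
    bc.apply(state, C_blood, dt)
    return state
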