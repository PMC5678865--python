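"""Extracellular CXCL12 transport on the voxel lattice.

Each voxel carries a free and an ECM-bound chemokine concentration (nM).
Per 0.1-s transport step the free field receives secretion from source
cells, diffuses (alternating-direction explicit scheme, no-flux outer
boundaries, vessel voxels excluded as internal walls), degrades with
first-order kinetics, and exchanges reversibly with the immobile
ECM-bound pool.

Diffusion scheme
----------------
Along each axis in turn we take the average of an upward and a downward
Saulyev explicit sweep.  Sweeps are written in conservative flux form,
with the flux through the face between voxels i and i+1 (upward sweep)

    phi_{i+1/2} = open_{i+1/2} * r * (u_{i+1} - u'_i),   r = D dt / dx^2,

so total mass telescopes exactly: closed faces (domain boundary, vessel
wall) carry zero flux and conservation holds to round-off at any r.  The
scheme is unconditionally stable; a warning is logged when r > 1 because
accuracy (and positivity) degrade there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellPlacement, Grid, VesselSpec
from .units import molecules_to_nM

__all__ = [
    "GridState",
    "TransportParams",
    "EcmParams",
    "DiffusionOperator",
    "secrete",
    "diffuse",
    "degrade",
    "ecm_exchange",
    "total_concentration",
    "save_state",
    "load_state",
]

log = logging.getLogger(__name__)

try:  # optional JIT fast path; the numpy route below is the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _saulyev_2d(um, oL, oR, r):  # pragma: no cover - numba-compiled
        n, m = um.shape
        up = np.empty_like(um)
        down = np.empty_like(um)
        for j in range(m):
            prev = 0.0
            for i in range(n):
                nxt = um[i + 1, j] if i + 1 < n else 0.0
                up[i, j] = (
                    um[i, j] * (1.0 - r * oL[i, j]) + r * oR[i, j] * nxt + r * oL[i, j] * prev
                ) / (1.0 + r * oR[i, j])
                prev = up[i, j]
            nxt_new = 0.0
            for i in range(n - 1, -1, -1):
                prv = um[i - 1, j] if i > 0 else 0.0
                down[i, j] = (
                    um[i, j] * (1.0 - r * oR[i, j]) + r * oL[i, j] * prv + r * oR[i, j] * nxt_new
                ) / (1.0 + r * oL[i, j])
                nxt_new = down[i, j]
            for i in range(n):
                um[i, j] = 0.5 * (up[i, j] + down[i, j])

except ImportError:  # pragma: no cover
    _saulyev_2d = None


@dataclass
class GridState:
    """Free and ECM-bound concentration fields (nM) plus the clock (s)."""

    free: np.ndarray
    bound: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, grid: Grid) -> "GridState":
        return cls(
            free=np.zeros(grid.dims, dtype=np.float64),
            bound=np.zeros(grid.dims, dtype=np.float64),
        )

    def total_mass(self) -> float:
        """Sum of free + bound over all voxels (nM * voxel)."""
        return float(self.free.sum() + self.bound.sum())


@dataclass(frozen=True)
class TransportParams:
    """Global transport parameters.

    D : diffusivity of free chemokine (um^2/s)
    k_deg : extracellular first-order degradation rate (1/s), free pool only
    dt : transport timestep (s)
    S : baseline secretion rate (molecules/cell/s)
    """

    D: float = 150.0
    k_deg: float = 1e-4
    dt: float = 0.1
    S: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if min(self.D, self.k_deg, self.S) < 0:
            raise ValueError("D, k_deg and S must be non-negative")


@dataclass(frozen=True)
class EcmParams:
    """Linear (non-saturable) ECM binding.

    k_on_ecm lumps the binding rate with the matrix site density (1/s);
    K_p = k_on_ecm / k_off_ecm is the equilibrium bound:free partition
    coefficient, the isoform-specific knob (gamma > beta > alpha).
    """

    k_on_ecm: float = 0.05
    K_p: float = 1.0

    @property
    def k_off_ecm(self) -> float:
        return self.k_on_ecm / self.K_p

    def __post_init__(self):
        if self.k_on_ecm < 0 or self.K_p <= 0:
            raise ValueError("k_on_ecm must be >= 0 and K_p > 0")


class DiffusionOperator:
    """Averaged-Saulyev (ADE) diffusion stepper for one grid geometry.

    Precomputes per-axis face-open masks; vessel voxels are excluded
    from the tissue domain (their faces are closed, their values pinned
    to zero).
    """

    def __init__(self, grid: Grid, vessel: VesselSpec | None = None):
        self.grid = grid
        self.blocked = (
            vessel.vessel_mask(grid.dims) if vessel is not None else np.zeros(grid.dims, bool)
        )
        tissue = ~self.blocked
        # open[a] has shape dims + 1 along axis a: face f between cells f-1, f
        self.face_open: list[np.ndarray] = []
        for a in range(3):
            shape = list(grid.dims)
            shape[a] += 1
            o = np.zeros(shape, dtype=np.float64)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[a] = slice(1, grid.dims[a])
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[a] = slice(0, grid.dims[a] - 1)
            hi[a] = slice(1, grid.dims[a])
            interior = tissue[tuple(lo)] & tissue[tuple(hi)]
            o[tuple(sl_lo)] = interior.astype(np.float64)
            self.face_open.append(o)
        # flattened (n, m) face masks per axis for the compiled sweep
        self._flat_faces = []
        for a in range(3):
            n = grid.dims[a]
            o2 = np.moveaxis(self.face_open[a], a, 0).reshape(n + 1, -1)
            self._flat_faces.append(
                (np.ascontiguousarray(o2[:-1]), np.ascontiguousarray(o2[1:]))
            )
        self.use_jit = True
        self._warned = False

    def step(self, u: np.ndarray, D: float, dt: float) -> np.ndarray:
        """Advance the field one timestep in place and return it."""
        r = D * dt / self.grid.voxel_size**2
        if r > 1.0 and not self._warned:
            log.warning("diffusion number D*dt/dx^2 = %.3g > 1: reduced accuracy", r)
            self._warned = True
        for a in range(3):
            if _saulyev_2d is not None and self.use_jit:
                n = self.grid.dims[a]
                view = np.moveaxis(u, a, 0)
                um = np.ascontiguousarray(view.reshape(n, -1))
                oL, oR = self._flat_faces[a]
                _saulyev_2d(um, oL, oR, r)
                view[:] = um.reshape(view.shape)
            else:
                u = self._sweep_axis(u, a, r)
        if self.blocked.any():
            u[self.blocked] = 0.0
        return u

    def _sweep_axis(self, u: np.ndarray, axis: int, r: float) -> np.ndarray:
        n = self.grid.dims[axis]
        um = np.moveaxis(u, axis, 0)  # view into u
        o = np.moveaxis(self.face_open[axis], axis, 0)
        oL, oR = o[:-1], o[1:]  # left/right face openness per cell

        up = np.empty_like(um)
        # upward: u'_i (1 + r oR) = u_i (1 - r oL) + r oR u_{i+1} + r oL u'_{i-1}
        denom_up = 1.0 + r * oR
        prev = np.zeros(um.shape[1:])
        for i in range(n):
            nxt = um[i + 1] if i + 1 < n else 0.0
            up[i] = (um[i] * (1.0 - r * oL[i]) + r * oR[i] * nxt + r * oL[i] * prev) / denom_up[i]
            prev = up[i]

        down = np.empty_like(um)
        # downward: u''_i (1 + r oL) = u_i (1 - r oR) + r oL u_{i-1} + r oR u''_{i+1}
        denom_dn = 1.0 + r * oL
        nxt_new = np.zeros(um.shape[1:])
        for i in range(n - 1, -1, -1):
            prv = um[i - 1] if i > 0 else 0.0
            down[i] = (um[i] * (1.0 - r * oR[i]) + r * oL[i] * prv + r * oR[i] * nxt_new) / denom_dn[i]
            nxt_new = down[i]

        um[:] = 0.5 * (up + down)
        return u


def secrete(
    state: GridState,
    placements: list[CellPlacement] | np.ndarray,
    S: float,
    dt: float,
    grid: Grid,
) -> GridState:
    """Deposit S*dt molecules from each secreting cell into its voxel.

    ``placements`` may be a list of CellPlacement or an (n, 3) integer
    index array.  The increment is converted to nM via the voxel volume.
    """
    if S < 0:
        raise ValueError("secretion rate must be non-negative")
    if S == 0 or len(placements) == 0:
        return state
    d_nm = molecules_to_nM(S * dt, grid.voxel_volume_l)
    if isinstance(placements, np.ndarray):
        idx = placements
    else:
        idx = np.array([p.voxel for p in placements], dtype=np.intp)
    np.add.at(state.free, (idx[:, 0], idx[:, 1], idx[:, 2]), d_nm)
    return state


def diffuse(
    state: GridState,
    params: TransportParams,
    grid: Grid,
    operator: DiffusionOperator | None = None,
) -> GridState:
    """Diffuse the free field one timestep; the bound field is immobile."""
    op = operator if operator is not None else DiffusionOperator(grid)
    state.free = op.step(state.free, params.D, params.dt)
    return state


def degrade(state: GridState, k_deg: float, dt: float) -> GridState:
    """First-order extracellular degradation of the free pool.

    Exact exponential decay; the ECM-bound pool is protected and left
    unchanged.
    """
    if k_deg > 0:
        state.free *= np.exp(-k_deg * dt)
    return state


def ecm_exchange(state: GridState, ecm: EcmParams, dt: float) -> GridState:
    """Reversible free <-> ECM-bound exchange, exact over dt.

    dB/dt = k_on F - k_off B with F + B conserved per voxel; each voxel
    relaxes exponentially toward B* = T K_p / (1 + K_p) at rate
    k_on + k_off, which keeps both pools non-negative at any dt.
    """
    if ecm.k_on_ecm == 0:
        return state
    k_off = ecm.k_off_ecm
    rate = ecm.k_on_ecm + k_off
    total = state.free + state.bound
    b_star = total * (ecm.K_p / (1.0 + ecm.K_p))
    decay = np.exp(-rate * dt)
    state.bound = b_star + (state.bound - b_star) * decay
    state.free = total - state.bound
    return state


def save_state(state: GridState, path) -> None:
    """Write the free/bound fields (axis order x, y, z; units nM) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["time_s"] = state.time
        f.attrs["axis_order"] = "xyz"
        f.attrs["units"] = "nM"
        f.create_dataset("free", data=state.free)
        f.create_dataset("bound", data=state.bound)


def load_state(path) -> GridState:
    """Read a field snapshot written by :func:`save_state`."""
    import h5py

    with h5py.File(path, "r") as f:
        return GridState(
            free=f["free"][...], bound=f["bound"][...], time=float(f.attrs["time_s"])
        )


def total_concentration(state: GridState, voxel: tuple[int, int, int]) -> float:
    """Free + bound concentration (nM) at one voxel."""
    for i, d in zip(voxel, state.free.shape):
        if not (0 <= i < d):
            raise IndexError(f"voxel {voxel} outside grid {state.free.shape}")
    return float(state.free[voxel] + state.bound[voxel])
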