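"""Circadian forcing and transvascular mass transfer."""

import numpy as np
import pytest

from cxclgrad import (
    CircadianParams,
    ExchangeParams,
    GridState,
    VesselBoundary,
    build_grid,
    circadian_value,
    place_vessel,
    vessel_exchange,
)
from cxclgrad.metrics import lining_distance_map


class TestCircadianForcing:
    def test_maximum_at_zero_phase(self):
        p = CircadianParams(X_max=2.0, X_min=1.0, t_start=0.0, t_max=12.0)
        # printed phase term: maximum when t = t_start - t_max (mod 24)
        assert circadian_value(p.t_start - p.t_max, p) == pytest.approx(2.0)

    def test_constant_when_flat(self):
        p = CircadianParams(X_max=1.5, X_min=1.5)
        t = np.linspace(0, 48, 97)
        np.testing.assert_allclose(circadian_value(t, p), 1.5)

    def test_period_average_is_midpoint(self):
        p = CircadianParams(X_max=3.0, X_min=1.0)
        t = np.linspace(0.0, 24.0, 24 * 3600, endpoint=False)
        assert np.mean(circadian_value(t, p)) == pytest.approx(2.0, rel=1e-9)

    def test_two_fold_daily_swing(self):
        p = CircadianParams.twofold(mean=0.25)
        t = np.linspace(0, 24, 24 * 60 + 1)
        x = circadian_value(t, p)
        assert x.max() / x.min() == pytest.approx(2.0, rel=1e-9)
        assert np.mean(x[:-1]) == pytest.approx(0.25, rel=1e-6)

    def test_periodicity(self):
        p = CircadianParams(X_max=2.0, X_min=1.0, frequency=1 / 24.0)
        t = np.linspace(0, 24, 49)
        np.testing.assert_allclose(
            circadian_value(t, p), circadian_value(t + 24.0, p), rtol=1e-12
        )

    def test_phase_conventions_differ_for_offset_start(self):
        kw = dict(X_max=2.0, X_min=1.0, t_start=6.0, t_max=12.0)
        printed = CircadianParams(**kw, phase_convention="printed")
        natural = CircadianParams(**kw, phase_convention="natural")
        assert circadian_value(12.0, natural) == pytest.approx(2.0)
        assert circadian_value(12.0, printed) != pytest.approx(2.0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            CircadianParams(X_max=1.0, X_min=2.0)


class TestVesselExchange:
    def test_zero_driving_force(self):
        assert vessel_exchange(0.5, 0.5, p=0.1, A=100.0, dt=0.1) == 0.0

    def test_delivery_sign_and_linearity(self):
        n1 = vessel_exchange(0.5, 0.1, p=0.1, A=100.0, dt=0.1)
        n2 = vessel_exchange(0.5, 0.1, p=0.2, A=100.0, dt=0.1)
        assert n1 > 0
        assert n2 == pytest.approx(2 * n1)
        assert vessel_exchange(0.0, 0.1, p=0.1, A=100.0, dt=0.1) < 0

    def test_moles_magnitude(self):
        # 1 nM across a 100 um^2 face at 0.1 um/s for 1 s: 1e-21 mol
        assert vessel_exchange(1.0, 0.0, 0.1, 100.0, 1.0) == pytest.approx(1e-21)


class TestVesselBoundary:
    def setup_method(self):
        self.grid = build_grid(100.0, 10.0)
        self.vessel = place_vessel(self.grid, 400.0)
        self.bc = VesselBoundary(self.grid, self.vessel, ExchangeParams(0.1))

    def test_exchange_areas_count_vessel_facing_faces(self):
        # 2x2 vessel: 8 face-adjacent lining voxels per layer exchange,
        # 4 diagonal corners do not
        per_layer = len(self.bc.exchange_area) / self.grid.dims[2]
        assert per_layer == 8
        assert set(self.bc.exchange_area) == {100.0}

    def test_uniform_tissue_at_blood_level_no_flux(self):
        state = GridState.zeros(self.grid)
        state.free[:] = 0.25
        moved = self.bc.apply(state, C_blood=0.25, dt=0.5)
        assert moved == 0.0

    def test_efflux_into_empty_blood(self):
        state = GridState.zeros(self.grid)
        state.free[:] = 0.25
        m0 = state.total_mass()
        moved = self.bc.apply(state, C_blood=0.0, dt=0.5)
        assert moved < 0
        assert state.total_mass() < m0

    def test_delivery_from_blood(self):
        state = GridState.zeros(self.grid)
        moved = self.bc.apply(state, C_blood=0.25, dt=0.5)
        assert moved > 0
        assert state.free.max() > 0


def test_steady_profile_decays_from_vessel():
    """With the vessel as the only source, the steady radial profile of
    concentration decreases monotonically with distance from the wall."""
    from cxclgrad import DiffusionOperator

    grid = build_grid(100.0, 10.0)
    vessel = place_vessel(grid, 400.0)
    bc = VesselBoundary(grid, vessel, ExchangeParams(0.1))
    op = DiffusionOperator(grid, vessel)
    state = GridState.zeros(grid)
    k_deg, dt = 5e-3, 0.5
    for _ in range(4000):
        state.free = op.step(state.free, 150.0, dt)
        bc.apply(state, 0.25, dt)
        state.free *= np.exp(-k_deg * dt)
    dist = lining_distance_map(grid, vessel)
    profile = [
        state.free[np.isclose(dist, d)].mean() for d in (10.0, 20.0, 30.0, 40.0)
    ]
    assert all(a > b for a, b in zip(profile, profile[1:]))


def test_quasi_1d_diffusion_degradation_length_scale():
    """A plane source with first-order loss decays with the classic
    sqrt(D/k) length scale: steady profile ~ cosh((L-x)/lambda)."""
    from cxclgrad import DiffusionOperator

    grid = build_grid(200.0, 10.0)
    op = DiffusionOperator(grid)
    D, k_deg, dt = 150.0, 0.06, 0.1  # lambda = 50 um << 200 um domain
    u = np.zeros(grid.dims)
    for _ in range(20000):
        u[0, :, :] = 1.0  # pinned source plane
        op.step(u, D, dt)
        u *= np.exp(-k_deg * dt)
    u[0, :, :] = 1.0
    profile = u.mean(axis=(1, 2))
    lam = np.sqrt(D / k_deg)
    x = (np.arange(20)) * 10.0
    expected = np.cosh((200.0 - 5.0 - x) / lam) / np.cosh((200.0 - 5.0) / lam)
    np.testing.assert_allclose(profile / profile[0], expected, rtol=0.12)
    # and strictly monotone decay
    assert np.all(np.diff(profile) < 0)
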