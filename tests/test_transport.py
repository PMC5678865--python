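"""Secretion, ADE diffusion, degradation, and ECM exchange."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cxclgrad import (
    DiffusionOperator,
    EcmParams,
    GridState,
    TransportParams,
    build_grid,
    degrade,
    ecm_exchange,
    place_vessel,
    secrete,
    total_concentration,
)


def _random_state(grid, rng, scale=1.0):
    st_ = GridState.zeros(grid)
    st_.free = rng.random(grid.dims) * scale
    st_.bound = rng.random(grid.dims) * scale
    return st_


class TestSecretion:
    def test_molecule_to_nM_conversion(self, grid200):
        # 602 molecules into a 1-pL voxel is one nM (Avogadro conversion)
        state = GridState.zeros(grid200)
        secrete(state, np.array([[5, 5, 5]]), S=602.0, dt=1.0, grid=grid200)
        assert state.free[5, 5, 5] == pytest.approx(1.0, rel=1e-3)
        assert np.count_nonzero(state.free) == 1

    def test_no_cells_or_zero_rate(self, grid100):
        state = GridState.zeros(grid100)
        secrete(state, [], S=5.0, dt=0.1, grid=grid100)
        secrete(state, np.array([[0, 0, 0]]), S=0.0, dt=0.1, grid=grid100)
        assert state.free.sum() == 0

    def test_negative_rate_rejected(self, grid100):
        with pytest.raises(ValueError):
            secrete(GridState.zeros(grid100), np.array([[0, 0, 0]]), -1.0, 0.1, grid100)

    def test_mass_growth_is_exact_with_sinks_off(self, grid100):
        state = GridState.zeros(grid100)
        op = DiffusionOperator(grid100)
        cells = np.array([[1, 1, 1], [5, 5, 5], [8, 2, 7]])
        S, dt = 10.0, 0.1
        for _ in range(200):
            secrete(state, cells, S, dt, grid100)
            state.free = op.step(state.free, 150.0, dt)
        from cxclgrad.units import molecules_to_nM

        expected = 200 * len(cells) * molecules_to_nM(S * dt, grid100.voxel_volume_l)
        assert state.total_mass() == pytest.approx(expected, rel=1e-9)


class TestDiffusion:
    def test_uniform_field_unchanged(self, grid100):
        op = DiffusionOperator(grid100)
        u = np.full(grid100.dims, 3.7)
        op.step(u, 150.0, 0.1)
        np.testing.assert_allclose(u, 3.7, rtol=1e-12)

    def test_jit_and_numpy_paths_agree(self, grid100, rng):
        v = place_vessel(grid100, 400.0)
        op_a, op_b = DiffusionOperator(grid100, v), DiffusionOperator(grid100, v)
        op_b.use_jit = False
        u = rng.random(grid100.dims)
        u[v.vessel_mask(grid100.dims)] = 0.0
        ua, ub = u.copy(), u.copy()
        for _ in range(10):
            op_a.step(ua, 150.0, 0.5)
            op_b.step(ub, 150.0, 0.5)
        np.testing.assert_array_equal(ua, ub)

    @given(seed=st.integers(0, 1000))
    def test_mass_conserved_and_no_new_extrema(self, seed):
        grid = build_grid(100.0, 10.0)
        op = DiffusionOperator(grid)
        u = np.random.default_rng(seed).random(grid.dims)
        lo, hi, m0 = u.min(), u.max(), u.sum()
        for _ in range(20):
            op.step(u, 150.0, 0.5)
        assert abs(u.sum() - m0) / m0 < 1e-12
        assert u.min() >= lo - 1e-12 and u.max() <= hi + 1e-12

    def test_vessel_voxels_are_walls(self, grid100, rng):
        v = place_vessel(grid100, 400.0)
        op = DiffusionOperator(grid100, v)
        u = rng.random(grid100.dims)
        vmask = v.vessel_mask(grid100.dims)
        u[vmask] = 0.0
        m0 = u.sum()
        for _ in range(50):
            op.step(u, 150.0, 0.5)
        assert np.all(u[vmask] == 0.0)
        assert abs(u.sum() - m0) / m0 < 1e-12

    def test_impulse_matches_lattice_eigen_series(self, grid200):
        # short-horizon check against the exact solution of the
        # spatially discrete no-flux diffusion system (cosine modes)
        op = DiffusionOperator(grid200)
        u = np.zeros(grid200.dims)
        u[10, 10, 10] = 100.0
        D, dt, steps = 150.0, 0.1, 50
        u0 = u.copy()
        for _ in range(steps):
            op.step(u, D, dt)
        n, dx, t = 20, 10.0, steps * dt
        k = np.arange(n)
        modes = np.cos(np.pi * np.outer(k, 2 * np.arange(n) + 1) / (2 * n))
        lam = -(4 * D / dx**2) * np.sin(np.pi * k / (2 * n)) ** 2
        norm = np.where(k == 0, n, n / 2)

        def prop(f):
            c = np.tensordot(modes, f, axes=(1, 0)) / norm.reshape(-1, 1, 1)
            c *= np.exp(lam * t).reshape(-1, 1, 1)
            return np.tensordot(modes.T, c, axes=(1, 0))

        ex = u0
        for ax in range(3):
            ex = np.moveaxis(prop(np.moveaxis(ex, ax, 0)), 0, ax)
        assert np.linalg.norm(u - ex) / np.linalg.norm(ex) < 0.01


class TestDegradation:
    def test_zero_rate_noop(self, grid100, rng):
        state = _random_state(grid100, rng)
        free0 = state.free.copy()
        degrade(state, 0.0, 0.1)
        np.testing.assert_array_equal(state.free, free0)

    def test_half_life(self, grid100, rng):
        state = _random_state(grid100, rng)
        free0 = state.free.copy()
        k = 1e-3
        t_half = np.log(2) / k
        degrade(state, k, t_half)
        np.testing.assert_allclose(state.free, free0 / 2, rtol=1e-12)

    def test_bound_pool_protected(self, grid100, rng):
        state = _random_state(grid100, rng)
        bound0 = state.bound.copy()
        degrade(state, 0.1, 100.0)
        np.testing.assert_array_equal(state.bound, bound0)


class TestEcmExchange:
    def test_empty_state_unchanged(self, grid100):
        state = GridState.zeros(grid100)
        ecm_exchange(state, EcmParams(0.05, 5.0), 0.1)
        assert state.total_mass() == 0.0

    def test_fixed_point_partition(self, grid100):
        state = GridState.zeros(grid100)
        state.free[:] = 1.0
        ecm = EcmParams(k_on_ecm=0.05, K_p=5.0)
        for _ in range(100):
            ecm_exchange(state, ecm, 10.0)
        ratio = state.bound / state.free
        np.testing.assert_allclose(ratio, 5.0, rtol=1e-3)

    @given(kp=st.floats(0.5, 50.0), seed=st.integers(0, 100))
    def test_total_conserved_per_voxel(self, kp, seed):
        grid = build_grid(50.0, 10.0)
        rng = np.random.default_rng(seed)
        state = _random_state(grid, rng)
        total0 = state.free + state.bound
        ecm_exchange(state, EcmParams(0.05, kp), 7.3)
        np.testing.assert_allclose(state.free + state.bound, total0, rtol=1e-12)
        assert state.free.min() >= 0 and state.bound.min() >= 0

    def test_bound_fraction_monotone_in_partition(self, grid100):
        fracs = []
        for kp in (1.0, 5.0, 25.0):
            state = GridState.zeros(grid100)
            state.free[:] = 1.0
            for _ in range(50):
                ecm_exchange(state, EcmParams(0.05, kp), 10.0)
            fracs.append(state.bound.sum() / state.total_mass())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_higher_partition_slows_effective_spreading(self, grid200):
        # ECM binding immobilizes chemokine: the total (free+bound) field
        # spreads less from a point source as K_p grows
        variances = []
        for kp in (1.0, 5.0, 25.0):
            state = GridState.zeros(grid200)
            state.free[10, 10, 10] = 100.0
            op = DiffusionOperator(grid200)
            ecm = EcmParams(k_on_ecm=0.5, K_p=kp)
            for _ in range(600):
                op.step(state.free, 150.0, 0.5)
                ecm_exchange(state, ecm, 0.5)
            total = state.free + state.bound
            idx = np.indices(total.shape)
            w = total / total.sum()
            var = sum(
                ((idx[a] - (idx[a] * w).sum()) ** 2 * w).sum() for a in range(3)
            )
            variances.append(var)
        assert variances[0] > variances[1] > variances[2]


class TestTotalConcentration:
    def test_sum_and_bounds(self, grid100):
        state = GridState.zeros(grid100)
        state.free[1, 2, 3] = 0.3
        state.bound[1, 2, 3] = 0.1
        assert total_concentration(state, (1, 2, 3)) == pytest.approx(0.4)
        assert total_concentration(state, (0, 0, 0)) == 0.0
        with pytest.raises(IndexError):
            total_concentration(state, (10, 0, 0))

    def test_unchanged_by_ecm_exchange(self, grid100, rng):
        state = _random_state(grid100, rng)
        before = total_concentration(state, (4, 4, 4))
        ecm_exchange(state, EcmParams(0.05, 25.0), 50.0)
        assert total_concentration(state, (4, 4, 4)) == pytest.approx(before, rel=1e-12)


def test_state_snapshot_round_trip(tmp_path, grid100, rng):
    from cxclgrad import load_state, save_state

    state = _random_state(grid100, rng)
    state.time = 123.4
    p = tmp_path / "fields.h5"
    save_state(state, p)
    back = load_state(p)
    np.testing.assert_array_equal(back.free, state.free)
    np.testing.assert_array_equal(back.bound, state.bound)
    assert back.time == state.time


def test_transport_params_validation():
    with pytest.raises(ValueError):
        TransportParams(dt=0.0)
    with pytest.raises(ValueError):
        TransportParams(D=-1.0)
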