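"""Equivalence of the wave, hydrodynamic, two-fluid and diffusive pictures."""

import numpy as np
import pytest

import macroquant as mq
from macroquant.errors import DomainError, RepresentationError


@pytest.fixture(scope="module")
def fine_grid():
    return mq.GridSpec(extent=(16.0,), points=(600,))


@pytest.fixture(scope="module")
def fine_states(params, fine_grid):
    pot = mq.harmonic_potential(params, 1.0)
    return pot, mq.stationary_states(pot, fine_grid, params, 3)


class TestWaveToHydro:
    def test_plane_wave_uniform_velocity(self, params):
        grid = mq.GridSpec(extent=(10.0,), points=(200,), boundary="periodic")
        x = grid.axes()[0]
        k = 2 * np.pi / 10.0 * 3
        w = mq.WaveField(np.exp(1j * k * x), grid, params).normalized()
        h = mq.wave_to_hydro(w)
        assert np.ptp(h.P) < 1e-12
        # discrete phase gradient: sin(k dx)/dx
        assert h.V[0] == pytest.approx(2 * params.D * k, rel=1e-2)
        assert np.ptp(h.V[0]) < 1e-10

    def test_real_state_zero_velocity(self, fine_states):
        _, sol = fine_states
        h = mq.wave_to_hydro(sol.states[0])
        assert np.abs(h.V).max() == 0.0
        assert h.P == pytest.approx(sol.states[0].density, abs=1e-12)


class TestHydroWaveRoundTrip:
    def test_real_density_round_trip(self, params, fine_grid):
        x = fine_grid.axes()[0]
        P = np.exp(-((x - 8.0) ** 2))
        h = mq.HydroField(P=P, V=np.zeros((1, 600)), grid=fine_grid, params=params)
        w = mq.hydro_to_wave(h)
        assert np.abs(w.psi.imag).max() < 1e-12

    def test_round_trip_fidelity(self, params, fine_grid):
        x = fine_grid.axes()[0]
        psi = np.exp(-((x - 8.0) ** 2) / 2) * np.exp(1j * 0.7 * x)
        w = mq.WaveField(psi, fine_grid, params).normalized()
        w2 = mq.hydro_to_wave(mq.wave_to_hydro(w), loop_tol=1e-4)
        assert abs(w.overlap(w2)) > 1 - 1e-6

    def test_2d_round_trip_preserves_density(self, params):
        grid = mq.GridSpec(extent=(8.0, 8.0), points=(64, 64), boundary="periodic")
        X, Y = grid.meshgrid()
        r2 = (X - 4) ** 2 + (Y - 4) ** 2
        theta = 0.2 * np.exp(-r2 / 6.0)
        V = 2 * params.D * np.stack(
            [theta * (-(X - 4) / 3.0), theta * (-(Y - 4) / 3.0)]
        )
        h = mq.HydroField(P=np.exp(-r2 / 3.0), V=V, grid=grid, params=params)
        w = mq.hydro_to_wave(h, loop_tol=1e-4)
        h2 = mq.wave_to_hydro(w)
        assert np.abs(h2.P - h.P).max() < 1e-8

    def test_vortex_rejected(self, params):
        grid = mq.GridSpec(extent=(8.0, 8.0), points=(48, 48), boundary="periodic")
        X, Y = grid.meshgrid()
        P = np.exp(-((X - 4) ** 2 + (Y - 4) ** 2) / 3.0)
        V = mq.vortex_velocity(grid, 1.0)
        h = mq.HydroField(P=P, V=V, grid=grid, params=params)
        with pytest.raises(RepresentationError):
            mq.hydro_to_wave(h)


class TestQuantumPotential:
    def test_uniform_density_gives_zero(self, params):
        grid = mq.GridSpec(extent=(5.0,), points=(100,), boundary="periodic")
        Q = mq.quantum_potential(np.ones(100), params, grid)
        assert np.nanmax(np.abs(Q)) < 1e-12

    def test_gaussian_center_value_1d(self, params):
        # Q(0) = m D^2 / (2 sigma^2) * ... closed form: Q = -mD^2(x^2/... )
        grid = mq.GridSpec(extent=(20.0,), points=(800,))
        x = grid.axes()[0]
        s2 = 1.3
        P = np.exp(-((x - 10.0) ** 2) / (2 * s2))
        Q = mq.quantum_potential(P, params, grid)
        expected_center = params.m * params.D**2 / s2
        i0 = np.argmin(np.abs(x - 10.0))
        assert Q[i0] == pytest.approx(expected_center, rel=1e-2)

    def test_3d_gaussian_matches_closed_form(self, params):
        # Q(r) = -D^2 (r^2 - 6 sigma^2) / (2 sigma^4) for m = 1
        grid = mq.GridSpec(extent=(10.0,) * 3, points=(64,) * 3)
        p1 = mq.MacroParams(D=params.D, m=1.0)
        sigma = 1.0
        P = mq.gaussian_density(grid, sigma=sigma)
        Q = mq.quantum_potential(P, p1, grid)
        X, Y, Z = grid.meshgrid()
        r2 = (X - 5) ** 2 + (Y - 5) ** 2 + (Z - 5) ** 2
        Qc = -p1.D**2 * (r2 - 6 * sigma**2) / (2 * sigma**4)
        m = np.isfinite(Q) & (P > 1e-4 * P.max())
        assert np.abs(Q - Qc)[m].max() / np.abs(Qc[m]).max() < 1e-2

    def test_log_form_agrees(self, params):
        rng = np.random.default_rng(7)
        grid = mq.GridSpec(extent=(10.0,), points=(400,), boundary="periodic")
        base = mq.smooth_random_potential(grid, rng, amplitude=0.5, correlation_length=1.5)
        P = np.exp(base)
        Q1 = mq.quantum_potential(P, params, grid)
        Q2 = mq.quantum_potential_log_form(P, params, grid)
        assert np.nanmax(np.abs(Q1 - Q2)) / np.nanmax(np.abs(Q1)) < 1e-3

    def test_log_form_gaussian_closed_form(self, params):
        grid = mq.GridSpec(extent=(20.0,), points=(800,))
        x = grid.axes()[0]
        s2 = 1.0
        P = np.exp(-((x - 10.0) ** 2) / (2 * s2))
        Q = mq.quantum_potential_log_form(P, params, grid)
        expected = -params.m * params.D**2 * (
            -1 / s2 + 0.5 * (x - 10.0) ** 2 / s2**2
        )
        m = np.isfinite(Q) & (P > 1e-4)
        assert np.abs(Q - expected)[m].max() / np.abs(expected[m]).max() < 1e-2

    def test_zero_density_rejected(self, params):
        grid = mq.GridSpec(extent=(5.0,), points=(64,))
        with pytest.raises(DomainError):
            mq.quantum_potential(np.zeros(64), params, grid)

    def test_stationarity_identity(self, params, fine_grid, fine_states):
        # Q + phi = E for an eigenstate, on the reliable region
        pot, sol = fine_states
        w0 = sol.states[0]
        Q = mq.quantum_potential(w0.density, params, fine_grid)
        tot = Q + pot.on_grid(fine_grid)
        v = tot[np.isfinite(tot)]
        assert v.std() / abs(v.mean()) < 1e-3
        assert v.mean() == pytest.approx(sol.energies[0], rel=1e-6)


class TestDiffusionPotentialReversal:
    def test_pointwise_sign_reversal(self, params, fine_grid):
        x = fine_grid.axes()[0]
        P = np.exp(-((x - 8.0) ** 2) / 2)
        Q = mq.quantum_potential(P, params, fine_grid)
        R = mq.diffusion_potential(P, params, fine_grid)
        assert np.nanmax(np.abs(Q + R)) == 0.0

    def test_mapped_heat_flow_satisfies_euler_equation(self, params):
        # V = v - D grad lnP with v = 0 maps the heat solution onto
        # (dt + V d/dx) V = -2 D^2 d/dx(Lap sqrt P / sqrt P)
        grid = mq.GridSpec(extent=(40.0,), points=(800,))
        x = grid.axes()[0]
        D = params.D
        for t in (1.0, 2.5, 4.5):
            s2 = 1.0 + 2 * D * t
            y = x - 20.0
            V = D * y / s2                     # analytic mapped velocity
            dV_dt = -2 * D**2 * y / s2**2
            adv = V * D / s2
            # -2 D^2 d/dx(Lap sqrt P / sqrt P) for the heat Gaussian
            rhs = -(D**2) * y / s2**2
            # grid evaluation of the diffusion-potential force
            P = np.exp(-(y**2) / (2 * s2))
            force = -np.gradient(
                mq.diffusion_potential(P, params, grid), x
            ) / params.m
            m = P > 1e-3
            assert np.abs(dV_dt + adv - rhs).max() / np.abs(rhs).max() < 1e-10
            assert np.abs(force - rhs)[m].max() / np.abs(rhs[m]).max() < 1e-3

    def test_reversed_potential_tracks_heat_solution(self, params):
        grid = mq.GridSpec(extent=(40.0,), points=(640,))
        x = grid.axes()[0]
        D = params.D
        sigma0sq = 1.0
        P0 = np.exp(-((x - 20.0) ** 2) / (2 * sigma0sq))
        V0 = (D * (x - 20.0) / sigma0sq)[None]
        h0 = mq.HydroField(P=P0, V=V0, grid=grid, params=params)
        t_end = 4.5
        h1 = mq.evolve_hydro(
            h0, mq.PotentialSpec(0.0), True, 1e-3, 4500, quantum_sign=-1.0
        )
        s2 = sigma0sq + 2 * D * t_end
        Pex = np.exp(-((x - 20.0) ** 2) / (2 * s2))
        Pex /= Pex.sum() * grid.cell_volume
        err = np.sqrt(np.sum((h1.P - Pex) ** 2) / np.sum(Pex**2))
        assert err < 1e-3

    def test_entropy_increases_under_diffusion(self, params):
        grid = mq.GridSpec(extent=(40.0,), points=(640,))
        x = grid.axes()[0]
        P0 = np.exp(-((x - 20.0) ** 2) / 2)
        d = mq.DiffusiveField(
            P=P0, v_plus=np.zeros((1, 640)), grid=grid, params=params
        )
        S = [mq.gibbs_entropy(d.P, grid)]
        for _ in range(8):
            d = mq.evolve_fokker_planck(d, 1e-3, 100)
            S.append(mq.gibbs_entropy(d.P, grid))
        assert np.all(np.diff(S) > 0)


class TestDiffusiveRepresentation:
    def test_real_state_velocity_symmetry(self, params, fine_grid, fine_states):
        _, sol = fine_states
        d = mq.wave_to_diffusive(sol.states[0])
        m = d.P > 1e-4 * d.P.max()
        assert np.abs(d.v_plus + d.v_minus)[..., m].max() < 1e-8

    def test_gaussian_forward_velocity_closed_form(self, params, fine_grid):
        x = fine_grid.axes()[0]
        s2 = 0.5
        psi = np.exp(-((x - 8.0) ** 2) / (4 * s2))
        w = mq.WaveField(psi, fine_grid, params).normalized()
        d = mq.wave_to_diffusive(w)
        expected = -params.D * (x - 8.0) / s2
        m = d.P > 1e-3 * d.P.max()
        assert np.abs(d.v_plus[0] - expected)[m].max() < 1e-3

    @pytest.mark.parametrize("state_index", [0, 1])
    def test_reconstruction_fidelity(self, fine_states, state_index):
        _, sol = fine_states
        w = sol.states[state_index]
        w2 = mq.diffusive_to_wave(mq.wave_to_diffusive(w))
        assert abs(w.overlap(w2)) > 1 - 1e-6

    def test_moving_packet_reconstruction(self, params, fine_grid):
        x = fine_grid.axes()[0]
        psi = np.exp(-((x - 8.0) ** 2) / 2) * np.exp(1j * 0.7 * x)
        w = mq.WaveField(psi, fine_grid, params).normalized()
        w2 = mq.diffusive_to_wave(mq.wave_to_diffusive(w))
        assert abs(w.overlap(w2)) > 1 - 1e-6


class TestQuantumPotentialPlus:
    def test_uniform_rest_gives_zero(self, params):
        grid = mq.GridSpec(extent=(5.0,), points=(100,), boundary="periodic")
        d = mq.DiffusiveField(
            P=np.ones(100), v_plus=np.zeros((1, 100)), grid=grid, params=params
        )
        assert np.nanmax(np.abs(mq.quantum_potential_plus(d))) < 1e-12

    def test_gaussian_closed_form(self, params, fine_grid):
        x = fine_grid.axes()[0]
        s2 = 0.5
        P = np.exp(-((x - 8.0) ** 2) / (2 * s2))
        vp = (-params.D * (x - 8.0) / s2)[None]
        d = mq.DiffusiveField(P=P, v_plus=vp, grid=fine_grid, params=params)
        Qp = mq.quantum_potential_plus(d)
        expected = -params.m * params.D**2 * ((x - 8.0) ** 2 / s2**2 - 1 / s2)
        m = np.isfinite(Qp) & (d.P > 1e-4 * d.P.max())
        assert np.abs(Qp - expected)[m].max() / np.abs(expected[m]).max() < 1e-2

    def test_energy_identity_across_representations(self, params):
        # (1/2) m v+^2 + phi + Q+ = (1/2) m V^2 + Q + phi pointwise
        grid = mq.GridSpec(extent=(16.0,), points=(1200,))
        pot = mq.harmonic_potential(params, 1.0)
        sol = mq.stationary_states(pot, grid, params, 1)
        w0 = sol.states[0]
        phi = pot.on_grid(grid)
        E_h = mq.energy_field(mq.wave_to_hydro(w0), phi)
        E_d = mq.energy_field_diffusive(mq.wave_to_diffusive(w0), phi)
        m = np.isfinite(E_h) & np.isfinite(E_d) & (w0.density > 1e-4 * w0.density.max())
        scale = np.abs(E_h[m]).mean()
        assert np.abs(E_h - E_d)[m].max() / scale < 1e-3

    def test_stationary_energy_equals_eigenvalue(self, params, fine_grid, fine_states):
        pot, sol = fine_states
        d = mq.wave_to_diffusive(sol.states[0])
        E = mq.energy_field_diffusive(d, pot.on_grid(fine_grid))
        v = E[np.isfinite(E) & (d.P > 1e-6 * d.P.max())]
        assert v.std() / abs(v.mean()) < 1e-2
        assert v.mean() == pytest.approx(sol.energies[0], rel=1e-2)


class TestEvolveHydro:
    def test_madelung_equivalence_one_trap_period(self, params):
        grid = mq.GridSpec(extent=(16.0,), points=(512,))
        x = grid.axes()[0]
        pot = mq.harmonic_potential(params, 1.0, center=8.0)
        sigma = np.sqrt(params.D)
        psi = np.exp(-((x - 9.0) ** 2) / (4 * sigma**2))
        w = mq.WaveField(psi, grid, params).normalized()
        T = 2 * np.pi
        h1 = mq.evolve_hydro(mq.wave_to_hydro(w), pot, True, T / 4000, 4000)
        w1 = mq.evolve(w, pot, 1e-3, int(round(T / 1e-3)))
        err = np.sqrt(np.sum((h1.P - w1.density) ** 2) / np.sum(w1.density**2))
        assert err < 1e-3

    def test_stationary_state_static(self, params):
        grid = mq.GridSpec(extent=(16.0,), points=(512,))
        x = grid.axes()[0]
        pot = mq.harmonic_potential(params, 1.0, center=8.0)
        sigma = np.sqrt(params.D)
        psi = np.exp(-((x - 8.0) ** 2) / (4 * sigma**2))
        w = mq.WaveField(psi, grid, params).normalized()
        h = mq.wave_to_hydro(w)
        h2 = mq.evolve_hydro(h, pot, True, 1e-3, 1000, depth_cap=12.0)
        interior = h.P > 1e-3 * h.P.max()
        assert np.abs(h2.P - h.P)[interior].max() / h.P.max() < 1e-6

    def test_classical_uniform_advection(self, params):
        grid = mq.GridSpec(extent=(16.0,), points=(512,))
        x = grid.axes()[0]
        P = np.exp(-((x - 7.0) ** 2))
        P /= P.sum() * grid.cell_volume
        h = mq.HydroField(
            P=P, V=np.full((1, 512), 0.8), grid=grid, params=params
        )
        h2 = mq.evolve_hydro(h, mq.PotentialSpec(0.0), False, 1e-3, 1000)
        expected = np.interp(x, x + 0.8, P)
        m = (x > 3) & (x < 13)
        assert np.abs(h2.P - expected)[m].max() / P.max() < 1e-3


class TestEvolveFokkerPlanck:
    def test_free_diffusion_variance_growth(self, params):
        grid = mq.GridSpec(extent=(40.0,), points=(640,))
        x = grid.axes()[0]
        P0 = np.exp(-((x - 20.0) ** 2) / 2)
        d = mq.DiffusiveField(
            P=P0, v_plus=np.zeros((1, 640)), grid=grid, params=params
        )
        t = 1.0
        d1 = mq.evolve_fokker_planck(d, 1e-3, 1000)
        mean = np.sum(d1.P * x) * grid.cell_volume
        var = np.sum(d1.P * (x - mean) ** 2) * grid.cell_volume
        assert var == pytest.approx(1.0 + 2 * params.D * t, rel=1e-2)

    def test_equilibrium_forward_velocity(self, params):
        # v+ = D grad lnP makes the forward equation static
        grid = mq.GridSpec(extent=(24.0,), points=(480,))
        x = grid.axes()[0]
        P0 = np.exp(-((x - 12.0) ** 2) / 2)
        P0 /= P0.sum() * grid.cell_volume
        # v+ = D grad(P)/P: the discrete form whose flux P v+ = D grad P
        vp = params.D * np.gradient(P0, x) / P0
        d = mq.DiffusiveField(P=P0, v_plus=vp[None], grid=grid, params=params)
        d1 = mq.evolve_fokker_planck(d, 1e-3, 1000)
        assert np.abs(d1.P - P0).max() / P0.max() < 1e-6

    def test_forward_backward_average_is_continuity(self, params, fine_grid, fine_states):
        # (rhs_forward + rhs_backward)/2 with v+- from one wave field
        # equals -div(P V): algebraic identity V = (v+ + v-)/2
        _, sol = fine_states
        w = sol.states[0]
        d = mq.wave_to_diffusive(w)
        h = mq.wave_to_hydro(w)
        D = params.D
        x = fine_grid.axes()[0]
        P = d.P
        fwd = -np.gradient(P * d.v_plus[0], x) + D * np.gradient(np.gradient(P, x), x)
        bwd = -np.gradient(P * d.v_minus[0], x) - D * np.gradient(np.gradient(P, x), x)
        cont = -np.gradient(P * h.V[0], x)
        m = P > 1e-4 * P.max()
        scale = max(np.abs(fwd[m]).max(), 1e-12)
        assert np.abs(0.5 * (fwd + bwd) - cont)[m].max() / scale < 1e-6


class TestTwoFluid:
    def test_plane_wave_residuals_vanish(self, params):
        grid = mq.GridSpec(extent=(10.0,), points=(100,), boundary="periodic")
        x = grid.axes()[0]
        k = 2 * np.pi / 10.0 * 3
        w = mq.WaveField(np.exp(1j * k * x), grid, params).normalized()
        tf = mq.two_fluid(w)
        assert np.abs(tf.U).max() < 1e-12
        assert np.ptp(tf.V[0]) < 1e-10
        assert tf.residual_V < 1e-8 and tf.residual_U < 1e-8

    def test_stationary_state_balance(self, params):
        grid = mq.GridSpec(extent=(16.0,), points=(1200,))
        pot = mq.harmonic_potential(params, 1.0)
        sol = mq.stationary_states(pot, grid, params, 1)
        tf = mq.two_fluid(sol.states[0], pot)
        assert np.abs(tf.V).max() == 0.0
        assert tf.residual_V < 1e-3

    def test_coherent_motion_residuals(self, params):
        grid = mq.GridSpec(extent=(16.0,), points=(1200,))
        x = grid.axes()[0]
        pot = mq.harmonic_potential(params, 1.0, center=8.0)
        sigma = np.sqrt(params.D)
        psi = np.exp(-((x - 9.0) ** 2) / (4 * sigma**2))
        w = mq.WaveField(psi, grid, params).normalized()
        w = mq.evolve(w, pot, 5e-4, 1400)  # a generic point in the cycle
        tf = mq.two_fluid(w, pot, dt=5e-5, mask_floor=1e-4)
        assert tf.residual_V < 1e-3 and tf.residual_U < 1e-3

    def test_U_definition(self, params, fine_grid, fine_states):
        _, sol = fine_states
        w = sol.states[0]
        tf = mq.two_fluid(w)
        x = fine_grid.axes()[0]
        expected = params.D * np.gradient(
            np.log(np.maximum(w.density, 1e-300)), x
        )
        m = w.density > 1e-3 * w.density.max()
        assert np.abs(tf.U[0] - expected)[m].max() < 1e-6


class TestGeodesicResidual:
    def test_free_plane_wave_machine_zero(self, params):
        grid = mq.GridSpec(extent=(10.0,), points=(100,), boundary="periodic")
        x = grid.axes()[0]
        w = mq.WaveField(np.exp(1j * 2 * np.pi * 3 / 10.0 * x), grid, params).normalized()
        assert mq.geodesic_residual(w) < 1e-8

    def test_ground_state_small_residual(self, params):
        grid = mq.GridSpec(extent=(16.0,), points=(1200,))
        pot = mq.harmonic_potential(params, 1.0)
        sol = mq.stationary_states(pot, grid, params, 1)
        assert mq.geodesic_residual(sol.states[0], pot) < 1e-2

    def test_corrupted_state_flagged(self, params):
        grid = mq.GridSpec(extent=(16.0,), points=(1200,))
        pot = mq.harmonic_potential(params, 1.0)
        sol = mq.stationary_states(pot, grid, params, 1)
        clean = mq.geodesic_residual(sol.states[0], pot)
        rng = np.random.default_rng(0)
        noisy = mq.WaveField(
            sol.states[0].psi * np.exp(1j * 0.1 * rng.standard_normal(1200)),
            grid,
            params,
        ).normalized()
        assert mq.geodesic_residual(noisy, pot) > 10 * clean


class TestFractalPaths:
    def test_diffusive_scaling_of_msd(self, params):
        ens = mq.make_fractal_paths(params, dt=1e-3, n_steps=100, n_paths=10_000, seed=1)
        t = np.arange(101) * 1e-3
        msd = ens.msd()
        assert msd[-1] == pytest.approx(2 * params.D * t[-1], rel=0.05)

    def test_increment_variance_rate(self, params):
        ens = mq.make_fractal_paths(params, dt=1e-3, n_steps=100, n_paths=2000, seed=2)
        inc = ens.increments
        assert inc.var() / 1e-3 == pytest.approx(2 * params.D, rel=0.05)

    def test_structure_scaling_exponent(self, params):
        ens = mq.make_fractal_paths(params, dt=1e-3, n_steps=2000, n_paths=100, seed=3)
        X = ens.positions[..., 0]
        lags = np.unique(np.round(np.logspace(0, 2, 12)).astype(int))
        s2 = [np.mean((X[:, lag:] - X[:, :-lag]) ** 2) for lag in lags]
        slope = np.polyfit(np.log(lags * 1e-3), np.log(s2), 1)[0]
        assert abs(slope - 1.0) < 0.05

    def test_deterministic_drift_limit(self):
        p = mq.MacroParams(D=1e-30, m=1.0)
        ens = mq.make_fractal_paths(p, dt=0.1, n_steps=10, n_paths=3, seed=0, drift=2.0)
        expected = 2.0 * 0.1 * np.arange(11)
        assert np.abs(ens.positions[..., 0] - expected).max() < 1e-10


class TestRepresentationClosure:
    def test_wave_hydro_diffusive_round_trips(self, params, fine_grid):
        x = fine_grid.axes()[0]
        psi = np.exp(-((x - 8.0) ** 2) / 2) * np.exp(1j * np.sin(0.5 * (x - 8.0)))
        w = mq.WaveField(psi, fine_grid, params).normalized()
        w_h = mq.hydro_to_wave(mq.wave_to_hydro(w), loop_tol=1e-4)
        w_d = mq.diffusive_to_wave(mq.wave_to_diffusive(w))
        assert abs(w.overlap(w_h)) > 1 - 1e-6
        assert abs(w.overlap(w_d)) > 1 - 1e-6
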