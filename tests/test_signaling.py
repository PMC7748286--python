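"""Signaling reaction-diffusion network: inputs, spatial operator, rate
equations, presets and solver-level oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spinalgrn.hill import RegulatoryTerm, hill_activation, hill_repression, competitive_regulation
from spinalgrn.signaling import (
    DomainGrid,
    SignalingParams,
    constant_input_profile,
    fgf8_mrna_initial_state,
    laplacian,
    mrna_decay_rate,
    signaling_rhs,
    simulate_signaling,
    spatial_decay_constant,
    signaling_preset,
)


class TestInputProfile:
    def test_caudal_amplitude_and_decay(self):
        grid = DomainGrid()
        f0 = constant_input_profile(grid, SignalingParams())
        assert f0[0] == pytest.approx(0.06)
        assert f0[-1] == pytest.approx(0.06 * np.exp(-5.0), rel=1e-12)
        assert np.all(np.diff(f0) < 0)

    def test_halving_lambda_doubles_length_scale(self):
        grid = DomainGrid()
        slow = constant_input_profile(grid, SignalingParams(f0_lambda=0.001))
        fast = constant_input_profile(grid, SignalingParams(f0_lambda=0.002))
        i1000 = np.argmin(np.abs(grid.x - 1000.0))
        i500 = np.argmin(np.abs(grid.x - 500.0))
        assert slow[i1000] == pytest.approx(fast[i500], rel=1e-12)


class TestLaplacian:
    def test_constant_field_is_flat(self):
        assert np.allclose(laplacian(np.full(20, 3.7), dx=1.0), 0.0)

    def test_parabola_curvature(self):
        x = np.linspace(0, 10, 101)
        lap = laplacian(x**2, dx=x[1] - x[0])
        assert np.allclose(lap[1:-1], 2.0, atol=1e-8)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            laplacian(np.array([1.0, 2.0]), dx=1.0)

    def test_zero_flux_conserves_mass(self):
        # pure diffusion with reflecting boundaries preserves the integral
        rng = np.random.default_rng(7)
        u0 = rng.uniform(0.5, 1.5, size=61)
        dx = 1.0
        x = np.arange(61) * dx
        sol = solve_ivp(lambda t, u: 5.0 * laplacian(u, dx), (0, 50), u0,
                        rtol=1e-9, atol=1e-12)
        assert np.trapezoid(sol.y[:, -1], x) == pytest.approx(
            np.trapezoid(u0, x), rel=1e-7)


class TestRhs:
    def setup_method(self):
        self.grid = DomainGrid(n_points=51)
        self.params = SignalingParams()

    def test_all_zero_state_pure_induction(self):
        state = np.zeros((51, 6))
        d = signaling_rhs(state, self.grid, self.params)
        f0 = constant_input_profile(self.grid, self.params)
        assert np.allclose(d[:, 0], self.params.alpha_Fm * f0)
        assert np.allclose(d[:, 1:], 0.0)

    def test_uniform_state_has_no_diffusion_flux(self):
        state = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], (51, 1))
        d = signaling_rhs(state, self.grid, self.params)
        p = self.params
        # protein equations reduce to pure reaction when spatially uniform
        assert np.allclose(d[:, 1], p.alpha_Fp * 1.0 - p.beta_Fp * 2.0)
        assert np.allclose(d[:, 3], p.alpha_Wp * 3.0 - p.beta_Wp * 4.0)

    def test_half_repression_at_hill_constant(self):
        # R at R_RF halves Fgf8 transcription at the caudal end
        state = np.zeros((51, 6))
        state[:, 5] = self.params.R_RF
        state[:, 0] = 2.0
        d = signaling_rhs(state, self.grid, self.params)
        expected = 1.0 * 0.06 * 0.5 - 0.006 * 2.0
        assert d[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_state_names_species_and_index(self):
        state = np.zeros((51, 6))
        state[7, 3] = np.nan
        with pytest.raises(FloatingPointError, match=r"W at grid index 7"):
            signaling_rhs(state, self.grid, self.params)

    def test_rhs_matches_printed_rate_laws(self):
        """Cross-check the vectorised RHS against a direct per-point
        transliteration of the six rate equations."""
        rng = np.random.default_rng(3)
        state = rng.uniform(0, 50, size=(51, 6))
        p, g = self.params, self.grid
        d = signaling_rhs(state, g, p)
        f0 = constant_input_profile(g, p)
        i = 17
        Fm, F, Wm, W, Rm, R = state[i]
        lapF = laplacian(state[:, 1], g.dx)[i]
        lapW = laplacian(state[:, 3], g.dx)[i]
        lapR = laplacian(state[:, 5], g.dx)[i]
        uR = (R / p.R_RF) ** 2
        assert d[i, 0] == pytest.approx(p.alpha_Fm * f0[i] / (1 + uR) - p.beta_Fm * Fm)
        assert d[i, 1] == pytest.approx(p.alpha_Fp * Fm - p.beta_Fp * F + p.D_F * lapF)
        uF = (F / p.F_FW) ** 2
        assert d[i, 2] == pytest.approx(p.alpha_Wm * uF / (1 + uF) - p.beta_Wm * Wm)
        assert d[i, 3] == pytest.approx(p.alpha_Wp * Wm - p.beta_Wp * W + p.D_W * lapW)
        uW, uRR, uF1 = (W / p.W_WR) ** 2, (R / p.R_RR) ** 2, (F / p.F_FR1) ** 2
        assert d[i, 4] == pytest.approx(
            p.alpha_Rm * (uW + uRR) / (1 + uW + uRR) / (1 + uF1) - p.beta_Rm * Rm)
        uF2 = (F / p.F_FR2) ** 2
        decay = p.beta_Rp * R * (1 + p.beta_FR * uF2 / (1 + uF2))
        assert d[i, 5] == pytest.approx(p.alpha_Rp * Rm - decay + p.D_R * lapR)


class TestPresets:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ("I", dict(F_FW=10, F_FR1=1, F_FR2=2, W_WR=1, R_RF=10, R_RR=50)),
            ("IV", dict(W_WR=0.5, R_RF=0.1)),
            ("VIII", dict(R_RR=300, R_RF=20)),
        ],
    )
    def test_column_values(self, column, expected):
        params = signaling_preset(column)
        for name, value in expected.items():
            assert getattr(params, name) == value

    def test_unknown_column(self):
        with pytest.raises(KeyError):
            signaling_preset("IX")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="D_F"):
            SignalingParams(D_F=-1.0)
        with pytest.raises(ValueError, match="beta_Fm"):
            SignalingParams(beta_Fm=0.0)


class TestSimulation:
    def test_zero_diffusion_matches_per_point_ode(self):
        """With diffusion off, the PDE solution at each grid point must
        match an independent pointwise ODE integration."""
        grid = DomainGrid(n_points=51, t_end=1500.0, output_dt=50.0)
        params = signaling_preset("II", D_F=0.0, D_W=0.0, D_R=0.0)
        field = simulate_signaling(params, grid)
        f0 = constant_input_profile(grid, params)
        y0_all = fgf8_mrna_initial_state(params, grid)

        def point_rhs(t, y, f0_i):
            Fm, F, Wm, W, Rm, R = np.maximum(y, 0.0)
            p = params
            dFm = p.alpha_Fm * f0_i * hill_repression(RegulatoryTerm(R, p.R_RF)) - p.beta_Fm * Fm
            dF = p.alpha_Fp * Fm - p.beta_Fp * F
            dWm = p.alpha_Wm * hill_activation(RegulatoryTerm(F, p.F_FW)) - p.beta_Wm * Wm
            dW = p.alpha_Wp * Wm - p.beta_Wp * W
            act = competitive_regulation(
                [RegulatoryTerm(W, p.W_WR), RegulatoryTerm(R, p.R_RR)])
            dRm = act * hill_repression(RegulatoryTerm(F, p.F_FR1)) * p.alpha_Rm - p.beta_Rm * Rm
            dR = p.alpha_Rp * Rm - p.beta_Rp * R * (
                1 + p.beta_FR * hill_activation(RegulatoryTerm(F, p.F_FR2)))
            return [dFm, dF, dWm, dW, dRm, dR]

        for i in (0, 25, 50):
            sol = solve_ivp(point_rhs, (0, grid.t_end), y0_all[i],
                            args=(f0[i],), method="LSODA",
                            rtol=1e-9, atol=1e-12, t_eval=[grid.t_end])
            pde = np.array([field.species(s)[-1, i] for s in
                            ("Fm", "F", "Wm", "W", "Rm", "R")])
            ode = sol.y[:, -1]
            scale = np.maximum(np.abs(ode), 1e-6)
            assert np.all(np.abs(pde - ode) / scale < 1e-4)

    def test_fgf8_mrna_relaxes_to_input_over_decay(self):
        """With RA production disabled, Fgf8 mRNA relaxes from zero to
        alpha_Fm*F0(x)/beta_Fm."""
        grid = DomainGrid(n_points=51, t_end=2500.0, output_dt=100.0)
        params = signaling_preset("II", W_WR=1e6, R_RR=1e6)  # no Raldh2 induction
        field = simulate_signaling(params, grid, initial=np.zeros((51, 6)))
        f0 = constant_input_profile(grid, params)
        expected = params.alpha_Fm * f0 / params.beta_Fm
        for i in (0, 25, 50):
            assert field.Fm[-1, i] == pytest.approx(expected[i], rel=1e-3)

    def test_deterministic_and_nonnegative(self):
        grid = DomainGrid(n_points=51, t_end=600.0, output_dt=50.0)
        a = simulate_signaling(signaling_preset("IV"), grid)
        b = simulate_signaling(signaling_preset("IV"), grid)
        for s in ("Fm", "F", "Wm", "W", "Rm", "R"):
            assert np.array_equal(a.species(s), b.species(s))
            assert a.species(s).min() >= 0.0

    def test_bad_initial_shape(self):
        grid = DomainGrid(n_points=51)
        with pytest.raises(ValueError, match="shape"):
            simulate_signaling(SignalingParams(), grid, initial=np.zeros((5, 6)))


def test_decay_constant_helpers():
    assert mrna_decay_rate(120.0) == pytest.approx(np.log(2) / 120.0)
    assert spatial_decay_constant(0.006, 3.0) == pytest.approx(0.002)
    with pytest.raises(ValueError):
        mrna_decay_rate(0.0)
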