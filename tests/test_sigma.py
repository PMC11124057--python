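"""Sigma grid, profiles and self-consistent potentials."""

import numpy as np
import pytest
from scipy.optimize import root

from desolv.config import EngineConfig, R_KJ
from desolv.sigma import (
    ConvergenceError,
    RelativePotential,
    SigmaGrid,
    SigmaProfile,
    exchange_energy,
    make_grid,
    mixture_potential,
    relative_potential,
    sigma_potential,
)
from desolv.systems import SolventSystem


class TestCanonicalGrid:
    def test_has_61_points_from_minus_to_plus_003(self):
        grid = make_grid()
        assert len(grid) == 61
        assert grid.bounds == (-0.03, 0.03)

    def test_uniform_step_of_0001(self):
        grid = make_grid()
        assert np.allclose(np.diff(grid.values), 0.001)

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError):
            SigmaGrid(np.array([0.0, 0.001, 0.003]))


class TestSigmaProfile:
    def test_areas_sum_to_total(self, profiles):
        for prof in profiles.values():
            assert np.all(prof.areas >= 0)
            assert np.isclose(prof.areas.sum(), prof.total_area)

    def test_zero_area_profile_rejected_in_potential(self):
        grid = make_grid()
        empty = SigmaProfile("empty", grid, np.zeros(61))
        with pytest.raises(ValueError):
            sigma_potential([empty], [1.0], 298.15)

    def test_negative_area_rejected(self):
        grid = make_grid()
        with pytest.raises(ValueError):
            SigmaProfile("bad", grid, np.full(61, -1.0))


class TestSigmaPotential:
    def test_neutral_profile_gives_even_potential_with_minimum_at_zero(self):
        grid = make_grid()
        areas = np.zeros(61)
        areas[30] = 200.0  # all surface at sigma = 0
        pot = sigma_potential([SigmaProfile("n", grid, areas)], [1.0], 298.15)
        assert np.allclose(pot.mu, pot.mu[::-1], atol=1e-10)
        assert pot.mu.argmin() == 30

    def test_self_mixture_equals_pure(self, profiles):
        prof = profiles["water"]
        pure = sigma_potential([prof], [1.0], 298.15)
        mixed = sigma_potential([prof, prof], [0.5, 0.5], 298.15)
        assert np.allclose(pure.mu, mixed.mu, atol=1e-12)

    def test_fixed_point_matches_dense_root_solve_oracle(self):
        """Damped iteration agrees with an independent nonlinear solve."""
        gv = np.linspace(-0.02, 0.02, 5)
        toy_grid = SigmaGrid(gv)
        toy = SigmaProfile("toy", toy_grid, np.array([10.0, 40.0, 100.0, 30.0, 20.0]))
        cfg = EngineConfig()
        T = 310.0
        pot = sigma_potential([toy], [1.0], T, cfg)
        K = np.exp(-exchange_energy(toy_grid, cfg) / (R_KJ * T))
        p = toy.p

        def residual(ln_g):
            return ln_g + np.log(K @ (p * np.exp(ln_g)))

        sol = root(residual, np.zeros(5), tol=1e-12)
        assert np.max(np.abs(residual(sol.x))) < 1e-10
        mu_oracle = R_KJ * T * sol.x / cfg.interactions.a_eff
        assert np.max(np.abs(mu_oracle - pot.mu)) < 1e-8

    def test_nonconvergence_reports_residual(self):
        grid = make_grid()
        areas = np.zeros(61)
        areas[30] = 200.0
        cfg = EngineConfig()
        from dataclasses import replace

        tight = replace(cfg, convergence=replace(cfg.convergence, max_iter=1))
        with pytest.raises(ConvergenceError) as err:
            sigma_potential(
                [SigmaProfile("n", grid, areas)], [1.0], 298.15, tight
            )
        assert err.value.residual > 0


class TestMixturePotential:
    def test_single_component_equals_pure(self, profiles):
        pot = mixture_potential(
            SolventSystem.neat("water"), profiles, 298.15
        )
        pure = sigma_potential([profiles["water"]], [1.0], 298.15)
        assert np.allclose(pot.mu, pure.mu)

    def test_linear_in_weights_and_permutation_invariant(self, profiles):
        T = 298.15
        sys_ab = SolventSystem("ab", ("water", "TEG"), (0.3, 0.7))
        sys_ba = SolventSystem("ba", ("TEG", "water"), (0.7, 0.3))
        mu_ab = mixture_potential(sys_ab, profiles, T).mu
        mu_ba = mixture_potential(sys_ba, profiles, T).mu
        assert np.allclose(mu_ab, mu_ba)
        mu_w = sigma_potential([profiles["water"]], [1.0], T).mu
        mu_t = sigma_potential([profiles["TEG"]], [1.0], T).mu
        assert np.allclose(mu_ab, 0.3 * mu_w + 0.7 * mu_t)

    def test_des_composition_convention(self):
        """ChCl:TEG 1:2 at x*_DES = 0.9 -> fractions (0.30, 0.60, 0.10)."""
        sys_ = SolventSystem.des("ChCl", "TEG", 2.0, 0.9)
        assert sys_.components == ("ChCl", "TEG", "water")
        assert np.allclose(sys_.fractions, (0.30, 0.60, 0.10))
        assert np.isclose(sum(sys_.fractions), 1.0)

    def test_missing_profile_names_compound(self, profiles):
        sys_ = SolventSystem.neat("unobtainium")
        with pytest.raises(KeyError, match="unobtainium"):
            mixture_potential(sys_, profiles, 298.15)


class TestRelativePotential:
    def test_self_difference_is_zero(self, profiles):
        pot = sigma_potential([profiles["water"]], [1.0], 298.15)
        rel = relative_potential(pot, pot)
        assert np.all(rel.delta_mu == 0.0)

    def test_antisymmetry(self, profiles):
        a = sigma_potential([profiles["water"]], [1.0], 298.15)
        b = sigma_potential([profiles["TEG"]], [1.0], 298.15)
        assert np.allclose(
            relative_potential(a, b).delta_mu,
            -relative_potential(b, a).delta_mu,
        )

    def test_temperature_mismatch_rejected(self, profiles):
        a = sigma_potential([profiles["water"]], [1.0], 298.15)
        b = sigma_potential([profiles["water"]], [1.0], 308.15)
        with pytest.raises(ValueError, match="[Tt]emperature"):
            relative_potential(a, b)
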