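"""Solver and analytic-oracle tests for the back-reaction diffusion model."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from geminate.dse_core import (DomainTooSmallError, GridSpec, MediumContext,
                               SolverConfig, asymptotic_roh,
                               brownian_geminate_oracle, debye_radius,
                               smoluchowski_survival_oracle, solve_dse)


def config(a=4.0, rd=7.0, D=9e-5, d=3.0, k_pt=0.2, k_a=0.2, **kw):
    return SolverConfig(contact_radius_a=a, debye_radius_RD=rd, D_cm2_per_s=D,
                        dimensionality_d=d, k_PT=k_pt, k_a=k_a, **kw)


class TestDebyeRadius:
    def test_published_radii_for_water_at_20C(self, medium):
        # anion charges 1, 2, 3 against a proton: 7, 14, 21 Å
        assert [round(debye_radius(z, 1, medium)) for z in (1, 2, 3)] == [7, 14, 21]

    def test_no_charge_product_no_coulomb_radius(self, medium):
        assert debye_radius(0, 1, medium) == 0.0

    @given(z1=st.integers(-3, 3), z2=st.integers(-2, 2),
           scale=st.floats(0.5, 4.0))
    def test_linear_in_charge_product_inverse_in_eps_and_T(self, z1, z2, scale):
        m = MediumContext()
        base = debye_radius(1, 1, m)
        assert debye_radius(z1, z2, m) == pytest.approx(abs(z1 * z2) * base)
        hot = MediumContext(m.relative_permittivity, m.temperature * scale)
        assert debye_radius(1, 1, hot) == pytest.approx(base / scale)
        polar = MediumContext(m.relative_permittivity * scale, m.temperature)
        assert debye_radius(1, 1, polar) == pytest.approx(base / scale)

    def test_nonfinite_charge_rejected(self, medium):
        with pytest.raises(ValueError):
            debye_radius(math.nan, 1, medium)
        with pytest.raises(ValueError):
            MediumContext(-1.0, 300.0)


class TestSolverLimits:
    def test_pure_dissociation_is_exponential(self):
        cfg = config(k_a=0.0)
        grid = GridSpec.auto(cfg, 20.0, np.linspace(0.1, 20, 50))
        tr = solve_dse(cfg, grid)
        assert np.max(np.abs(tr.p_bound - np.exp(-cfg.k_PT * tr.times))) <= 1e-4
        assert tr.p_bound[0] <= 1.0

    def test_no_dissociation_stays_bound(self):
        cfg = config(k_pt=0.0)
        tr = solve_dse(cfg, GridSpec.auto(cfg, 10.0, np.linspace(0.5, 10, 20)))
        assert np.all(tr.p_bound == 1.0)
        assert np.all(tr.separated_fraction == 0.0)

    def test_mass_conserved_and_probability_bounded(self, registry):
        for spec in registry.values():
            for cfg in (spec.buffer, spec.fibrils):
                tr = solve_dse(cfg, GridSpec.auto(cfg, 50.0, np.geomspace(0.01, 50, 60)))
                assert tr.mass_balance_error <= 1e-4
                assert np.all(tr.p_bound >= -1e-12)
                assert np.all(tr.p_bound <= 1.0 + 1e-12)

    def test_tau_accessors(self):
        cfg = config(k_pt=0.2, k_a=0.5)
        assert cfg.tau_PT == pytest.approx(5.0)
        assert cfg.tau_a == pytest.approx(2.0)
        assert config(k_pt=0.0).tau_PT == math.inf

    def test_monotone_in_rates_on_lattice(self):
        # more dissociation -> lower survival; more recombination -> higher
        times = np.linspace(0.5, 10, 10)
        grids = {}
        for k_pt in (0.2, 0.5, 1.0):
            for k_a in (0.1, 1.0, 5.0):
                cfg = config(k_pt=k_pt, k_a=k_a)
                grids[(k_pt, k_a)] = solve_dse(
                    cfg, GridSpec.auto(cfg, 10.0, times)).p_bound
        for k_a in (0.1, 1.0, 5.0):
            assert np.all(grids[(0.2, k_a)] >= grids[(0.5, k_a)] - 1e-10)
            assert np.all(grids[(0.5, k_a)] >= grids[(1.0, k_a)] - 1e-10)
        for k_pt in (0.2, 0.5, 1.0):
            assert np.all(grids[(k_pt, 5.0)] >= grids[(k_pt, 1.0)] - 1e-10)
            assert np.all(grids[(k_pt, 1.0)] >= grids[(k_pt, 0.1)] - 1e-10)

    def test_flat_key_round_trip(self):
        cfg = config(rd=14.0, k_pt=1.0, k_a=0.8, anion_charge_Z1=2)
        assert SolverConfig.from_flat(cfg.to_flat()) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            config(a=-1.0)
        with pytest.raises(ValueError):
            config(d=0.4)
        with pytest.raises(ValueError):
            config(k_pt=-0.1)
        cfg = config()
        with pytest.raises(ValueError):
            GridSpec.auto(cfg, 10.0, np.linspace(1, 20, 5))  # beyond t_max
        with pytest.raises(ValueError):
            GridSpec(r_max=500.0, t_max=10.0, output_times=[1.0], n_r=50)

    def test_outer_boundary_guard(self):
        # a domain far too small for the diffusion length must be refused
        cfg = config(k_pt=5.0, k_a=0.0)
        grid = GridSpec(r_max=30.0, t_max=50.0,
                        output_times=np.linspace(1, 50, 20), n_r=150)
        with pytest.raises(DomainTooSmallError):
            solve_dse(cfg, grid)


class TestOracles:
    def test_absorbing_limit_matches_smoluchowski(self):
        # strong sink k_a = 1e5 Å/ns emulates the perfectly absorbing sphere
        cfg = config(rd=0.0, k_pt=0.0, k_a=1e5)
        ts = np.geomspace(0.1, 50, 40)
        tr = solve_dse(cfg, GridSpec.auto(cfg, 50.0, ts), initial=("delta", 8.0))
        survival = 1.0 - tr.p_bound
        exact = smoluchowski_survival_oracle(4.0, cfg.diffusion_D, 8.0, ts)
        assert np.max(np.abs(survival / exact - 1.0)) < 0.01

    def test_smoluchowski_limits(self):
        assert smoluchowski_survival_oracle(4.0, 900.0, 8.0, 0.0) == pytest.approx(1.0)
        assert smoluchowski_survival_oracle(4.0, 900.0, 8.0, 1e9) == pytest.approx(
            1.0 - 4.0 / 8.0, rel=1e-3)
        with pytest.raises(ValueError):
            smoluchowski_survival_oracle(4.0, 900.0, 2.0, 1.0)

    def test_brownian_oracle_deterministic_and_bound_without_dissociation(self):
        cfg = config(k_pt=0.0, k_a=0.2)
        a = brownian_geminate_oracle(cfg, 10_000, seed=3)
        b = brownian_geminate_oracle(cfg, 10_000, seed=3)
        assert np.array_equal(a.p_bound, b.p_bound)
        assert np.all(a.p_bound == 1.0)

    def test_brownian_oracle_rejects_coarse_step(self):
        with pytest.raises(ValueError):
            brownian_geminate_oracle(config(k_a=150.0), 10_000, seed=0, dt=0.05)
        with pytest.raises(ValueError):
            brownian_geminate_oracle(config(), 100, seed=0)


class TestAsymptoticLaw:
    def test_scalings(self):
        cfg = config(k_pt=1.0, k_a=5.0)
        v1 = asymptotic_roh(10.0, cfg)
        # doubling k_PT halves the intensity
        cfg2 = config(k_pt=2.0, k_a=5.0)
        assert asymptotic_roh(10.0, cfg2) == pytest.approx(v1 / 2.0)
        # pure t^{-d/2} power law in 3 dimensions
        assert asymptotic_roh(40.0, cfg) / v1 == pytest.approx(4.0 ** -1.5)
        with pytest.raises(ValueError):
            asymptotic_roh(10.0, config(k_pt=0.0))
        with pytest.raises(ValueError):
            asymptotic_roh(-1.0, cfg)

    def test_solver_tail_matches_power_law_shape(self):
        # long-time survival follows the t^{-d/2} law; the prefactor
        # convention differs, so a single constant is fitted
        cfg = config(k_pt=0.2, k_a=0.2)
        tr = solve_dse(cfg, GridSpec.auto(cfg, 400.0, np.geomspace(0.01, 400, 400)))
        sel = tr.times >= 100.0
        asym = asymptotic_roh(tr.times[sel], cfg)
        const = np.exp(np.mean(np.log(tr.p_bound[sel]) - np.log(asym)))
        assert np.max(np.abs(const * asym / tr.p_bound[sel] - 1.0)) < 0.10
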