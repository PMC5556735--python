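"""Size-spectrum rates, stepping, budget closure, and spin-up behavior."""

import numpy as np
import pytest

from blueharvest.ecology import (
    EcologyError,
    SpectrumState,
    _StepWork,
    energy_input,
    growth_rate,
    maturity_allocation,
    natural_mortality,
    recruitment_flux,
    spinup_pristine,
    stable_dt,
    step_cells,
    step_ecology,
    temperature_factor,
    trophic_steps,
)


class TestTemperatureFactor:
    def test_identity_at_reference(self):
        assert temperature_factor(10.0, 0.45, 10.0) == pytest.approx(1.0)

    def test_frozen_value(self):
        # independent hand evaluation of the Arrhenius formula
        assert temperature_factor(20.0, 0.45, 10.0) == pytest.approx(
            1.8760037528014457, rel=1e-12
        )

    def test_monotone_increasing_in_T(self):
        T = np.linspace(-2, 35, 50)
        f = temperature_factor(T, 0.45, 10.0)
        assert (np.diff(f) > 0).all()


class TestEnergyInput:
    def test_zero_npp_gives_zero(self, params):
        assert energy_input(0.0, 15.0, params) == 0.0

    def test_linear_in_npp(self, params):
        a = energy_input(10.0, 12.0, params)
        b = energy_input(20.0, 12.0, params)
        assert b == pytest.approx(2 * a)

    def test_no_trophic_loss_at_unit_efficiency(self, params):
        p = params.replace(epsilon_trophic=1.0 - 1e-12)
        expected = 30.0 * 12.011e-3 * p.wet_per_carbon * 365.25
        assert energy_input(30.0, p.T_ref, p) == pytest.approx(expected, rel=1e-6)

    def test_power_law_attenuation(self, params):
        # epsilon=0.1 over n steps -> 10^-n of converted NPP at T_ref
        p = params.replace(epsilon_trophic=0.1, ppmr=1000.0,
                           phyto_cell_mass=1e-8)
        n = trophic_steps(p)
        assert n == pytest.approx(3.0)
        converted = 30.0 * 12.011e-3 * p.wet_per_carbon * 365.25
        assert energy_input(30.0, p.T_ref, p) == pytest.approx(
            converted * 1e-3, rel=1e-9
        )

    def test_warmer_water_transfers_less(self, params):
        assert energy_input(30.0, 25.0, params) < energy_input(30.0, 5.0, params)


class TestAllometricRates:
    def test_growth_direct_evaluation(self, params):
        p = params.replace(growth_coef=4.5, growth_exp=0.7)
        got = growth_rate(100.0, p.T_ref, p, food_limitation=1.0)
        assert got == pytest.approx(4.5 * 100**0.7)

    def test_growth_zero_without_food(self, params):
        assert growth_rate(100.0, 15.0, params, food_limitation=0.0) == 0.0

    def test_allocation_only_reduces_growth(self, params):
        m_asym = 1e4
        with_psi = growth_rate(1e4, params.T_ref, params, 1.0, m_asym=m_asym)
        no_psi = growth_rate(1e4, params.T_ref, params, 1.0)
        assert with_psi <= no_psi
        # and the bound gamma(m) <= gamma(m/10) * 10^b holds
        assert with_psi <= growth_rate(1e3, params.T_ref, params, 1.0,
                                       m_asym=m_asym) * 10**params.growth_exp

    def test_mortality_direct_evaluation(self, params):
        p = params.replace(mort_coef=1.5, mort_exp=0.5)
        assert natural_mortality(10.0, p.T_ref, p) == pytest.approx(
            1.5 * 10 ** (-0.5)
        )

    def test_mortality_mass_scaling(self, params):
        p = params.replace(mort_exp=0.5)
        r = natural_mortality(20.0, p.T_ref, p) / natural_mortality(
            10.0, p.T_ref, p
        )
        assert r == pytest.approx(2 ** (-0.5))

    def test_mortality_mass_independent_at_h_one(self, params):
        p = params.replace(mort_exp=1.0 - 1e-12)
        a = natural_mortality(10.0, p.T_ref, p)
        b = natural_mortality(1e4, p.T_ref, p)
        assert a == pytest.approx(b, rel=1e-6)


class TestRecruitment:
    def test_zero_biomass_zero_recruitment(self, params, axis):
        state = SpectrumState(np.zeros((axis.n_groups, axis.n_bins)))
        R = recruitment_flux(state, 15.0, params, npp=30.0, axis=axis)
        assert (R == 0).all()

    def test_half_saturation_identity(self, params, axis):
        """When egg flux equals K, recruitment is half its asymptote."""
        # construct a biomass level whose egg flux hits exactly K by scaling
        work = _StepWork(axis, params)
        B0 = np.where(axis.active, 1.0, 0.0)
        state = SpectrumState(B0)
        from blueharvest.ecology import _rates
        r = _rates(work, B0[None], np.array([30.0]), np.array([params.T_ref]))
        # egg flux is linear in biomass while food is not limiting
        egg1 = r["recruit"]  # not the egg flux; recompute directly
        p = params
        per_mass = p.growth_coef * work.m_pow_bm1[None, :]
        egg_flux = p.egg_survival * (work.psi * per_mass * B0).sum()
        # pick scale so that egg flux == K for group 0 alone:
        egg_g0 = p.egg_survival * (work.psi[0] * per_mass[0] * B0[0]).sum()
        scale = p.recruitment_half_sat / egg_g0
        state = SpectrumState(B0 * scale)
        R = recruitment_flux(state, p.T_ref, p, npp=30.0, axis=axis)
        r_sat = energy_input(30.0, p.T_ref, p) / axis.n_groups
        assert R[0] == pytest.approx(r_sat / 2, rel=1e-6)

    def test_recruitment_saturates(self, params, axis):
        r_sat = energy_input(30.0, params.T_ref, params) / axis.n_groups
        prev = -1.0
        for level in (0.01, 0.1, 1.0, 10.0, 100.0):
            state = SpectrumState(np.where(axis.active, level, 0.0))
            R = recruitment_flux(state, params.T_ref, params, npp=30.0,
                                 axis=axis)
            assert R[0] >= prev - 1e-12
            assert R[0] <= r_sat + 1e-12
            prev = R[0]


class TestStepEcology:
    def test_null_dynamics_preserves_state(self, params, axis):
        """gamma = 0 (no food), Z = 0, no biomass -> state unchanged."""
        p = params.replace(mort_coef=1e-300, egg_survival=1e-300)
        B = np.where(axis.active, 2.0, 0.0)
        state = SpectrumState(B.copy())
        # kill growth via zero food: no energy input
        out = step_ecology(state, {"npp": 0.0, "sst": p.T_ref}, 0.0, 0.01, p,
                           axis)
        np.testing.assert_allclose(out.biomass, B, rtol=1e-12)

    def test_pure_exponential_decay(self, params, axis):
        """With growth and recruitment off, every bin decays as exp(-z dt)."""
        z = 0.7
        p = params.replace(mort_coef=z, mort_exp=1.0 - 1e-15,
                           egg_survival=1e-300)
        B = np.where(axis.active, 1.0, 0.0)
        state = SpectrumState(B.copy())
        dt = 0.02
        out = step_ecology(state, {"npp": 0.0, "sst": p.T_ref}, 0.0, dt, p,
                           axis)
        expected = B * np.exp(-z * dt)
        np.testing.assert_allclose(out.biomass[axis.active],
                                   expected[axis.active], rtol=1e-6)

    def test_mass_budget_closure(self, params, axis):
        """Total biomass change equals recruitment - deaths - top-bin loss."""
        rng = np.random.default_rng(0)
        B = np.where(axis.active, rng.uniform(0.01, 1.0,
                                              (axis.n_groups, axis.n_bins)), 0.0)
        dt = stable_dt(params, axis, 15.0)
        F = 0.2 * np.ones((1, axis.n_groups, axis.n_bins))
        Bn, diag = step_cells(B[None], [30.0], [15.0], F, params, axis, dt)
        change = Bn.sum() - B.sum()
        budget = diag["recruit_total"][0] - diag["died_total"][0] - diag["top_loss"][0]
        assert change == pytest.approx(budget, rel=1e-8, abs=1e-12)

    def test_positivity_preserved(self, params, axis):
        rng = np.random.default_rng(1)
        B = np.where(axis.active, rng.uniform(0, 1, (axis.n_groups,
                                                     axis.n_bins)), 0.0)
        dt = stable_dt(params, axis, 30.0)
        F = 5.0 * np.ones((1, axis.n_groups, axis.n_bins))  # brutal fishing
        for _ in range(50):
            B1, _ = step_cells(B[None], [30.0], [28.0], F, params, axis, dt)
            B = B1[0]
            assert (B >= 0).all()

    def test_unstable_dt_raises_with_bin(self, params, axis):
        state = SpectrumState(np.where(axis.active, 1.0, 0.0))
        with pytest.raises(EcologyError, match="bin"):
            step_ecology(state, {"npp": 30.0, "sst": 25.0}, 0.0, 1.0, params,
                         axis)

    def test_energy_conservation_cap(self, params, axis):
        """Community production never exceeds the energy input."""
        B = np.where(axis.active, 50.0, 0.0)  # huge standing stock
        dt = stable_dt(params, axis, 15.0)
        _, diag = step_cells(B[None], [30.0], [15.0], np.zeros((1, 1, 1)),
                             params, axis, dt)
        assert diag["food"][0] <= 1.0


class TestSpinup:
    def test_zero_npp_zero_pristine(self, params):
        st = spinup_pristine({"npp": 0.0, "sst": 15.0}, params)
        assert st.pristine_biomass == pytest.approx(0.0, abs=1e-6)

    def test_pristine_monotone_in_npp(self, params, axis):
        lo = spinup_pristine({"npp": 20.0, "sst": 15.0}, params, axis=axis)
        hi = spinup_pristine({"npp": 60.0, "sst": 15.0}, params, axis=axis)
        assert hi.pristine_biomass > lo.pristine_biomass

    def test_independent_of_initial_condition(self, params, axis):
        from blueharvest.ecology import spinup_cells
        tol = 3e-4
        B1, t1 = spinup_cells([40.0], [12.0], params, axis, tol=tol)
        big = np.where(axis.active, 30.0, 0.0)[None]
        B2, t2 = spinup_cells([40.0], [12.0], params, axis, tol=tol, B0=big)
        assert t2[0] == pytest.approx(t1[0], rel=2e-2)

    def test_warmer_water_lower_pristine(self, params, axis):
        cold = spinup_pristine({"npp": 40.0, "sst": 8.0}, params, axis=axis)
        warm = spinup_pristine({"npp": 40.0, "sst": 18.0}, params, axis=axis)
        assert warm.pristine_biomass < cold.pristine_biomass

    def test_tolerance_consistency(self, params, axis):
        """Halving tol changes the pristine estimate by less than 10x tol."""
        a = spinup_pristine({"npp": 50.0, "sst": 15.0}, params, axis=axis,
                            tol=2e-3)
        b = spinup_pristine({"npp": 50.0, "sst": 15.0}, params, axis=axis,
                            tol=1e-3)
        assert abs(a.pristine_biomass - b.pristine_biomass) \
            <= 10 * 2e-3 * b.pristine_biomass


class TestMaturityAllocation:
    def test_midpoint_half_saturation(self, params):
        m_asym = 1e4
        psi = maturity_allocation(0.25 * m_asym, m_asym, params)
        assert psi == pytest.approx(params.repro_frac_at_maturity / 2)

    def test_bounded_and_monotone(self, params):
        m = np.logspace(1, 5, 60)
        psi = maturity_allocation(m, 1e4, params)
        assert (np.diff(psi) >= 0).all()
        assert psi.max() <= params.repro_frac_at_maturity


class TestKernelEquivalence:
    def test_fused_kernel_matches_numpy_reference(self, params, axis):
        """The numba substep and the numpy reference agree to round-off."""
        from blueharvest._kernels import HAVE_NUMBA
        if not HAVE_NUMBA:
            pytest.skip("numba unavailable; only the reference path exists")
        rng = np.random.default_rng(7)
        nc = 40
        B = rng.uniform(0, 2, (nc, axis.n_groups, axis.n_bins)) * axis.active
        npp = rng.uniform(0, 80, nc)
        T = rng.uniform(-2, 30, nc)
        F = rng.uniform(0, 1.5, (nc, axis.n_groups, axis.n_bins))
        dt = stable_dt(params, axis, 30.0)
        B1, d1 = step_cells(B, npp, T, F, params, axis, dt, impl="numpy")
        B2, d2 = step_cells(B, npp, T, F, params, axis, dt, impl="auto")
        np.testing.assert_allclose(B2, B1, rtol=1e-12, atol=1e-300)
        for key in ("harvest", "died_total", "recruit_total", "top_loss",
                    "food"):
            np.testing.assert_allclose(d2[key], d1[key], rtol=1e-10,
                                       atol=1e-18)
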