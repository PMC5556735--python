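"""Coupled per-cell runs, global orchestration, and the MSY ramp."""

import numpy as np
import pytest

import blueharvest as bh
from blueharvest import diagnostics
from blueharvest.ecology import _StepWork, step_cells, stable_dt
from blueharvest.economics import ScenarioSpec, TechSpec, selectivity_matrix
from blueharvest.experiments import (
    compute_msy,
    run_cell,
    run_global,
    run_hindcast,
)

CELL = {"npp": 50.0, "sst": 14.0}


@pytest.fixture(scope="module")
def oa_scenario():
    return ScenarioSpec(tech=TechSpec(mode="exponential", rate=0.05,
                                      t_start=1950))


class TestRunCell:
    def test_no_fishing_limit(self, params, axis, oa_scenario):
        """With catchability driven to zero, biomass stays pristine."""
        p = params.replace(q0=1e-12)
        traj = run_cell(CELL, p, oa_scenario, (1950, 1990), axis=axis)
        assert np.allclose(traj.harvest, 0.0, atol=1e-12)
        bf = traj.biomass_fraction[:, 0]
        assert (np.abs(bf - 1.0) < 0.05).all()

    def test_output_length_matches_span(self, params, axis, oa_scenario):
        traj = run_cell(CELL, params, oa_scenario, (1950, 1975), axis=axis)
        assert traj.harvest.shape == (25, 1)

    def test_richer_cell_harvests_more(self, params, axis, oa_scenario):
        """Doubling NPP raises open-access equilibrium harvest."""
        lo = run_cell({"npp": 30.0, "sst": 14.0}, params, oa_scenario,
                      (1950, 2010), axis=axis)
        hi = run_cell({"npp": 60.0, "sst": 14.0}, params, oa_scenario,
                      (1950, 2010), axis=axis)
        assert hi.harvest[-10:, 0].mean() > lo.harvest[-10:, 0].mean()


class TestRunGlobal:
    def test_single_cell_grid_matches_run_cell(self, params, axis,
                                               oa_scenario):
        from blueharvest.forcing import Grid, ForcingFields
        years = np.arange(1950.0, 1980.0)
        grid = Grid(resolution_deg=0.0, lat_centers=np.array([0.0]),
                    lon_centers=np.array([0.0]), cell_area=np.array([[1.0]]),
                    ocean_mask=np.array([[True]]),
                    coastal_mask=np.array([[True]]))
        forcing = ForcingFields(
            grid=grid, time=years,
            sst=np.full((30, 1, 1), CELL["sst"]),
            npp=np.full((30, 1, 1), CELL["npp"]),
        )
        cells, g, _ = run_global(forcing, params, oa_scenario)
        ref = run_cell(CELL, params, oa_scenario, (1950, 1980), axis=axis)
        np.testing.assert_allclose(cells.harvest, ref.harvest, rtol=1e-10)

    def test_global_harvest_is_area_weighted_sum(self, params, forcing8):
        sub = bh.ForcingFields(grid=forcing8.grid,
                               time=forcing8.time[:3],
                               sst=forcing8.sst[:3], npp=forcing8.npp[:3])
        scen = ScenarioSpec()
        cells, g, _ = run_global(sub, params, scen,
                                 years=np.arange(1950.0, 1953.0))
        manual = (cells.harvest * cells.cell_area[None]).sum(axis=1) / 1e12
        np.testing.assert_allclose(g.harvest, manual, rtol=1e-12)


class TestHindcastShape:
    """Qualitative structure of the open-access historical run."""

    @pytest.fixture(scope="class")
    def runs(self, params, forcing8):
        flat = ScenarioSpec(tech=TechSpec(mode="constant"))
        tech5 = ScenarioSpec(tech=TechSpec(mode="exponential", rate=0.05,
                                           t_start=1950))
        out = {}
        for name, scen in (("flat", flat), ("tech5", tech5)):
            cells, g, state = run_hindcast(forcing8, params, scen,
                                           years=np.arange(1950.0, 2031.0))
            out[name] = (cells, g)
        return out

    def test_constant_technology_no_rising_trend(self, runs):
        """Without technological progress harvest does not trend upward."""
        g = runs["flat"][1]
        early = g.harvest[5:15].mean()
        late = g.harvest[-10:].mean()
        assert late <= early * 1.2

    def test_technology_growth_produces_rise_and_peak(self, runs):
        g = runs["tech5"][1]
        ipk = int(np.argmax(g.harvest))
        assert 0 < ipk < len(g.harvest) - 1          # interior peak
        assert g.harvest[ipk] > 2.0 * g.harvest[0]    # substantial rise

    def test_harvest_nonnegative(self, runs):
        for _, g in runs.values():
            assert (g.harvest >= 0).all()

    def test_biomass_declines_while_fishery_grows(self, runs):
        g = runs["tech5"][1]
        ipk = int(np.argmax(g.harvest))
        assert g.biomass_fraction[ipk] < g.biomass_fraction[0]

    def test_coastal_share_declines_as_fishery_expands(self, runs):
        cells = runs["tech5"][0]
        s1950 = diagnostics.coastal_share(cells, 1960)
        s2000 = diagnostics.coastal_share(cells, 2000)
        assert s2000 < s1950

    def test_rich_coastal_cells_peak_before_poor_open_cells(self, runs):
        cells = runs["tech5"][0]
        ipk = np.argmax(cells.harvest, axis=0)
        fished = cells.harvest.max(axis=0) > 1e-6
        coast = cells.is_coastal & fished
        open_ = ~cells.is_coastal & fished
        assert ipk[coast].mean() < ipk[open_].mean()


class TestMsy:
    def test_zero_npp_cell_contributes_nothing(self, params, axis):
        from blueharvest.forcing import Grid, ForcingFields
        grid = Grid(resolution_deg=0.0,
                    lat_centers=np.array([0.0]),
                    lon_centers=np.array([0.0, 1.0]),
                    cell_area=np.array([[1e12, 1e12]]),
                    ocean_mask=np.array([[True, True]]),
                    coastal_mask=np.array([[True, False]]))
        forcing = ForcingFields(
            grid=grid, time=np.array([2000.0]),
            sst=np.array([[[14.0, 14.0]]]),
            npp=np.array([[[50.0, 0.0]]]),
        )
        res = compute_msy(forcing, params, ramp={"years": 150, "growth": 0.04},
                          axis=axis)
        assert res.cell_max_harvest[1] == pytest.approx(0.0, abs=1e-6)
        assert res.cell_max_harvest[0] > 0

    def test_msy_invariant_to_price_and_cost(self, params, axis):
        from blueharvest.forcing import Grid, ForcingFields
        grid = Grid(resolution_deg=0.0, lat_centers=np.array([0.0]),
                    lon_centers=np.array([0.0]), cell_area=np.array([[1e12]]),
                    ocean_mask=np.array([[True]]),
                    coastal_mask=np.array([[True]]))
        forcing = ForcingFields(grid=grid, time=np.array([2000.0]),
                                sst=np.array([[[14.0]]]),
                                npp=np.array([[[50.0]]]))
        base = compute_msy(forcing, params,
                           ramp={"years": 150, "growth": 0.04}, axis=axis)
        for fac in (0.5, 1.5):
            p = params.replace(price0=params.price0 * fac,
                               cost0=params.cost0 * fac)
            res = compute_msy(forcing, p, ramp={"years": 150, "growth": 0.04},
                              axis=axis)
            assert res.global_msy == pytest.approx(base.global_msy, rel=1e-12)

    def test_ramp_matches_brute_force_constant_q(self, params, axis):
        """Per-cell ramp maximum vs equilibrium yields on a fine q grid.

        The oracle holds fishing mortality constant at 40 levels and
        integrates each to equilibrium; the maximum equilibrium yield
        should agree with the transient-ramp estimate within 5%.
        """
        from blueharvest.ecology import spinup_cells
        from blueharvest.forcing import Grid, ForcingFields
        sample = [(50.0, 14.0), (80.0, 14.0), (20.0, 2.0)]
        sel = selectivity_matrix(axis, params)
        work = _StepWork(axis, params)
        for npp, sst in sample:
            grid = Grid(resolution_deg=0.0, lat_centers=np.array([0.0]),
                        lon_centers=np.array([0.0]),
                        cell_area=np.array([[1.0]]),
                        ocean_mask=np.array([[True]]),
                        coastal_mask=np.array([[True]]))
            forcing = ForcingFields(grid=grid, time=np.array([2000.0]),
                                    sst=np.array([[[sst]]]),
                                    npp=np.array([[[npp]]]))
            ramp = compute_msy(forcing, params, axis=axis)
            # brute force: constant-F levels run to equilibrium, batched
            B0, _ = spinup_cells([npp], [sst], params, axis)
            levels = np.geomspace(0.02, 3.0, 40)
            nb = len(levels)
            B = np.repeat(B0, nb, axis=0)
            F = levels[:, None, None] * sel[None]
            dt = stable_dt(params, axis, sst)
            nsub = int(np.ceil(1.0 / dt))
            npp_v = np.full(nb, npp)
            sst_v = np.full(nb, sst)
            h_last = np.zeros(nb)
            for year in range(150):
                h_year = np.zeros(nb)
                for _ in range(nsub):
                    B, diag = step_cells(B, npp_v, sst_v, F, params, axis,
                                         1.0 / nsub, work)
                    h_year += diag["harvest"]
                h_last = h_year
            brute = h_last.max()
            assert ramp.cell_max_harvest[0] == pytest.approx(brute, rel=0.05)
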