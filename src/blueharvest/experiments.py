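"""Experiment orchestration: spin-up, hindcast, projections, MSY ramps.

Cells are dynamically independent (no movement of fish or fleets between
cells), so the coupled human-natural system is stepped for all ocean cells
at once with vectorized array operations.  Per year the operation order is
fixed: ecology substeps (with the current fishing mortality) -> harvest
accumulation -> effort update, using a shared substep that respects the
size-spectrum stability limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diagnostics
from .ecology import (
    MassAxis,
    SpectrumState,
    _StepWork,
    spinup_cells,
    stable_dt,
    step_cells,
)
from .economics import (
    ScenarioSpec,
    catchability_schedule,
    cost_schedule,
    effort_tendency,
    price_schedule,
    selectivity_matrix,
)
from .forcing import ForcingFields
from .params import ParameterSet

__all__ = [
    "CellTrajectories",
    "MsyResult",
    "CellEnsembleState",
    "spinup_grid",
    "run_cell",
    "run_global",
    "run_hindcast",
    "run_projection",
    "compute_msy",
    "ExperimentError",
]


class ExperimentError(RuntimeError):
    pass


@dataclass
class CellTrajectories:
    """Annual per-cell output of a global run (arrays ``(ntime, ncell)``)."""

    time: np.ndarray
    harvest: np.ndarray        # g m^-2 yr^-1, annual total
    effort: np.ndarray         # W m^-2, annual mean
    biomass: np.ndarray        # g m^-2, end-of-year total
    pristine: np.ndarray       # (ncell,) g m^-2
    cell_area: np.ndarray      # (ncell,) m^2
    is_coastal: np.ndarray     # (ncell,) bool
    q_ratio: np.ndarray        # (ntime,) q/q0
    price: np.ndarray          # (ntime,) $ kg^-1
    cost: np.ndarray           # (ntime,) $ W^-1 yr^-1

    @property
    def biomass_fraction(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.pristine[None, :] > 0,
                            self.biomass / np.maximum(self.pristine[None, :], 1e-300),
                            0.0)

    def subset(self, idx) -> "CellTrajectories":
        return CellTrajectories(
            time=self.time, harvest=self.harvest[:, idx],
            effort=self.effort[:, idx], biomass=self.biomass[:, idx],
            pristine=self.pristine[idx], cell_area=self.cell_area[idx],
            is_coastal=self.is_coastal[idx], q_ratio=self.q_ratio,
            price=self.price, cost=self.cost,
        )


@dataclass
class CellEnsembleState:
    """Prognostic state of all ocean cells at one instant."""

    biomass: np.ndarray    # (ncell, ngroup, nbin)
    effort: np.ndarray     # (ncell,)
    pristine: np.ndarray   # (ncell,) total pristine biomass

    def copy(self) -> "CellEnsembleState":
        return CellEnsembleState(self.biomass.copy(), self.effort.copy(),
                                 self.pristine.copy())


@dataclass
class MsyResult:
    """Result of a transient catchability-ramp MSY estimate."""

    cell_max_harvest: np.ndarray  # (ncell,) g m^-2 yr^-1
    q_at_max: np.ndarray          # (ncell,) catchability at the cell max
    global_msy: float             # Mt yr^-1
    cell_area: np.ndarray
    quasi_static: bool            # False if too many cells peaked at ramp end


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _ocean_arrays(forcing: ForcingFields):
    """Flatten forcing to ocean cells: returns (npp, sst) of shape (nt, nc)."""
    ocean = forcing.grid.ocean_mask
    return forcing.npp[:, ocean], forcing.sst[:, ocean]


def _forcing_of_year(forcing: ForcingFields, year: float):
    t = np.asarray(forcing.time)
    i = int(np.clip(np.searchsorted(t, year + 0.5) - 1, 0, len(t) - 1))
    npp, sst = _ocean_arrays(forcing)
    return npp[i], sst[i]


def spinup_grid(forcing: ForcingFields, params: ParameterSet,
                axis: MassAxis | None = None, tol: float = 1e-3,
                max_years: int = 1000) -> CellEnsembleState:
    """Spin all ocean cells to pristine equilibrium under climatology."""
    axis = axis or MassAxis.default()
    clim = forcing.climatology()
    npp, sst = _ocean_arrays(clim)
    # best-effort: a marginal parameter draw that has not fully settled
    # after max_years still yields a usable pristine reference (the
    # residual drift is absorbed by the biomass-fraction overshoot margin)
    B, tot = spinup_cells(npp[0], sst[0], params, axis, tol=tol,
                          max_years=max_years, strict=False)
    return CellEnsembleState(
        biomass=B,
        effort=np.full(B.shape[0], params.effort_init),
        pristine=tot,
    )


def _run_years(state: CellEnsembleState, forcing: ForcingFields,
               params: ParameterSet, scenario: ScenarioSpec,
               years: np.ndarray, axis: MassAxis,
               effort_dynamic: bool = True,
               fixed_effort: np.ndarray | None = None,
               q_override=None) -> CellTrajectories:
    """Core annual loop; mutates ``state`` in place and returns trajectories.

    ``q_override``: optional callable year -> catchability, bypassing the
    scenario schedule (used by the MSY ramp).  With ``effort_dynamic=False``
    the nominal effort field is held at ``fixed_effort``.
    """
    grid = forcing.grid
    ocean = grid.ocean_mask
    nc = state.biomass.shape[0]
    sel = selectivity_matrix(axis, params)[None]  # (1, ng, nb)
    work = _StepWork(axis, params)

    npp_all, sst_all = _ocean_arrays(forcing)
    t_forcing = np.asarray(forcing.time)
    sst_max = float(np.nanmax(sst_all))
    dt = stable_dt(params, axis, sst_max)
    nsub = int(np.ceil(1.0 / dt))
    dt = 1.0 / nsub

    nt = len(years)
    out_h = np.zeros((nt, nc))
    out_e = np.zeros((nt, nc))
    out_b = np.zeros((nt, nc))
    q_ratio = np.zeros(nt)
    price_s = np.zeros(nt)
    cost_s = np.zeros(nt)

    B = state.biomass
    E = state.effort
    for k, yr in enumerate(years):
        i = int(np.clip(np.searchsorted(t_forcing, yr + 0.5) - 1, 0,
                        len(t_forcing) - 1))
        npp, sst = npp_all[i], sst_all[i]
        q = (float(q_override(yr)) if q_override is not None
             else float(catchability_schedule(scenario, params, yr)))
        price = float(price_schedule(scenario, yr))
        cost = float(cost_schedule(scenario, params, yr))

        if not effort_dynamic and fixed_effort is not None:
            E = np.asarray(fixed_effort, dtype=float).copy()

        h_year = np.zeros(nc)
        e_accum = np.zeros(nc)
        for _ in range(nsub):
            F = q * E[:, None, None] * sel
            B, diag = step_cells(B, npp, sst, F, params, axis, dt, work)
            h_sub = diag["harvest"] / dt       # g m^-2 yr^-1 over the substep
            h_year += diag["harvest"]
            e_accum += E * dt
            if effort_dynamic:
                E = E + dt * effort_tendency(E, h_sub, price, cost, params)
                np.clip(E, params.effort_floor, None, out=E)
        if not np.isfinite(B).all():
            bad = np.nonzero(~np.isfinite(B.sum(axis=(1, 2))))[0]
            raise ExperimentError(
                f"numerical blow-up in year {yr:.0f}, cell index {bad[:5]}"
            )
        out_h[k] = h_year          # g m^-2 over one year == g m^-2 yr^-1
        out_e[k] = e_accum
        out_b[k] = B.sum(axis=(1, 2))
        q_ratio[k] = q / params.q0
        price_s[k] = price
        cost_s[k] = cost

    state.biomass = B
    state.effort = E
    return CellTrajectories(
        time=np.asarray(years, dtype=float),
        harvest=out_h, effort=out_e, biomass=out_b,
        pristine=state.pristine,
        cell_area=grid.cell_area[ocean],
        is_coastal=grid.coastal_mask[ocean],
        q_ratio=q_ratio, price=price_s, cost=cost_s,
    )


# ---------------------------------------------------------------------------
# public experiment drivers
# ---------------------------------------------------------------------------


def run_cell(forcing_cell: dict, params: ParameterSet, scenario: ScenarioSpec,
             t_span: tuple[float, float], initial: SpectrumState | None = None,
             axis: MassAxis | None = None):
    """Run the coupled system for a single patch of ocean.

    ``forcing_cell`` maps ``npp``/``sst`` to scalars or arrays over the run
    years.  Starts from the pristine spin-up state unless ``initial`` is
    given.  Returns a :class:`CellTrajectories` with one cell, whose length
    equals the number of years in ``t_span``.
    """
    axis = axis or MassAxis.default()
    years = np.arange(t_span[0], t_span[1])
    nt = len(years)
    npp = np.broadcast_to(np.asarray(forcing_cell["npp"], float), (nt,))
    sst = np.broadcast_to(np.asarray(forcing_cell["sst"], float), (nt,))

    from .forcing import Grid  # single synthetic 1 m^2 cell
    grid = Grid(
        resolution_deg=0.0,
        lat_centers=np.array([0.0]), lon_centers=np.array([0.0]),
        cell_area=np.array([[1.0]]),
        ocean_mask=np.array([[True]]), coastal_mask=np.array([[True]]),
    )
    forcing = ForcingFields(grid=grid, time=years.astype(float),
                            sst=sst[:, None, None].copy(),
                            npp=npp[:, None, None].copy())

    if initial is None:
        state = spinup_grid(forcing, params, axis)
    else:
        state = CellEnsembleState(
            biomass=initial.biomass[None].copy(),
            effort=np.array([params.effort_init]),
            pristine=np.array([initial.pristine_biomass
                               if np.isfinite(initial.pristine_biomass)
                               else initial.biomass.sum()]),
        )
    return _run_years(state, forcing, params, scenario, years, axis)


def run_global(forcing: ForcingFields, params: ParameterSet,
               scenario: ScenarioSpec, initial: CellEnsembleState | None = None,
               years: np.ndarray | None = None, axis: MassAxis | None = None):
    """Run all ocean cells and aggregate.

    Returns ``(cells, global_trajectory, end_state)``.
    """
    axis = axis or MassAxis.default()
    if years is None:
        years = np.asarray(forcing.time, dtype=float)
    state = (initial.copy() if initial is not None
             else spinup_grid(forcing, params, axis))
    cells = _run_years(state, forcing, params, scenario, np.asarray(years, float),
                       axis)
    return cells, diagnostics.aggregate_global(cells, forcing.grid), state


def run_hindcast(forcing: ForcingFields, params: ParameterSet,
                 scenario: ScenarioSpec | None = None,
                 years: np.ndarray | None = None,
                 axis: MassAxis | None = None,
                 pre_years: int = 50,
                 pristine: CellEnsembleState | None = None):
    """Historical open-access hindcast.

    Three phases: (1) spin-up to the pristine equilibrium under
    climatological forcing; (2) ``pre_years`` of open-access dynamics at
    constant start-year technology, so the fishery begins the transient at
    its contemporary bionomic quasi-equilibrium rather than from a bare
    exploratory fleet; (3) the transient itself (by default the forcing's
    span) under the scenario — 5 %/yr exponential technology growth with
    constant price and cost unless configured otherwise.
    """
    if scenario is None:
        scenario = ScenarioSpec()  # exponential 5%/yr from 1950, constant price
    scenario.validate()
    axis = axis or MassAxis.default()
    if years is None:
        years = np.asarray(forcing.time, dtype=float)
    years = np.asarray(years, dtype=float)
    state = (pristine.copy() if pristine is not None
             else spinup_grid(forcing, params, axis))
    state.effort = np.full_like(state.effort, params.effort_init)
    if pre_years > 0:
        from dataclasses import replace as _replace
        const_tech = ScenarioSpec(
            tech=_replace(scenario.tech, mode="constant"),
            price=scenario.price, cost=scenario.cost,
        )
        pre_span = years[0] - pre_years + np.arange(pre_years)
        _run_years(state, forcing, params, const_tech, pre_span, axis)
    return run_global(forcing, params, scenario, initial=state, years=years,
                      axis=axis)


def run_projection(forcing: ForcingFields, params: ParameterSet,
                   initial: CellEnsembleState,
                   tech_mode: str = "exponential",
                   price_mode: str = "constant",
                   years: np.ndarray | None = None,
                   scenario_base: ScenarioSpec | None = None,
                   axis: MassAxis | None = None):
    """Project forward from a hindcast end-state (2006-2100 style runs).

    ``tech_mode``: "exponential" (continued growth) or "stabilizing"
    (ramp-down to zero by t_rampdown_end).  ``price_mode``: "constant" or
    "linear" (1 -> 3 $/kg by 2100 by default).
    """
    base = scenario_base or ScenarioSpec()
    from dataclasses import replace
    tech = replace(base.tech, mode=tech_mode)
    price = replace(base.price, mode=price_mode)
    scenario = ScenarioSpec(tech=tech, price=price, cost=base.cost)
    scenario.validate()
    if years is None:
        years = np.asarray(forcing.time, dtype=float)
    return run_global(forcing, params, scenario, initial=initial, years=years,
                      axis=axis)


def compute_msy(forcing: ForcingFields, params: ParameterSet,
                ramp: dict | None = None, year: float | None = None,
                axis: MassAxis | None = None,
                initial: CellEnsembleState | None = None) -> MsyResult:
    """Estimate MSY by a slow transient catchability ramp.

    Effort dynamics are bypassed: the nominal effort field is held fixed
    (the technical harvesting capacity) while catchability rises slowly
    from a small value, so each cell traverses the full range of fishing
    mortality quasi-statically.  The running maximum of annual harvest per
    cell is recorded; the global MSY is the area-weighted sum of per-cell
    maxima, in Mt yr^-1.  Independent of price and cost by construction.

    ``ramp`` keys: ``f_start`` (initial fishing mortality scale, yr^-1),
    ``growth`` (fractional catchability growth per year), ``years``,
    ``effort`` (fixed nominal effort density, W m^-2).
    ``year``: evaluate the forcing of that year (held constant); default is
    the climatological mean.
    """
    axis = axis or MassAxis.default()
    ramp = {"f_start": 0.005, "growth": 0.02, "years": 300, "effort": 1e-5,
            **(ramp or {})}
    clim = forcing.climatology() if year is None else forcing.at_year(year)
    npp0, sst0 = _ocean_arrays(clim)

    if initial is None:
        state = spinup_grid(clim, params, axis)
    else:
        state = initial.copy()
    nc = state.biomass.shape[0]
    e_fix = np.full(nc, ramp["effort"])
    q_start = ramp["f_start"] / ramp["effort"]
    n_years = int(ramp["years"])
    y0 = float(clim.time[0])

    def q_of(yr):
        return q_start * (1.0 + ramp["growth"]) ** (yr - y0)

    years = y0 + np.arange(n_years)
    b_init = state.biomass.sum(axis=(1, 2))
    cells = _run_years(state, clim, params, ScenarioSpec(), years, axis,
                       effort_dynamic=False, fixed_effort=e_fix,
                       q_override=q_of)

    # quasi-static correction: sustainable yield at the current stock equals
    # harvest plus the biomass tendency (the tendency vanishes at
    # equilibrium; during the ramp it is negative, removing the transient
    # stock-mining contribution from the running maximum).
    db = np.diff(np.vstack([b_init[None], cells.biomass]), axis=0)
    h_sustainable = np.clip(cells.harvest + db, 0.0, None)
    imax = np.argmax(h_sustainable, axis=0)           # (ncell,)
    cell_max = h_sustainable[imax, np.arange(nc)]
    q_at_max = q_of(years[imax])
    area = cells.cell_area
    fished = cell_max > 0
    frac_at_end = (float(np.mean(imax[fished] == n_years - 1))
                   if fished.any() else 0.0)
    return MsyResult(
        cell_max_harvest=cell_max,
        q_at_max=np.asarray(q_at_max, dtype=float),
        global_msy=float((cell_max * area).sum() / diagnostics.G_PER_MT),
        cell_area=area,
        quasi_static=frac_at_end <= 0.10,
    )
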