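"""Open-access fishery economics: harvest, effort dynamics, scenarios.

Fishing follows the classic open-access (Gordon) paradigm: nominal effort in
each grid cell grows or shrinks in proportion to local profit — revenue
(price times harvest) minus cost (cost per unit effort times effort) — at a
rate set by the fleet responsiveness.  Technology acts multiplicatively on
the catchability q, so effective effort is nominal effort times q/q0.

Scenario schedules prescribe the exogenous drivers: catchability growth
(constant, exponential, or a ramp-down to stabilized technology), ex-vessel
price (constant, linear, or tabulated), and cost per unit effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .ecology import MassAxis, SpectrumState
from .params import ParameterSet

__all__ = [
    "EconState",
    "TechSpec",
    "PriceSpec",
    "CostSpec",
    "ScenarioSpec",
    "selectivity",
    "harvest_rate",
    "step_effort",
    "catchability_schedule",
    "price_schedule",
    "cost_schedule",
    "cost_from_steady_state",
]


@dataclass
class EconState:
    """Per-cell economic state: nominal effort density and catchability."""

    effort: float          # W m^-2
    catchability: float    # m^2 W^-1 yr^-1


# ---------------------------------------------------------------------------
# Selectivity and harvest
# ---------------------------------------------------------------------------


def selectivity(m, group_mass, p: ParameterSet):
    """Gear selectivity in [0, 1]: logistic in log mass.

    Equals 0.5 at ``sel_mass_ratio`` times the group's asymptotic mass and
    rises monotonically with body mass.
    """
    m = np.asarray(m, dtype=float)
    mid = p.sel_mass_ratio * np.asarray(group_mass, dtype=float)
    x = (np.log10(m) - np.log10(mid)) / p.sel_width
    return 1.0 / (1.0 + np.exp(-x))


def selectivity_matrix(axis: MassAxis, p: ParameterSet) -> np.ndarray:
    """(ngroup, nbin) selectivity, zero outside each group's active bins."""
    sel = selectivity(axis.centers[None, :], axis.group_masses[:, None], p)
    return sel * axis.active


def harvest_rate(spectrum: SpectrumState, econ: EconState, p: ParameterSet,
                 axis: MassAxis | None = None):
    """Instantaneous harvest from one cell.

    Fishing mortality F(group, bin) = q * effort * selectivity(m); the
    harvest flux is h = sum(F * biomass), g m^-2 yr^-1.
    """
    axis = axis or MassAxis.default()
    F = econ.catchability * econ.effort * selectivity_matrix(axis, p)
    h = float((F * spectrum.biomass).sum())
    return h, F


# ---------------------------------------------------------------------------
# Effort dynamics
# ---------------------------------------------------------------------------


def step_effort(econ: EconState, h: float, price: float, cost: float,
                p: ParameterSet, dt: float) -> EconState:
    """Open-access effort update (forward Euler).

    dE/dt = k_e * (price * h / 1000 - cost * E): effort enters where fishing
    is profitable and exits where it runs at a loss.  The 1/1000 converts
    price from $/kg to $/g to match the internal gram-based harvest flux.
    Effort is floored at ``effort_floor`` so that cells can be re-entered
    when technology later makes them profitable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    profit = price * h / 1000.0 - cost * econ.effort  # $ m^-2 yr^-1
    e_new = econ.effort + dt * p.fleet_response * profit
    return EconState(effort=max(e_new, p.effort_floor),
                     catchability=econ.catchability)


def effort_tendency(effort, h, price, cost, p: ParameterSet):
    """Vectorized dE/dt (W m^-2 yr^-1) for the coupled stepping loops."""
    return p.fleet_response * (price * np.asarray(h) / 1000.0
                               - cost * np.asarray(effort))


# ---------------------------------------------------------------------------
# Scenario schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TechSpec:
    """Catchability schedule.

    ``constant``: q = q0.  ``exponential``: q grows by ``rate`` (fraction
    per year, e.g. 0.05) compounded from ``t_start``.  ``stabilizing``:
    exponential up to ``t_rampdown_start``, then the annual growth rate
    declines linearly to zero at ``t_rampdown_end`` and q stays constant
    afterwards.
    """

    mode: str = "exponential"
    rate: float = 0.05
    t_start: float = 1950.0
    t_rampdown_start: float = 2006.0
    t_rampdown_end: float = 2036.0

    def validate(self):
        if self.mode not in ("constant", "exponential", "stabilizing"):
            raise ValueError(f"unknown tech mode {self.mode!r}")
        if self.rate < 0:
            raise ValueError("tech rate must be >= 0")
        if self.mode == "stabilizing" and not (
            self.t_start <= self.t_rampdown_start < self.t_rampdown_end
        ):
            raise ValueError("tech schedule times must be ordered")


@dataclass(frozen=True)
class PriceSpec:
    """Ex-vessel price schedule, $ kg^-1."""

    mode: str = "constant"
    p_start: float = 1.0
    p_end: float = 3.0
    t_start: float = 2006.0
    t_end: float = 2100.0
    table: tuple = ()   # ((year, price), ...) for mode="table"

    def validate(self):
        if self.mode not in ("constant", "linear", "table"):
            raise ValueError(f"unknown price mode {self.mode!r}")
        if self.mode == "linear" and not self.t_end > self.t_start:
            raise ValueError("price schedule times must be ordered")
        if self.mode == "table" and len(self.table) == 0:
            raise ValueError("table price mode requires a table")


@dataclass(frozen=True)
class CostSpec:
    """Cost per unit effort schedule, $ W^-1 yr^-1."""

    mode: str = "constant"
    c0: float | None = None   # None -> ParameterSet.cost0
    table: tuple = ()

    def validate(self):
        if self.mode not in ("constant", "table"):
            raise ValueError(f"unknown cost mode {self.mode!r}")
        if self.mode == "table" and len(self.table) == 0:
            raise ValueError("table cost mode requires a table")


@dataclass(frozen=True)
class ScenarioSpec:
    """Bundle of the three exogenous economic schedules."""

    tech: TechSpec = field(default_factory=TechSpec)
    price: PriceSpec = field(default_factory=PriceSpec)
    cost: CostSpec = field(default_factory=CostSpec)

    def validate(self):
        self.tech.validate()
        self.price.validate()
        self.cost.validate()

    # -- YAML round trip ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tech = TechSpec(**raw.get("tech", {}))
        price = raw.get("price", {})
        if "table" in price:
            price["table"] = tuple(map(tuple, price["table"]))
        cost = raw.get("cost", {})
        if "table" in cost:
            cost["table"] = tuple(map(tuple, cost["table"]))
        s = cls(tech=tech, price=PriceSpec(**price), cost=CostSpec(**cost))
        s.validate()
        return s

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        raw = {"tech": asdict(self.tech), "price": asdict(self.price),
               "cost": asdict(self.cost)}
        for sec in ("price", "cost"):
            raw[sec]["table"] = [list(row) for row in raw[sec]["table"]]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


def catchability_schedule(s: ScenarioSpec, p: ParameterSet, t) -> np.ndarray:
    """Catchability q(t), m^2 W^-1 yr^-1, under the scenario's tech mode.

    Exponential mode compounds annually: q = q0 * (1 + rate)^(t - t_start).
    Stabilizing mode compounds a growth rate that declines linearly from
    ``rate`` at ``t_rampdown_start`` to zero at ``t_rampdown_end``; q is
    constant afterwards.
    """
    tech = s.tech
    tech.validate()
    t = np.asarray(t, dtype=float)
    if tech.mode == "constant" or tech.rate == 0:
        return np.broadcast_to(p.q0, t.shape).copy() if t.ndim else float(p.q0)

    if tech.mode == "exponential":
        q = p.q0 * (1.0 + tech.rate) ** (t - tech.t_start)
        return q if t.ndim else float(q)

    # stabilizing: integrate ln(1+g(t)) with g linear on the ramp
    def _log_factor(tt):
        tt = np.asarray(tt, dtype=float)
        t0, t1 = tech.t_rampdown_start, tech.t_rampdown_end
        # exponential segment
        le = np.log1p(tech.rate) * (np.minimum(tt, t0) - tech.t_start)
        # ramp segment: yearly compounding of g(year) = rate*(1 - (yr-t0)/(t1-t0))
        out = np.zeros_like(tt)
        for i, ti in np.ndenumerate(tt):
            acc = 0.0
            yr = t0
            while yr < min(ti, t1):
                step = min(1.0, min(ti, t1) - yr)
                g = tech.rate * max(0.0, 1.0 - (yr - t0) / (t1 - t0))
                acc += np.log1p(g) * step
                yr += step
            out[i] = acc
        return le + out

    q = p.q0 * np.exp(_log_factor(t))
    return q if t.ndim else float(q)


def price_schedule(s: ScenarioSpec, t) -> np.ndarray:
    """Ex-vessel price at time t, $ kg^-1."""
    pr = s.price
    pr.validate()
    t = np.asarray(t, dtype=float)
    if pr.mode == "constant":
        out = np.full(t.shape, pr.p_start)
    elif pr.mode == "linear":
        frac = np.clip((t - pr.t_start) / (pr.t_end - pr.t_start), 0.0, 1.0)
        out = pr.p_start + (pr.p_end - pr.p_start) * frac
    else:
        tab = np.asarray(pr.table, dtype=float)
        out = np.interp(t, tab[:, 0], tab[:, 1])
    return out if t.ndim else float(out)


def cost_schedule(s: ScenarioSpec, p: ParameterSet, t) -> np.ndarray:
    """Cost per unit effort at time t, $ W^-1 yr^-1."""
    c = s.cost
    c.validate()
    t = np.asarray(t, dtype=float)
    if c.mode == "constant":
        out = np.full(t.shape, p.cost0 if c.c0 is None else c.c0)
    else:
        tab = np.asarray(c.table, dtype=float)
        out = np.interp(t, tab[:, 0], tab[:, 1])
    return out if t.ndim else float(out)


def cost_from_steady_state(price: float, global_harvest: float,
                           global_effort: float) -> float:
    """Cost per unit effort from the open-access zero-profit identity.

    At bionomic equilibrium revenue equals cost, so c = price * harvest /
    effort with price in $ kg^-1, harvest in kg yr^-1, effort in W.  This is
    how the historical global-average cost anchor is reconstructed from
    observed price, harvest and effort.
    """
    if global_effort <= 0:
        raise ValueError("global effort must be positive")
    return price * global_harvest / global_effort
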