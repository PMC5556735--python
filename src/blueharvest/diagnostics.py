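"""Aggregation and summary diagnostics for global runs.

Converts per-cell trajectories into the global time series used throughout:
harvest in Mt yr^-1, nominal and effective effort in GW, biomass as a
fraction of pristine biomass (ratio of area-weighted totals), and aggregate
profit in billion $ yr^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GlobalTrajectory",
    "aggregate_global",
    "detect_peak",
    "coastal_share",
    "ensemble_stats",
    "G_PER_MT",
    "W_PER_GW",
]

G_PER_MT = 1e12
W_PER_GW = 1e9


@dataclass
class GlobalTrajectory:
    """Area-integrated global time series of one run."""

    time: np.ndarray              # years
    harvest: np.ndarray           # Mt yr^-1
    nominal_effort: np.ndarray    # GW
    effective_effort: np.ndarray  # GW (nominal * q/q0)
    biomass_fraction: np.ndarray  # dimensionless
    profit: np.ndarray            # billion $ yr^-1

    def validate(self, overshoot_tol: float = 0.05) -> None:
        if (self.harvest < 0).any() or (self.nominal_effort < 0).any():
            raise ValueError("harvest and effort must be non-negative")
        bf = self.biomass_fraction
        if ((bf < 0) | (bf > 1 + overshoot_tol)).any():
            raise ValueError("biomass_fraction outside [0, 1+tol]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.time,
                "harvest_Mt": self.harvest,
                "nominal_GW": self.nominal_effort,
                "effective_GW": self.effective_effort,
                "biomass_fraction": self.biomass_fraction,
                "profit_B$": self.profit,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def aggregate_global(cells, grid) -> GlobalTrajectory:
    """Aggregate per-cell trajectories to global series.

    ``cells`` is a :class:`~blueharvest.experiments.CellTrajectories`-like
    object with per-cell arrays ``(ntime, ncell)``: harvest (g m^-2 yr^-1),
    effort (W m^-2), biomass (g m^-2), pristine biomass (g m^-2, per cell),
    plus scalar series q_ratio (q/q0), price ($ kg^-1) and cost
    ($ W^-1 yr^-1).  ``grid`` supplies the cell areas (m^2) of the same
    cells.  Biomass fraction is the ratio of area-weighted totals.
    """
    area = np.asarray(cells.cell_area, dtype=float)  # (ncell,)
    harvest_g = cells.harvest @ area                  # g yr^-1
    effort_w = cells.effort @ area                    # W
    biomass_g = cells.biomass @ area
    pristine_g = float(np.asarray(cells.pristine) @ area)
    q_ratio = np.asarray(cells.q_ratio, dtype=float)
    price = np.asarray(cells.price, dtype=float)
    cost = np.asarray(cells.cost, dtype=float)

    # $/yr: price($/kg)*harvest(g)/1000 - cost($/W/yr)*effort(W)
    profit_dollars = price * harvest_g / 1000.0 - cost * effort_w
    return GlobalTrajectory(
        time=np.asarray(cells.time, dtype=float),
        harvest=harvest_g / G_PER_MT,
        nominal_effort=effort_w / W_PER_GW,
        effective_effort=effort_w * q_ratio / W_PER_GW,
        biomass_fraction=biomass_g / pristine_g if pristine_g > 0
        else np.zeros_like(biomass_g),
        profit=profit_dollars / 1e9,
    )


def detect_peak(series, time=None):
    """Locate the maximum of a series (first occurrence on ties).

    Returns ``(year, value, ratio, boundary)`` where ``ratio`` is
    value/series[0] (inf if the series starts at zero) and ``boundary`` is
    True — with a warning — when the maximum sits on either end of the
    record, i.e. the peak may lie outside the window.
    """
    series = np.asarray(series, dtype=float)
    if time is None:
        time = np.arange(len(series))
    time = np.asarray(time)
    i = int(np.argmax(series))
    boundary = i == 0 or i == len(series) - 1
    if boundary:
        warnings.warn("series maximum lies on the record boundary; "
                      "the peak may not be resolved", stacklevel=2)
    ratio = series[i] / series[0] if series[0] != 0 else np.inf
    return time[i], float(series[i]), float(ratio), boundary


def coastal_share(cells, year) -> float:
    """Fraction of global harvest taken in coastal cells in a given year.

    Raises on zero total harvest (the share is undefined).
    """
    t = np.asarray(cells.time)
    i = int(np.argmin(np.abs(t - year)))
    area = np.asarray(cells.cell_area, dtype=float)
    h = cells.harvest[i] * area
    total = h.sum()
    if total <= 0:
        raise ValueError(f"no harvest in year {year}: coastal share undefined")
    return float(h[cells.is_coastal].sum() / total)


def ensemble_stats(trajectories):
    """Pointwise ensemble mean and sample s.d. (ddof=1) of global series.

    Returns two :class:`GlobalTrajectory` objects (mean, sd); the sd
    trajectory carries standard deviations in every field.
    """
    if len(trajectories) == 0:
        raise ValueError("empty ensemble")
    fields = ("harvest", "nominal_effort", "effective_effort",
              "biomass_fraction", "profit")
    t0 = trajectories[0].time
    mean_kw, sd_kw = {}, {}
    for name in fields:
        stack = np.stack([getattr(tr, name) for tr in trajectories])
        mean_kw[name] = stack.mean(axis=0)
        sd_kw[name] = (stack.std(axis=0, ddof=1) if len(trajectories) > 1
                       else np.zeros_like(stack[0]))
    return (GlobalTrajectory(time=t0.copy(), **mean_kw),
            GlobalTrajectory(time=t0.copy(), **sd_kw))


def plot_global(trajectories, sd=None, labels=None, ax=None):
    """Plot global harvest trajectories (ensemble mean +/- 1 s.d. band).

    ``trajectories`` is a GlobalTrajectory or a list of them; ``sd`` an
    optional matching s.d. trajectory (as from :func:`ensemble_stats`).
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if isinstance(trajectories, GlobalTrajectory):
        trajectories = [trajectories]
    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 4))
    for i, tr in enumerate(trajectories):
        label = labels[i] if labels else None
        line, = ax.plot(tr.time, tr.harvest, label=label)
        if sd is not None and i == 0:
            ax.fill_between(tr.time, tr.harvest - sd.harvest,
                            tr.harvest + sd.harvest, alpha=0.25,
                            color=line.get_color())
    ax.set_xlabel("year")
    ax.set_ylabel("global harvest (Mt yr$^{-1}$)")
    if labels:
        ax.legend(frameon=False)
    return ax
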