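"""Model/Results front end.

:class:`FisheryModel` bundles forcing, priors and calibration targets the
way a statsmodels model bundles data and design; ``fit()`` runs the
rejection-ABC calibration and returns a :class:`FisheryResults` carrying the
5-member ensemble, its distances and posterior ranges, with experiment
methods (hindcast, projection, MSY) and a ``summary()`` table hanging off
the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import calibration as cal
from . import diagnostics, experiments
from .ecology import MassAxis
from .economics import ScenarioSpec
from .forcing import ForcingFields, make_region_mask
from .params import CALIBRATED_NAMES, ParameterSet

__all__ = ["FisheryModel", "FisheryResults"]


class FisheryModel:
    """Coupled fish size-spectrum / open-access economy model on a grid.

    Parameters
    ----------
    forcing : ForcingFields
        Gridded SST/NPP boundary condition for the calibration period.
    target : CalibrationTarget, optional
        Regional summaries to calibrate against.  If omitted, synthetic
        targets are generated from ``truth`` (default reference parameters)
        at fit time.
    priors : PriorSpec, optional
    scenario : ScenarioSpec, optional
        Economic scenario of the calibration hindcast (default: 5 %/yr
        technology growth, constant price and cost).
    n_regions : int
        Number of coastal aggregation regions for the reduced calibration
        simulator.
    """

    def __init__(self, forcing: ForcingFields, target=None, priors=None,
                 scenario: ScenarioSpec | None = None, n_regions: int = 20,
                 truth: ParameterSet | None = None,
                 axis: MassAxis | None = None):
        self.forcing = forcing
        self.priors = priors or cal.default_priors()
        self.scenario = scenario or ScenarioSpec()
        self.axis = axis or MassAxis.default()
        self.truth = truth or ParameterSet()
        self.regions = make_region_mask(forcing.grid, n_regions)
        self.regional_forcing = cal.regionalize(forcing, self.regions)
        self.target = target

    def fit(self, n_samples: int = 200, quantile: float = 0.05, k: int = 5,
            seed: int = 0, progress: bool = False) -> "FisheryResults":
        """Calibrate by rejection ABC and select the spread ensemble."""
        target = self.target
        if target is None:
            target = cal.make_targets(self.regional_forcing, self.truth,
                                      self.scenario, self.axis)
        result = cal.calibrate(
            self.regional_forcing, target, self.priors, n=n_samples,
            quantile=quantile, k=k, seed=seed, scenario=self.scenario,
            axis=self.axis, base=self.truth, progress=progress,
        )
        return FisheryResults(self, result, target)


@dataclass
class FisheryResults:
    """Calibrated ensemble with experiment drivers and a summary table."""

    model: FisheryModel
    ensemble: cal.EnsembleResult
    target: cal.CalibrationTarget

    @property
    def members(self) -> list[ParameterSet]:
        return self.ensemble.selected

    def params_frame(self) -> pd.DataFrame:
        return self.ensemble.selected_frame()

    def posterior_ranges(self) -> pd.DataFrame:
        acc = self.ensemble.accepted_frame()
        rows = []
        for name in CALIBRATED_NAMES:
            a = acc[name]
            rows.append({"parameter": name, "accepted_min": a.min(),
                         "accepted_median": a.median(),
                         "accepted_max": a.max()})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        lines = [
            "Coupled fishery model — rejection-ABC calibration",
            "=" * 58,
            f"accepted draws: {len(self.ensemble.accepted)}   "
            f"distance threshold: {self.ensemble.threshold:.4f}",
            f"ensemble members: {len(self.members)}   "
            f"member distances: "
            + ", ".join(f"{d:.3f}" for d in self.ensemble.selected_distances),
            "",
            "Posterior (accepted) parameter ranges:",
        ]
        pr = self.posterior_ranges()
        for _, r in pr.iterrows():
            lines.append(
                f"  {r['parameter']:<24s} {r['accepted_min']:>10.4g} "
                f"{r['accepted_median']:>10.4g} {r['accepted_max']:>10.4g}"
            )
        return "\n".join(lines)

    # -- experiments over the ensemble ------------------------------------
    def hindcast(self, forcing: ForcingFields | None = None,
                 scenario: ScenarioSpec | None = None, years=None):
        """Open-access hindcast for every member; returns per-member output.

        Each element is ``(cells, global_trajectory, end_state)``.
        """
        forcing = forcing or self.model.forcing
        scenario = scenario or self.model.scenario
        return [
            experiments.run_hindcast(forcing, p, scenario, years=years,
                                     axis=self.model.axis)
            for p in self.members
        ]

    def msy(self, forcing: ForcingFields | None = None, year=None,
            ramp: dict | None = None) -> list[experiments.MsyResult]:
        """Transient-ramp MSY for every member (Mt yr^-1 in .global_msy)."""
        forcing = forcing or self.model.forcing
        return [
            experiments.compute_msy(forcing, p, ramp=ramp, year=year,
                                    axis=self.model.axis)
            for p in self.members
        ]

    def ensemble_mean(self, runs):
        """Mean/sd GlobalTrajectory from a list of hindcast outputs."""
        return diagnostics.ensemble_stats([g for _, g, _ in runs])
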