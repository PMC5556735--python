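"""Rejection-ABC calibration of the 13 uncertain parameters.

Parameter draws are scored by running the coupled model on a reduced,
region-aggregated representation of the forcing (each coastal region
becomes one virtual cell with its area-mean SST and NPP and total area —
the desk-scale analogue of aggregating at the scale of large coastal
ecosystems), and comparing two summaries per region against targets: the
peak annual catch density and the late-period biomass fraction.  Distances
are root-mean-square log ratios, draws below a distance quantile are
accepted, and a maximally spread 5-member ensemble is picked from the
accepted cloud by greedy max-min selection in prior-normalized space.

Because observed regional catch/biomass datasets are outside this package's
scope, targets are normally synthesized from a run with a known "truth"
parameter set (see :func:`make_targets` and :func:`recovery_test`); users
with real regional data can supply a :class:`CalibrationTarget` directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecology import MassAxis, spinup_cells
from .economics import ScenarioSpec
from .experiments import CellEnsembleState, _run_years
from .forcing import ForcingFields, Grid, RegionMask
from .params import CALIBRATED_NAMES, ParameterSet

__all__ = [
    "PriorSpec",
    "CalibrationTarget",
    "EnsembleResult",
    "default_priors",
    "sample_parameters",
    "regional_series",
    "make_targets",
    "score_parameters",
    "abc_accept",
    "select_ensemble",
    "calibrate",
    "recovery_test",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, per parameter, on a linear or log scale."""

    bounds: dict  # name -> (lower, upper, scale) with scale in {linear, log}

    def validate(self) -> None:
        for name, (lo, hi, scale) in self.bounds.items():
            if name not in CALIBRATED_NAMES:
                raise CalibrationError(f"{name!r} is not a calibrated slot")
            if not lo < hi:
                raise CalibrationError(f"prior for {name}: lower >= upper")
            if scale not in ("linear", "log"):
                raise CalibrationError(f"prior for {name}: bad scale {scale!r}")
            if scale == "log" and lo <= 0:
                raise CalibrationError(f"log prior for {name} needs positive bounds")
        missing = set(CALIBRATED_NAMES) - set(self.bounds)
        if missing:
            raise CalibrationError(f"priors missing for {sorted(missing)}")

    def normalize(self, values: dict) -> np.ndarray:
        """Map a parameter dict to [0,1]^13 on each prior's scale."""
        out = np.empty(len(CALIBRATED_NAMES))
        for i, name in enumerate(CALIBRATED_NAMES):
            lo, hi, scale = self.bounds[name]
            v = values[name]
            if scale == "log":
                out[i] = np.log(v / lo) / np.log(hi / lo)
            else:
                out[i] = (v - lo) / (hi - lo)
        return out

    @classmethod
    def from_csv(cls, path) -> "PriorSpec":
        df = pd.read_csv(path)
        bounds = {r["name"]: (float(r["lower"]), float(r["upper"]), r["scale"])
                  for _, r in df.iterrows()}
        spec = cls(bounds=bounds)
        spec.validate()
        return spec

    def to_csv(self, path) -> None:
        rows = [{"name": k, "lower": lo, "upper": hi, "scale": s}
                for k, (lo, hi, s) in self.bounds.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_priors() -> PriorSpec:
    """Broad literature-plausible priors around the reference values."""
    spec = PriorSpec(bounds={
        "epsilon_trophic": (0.05, 0.20, "log"),
        "ppmr": (300.0, 3000.0, "log"),
        "growth_coef": (2.0, 9.0, "log"),
        "growth_exp": (0.60, 0.80, "linear"),
        "mort_coef": (0.4, 3.0, "log"),
        "mort_exp": (0.40, 0.70, "linear"),
        "activation_energy": (0.30, 0.60, "linear"),
        "egg_survival": (0.1, 0.6, "log"),
        "recruitment_half_sat": (0.001, 0.02, "log"),
        "repro_frac_at_maturity": (0.10, 0.40, "linear"),
        "q0": (200.0, 2500.0, "log"),
        "fleet_response": (0.01, 0.20, "log"),
        "sel_mass_ratio": (0.01, 0.20, "log"),
    })
    spec.validate()
    return spec


def sample_parameters(priors: PriorSpec, n: int, seed: int,
                      base: ParameterSet | None = None) -> list[ParameterSet]:
    """Draw ``n`` independent parameter sets from the priors.

    Uniform on the stated scale (linear or log10-equivalent); fixed
    constants are taken from ``base``.  Reproducible under the seed.
    """
    priors.validate()
    base = base or ParameterSet()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        draws = {}
        for name in CALIBRATED_NAMES:
            lo, hi, scale = priors.bounds[name]
            u = rng.uniform()
            draws[name] = (lo * (hi / lo) ** u if scale == "log"
                           else lo + (hi - lo) * u)
        out.append(base.replace(**draws))
    return out


# ---------------------------------------------------------------------------
# Reduced regional simulator
# ---------------------------------------------------------------------------


@dataclass
class RegionalForcing:
    """Region-aggregated forcing: one virtual cell per coastal region."""

    time: np.ndarray
    sst: np.ndarray      # (ntime, nregion)
    npp: np.ndarray      # (ntime, nregion)
    area: np.ndarray     # (nregion,) m^2

    @property
    def n_regions(self) -> int:
        return len(self.area)


def regionalize(forcing: ForcingFields, regions: RegionMask) -> RegionalForcing:
    """Area-weighted mean SST/NPP per coastal region."""
    grid = forcing.grid
    nt = len(forcing.time)
    nr = regions.n_regions
    sst = np.empty((nt, nr))
    npp = np.empty((nt, nr))
    area = np.empty(nr)
    for r in range(1, nr + 1):
        m = regions.cells_of(r)
        w = grid.cell_area[m]
        area[r - 1] = w.sum()
        sst[:, r - 1] = (forcing.sst[:, m] * w).sum(axis=1) / w.sum()
        npp[:, r - 1] = (forcing.npp[:, m] * w).sum(axis=1) / w.sum()
    return RegionalForcing(time=np.asarray(forcing.time, float),
                           sst=sst, npp=npp, area=area)


def _regional_as_fields(rf: RegionalForcing) -> ForcingFields:
    """Wrap regional forcing as a 1-row pseudo-grid ForcingFields."""
    nr = rf.n_regions
    grid = Grid(
        resolution_deg=0.0,
        lat_centers=np.array([0.0]),
        lon_centers=np.arange(nr, dtype=float),
        cell_area=rf.area[None, :].copy(),
        ocean_mask=np.ones((1, nr), dtype=bool),
        coastal_mask=np.ones((1, nr), dtype=bool),
    )
    return ForcingFields(grid=grid, time=rf.time.copy(),
                         sst=rf.sst[:, None, :].copy(),
                         npp=rf.npp[:, None, :].copy())


def regional_series(rf: RegionalForcing, params: ParameterSet,
                    scenario: ScenarioSpec, axis: MassAxis | None = None,
                    spinup_tol: float = 1e-3, spinup_max_years: int = 300,
                    pre_years: int = 50):
    """Hindcast the reduced regional model.

    Mirrors the full hindcast protocol: pristine spin-up, ``pre_years`` of
    open access at constant start-year technology, then the transient.
    Returns ``(catch, biomass_fraction)`` with shape ``(ntime, nregion)``;
    catch is in g m^-2 yr^-1, numerically equal to t km^-2 yr^-1.
    """
    axis = axis or MassAxis.default()
    fields = _regional_as_fields(rf)
    npp_clim = rf.npp.mean(axis=0)
    sst_clim = rf.sst.mean(axis=0)
    B, tot = spinup_cells(npp_clim, sst_clim, params, axis,
                          tol=spinup_tol, max_years=spinup_max_years,
                          strict=False)
    state = CellEnsembleState(
        biomass=B, effort=np.full(rf.n_regions, params.effort_init),
        pristine=tot,
    )
    if pre_years > 0:
        from dataclasses import replace as _replace
        const_tech = ScenarioSpec(tech=_replace(scenario.tech, mode="constant"),
                                  price=scenario.price, cost=scenario.cost)
        pre_span = rf.time[0] - pre_years + np.arange(pre_years)
        _run_years(state, fields, params, const_tech, pre_span, axis)
    cells = _run_years(state, fields, params, scenario, rf.time, axis)
    return cells.harvest, cells.biomass_fraction


@dataclass
class CalibrationTarget:
    """Per-region summaries the calibration tries to match.

    ``peak_catch``: maximum annual catch density per region (t km^-2 yr^-1).
    ``late_biomass_fraction``: mean biomass fraction over the last decade.
    Optional ``weights`` (per region) default to 1.
    """

    peak_catch: np.ndarray
    late_biomass_fraction: np.ndarray
    weights: np.ndarray | None = None

    def validate(self) -> None:
        if not np.isfinite(self.peak_catch).any():
            raise CalibrationError("no region with finite target data")

    @classmethod
    def from_csv(cls, path) -> "CalibrationTarget":
        df = pd.read_csv(path).sort_values("region_id")
        return cls(peak_catch=df["peak_catch"].to_numpy(float),
                   late_biomass_fraction=df["late_biomass_fraction"].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "region_id": np.arange(1, len(self.peak_catch) + 1),
            "peak_catch": self.peak_catch,
            "late_biomass_fraction": self.late_biomass_fraction,
        }).to_csv(path, index=False)


def summarize_run(catch: np.ndarray, bfrac: np.ndarray,
                  late_years: int = 10) -> CalibrationTarget:
    """Reduce regional series to the two calibration summaries."""
    return CalibrationTarget(
        peak_catch=catch.max(axis=0),
        late_biomass_fraction=bfrac[-late_years:].mean(axis=0),
    )


def make_targets(rf: RegionalForcing, truth: ParameterSet,
                 scenario: ScenarioSpec, axis: MassAxis | None = None,
                 noise_sd: float = 0.0, seed: int = 0) -> CalibrationTarget:
    """Synthesize calibration targets from a run with known parameters.

    Optional multiplicative lognormal observation noise of sigma
    ``noise_sd`` is applied to both summaries.
    """
    catch, bfrac = regional_series(rf, truth, scenario, axis)
    tgt = summarize_run(catch, bfrac)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tgt = CalibrationTarget(
            peak_catch=tgt.peak_catch * rng.lognormal(0, noise_sd,
                                                      tgt.peak_catch.shape),
            late_biomass_fraction=np.clip(
                tgt.late_biomass_fraction
                * rng.lognormal(0, noise_sd, tgt.peak_catch.shape), 0, 1.05),
        )
    tgt.validate()
    return tgt


# ---------------------------------------------------------------------------
# Distance, acceptance, ensemble selection
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-6


def score_parameters(simulated: CalibrationTarget,
                     target: CalibrationTarget) -> float:
    """Weighted RMS of log-ratio misfits across regions and both summaries.

    Symmetric under sim/target exchange and under multiplicative error
    inversion (2x and 0.5x are equally wrong); zero iff the summaries match
    exactly.
    """
    w = (target.weights if target.weights is not None
         else np.ones_like(target.peak_catch))
    terms = []
    weights = []
    for sim, obs in ((simulated.peak_catch, target.peak_catch),
                     (simulated.late_biomass_fraction,
                      target.late_biomass_fraction)):
        sim = np.maximum(np.asarray(sim, float), _LOG_FLOOR)
        obs = np.maximum(np.asarray(obs, float), _LOG_FLOOR)
        ok = np.isfinite(obs)
        terms.append((np.log(sim[ok] / obs[ok])) ** 2)
        weights.append(np.broadcast_to(w, obs.shape)[ok])
    sq = np.concatenate(terms)
    ww = np.concatenate(weights)
    return float(np.sqrt((ww * sq).sum() / ww.sum()))


def abc_accept(samples: list, distances, quantile: float = 0.05):
    """Rejection step: keep draws with distance <= the given quantile.

    Returns ``(accepted_samples, accepted_distances, threshold)``.
    """
    distances = np.asarray(distances, dtype=float)
    if not 0 < quantile <= 1:
        raise CalibrationError("quantile must lie in (0, 1]")
    threshold = float(np.quantile(distances, quantile))
    keep = distances <= threshold
    return ([s for s, k in zip(samples, keep) if k], distances[keep], threshold)


@dataclass
class EnsembleResult:
    """Output of a calibration: accepted cloud and the spread-out ensemble."""

    accepted: list            # ParameterSet
    accepted_distances: np.ndarray
    selected: list            # ParameterSet, len k
    selected_distances: np.ndarray
    threshold: float
    priors: PriorSpec

    def accepted_frame(self) -> pd.DataFrame:
        rows = [p.calibrated_values() for p in self.accepted]
        df = pd.DataFrame(rows)
        df["distance"] = self.accepted_distances
        return df

    def selected_frame(self) -> pd.DataFrame:
        rows = [p.calibrated_values() for p in self.selected]
        df = pd.DataFrame(rows)
        df["distance"] = self.selected_distances
        return df


def select_ensemble(accepted: list, distances, priors: PriorSpec,
                    k: int = 5) -> EnsembleResult:
    """Greedy max-min pick of ``k`` members spanning the accepted cloud.

    Starts from the lowest-distance member; each subsequent pick maximizes
    the minimum Euclidean distance, in prior-normalized parameter space, to
    the members already selected.
    """
    distances = np.asarray(distances, dtype=float)
    if len(accepted) < k:
        raise CalibrationError(
            f"only {len(accepted)} accepted draws < ensemble size {k}; "
            "increase the number of samples or loosen the quantile"
        )
    X = np.stack([priors.normalize(p.calibrated_values()) for p in accepted])
    chosen = [int(np.argmin(distances))]
    while len(chosen) < k:
        d2 = np.min(
            ((X[:, None, :] - X[None, chosen, :]) ** 2).sum(axis=2), axis=1
        )
        d2[chosen] = -1.0
        chosen.append(int(np.argmax(d2)))
    return EnsembleResult(
        accepted=list(accepted),
        accepted_distances=distances,
        selected=[accepted[i] for i in chosen],
        selected_distances=distances[chosen],
        threshold=float(distances.max()),
        priors=priors,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def calibrate(rf: RegionalForcing, target: CalibrationTarget,
              priors: PriorSpec | None = None, n: int = 200,
              quantile: float = 0.05, k: int = 5, seed: int = 0,
              scenario: ScenarioSpec | None = None,
              axis: MassAxis | None = None,
              base: ParameterSet | None = None,
              progress: bool = False) -> EnsembleResult:
    """Run the Monte-Carlo rejection calibration end to end."""
    priors = priors or default_priors()
    scenario = scenario or ScenarioSpec()
    axis = axis or MassAxis.default()
    samples = sample_parameters(priors, n, seed, base=base)
    distances = np.empty(n)
    for i, p in enumerate(samples):
        try:
            catch, bfrac = regional_series(rf, p, scenario, axis)
            distances[i] = score_parameters(summarize_run(catch, bfrac), target)
        except RuntimeError:
            distances[i] = np.inf  # non-convergent draw: effectively rejected
        if progress and (i + 1) % 25 == 0:
            print(f"  scored {i + 1}/{n} draws")
    accepted, acc_d, threshold = abc_accept(samples, distances, quantile)
    result = select_ensemble(accepted, acc_d, priors, k=k)
    result.threshold = threshold
    return result


def recovery_test(truth: ParameterSet, priors: PriorSpec | None = None,
                  rf: RegionalForcing | None = None, n: int = 500,
                  seed: int = 0, quantile: float = 0.05,
                  scenario: ScenarioSpec | None = None,
                  axis: MassAxis | None = None) -> pd.DataFrame:
    """Self-calibration check: can ABC recover a known truth?

    Targets are generated noise-free from ``truth``; the full calibration is
    run; the report states, per parameter, the accepted min/max, whether
    truth lies inside that hull, and the accepted-range shrinkage relative
    to the prior (in normalized units).
    """
    priors = priors or default_priors()
    scenario = scenario or ScenarioSpec()
    if rf is None:
        from .forcing import ForcingSpec, generate_synthetic_forcing, \
            make_region_mask
        f = generate_synthetic_forcing(ForcingSpec(resolution_deg=8))
        rf = regionalize(f, make_region_mask(f.grid, 8))
    target = make_targets(rf, truth, scenario, axis)
    result = calibrate(rf, target, priors, n=n, quantile=quantile, seed=seed,
                       scenario=scenario, axis=axis, base=truth)
    acc = result.accepted_frame()
    rows = []
    tv = truth.calibrated_values()
    for name in CALIBRATED_NAMES:
        lo, hi, scale = priors.bounds[name]
        a = acc[name].to_numpy()
        if scale == "log":
            shrink = np.log(a.max() / a.min()) / np.log(hi / lo)
        else:
            shrink = (a.max() - a.min()) / (hi - lo)
        rows.append({
            "parameter": name,
            "truth": tv[name],
            "accepted_min": a.min(),
            "accepted_max": a.max(),
            "truth_in_hull": bool(a.min() <= tv[name] <= a.max()),
            "range_fraction_of_prior": float(shrink),
        })
    return pd.DataFrame(rows)
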