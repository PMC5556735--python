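"""Model parameters.

A single :class:`ParameterSet` carries both the ecological and the economic
slots of one ensemble member.  Thirteen of them (``CALIBRATED_NAMES``) are
treated as uncertain and estimated by rejection ABC against region-aggregated
catch and biomass; the remainder are fixed structural constants.

Units follow the internal convention: mass in grams wet weight, areal
densities per m^2, time in years, temperature in degrees Celsius, effort in
W m^-2, money in US dollars.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace, fields

__all__ = ["ParameterSet", "CALIBRATED_NAMES", "default_parameters"]

#: Names of the 13 slots estimated by the calibration module.
CALIBRATED_NAMES: tuple[str, ...] = (
    "epsilon_trophic",
    "ppmr",
    "growth_coef",
    "growth_exp",
    "mort_coef",
    "mort_exp",
    "activation_energy",
    "egg_survival",
    "recruitment_half_sat",
    "repro_frac_at_maturity",
    "q0",
    "fleet_response",
    "sel_mass_ratio",
)


@dataclass(frozen=True)
class ParameterSet:
    """One ensemble member: calibrated slots plus fixed constants.

    The defaults constitute the reference ("truth") member.  Ecological
    values follow standard metabolic and size-spectrum scaling; the economic
    scale (baseline catchability, cost per unit effort, fleet response) is
    anchored to 20th-century global fishery magnitudes — harvest of order
    10^2 Mt/yr, nominal effort of order 10 GW, ex-vessel price ~1 $/kg —
    with the cost anchor obtained from the open-access steady-state identity
    c = p*H/E.
    """

    # --- ecology (calibrated) -------------------------------------------
    epsilon_trophic: float = 0.10
    """Trophic transfer efficiency per trophic level (dimensionless)."""
    ppmr: float = 1000.0
    """Predator-prey mass ratio; sets trophic steps from phytoplankton."""
    growth_coef: float = 4.5
    """Allometric growth coefficient A, g^(1-b) yr^-1."""
    growth_exp: float = 0.7
    """Allometric growth exponent b (dimensionless, 0<b<1)."""
    mort_coef: float = 1.2
    """Natural mortality coefficient zeta, g^(1-h) yr^-1."""
    mort_exp: float = 0.55
    """Mortality mass exponent h (dimensionless, 0<h<1)."""
    activation_energy: float = 0.45
    """Arrhenius activation energy Ea (eV) shared by growth, mortality and
    trophic transfer."""
    egg_survival: float = 0.25
    """Fraction of reproductive biomass output surviving to recruitment size."""
    recruitment_half_sat: float = 0.005
    """Half-saturation of the egg-production flux in the Beverton-Holt
    recruitment, g m^-2 yr^-1."""
    repro_frac_at_maturity: float = 0.2
    """Asymptotic fraction of assimilated energy routed to reproduction."""

    # --- economics (calibrated) -----------------------------------------
    q0: float = 870.0
    """Baseline catchability at the technology-schedule origin,
    m^2 W^-1 yr^-1."""
    fleet_response: float = 0.10
    """Fleet responsiveness k_e (W $^-1): effort change per unit profit."""
    sel_mass_ratio: float = 0.05
    """Gear selectivity midpoint as a fraction of group asymptotic mass."""

    # --- fixed constants -------------------------------------------------
    T_ref: float = 10.0
    """Reference temperature for the Arrhenius factor, degC."""
    phyto_cell_mass: float = 1e-7
    """Effective phytoplankton cell mass m_p (g, ~100 pg nanophytoplankton)
    for the trophic-step count."""
    cost0: float = 8.0
    """Baseline cost per unit effort, $ W^-1 yr^-1."""
    price0: float = 1.0
    """Baseline ex-vessel price, $ kg^-1."""
    effort_floor: float = 1e-12
    """Minimal exploratory effort (W m^-2) allowing re-entry under open
    access."""
    effort_init: float = 1e-8
    """Initial nominal effort density for transient runs (W m^-2)."""
    wet_per_carbon: float = 10.0
    """Wet biomass per unit carbon biomass (g wet / g C)."""
    sel_width: float = 0.2
    """Selectivity logistic width in log10-mass units."""
    maturity_width: float = 0.2
    """Maturity-allocation logistic width in log10-mass units."""

    # ------------------------------------------------------------------
    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    def calibrated_values(self) -> dict:
        d = self.to_dict()
        return {k: d[k] for k in CALIBRATED_NAMES}

    def validate(self) -> None:
        p = self
        if not (0.0 < p.epsilon_trophic < 1.0):
            raise ValueError("epsilon_trophic must lie in (0, 1)")
        if not (0.0 < p.growth_exp < 1.0):
            raise ValueError("growth_exp must lie in (0, 1)")
        if not (0.0 < p.mort_exp < 1.0):
            raise ValueError("mort_exp must lie in (0, 1)")
        positive = (
            "ppmr", "growth_coef", "mort_coef", "egg_survival",
            "recruitment_half_sat", "repro_frac_at_maturity", "q0",
            "fleet_response", "sel_mass_ratio", "cost0", "price0",
            "phyto_cell_mass", "wet_per_carbon",
        )
        d = self.to_dict()
        for name in positive:
            if not d[name] > 0:
                raise ValueError(f"{name} must be positive, got {d[name]!r}")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


def default_parameters() -> ParameterSet:
    """Return the reference parameter set (validated)."""
    p = ParameterSet()
    p.validate()
    return p
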