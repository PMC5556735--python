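"""Fish size-spectrum dynamics for one (or many) ocean grid cells.

The fish community is represented as biomass density distributed across
individual body mass (10 g to 100 kg) for three groups distinguished by
asymptotic mass.  Energy produced by phytoplankton, attenuated by trophic
transfer losses, fuels somatic growth (advection towards larger mass),
reproduction, and recruitment at the small-mass boundary; allometric and
temperature-dependent rates follow standard metabolic scaling.

The governing equation per group is the size-spectrum continuity equation

    df/dt + d(gamma * f)/dm = -(Z_nat + F) * f

with f the biomass density in mass space, gamma the individual growth rate,
Z_nat natural mortality and F fishing mortality.  It is discretized with
first-order upwind fluxes on a logarithmic mass axis; mortality is applied
as an exact exponential within each substep, so biomass stays non-negative
for any admissible time step.

All stepping routines are vectorized over a leading "cell" axis; arrays are
shaped ``(ncell, ngroup, nbin)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "BOLTZMANN_EV",
    "MassAxis",
    "SpectrumState",
    "temperature_factor",
    "trophic_steps",
    "energy_input",
    "maturity_allocation",
    "growth_rate",
    "natural_mortality",
    "recruitment_flux",
    "step_ecology",
    "step_cells",
    "stable_dt",
    "spinup_pristine",
    "EcologyError",
]

BOLTZMANN_EV = 8.617e-5  # eV K^-1
_DAYS_PER_YEAR = 365.25


class EcologyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Mass axis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MassAxis:
    """Logarithmic mass grid shared by all groups.

    Bins span 10 g to 100 kg; each group only occupies bins up to its
    asymptotic mass (the ``active`` mask), and growth flux out of a group's
    largest active bin is lost (a sink).
    """

    bin_edges: np.ndarray        # (nbin+1,) g
    group_masses: np.ndarray     # (ngroup,) asymptotic masses, g

    @classmethod
    def default(cls, m_min: float = 10.0, m_max: float = 1e5, n_bins: int = 30,
                group_masses=(3e2, 1e4, 1e5)) -> "MassAxis":
        edges = np.logspace(np.log10(m_min), np.log10(m_max), n_bins + 1)
        return cls(bin_edges=edges, group_masses=np.asarray(group_masses, float))

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def n_groups(self) -> int:
        return len(self.group_masses)

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def m_min(self) -> float:
        return float(self.bin_edges[0])

    @property
    def active(self) -> np.ndarray:
        """(ngroup, nbin) bool: bins a group occupies (center <= m_asym)."""
        return self.centers[None, :] <= self.group_masses[:, None] * (1 + 1e-12)


@dataclass
class SpectrumState:
    """Biomass spectrum of one cell: (ngroup, nbin) g m^-2 per bin."""

    biomass: np.ndarray
    pristine_biomass: float = np.nan  # scalar total, set after spin-up

    @property
    def total(self) -> float:
        return float(self.biomass.sum())

    def copy(self) -> "SpectrumState":
        return SpectrumState(self.biomass.copy(), self.pristine_biomass)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------


def temperature_factor(T, Ea: float, T_ref: float):
    """Arrhenius factor exp(-Ea/kB * (1/T - 1/T_ref)), temperatures in degC.

    Equals 1 at ``T_ref`` and increases with temperature for Ea > 0.
    """
    T = np.asarray(T, dtype=float)
    return np.exp(-Ea / BOLTZMANN_EV * (1.0 / (T + 273.15) - 1.0 / (T_ref + 273.15)))


def trophic_steps(p: ParameterSet, m_min: float = 10.0) -> float:
    """Number of predator-prey steps from phytoplankton to the smallest fish."""
    return float(np.log(m_min / p.phyto_cell_mass) / np.log(p.ppmr))


def energy_input(npp, T, p: ParameterSet, m_min: float = 10.0):
    """Energy flux entering the fish community, g wet m^-2 yr^-1.

    NPP (mmol C m^-2 d^-1) is converted to wet-biomass production and
    attenuated through ``n`` trophic steps with efficiency epsilon_trophic
    per step, divided by the overall metabolic temperature factor: warmer
    water dissipates more of the production before it reaches fish.
    Linear in NPP.
    """
    npp = np.asarray(npp, dtype=float)
    converted = npp * (12.011e-3) * p.wet_per_carbon * _DAYS_PER_YEAR
    n = trophic_steps(p, m_min)
    tf = temperature_factor(T, p.activation_energy, p.T_ref)
    return converted * p.epsilon_trophic**n / tf


def maturity_allocation(m, m_asym, p: ParameterSet):
    """Fraction psi(m) of assimilated energy routed to reproduction.

    Logistic ramp in log10 mass, centered at one quarter of the group's
    asymptotic mass, saturating at ``repro_frac_at_maturity``.
    """
    m = np.asarray(m, dtype=float)
    x = (np.log10(m) - np.log10(0.25 * np.asarray(m_asym, float))) / p.maturity_width
    return p.repro_frac_at_maturity / (1.0 + np.exp(-x))


def growth_rate(m, T, p: ParameterSet, food_limitation=1.0, m_asym=None):
    """Individual somatic growth rate gamma, g yr^-1.

    gamma = A * tf(T) * m^b * food * (1 - psi(m)); the maturity allocation
    psi only ever reduces growth.  ``food_limitation`` in [0, 1] is the
    ratio of available energy input to unconstrained community demand.
    """
    m = np.asarray(m, dtype=float)
    tf = temperature_factor(T, p.activation_energy, p.T_ref)
    psi = 0.0 if m_asym is None else maturity_allocation(m, m_asym, p)
    return p.growth_coef * tf * m**p.growth_exp * food_limitation * (1.0 - psi)


def natural_mortality(m, T, p: ParameterSet):
    """Allometric natural mortality Z_nat = zeta * tf(T) * m^(h-1), yr^-1."""
    m = np.asarray(m, dtype=float)
    tf = temperature_factor(T, p.activation_energy, p.T_ref)
    return p.mort_coef * tf * m ** (p.mort_exp - 1.0)


# ---------------------------------------------------------------------------
# Vectorized stepping core
# ---------------------------------------------------------------------------


class _StepWork:
    """Precomputed per-(axis, params) quantities reused every substep."""

    def __init__(self, axis: MassAxis, p: ParameterSet):
        self.axis = axis
        self.p = p
        mc = axis.centers
        self.active = axis.active                      # (ng, nb)
        self.psi = (maturity_allocation(mc[None, :], axis.group_masses[:, None], p)
                    * self.active)
        self.m_pow_b = mc**p.growth_exp                # (nb,)
        self.m_pow_bm1 = mc ** (p.growth_exp - 1.0)
        self.m_pow_hm1 = mc ** (p.mort_exp - 1.0)
        self.widths = axis.widths
        # constants for the fused kernel path
        self.eps_pow_n = float(p.epsilon_trophic ** trophic_steps(p, axis.m_min))
        self.conv = float(12.011e-3 * p.wet_per_carbon * _DAYS_PER_YEAR)


def _rates(work: _StepWork, B, npp, T):
    """Common rate fields; returns dict of arrays broadcast to B's shape."""
    p = work.p
    tf = temperature_factor(T, p.activation_energy, p.T_ref)  # (nc,)
    tf3 = tf[:, None, None]
    einput = energy_input(npp, T, p, work.axis.m_min)          # (nc,)

    # unconstrained assimilation demand, g m^-2 yr^-1
    per_mass = p.growth_coef * tf3 * work.m_pow_bm1[None, None, :] * work.active
    demand = (per_mass * B).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        food = np.where(demand > 0, np.minimum(1.0, einput / np.maximum(demand, 1e-300)), 1.0)

    gamma = (p.growth_coef * tf3 * work.m_pow_b[None, None, :]
             * food[:, None, None] * (1.0 - work.psi)[None] * work.active[None])
    z_nat = p.mort_coef * tf3 * work.m_pow_hm1[None, None, :]

    # reproductive output flux per group, g m^-2 yr^-1
    repro = (work.psi[None] * per_mass * B * food[:, None, None]).sum(axis=2)
    egg = p.egg_survival * repro                                # (nc, ng)
    r_sat = einput[:, None] / work.axis.n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        recruit = np.where(egg > 0,
                           r_sat * egg / (egg + p.recruitment_half_sat), 0.0)
    return dict(tf=tf, einput=einput, food=food, gamma=gamma, z_nat=z_nat,
                recruit=recruit)


def step_cells(B, npp, T, F, p: ParameterSet, axis: MassAxis, dt: float,
               work: _StepWork | None = None, impl: str = "auto"):
    """Advance the biomass spectra of many cells by one substep.

    Parameters
    ----------
    B : (ncell, ngroup, nbin) biomass per bin, g m^-2
    npp, T : (ncell,) forcing
    F : fishing mortality, yr^-1, broadcastable to B's shape
    dt : substep, years (caller must respect :func:`stable_dt`)
    impl : "auto" uses the fused numba kernel when available; "numpy"
        forces the reference implementation.

    Returns ``(B_new, diag)`` with ``diag`` holding per-cell harvested
    biomass over the step (g m^-2), the discrete mass-budget residual
    terms, and the food limitation factor.
    """
    if work is None:
        work = _StepWork(axis, p)
    B = np.asarray(B, dtype=float)
    npp = np.atleast_1d(np.asarray(npp, dtype=float))
    T = np.atleast_1d(np.asarray(T, dtype=float))
    F = np.broadcast_to(np.asarray(F, dtype=float), B.shape)

    if impl == "auto" and _HAVE_KERNEL:
        return _step_cells_kernel(work, B, npp, T, F, dt)

    r = _rates(work, B, npp, T)
    gamma, z_nat, recruit = r["gamma"], r["z_nat"], r["recruit"]

    # upwind advective flux through bin upper edges (biomass form):
    # f = B / width; flux_out_i = gamma_i * f_i
    flux = gamma * B / work.widths[None, None, :]
    flux = flux * work.active[None]          # no flux from inactive bins
    influx = np.zeros_like(flux)
    influx[..., 1:] = flux[..., :-1]
    influx *= work.active[None]              # flux past a group's top bin is lost
    top_loss = flux.sum(axis=2) - (influx.sum(axis=2))  # (nc, ng) g m^-2 yr^-1

    B_adv = B + dt * (influx - flux)
    B_adv[..., 0] += dt * recruit * work.active[None][..., 0]
    # guard tiny negative round-off from the explicit advection
    np.clip(B_adv, 0.0, None, out=B_adv)

    # mortality: exact exponential split
    z_tot = (z_nat + F) * work.active[None]
    decay = np.exp(-z_tot * dt)
    B_new = B_adv * decay
    died = B_adv * (1.0 - decay)
    with np.errstate(divide="ignore", invalid="ignore"):
        fshare = np.where(z_tot > 0, F / np.maximum(z_tot, 1e-300), 0.0)
    harvested = (died * fshare).sum(axis=(1, 2))          # (nc,) g m^-2

    diag = {
        "harvest": harvested,
        "died_total": died.sum(axis=(1, 2)),
        "recruit_total": (recruit * work.active[:, 0][None]).sum(axis=1) * dt,
        "top_loss": top_loss.sum(axis=1) * dt,
        "food": r["food"],
        "einput": r["einput"],
    }
    return B_new, diag


try:
    from ._kernels import HAVE_NUMBA as _HAVE_KERNEL, substep_kernel
except Exception:  # pragma: no cover
    _HAVE_KERNEL = False


def _step_cells_kernel(work: _StepWork, B, npp, T, F, dt: float):
    """Fused-kernel path; numerically equivalent to the numpy reference."""
    p = work.p
    nc = B.shape[0]
    B = np.ascontiguousarray(B)
    F = np.ascontiguousarray(F)
    B_out = np.empty_like(B)
    harvest = np.empty(nc)
    died_tot = np.empty(nc)
    recruit_tot = np.empty(nc)
    top_loss = np.empty(nc)
    food = np.empty(nc)
    substep_kernel(
        B, np.ascontiguousarray(npp), np.ascontiguousarray(T), F, dt,
        work.widths, work.active, work.psi, work.m_pow_b, work.m_pow_bm1,
        work.m_pow_hm1, work.eps_pow_n, work.conv, p.growth_coef,
        p.mort_coef, p.egg_survival, p.recruitment_half_sat,
        p.activation_energy / BOLTZMANN_EV, p.T_ref + 273.15,
        B_out, harvest, died_tot, recruit_tot, top_loss, food,
    )
    diag = {
        "harvest": harvest,
        "died_total": died_tot,
        "recruit_total": recruit_tot,
        "top_loss": top_loss,
        "food": food,
        "einput": energy_input(npp, T, p, work.axis.m_min),
    }
    return B_out, diag


def stable_dt(p: ParameterSet, axis: MassAxis, T_max: float,
              cfl: float = 0.8, dt_max: float = 0.25) -> float:
    """Largest admissible substep: dt <= cfl * min(bin width / max growth).

    Uses the unfished, food-replete growth rate at the warmest temperature,
    which bounds gamma from above.
    """
    tf = float(temperature_factor(T_max, p.activation_energy, p.T_ref))
    gamma_max = p.growth_coef * tf * axis.centers**p.growth_exp
    dt = cfl * float(np.min(axis.widths / gamma_max))
    return min(dt, dt_max)


def step_ecology(state: SpectrumState, forcing_cell: dict, fishing_mortality,
                 dt: float, p: ParameterSet,
                 axis: MassAxis | None = None) -> SpectrumState:
    """Advance one cell's spectrum by ``dt`` years (convenience wrapper).

    ``forcing_cell`` is a mapping with keys ``npp`` (mmol C m^-2 d^-1) and
    ``sst`` (degC).  Raises :class:`EcologyError` if ``dt`` exceeds the
    CFL-style stability limit, naming the limiting bin.
    """
    axis = axis or MassAxis.default()
    T = float(forcing_cell["sst"])
    npp = float(forcing_cell["npp"])
    tf = float(temperature_factor(T, p.activation_energy, p.T_ref))
    gamma_max = p.growth_coef * tf * axis.centers**p.growth_exp
    limits = axis.widths / gamma_max
    i_lim = int(np.argmin(limits))
    if dt > 0.8 * limits[i_lim] * (1 + 1e-9):
        raise EcologyError(
            f"dt={dt:g} yr exceeds stability limit {0.8 * limits[i_lim]:g} yr "
            f"set by mass bin {i_lim} (center {axis.centers[i_lim]:.3g} g)"
        )
    F = np.broadcast_to(np.asarray(fishing_mortality, dtype=float),
                        (axis.n_groups, axis.n_bins))
    B, _ = step_cells(state.biomass[None], [npp], [T], F[None], p, axis, dt)
    return SpectrumState(B[0], state.pristine_biomass)


# ---------------------------------------------------------------------------
# Spin-up
# ---------------------------------------------------------------------------


def _seed_biomass(axis: MassAxis, level: float = 1e-3) -> np.ndarray:
    """Small uniform seed spectrum; recruitment needs standing stock to start."""
    return np.where(axis.active, level, 0.0)


def spinup_cells(npp, T, p: ParameterSet, axis: MassAxis,
                 tol: float = 1e-3, max_years: int = 1000,
                 B0: np.ndarray | None = None, strict: bool = True):
    """Integrate many cells to the unfished (pristine) equilibrium.

    Convergence: relative change of each cell's total biomass per decade
    below ``tol`` (cells with vanishing biomass count as converged).
    Returns ``(B, total)``.  Raises on non-convergence.
    """
    npp = np.atleast_1d(np.asarray(npp, dtype=float))
    T = np.atleast_1d(np.asarray(T, dtype=float))
    nc = len(npp)
    work = _StepWork(axis, p)
    if B0 is None:
        B = np.broadcast_to(_seed_biomass(axis)[None], (nc, axis.n_groups, axis.n_bins)).copy()
    else:
        B = np.asarray(B0, dtype=float).copy()
    dt = stable_dt(p, axis, float(np.max(T)))
    nsub = int(np.ceil(1.0 / dt))
    dt = 1.0 / nsub
    F = np.zeros((1, 1, 1))
    prev = B.sum(axis=(1, 2))
    residual = np.inf
    # converged cells are frozen and dropped from the stepped set, so late
    # decades only integrate the slowest (cold, multi-generation) cells
    open_idx = np.arange(nc)
    for decade_start in range(0, max_years, 10):
        Bsub = B[open_idx]
        npps, Ts = npp[open_idx], T[open_idx]
        for _ in range(10 * nsub):
            Bsub, _d = step_cells(Bsub, npps, Ts, F, p, axis, dt, work)
        B[open_idx] = Bsub
        tot = B.sum(axis=(1, 2))
        scale = np.maximum(prev, 1e-12)
        # cells below 1e-6 g m^-2 are biologically extinct: converged
        cell_res = np.abs(tot - prev) / scale * (tot > 1e-6)
        residual = float(np.max(cell_res))
        if residual < tol:
            return B, tot
        prev = tot
        open_idx = np.nonzero(cell_res >= tol)[0]
    if not strict:
        return B, prev
    raise EcologyError(
        f"spin-up did not converge within {max_years} years "
        f"(residual per decade {residual:.3g} > tol {tol:g})"
    )


def spinup_pristine(forcing_cell: dict, p: ParameterSet,
                    tol: float = 1e-3, axis: MassAxis | None = None,
                    max_years: int = 1000) -> SpectrumState:
    """Spin one cell to its pristine equilibrium under constant forcing.

    Records the pristine total biomass on the returned state; used as the
    reference for biomass-fraction diagnostics.
    """
    axis = axis or MassAxis.default()
    B, tot = spinup_cells([float(forcing_cell["npp"])], [float(forcing_cell["sst"])],
                          p, axis, tol=tol, max_years=max_years)
    return SpectrumState(B[0], pristine_biomass=float(tot[0]))


def recruitment_flux(state: SpectrumState, T, p: ParameterSet,
                     npp, axis: MassAxis | None = None) -> np.ndarray:
    """Beverton-Holt recruitment into the smallest bin, g m^-2 yr^-1 per group.

    Egg production e = egg_survival * (reproductive allocation summed over
    the group's spectrum); recruitment R = R_sat * e / (e + K) with the
    saturating flux R_sat given by the cell's energy input split equally
    among groups.
    """
    axis = axis or MassAxis.default()
    work = _StepWork(axis, p)
    r = _rates(work, state.biomass[None], np.atleast_1d(float(npp)),
               np.atleast_1d(float(T)))
    return r["recruit"][0]
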