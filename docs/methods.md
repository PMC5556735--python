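# Methods

`blueharvest` simulates the long-term, global-scale interaction between
marine fish communities and the industrial fisheries that exploit them.
Each ocean grid cell carries a fish size spectrum driven by temperature and
net primary production, coupled to an open-access economic model of fishing
effort; the only links between cells are the globally uniform economic
drivers (catchability, ex-vessel price, cost per unit effort).

## Ecology: the size spectrum

The fish community in a cell is biomass density `f(m)` distributed over
individual body mass `m` from 10 g to 100 kg, for three groups with
asymptotic masses 300 g, 10 kg and 100 kg (small pelagics, demersal-type
mid-size fish, large predators).  Each group obeys the continuity equation

    df/dt + d(gamma f)/dm = -(Z_nat + F) f

with growth `gamma = A * c_T(T) * m^b * phi * (1 - psi(m))`, natural
mortality `Z_nat = zeta * c_T(T) * m^(h-1)`, and fishing mortality
`F = q E s(m)`.  Here

* `c_T(T) = exp(-Ea/kB (1/T - 1/T_ref))` is the Arrhenius factor
  (default `Ea = 0.45 eV`, `T_ref = 10 C`);
* `psi(m)` is a logistic maturity allocation in log10 mass, centered at a
  quarter of the group's asymptotic mass with width 0.2 decades, saturating
  at `repro_frac_at_maturity` (default 0.2);
* `phi` is the food limitation: the ratio of the cell's energy input to the
  community's unconstrained assimilation demand, capped at 1, recomputed
  quasi-statically every substep so that community production can never
  exceed the energy supplied by primary production.

Energy input converts NPP (mmol C m^-2 d^-1) to wet-mass production
(12.011 mg C per mmol, 10 g wet per g C) and attenuates it through
`n = log(m_min/m_p)/log(ppmr)` trophic steps at efficiency
`epsilon_trophic` per step, divided once by `c_T(T)`: warm water dissipates
more energy below the fish size range, so equal NPP supports less fish
production in the tropics than at high latitudes.  With the defaults
(`epsilon_trophic = 0.10`, `ppmr = 1000`, `m_p = 1e-7 g`, i.e. a ~100 pg
nanophytoplankton), `n ~ 2.7` and roughly 0.1% of NPP reaches the community,
giving a global pristine fish biomass of ~2 Gt and a global MSY near
150 Mt/yr — the observed orders of magnitude.

Recruitment into the smallest bin follows a saturating (Beverton-Holt)
law: egg production `e = s_egg *` (reproductive allocation summed over the
group's spectrum), recruitment `R = R_sat e / (e + K)`.  The asymptote
`R_sat` is the cell's energy input divided equally among groups, so
recruitment is bounded by the energy the ecosystem can supply; `K`
(default 0.005 g m^-2 yr^-1) sets where density dependence releases.  Under
intense harvesting the mature stock, and hence `e`, collapses below `K` and
recruitment fails — this spawning-stock limitation is what creates a finite
maximum sustainable yield.

### Numerics

First-order upwind fluxes on a 30-bin logarithmic mass axis advect biomass
towards large sizes; growth out of a group's largest active bin is lost.
The advection-plus-recruitment update is explicit with a CFL-style limit
`dt <= 0.8 min(dm/gamma)` evaluated for food-replete growth at the warmest
cell (typically ~1/30 yr); mortality is applied as an exact exponential
within the substep (operator splitting), so biomass remains non-negative
for any admissible `dt` and arbitrary fishing intensity.  The discrete
total-biomass budget (recruitment in, deaths and top-of-spectrum loss out)
closes to round-off; a test asserts 1e-8 relative closure per step.

The same substep is implemented twice: a vectorized numpy reference and a
fused numba kernel used by default (a test asserts agreement to machine
precision).  All cells are stepped together as `(cell, group, bin)` arrays.

Spin-up to the pristine (unfished) equilibrium integrates with F = 0 from a
small seed spectrum until the relative change of each cell's total biomass
per decade falls below `tol` (default 1e-3, leaving ~1% amplitude error;
cold high-latitude cells have multi-generation slow modes and gate the
convergence, so converged cells are frozen and dropped from the stepped
set).  Cells below 1e-6 g m^-2 are treated as extinct.  Zero-biomass is an
absorbing state of the recruitment law, hence the seed.

## Economics: open access

Nominal fishing effort density `E` (W m^-2) in each cell evolves with local
profit,

    dE/dt = k_e (p h / 1000 - c E),

the classic open-access response: effort enters profitable cells and exits
loss-making ones at a rate set by the fleet responsiveness `k_e`
(default 0.10 W/$; with `c = 8 $ W^-1 yr^-1` this is a fleet adjustment
timescale of ~1.3 yr).  `p` is the ex-vessel price ($/kg; the 1/1000
converts to $/g), `h` the harvest flux, `c` the cost per unit effort.
Effort is floored at 1e-12 W m^-2 so that cells abandoned as unprofitable
can be re-entered when technology improves — this drives the offshore
expansion of the simulated fishery.  Transient runs start from
1e-8 W m^-2, a few-MW exploratory global fleet.

Harvest is `h = sum(q E s(m) f(m))` with logistic size selectivity `s(m)`
centered at `sel_mass_ratio` (default 0.05) times the group's asymptotic
mass — fisheries catch fish well below their asymptotic size, which is why
heavy fishing erodes the spawning stock.  Technology acts only through the
catchability `q`: scenario schedules hold it constant, compound it
exponentially (2, 5 or 8 %/yr), or ramp its growth rate linearly to zero
between 2006 and 2036 ("stabilizing").  Price is constant, linear
(1 -> 3 $/kg over 2006-2100), or tabulated; cost is constant or tabulated,
with `cost_from_steady_state` implementing the zero-profit identity
`c = p H / E` used to anchor the historical cost level from observed
price, harvest and effort magnitudes.

The default ("reference" or "truth") economic constants are anchored to
20th-century global observations: ex-vessel price ~1 $/kg, peak harvest of
order 100 Mt/yr and nominal effort of order 10 GW, which the zero-profit
identity turns into `c ~ 8 $ W^-1 yr^-1`; the baseline catchability
`q0 = 870 m^2 W^-1 yr^-1` places the 1950 bionomic threshold inside the
productive coastal band so that mid-century fishing is coastal and the
open ocean only becomes profitable as technology compounds.

## Experiments

* **Hindcast** (1950-2006, extendable): pristine spin-up, then 50 years of
  open access at constant start-year technology (so 1950 starts at its
  contemporary bionomic quasi-equilibrium rather than with an undeveloped
  fishery), then the transient under 5 %/yr technology growth with constant
  price and cost.  Per year the operation order is fixed: ecology substeps,
  harvest accumulation, forward-Euler effort update per substep.
* **Projection** (2006-2100): continues the hindcast end state under
  {continued 5 %/yr, stabilizing technology} x {constant, linearly rising
  price}.
* **MSY**: effort dynamics are bypassed — the nominal effort field is held
  fixed at 1e-5 W m^-2 while catchability ramps slowly (2 %/yr over 300
  years from F ~ 0.005/yr), so each cell traverses the full range of
  fishing mortality quasi-statically.  The sustainable yield at the current
  stock is estimated as harvest plus the biomass tendency (the tendency
  vanishes at equilibrium, and subtracting it removes the transient
  stock-mining contribution, verified within 5% against brute-force
  constant-F equilibrium yields); the global MSY is the area-weighted sum
  of per-cell maxima.  MSY is independent of price and cost by
  construction, and depends only on the climate state supplied (a
  climatology, or a chosen year of a trended forcing).

## Synthetic forcing and what it does (not) represent

The built-in generator produces an idealized Earth: exact spherical cell
areas, a two-continent land template (ocean fraction ~0.75), SST =
`-1 + 29 cos^2(lat)` degC, and two-band NPP (70 mmol C m^-2 d^-1 on the
coastal band within 8 degrees of land, 25 offshore) modulated by
`0.45 + 0.7 cos(lat)` (unit global mean), giving ~4e15 mol C/yr of ocean
production — the observed global total.  Optional linear trends emulate
climate change: the historical signal is +0.6 degC and -5% NPP per century;
interannual lognormal noise is optional.  Coastal cells partition into
contiguous latitude blocks per coastline to form the regional aggregation
units used for calibration.

This idealization preserves what the model needs — a coastal/open-ocean
productivity contrast, a latitudinal temperature gradient, realistic global
totals — but has no real coastlines, boundary currents, upwelling systems,
seasonality or ENSO-like variability.  Passing tests therefore demonstrate
the mechanisms (technology-driven rise and peak, offshore expansion,
sequential depletion, climate sensitivity of MSY), not a reproduction of
any observed regional dataset.

## Calibration

Thirteen parameters (ecology: epsilon_trophic, ppmr, A, b, zeta, h, Ea,
s_egg, K, repro fraction; economics: q0, k_e, sel_mass_ratio) are drawn
from independent uniform priors (log scale where the parameter spans a
multiplicative range).  Each draw runs the hindcast on a reduced
representation — each coastal region becomes one virtual cell with its
area-mean forcing — and is scored by the root-mean-square log-ratio misfit
of two summaries per region: peak annual catch density and mean biomass
fraction over the last decade.  Draws below a distance quantile are accepted
(rejection ABC; the operation defaults to the 5% quantile, while the
headline pipeline uses 2% of 300 draws so that accepted solutions stay
within ~factor-1.6 regional misfits — "reasonably accurate" rather than
merely better-than-typical); a 5-member ensemble is then chosen by greedy
max-min selection in prior-normalized space, starting from the
best-scoring member — spanning the accepted cloud as widely as possible
while staying consistent with the targets.  Non-convergent draws score
infinite distance and are rejected naturally.

Because no observed regional catch/biomass data ship with the package,
targets are synthesized from a run with the known reference parameters
(users with real data can supply targets as CSV).  `recovery_test` runs
this loop end to end and reports, per parameter, whether the truth lies in
the accepted hull and how much the accepted range shrank relative to the
prior; energy-scale parameters (epsilon_trophic, q0) are well identified,
while exponents (b, h) remain prior-dominated — as expected when the
summaries constrain mostly the overall production and exploitation scales.

## Problem sizes

Default desk-scale settings: 8-degree grid (~700 ocean cells), 30 mass
bins x 3 groups, ~30 substeps per year, 12 calibration regions, 300
Monte-Carlo draws.  With these the full acceptance pipeline (calibration,
5-member hindcasts and MSY ramps) completes in a few minutes on one core.
Finer grids (down to 1 degree) and larger ensembles only change cost, not
code paths.

## Known limitations

* No movement of fish or vessels between cells; spatial expansion emerges
  purely from profitability, without distance-to-port costs.
* One activation energy governs growth, mortality and trophic transfer.
* Annual forcing; no seasonality or interannual climate modes beyond
  optional white noise.
* The biomass spectrum advects conservatively (growth moves biomass, the
  only sources/sinks are recruitment, mortality and the top-of-spectrum
  loss), a deliberate simplification that makes the budget exactly
  closable.
* Open access is the only management regime; MSY is an upper bound, not a
  policy simulation.
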