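"""Gridded climate boundary conditions: SST and net primary production.

The simulator is driven by annual-mean sea-surface temperature (degC) and
vertically integrated net primary production (mmol C m^-2 d^-1) on a regular
latitude-longitude grid.  Real forcing can be read from CF-style NetCDF;
the built-in generator produces an idealized Earth-like planet — a
latitudinal SST gradient, coastally enhanced NPP with realistic global
totals, and optional linear warming / NPP-decline trends emulating a
high-emissions climate trajectory.

Land is an idealized two-continent template (no real coastlines); the
coastal / open-ocean distinction it induces is what the economics of
spatial fishery expansion acts on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "EARTH_RADIUS_M",
    "GC_PER_MMOLC",
    "Grid",
    "ForcingSpec",
    "ForcingFields",
    "RegionMask",
    "make_grid",
    "generate_synthetic_forcing",
    "save_forcing",
    "load_forcing",
    "make_region_mask",
]

EARTH_RADIUS_M = 6_371_000.0
#: grams of carbon per mmol of carbon
GC_PER_MMOLC = 12.011e-3

_VALID_RESOLUTIONS = (1, 2, 4, 8)

# Idealized two-continent land template, degrees east / north.
# (lon_min, lon_max, lat_min, lat_max)
_CONTINENTS = (
    (-80.0, -30.0, -60.0, 75.0),
    (30.0, 75.0, -45.0, 70.0),
)
_POLAR_CAP_SOUTH = -78.0  # land poleward of this southern latitude

#: half-width (degrees) of the coastal band adjacent to land
COASTAL_BAND_DEG = 8.0


class ForcingError(ValueError):
    """Raised for invalid forcing configuration or unreadable files."""


@dataclass(frozen=True)
class Grid:
    """Regular lat-lon grid with spherical cell areas and a land template.

    Arrays are 2-D ``(nlat, nlon)`` except the coordinate vectors.
    """

    resolution_deg: float
    lat_centers: np.ndarray  # (nlat,) degrees north
    lon_centers: np.ndarray  # (nlon,) degrees east
    cell_area: np.ndarray    # (nlat, nlon) m^2
    ocean_mask: np.ndarray   # (nlat, nlon) bool
    coastal_mask: np.ndarray  # (nlat, nlon) bool, subset of ocean_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_area.shape

    @property
    def ocean_area(self) -> float:
        return float(self.cell_area[self.ocean_mask].sum())

    @property
    def ocean_fraction(self) -> float:
        return self.ocean_area / float(self.cell_area.sum())

    def depth_class(self) -> np.ndarray:
        """Return string array: 'land', 'coastal' or 'open-ocean'."""
        out = np.full(self.shape, "land", dtype=object)
        out[self.ocean_mask] = "open-ocean"
        out[self.coastal_mask] = "coastal"
        return out


def make_grid(resolution_deg: int | float) -> Grid:
    """Build the global grid at one of the supported resolutions.

    Cell areas follow spherical geometry (proportional to cos latitude) and
    sum to the sphere area 4*pi*R^2 to well within 0.1%.  The land layout is
    a fixed built-in template, so ocean fraction is nearly invariant across
    resolutions.
    """
    if resolution_deg not in _VALID_RESOLUTIONS:
        raise ForcingError(
            f"resolution must be one of {_VALID_RESOLUTIONS} degrees, "
            f"got {resolution_deg!r}"
        )
    res = float(resolution_deg)
    nlat = int(round(180.0 / res))
    nlon = int(round(360.0 / res))
    lat_edges = np.linspace(-90.0, 90.0, nlat + 1)
    lat_centers = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon_centers = -180.0 + res * (np.arange(nlon) + 0.5)

    # exact spherical band areas: 2*pi*R^2*(sin(top)-sin(bot)) / nlon
    band = (
        2.0 * np.pi * EARTH_RADIUS_M**2
        * (np.sin(np.deg2rad(lat_edges[1:])) - np.sin(np.deg2rad(lat_edges[:-1])))
    )
    cell_area = np.repeat((band / nlon)[:, None], nlon, axis=1)

    lat2 = lat_centers[:, None]
    lon2 = lon_centers[None, :]
    land = np.zeros((nlat, nlon), dtype=bool)
    for lon0, lon1, lat0, lat1 in _CONTINENTS:
        land |= (lon2 >= lon0) & (lon2 <= lon1) & (lat2 >= lat0) & (lat2 <= lat1)
    land |= lat2 <= _POLAR_CAP_SOUTH
    ocean = ~land

    coastal = _coastal_from_land(land, lat_centers, lon_centers)
    return Grid(
        resolution_deg=res,
        lat_centers=lat_centers,
        lon_centers=lon_centers,
        cell_area=cell_area,
        ocean_mask=ocean,
        coastal_mask=coastal & ocean,
    )


def _coastal_from_land(
    land: np.ndarray, lat_centers: np.ndarray, lon_centers: np.ndarray
) -> np.ndarray:
    """Ocean cells within COASTAL_BAND_DEG of land (Chebyshev, lon wraps)."""
    res = abs(lat_centers[1] - lat_centers[0])
    halo = max(1, int(round(COASTAL_BAND_DEG / res)))
    near = land.copy()
    for _ in range(halo):
        grown = near.copy()
        grown[1:, :] |= near[:-1, :]
        grown[:-1, :] |= near[1:, :]
        grown |= np.roll(near, 1, axis=1)
        grown |= np.roll(near, -1, axis=1)
        near = grown
    return near & ~land


@dataclass(frozen=True)
class ForcingSpec:
    """Configuration of the synthetic-forcing generator.

    Trends are linear over the run: ``warming_trend`` in degC per century,
    ``npp_trend`` in percent per century (negative for decline).  ``noise_sd``
    is the lognormal sigma of multiplicative interannual NPP noise; SST
    receives additive Gaussian noise with standard deviation
    ``noise_sd * (sst_equator - sst_pole) / 10`` degC.
    """

    resolution_deg: int = 4
    base_year: int = 1950
    end_year: int = 2006
    sst_equator: float = 28.0
    sst_pole: float = -1.0
    npp_open: float = 25.0      # mmol C m^-2 d^-1
    npp_coastal: float = 70.0   # mmol C m^-2 d^-1
    warming_trend: float = 0.0  # degC per century
    npp_trend: float = 0.0      # % per century
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.resolution_deg not in _VALID_RESOLUTIONS:
            raise ForcingError(f"invalid resolution {self.resolution_deg!r}")
        if not self.end_year > self.base_year:
            raise ForcingError("end_year must exceed base_year")
        if self.noise_sd < 0:
            raise ForcingError("noise_sd must be non-negative")
        if self.npp_open < 0 or self.npp_coastal < 0:
            raise ForcingError("NPP levels must be non-negative")


@dataclass
class ForcingFields:
    """Annual gridded forcing: the climate boundary condition.

    ``sst`` and ``npp`` have shape ``(ntime, nlat, nlon)`` and are NaN over
    land.
    """

    grid: Grid
    time: np.ndarray  # (ntime,) years CE
    sst: np.ndarray   # degC
    npp: np.ndarray   # mmol C m^-2 d^-1

    def validate(self) -> None:
        t = np.asarray(self.time)
        if t.ndim != 1 or len(t) < 1:
            raise ForcingError("time must be a non-empty 1-D array")
        if len(t) > 1:
            dt = np.diff(t)
            if not np.all(dt > 0):
                raise ForcingError("time must be strictly increasing")
            if not np.allclose(dt, dt[0]):
                raise ForcingError("time must have uniform annual spacing")
        ocean = self.grid.ocean_mask
        for name, arr in (("sst", self.sst), ("npp", self.npp)):
            if arr.shape != (len(t), *self.grid.shape):
                raise ForcingError(f"{name} has shape {arr.shape}, expected "
                                   f"{(len(t), *self.grid.shape)}")
            sub = arr[:, ocean]
            if np.isnan(sub).any():
                raise ForcingError(f"{name} contains NaN over ocean cells")
        if (self.npp[:, ocean] < 0).any():
            raise ForcingError("npp must be non-negative")
        if ((self.sst[:, ocean] < -2.0) | (self.sst[:, ocean] > 35.0)).any():
            raise ForcingError("sst outside physical range [-2, 35] degC")

    # -- convenience views -------------------------------------------------
    def climatology(self) -> "ForcingFields":
        """Time-mean forcing as a single-step ForcingFields."""
        return ForcingFields(
            grid=self.grid,
            time=np.array([float(np.mean(self.time))]),
            sst=self.sst.mean(axis=0, keepdims=True),
            npp=self.npp.mean(axis=0, keepdims=True),
        )

    def at_year(self, year: float) -> "ForcingFields":
        """Forcing of the single year closest to ``year``."""
        i = int(np.argmin(np.abs(np.asarray(self.time) - year)))
        return ForcingFields(
            grid=self.grid,
            time=self.time[i : i + 1].copy(),
            sst=self.sst[i : i + 1].copy(),
            npp=self.npp[i : i + 1].copy(),
        )

    def area_weighted_mean_sst(self) -> np.ndarray:
        """Ocean-area-weighted mean SST per year."""
        w = self.grid.cell_area[self.grid.ocean_mask]
        vals = self.sst[:, self.grid.ocean_mask]
        return (vals * w).sum(axis=1) / w.sum()

    def global_npp_molc_per_year(self) -> np.ndarray:
        """Ocean-integrated NPP in mol C yr^-1 per year."""
        w = self.grid.cell_area[self.grid.ocean_mask]
        vals = self.npp[:, self.grid.ocean_mask]  # mmol C m^-2 d^-1
        return (vals * w).sum(axis=1) * 365.25 * 1e-3


def historical_trend_spec(resolution_deg: int = 8, base_year: int = 1850,
                          end_year: int = 2015, noise_sd: float = 0.0,
                          seed: int = 0) -> ForcingSpec:
    """Spec emulating the historical climate-change signal.

    Linear warming of 0.6 degC per century and a 5% per century decline of
    NPP, the canonical magnitudes of the observed 20th-century ocean surface
    warming and the simulated productivity response.  Used for
    climate-sensitive MSY estimates.
    """
    return ForcingSpec(resolution_deg=resolution_deg, base_year=base_year,
                       end_year=end_year, warming_trend=0.6, npp_trend=-5.0,
                       noise_sd=noise_sd, seed=seed)


def _npp_lat_modulation(lat_deg: np.ndarray) -> np.ndarray:
    # 0.45 + 0.7*cos(lat): area-weighted global mean is exactly 1
    return 0.45 + 0.7 * np.cos(np.deg2rad(lat_deg))


def generate_synthetic_forcing(spec: ForcingSpec) -> ForcingFields:
    """Generate idealized Earth-like annual forcing from a spec.

    SST(lat, t) = sst_pole + (sst_equator - sst_pole)*cos^2(lat)
                  + warming_trend*(t - base)/100 + noise.
    NPP is two-band (coastal vs open ocean) times a latitudinal factor with
    unit global mean, times lognormal noise and the relative trend.
    Deterministic under a fixed seed.
    """
    spec.validate()
    grid = make_grid(spec.resolution_deg)
    years = np.arange(spec.base_year, spec.end_year + 1, dtype=float)
    nt = len(years)
    nlat, nlon = grid.shape
    rng = np.random.default_rng(spec.seed)

    lat2 = grid.lat_centers[:, None]
    sst_clim = spec.sst_pole + (spec.sst_equator - spec.sst_pole) * np.cos(
        np.deg2rad(lat2)
    ) ** 2
    sst_clim = np.broadcast_to(sst_clim, (nlat, nlon))

    npp_clim = np.where(grid.coastal_mask, spec.npp_coastal, spec.npp_open)
    npp_clim = npp_clim * _npp_lat_modulation(np.broadcast_to(lat2, (nlat, nlon)))

    dt_century = (years - spec.base_year) / 100.0
    sst = sst_clim[None] + spec.warming_trend * dt_century[:, None, None]
    npp = npp_clim[None] * (1.0 + spec.npp_trend / 100.0 * dt_century[:, None, None])

    if spec.noise_sd > 0:
        sd_t = spec.noise_sd * (spec.sst_equator - spec.sst_pole) / 10.0
        sst = sst + rng.normal(0.0, sd_t, size=(nt, nlat, nlon))
        npp = npp * rng.lognormal(
            mean=-0.5 * spec.noise_sd**2, sigma=spec.noise_sd, size=(nt, nlat, nlon)
        )

    sst = np.clip(sst, -2.0, 35.0)
    npp = np.clip(npp, 0.0, None)
    land = ~grid.ocean_mask
    sst[:, land] = np.nan
    npp[:, land] = np.nan

    out = ForcingFields(grid=grid, time=years, sst=sst, npp=npp)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style; scipy backend, NetCDF3 classic)
# ---------------------------------------------------------------------------

_SST_UNITS = "degC"
_NPP_UNITS = "mmol C m-2 d-1"


def to_xarray(forcing: ForcingFields) -> xr.Dataset:
    g = forcing.grid
    ds = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), forcing.sst, {"units": _SST_UNITS}),
            "npp": (("time", "lat", "lon"), forcing.npp, {"units": _NPP_UNITS}),
            "cell_area": (("lat", "lon"), g.cell_area, {"units": "m2"}),
            "ocean_mask": (("lat", "lon"), g.ocean_mask.astype(np.int8)),
            "coastal_mask": (("lat", "lon"), g.coastal_mask.astype(np.int8)),
        },
        coords={
            "time": ("time", np.asarray(forcing.time, dtype=float),
                     {"units": "year CE"}),
            "lat": ("lat", g.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", g.lon_centers, {"units": "degrees_east"}),
        },
        attrs={"resolution_deg": g.resolution_deg},
    )
    return ds


def save_forcing(forcing: ForcingFields, path) -> None:
    """Write forcing to NetCDF (classic format, portable)."""
    to_xarray(forcing).to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")


def load_forcing(path) -> ForcingFields:
    """Read forcing from a CF-style NetCDF file.

    Requires ``sst(time, lat, lon)`` and ``npp(time, lat, lon)`` with units
    attributes.  NPP in g C m^-2 d^-1 is converted to mmol C m^-2 d^-1 by
    1000/12.011.  Files written by :func:`save_forcing` round-trip exactly.
    """
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds = ds.load()
    for var in ("sst", "npp"):
        if var not in ds:
            raise ForcingError(f"forcing file is missing variable {var!r}")
        if "units" not in ds[var].attrs:
            raise ForcingError(f"variable {var!r} has no units attribute")

    sst = np.asarray(ds["sst"].values, dtype=float)
    npp = np.asarray(ds["npp"].values, dtype=float)

    su = ds["sst"].attrs["units"]
    if su not in ("degC", "degrees_Celsius", "celsius", "C"):
        raise ForcingError(f"unsupported sst units {su!r}; expected degC")
    nu = ds["npp"].attrs["units"]
    if nu in (_NPP_UNITS, "mmol C m^-2 d^-1", "mmolC m-2 d-1"):
        pass
    elif nu in ("g C m-2 d-1", "gC m-2 d-1", "g C m^-2 d^-1"):
        npp = npp * (1000.0 / 12.011)
    else:
        raise ForcingError(f"unsupported npp units {nu!r}")

    res = float(ds.attrs.get("resolution_deg", 180.0 / ds.sizes["lat"]))
    grid = make_grid(int(round(res)))
    if grid.shape != (ds.sizes["lat"], ds.sizes["lon"]):
        raise ForcingError("grid shape in file does not match a supported "
                           "resolution")
    if "ocean_mask" in ds:
        ocean = np.asarray(ds["ocean_mask"].values).astype(bool)
        coastal = (np.asarray(ds["coastal_mask"].values).astype(bool)
                   if "coastal_mask" in ds else grid.coastal_mask)
        area = (np.asarray(ds["cell_area"].values, dtype=float)
                if "cell_area" in ds else grid.cell_area)
        grid = Grid(
            resolution_deg=grid.resolution_deg,
            lat_centers=np.asarray(ds["lat"].values, dtype=float),
            lon_centers=np.asarray(ds["lon"].values, dtype=float),
            cell_area=area,
            ocean_mask=ocean,
            coastal_mask=coastal & ocean,
        )

    out = ForcingFields(
        grid=grid,
        time=np.asarray(ds["time"].values, dtype=float),
        sst=sst,
        npp=npp,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Region masks (synthetic analogue of coastal aggregation regions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionMask:
    """Partition of coastal ocean cells into contiguous lat-lon blocks.

    ``region_id`` is 0 on open-ocean and land cells, 1..n_regions on coastal
    cells.  Regions stand in for the coastal aggregation units (LME-scale)
    used to compare simulated with observed catch and biomass.
    """

    region_id: np.ndarray  # (nlat, nlon) int
    n_regions: int

    def cells_of(self, region: int) -> np.ndarray:
        return self.region_id == region


def make_region_mask(grid: Grid, n_regions: int = 20) -> RegionMask:
    """Split coastal cells into ``n_regions`` contiguous coastal blocks.

    Cells are grouped by nearest coastline meridian, ordered by latitude
    along each coast, and chopped into consecutive runs of near-equal size
    (region sizes stay within a small factor of each other).
    """
    if n_regions < 1:
        raise ForcingError("n_regions must be >= 1")
    ii, jj = np.nonzero(grid.coastal_mask)
    ncoast = len(ii)
    if n_regions > ncoast:
        raise ForcingError(
            f"n_regions={n_regions} exceeds coastal cell count {ncoast}"
        )
    lons = grid.lon_centers[jj]
    lats = grid.lat_centers[ii]

    # nearest coastline meridian (continent edges)
    coast_lons = np.array(
        sorted({c[0] for c in _CONTINENTS} | {c[1] for c in _CONTINENTS})
    )
    dlon = np.abs(lons[:, None] - coast_lons[None, :])
    dlon = np.minimum(dlon, 360.0 - dlon)
    coast_idx = np.argmin(dlon, axis=1)

    # order: coast, then latitude, then longitude -> contiguous runs
    order = np.lexsort((lons, lats, coast_idx))
    region_id = np.zeros(grid.shape, dtype=int)
    bounds = np.linspace(0, ncoast, n_regions + 1).round().astype(int)
    for r in range(n_regions):
        sel = order[bounds[r] : bounds[r + 1]]
        region_id[ii[sel], jj[sel]] = r + 1
    return RegionMask(region_id=region_id, n_regions=n_regions)
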