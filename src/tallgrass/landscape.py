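"""Synthetic tallgrass-prairie landscapes with known forage ground truth.

Generates the inputs the downstream analysis assumes: smooth correlated
terrain (elevation / slope / aspect), prescribed spring-burn schedules on
strip watersheds, daily weather with drought years, an analytically
evaluable forage-truth surface (crude protein % and herbaceous biomass
g/m²), and plot samples from which the calibration and forage models are
recoverable.

Conventions: planar metric coordinates; aspect in radians clockwise from
north (0 = north, π = south), so a southerly preference is a *negative*
coefficient on cos(aspect); flat cells get aspect π/2 (cos = 0, a neutral
covariate value).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import RasterGrid
from .rng import substream
from .seasons import julian_terms, season_end, season_start

SPRING_WINDOW = ((3, 15), (5, 5))  # mid-March .. early May
BURN_INTERVALS = (1, 2, 4, 20)
SCHEDULE_EPOCH = 1980  # burn counting starts here


# --------------------------------------------------------------------------
# terrain
# --------------------------------------------------------------------------

@dataclass
class TerrainGrid:
    """Aligned elevation (m), slope (deg) and aspect (rad cw from N) grids."""

    elevation: RasterGrid
    slope: RasterGrid
    aspect: RasterGrid

    def __post_init__(self) -> None:
        if not (self.elevation.shape == self.slope.shape == self.aspect.shape):
            raise ValueError("terrain grids must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def cell_size(self) -> float:
        return self.elevation.cell_size

    def cos_aspect(self) -> RasterGrid:
        return self.elevation.like(np.cos(self.aspect.data))

    def sin_aspect(self) -> RasterGrid:
        return self.elevation.like(np.sin(self.aspect.data))


def derive_slope_aspect(elevation: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (radians cw from north) by Horn's 3×3
    finite differences, edges handled by replication.

    Flat cells (zero gradient) get slope 0 and aspect π/2, i.e. cos(aspect)
    = 0, so an undefined downslope direction contributes a neutral covariate.
    Exact for affine surfaces.
    """
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2 or min(z.shape) < 3:
        raise ValueError("elevation grid must be at least 3x3")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    # odd reflection = linear extrapolation: keeps Horn exact on affine surfaces
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    # row index increases northward
    n = zp[2:, 1:-1]
    s = zp[:-2, 1:-1]
    e = zp[1:-1, 2:]
    w = zp[1:-1, :-2]
    ne = zp[2:, 2:]
    nw = zp[2:, :-2]
    se = zp[:-2, 2:]
    sw = zp[:-2, :-2]
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8.0 * cell_size)
    dzdy = ((ne + 2 * n + nw) - (se + 2 * s + sw)) / (8.0 * cell_size)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.mod(np.arctan2(-dzdx, -dzdy), 2.0 * np.pi)
    flat = grad < 1e-12
    aspect[flat] = np.pi / 2.0
    return slope, aspect


def generate_terrain(
    rows: int,
    cols: int,
    cell_size: float = 10.0,
    relief_amplitude: float = 50.0,
    base_elevation: float = 380.0,
    correlation_length: float = 150.0,
    seed: int = 0,
) -> TerrainGrid:
    """Smooth correlated elevation field with derived slope/aspect.

    The field is Gaussian white noise smoothed at ``correlation_length``
    and rescaled so max − min equals ``relief_amplitude`` exactly.
    Bit-reproducible per seed.
    """
    if rows < 3 or cols < 3:
        raise ValueError("terrain grid must be at least 3x3")
    if relief_amplitude < 0 or cell_size <= 0:
        raise ValueError("relief_amplitude and cell_size must be positive")
    rng = substream(seed, "terrain")
    noise = rng.standard_normal((rows, cols))
    sigma = max(correlation_length / cell_size, 1.0)
    z = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    span = z.max() - z.min()
    if span > 0:
        z = (z - z.min()) / span * relief_amplitude
    else:
        z = np.zeros_like(z)
    z = z + base_elevation
    elev = RasterGrid(z, cell_size)
    slope, aspect = derive_slope_aspect(z, cell_size)
    return TerrainGrid(elev, elev.like(slope), elev.like(aspect))


# --------------------------------------------------------------------------
# burn history
# --------------------------------------------------------------------------

@dataclass
class Watershed:
    watershed_id: str
    col_slice: tuple[int, int]  # [start, stop) columns of the strip
    burn_interval: int
    burn_dates: list[dt.date]           # within the simulated years
    _schedule: list[dt.date] = field(default_factory=list, repr=False)

    def burns_since_1980(self, year: int) -> int:
        return sum(1 for d in self._schedule if SCHEDULE_EPOCH <= d.year <= year)

    def burned_in(self, year: int) -> bool:
        return any(d.year == year for d in self._schedule)

    def last_burn_on_or_before(self, when: dt.date) -> dt.date | None:
        prior = [d for d in self._schedule if d <= when]
        return max(prior) if prior else None

    def days_since_burn(self, when: dt.date) -> float:
        last = self.last_burn_on_or_before(when)
        if last is None:
            raise ValueError(f"no burn on record before {when} for {self.watershed_id}")
        return float((when - last).days)


@dataclass
class BurnHistory:
    """Strip watersheds with prescribed spring-burn schedules.

    Watersheds are axis-aligned column strips of the grid; each carries a
    1-, 2-, 4- or 20-year burn interval with the burn date drawn uniformly
    in the spring window (15 Mar – 5 May). Schedules extend back to 1980 so
    days-since-burn is defined from the first simulated day.
    """

    watersheds: list[Watershed]
    shape: tuple[int, int]

    def watershed_of_col(self, col: np.ndarray) -> np.ndarray:
        """Index into ``watersheds`` for each grid column."""
        bounds = np.array([w.col_slice[0] for w in self.watersheds])
        return np.clip(np.searchsorted(bounds, np.asarray(col), side="right") - 1, 0, len(self.watersheds) - 1)

    def watershed_index_grid(self) -> np.ndarray:
        cols = np.arange(self.shape[1])
        return np.broadcast_to(self.watershed_of_col(cols), self.shape).copy()

    def days_since_burn_grid(self, when: dt.date) -> np.ndarray:
        per_ws = np.array([w.days_since_burn(when) for w in self.watersheds])
        return per_ws[self.watershed_index_grid()]

    def interval_grid(self) -> np.ndarray:
        per_ws = np.array([w.burn_interval for w in self.watersheds], dtype=float)
        return per_ws[self.watershed_index_grid()]

    def burned_this_year_grid(self, year: int) -> np.ndarray:
        per_ws = np.array([float(w.burned_in(year)) for w in self.watersheds])
        return per_ws[self.watershed_index_grid()]

    def burns_since_1980_grid(self, year: int) -> np.ndarray:
        per_ws = np.array([float(w.burns_since_1980(year)) for w in self.watersheds])
        return per_ws[self.watershed_index_grid()]


def generate_burn_history(
    shape: tuple[int, int],
    intervals: list[int],
    years: list[int],
    seed: int = 0,
) -> BurnHistory:
    """Assign one burn interval per strip watershed and draw spring burn
    dates for every scheduled year from 1980 through the last simulated year."""
    for k in intervals:
        if k not in BURN_INTERVALS:
            raise ValueError(f"unknown burn interval {k}; must be one of {BURN_INTERVALS}")
    if not years:
        raise ValueError("years must be non-empty")
    rng = substream(seed, "burns")
    rows, cols = shape
    n_ws = len(intervals)
    edges = np.linspace(0, cols, n_ws + 1).astype(int)
    (m0, d0), (m1, d1) = SPRING_WINDOW
    watersheds = []
    last_year = max(years)
    for i, k in enumerate(intervals):
        schedule = []
        for y in range(SCHEDULE_EPOCH, last_year + 1):
            if (y - SCHEDULE_EPOCH) % k != 0:
                continue
            start = dt.date(y, m0, d0)
            span = (dt.date(y, m1, d1) - start).days
            schedule.append(start + dt.timedelta(days=int(rng.integers(0, span + 1))))
        in_study = [d for d in schedule if d.year in set(years)]
        watersheds.append(
            Watershed(
                watershed_id=f"W{i + 1:02d}",
                col_slice=(int(edges[i]), int(edges[i + 1])),
                burn_interval=k,
                burn_dates=in_study,
                _schedule=schedule,
            )
        )
    return BurnHistory(watersheds=watersheds, shape=shape)


# --------------------------------------------------------------------------
# weather
# --------------------------------------------------------------------------

@dataclass
class WeatherParams:
    mean_annual_precip_mm: float = 835.0
    growing_season_fraction: float = 0.75  # share of precip in Apr-Sep
    wet_day_prob_gs: float = 0.30
    wet_day_prob_off: float = 0.18
    gamma_shape: float = 0.65
    mean_temp_c: float = 12.8
    temp_seasonal_amplitude_c: float = 14.0
    temp_noise_sd_c: float = 3.0
    drought_precip_factor: float = 0.6
    drought_temp_offset_c: float = 2.0
    anpp_base: float = 300.0      # 0.1 g/m² units
    anpp_per_mm: float = 6.0      # 0.1 g/m² per mm growing-season precip


@dataclass
class WeatherSeries:
    """Daily precipitation/temperature with Mar-1-anchored cumulative precip.

    The ANPP proxy is a deterministic increasing function of growing-season
    (Apr–Sep) precipitation, in 0.1 g/m² units as conventionally reported.
    """

    daily: pd.DataFrame  # columns: date, precip_mm, temp_c, cum_precip_mm
    params: WeatherParams
    drought_years: frozenset[int]

    def _year_rows(self, year: int, start: dt.date, end: dt.date) -> pd.DataFrame:
        d = self.daily["date"]
        return self.daily[(d >= pd.Timestamp(start)) & (d <= pd.Timestamp(end))]

    def cum_precip(self, when: dt.date | dt.datetime) -> float:
        """Cumulative precipitation (mm) since 1 March of ``when``'s year."""
        ts = pd.Timestamp(when).normalize()
        row = self.daily[self.daily["date"] == ts]
        if row.empty:
            raise ValueError(f"{when} outside the simulated weather record")
        return float(row["cum_precip_mm"].iloc[0])

    def annual_precip(self, year: int) -> float:
        return float(self._year_rows(year, dt.date(year, 1, 1), dt.date(year, 12, 31))["precip_mm"].sum())

    def growing_season_precip(self, year: int) -> float:
        return float(self._year_rows(year, dt.date(year, 4, 1), dt.date(year, 9, 30))["precip_mm"].sum())

    def growing_season_temp(self, year: int) -> float:
        """Mean daily temperature (°C), April–October."""
        return float(self._year_rows(year, dt.date(year, 4, 1), dt.date(year, 10, 31))["temp_c"].mean())

    def anpp(self, year: int) -> float:
        """ANPP proxy (0.1 g/m²) for ``year``, driven by its Apr-Sep precipitation."""
        return self.params.anpp_base + self.params.anpp_per_mm * self.growing_season_precip(year)


def generate_weather(years: list[int], params: WeatherParams | None = None,
                     drought_years: list[int] | None = None, seed: int = 0) -> WeatherSeries:
    """Daily weather for the given calendar years.

    Precipitation is a seasonal wet-day/gamma-amount process whose expected
    annual total equals the configured mean (default 835 mm, 75% of it in
    the Apr–Sep growing season). Drought years scale every precipitation
    amount down and shift temperature up.
    """
    params = params or WeatherParams()
    if params.mean_annual_precip_mm <= 0:
        raise ValueError("mean annual precipitation must be positive")
    drought = frozenset(drought_years or [])
    rng = substream(seed, "weather")
    frames = []
    for year in sorted(set(years)):
        dates = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31), freq="D")
        doy = dates.dayofyear.to_numpy()
        in_gs = (dates.month >= 4) & (dates.month <= 9)
        n_gs = int(in_gs.sum())
        n_off = len(dates) - n_gs
        # wet-day gamma scales chosen so expected totals hit the target split
        tgt_gs = params.mean_annual_precip_mm * params.growing_season_fraction
        tgt_off = params.mean_annual_precip_mm * (1 - params.growing_season_fraction)
        scale_gs = tgt_gs / n_gs / params.wet_day_prob_gs / params.gamma_shape
        scale_off = tgt_off / n_off / params.wet_day_prob_off / params.gamma_shape
        p_wet = np.where(in_gs, params.wet_day_prob_gs, params.wet_day_prob_off)
        wet = rng.random(len(dates)) < p_wet
        amounts = rng.gamma(params.gamma_shape, 1.0, size=len(dates))
        amounts *= np.where(in_gs, scale_gs, scale_off)
        precip = np.where(wet, amounts, 0.0)
        temp = (
            params.mean_temp_c
            + params.temp_seasonal_amplitude_c * np.cos(2 * np.pi * (doy - 196) / 365.0)
            + rng.normal(0.0, params.temp_noise_sd_c, size=len(dates))
        )
        if year in drought:
            precip = precip * params.drought_precip_factor
            temp = temp + params.drought_temp_offset_c
        frames.append(pd.DataFrame({"date": dates, "precip_mm": precip, "temp_c": temp}))
    daily = pd.concat(frames, ignore_index=True)
    # cumulative precipitation since the most recent 1 March
    anchor_year = daily["date"].dt.year - (daily["date"].dt.month < 3)
    daily["cum_precip_mm"] = daily.groupby(anchor_year)["precip_mm"].cumsum()
    pre_mar = daily["date"].dt.month < 3
    # the anchor group for Jan-Feb belongs to the previous year's season;
    # for the first simulated year there is no prior 1 March, start at 0
    daily.loc[pre_mar & (daily["date"].dt.year == min(years)), "cum_precip_mm"] = np.nan
    return WeatherSeries(daily=daily, params=params, drought_years=drought)


# --------------------------------------------------------------------------
# forage ground truth
# --------------------------------------------------------------------------

@dataclass
class ForageTruthParams:
    """Smooth parametric forage response; analytically evaluable ground truth.

    Protein (%CP) declines with time since burn (logistic flush after a
    spring fire plus a slow linear decay), is higher on uplands and lower
    where biomass is high. Biomass (g/m²) rises with cumulative
    precipitation (saturating), with time since burn (saturating regrowth)
    and peaks mid-summer; uplands carry less biomass.
    """

    elev_ref: float = 380.0
    elev_scale: float = 50.0
    protein_base: float = 7.0
    protein_burn_boost: float = 8.0
    protein_burn_t0_days: float = 60.0
    protein_burn_steepness: float = 25.0
    protein_decay_per_day: float = 0.002
    protein_upland_gain: float = 1.5
    protein_biomass_coef: float = 0.004
    protein_floor: float = 1.0
    biomass_floor: float = 15.0
    biomass_amplitude: float = 400.0
    precip_half_sat_mm: float = 150.0
    regrowth_timescale_days: float = 90.0
    regrowth_floor: float = 0.15
    season_peak_doy: float = 200.0
    season_width_days: float = 80.0
    season_floor: float = 0.55
    upland_biomass_penalty: float = 0.35


def forage_truth(
    elevation,
    slope,
    cos_aspect,
    days_since_burn,
    cum_precip,
    julian_day,
    params: ForageTruthParams | None = None,
    noise_sd: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (protein %CP, biomass g/m²) at the given covariates.

    Deterministic at zero noise. Inputs broadcast; ``days_since_burn`` must
    be non-negative.
    """
    p = params or ForageTruthParams()
    elevation = np.asarray(elevation, dtype=float)
    dsb = np.asarray(days_since_burn, dtype=float)
    precip = np.asarray(cum_precip, dtype=float)
    jday = np.asarray(julian_day, dtype=float)
    if np.any(dsb < 0):
        raise ValueError("days_since_burn must be non-negative")
    if np.any(precip < 0):
        raise ValueError("cumulative precipitation must be non-negative")
    elev_rel = np.clip((elevation - p.elev_ref) / p.elev_scale, 0.0, 1.0)

    regrow = p.regrowth_floor + (1 - p.regrowth_floor) * (1.0 - np.exp(-dsb / p.regrowth_timescale_days))
    sat = precip / (precip + p.precip_half_sat_mm)
    season = p.season_floor + (1 - p.season_floor) * np.exp(
        -(((jday - p.season_peak_doy) / p.season_width_days) ** 2)
    )
    biomass = p.biomass_floor + p.biomass_amplitude * regrow * sat * season * (
        1.0 - p.upland_biomass_penalty * elev_rel
    )

    # protect against overflow in the logistic tail for decades-old burns
    z = np.clip((dsb - p.protein_burn_t0_days) / p.protein_burn_steepness, -500, 500)
    flush = p.protein_burn_boost / (1.0 + np.exp(z))
    protein = (
        p.protein_base
        + flush
        - p.protein_decay_per_day * dsb
        + p.protein_upland_gain * elev_rel
        - p.protein_biomass_coef * biomass
    )
    protein = np.maximum(protein, p.protein_floor)

    if noise_sd != (0.0, 0.0):
        if rng is None:
            raise ValueError("rng required when noise_sd is nonzero")
        protein = protein + rng.normal(0.0, noise_sd[0], size=np.shape(protein))
        biomass = biomass + rng.normal(0.0, noise_sd[1], size=np.shape(biomass))
        protein = np.maximum(protein, p.protein_floor)
        biomass = np.maximum(biomass, 0.0)
    return protein, biomass


# --------------------------------------------------------------------------
# shrub mask
# --------------------------------------------------------------------------

@dataclass
class ShrubMask:
    """Cells excluded from forage projection (known shrub cover)."""

    mask: np.ndarray  # True = shrub, excluded
    exclusion_radius_m: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def generate_shrub_mask(shape: tuple[int, int], fraction: float = 0.02, seed: int = 0) -> ShrubMask:
    if not 0 <= fraction < 1:
        raise ValueError("shrub fraction must be in [0, 1)")
    rng = substream(seed, "shrubs")
    return ShrubMask(mask=rng.random(shape) < fraction)


# --------------------------------------------------------------------------
# plot sampling
# --------------------------------------------------------------------------

def _covariates_for(
    terrain: TerrainGrid,
    burns: BurnHistory,
    weather: WeatherSeries,
    rows: np.ndarray,
    cols: np.ndarray,
    dates: list[dt.date],
) -> pd.DataFrame:
    elev = terrain.elevation.data[rows, cols]
    slope = terrain.slope.data[rows, cols]
    asp = terrain.aspect.data[rows, cols]
    ws_idx = burns.watershed_of_col(cols)
    recs = []
    for i, d in enumerate(dates):
        w = burns.watersheds[ws_idx[i]]
        sj, cj = julian_terms(d)
        recs.append(
            {
                "date": pd.Timestamp(d),
                "year": d.year,
                "elevation": elev[i],
                "slope": slope[i],
                "sin_aspect": np.sin(asp[i]),
                "cos_aspect": np.cos(asp[i]),
                "days_since_burn": w.days_since_burn(d),
                "cum_precip": weather.cum_precip(d),
                "burns_since_1980": w.burns_since_1980(d.year),
                "burn_interval": w.burn_interval,
                "burned_this_year": float(w.burned_in(d.year)),
                "sin_jday": sj,
                "cos_jday": cj,
                "julian_day": d.timetuple().tm_yday,
            }
        )
    return pd.DataFrame(recs)


def sample_plots(
    terrain: TerrainGrid,
    burns: BurnHistory,
    weather: WeatherSeries,
    years: list[int],
    n_protein: int,
    n_biomass: int,
    protein_noise_sd: float = 0.5,
    height_noise_cm: float = 0.0,
    calibrations: dict[int, tuple[float, float]] | None = None,
    truth_params: ForageTruthParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic plot campaigns: foliar-protein plots and disk-meter plots.

    Plots fall on uniform-random cells and uniform-random in-season dates
    (the real campaigns were opportunistic; the design is not stated, so a
    uniform design is assumed). Disk heights are generated by inverting the
    per-year linear height→biomass calibration (default: slope 2.40 /
    intercept 3.70), so the calibration regression is exactly recoverable at
    zero noise.
    """
    if n_protein < 30 or n_biomass < 30:
        raise ValueError("at least 30 plots of each kind are required")
    calibrations = calibrations or {y: (2.40, 3.70) for y in years}
    rng = substream(seed, "plots")
    rows_n, cols_n = terrain.shape

    def draw(n: int) -> tuple[np.ndarray, np.ndarray, list[dt.date]]:
        r = rng.integers(0, rows_n, size=n)
        c = rng.integers(0, cols_n, size=n)
        ys = rng.choice(np.asarray(years), size=n)
        dates = []
        for y in ys:
            span = (season_end(int(y)) - season_start(int(y))).days
            dates.append(season_start(int(y)) + dt.timedelta(days=int(rng.integers(0, span))))
        return r, c, dates

    def truth_for(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return forage_truth(
            df["elevation"].to_numpy(),
            df["slope"].to_numpy(),
            df["cos_aspect"].to_numpy(),
            df["days_since_burn"].to_numpy(),
            df["cum_precip"].to_numpy(),
            df["julian_day"].to_numpy(),
            params=truth_params,
        )

    r, c, dates = draw(n_protein)
    prot_df = _covariates_for(terrain, burns, weather, r, c, dates)
    protein, _ = truth_for(prot_df)
    if protein_noise_sd > 0:
        protein = np.maximum(protein + rng.normal(0, protein_noise_sd, n_protein), 0.1)
    prot_df["protein"] = protein

    r, c, dates = draw(n_biomass)
    bio_df = _covariates_for(terrain, burns, weather, r, c, dates)
    _, biomass = truth_for(bio_df)
    bio_df["biomass"] = biomass
    heights = np.empty(n_biomass)
    for y in sorted(set(bio_df["year"])):
        if y not in calibrations:
            raise ValueError(f"no disk calibration configured for year {y}")
        slope_c, intercept_c = calibrations[y]
        sel = (bio_df["year"] == y).to_numpy()
        heights[sel] = (biomass[sel] - intercept_c) / slope_c
    if height_noise_cm > 0:
        heights = heights + rng.normal(0, height_noise_cm, n_biomass)
    bio_df["height_cm"] = np.maximum(heights, 0.0)
    return prot_df, bio_df
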