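"""Synthetic study world: gridded environmental fields and reproductive
histories with the statistical structure the matched analysis assumes.

The generator emulates (a) a right-skewed, seasonally peaked fire-PM2.5
field — Gaussian spatial kernels around hotspot centres, lognormal
monthly multipliers, configurable peak months — superimposed on a smooth
non-fire field with a mild winter cycle; and (b) mother-level
reproductive histories in which the probability of pregnancy loss
follows a mother-stratified logistic model with per-ug/m3 fire and
non-fire effects, maternal-age-band offsets, weather effects,
conception-month seasonality and a secular trend.

Every mother draws one latent risk-window length g (months, 1-9) from
the loss-gestation mixture; each of her pregnancies' loss probability is
driven by exposure averaged over the first g months from conception, a
loss realises gestation g, and a live birth runs the full 9 months.
Because controls are later analysed over windows of the case's
gestation length, the generative covariate coincides exactly with the
analysis covariate and the matched-design estimator is consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy.special import expit, logit

from . import exposure as exp_mod
from .timeaxis import cmc, cmc_month, cmc_year, month_range

__all__ = [
    "WorldConfig",
    "FireParams",
    "NonfireParams",
    "WeatherParams",
    "SimulatedFields",
    "SyntheticCohort",
    "simulate_fields",
    "simulate_mothers",
    "simulate_world",
    "simulate_matched_sets",
    "AGE_BANDS",
    "age_band",
    "age_group3",
    "write_events",
    "read_events",
]

AGE_BANDS = ("<20", "20-24", "25-29", "30-34", "35-39", ">=40")

LIVE_BIRTH_GESTATION = 9


def age_band(age_years):
    """Six maternal-age bands used as the categorical age covariate."""
    edges = [20, 25, 30, 35, 40]
    idx = np.digitize(np.asarray(age_years, dtype=float), edges)
    return np.asarray(AGE_BANDS, dtype=object)[idx]


def age_group3(age_years):
    """Coarse three-level age grouping used in subgroup analyses."""
    a = np.asarray(age_years, dtype=float)
    out = np.where(a < 30, "<30", np.where(a < 35, "30-34", ">=35"))
    return out


# ----------------------------------------------------------------------
@dataclass
class FireParams:
    """Fire-PM2.5 field: hotspot kernels x seasonal weights x lognormal noise."""

    hotspot_centers: tuple = ((22.0, 82.0), (25.5, 84.5), (23.5, 86.5))
    hotspot_sigma_deg: float = 1.2
    hotspot_peak_mean: float = 5.0  # long-term peak-season mean at a hotspot centre, ug/m3
    peak_months: tuple = (3, 4, 5, 10, 11)  # pre-monsoon + post-monsoon burning
    offseason_level: float = 0.15  # seasonal weight outside the peak months
    lognormal_sdlog: float = 0.8  # month-to-month skewed variability
    burn_kernel_threshold: float = 0.35  # kernel value above which local burning occurs
    burned_frac_scale: float = 3.0  # % burned area at a hotspot centre in a peak month
    dry_matter_per_burn: float = 0.5  # dry-matter emission per % burned area


@dataclass
class NonfireParams:
    """Smooth non-fire PM2.5: low-order spatial surface + winter cycle."""

    base_level: float = 45.0
    spatial_amplitude: float = 12.0
    seasonal_amplitude: float = 0.20  # relative, peaks in January
    noise_sd: float = 2.0


@dataclass
class WeatherParams:
    temp_mean: float = 26.0
    temp_seasonal_amp: float = 6.0
    temp_lat_gradient: float = -0.6  # degC per degree latitude northwards
    temp_noise_sd: float = 1.0
    humid_mean: float = 65.0
    humid_seasonal_amp: float = 15.0
    humid_noise_sd: float = 3.0


@dataclass
class WorldConfig:
    """Full configuration of the synthetic study world.

    Effect sizes are log-odds per unit: the defaults inject a fire
    effect of ln(1.051) per ug/m3 and a non-fire effect of ln(1.014)
    per ug/m3, with age-band offsets, weather effects, conception-month
    seasonality and a downward secular trend, on top of normally
    distributed mother-level intercepts (cancelled by the matching).
    """

    rng_seed: int = 0
    lat_min: float = 20.0
    lat_max: float = 28.0
    lon_min: float = 80.0
    lon_max: float = 88.0
    coarse_res: float = 0.5
    fine_res: float = 0.1
    year_start: int = 2000
    year_end: int = 2014
    n_mothers: int = 20000
    n_clusters: int = 250
    true_log_or_fire: float = float(np.log(1.051))
    true_log_or_nonfire: float = float(np.log(1.014))
    fire_log_or_by_age_group: Optional[dict] = None  # {'<30':..,'30-34':..,'>=35':..}
    age_effects: dict = field(
        default_factory=lambda: {
            "<20": 0.20,
            "20-24": 0.0,
            "25-29": 0.05,
            "30-34": 0.15,
            "35-39": 0.35,
            ">=40": 0.60,
        }
    )
    temp_effect: float = 0.010  # log-odds per degC
    humid_effect: float = 0.004  # log-odds per % RH
    seasonal_amplitude: float = 0.15  # log-odds, sinusoid in conception month
    trend_slope: float = -0.010  # log-odds per calendar year
    mother_intercept_mean: float = float(logit(0.11))
    mother_intercept_sd: float = 1.0
    nonfire_reference: float = 45.0  # centres the non-fire term in the risk model
    gestation_loss_probs: tuple = (0.04, 0.18, 0.25, 0.21, 0.12, 0.08, 0.06, 0.04, 0.02)
    mean_extra_pregnancies: float = 2.3  # pregnancies per mother = 1 + Poisson(this)
    max_pregnancies: int = 8
    satellite_factor_mean: float = 0.95  # satellite = factor x annual mean with-fire
    satellite_factor_sd: float = 0.05
    fire: FireParams = field(default_factory=FireParams)
    nonfire: NonfireParams = field(default_factory=NonfireParams)
    weather: WeatherParams = field(default_factory=WeatherParams)

    def __post_init__(self):
        if self.coarse_res <= 0 or self.fine_res <= 0:
            raise ValueError("grid resolution must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("degenerate grid extent")
        if self.n_mothers <= 0:
            raise ValueError("n_mothers must be positive")
        p = np.asarray(self.gestation_loss_probs, dtype=float)
        if p.size != 9 or abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
            raise ValueError("gestation_loss_probs must be 9 probabilities summing to 1")

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(d), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        d = dict(d)
        if "rng_seed" not in d:
            raise ValueError("world config requires an explicit rng_seed")
        for key, sub in (("fire", FireParams), ("nonfire", NonfireParams), ("weather", WeatherParams)):
            if key in d and isinstance(d[key], dict):
                dd = dict(d[key])
                for k, v in dd.items():
                    if isinstance(v, list):
                        dd[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                d[key] = sub(**dd)
        for k in ("gestation_loss_probs",):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ----------------------------------------------------------------------
@dataclass
class SimulatedFields:
    """Coarse CTM-style monthly stack plus the fine annual satellite raster."""

    coarse: xr.Dataset
    satellite: xr.DataArray  # (year, lat, lon) on the fine grid
    fine_lat: np.ndarray
    fine_lon: np.ndarray


def _axes(lo, hi, res):
    n = int(round((hi - lo) / res))
    if n < 1:
        raise ValueError("grid extent smaller than one cell")
    return lo + res * (np.arange(n) + 0.5)


def simulate_fields(config: WorldConfig, rng: Optional[np.random.Generator] = None) -> SimulatedFields:
    """Generate the monthly coarse field stack and fine satellite reference.

    With-fire PM2.5 is the non-fire field plus the fire component, so the
    two runs differ by exactly the injected fire concentration; the
    annual satellite raster is a noisy multiple of the annual mean of the
    (downscaled) with-fire field.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[0])
    lat = _axes(config.lat_min, config.lat_max, config.coarse_res)
    lon = _axes(config.lon_min, config.lon_max, config.coarse_res)
    months = month_range(config.year_start, config.year_end)
    moy = cmc_month(months)
    nm, nlat, nlon = months.size, lat.size, lon.size
    LAT, LON = np.meshgrid(lat, lon, indexing="ij")

    fp, nfp, wp = config.fire, config.nonfire, config.weather

    # fire component: hotspot kernels x seasonal weight x lognormal month noise
    season_w = np.where(np.isin(moy, fp.peak_months), 1.0, fp.offseason_level)
    fire = np.zeros((nm, nlat, nlon))
    burned = np.zeros((nm, nlat, nlon))
    meanlog = -0.5 * fp.lognormal_sdlog**2  # unit-mean lognormal
    for clat, clon in fp.hotspot_centers:
        kern = np.exp(-(((LAT - clat) ** 2 + (LON - clon) ** 2) / (2 * fp.hotspot_sigma_deg**2)))
        mult = rng.lognormal(meanlog, fp.lognormal_sdlog, size=nm)
        fire += fp.hotspot_peak_mean * kern[None] * (season_w * mult)[:, None, None]
        local = np.maximum(kern - fp.burn_kernel_threshold, 0.0) / (1 - fp.burn_kernel_threshold)
        peak = np.isin(moy, fp.peak_months).astype(float)
        burned += fp.burned_frac_scale * local[None] * (peak * mult)[:, None, None]
    dry_matter = fp.dry_matter_per_burn * burned

    # smooth non-fire surface + winter seasonal cycle + weak noise
    u = (LAT - LAT.mean()) / max(np.ptp(LAT), 1e-9)
    v = (LON - LON.mean()) / max(np.ptp(LON), 1e-9)
    surface = nfp.base_level + nfp.spatial_amplitude * (u + 0.6 * v + 0.8 * u * v)
    seas = 1.0 + nfp.seasonal_amplitude * np.cos(2 * np.pi * (moy - 1) / 12.0)
    nonfire = surface[None] * seas[:, None, None] + rng.normal(0, nfp.noise_sd, (nm, nlat, nlon))
    nonfire = np.maximum(nonfire, 1.0)

    wfire = nonfire + fire  # additivity exact by construction

    temp = (
        wp.temp_mean
        + wp.temp_lat_gradient * (LAT - LAT.mean())[None]
        - wp.temp_seasonal_amp * np.cos(2 * np.pi * (moy[:, None, None] - 1) / 12.0)
        + rng.normal(0, wp.temp_noise_sd, (nm, nlat, nlon))
    )
    humid = np.clip(
        wp.humid_mean
        - wp.humid_seasonal_amp * np.cos(2 * np.pi * (moy[:, None, None] - 2) / 12.0)
        + rng.normal(0, wp.humid_noise_sd, (nm, nlat, nlon)),
        10.0,
        100.0,
    )

    years = np.arange(config.year_start, config.year_end + 1)
    coarse = xr.Dataset(
        {
            "pm_wfire": (("month", "lat", "lon"), wfire),
            "pm_nofire": (("month", "lat", "lon"), nonfire),
            "burned_frac": (("month", "lat", "lon"), burned),
            "dry_matter": (("month", "lat", "lon"), dry_matter),
            "temperature": (("month", "lat", "lon"), temp),
            "humidity": (("month", "lat", "lon"), humid),
        },
        coords={"month": months, "lat": lat, "lon": lon, "year": years},
    )

    fine_lat, fine_lon = exp_mod.fine_axes(
        config.lat_min, config.lat_max, config.lon_min, config.lon_max, config.fine_res
    )
    wfire_fine = exp_mod.idw_downscale(wfire, lat, lon, fine_lat, fine_lon)
    annual = wfire_fine.reshape(years.size, 12, fine_lat.size, fine_lon.size).mean(axis=1)
    factor = np.clip(
        rng.normal(config.satellite_factor_mean, config.satellite_factor_sd, annual.shape),
        0.5,
        None,
    )
    satellite = xr.DataArray(
        factor * annual,
        dims=("year", "lat", "lon"),
        coords={"year": years, "lat": fine_lat, "lon": fine_lon},
        name="pm_satellite",
    )
    return SimulatedFields(coarse, satellite, fine_lat, fine_lon)


def calibrated_from_fields(fields: SimulatedFields) -> xr.Dataset:
    """Downscale the coarse stack and calibrate it against the satellite."""
    fine = exp_mod.downscale_stack(fields.coarse, fields.fine_lat, fields.fine_lon)
    return exp_mod.calibrate_stack(fine, fields.satellite)


# ----------------------------------------------------------------------
EVENT_COLUMNS = [
    "mother_id",
    "cluster_id",
    "lat",
    "lon",
    "outcome",
    "conception_cmc",
    "termination_cmc",
    "gestation_months",
    "singleton",
    "survival_months",
    "parity_before",
    "mother_birth_cmc",
    "survey_cmc",
    "education",
    "residence",
    "insurance",
]


@dataclass
class SyntheticCohort:
    """Reproductive histories (one row per pregnancy event) plus mother table."""

    events: pd.DataFrame
    mothers: pd.DataFrame
    clusters: pd.DataFrame  # cluster_id, lat, lon


def simulate_mothers(
    config: WorldConfig,
    fields: SimulatedFields,
    calibrated: Optional[xr.Dataset] = None,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticCohort:
    """Simulate reproductive histories whose loss risk follows the
    mother-stratified logistic model on the calibrated exposure series.

    Pass ``calibrated`` to reuse an already downscaled/calibrated stack.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[1])
    if calibrated is None:
        calibrated = calibrated_from_fields(fields)

    months = calibrated["month"].values
    start_cmc, end_cmc = int(months[0]), int(months[-1])

    # survey clusters (village locations), inset from the grid edge
    pad = config.fine_res
    clat = rng.uniform(config.lat_min + pad, config.lat_max - pad, config.n_clusters)
    clon = rng.uniform(config.lon_min + pad, config.lon_max - pad, config.n_clusters)
    series = exp_mod.extract_at_points(calibrated, clat, clon)
    clusters = pd.DataFrame(
        {"cluster_id": np.arange(config.n_clusters), "lat": clat, "lon": clon}
    )

    n = config.n_mothers
    cluster = rng.integers(0, config.n_clusters, n)
    alpha = rng.normal(config.mother_intercept_mean, config.mother_intercept_sd, n)
    g_mother = rng.choice(
        np.arange(1, 10), size=n, p=np.asarray(config.gestation_loss_probs)
    )
    education = rng.choice(["none", "primary", "secondary+"], size=n, p=[0.35, 0.35, 0.30])
    residence = rng.choice(["rural", "urban"], size=n, p=[0.7, 0.3])
    insurance = rng.choice(["no", "yes"], size=n, p=[0.8, 0.2])
    n_preg = np.minimum(1 + rng.poisson(config.mean_extra_pregnancies, n), config.max_pregnancies)
    survey_cmc = end_cmc + rng.integers(1, 12, n)

    age_first = rng.uniform(17.0, 32.0, n)  # age at first conception, years
    first_c = rng.integers(start_cmc - 24, end_cmc - 8, n)  # some spill outside the period
    birth_cmc = first_c - np.round(age_first * 12).astype(int)

    # long event arrays (chronological within mother)
    mid = np.repeat(np.arange(n), n_preg)
    gaps = rng.integers(10, 40, mid.size)
    first_of_mother = np.r_[True, mid[1:] != mid[:-1]]
    gaps[first_of_mother] = 0
    # cumulative gaps within mother
    cum = np.cumsum(gaps)
    cum = cum - np.repeat(cum[first_of_mother], n_preg)
    conception = first_c[mid] + cum

    keep = (conception >= start_cmc) & (conception + LIVE_BIRTH_GESTATION - 1 <= end_cmc)
    mid = mid[keep]
    conception = conception[keep]

    g = g_mother[mid]
    cl = cluster[mid]
    fire_w, valid_f = series.window_means("fire", cl, conception, g)
    nonfire_w, _ = series.window_means("nonfire", cl, conception, g)
    temp_w, _ = series.window_means("temperature", cl, conception, g)
    humid_w, _ = series.window_means("humidity", cl, conception, g)
    assert valid_f.all(), "generator produced an event outside the field months"

    window_end = conception + g - 1
    age_years = (window_end - birth_cmc[mid]) / 12.0
    bands = age_band(age_years)
    age_off = np.vectorize(config.age_effects.__getitem__)(bands).astype(float)

    if config.fire_log_or_by_age_group:
        grp = age_group3(age_years)
        beta_f = np.vectorize(config.fire_log_or_by_age_group.__getitem__)(grp).astype(float)
    else:
        beta_f = config.true_log_or_fire

    moy_c = cmc_month(conception)
    year_c = cmc_year(conception)
    lp = (
        alpha[mid]
        + beta_f * fire_w
        + config.true_log_or_nonfire * (nonfire_w - config.nonfire_reference)
        + age_off
        + config.temp_effect * (temp_w - config.weather.temp_mean)
        + config.humid_effect * (humid_w - config.weather.humid_mean)
        + config.seasonal_amplitude * np.sin(2 * np.pi * moy_c / 12.0)
        + config.trend_slope * (year_c - config.year_start)
    )
    loss = rng.uniform(size=lp.size) < expit(lp)
    gestation = np.where(loss, g, LIVE_BIRTH_GESTATION)
    termination = conception + gestation - 1

    live = (~loss).astype(int)
    parity_before = (
        pd.Series(live).groupby(pd.Series(mid)).cumsum().to_numpy() - live
    )

    singleton = np.where(loss, True, rng.uniform(size=loss.size) > 0.015)
    died = (~loss) & (rng.uniform(size=loss.size) < 0.05)
    surv = np.where(
        died,
        rng.integers(0, 12, loss.size).astype(float),
        (survey_cmc[mid] - termination).astype(float),
    )
    surv[loss] = np.nan
    unknown = (~loss) & (rng.uniform(size=loss.size) < 0.02)
    surv[unknown] = np.nan

    events = pd.DataFrame(
        {
            "mother_id": mid,
            "cluster_id": cl,
            "lat": clat[cl],
            "lon": clon[cl],
            "outcome": np.where(loss, "loss", "live"),
            "conception_cmc": conception,
            "termination_cmc": termination,
            "gestation_months": gestation,
            "singleton": singleton,
            "survival_months": surv,
            "parity_before": parity_before,
            "mother_birth_cmc": birth_cmc[mid],
            "survey_cmc": survey_cmc[mid],
            "education": education[mid],
            "residence": residence[mid],
            "insurance": insurance[mid],
        }
    )

    counts = np.bincount(mid, minlength=n)
    mothers = pd.DataFrame(
        {
            "mother_id": np.arange(n),
            "cluster_id": cluster,
            "n_events": counts,
            "no_pregnancy_in_period": counts == 0,
            "risk_window_months": g_mother,
            "intercept": alpha,
            "education": education,
            "residence": residence,
            "insurance": insurance,
            "survey_cmc": survey_cmc,
        }
    )
    return SyntheticCohort(events, mothers, clusters)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    fields: SimulatedFields
    calibrated: xr.Dataset
    cohort: SyntheticCohort


def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Fields + calibration + mothers in one seeded call."""
    ss = np.random.SeedSequence(config.rng_seed).spawn(2)
    fields = simulate_fields(config, rng=np.random.default_rng(ss[0]))
    calibrated = calibrated_from_fields(fields)
    cohort = simulate_mothers(
        config, fields, calibrated=calibrated, rng=np.random.default_rng(ss[1])
    )
    return SyntheticWorld(config, fields, calibrated, cohort)


# ----------------------------------------------------------------------
def simulate_matched_sets(
    n_mothers: int,
    beta: dict,
    rng,
    n_pregnancies: int = 3,
    intercept_mean: float = -2.0,
    intercept_sd: float = 1.0,
    covariate_sampler=None,
):
    """Reduced generator: matched sets straight from the stratified logistic.

    Skips the spatial field machinery: per mother, ``n_pregnancies``
    events draw covariates from ``covariate_sampler(rng, size)`` (default:
    a single right-skewed ``fire`` exposure, lognormal with mean ~1.2
    ug/m3), outcomes from ``logit p = alpha_i + x @ beta``, and the
    matched cohort keeps mothers with at least one loss and one live
    birth, the most recent loss serving as the case.  Intended for
    estimator calibration studies (bias, CI coverage, test power) where
    thousands of replicates are needed.

    Returns a long DataFrame with ``set_id``, ``is_case`` and the
    covariate columns.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    size = n_mothers * n_pregnancies
    if covariate_sampler is None:
        def covariate_sampler(r, s):
            return pd.DataFrame({"fire": r.lognormal(mean=-0.2, sigma=0.9, size=s)})

    X = covariate_sampler(rng, size)
    missing = set(beta) - set(X.columns)
    if missing:
        raise ValueError(f"beta names not produced by sampler: {sorted(missing)}")
    alpha = np.repeat(rng.normal(intercept_mean, intercept_sd, n_mothers), n_pregnancies)
    lp = alpha + sum(beta[k] * X[k].to_numpy() for k in beta)
    loss = rng.uniform(size=size) < expit(lp)

    mid = np.repeat(np.arange(n_mothers), n_pregnancies)
    df = X.copy()
    df["set_id"] = mid
    df["loss"] = loss
    df["order"] = np.tile(np.arange(n_pregnancies), n_mothers)

    # most recent loss is the case; live births are the controls
    grp = df.groupby("set_id")["loss"]
    has_loss = grp.transform("any")
    has_live = (~df["loss"]).groupby(df["set_id"]).transform("any")
    df = df[has_loss & has_live]
    loss_order = df["order"].where(df["loss"], -1)
    case_order = loss_order.groupby(df["set_id"]).transform("max")
    df = df[(~df["loss"]) | (df["order"] == case_order)].copy()
    df["is_case"] = df["loss"].astype(int)
    return df.drop(columns=["loss", "order"]).reset_index(drop=True)


# ----------------------------------------------------------------------
def write_events(events: pd.DataFrame, path) -> None:
    """Write the pregnancy-event table (documented column set) to CSV."""
    events.to_csv(path, index=False, columns=[c for c in EVENT_COLUMNS if c in events.columns])


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df
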