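"""Synthetic life-table, weather and climate-raster generators.

These generators emulate the statistical structure of a constant-
temperature life-table study and of the climate inputs the mapping
pipeline consumes, so the full analysis is testable end to end without
any external data:

* stage durations are logistic-in-log around the truth model's median
  (matching the logit development-time distribution);
* stage deaths are Bernoulli draws from the truth mortality curves;
* lifetime fecundity is a Gamma-mixed Poisson (negative binomial)
  around the truth total-fecundity curve, allocated to days by the
  relative-oviposition schedule;
* daily weather is a mid-month-interpolated seasonal cycle plus
  Gaussian day-to-day anomalies;
* climate rasters carry a linear meridional temperature gradient with
  a seasonal cycle and an optional nodata mask.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import ValidationError, evaluate
from .grids import ClimateGrid, GridSpec, NODATA_DEFAULT
from .life_tables import LifeTableObservations
from .mapping import N_DAYS, interpolate_daily
from .reference import reference_model
from .simulation import PhenologyModel

#: a Cotonou-like coastal West African monthly climate (tmin, tmax) used as
#: the default seasonal cycle for the validation weather series
DEFAULT_MONTHLY_TMIN = (24.0, 25.0, 25.5, 25.0, 24.5, 23.5, 23.0, 22.5, 23.0, 23.5, 24.5, 24.0)
DEFAULT_MONTHLY_TMAX = (31.5, 32.5, 32.5, 32.0, 31.5, 29.5, 28.5, 28.0, 29.0, 30.0, 31.5, 31.5)


@dataclass
class GeneratorConfig:
    """Study design for the synthetic life-table experiment.

    Defaults mirror the laboratory design the truth parameters come
    from: cohorts of 100 neonates at 20/25/28/30/32 deg C and 30 adult
    pairs per temperature.  ``fecundity_dispersion`` is the Gamma shape
    of the negative-binomial lifetime egg count (larger = closer to
    Poisson).
    """

    seed: int
    truth: PhenologyModel = field(default_factory=reference_model)
    temperatures: tuple = (20.0, 25.0, 28.0, 30.0, 32.0)
    n_per_temperature: int = 100
    n_pairs: int = 30
    fecundity_dispersion: float = 5.0

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_per_temperature < 1 or self.n_pairs < 0:
            raise ValidationError("cohort sizes must be positive")
        if self.fecundity_dispersion <= 0:
            raise ValidationError("fecundity_dispersion must be positive")


def _sample_duration(rng, median: float, slope: float) -> float:
    return median * math.exp(rng.logistic() / slope)


def generate_life_table(cfg: GeneratorConfig) -> LifeTableObservations:
    """Simulate the constant-temperature experiment under the truth model.

    Per temperature: ``n_per_temperature`` neonates followed through
    egg/larva/pupa (death or completion per stage), plus ``n_pairs``
    adult females and males whose longevity and daily egg counts are
    recorded.  Egg durations below one day are recorded as 0.5 d (the
    sub-daily hatching convention).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = cfg.truth
    ind_rows = []
    fec_rows = []
    for T in cfg.temperatures:
        stage_specs = []
        for st in truth.stages:
            r = evaluate(st.development_rate, float(T))
            m = evaluate(st.mortality, float(T))
            if r <= 0:
                raise ValidationError(f"truth model not viable at {T} C (stage {st.name})")
            stage_specs.append((st.name, 1.0 / r, m, st.time_slope))

        for i in range(cfg.n_per_temperature):
            ind_id = f"T{T:g}_N{i:03d}"
            sex = "F" if rng.random() < truth.sex_ratio else "M"
            for name, median, mort, slope in stage_specs:
                died = bool(rng.random() < mort)
                if died:
                    ind_rows.append((ind_id, T, name, np.nan, True, "unknown"))
                    break
                dur = _sample_duration(rng, median, slope)
                if name == "egg" and dur < 1.0:
                    dur = 0.5
                ind_rows.append((ind_id, T, name, dur, False, "unknown"))
            else:
                stage = "adult_female" if sex == "F" else "adult_male"
                sen = truth.female_senescence if sex == "F" else truth.male_senescence
                slope = truth.female_time_slope if sex == "F" else truth.male_time_slope
                s = evaluate(sen, float(T))
                longevity = _sample_duration(rng, 1.0 / max(s, 1e-6), slope)
                ind_rows.append((ind_id, T, stage, longevity, False, sex))

        # adult pairs: fecundity + longevity
        fec_mean = evaluate(truth.total_fecundity, float(T))
        s_f = evaluate(truth.female_senescence, float(T))
        s_m = evaluate(truth.male_senescence, float(T))
        for k in range(cfg.n_pairs):
            fid = f"T{T:g}_P{k:02d}F"
            mid = f"T{T:g}_P{k:02d}M"
            lf = _sample_duration(rng, 1.0 / max(s_f, 1e-6), truth.female_time_slope)
            lm = _sample_duration(rng, 1.0 / max(s_m, 1e-6), truth.male_time_slope)
            ind_rows.append((fid, T, "adult_female", lf, False, "F"))
            ind_rows.append((mid, T, "adult_male", lm, False, "M"))
            # lifetime egg complement: Gamma-mixed Poisson around F(T)
            if fec_mean > 0:
                lam = rng.gamma(cfg.fecundity_dispersion, fec_mean / cfg.fecundity_dispersion)
                total = int(rng.poisson(lam))
            else:
                total = 0
            n_days = max(int(math.ceil(lf)), 1)
            ages = np.arange(1, n_days + 1, dtype=float)
            e = np.minimum(ages / lf, 1.0)
            o = evaluate(truth.relative_oviposition, e)
            o_prev = evaluate(truth.relative_oviposition, np.concatenate([[0.0], e[:-1]]))
            w = np.clip(o - o_prev, 0.0, None)
            if total > 0 and w.sum() > 0:
                counts = rng.multinomial(total, w / w.sum())
            else:
                counts = np.zeros(n_days, dtype=int)
            for age, eggs in zip(ages.astype(int), counts):
                fec_rows.append((fid, T, age, int(eggs)))

    individuals = pd.DataFrame(
        ind_rows,
        columns=["individual_id", "temperature_C", "stage", "duration_days", "died_in_stage", "sex"],
    )
    fecundity = pd.DataFrame(
        fec_rows, columns=["female_id", "temperature_C", "age_day", "eggs"]
    )
    return LifeTableObservations(individuals=individuals, fecundity=fecundity)


def generate_daily_series(
    years: int,
    base_climate: tuple = (DEFAULT_MONTHLY_TMIN, DEFAULT_MONTHLY_TMAX),
    jitter_sd: float = 1.5,
    seed: int = 0,
    start_date: str = "2019-01-01",
) -> pd.DataFrame:
    """Daily (date, tmin_C, tmax_C) weather emulating a multi-year station record.

    The seasonal signal is the mid-month interpolation of
    ``base_climate`` repeated for each 365-day year; a single Gaussian
    day-to-day anomaly (sd ``jitter_sd``) is added to both tmin and
    tmax, preserving tmin <= tmax.
    """
    if years < 1:
        raise ValidationError("years must be >= 1")
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    season = interpolate_daily(*base_climate)
    n = years * N_DAYS
    idx = np.tile(np.arange(N_DAYS), years)
    anomaly = rng.normal(0.0, jitter_sd, size=n) if jitter_sd > 0 else np.zeros(n)
    tmin = season.tmin[idx] + anomaly
    tmax = season.tmax[idx] + anomaly
    dates = pd.date_range(start_date, periods=n, freq="D")
    return pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "tmin_C": tmin, "tmax_C": tmax})


def daily_means_from_series(df: pd.DataFrame) -> np.ndarray:
    """(tmin + tmax) / 2 from a weather frame with tmin_C/tmax_C columns."""
    return 0.5 * (df["tmin_C"].to_numpy(float) + df["tmax_C"].to_numpy(float))


def generate_climate_raster(
    shape: tuple[int, int],
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    mean_at_equator: float = 27.0,
    gradient_per_degree: float = -0.5,
    seasonal_amplitude: float = 3.0,
    diurnal_range: float = 8.0,
    mask_fraction: float = 0.0,
    seed: int = 0,
) -> ClimateGrid:
    """Synthetic monthly climate normals with a linear meridional gradient.

    The annual-mean temperature at latitude phi is
    ``mean_at_equator + gradient_per_degree * |phi|``; each month adds
    a sinusoidal seasonal cycle of amplitude ``seasonal_amplitude``
    (winter-centred in the hemisphere of the pixel) and tmin/tmax
    straddle the monthly mean by ``diurnal_range / 2``.  Exactly
    ``floor(mask_fraction * cells)`` pixels are set to nodata.
    """
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise ValidationError("shape must be at least 1x1")
    if not (lat_range[0] < lat_range[1]) or not (lon_range[0] < lon_range[1]):
        raise ValidationError("lat/lon ranges must be increasing")
    rng = np.random.default_rng(seed)
    cellsize = (lat_range[1] - lat_range[0]) / nrows
    spec = GridSpec(
        nrows=nrows,
        ncols=ncols,
        xllcorner=lon_range[0],
        yllcorner=lat_range[0],
        cellsize=cellsize,
        nodata=NODATA_DEFAULT,
    )
    lat = spec.lat_centers()[:, None] * np.ones((1, ncols))
    annual_mean = mean_at_equator + gradient_per_degree * np.abs(lat)
    months = np.arange(12)
    # seasonal phase flips across the equator (July-peak north, January-peak south)
    tmin = np.empty((12, nrows, ncols))
    tmax = np.empty((12, nrows, ncols))
    for m in months:
        phase = np.where(lat >= 0, 1.0, -1.0) * np.cos(2 * np.pi * (m + 0.5 - 6.5) / 12.0)
        monthly_mean = annual_mean + seasonal_amplitude * phase
        tmin[m] = monthly_mean - diurnal_range / 2.0
        tmax[m] = monthly_mean + diurnal_range / 2.0
    n_mask = int(math.floor(mask_fraction * nrows * ncols))
    if n_mask > 0:
        flat = rng.choice(nrows * ncols, size=n_mask, replace=False)
        rr, cc = np.unravel_index(flat, (nrows, ncols))
        tmin[:, rr, cc] = spec.nodata
        tmax[:, rr, cc] = spec.nodata
    return ClimateGrid(tmin=tmin, tmax=tmax, spec=spec)
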