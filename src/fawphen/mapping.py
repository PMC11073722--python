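"""Climate risk indices for pest establishment, activity and generations.

Three annual indices summarise what a daily temperature regime means
for the insect:

* **ERI** (establishment risk index): the fraction of the 365-day year
  on which every immature stage is viable — positive development rate
  and survivable mortality at the day's mean temperature.  An
  alternative convention (the mean daily product of stage survivals)
  is available via ``method="survival"``.
* **GI** (generation index): potential generations per year,
  ``sum_x 1/T(x)`` over start days x = 1..365, where T(x) is the
  rate-summation generation length — egg-to-adult development plus the
  adult days until half the lifetime egg complement is laid — for a
  generation starting on day x, following the series cyclically.
  Start days whose generation cannot complete within two years
  contribute zero.
* **AI** (activity index): ``sum_x log10 lambda(tmean_x)``, the log10
  of the annual product of daily finite rates of increase; lambda(T)
  is read from a precomputed constant-temperature lookup (0.5 deg C
  grid, linear interpolation) and floored at ``lambda_floor`` where the
  population is non-viable.

Daily series are derived from monthly tmin/tmax normals by
piecewise-linear interpolation between mid-month anchors (the 15th),
wrapping December to January; ``tmean = (tmin + tmax)/2``.  A 365-day
year is used throughout (no leap handling; Julian day 1 = 1 January).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .curves import ValidationError, evaluate
from .grids import AlignmentError, ClimateGrid, GridSpec
from .simulation import PhenologyModel, life_table_parameters

N_DAYS = 365
#: first day-of-year of each month in a 365-day year
MONTH_START = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])
#: mid-month anchor day-of-year (the 15th of each month)
MONTH_ANCHOR = MONTH_START + 15

#: default classification breaks (low < b1 <= medium < b2 <= high)
DEFAULT_BREAKS = {"eri": (1.0 / 3.0, 2.0 / 3.0), "gi": (4.0, 8.0), "ai": (10.0, 25.0)}
#: km per degree at the equator (spherical approximation)
KM_PER_DEG_LON = 111.320
KM_PER_DEG_LAT = 110.574

GENERATION_CAP_DAYS = 2 * N_DAYS


@dataclass(frozen=True)
class DailySeries:
    """One synthetic year of daily temperatures (Julian days 1-365)."""

    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tmin", np.asarray(self.tmin, dtype=float))
        object.__setattr__(self, "tmax", np.asarray(self.tmax, dtype=float))
        if self.tmin.shape != (N_DAYS,) or self.tmax.shape != (N_DAYS,):
            raise ValidationError("daily series must hold exactly 365 values")
        if np.any(self.tmin > self.tmax):
            raise ValidationError("tmin exceeds tmax on some days")

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    @classmethod
    def constant(cls, T: float) -> "DailySeries":
        return cls(np.full(N_DAYS, float(T)), np.full(N_DAYS, float(T)))


def interpolate_daily(monthly_tmin, monthly_tmax) -> DailySeries:
    """Daily series from 12 monthly values, linear between mid-month anchors.

    Anchor days are the 15th of each month; the interpolation wraps
    December to January, so day 1 lies between the Dec-15 and Jan-15
    anchors.
    """
    tmin = np.asarray(monthly_tmin, dtype=float)
    tmax = np.asarray(monthly_tmax, dtype=float)
    if tmin.shape != (12,) or tmax.shape != (12,):
        raise ValidationError("need exactly 12 monthly tmin and tmax values")
    days = np.arange(1, N_DAYS + 1)
    # wrap: Dec anchor of the previous year and Jan anchor of the next
    anchors = np.concatenate([[MONTH_ANCHOR[-1] - N_DAYS], MONTH_ANCHOR, [MONTH_ANCHOR[0] + N_DAYS]])

    def interp(vals):
        ext = np.concatenate([[vals[-1]], vals, [vals[0]]])
        return np.interp(days, anchors, ext)

    return DailySeries(interp(tmin), interp(tmax))


# ---------------------------------------------------------------------------
# scalar indices
# ---------------------------------------------------------------------------


def _viability(model: PhenologyModel, tmean: np.ndarray):
    """Per-day development rates, mortalities and viability of immatures."""
    rates = [evaluate(st.development_rate, tmean) for st in model.stages]
    morts = [evaluate(st.mortality, tmean) for st in model.stages]
    viable = np.ones(len(tmean), dtype=bool)
    for r, m in zip(rates, morts):
        viable &= (r > 0) & (m < 1)
    return rates, morts, viable


def compute_eri(model: PhenologyModel, series: DailySeries, method: str = "binary") -> float:
    """Establishment risk index in [0, 1]."""
    rates, morts, viable = _viability(model, series.tmean)
    if method == "binary":
        return float(np.mean(viable))
    if method == "survival":
        surv = np.ones(N_DAYS)
        for m in morts:
            surv *= 1.0 - m
        return float(np.mean(surv))
    raise ValidationError(f"unknown ERI method {method!r}")


def _e_star(model: PhenologyModel) -> float:
    """Normalised reproductive age at which half the eggs are laid."""
    o = model.relative_oviposition

    def f(E):
        return evaluate(o, E) - 0.5

    if f(1.0) <= 0:
        return 1.0  # half-complement never reached before death; use full span
    return float(optimize.brentq(f, 1e-9, 1.0, xtol=1e-12))


def _advance(cumrate: np.ndarray, rate: np.ndarray, t0: np.ndarray, amount: float) -> np.ndarray:
    """Continuous completion times of an accumulation of *amount* started at t0.

    ``cumrate[k]`` is the rate sum over days [0, k); accumulation is
    linear within days.  Returns inf where the accumulation cannot
    complete inside the series.
    """
    n = len(rate)
    t0f = np.where(np.isfinite(t0), t0, 0.0)
    d0 = np.floor(t0f).astype(int)
    ok = np.isfinite(t0) & (d0 < n)
    d0c = np.clip(d0, 0, n - 1)
    base = cumrate[d0c] + (t0f - d0c) * rate[d0c]
    target = base + amount
    j = np.searchsorted(cumrate, target, side="left")
    out = np.full(t0.shape, np.inf)
    inside = ok & (j <= n)
    jj = np.clip(j, 1, n)
    exact = inside & (cumrate[np.clip(j, 0, n)] == target)
    out[exact] = j[exact].astype(float)
    part = inside & ~exact
    r_at = rate[np.clip(jj - 1, 0, n - 1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (target - cumrate[jj - 1]) / r_at
    cand = (jj - 1) + frac
    good = part & (r_at > 0) & np.isfinite(cand)
    out[good] = cand[good]
    return out


def generation_lengths(model: PhenologyModel, series: DailySeries) -> np.ndarray:
    """Generation length T(x) in days for each start day x = 1..365.

    Rate summation along the cyclically repeated series: egg, larva and
    pupa development to completion, then adult senescence accumulation
    to the median-oviposition age.  inf where the generation does not
    complete within two years.
    """
    reps = 4  # enough wrapped years to cover start day 365 + a 2-year cap
    tmean = np.tile(series.tmean, reps)
    rates = [evaluate(st.development_rate, tmean) for st in model.stages]
    morts = [evaluate(st.mortality, tmean) for st in model.stages]
    sen = evaluate(model.female_senescence, tmean)
    e_star = _e_star(model)

    t = np.arange(N_DAYS, dtype=float)  # start times (day x-1 at 00:00)
    start = t.copy()
    for r, m in zip(rates, morts):
        # a stage is blocked on days with certain death; zero its rate there
        r = np.where(m >= 1.0, 0.0, r)
        cum = np.concatenate([[0.0], np.cumsum(r)])
        t = _advance(cum, r, t, 1.0)
    cum_s = np.concatenate([[0.0], np.cumsum(sen)])
    t = _advance(cum_s, sen, t, e_star)
    length = t - start
    length[length > GENERATION_CAP_DAYS] = np.inf
    return length


def compute_gi(model: PhenologyModel, series: DailySeries) -> float:
    """Generation index: mean potential generations per year."""
    lengths = generation_lengths(model, series)
    with np.errstate(divide="ignore"):
        contrib = np.where(np.isfinite(lengths), 1.0 / lengths, 0.0)
    return float(np.sum(contrib))


@dataclass
class LambdaLookup:
    """Constant-temperature finite rate of increase on a regular grid."""

    temps: np.ndarray
    lams: np.ndarray
    lambda_floor: float

    @classmethod
    def build(
        cls,
        model: PhenologyModel,
        t_lo: float,
        t_hi: float,
        step: float = 0.5,
        lambda_floor: float = 0.5,
    ) -> "LambdaLookup":
        temps = np.arange(math.floor(t_lo / step) * step, t_hi + step, step)
        lams = np.empty_like(temps)
        for i, T in enumerate(temps):
            p = life_table_parameters(model, float(T), mode="deterministic")
            lam = p.lam if p.status == "ok" else lambda_floor
            lams[i] = max(lam, lambda_floor)
        return cls(temps=temps, lams=lams, lambda_floor=lambda_floor)

    def __call__(self, T) -> np.ndarray:
        return np.interp(T, self.temps, self.lams, left=self.lambda_floor, right=self.lambda_floor)


def compute_ai(
    model: PhenologyModel,
    series: DailySeries,
    lookup: LambdaLookup | None = None,
    lambda_floor: float = 0.5,
    step: float = 0.5,
) -> float:
    """Activity index: log10 of the annual product of daily lambda."""
    tmean = series.tmean
    if lookup is None:
        lookup = LambdaLookup.build(
            model, float(tmean.min()), float(tmean.max()), step=step, lambda_floor=lambda_floor
        )
    return float(np.sum(np.log10(lookup(tmean))))


# ---------------------------------------------------------------------------
# raster application
# ---------------------------------------------------------------------------


@dataclass
class RiskSurface:
    """Per-pixel ERI/GI/AI on a geographic grid (NaN where nodata)."""

    eri: np.ndarray
    gi: np.ndarray
    ai: np.ndarray
    spec: GridSpec
    classes: dict = field(default_factory=dict)

    def index(self, name: str) -> np.ndarray:
        return {"eri": self.eri, "gi": self.gi, "ai": self.ai}[name]


def map_indices(
    model: PhenologyModel,
    climate: ClimateGrid,
    lambda_floor: float = 0.5,
    lambda_step: float = 0.5,
    eri_method: str = "binary",
) -> RiskSurface:
    """Compute the three risk indices for every valid pixel of *climate*."""
    spec = climate.spec
    mask = climate.valid_mask
    shape = (spec.nrows, spec.ncols)
    eri = np.full(shape, np.nan)
    gi = np.full(shape, np.nan)
    ai = np.full(shape, np.nan)
    if mask.any():
        tmin_v = climate.tmin[:, mask]
        tmax_v = climate.tmax[:, mask]
        tmean_lo = 0.5 * (tmin_v + tmax_v).min()
        tmean_hi = 0.5 * (tmin_v + tmax_v).max()
        lookup = LambdaLookup.build(
            model, tmean_lo - 1.0, tmean_hi + 1.0, step=lambda_step, lambda_floor=lambda_floor
        )
        rows, cols = np.where(mask)
        for rr, cc in zip(rows, cols):
            series = interpolate_daily(climate.tmin[:, rr, cc], climate.tmax[:, rr, cc])
            eri[rr, cc] = compute_eri(model, series, method=eri_method)
            gi[rr, cc] = compute_gi(model, series)
            ai[rr, cc] = compute_ai(model, series, lookup=lookup)
    return RiskSurface(eri=eri, gi=gi, ai=ai, spec=spec)


def pixel_areas_km2(spec: GridSpec) -> np.ndarray:
    """Spherical-approximation pixel areas: 111.320*dlon * 110.574*dlat * cos(lat)."""
    lat = np.deg2rad(spec.lat_centers())
    row_area = (
        KM_PER_DEG_LON * spec.cellsize * KM_PER_DEG_LAT * spec.cellsize * np.cos(lat)
    )
    return np.repeat(row_area[:, None], spec.ncols, axis=1)


def classify_and_area(surface: RiskSurface, breaks: dict | None = None) -> pd.DataFrame:
    """Classify each index into low/medium/high and account class areas.

    ``breaks`` maps index name to two strictly increasing cut points.
    Class codes stored on the surface: 0 nodata, 1 low, 2 medium,
    3 high.  Returns a frame (index, class, area_km2).
    """
    breaks = {**DEFAULT_BREAKS, **(breaks or {})}
    areas = pixel_areas_km2(surface.spec)
    rows = []
    for name in ("eri", "gi", "ai"):
        b1, b2 = breaks[name]
        if not b1 < b2:
            raise ValidationError(f"breaks for {name} must be strictly increasing")
        vals = surface.index(name)
        classed = np.zeros(vals.shape, dtype=np.uint8)
        finite = np.isfinite(vals)
        classed[finite & (vals < b1)] = 1
        classed[finite & (vals >= b1) & (vals < b2)] = 2
        classed[finite & (vals >= b2)] = 3
        surface.classes[name] = classed
        for code, label in ((1, "low"), (2, "medium"), (3, "high")):
            rows.append(
                {
                    "index": name,
                    "class": label,
                    "area_km2": float(areas[classed == code].sum()),
                }
            )
    return pd.DataFrame(rows)


def area_change(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-(index, class) area differences between two scenarios (b - a)."""
    a = table_a.set_index(["index", "class"])["area_km2"]
    b = table_b.set_index(["index", "class"])["area_km2"]
    out = (b - a).reset_index().rename(columns={"area_km2": "change_km2"})
    return out
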