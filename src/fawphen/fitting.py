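"""Nonlinear least-squares fitting of temperature-response curves.

Fits any catalog curve to (temperature, response) points by multi-start
nonlinear least squares (16 Latin-hypercube starts within the catalog's
default parameter box plus one data-driven heuristic start), ranks
competing fits by AIC with an R-squared tie-break, and fits the logit
development-time distribution by maximum likelihood.

AIC is computed as ``n*ln(RSS/n) + 2k`` with k the number of curve
parameters; the p-value is from the F-test of the fitted curve against
the mean-only model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .curves import (
    CatalogEntry,
    ResponseFunction,
    ValidationError,
    catalog_entry,
)

logger = logging.getLogger(__name__)

#: Internal seed for the Latin-hypercube start points; fitting is a
#: deterministic function of its inputs.
_LHS_SEED = 20240506
_N_STARTS = 16
_MAX_ITER = 500
_XTOL = 1e-12
_FTOL = 1e-10

#: Cap for the logit slope when durations are (numerically) a point mass.
B_MAX = 1e4


@dataclass
class FitResult:
    """Outcome of one nonlinear least-squares fit."""

    fn: ResponseFunction
    r_squared: float
    aic: float
    df: int
    p_value: float
    residuals: np.ndarray
    converged: bool
    rss: float = math.nan
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.fn.name,
            "family": self.fn.family,
            "params": {k: float(v) for k, v in self.fn.params.items()},
            "fit_stats": {
                "R2": float(self.r_squared),
                "AIC": float(self.aic),
                "df": int(self.df),
                "p": float(self.p_value),
            },
            "converged": bool(self.converged),
        }


def _starts(entry: CatalogEntry, x, y) -> list[dict]:
    bounds = entry.default_bounds(x, y)
    names = entry.param_names
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=_LHS_SEED)
    unit = sampler.random(_N_STARTS)
    pts = lo + unit * (hi - lo)
    starts = [dict(zip(names, p)) for p in pts]
    heur = entry.initializer(x, y)
    heur = {n: float(np.clip(heur[n], bounds[n][0], bounds[n][1])) for n in names}
    return [heur] + starts


def fit_response(
    name: str,
    points,
    weights=None,
    family: str | None = None,
    temp_domain=None,
) -> FitResult:
    """Fit the named catalog curve to (x, y) points by least squares.

    Parameters
    ----------
    name
        Catalog identifier of the curve to fit.
    points
        Sequence of (x, y) pairs, or a DataFrame whose first two columns
        are x and y.
    weights
        Optional per-point weights; residuals are scaled by sqrt(w).
        Invariant to affine rescaling of the weights.
    family
        Family to record on the fitted function (defaults to the
        catalog's primary family for the curve).
    temp_domain
        Validity interval recorded on the fitted function; defaults to
        the observed x-range padded by 2 degrees.

    Returns
    -------
    FitResult
        With ``converged=False`` (never an exception) if no start
        converges.
    """
    entry = catalog_entry(name)
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    n = len(x)
    k = len(entry.param_names)
    if n < k + 1:
        raise ValidationError(
            f"{name!r} has {k} parameters; need at least {k + 1} points, got {n}"
        )
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        w = w / w.mean()  # affine-invariant normalisation
    sw = np.sqrt(w)

    names = entry.param_names
    bounds = entry.default_bounds(x, y)
    lo = np.array([bounds[nm][0] for nm in names])
    hi = np.array([bounds[nm][1] for nm in names])

    def residual(theta):
        p = dict(zip(names, theta))
        with np.errstate(over="ignore", invalid="ignore"):
            pred = entry.raw(p, x)
        pred = np.nan_to_num(pred, nan=1e6, posinf=1e6, neginf=-1e6)
        return sw * (pred - y)

    def _solve(theta0, max_nfev):
        try:
            sol = optimize.least_squares(
                residual,
                theta0,
                bounds=(lo, hi),
                method="trf",
                x_scale=np.maximum(hi - lo, 1e-12),
                xtol=_XTOL,
                ftol=_FTOL,
                max_nfev=max_nfev,
            )
        except Exception:  # numerical failure on this start only
            return None
        if not np.all(np.isfinite(sol.x)):
            return None
        return sol

    # phase 1: cheap exploration from every start; phase 2: full refinement
    # of the three most promising solutions
    explored = []
    for start in _starts(entry, x, y):
        theta0 = np.clip([start[nm] for nm in names], lo, hi)
        sol = _solve(theta0, max_nfev=30 * (k + 1))
        if sol is not None:
            explored.append((float(2 * sol.cost), sol))
    explored.sort(key=lambda t: t[0])
    best = None
    for _, rough in explored[:3]:
        sol = _solve(rough.x, max_nfev=_MAX_ITER * (k + 1))
        if sol is None:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-14:
            best = (rss, sol)

    ybar = float(np.average(y, weights=w))
    tss = float(np.sum(w * (y - ybar) ** 2))
    df = n - k

    if best is None:
        heur = entry.initializer(x, y)
        theta = np.clip([heur[nm] for nm in names], lo, hi)
        fn = ResponseFunction(
            name=name,
            family=family or _primary_family(entry),
            params=dict(zip(names, (float(v) for v in theta))),
            temp_domain=_default_domain(x, temp_domain),
        )
        return FitResult(
            fn=fn, r_squared=-math.inf, aic=math.inf, df=df, p_value=1.0,
            residuals=np.full(n, np.nan), converged=False, rss=math.inf, n_points=n,
        )

    rss, sol = best
    params = dict(zip(names, (float(v) for v in sol.x)))
    fn = ResponseFunction(
        name=name,
        family=family or _primary_family(entry),
        params=params,
        temp_domain=_default_domain(x, temp_domain),
    )
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else -math.inf)
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
    p_value = _f_test_p(rss, tss, n, k)
    return FitResult(
        fn=fn,
        r_squared=r2,
        aic=aic,
        df=df,
        p_value=p_value,
        residuals=sol.fun / sw,
        converged=bool(sol.success or sol.status > 0),
        rss=rss,
        n_points=n,
    )


def _primary_family(entry: CatalogEntry) -> str:
    order = [
        "development_rate",
        "mortality",
        "total_fecundity",
        "senescence",
        "relative_oviposition",
        "time_distribution",
    ]
    for fam in order:
        if fam in entry.families:
            return fam
    return next(iter(entry.families))


def _default_domain(x, temp_domain):
    if temp_domain is not None:
        return tuple(temp_domain)
    return (float(np.min(x)) - 2.0, float(np.max(x)) + 2.0)


def _f_test_p(rss: float, tss: float, n: int, k: int) -> float:
    df1, df2 = max(k - 1, 1), n - k
    if df2 <= 0 or tss <= rss:
        return 1.0
    if rss <= 1e-300:
        return 0.0
    f = ((tss - rss) / df1) / (rss / df2)
    return float(stats.f.sf(f, df1, df2))


def rank_models(fits) -> list[FitResult]:
    """Order fits: converged before non-converged, then ascending AIC,
    ties (|dAIC| < 0.01) broken by descending R-squared."""
    fits = list(fits)
    if not fits:
        raise ValidationError("rank_models requires at least one fit")

    def key(fr: FitResult):
        # quantize AIC so that near-ties fall back on R^2
        aic_q = round(fr.aic / 0.01) * 0.01 if math.isfinite(fr.aic) else math.inf
        return (not fr.converged, aic_q, -fr.r_squared)

    return sorted(fits, key=key)


def fit_report(fits) -> pd.DataFrame:
    """Human-readable comparison table for a set of fits."""
    rows = []
    for fr in rank_models(fits):
        rows.append(
            {
                "model": fr.fn.name,
                "params": ", ".join(f"{k}={v:.5g}" for k, v in fr.fn.params.items()),
                "R2": fr.r_squared,
                "AIC": fr.aic,
                "df": fr.df,
                "p": fr.p_value,
                "converged": fr.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# development-time distribution (logit CDF in log time)
# ---------------------------------------------------------------------------


@dataclass
class DevTimeDistribution:
    """Logit development-time distribution, F(x) = 1/(1+exp(-(a + b ln x))).

    Equivalent to ln(t) following a logistic distribution with location
    ``-a/b`` and scale ``1/b``; the median time is ``exp(-a/b)``.  In
    ``absolute`` mode a common slope b is shared across temperatures
    with one intercept per temperature; in ``normalized`` mode times are
    pre-divided by the per-temperature median and a single intercept
    (approximately 0) is fitted.
    """

    stage: str
    slope_b: float
    intercepts: dict = field(default_factory=dict)
    mode: str = "normalized"
    degenerate: bool = False

    def median(self, temperature=None) -> float:
        a = self.intercepts[temperature] if temperature is not None else next(
            iter(self.intercepts.values())
        )
        return math.exp(-a / self.slope_b)


def fit_dev_time_distribution(times, mode: str = "normalized", stage: str = "") -> DevTimeDistribution:
    """Maximum-likelihood fit of the logit time distribution.

    Parameters
    ----------
    times
        In ``normalized`` mode: a 1-d array of normalised durations or
        the frame produced by :func:`fawphen.life_tables.normalized_times`.
        In ``absolute`` mode: a DataFrame with columns
        ``temperature_C`` and a duration column (``x`` or
        ``duration_days``).
    mode
        ``"normalized"`` or ``"absolute"``.

    Notes
    -----
    ln(t) ~ logistic(mu, s) with b = 1/s and a = -mu/b.  A point mass
    of durations makes the ML slope diverge; it is capped at
    ``B_MAX = 1e4`` and the result flagged ``degenerate``.
    """
    if mode not in ("normalized", "absolute"):
        raise ValidationError(f"unknown mode {mode!r}")

    if isinstance(times, pd.DataFrame):
        col = "x" if "x" in times.columns else "duration_days"
        if mode == "absolute":
            groups = {
                float(t): g[col].to_numpy(dtype=float)
                for t, g in times.groupby("temperature_C")
            }
        else:
            groups = {None: times[col].to_numpy(dtype=float)}
    else:
        groups = {None: np.asarray(times, dtype=float)}

    all_t = np.concatenate(list(groups.values()))
    if len(all_t) < 5:
        raise ValidationError("need at least 5 completed durations")
    if np.any(all_t <= 0):
        raise ValidationError("durations must be positive")

    logs = {key: np.log(v) for key, v in groups.items()}
    pooled_spread = np.mean([np.std(v) for v in logs.values()])
    if pooled_spread < 1e-12:
        logger.warning("degenerate duration distribution (point mass); slope capped at %g", B_MAX)
        b = B_MAX
        intercepts = {key: -b * float(np.mean(v)) for key, v in logs.items()}
        return DevTimeDistribution(
            stage=stage, slope_b=b, intercepts=intercepts, mode=mode, degenerate=True
        )

    keys = list(logs.keys())

    def nll(theta):
        log_s = theta[0]
        s = math.exp(log_s)
        total = 0.0
        for mu, key in zip(theta[1:], keys):
            z = (logs[key] - mu) / s
            # logistic log-density: -z - 2*log1p(exp(-z)) - log s
            total -= np.sum(-z - 2 * np.logaddexp(0.0, -z) - log_s)
        return total

    theta0 = np.array([math.log(max(pooled_spread * math.sqrt(3) / math.pi, 1e-6))]
                      + [float(np.mean(logs[k])) for k in keys])
    sol = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    s = math.exp(sol.x[0])
    b = min(1.0 / s, B_MAX)
    intercepts = {key: -float(mu) * b for key, mu in zip(keys, sol.x[1:])}
    return DevTimeDistribution(
        stage=stage, slope_b=b, intercepts=intercepts, mode=mode, degenerate=b >= B_MAX
    )
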