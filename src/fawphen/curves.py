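"""Catalog of temperature-response functions for insect phenology models.

Each life-history trait (development rate, stage mortality, fecundity,
adult senescence, oviposition timing, development-time scatter) is
described by a named parametric curve.  The catalog collects the curve
families used for *Spodoptera frugiperda* — the Logan and Hilbert–Logan
development-rate models, the Wang mortality models, Gaussian fecundity
curves, exponential senescence — plus a Taylor-type and a linear
baseline for model comparison.

Conventions
-----------
* Temperatures are in degrees Celsius; rates are per day.
* Mortality outputs are clamped to [0, 1]; development, senescence and
  fecundity outputs are clamped to >= 0.
* Outside a function's ``temp_domain`` the convention is graceful
  degradation: development and fecundity evaluate to 0 and mortality to
  1, so that maps over extreme climates remain well defined.
* ``relative_oviposition`` curves take normalised reproductive age (not
  temperature) and ``time_distribution`` curves take a development time,
  so the domain convention does not apply to them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ResponseFunction",
    "CatalogEntry",
    "CATALOG",
    "FAMILIES",
    "catalog_entry",
    "evaluate",
    "evaluate_raw",
    "quantile_of_time_distribution",
    "logit_cdf",
    "response_to_dict",
    "response_from_dict",
    "write_model_json",
    "read_model_json",
]

FAMILIES = (
    "development_rate",
    "mortality",
    "total_fecundity",
    "relative_oviposition",
    "senescence",
    "time_distribution",
)

#: Families whose argument is a temperature in deg C (domain convention applies).
_TEMPERATURE_FAMILIES = frozenset(
    {"development_rate", "mortality", "total_fecundity", "senescence"}
)


class CatalogError(KeyError):
    """Raised when a response-function name is not in the catalog."""


class ValidationError(ValueError):
    """Raised for invalid parameters or arguments."""


@dataclass(frozen=True)
class ResponseFunction:
    """A named temperature-response curve with parameter values.

    Parameters
    ----------
    name
        Catalog identifier, e.g. ``"logan_1"``.
    family
        One of :data:`FAMILIES`.
    params
        Mapping parameter-name -> value.  Must contain exactly the
        parameters the named formula requires.
    temp_domain
        Closed interval (lo, hi) in deg C over which the curve is
        considered valid.  Ignored for non-temperature families.
    """

    name: str
    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    temp_domain: tuple[float, float] = (-100.0, 100.0)

    def __post_init__(self) -> None:
        entry = catalog_entry(self.name)
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family not in entry.families:
            raise ValidationError(
                f"{self.name!r} cannot be used as {self.family!r}; "
                f"allowed families: {sorted(entry.families)}"
            )
        given = set(self.params)
        wanted = set(entry.param_names)
        if given != wanted:
            raise ValidationError(
                f"{self.name!r} requires parameters {sorted(wanted)}, "
                f"got {sorted(given)}"
            )
        for key, value in self.params.items():
            if not math.isfinite(float(value)):
                raise ValidationError(f"parameter {key!r} of {self.name!r} is not finite")
        if not self.temp_domain[0] < self.temp_domain[1]:
            raise ValidationError("temp_domain must be an increasing interval")
        object.__setattr__(self, "params", dict(self.params))

    def __call__(self, x):
        return evaluate(self, x)

    def with_params(self, params: Mapping[str, float]) -> "ResponseFunction":
        return replace(self, params=dict(params))


@dataclass(frozen=True)
class CatalogEntry:
    """Registry record for one curve family.

    ``default_bounds`` are (low, high) boxes used by the fitting module's
    multi-start search; ``initializer`` maps observed (x, y) data to a
    heuristic start point.
    """

    name: str
    families: frozenset
    param_names: tuple
    formula_text: str
    raw: Callable
    default_bounds: Callable
    initializer: Callable


# ---------------------------------------------------------------------------
# raw formulas (no clamping; used by both evaluation and fitting)
# ---------------------------------------------------------------------------


def _logan_5(p, T):
    return p["alph"] * (
        1.0 / (1.0 + p["k"] * np.exp(-p["b"] * T))
        - np.exp(-(p["Tmax"] - T) / p["Dt"])
    )


def _hilbert_logan_2(p, T):
    return p["trid"] * (
        T**2 / (T**2 + p["D"]) - np.exp(-(p["Tmax"] - T) / p["Dt"])
    )


def _logan_1(p, T):
    return p["Y"] * (
        np.exp(p["p"] * T) - np.exp(p["p"] * p["Tmax"] - (p["Tmax"] - T) / p["v"])
    )


def _wang_core(T, lo, hi, B, H):
    acc = (1.0 + np.exp(-(T - lo) / B)) * (1.0 + np.exp(-(hi - T) / B))
    return 1.0 - np.exp(-acc * H)


def _wang_1(p, T):
    return _wang_core(T, p["Topt"], p["Topt"], p["B"], p["H"])


def _wang_2(p, T):
    return _wang_core(T, p["Tl"], p["Th"], p["B"], p["H"])


def _gaussian_log(p, T):
    ratio = np.abs(np.asarray(T, dtype=float) / p["x0"])
    with np.errstate(divide="ignore"):
        z = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)), -np.inf)
    return p["y0"] + p["a"] * np.exp(-0.5 * (z / p["b"]) ** 2)


def _gaussian(p, T):
    return p["y0"] + p["a"] * np.exp(-0.5 * ((T - p["x0"]) / p["b"]) ** 2)


def _hilbert_logan_3(p, T):
    u = T - p["Tmin"]
    return (
        p["trid"]
        * (u**2 / (u**2 + p["D"]) - np.exp(-(p["Tmax"] - u) / p["Dt"]))
        + p["Smin"]
    )


def _exponential_simple(p, T):
    return p["b1"] * np.exp(p["b2"] * T)


def _exponential_modified_1(p, E):
    E = np.asarray(E, dtype=float)
    return 1.0 - np.exp(-(p["a"] * E + p["b"] * E**2 + p["c"] * E**3))


def _logit_cdf(p, x):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        lnx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)
    return 1.0 / (1.0 + np.exp(-(p["a"] + p["b"] * lnx)))


def _taylor(p, T):
    # Gaussian-shaped rate model (Taylor): Rm * exp(-0.5*((T-Tm)/To)^2)
    return p["Rm"] * np.exp(-0.5 * ((T - p["Tm"]) / p["To"]) ** 2)


def _linear_rate(p, T):
    return p["a"] + p["b"] * np.asarray(T, dtype=float)


# ---------------------------------------------------------------------------
# default bounds and heuristic initializers (data-driven, used by fitting)
# ---------------------------------------------------------------------------


def _span(x):
    x = np.asarray(x, dtype=float)
    return float(x.min()), float(x.max())


def _b_logan_5(x, y):
    tlo, thi = _span(x)
    ymax = float(np.max(np.abs(y))) or 1.0
    return {
        "alph": (1e-6, 100 * ymax),
        "k": (1e-3, 1e6),
        "b": (1e-3, 2.0),
        "Tmax": (thi, thi + 25.0),
        "Dt": (0.1, 20.0),
    }


def _i_logan_5(x, y):
    tlo, thi = _span(x)
    return {"alph": 5 * float(np.max(y)), "k": 500.0, "b": 0.2, "Tmax": thi + 3.0, "Dt": 3.0}


def _b_hl2(x, y):
    tlo, thi = _span(x)
    return {
        "trid": (1e-3, 1e7),
        "D": (1.0, 1e10),
        "Tmax": (thi, thi + 60.0),
        "Dt": (0.1, 20.0),
    }


def _i_hl2(x, y):
    tlo, thi = _span(x)
    tm = 0.5 * (tlo + thi)
    D = 1e6
    ym = float(np.median(y))
    return {"trid": max(ym * (tm**2 + D) / tm**2, 1.0), "D": D, "Tmax": thi + 30.0, "Dt": 3.0}


def _b_logan_1(x, y):
    tlo, thi = _span(x)
    return {
        "Y": (1e-8, 10.0),
        "p": (1e-3, 0.5),
        "v": (0.01, 20.0),
        "Tmax": (thi, thi + 25.0),
    }


def _i_logan_1(x, y):
    tlo, thi = _span(x)
    p0 = 0.1
    ymid = float(np.median(y)) or 0.1
    return {"Y": ymid / math.exp(p0 * 0.5 * (tlo + thi)), "p": p0, "v": 0.5, "Tmax": thi + 2.0}


def _b_wang_1(x, y):
    tlo, thi = _span(x)
    return {"Topt": (tlo - 5.0, thi + 5.0), "B": (0.1, 20.0), "H": (1e-5, 2.0)}


def _i_wang_1(x, y):
    x = np.asarray(x, dtype=float)
    ymin = float(np.clip(np.min(y), 1e-6, 0.999))
    return {"Topt": float(x[np.argmin(y)]), "B": 2.0, "H": -math.log(1.0 - ymin) / 4.0}


def _b_wang_2(x, y):
    tlo, thi = _span(x)
    return {
        "Tl": (tlo - 10.0, thi + 5.0),
        "Th": (tlo - 10.0, thi + 10.0),
        "B": (0.1, 20.0),
        "H": (1e-5, 2.0),
    }


def _i_wang_2(x, y):
    start = _i_wang_1(x, y)
    return {"Tl": start["Topt"], "Th": start["Topt"], "B": start["B"], "H": start["H"]}


def _b_gaussian_log(x, y):
    tlo, thi = _span(x)
    ymax = float(np.max(np.abs(y))) or 1.0
    return {
        "y0": (-2 * ymax, 2 * ymax),
        "a": (-2 * ymax, 2 * ymax),
        "x0": (max(tlo - 10.0, 1.0), thi + 10.0),
        "b": (0.05, 10.0),
    }


def _i_gaussian_log(x, y):
    x = np.asarray(x, dtype=float)
    return {
        "y0": float(np.max(y)),
        "a": float(np.min(y) - np.max(y)),
        "x0": float(x[np.argmin(y)]),
        "b": 0.8,
    }


def _b_gaussian(x, y):
    # the amplitude is kept positive: this curve models peaked responses
    # (a thermal optimum); troughs belong to the mortality-family curves
    tlo, thi = _span(x)
    ymax = float(np.max(np.abs(y))) or 1.0
    return {
        "y0": (-3 * ymax, 3 * ymax),
        "a": (0.0, 3 * ymax),
        "x0": (tlo - 15.0, thi + 15.0),
        "b": (0.1, 5 * (thi - tlo + 1.0)),
    }


def _i_gaussian(x, y):
    x = np.asarray(x, dtype=float)
    tlo, thi = _span(x)
    return {
        "y0": 0.0,
        "a": float(np.max(y)),
        "x0": float(x[np.argmax(y)]),
        "b": max((thi - tlo) / 4.0, 1.0),
    }


def _b_hl3(x, y):
    tlo, thi = _span(x)
    ymax = float(np.max(np.abs(y))) or 1.0
    return {
        "trid": (1e-3, 1e9),
        "Tmax": (thi, thi + 40.0),
        "Tmin": (tlo - 30.0, thi),
        "D": (1.0, 1e12),
        "Dt": (1e-3, 20.0),
        "Smin": (0.0, 2 * ymax),
    }


def _i_hl3(x, y):
    tlo, thi = _span(x)
    D = 1e8
    return {
        "trid": 1e6,
        "Tmax": thi + 7.0,
        "Tmin": tlo + 1.0,
        "D": D,
        "Dt": 0.02,
        "Smin": float(np.min(y)),
    }


def _b_exponential_simple(x, y):
    ymax = float(np.max(np.abs(y))) or 1.0
    return {"b1": (1e-8, 10 * ymax), "b2": (-1.0, 1.0)}


def _i_exponential_simple(x, y):
    x = np.asarray(x, dtype=float)
    y = np.clip(np.asarray(y, dtype=float), 1e-9, None)
    slope, intercept = np.polyfit(x, np.log(y), 1)
    return {"b1": math.exp(intercept), "b2": float(slope)}


def _b_exp_mod1(x, y):
    return {"a": (-10.0, 10.0), "b": (-10.0, 20.0), "c": (-10.0, 20.0)}


def _i_exp_mod1(x, y):
    return {"a": 0.0, "b": 1.0, "c": 1.0}


def _b_logit(x, y):
    return {"a": (-200.0, 200.0), "b": (1e-3, 1e4)}


def _i_logit(x, y):
    return {"a": 0.0, "b": 5.0}


def _b_taylor(x, y):
    tlo, thi = _span(x)
    ymax = float(np.max(np.abs(y))) or 1.0
    return {"Rm": (1e-8, 10 * ymax), "Tm": (tlo - 10.0, thi + 10.0), "To": (0.5, 50.0)}


def _i_taylor(x, y):
    x = np.asarray(x, dtype=float)
    tlo, thi = _span(x)
    return {"Rm": float(np.max(y)), "Tm": float(x[np.argmax(y)]), "To": (thi - tlo) / 4.0}


def _b_linear(x, y):
    ymax = float(np.max(np.abs(y))) or 1.0
    return {"a": (-100 * ymax, 100 * ymax), "b": (-100 * ymax, 100 * ymax)}


def _i_linear(x, y):
    slope, intercept = np.polyfit(np.asarray(x, float), np.asarray(y, float), 1)
    return {"a": float(intercept), "b": float(slope)}


def _entry(name, families, params, formula, raw, bounds, init):
    return CatalogEntry(
        name=name,
        families=frozenset(families),
        param_names=tuple(params),
        formula_text=formula,
        raw=raw,
        default_bounds=bounds,
        initializer=init,
    )


CATALOG: dict[str, CatalogEntry] = {
    e.name: e
    for e in [
        _entry(
            "logan_5",
            {"development_rate"},
            ("alph", "k", "b", "Tmax", "Dt"),
            "r(T) = alph*(1/(1+k*exp(-b*T)) - exp(-(Tmax-T)/Dt))",
            _logan_5,
            _b_logan_5,
            _i_logan_5,
        ),
        _entry(
            "hilbert_logan_2",
            {"development_rate"},
            ("trid", "D", "Tmax", "Dt"),
            "r(T) = trid*(T^2/(T^2+D) - exp(-(Tmax-T)/Dt))",
            _hilbert_logan_2,
            _b_hl2,
            _i_hl2,
        ),
        _entry(
            "logan_1",
            {"development_rate"},
            ("Y", "p", "v", "Tmax"),
            "r(T) = Y*(exp(p*T) - exp(p*Tmax - (Tmax-T)/v))",
            _logan_1,
            _b_logan_1,
            _i_logan_1,
        ),
        _entry(
            "wang_1",
            {"mortality"},
            ("Topt", "B", "H"),
            "m(T) = 1 - exp(-(1+exp(-(T-Topt)/B))*(1+exp(-(Topt-T)/B))*H)",
            _wang_1,
            _b_wang_1,
            _i_wang_1,
        ),
        _entry(
            "wang_2",
            {"mortality"},
            ("Tl", "Th", "B", "H"),
            "m(T) = 1 - exp(-(1+exp(-(T-Tl)/B))*(1+exp(-(Th-T)/B))*H)",
            _wang_2,
            _b_wang_2,
            _i_wang_2,
        ),
        _entry(
            "gaussian_log",
            {"mortality"},
            ("y0", "a", "x0", "b"),
            "m(T) = y0 + a*exp(-0.5*(ln|T/x0|/b)^2)",
            _gaussian_log,
            _b_gaussian_log,
            _i_gaussian_log,
        ),
        _entry(
            "gaussian",
            {"total_fecundity", "mortality", "development_rate"},
            ("y0", "a", "x0", "b"),
            "f(T) = y0 + a*exp(-0.5*((T-x0)/b)^2)",
            _gaussian,
            _b_gaussian,
            _i_gaussian,
        ),
        _entry(
            "hilbert_logan_3",
            {"senescence"},
            ("trid", "Tmax", "Tmin", "D", "Dt", "Smin"),
            "s(T) = trid*((T-Tmin)^2/((T-Tmin)^2+D) - exp(-(Tmax-(T-Tmin))/Dt)) + Smin",
            _hilbert_logan_3,
            _b_hl3,
            _i_hl3,
        ),
        _entry(
            "exponential_simple",
            {"senescence"},
            ("b1", "b2"),
            "s(T) = b1*exp(b2*T)",
            _exponential_simple,
            _b_exponential_simple,
            _i_exponential_simple,
        ),
        _entry(
            "exponential_modified_1",
            {"relative_oviposition"},
            ("a", "b", "c"),
            "O(E) = 1 - exp(-(a*E + b*E^2 + c*E^3))",
            _exponential_modified_1,
            _b_exp_mod1,
            _i_exp_mod1,
        ),
        _entry(
            "logit_cdf",
            {"time_distribution"},
            ("a", "b"),
            "F(x) = 1/(1 + exp(-(a + b*ln x)))",
            _logit_cdf,
            _b_logit,
            _i_logit,
        ),
        _entry(
            "taylor",
            {"development_rate"},
            ("Rm", "Tm", "To"),
            "r(T) = Rm*exp(-0.5*((T-Tm)/To)^2)",
            _taylor,
            _b_taylor,
            _i_taylor,
        ),
        _entry(
            "linear",
            {"development_rate"},
            ("a", "b"),
            "r(T) = a + b*T",
            _linear_rate,
            _b_linear,
            _i_linear,
        ),
    ]
}


def catalog_entry(name: str) -> CatalogEntry:
    """Look up a catalog entry by name; raise :class:`CatalogError` if absent."""
    try:
        return CATALOG[name]
    except KeyError:
        raise CatalogError(f"unknown response function {name!r}") from None


def evaluate_raw(fn: ResponseFunction, x):
    """Evaluate the bare formula with no clamping or domain convention.

    Used internally by the fitting module, where clamping would destroy
    gradients, and for diagnostics.
    """
    return catalog_entry(fn.name).raw(fn.params, np.asarray(x, dtype=float))


def evaluate(fn: ResponseFunction, x):
    """Evaluate *fn* at *x* with family clamps and the domain convention.

    Clamps: mortality to [0, 1]; development, senescence, fecundity to
    >= 0; probabilities to [0, 1].  Outside ``temp_domain``:
    development, fecundity and senescence evaluate to 0, mortality to 1.
    Returns a scalar for scalar input, an array otherwise.
    """
    scalar = np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0)
    xv = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xv)):
        raise ValidationError("evaluation point must be finite")
    y = np.asarray(catalog_entry(fn.name).raw(fn.params, xv), dtype=float)

    fam = fn.family
    if fam == "mortality":
        y = np.clip(y, 0.0, 1.0)
    elif fam in ("development_rate", "senescence", "total_fecundity"):
        y = np.clip(y, 0.0, None)
    elif fam in ("relative_oviposition", "time_distribution"):
        y = np.clip(y, 0.0, 1.0)

    if fam in _TEMPERATURE_FAMILIES:
        lo, hi = fn.temp_domain
        outside = (xv < lo) | (xv > hi)
        if np.any(outside):
            fill = 1.0 if fam == "mortality" else 0.0
            y = np.where(outside, fill, y)
    if scalar:
        return float(y)
    return y


def logit_cdf(a: float, b: float, x):
    """Cumulative logit distribution in log time, F(x) = 1/(1+exp(-(a+b ln x)))."""
    return _logit_cdf({"a": a, "b": b}, x)


def quantile_of_time_distribution(a: float, b: float, u: float) -> float:
    """Invert the logit development-time CDF: the time x with F(x) = u.

    The median (u = 0.5) is ``exp(-a/b)``.

    Parameters
    ----------
    a, b
        Intercept and slope of the logit CDF in log time; ``b > 0``.
    u
        Probability strictly inside (0, 1).
    """
    if not 0.0 < u < 1.0:
        raise ValidationError(f"quantile level u={u} outside (0, 1)")
    if b <= 0:
        raise ValidationError(f"slope b={b} must be positive")
    return math.exp((math.log(u / (1.0 - u)) - a) / b)


# ---------------------------------------------------------------------------
# JSON serialization of fitted response functions
# ---------------------------------------------------------------------------


def response_to_dict(fn: ResponseFunction, stage: str | None = None, fit_stats=None) -> dict:
    d = {
        "name": fn.name,
        "family": fn.family,
        "params": {k: float(v) for k, v in fn.params.items()},
        "temp_domain": [float(fn.temp_domain[0]), float(fn.temp_domain[1])],
    }
    if stage is not None:
        d["stage"] = stage
    if fit_stats is not None:
        d["fit_stats"] = fit_stats
    return d


def response_from_dict(d: Mapping) -> ResponseFunction:
    return ResponseFunction(
        name=d["name"],
        family=d["family"],
        params=dict(d["params"]),
        temp_domain=tuple(d.get("temp_domain", (-100.0, 100.0))),
    )


def write_model_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model_json(path):
    return json.loads(Path(path).read_text())
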