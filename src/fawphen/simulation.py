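"""Cohort phenology simulation and life-table parameters.

A :class:`PhenologyModel` composes the fitted temperature responses of
the immature stages (development rate, mortality, development-time
scatter) with the adult components (senescence, total fecundity,
relative oviposition) into a simulable life cycle.

Two computational paths produce age schedules (x, l_x, m_x):

* a deterministic schedule builder using rate summation with exact
  (fractional-day) stage boundaries — fast, smooth in temperature, used
  for constant-temperature life-table parameters and the lambda(T)
  lookup behind the activity index;
* an individual-based daily simulation (:func:`simulate_cohort`) with
  sampled development thresholds and Bernoulli survival — the
  stochastic analogue of the deterministic path.

Life-table parameters follow the classical definitions: net
reproductive rate Ro = sum l_x m_x (daughters per newborn female),
gross reproductive rate GRR = sum M_x (no survival discount), intrinsic
rate of increase rm solving the Euler-Lotka equation
sum exp(-rm x) l_x m_x = 1, mean generation time Tc = ln(Ro)/rm,
finite rate lambda = exp(rm) and doubling time Dt = ln(2)/rm.

Daily mechanics
---------------
Each individual accumulates physiological age r_s(T_d) per day in stage
s and transitions when the accumulation reaches its development
threshold (1 at the median; sampled from the stage's logit distribution
in stochastic mode).  Daily survival is (1 - m_s(T_d))**r_s(T_d), so
the product over a full stage at constant temperature equals
1 - m_s(T).  Adults accumulate senescence s(T_d) and die when the
accumulation reaches their threshold; a female's daily egg output is
F(T_d) * [O(E_d) - O(E_{d-1})] with E her cumulative senescence
(physiological reproductive age), so oviposition compresses at warm
temperatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .curves import (
    ResponseFunction,
    ValidationError,
    evaluate,
    response_from_dict,
    response_to_dict,
)

IMMATURE_STAGES = ("egg", "larva", "pupa")

#: adult-age integration step (days) for the deterministic schedule
_ADULT_DT = 0.1
#: cohort-size floor used when reporting the decline rate of a
#: non-viable population
_N_FLOOR = 1e-12


class HorizonError(RuntimeError):
    """The temperature series ended before the cohort completed."""


class NoReproductionError(ValueError):
    """Euler-Lotka is undefined when the net maternity schedule is zero."""


@dataclass(frozen=True)
class StageModel:
    """Temperature responses of one immature stage."""

    name: str
    development_rate: ResponseFunction
    mortality: ResponseFunction
    time_slope: float = 50.0  # logit slope of normalised dev-time scatter

    def __post_init__(self):
        if self.development_rate.family != "development_rate":
            raise ValidationError(f"{self.name}: development_rate has wrong family")
        if self.mortality.family != "mortality":
            raise ValidationError(f"{self.name}: mortality has wrong family")
        if not self.time_slope > 0:
            raise ValidationError(f"{self.name}: time_slope must be positive")


@dataclass(frozen=True)
class PhenologyModel:
    """Composed temperature-dependent life cycle (egg -> larva -> pupa -> adult)."""

    egg: StageModel
    larva: StageModel
    pupa: StageModel
    female_senescence: ResponseFunction
    male_senescence: ResponseFunction
    total_fecundity: ResponseFunction
    relative_oviposition: ResponseFunction
    sex_ratio: float = 0.5
    female_time_slope: float = 10.0
    male_time_slope: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValidationError("sex_ratio must be in (0, 1)")
        for fn, fam in [
            (self.female_senescence, "senescence"),
            (self.male_senescence, "senescence"),
            (self.total_fecundity, "total_fecundity"),
            (self.relative_oviposition, "relative_oviposition"),
        ]:
            if fn.family != fam:
                raise ValidationError(f"component {fn.name!r} must have family {fam!r}")

    @property
    def stages(self) -> tuple[StageModel, StageModel, StageModel]:
        return (self.egg, self.larva, self.pupa)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "stages": {
                st.name: {
                    "development_rate": response_to_dict(st.development_rate),
                    "mortality": response_to_dict(st.mortality),
                    "time_slope": st.time_slope,
                }
                for st in self.stages
            },
            "adult": {
                "female_senescence": response_to_dict(self.female_senescence),
                "male_senescence": response_to_dict(self.male_senescence),
                "total_fecundity": response_to_dict(self.total_fecundity),
                "relative_oviposition": response_to_dict(self.relative_oviposition),
                "female_time_slope": self.female_time_slope,
                "male_time_slope": self.male_time_slope,
            },
            "sex_ratio": self.sex_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhenologyModel":
        stages = {
            name: StageModel(
                name=name,
                development_rate=response_from_dict(sd["development_rate"]),
                mortality=response_from_dict(sd["mortality"]),
                time_slope=float(sd.get("time_slope", 50.0)),
            )
            for name, sd in d["stages"].items()
        }
        adult = d["adult"]
        return cls(
            egg=stages["egg"],
            larva=stages["larva"],
            pupa=stages["pupa"],
            female_senescence=response_from_dict(adult["female_senescence"]),
            male_senescence=response_from_dict(adult["male_senescence"]),
            total_fecundity=response_from_dict(adult["total_fecundity"]),
            relative_oviposition=response_from_dict(adult["relative_oviposition"]),
            sex_ratio=float(d.get("sex_ratio", 0.5)),
            female_time_slope=float(adult.get("female_time_slope", 10.0)),
            male_time_slope=float(adult.get("male_time_slope", 10.0)),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "PhenologyModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LifeTableParameters:
    """Demographic summary of one thermal environment.

    rm: intrinsic rate of increase (1/day); Ro: net reproductive rate
    (daughters/female); GRR: gross reproductive rate; Tc: mean
    generation time (days); lam: finite rate of increase per day;
    Dt: doubling time (days).  ``status`` is ``"ok"`` or
    ``"non-viable"`` (rm then reports the cohort's exponential decline
    and the reproductive quantities are zero).
    """

    rm: float
    Ro: float
    GRR: float
    Tc: float
    lam: float
    Dt: float
    status: str = "ok"

    @classmethod
    def from_rm_ro(cls, rm: float, Ro: float, GRR: float = math.nan, status: str = "ok"):
        """Complete the identity set lam=e^rm, Dt=ln2/rm, Tc=ln(Ro)/rm."""
        lam = math.exp(rm)
        Dt = math.log(2.0) / rm if rm != 0 else math.inf
        Tc = math.log(Ro) / rm if (Ro > 0 and rm != 0) else math.nan
        return cls(rm=rm, Ro=Ro, GRR=GRR, Tc=Tc, lam=lam, Dt=Dt, status=status)

    @classmethod
    def from_schedule(cls, x, lx, mx, GRR: float | None = None):
        x = np.asarray(x, dtype=float)
        lx = np.asarray(lx, dtype=float)
        mx = np.asarray(mx, dtype=float)
        Ro = float(np.sum(lx * mx))
        if Ro <= 0:
            raise NoReproductionError("schedule has no net reproduction")
        rm = euler_lotka_solve(x, lx, mx)
        grr = float(np.sum(mx)) if GRR is None else float(GRR)
        return cls.from_rm_ro(rm=rm, Ro=Ro, GRR=grr)

    def to_dict(self) -> dict:
        return {
            "rm": self.rm, "Ro": self.Ro, "GRR": self.GRR,
            "Tc": self.Tc, "lambda": self.lam, "Dt": self.Dt, "status": self.status,
        }


def euler_lotka_solve(x, lx, mx=None) -> float:
    """Solve sum exp(-rm x) l_x m_x = 1 for the intrinsic rate rm.

    Bracketing + Brent's method followed by a Newton polish; the
    residual at the returned root is below 1e-10.  ``mx`` may be
    omitted if ``lx`` already holds the net maternity l_x*m_x.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(lx, dtype=float) * (1.0 if mx is None else np.asarray(mx, dtype=float))
    keep = phi > 0
    if not np.any(keep):
        raise NoReproductionError("all m_x are zero")
    x, phi = x[keep], phi[keep]
    if np.any(x <= 0):
        raise ValidationError("ages must be positive")

    def f(r):
        return float(np.sum(np.exp(-r * x) * phi) - 1.0)

    lo, hi = -1.0, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValidationError("Euler-Lotka root not bracketed from above")
    while f(lo) < 0:
        lo *= 2.0
        if lo < -1e3:
            raise ValidationError("Euler-Lotka root not bracketed from below")
    rm = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    # Newton polish
    for _ in range(3):
        deriv = float(np.sum(-x * np.exp(-rm * x) * phi))
        if deriv == 0:
            break
        step = f(rm) / deriv
        rm -= step
        if abs(step) < 1e-15:
            break
    return float(rm)


# ---------------------------------------------------------------------------
# deterministic schedules
# ---------------------------------------------------------------------------


def _stage_arrays(model: PhenologyModel, temps: np.ndarray):
    rates = [evaluate(st.development_rate, temps) for st in model.stages]
    morts = [evaluate(st.mortality, temps) for st in model.stages]
    return rates, morts


def constant_schedule(model: PhenologyModel, T: float):
    """Deterministic net-maternity schedule at a constant temperature.

    Returns ``(x, lx, mx)`` with continuous stage boundaries (duration
    1/r_s), immature survival prod(1 - m_s), and the adult reproduction
    schedule on a 0.1-day grid, or ``None`` when the environment is
    non-viable (no development, certain death, or zero fecundity).
    """
    T = float(T)
    rates = [evaluate(st.development_rate, T) for st in model.stages]
    morts = [evaluate(st.mortality, T) for st in model.stages]
    if min(rates) <= 0 or max(morts) >= 1:
        return None
    dev_days = sum(1.0 / r for r in rates)
    l_im = float(np.prod([1.0 - m for m in morts]))
    s = evaluate(model.female_senescence, T)
    fec = evaluate(model.total_fecundity, T)
    if s <= 0 or fec <= 0:
        return None
    lifespan = 1.0 / s  # deterministic death at cumulative senescence 1
    tau = np.arange(_ADULT_DT, lifespan + _ADULT_DT, _ADULT_DT)
    e_hi = np.minimum(tau * s, 1.0)
    e_lo = np.minimum((tau - _ADULT_DT) * s, 1.0)
    o = model.relative_oviposition
    mx = fec * np.clip(evaluate(o, e_hi) - evaluate(o, e_lo), 0.0, None) * model.sex_ratio
    x = dev_days + tau
    lx = np.full_like(x, l_im)
    return x, lx, mx


def series_schedule(model: PhenologyModel, temps):
    """Deterministic daily schedule for a cohort starting on day 0 of *temps*.

    Rate summation with fractional-day stage boundaries; returns
    ``(x, lx, mx)`` on a daily grid or ``None`` if non-viable within
    the series.
    """
    temps = np.asarray(temps, dtype=float)
    n = len(temps)
    rates, morts = _stage_arrays(model, temps)
    # walk through immature stages with fractional-day boundaries
    t = 0.0  # continuous age in days
    log_l = 0.0
    for r, m in zip(rates, morts):
        need = 1.0
        while need > 1e-12:
            d = int(t)
            if d >= n:
                return None
            frac_left = (d + 1) - t
            if m[d] >= 1.0:
                return None
            gain = r[d] * frac_left
            if gain <= 0 and r[d] <= 0:
                # no development this day; mortality still applies
                log_l += frac_left * math.log(max(1.0 - m[d], _N_FLOOR)) * max(r[d], 0.0)
                t = d + 1.0
                continue
            if gain >= need:
                used = need / r[d]
                log_l += r[d] * used * math.log(1.0 - m[d])
                t += used
                need = 0.0
            else:
                log_l += r[d] * frac_left * math.log(1.0 - m[d])
                t = d + 1.0
                need -= gain
    l_im = math.exp(log_l)
    dev_days = t
    s_daily = evaluate(model.female_senescence, temps)
    fec_daily = evaluate(model.total_fecundity, temps)
    o = model.relative_oviposition
    xs, mxs = [], []
    e = 0.0
    d = int(math.ceil(dev_days))
    age = float(d)
    while e < 1.0:
        if d >= n:
            return None
        e_next = min(e + max(s_daily[d], 1e-6), 1.0)
        eggs = fec_daily[d] * max(evaluate(o, e_next) - evaluate(o, e), 0.0)
        xs.append(age + 1.0)
        mxs.append(eggs * model.sex_ratio)
        e = e_next
        d += 1
        age += 1.0
    x = np.asarray(xs)
    return x, np.full_like(x, l_im), np.asarray(mxs)


def _decline_rate(model: PhenologyModel, T: float, horizon: int = 180) -> float:
    """Exponential decline rate of a non-viable cohort at constant T.

    Follows the deterministic cohort through whichever stage it occupies;
    a stage with zero development rate holds the cohort with daily
    survival (1-m)^(1/horizon) (the stage cannot complete within the
    horizon).  Returns ln(N(horizon))/horizon, floored so the result is
    finite.
    """
    rates = [evaluate(st.development_rate, float(T)) for st in model.stages]
    morts = [evaluate(st.mortality, float(T)) for st in model.stages]
    log_n = 0.0
    stage = 0
    cum = 0.0
    for _ in range(horizon):
        if stage >= len(rates):
            # adult phase of a cohort that cannot reproduce: senescence kills it
            s = max(evaluate(model.female_senescence, float(T)), 1.0 / horizon)
            log_n += math.log(max(1.0 - min(s, 1.0), _N_FLOOR))
            continue
        r, m = rates[stage], morts[stage]
        exponent = r if r > 0 else 1.0 / horizon
        log_n += exponent * math.log(max(1.0 - m, _N_FLOOR))
        cum += r
        if cum >= 1.0:
            stage += 1
            cum = 0.0
    return max(log_n, math.log(_N_FLOOR)) / horizon


def life_table_parameters(
    model: PhenologyModel,
    temps,
    mode: str = "deterministic",
    seed: int | None = None,
    n_eggs: int = 100,
) -> LifeTableParameters:
    """Life-table parameters at a constant temperature or along a daily series.

    ``temps`` is a scalar temperature (deg C) or a daily mean series.
    ``mode`` is ``"deterministic"`` (schedule construction) or
    ``"stochastic"`` (individual-based simulation; ``seed`` required).
    A non-viable environment yields a flagged result whose rm is the
    cohort's exponential decline rate.
    """
    scalar = np.isscalar(temps)
    if mode == "deterministic":
        sched = constant_schedule(model, float(temps)) if scalar else series_schedule(model, np.asarray(temps, float))
        if sched is None or float(np.sum(sched[1] * sched[2])) <= 0:
            T_ref = float(temps) if scalar else float(np.mean(temps))
            rm = _decline_rate(model, T_ref)
            return LifeTableParameters(
                rm=rm, Ro=0.0, GRR=0.0, Tc=math.nan,
                lam=math.exp(rm), Dt=math.nan, status="non-viable",
            )
        return LifeTableParameters.from_schedule(*sched)
    if mode != "stochastic":
        raise ValidationError(f"unknown mode {mode!r}")
    if seed is None:
        raise ValidationError("stochastic mode requires a seed")
    series = _ensure_series(model, temps)
    traj = simulate_cohort(model, series, n_eggs=n_eggs, seed=seed, mode="stochastic")
    return parameters_from_trajectory(traj, model, n_eggs)


def _ensure_series(model: PhenologyModel, temps) -> np.ndarray:
    if np.isscalar(temps):
        sched = constant_schedule(model, float(temps))
        horizon = 400 if sched is None else int(3.0 * sched[0].max()) + 60
        return np.full(horizon, float(temps))
    return np.asarray(temps, dtype=float)


# ---------------------------------------------------------------------------
# individual-based cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortTrajectory:
    """Daily stage counts and the per-individual event log of one run."""

    counts: pd.DataFrame  # day, egg, larva, pupa, adult_female, adult_male, dead
    events: pd.DataFrame  # individual_id, day, event, stage, value
    seed: int | None
    temps: np.ndarray
    n_eggs: int
    mode: str

    def conserved(self) -> bool:
        """Total individuals alive + cumulative dead equals the initial cohort every day."""
        alive = self.counts[["egg", "larva", "pupa", "adult_female", "adult_male"]].sum(axis=1)
        return bool(np.all(alive + self.counts["dead"] == self.n_eggs))


def _sample_threshold(rng, slope: float) -> float:
    z = rng.logistic()
    return math.exp(z / slope)


def simulate_cohort(
    model: PhenologyModel,
    temps,
    n_eggs: int = 100,
    seed: int | None = None,
    mode: str = "stochastic",
) -> CohortTrajectory:
    """Simulate a cohort of *n_eggs* eggs day by day along *temps*.

    Stochastic mode samples development/senescence thresholds from the
    logit distributions and applies Bernoulli daily survival; runs are
    reproducible given the seed.  Deterministic mode uses median
    thresholds for every individual and applies stage mortality as a
    deterministic kill of round(n * m_stage) individuals on the stage's
    completion day, so a fixed series is bit-reproducible.

    Raises :class:`HorizonError` (naming the shortfall day) if any
    individual is still alive when the series ends.
    """
    if n_eggs < 1:
        raise ValidationError("n_eggs must be >= 1")
    if mode not in ("stochastic", "deterministic"):
        raise ValidationError(f"unknown mode {mode!r}")
    temps = np.asarray(temps, dtype=float)
    n_days = len(temps)
    rng = np.random.default_rng(seed)

    rates, morts = _stage_arrays(model, temps)
    sen = {
        "F": evaluate(model.female_senescence, temps),
        "M": evaluate(model.male_senescence, temps),
    }
    fec_daily = evaluate(model.total_fecundity, temps)
    ovi = model.relative_oviposition
    slopes = [st.time_slope for st in model.stages]
    adult_slope = {"F": model.female_time_slope, "M": model.male_time_slope}

    stochastic = mode == "stochastic"
    if stochastic:
        sexes = np.where(rng.random(n_eggs) < model.sex_ratio, "F", "M")
        dev_thresholds = np.array(
            [[_sample_threshold(rng, b) for b in slopes] for _ in range(n_eggs)]
        )
        adult_thresholds = np.array(
            [_sample_threshold(rng, adult_slope[s]) for s in sexes]
        )
    else:
        n_f = int(round(n_eggs * model.sex_ratio))
        sexes = np.array(["F"] * n_f + ["M"] * (n_eggs - n_f))
        dev_thresholds = np.ones((n_eggs, 3))
        adult_thresholds = np.ones(n_eggs)

    # per-individual state
    stage = np.zeros(n_eggs, dtype=int)  # 0 egg, 1 larva, 2 pupa, 3 adult, 4 dead
    cum = np.zeros(n_eggs)
    e_age = np.zeros(n_eggs)  # adult physiological age
    alive = np.ones(n_eggs, dtype=bool)

    events: list[tuple] = []
    count_rows = []
    stage_names = ("egg", "larva", "pupa")

    # deterministic mortality bookkeeping: per-stage survival quota, applied
    # as a kill of round(n * m_stage) individuals on the stage's completion day
    det_logsurv = np.zeros(n_eggs)
    pending_kill: dict[int, list[int]] = {}

    for d in range(n_days):
        draws = rng.random(n_eggs) if stochastic else None
        pending_kill.clear()
        for i in range(n_eggs):
            if not alive[i]:
                continue
            frac = 1.0  # remaining fraction of the day
            # immature development with fractional carry across stages
            while frac > 1e-12 and stage[i] < 3:
                s_idx = stage[i]
                r, m = rates[s_idx][d], morts[s_idx][d]
                if m >= 1.0:
                    alive[i] = False
                    stage[i] = 4
                    events.append((i, d, "death", stage_names[s_idx], np.nan))
                    break
                if r <= 0.0:
                    frac = 0.0  # no development possible today; no exposure either
                    break
                need = dev_thresholds[i, s_idx] - cum[i]
                gain = r * frac
                used = min(frac, need / r) if need > 0 else 0.0
                exposure = r * used
                det_logsurv[i] += exposure * math.log(1.0 - m)
                if gain >= need:
                    cum[i] = 0.0
                    frac -= used
                    stage[i] += 1
                    tcont = d + (1.0 - frac)  # continuous transition time in days
                    if stage[i] < 3:
                        events.append((i, d, "transition", stage_names[stage[i]], tcont))
                    else:
                        events.append((i, d, "transition", "adult", tcont))
                    if stochastic:
                        if draws[i] >= math.exp(det_logsurv[i]):
                            alive[i] = False
                            stage[i] = 4
                            events.pop()  # the transition did not happen
                            events.append((i, d, "death", stage_names[s_idx], np.nan))
                        draws[i] = rng.random()  # fresh draw for the next segment
                    else:
                        pending_kill.setdefault(s_idx, []).append((i, det_logsurv[i]))
                    det_logsurv[i] = 0.0
                else:
                    cum[i] += gain
                    frac = 0.0
                    if stochastic:
                        if draws[i] >= math.exp(det_logsurv[i]):
                            alive[i] = False
                            stage[i] = 4
                            events.append((i, d, "death", stage_names[s_idx], np.nan))
                        det_logsurv[i] = 0.0
            if not alive[i]:
                continue
            # adult phase (possibly a partial first day)
            if stage[i] == 3 and frac > 1e-12:
                sx = sexes[i]
                s_rate = sen[sx][d]
                theta = adult_thresholds[i]
                e_prev = e_age[i]
                e_age[i] = e_prev + s_rate * frac
                if sx == "F":
                    e0 = min(e_prev, theta) / theta
                    e1 = min(e_age[i], theta) / theta
                    inc = max(
                        float(evaluate(ovi, e1)) - float(evaluate(ovi, e0)), 0.0
                    )
                    eggs = fec_daily[d] * inc
                    if eggs > 0:
                        events.append((i, d, "eggs", "adult_female", eggs))
                if e_age[i] >= theta:
                    alive[i] = False
                    stage[i] = 4
                    events.append(
                        (i, d, "death", f"adult_{'female' if sx == 'F' else 'male'}", np.nan)
                    )

        if not stochastic:
            for s_idx, members in pending_kill.items():
                members = [(i, ls) for i, ls in members if alive[i]]
                if not members:
                    continue
                surv_frac = math.exp(float(np.mean([ls for _, ls in members])))
                n_survive = int(round(len(members) * surv_frac))
                for i, _ in members[n_survive:]:
                    alive[i] = False
                    stage[i] = 4
                    events.append((i, d, "death", stage_names[s_idx], np.nan))

        count_rows.append(
            {
                "day": d,
                "egg": int(np.sum(alive & (stage == 0))),
                "larva": int(np.sum(alive & (stage == 1))),
                "pupa": int(np.sum(alive & (stage == 2))),
                "adult_female": int(np.sum(alive & (stage == 3) & (sexes == "F"))),
                "adult_male": int(np.sum(alive & (stage == 3) & (sexes == "M"))),
                "dead": int(np.sum(~alive)),
            }
        )
        if not np.any(alive):
            break

    if np.any(alive):
        raise HorizonError(
            f"temperature series ended on day {n_days} with {int(np.sum(alive))} "
            "individuals still alive"
        )

    counts = pd.DataFrame(count_rows)
    ev = pd.DataFrame(events, columns=["individual_id", "day", "event", "stage", "value"])
    return CohortTrajectory(
        counts=counts, events=ev, seed=seed, temps=temps, n_eggs=n_eggs, mode=mode
    )


def parameters_from_trajectory(
    traj: CohortTrajectory, model: PhenologyModel, n_eggs: int
) -> LifeTableParameters:
    """Estimate life-table parameters from a simulated cohort's event log.

    Net maternity phi_x = daughters laid at age x per initial female;
    GRR sums daily daughters per female alive.
    """
    ev = traj.events
    eggs = ev[ev["event"] == "eggs"]
    n_females_initial = max(traj.n_eggs * model.sex_ratio, 1e-9)
    if eggs.empty:
        rm = _decline_rate(model, float(np.mean(traj.temps)))
        return LifeTableParameters(
            rm=rm, Ro=0.0, GRR=0.0, Tc=math.nan, lam=math.exp(rm),
            Dt=math.nan, status="non-viable",
        )
    daily = eggs.groupby("day")["value"].sum() * model.sex_ratio
    x = daily.index.to_numpy(dtype=float) + 1.0
    phi = daily.to_numpy() / n_females_initial
    # GRR: daughters per female alive, summed over ages (no survival discount)
    females_alive = traj.counts.set_index("day")["adult_female"]
    per_female = []
    for day, total in (eggs.groupby("day")["value"].sum()).items():
        n_alive = females_alive.get(day, 0)
        if n_alive > 0:
            per_female.append(total / n_alive * model.sex_ratio)
    grr = float(np.sum(per_female))
    Ro = float(np.sum(phi))
    rm = euler_lotka_solve(x, phi)
    out = LifeTableParameters.from_rm_ro(rm=rm, Ro=Ro, GRR=grr)
    return out


def stochastic_life_table_replicates(
    model: PhenologyModel,
    temps,
    n_eggs: int = 100,
    seed: int = 0,
    replicates: int = 5,
) -> pd.DataFrame:
    """Run several seeded stochastic life-table estimates (default 5)."""
    rows = []
    for k in range(replicates):
        params = life_table_parameters(
            model, temps, mode="stochastic", seed=seed + k, n_eggs=n_eggs
        )
        row = params.to_dict()
        row["replicate"] = k
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation against observations
# ---------------------------------------------------------------------------


def validate_against_observations(
    model: PhenologyModel,
    temps,
    obs,
    n_eggs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare simulated and observed stage statistics under a daily series.

    Simulates a cohort under *temps* and pairs its per-stage median
    development times and mortalities with the observed ones (pooled
    over the observation temperatures).  Returns a frame with columns
    ``quantity, stage, observed, simulated, abs_diff, rel_diff``.
    No hypothesis testing is performed.
    """
    from . import life_tables as lt

    if obs.individuals.empty:
        raise ValidationError("observations are empty")
    temps = np.asarray(temps, dtype=float)
    traj = simulate_cohort(model, temps, n_eggs=n_eggs, seed=seed, mode="stochastic")
    ev = traj.events

    # reconstruct per-individual stage durations and deaths from the event log
    durations: dict[str, list] = {s: [] for s in IMMATURE_STAGES}
    death_counts = {s: 0 for s in IMMATURE_STAGES}
    entered = {s: 0 for s in IMMATURE_STAGES}
    per_ind = ev[ev["event"].isin(["transition", "death"])].sort_values(["individual_id", "day"])
    for ind, g in per_ind.groupby("individual_id"):
        t0 = 0.0  # continuous time the individual entered its current stage
        stage_idx = 0
        for _, row in g.iterrows():
            current = IMMATURE_STAGES[stage_idx] if stage_idx < 3 else None
            if row["event"] == "transition":
                if current is not None:
                    entered[current] += 1
                    durations[current].append(row["value"] - t0)
                t0 = row["value"]
                stage_idx += 1
                if stage_idx >= 3:
                    break
            else:
                if current is not None and row["stage"] == current:
                    entered[current] += 1
                    death_counts[current] += 1
                break
    obs_summary = lt.summarize(obs)
    rows = []
    for s in IMMATURE_STAGES:
        obs_rows = obs_summary[obs_summary["stage"] == s]
        if obs_rows.empty:
            continue
        obs_med = float(obs_rows["median_dev_days"].mean())
        obs_mort = float(obs_rows["mortality"].mean())
        sim_med = float(np.median(durations[s])) if durations[s] else math.nan
        sim_mort = death_counts[s] / entered[s] if entered[s] else math.nan
        for qty, o, m in [
            ("median_dev_days", obs_med, sim_med),
            ("mortality", obs_mort, sim_mort),
        ]:
            rows.append(
                {
                    "quantity": qty,
                    "stage": s,
                    "observed": o,
                    "simulated": m,
                    "abs_diff": abs(m - o),
                    "rel_diff": abs(m - o) / abs(o) if o else math.nan,
                }
            )
    return pd.DataFrame(rows)
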