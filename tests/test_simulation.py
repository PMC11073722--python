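"""Cohort simulation, Euler-Lotka, life-table parameters."""

import math

import numpy as np
import pytest

from fawphen.curves import ResponseFunction, evaluate
from fawphen.simulation import (
    HorizonError,
    LifeTableParameters,
    NoReproductionError,
    PhenologyModel,
    StageModel,
    constant_schedule,
    euler_lotka_solve,
    life_table_parameters,
    simulate_cohort,
    validate_against_observations,
)


def _zero_mortality(model, time_slope=None):
    def swap(st):
        zero = ResponseFunction(
            "wang_1", "mortality", {"Topt": 25.0, "B": 2.0, "H": 0.0}, (-100, 100)
        )
        return StageModel(st.name, st.development_rate, zero,
                          time_slope if time_slope else st.time_slope)

    return PhenologyModel(
        swap(model.egg), swap(model.larva), swap(model.pupa),
        model.female_senescence, model.male_senescence,
        model.total_fecundity, model.relative_oviposition,
        model.sex_ratio, model.female_time_slope, model.male_time_slope,
    )


# ---------------------------------------------------------------------------
# Euler-Lotka solver
# ---------------------------------------------------------------------------


def test_euler_lotka_single_reproduction_closed_form():
    """l_1 = 1, m_1 = 2: e^(-r) * 2 = 1 so r = ln 2."""
    rm = euler_lotka_solve([1.0], [1.0], [2.0])
    assert rm == pytest.approx(math.log(2.0), abs=1e-12)


def test_euler_lotka_concentrated_schedule_matches_log_ro_over_age():
    """Reproduction concentrated at one age: rm = ln(Ro)/age."""
    rm = euler_lotka_solve([28.32548], [1.0], [211.68])
    assert rm == pytest.approx(math.log(211.68) / 28.32548, rel=1e-10)
    assert rm == pytest.approx(0.189055, abs=2e-6)


def test_euler_lotka_against_brute_force_grid(rng):
    """100 random schedules: solver agrees with a 1e-6 grid scan."""

    def oracle(x, phi):
        # coarse bracketing scan then a 1e-6 grid within the bracket
        def f(r):
            return np.sum(np.exp(-r * x) * phi) - 1.0

        coarse = np.arange(-1.0, 1.5, 1e-3)
        vals = np.array([f(r) for r in coarse])
        k = np.where(np.diff(np.sign(vals)) < 0)[0][0]
        fine = np.arange(coarse[k], coarse[k + 1] + 1e-6, 1e-6)
        fvals = np.exp(-np.outer(fine, x)) @ phi - 1.0
        j = np.argmin(np.abs(fvals))
        return fine[j]

    for _ in range(100):
        n = rng.integers(3, 25)
        x = np.sort(rng.uniform(1.0, 60.0, size=n))
        phi = rng.uniform(0.0, 2.0, size=n)
        phi[rng.integers(0, n)] += 0.5  # ensure some reproduction
        rm = euler_lotka_solve(x, phi)
        assert abs(rm - oracle(x, phi)) < 1e-5
        # residual of the renewal equation vanishes at the root
        assert abs(np.sum(np.exp(-rm * x) * phi) - 1.0) < 1e-10


def test_euler_lotka_no_reproduction_is_an_error():
    with pytest.raises(NoReproductionError):
        euler_lotka_solve([1.0, 2.0], [1.0, 0.5], [0.0, 0.0])


# ---------------------------------------------------------------------------
# life-table parameter identities
# ---------------------------------------------------------------------------


def test_identities_hold_on_every_output(ref_model):
    for T in (20.0, 25.0, 28.0, 30.0, 32.0):
        p = life_table_parameters(ref_model, T)
        assert p.status == "ok"
        assert p.lam == pytest.approx(math.exp(p.rm), rel=1e-12)
        assert p.Dt == pytest.approx(math.log(2) / p.rm, rel=1e-12)
        assert p.Tc == pytest.approx(math.log(p.Ro) / p.rm, rel=1e-12)
        assert p.GRR >= p.Ro >= 0


def test_replacement_level_population():
    p = LifeTableParameters.from_rm_ro(rm=0.0, Ro=1.0)
    assert p.lam == 1.0
    assert math.isinf(p.Dt)


def test_rm_curve_unimodal_with_warm_peak(ref_model):
    """rm(T) on a 0.5 C grid rises to a single peak between 25 and 30 C."""
    temps = np.arange(15.0, 35.01, 0.5)
    rms = []
    for T in temps:
        p = life_table_parameters(ref_model, float(T))
        rms.append(p.rm if p.status == "ok" else np.nan)
    rms = np.array(rms)
    finite = np.isfinite(rms)
    peak_T = temps[np.nanargmax(rms)]
    assert 25.0 <= peak_T <= 30.0
    v = rms[finite]
    d = np.sign(np.diff(v))
    d = d[d != 0]
    assert int(np.sum(np.diff(d) != 0)) == 1  # exactly one direction change


def test_non_viable_environment_is_flagged(ref_model):
    p = life_table_parameters(ref_model, 5.0)  # far below the thermal window
    assert p.status == "non-viable"
    assert p.rm < 0
    assert math.isfinite(p.lam)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def test_deterministic_zero_mortality_cohort_reaches_adult_together(ref_model):
    model = _zero_mortality(ref_model)
    temps = np.full(200, 25.0)
    traj = simulate_cohort(model, temps, n_eggs=30, seed=0, mode="deterministic")
    total = sum(1.0 / evaluate(st.development_rate, 25.0) for st in model.stages)
    tr = traj.events[(traj.events["event"] == "transition") & (traj.events["stage"] == "adult")]
    days = np.unique(tr["day"].to_numpy()) + 1  # day numbers are 1-based here
    assert len(tr) == 30
    assert list(days) == [math.ceil(total)]


def test_stochastic_stage_survival_matches_binomial_law(ref_model):
    """Realised per-stage survival at constant T within 3 binomial sigma."""
    n = 600
    temps = np.full(300, 25.0)
    traj = simulate_cohort(ref_model, temps, n_eggs=n, seed=21, mode="stochastic")
    ev = traj.events
    entered = {"egg": n}
    for s_prev, s_next in (("egg", "larva"), ("larva", "pupa"), ("pupa", "adult")):
        entered[s_next] = int(
            (ev[(ev["event"] == "transition") & (ev["stage"] == s_next)]).shape[0]
        )
    for stage_model, (s, s_next) in zip(
        (ref_model.egg, ref_model.larva, ref_model.pupa),
        (("egg", "larva"), ("larva", "pupa"), ("pupa", "adult")),
    ):
        m = evaluate(stage_model.mortality, 25.0)
        n_in = entered[s]
        frac = entered[s_next] / n_in
        assert abs(frac - (1 - m)) <= 3 * math.sqrt(m * (1 - m) / n_in)


def test_same_seed_identical_event_logs(ref_model):
    temps = np.full(300, 28.0)
    a = simulate_cohort(ref_model, temps, n_eggs=50, seed=9, mode="stochastic")
    b = simulate_cohort(ref_model, temps, n_eggs=50, seed=9, mode="stochastic")
    assert a.events.equals(b.events)
    assert a.counts.equals(b.counts)
    c = simulate_cohort(ref_model, temps, n_eggs=50, seed=10, mode="stochastic")
    assert not a.events.equals(c.events)


def test_cohort_conservation_every_day(ref_model):
    temps = np.full(300, 30.0)
    for mode, seed in (("stochastic", 4), ("deterministic", 0)):
        traj = simulate_cohort(ref_model, temps, n_eggs=80, seed=seed, mode=mode)
        assert traj.conserved()


def test_short_series_raises_horizon_error(ref_model):
    with pytest.raises(HorizonError, match="day 10"):
        simulate_cohort(ref_model, np.full(10, 25.0), n_eggs=10, seed=1)


def test_deterministic_is_large_n_limit_of_stochastic(ref_model):
    """Stage-transition day medians of a 10k stochastic cohort track the
    deterministic run within one day."""
    temps = np.full(300, 25.0)
    det = simulate_cohort(ref_model, temps, n_eggs=100, seed=0, mode="deterministic")
    sto = simulate_cohort(ref_model, temps, n_eggs=10_000, seed=3, mode="stochastic")
    for target in ("larva", "pupa", "adult"):
        d_med = det.events[
            (det.events["event"] == "transition") & (det.events["stage"] == target)
        ]["day"].median()
        s_med = sto.events[
            (sto.events["event"] == "transition") & (sto.events["stage"] == target)
        ]["day"].median()
        assert abs(d_med - s_med) <= 1.0


def test_stochastic_parameters_track_deterministic(ref_model):
    det = life_table_parameters(ref_model, 28.0)
    sto = life_table_parameters(ref_model, 28.0, mode="stochastic", seed=5, n_eggs=400)
    assert sto.status == "ok"
    assert sto.rm == pytest.approx(det.rm, abs=0.03)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


def test_validation_self_consistency(ref_model, synthetic_obs):
    """A model validated against data generated from itself agrees closely."""
    rng = np.random.default_rng(6)
    # modest fluctuation: the observations come from constant 25 C, so a
    # wide-amplitude series would legitimately shift medians (rate-curve
    # curvature), which is not what this self-consistency check probes
    temps = 25.0 + rng.normal(0, 0.5, size=400)
    obs25 = synthetic_obs.individuals[synthetic_obs.individuals["temperature_C"] == 25.0]
    from fawphen.life_tables import LifeTableObservations

    obs = LifeTableObservations(individuals=obs25)
    report = validate_against_observations(ref_model, temps, obs, n_eggs=100, seed=2)
    med = report[report["quantity"] == "median_dev_days"]
    assert not med.empty
    assert (med["rel_diff"] < 0.10).all()


def test_validation_requires_observations(ref_model):
    import pandas as pd

    from fawphen.life_tables import INDIVIDUAL_COLUMNS, LifeTableObservations

    empty = LifeTableObservations(
        individuals=pd.DataFrame(columns=list(INDIVIDUAL_COLUMNS))
    )
    with pytest.raises(Exception):
        validate_against_observations(ref_model, np.full(100, 25.0), empty)


def test_constant_series_reduces_to_constant_schedule(ref_model):
    """A degenerate 'fluctuating' series equals the constant-T parameters."""
    det = life_table_parameters(ref_model, 25.0)
    series = life_table_parameters(ref_model, np.full(400, 25.0))
    assert series.status == "ok"
    assert series.rm == pytest.approx(det.rm, abs=0.01)
    assert series.Ro == pytest.approx(det.Ro, rel=0.05)
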