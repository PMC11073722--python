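"""Nonlinear least squares: recovery, ranking, distribution fits."""

import math

import numpy as np
import pandas as pd
import pytest

from fawphen.curves import ResponseFunction, ValidationError, evaluate_raw
from fawphen.fitting import (
    B_MAX,
    FitResult,
    fit_dev_time_distribution,
    fit_response,
    rank_models,
)

TABLE_FEC = [(20, 776.3889), (25, 851.5870), (28, 581.5806), (30, 353.7500), (32, 176.4444)]


def test_gaussian_refit_of_published_fecundity_means():
    """The five mean-fecundity points pin down the thermal optimum near 23 C."""
    fr = fit_response("gaussian", TABLE_FEC)
    assert fr.converged
    assert fr.fn.params["x0"] == pytest.approx(23.0144, abs=0.01)
    assert fr.fn.params["a"] == pytest.approx(1005.384, rel=1e-3)
    assert fr.fn.params["b"] == pytest.approx(5.4884, rel=1e-3)
    assert fr.fn.params["y0"] == pytest.approx(-88.5085, rel=1e-3)
    assert fr.r_squared >= 0.99


@pytest.mark.parametrize(
    "name,params,xgrid",
    [
        ("gaussian", {"y0": 10.0, "a": 500.0, "x0": 24.0, "b": 4.0}, np.arange(16, 35, 2.0)),
        ("wang_1", {"Topt": 24.8, "B": 1.76, "H": 0.017}, np.arange(18, 35, 2.0)),
        ("exponential_simple", {"b1": 0.02, "b2": 0.0773}, np.arange(18, 35, 2.0)),
        ("taylor", {"Rm": 0.11, "Tm": 29.0, "To": 5.0}, np.arange(16, 35, 2.0)),
    ],
)
def test_zero_noise_fit_has_zero_residual(name, params, xgrid):
    entryless = ResponseFunction(name, _family_of(name), params, (-100, 100))
    y = evaluate_raw(entryless, xgrid)
    fr = fit_response(name, list(zip(xgrid, y)))
    assert fr.converged
    assert fr.r_squared >= 1 - 1e-9


def _family_of(name):
    return {
        "gaussian": "total_fecundity",
        "wang_1": "mortality",
        "exponential_simple": "senescence",
        "taylor": "development_rate",
    }[name]


def test_wang1_topt_recovery_vs_grid_oracle(rng):
    """Noisy mortality points: NLS matches a brute-force grid search."""
    truth = {"Topt": 24.8, "B": 1.76, "H": 0.017}
    temps = np.arange(18.0, 35.0, 2.0)
    fn = ResponseFunction("wang_1", "mortality", truth, (-100, 100))
    y = evaluate_raw(fn, temps) + rng.normal(0, 0.01, size=len(temps))
    fr = fit_response("wang_1", list(zip(temps, y)))
    assert fr.converged
    assert abs(fr.fn.params["Topt"] - truth["Topt"]) <= 0.5

    # dense grid oracle over (Topt, B, H)
    best = (np.inf, None)
    for topt in np.arange(20.0, 30.0, 0.1):
        for B in np.arange(0.5, 4.01, 0.25):
            for H in np.arange(0.002, 0.062, 0.004):
                pred = evaluate_raw(
                    ResponseFunction("wang_1", "mortality", {"Topt": topt, "B": B, "H": H}),
                    temps,
                )
                rss = float(np.sum((pred - y) ** 2))
                if rss < best[0]:
                    best = (rss, topt)
    grid_rss, grid_topt = best
    assert abs(grid_topt - truth["Topt"]) <= 0.5
    assert fr.rss <= grid_rss + 1e-9  # NLS at least as good as the grid


def test_rank_models_order_and_tie_breaks():
    def stub(aic, r2, converged=True):
        fn = ResponseFunction("linear", "development_rate", {"a": 0.0, "b": 0.01})
        return FitResult(
            fn=fn, r_squared=r2, aic=aic, df=3, p_value=0.01,
            residuals=np.zeros(5), converged=converged, rss=1.0, n_points=5,
        )

    a, b = stub(-30.68, 0.985), stub(5.98, 0.952)
    assert rank_models([b, a])[0].aic == pytest.approx(-30.68)
    tie1, tie2 = stub(10.0, 0.99), stub(10.0, 0.95)
    assert rank_models([tie2, tie1])[0].r_squared == pytest.approx(0.99)
    good, bad = stub(50.0, 0.5), stub(-100.0, 0.99, converged=False)
    assert rank_models([bad, good])[0] is good
    with pytest.raises(ValidationError):
        rank_models([])


def test_fit_invariant_to_point_order_and_weight_scale():
    pts = TABLE_FEC
    f1 = fit_response("gaussian", pts)
    f2 = fit_response("gaussian", list(reversed(pts)))
    w = np.array([1.0, 2.0, 1.0, 1.0, 0.5])
    f3 = fit_response("gaussian", pts, weights=w)
    f4 = fit_response("gaussian", pts, weights=5.0 * w)
    for k in f1.fn.params:
        assert f1.fn.params[k] == pytest.approx(f2.fn.params[k], rel=1e-6, abs=1e-8)
        assert f3.fn.params[k] == pytest.approx(f4.fn.params[k], rel=1e-6, abs=1e-8)


def test_too_few_points_is_an_error():
    with pytest.raises(ValidationError):
        fit_response("gaussian", TABLE_FEC[:4])


def test_dev_time_point_mass_caps_slope():
    dist = fit_dev_time_distribution(np.full(20, 7.5), mode="normalized")
    assert dist.degenerate
    assert dist.slope_b == B_MAX
    assert dist.median() == pytest.approx(7.5, rel=1e-9)


def test_dev_time_logistic_sample_recovery(rng):
    """ln t ~ logistic(ln 10, 1/8): ML slope and median land in sampling bounds."""
    z = rng.logistic(size=500)
    t = np.exp(math.log(10) + z / 8.0)
    dist = fit_dev_time_distribution(t, mode="normalized")
    assert 6.4 <= dist.slope_b <= 9.6
    assert 9.0 <= dist.median() <= 11.0


def test_dev_time_normalized_mode_intercept_near_zero(rng):
    z = rng.logistic(size=400)
    x = np.exp(z / 30.0)  # median exactly 1 in distribution
    dist = fit_dev_time_distribution(x, mode="normalized")
    assert abs(next(iter(dist.intercepts.values())) / dist.slope_b) < 0.02


def test_dev_time_absolute_mode_shares_slope():
    rng = np.random.default_rng(99)
    frames = []
    for T, med in [(20.0, 16.0), (25.0, 10.0), (30.0, 7.0)]:
        t = med * np.exp(rng.logistic(size=200) / 20.0)
        frames.append(pd.DataFrame({"temperature_C": T, "duration_days": t}))
    df = pd.concat(frames)
    dist = fit_dev_time_distribution(df, mode="absolute")
    assert set(dist.intercepts) == {20.0, 25.0, 30.0}
    assert 16.0 <= dist.slope_b <= 25.0
    for T, med in [(20.0, 16.0), (25.0, 10.0), (30.0, 7.0)]:
        assert dist.median(T) == pytest.approx(med, rel=0.05)


def test_dev_time_rejects_nonpositive_durations():
    with pytest.raises(ValidationError):
        fit_dev_time_distribution(np.array([1.0, 2.0, -1.0, 3.0, 4.0]))


def test_aic_selects_generating_model():
    """Data simulated from the Taylor curve: AIC picks it over shape-distinct rivals.

    The rivals (a line and a monotone exponential) cannot reproduce the
    thermal optimum, so with 5%-of-range noise the generating curve
    should win the AIC ranking in at least 80% of replicates.
    """
    temps = np.arange(16.0, 33.0, 2.0)
    truth = ResponseFunction("taylor", "development_rate", {"Rm": 0.11, "Tm": 27.0, "To": 4.0})
    clean = evaluate_raw(truth, temps)
    sigma = 0.05 * (clean.max() - clean.min())
    rng = np.random.default_rng(2024)
    wins = 0
    n_rep = 200
    for _ in range(n_rep):
        y = clean + rng.normal(0, sigma, size=len(temps))
        fits = [
            fit_response(name, list(zip(temps, y)))
            for name in ("taylor", "linear", "exponential_simple")
        ]
        best = rank_models(fits)[0]
        wins += best.fn.name == "taylor"
    assert wins / n_rep >= 0.8
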