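"""Daily interpolation, risk indices, raster application, classification."""

import math

import numpy as np
import pytest

from fawphen.curves import ValidationError
from fawphen.grids import AlignmentError, ClimateGrid, GridSpec
from fawphen.mapping import (
    DailySeries,
    LambdaLookup,
    classify_and_area,
    area_change,
    compute_ai,
    compute_eri,
    compute_gi,
    generation_lengths,
    interpolate_daily,
    map_indices,
    pixel_areas_km2,
)
from fawphen.simulation import life_table_parameters
from fawphen.synthetic import generate_climate_raster


def test_interpolate_daily_constant_field():
    series = interpolate_daily([25.0] * 12, [25.0] * 12)
    assert np.all(series.tmin == 25.0) and np.all(series.tmax == 25.0)
    assert len(series.tmean) == 365


def test_interpolate_daily_hits_monthly_values_at_anchors():
    vals = np.arange(12, dtype=float) + 10.0
    series = interpolate_daily(vals, vals + 5.0)
    from fawphen.mapping import MONTH_ANCHOR

    for m, anchor in enumerate(MONTH_ANCHOR):
        assert series.tmin[anchor - 1] == pytest.approx(vals[m], abs=1e-12)


def test_interpolate_daily_linear_between_anchors():
    """Day 31 sits 16/31 of the way from the Jan-15 to the Feb-15 anchor."""
    tmin = [10.0, 20.0] + [15.0] * 10
    series = interpolate_daily(tmin, tmin)
    assert series.tmin[30] == pytest.approx(10 + 16 / 31 * 10, rel=1e-12)


def test_interpolate_daily_requires_12_months():
    with pytest.raises(ValidationError):
        interpolate_daily([25.0] * 11, [25.0] * 11)


def test_eri_trivial_extremes(ref_model):
    assert compute_eri(ref_model, DailySeries.constant(25.0)) == 1.0
    assert compute_eri(ref_model, DailySeries.constant(5.0)) == 0.0


def test_eri_counts_viable_days(ref_model):
    """183 viable days out of 365 gives ERI = 183/365."""
    t = np.concatenate([np.full(183, 25.0), np.full(182, 5.0)])
    series = DailySeries(t, t)
    assert compute_eri(ref_model, series) == pytest.approx(183 / 365, rel=1e-12)


def test_eri_invariant_to_day_permutation(ref_model, rng):
    t = np.concatenate([np.full(100, 25.0), np.full(265, 2.0)])
    shuffled = rng.permutation(t)
    a = compute_eri(ref_model, DailySeries(t, t))
    b = compute_eri(ref_model, DailySeries(shuffled, shuffled))
    assert a == b


def test_eri_survival_method_bounded(ref_model):
    eri = compute_eri(ref_model, DailySeries.constant(25.0), method="survival")
    assert 0.0 < eri < 1.0  # mean product of stage survivals, not a count


def test_gi_constant_series_closed_form(ref_model):
    """All start days share one generation length; GI = 365 / T."""
    series = DailySeries.constant(25.0)
    lengths = generation_lengths(ref_model, series)
    assert np.all(np.isfinite(lengths))
    assert np.ptp(lengths) < 1e-6
    gi = compute_gi(ref_model, series)
    assert gi == pytest.approx(365.0 / lengths[0], rel=1e-9)


def test_gi_zero_when_no_development(ref_model):
    assert compute_gi(ref_model, DailySeries.constant(2.0)) == 0.0


def test_gi_partial_year(ref_model):
    """Cold half of the year stops development; GI falls accordingly."""
    warm = compute_gi(ref_model, DailySeries.constant(28.0))
    t = np.concatenate([np.full(182, 28.0), np.full(183, 2.0)])
    series = DailySeries(t, t)
    mixed = compute_gi(ref_model, series)
    assert 0.0 < mixed < warm
    # generations started in the cold season stall until warmth returns,
    # so they are strictly longer than warm-season generations
    lengths = generation_lengths(ref_model, series)
    assert lengths[200] > lengths[10]


def test_ai_zero_at_unit_lambda(ref_model):
    lookup = LambdaLookup(temps=np.array([0.0, 50.0]), lams=np.array([1.0, 1.0]), lambda_floor=0.5)
    ai = compute_ai(ref_model, DailySeries.constant(25.0), lookup=lookup)
    assert ai == 0.0


def test_ai_floor_saturation(ref_model):
    """A year of non-viable days saturates at 365*log10(lambda_floor)."""
    ai = compute_ai(ref_model, DailySeries.constant(2.0), lambda_floor=0.5)
    assert ai == pytest.approx(365 * math.log10(0.5), rel=1e-12)


def test_ai_constant_series_closed_form(ref_model):
    """On a grid point the lookup is exact, so AI = 365*log10(lambda(T))."""
    p = life_table_parameters(ref_model, 25.0)
    ai = compute_ai(ref_model, DailySeries.constant(25.0))
    assert ai == pytest.approx(365 * math.log10(p.lam), abs=1e-9)


# ---------------------------------------------------------------------------
# raster path
# ---------------------------------------------------------------------------


def _constant_grid(T, shape=(1, 1)):
    nrows, ncols = shape
    spec = GridSpec(nrows=nrows, ncols=ncols, xllcorner=0.0, yllcorner=0.0, cellsize=1.0)
    stack = np.full((12, nrows, ncols), float(T))
    return ClimateGrid(tmin=stack.copy(), tmax=stack.copy(), spec=spec)


def test_single_pixel_equals_scalar_path(ref_model):
    grid = _constant_grid(25.0)
    surface = map_indices(ref_model, grid)
    series = DailySeries.constant(25.0)
    assert surface.eri[0, 0] == compute_eri(ref_model, series)
    assert surface.gi[0, 0] == pytest.approx(compute_gi(ref_model, series), rel=1e-12)
    assert surface.ai[0, 0] == pytest.approx(compute_ai(ref_model, series), abs=1e-9)


def test_nodata_pixels_propagate(ref_model):
    grid = _constant_grid(25.0, shape=(2, 2))
    grid.tmin[:, 0, 1] = grid.spec.nodata
    grid.tmax[:, 0, 1] = grid.spec.nodata
    surface = map_indices(ref_model, grid)
    assert np.isnan(surface.eri[0, 1])
    assert np.isfinite(surface.eri).sum() == 3


def test_ai_monotone_along_cool_side_gradient(ref_model):
    """Where tmean stays below the lambda(T) peak, AI rises with warmth."""
    grid = generate_climate_raster(
        (8, 2), (0.0, 40.0), (0.0, 4.0),
        mean_at_equator=24.0, gradient_per_degree=-0.35,
        seasonal_amplitude=0.0, diurnal_range=6.0, seed=0,
    )
    surface = map_indices(ref_model, grid)
    col = surface.ai[:, 0]
    # row 0 is the northernmost = coldest; AI must increase toward the equator
    assert np.all(np.diff(col) > 0)


def test_classification_conserves_area(ref_model):
    grid = generate_climate_raster(
        (6, 5), (-30.0, 30.0), (0.0, 25.0),
        mean_at_equator=30.0, gradient_per_degree=-0.6, seed=1, mask_fraction=0.1,
    )
    surface = map_indices(ref_model, grid)
    table = classify_and_area(surface)
    areas = pixel_areas_km2(grid.spec)
    valid_total = float(areas[np.isfinite(surface.eri)].sum())
    for name in ("eri", "gi", "ai"):
        class_total = table[table["index"] == name]["area_km2"].sum()
        assert class_total == pytest.approx(valid_total, rel=1e-12)


def test_equator_pixel_area():
    spec = GridSpec(nrows=1, ncols=1, xllcorner=0.0, yllcorner=-0.5, cellsize=1.0)
    area = pixel_areas_km2(spec)[0, 0]
    assert area == pytest.approx(111.320 * 110.574, rel=1e-3)


def test_uniform_surface_single_class(ref_model):
    grid = _constant_grid(25.0, shape=(2, 2))
    surface = map_indices(ref_model, grid)
    table = classify_and_area(surface, breaks={"eri": (1.5, 2.0), "gi": (90.0, 95.0), "ai": (90.0, 95.0)})
    for name in ("eri", "gi", "ai"):
        sub = table[table["index"] == name].set_index("class")["area_km2"]
        assert sub["low"] > 0
        assert sub["medium"] == 0 and sub["high"] == 0


def test_area_change_identity(ref_model):
    grid = _constant_grid(25.0, shape=(2, 2))
    surface = map_indices(ref_model, grid)
    table = classify_and_area(surface)
    change = area_change(table, table)
    assert (change["change_km2"] == 0).all()


def test_non_monotone_breaks_rejected(ref_model):
    grid = _constant_grid(25.0)
    surface = map_indices(ref_model, grid)
    with pytest.raises(ValidationError):
        classify_and_area(surface, breaks={"eri": (0.8, 0.2)})


def test_resolution_doubling_stable_class_areas(ref_model):
    """Halving the cell size changes class areas by <0.5% on a smooth field."""
    kwargs = dict(
        lat_range=(-20.0, 20.0), lon_range=(0.0, 20.0),
        mean_at_equator=29.0, gradient_per_degree=-0.5,
        seasonal_amplitude=2.0, seed=3,
    )
    coarse = generate_climate_raster((10, 10), **kwargs)
    fine = generate_climate_raster((20, 20), **kwargs)
    t_coarse = classify_and_area(map_indices(ref_model, coarse))
    t_fine = classify_and_area(map_indices(ref_model, fine))
    a = t_coarse.groupby("index")["area_km2"].sum()
    b = t_fine.groupby("index")["area_km2"].sum()
    for name in a.index:
        assert abs(a[name] - b[name]) / a[name] < 0.005
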