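"""End-to-end pipeline: life-table observations to a fitted phenology model.

Summarises raw observations, fits the competing catalog curves for each
life-history trait, ranks them by AIC, and assembles the winners into a
:class:`~fawphen.simulation.PhenologyModel` ready for simulation and
mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import life_tables as lt
from .curves import ResponseFunction, ValidationError, evaluate
from .fitting import FitResult, fit_dev_time_distribution, fit_response, rank_models
from .simulation import PhenologyModel, StageModel

DEV_CANDIDATES = ("logan_5", "hilbert_logan_2", "logan_1", "taylor", "linear")
MORT_CANDIDATES = ("wang_1", "wang_2", "gaussian_log")
SEN_CANDIDATES = ("exponential_simple", "hilbert_logan_3")


@dataclass
class FittedPhenology:
    """A fitted model plus the per-trait fit comparison tables."""

    model: PhenologyModel
    reports: dict  # trait name -> DataFrame of ranked fits

    def report_frame(self) -> pd.DataFrame:
        frames = []
        for trait, df in self.reports.items():
            df = df.copy()
            df.insert(0, "trait", trait)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _best(fits: list[FitResult], trait: str) -> FitResult:
    ranked = rank_models(fits)
    best = ranked[0]
    if not best.converged:
        raise ValidationError(f"no converged fit for {trait}")
    return best


def _report(fits) -> pd.DataFrame:
    from .fitting import fit_report

    return fit_report(fits)


def fit_phenology_model(
    obs: lt.LifeTableObservations,
    temp_domain: tuple[float, float] | None = None,
    time_mode: str = "normalized",
) -> FittedPhenology:
    """Fit every component of the phenology model from observations.

    Development rates use the reciprocal of the median development
    time per temperature; mortalities the per-stage death fractions;
    fecundity the per-female lifetime egg totals; senescence the
    reciprocal median adult longevity per sex; oviposition timing the
    pooled cumulative egg fraction against normalised female age.
    """
    summary = lt.summarize(obs)
    temps_all = summary["temperature_C"].unique()
    if temp_domain is None:
        temp_domain = (float(temps_all.min()) - 2.0, float(temps_all.max()) + 2.0)

    reports: dict[str, pd.DataFrame] = {}
    stage_models = {}
    for stage in lt.IMMATURE_STAGES:
        pts = lt.stage_development_points(summary, stage)
        dev_fits = []
        for name in DEV_CANDIDATES:
            try:
                dev_fits.append(
                    fit_response(name, pts, family="development_rate", temp_domain=temp_domain)
                )
            except ValidationError:
                continue
        best_dev = _best(dev_fits, f"{stage} development rate")
        reports[f"{stage}_development"] = _report(dev_fits)

        rows = summary[summary["stage"] == stage]
        mort_pts = pd.DataFrame(
            {"temperature_C": rows["temperature_C"], "y": rows["mortality"]}
        )
        mort_fits = []
        for name in MORT_CANDIDATES:
            try:
                mort_fits.append(
                    fit_response(name, mort_pts, family="mortality", temp_domain=temp_domain)
                )
            except ValidationError:
                continue
        best_mort = _best(mort_fits, f"{stage} mortality")
        reports[f"{stage}_mortality"] = _report(mort_fits)

        dist = fit_dev_time_distribution(
            lt.normalized_times(obs, stage), mode=time_mode, stage=stage
        )
        stage_models[stage] = StageModel(
            name=stage,
            development_rate=best_dev.fn,
            mortality=best_mort.fn,
            time_slope=dist.slope_b,
        )

    # fecundity: mean lifetime eggs per female per temperature
    fec_rows = summary[(summary["stage"] == "adult_female") & summary["mean_total_eggs"].notna()]
    fec_pts = pd.DataFrame(
        {"temperature_C": fec_rows["temperature_C"], "y": fec_rows["mean_total_eggs"]}
    )
    fec_fit = fit_response("gaussian", fec_pts, family="total_fecundity", temp_domain=temp_domain)
    reports["total_fecundity"] = _report([fec_fit])
    if not fec_fit.converged:
        raise ValidationError("fecundity fit did not converge")

    # senescence: reciprocal median adult longevity per sex
    sen_fns = {}
    slopes = {}
    for sex, stage in (("F", "adult_female"), ("M", "adult_male")):
        rows = summary[summary["stage"] == stage]
        pts = pd.DataFrame(
            {
                "temperature_C": rows["temperature_C"],
                "y": 1.0 / rows["median_dev_days"],
            }
        ).dropna()
        fits = []
        for name in SEN_CANDIDATES:
            try:
                fits.append(fit_response(name, pts, family="senescence", temp_domain=temp_domain))
            except ValidationError:
                continue
        best = _best(fits, f"{stage} senescence")
        reports[f"{stage}_senescence"] = _report(fits)
        sen_fns[sex] = best.fn
        ind = obs.individuals
        sel = ind[(ind["stage"] == stage) & ind["duration_days"].notna() & ~ind["died_in_stage"]]
        dist = fit_dev_time_distribution(
            lt.normalized_times(obs, stage), mode="normalized", stage=stage
        ) if not sel.empty else None
        slopes[sex] = dist.slope_b if dist is not None else 10.0

    ovi_fit = _fit_relative_oviposition(obs, temp_domain)
    reports["relative_oviposition"] = _report([ovi_fit])

    # sex ratio among adults that emerged from the immature cohorts
    ind = obs.individuals
    adults = ind[ind["stage"].isin(["adult_female", "adult_male"])]
    n_f = int((adults["stage"] == "adult_female").sum())
    n_total = len(adults)
    sex_ratio = n_f / n_total if n_total else 0.5
    sex_ratio = min(max(sex_ratio, 0.05), 0.95)

    model = PhenologyModel(
        egg=stage_models["egg"],
        larva=stage_models["larva"],
        pupa=stage_models["pupa"],
        female_senescence=sen_fns["F"],
        male_senescence=sen_fns["M"],
        total_fecundity=fec_fit.fn,
        relative_oviposition=ovi_fit.fn,
        sex_ratio=sex_ratio,
        female_time_slope=slopes["F"],
        male_time_slope=slopes["M"],
    )
    return FittedPhenology(model=model, reports=reports)


def _fit_relative_oviposition(obs: lt.LifeTableObservations, temp_domain) -> FitResult:
    """Fit the cumulative egg-fraction curve against normalised female age."""
    fec = obs.fecundity
    ind = obs.individuals
    if fec.empty:
        raise ValidationError("no fecundity records to fit oviposition timing")
    longevity = (
        ind[ind["stage"] == "adult_female"]
        .set_index(["individual_id", "temperature_C"])["duration_days"]
    )
    pts = []
    for (fid, T), g in fec.groupby(["female_id", "temperature_C"]):
        total = g["eggs"].sum()
        if total <= 0:
            continue
        try:
            span = float(longevity.loc[(fid, T)])
        except KeyError:
            span = float(g["age_day"].max())
        g = g.sort_values("age_day")
        cum = g["eggs"].cumsum() / total
        e = np.minimum(g["age_day"].to_numpy(float) / span, 1.0)
        pts.extend(zip(e, cum))
    pts_df = pd.DataFrame(pts, columns=["E", "cum_fraction"])
    # thin to a manageable, deterministic subset for the NLS
    if len(pts_df) > 500:
        pts_df = pts_df.sort_values(["E", "cum_fraction"]).iloc[:: len(pts_df) // 500 + 1]
    return fit_response(
        "exponential_modified_1", pts_df, family="relative_oviposition", temp_domain=temp_domain
    )
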