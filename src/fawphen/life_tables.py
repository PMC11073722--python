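"""Data model and CSV I/O for constant-temperature life-table experiments.

The experimental unit is a cohort of neonates reared individually at a
set of constant temperatures, with daily checks of stage transitions and
deaths, plus separate adult pairs whose longevity and daily egg
deposition are recorded.  Records are long-format:

``individuals`` CSV columns
    individual_id, temperature_C, stage, duration_days, died_in_stage, sex
``fecundity`` CSV columns
    female_id, temperature_C, age_day, eggs

The stage chain is fixed ``egg -> larva -> pupa -> adult``; larval
instars are pre-merged into a single larval stage, as are pre-pupa and
pupa.  An individual contributes one row per stage it entered; a row
with ``died_in_stage=True`` closes its record.  Individuals that die in
a stage count in that stage's mortality denominator and are excluded
from development-time summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("egg", "larva", "pupa", "adult_female", "adult_male")
IMMATURE_STAGES = ("egg", "larva", "pupa")
SEXES = ("F", "M", "unknown")

INDIVIDUAL_COLUMNS = (
    "individual_id",
    "temperature_C",
    "stage",
    "duration_days",
    "died_in_stage",
    "sex",
)
FECUNDITY_COLUMNS = ("female_id", "temperature_C", "age_day", "eggs")


class SchemaError(ValueError):
    """A CSV file does not match the documented schema."""


class ValidationError(ValueError):
    """Record values violate an invariant; offending rows are listed."""


@dataclass
class LifeTableObservations:
    """Raw per-individual life-table records for a set of temperatures."""

    individuals: pd.DataFrame
    fecundity: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(FECUNDITY_COLUMNS)))

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.fecundity = self.fecundity.reset_index(drop=True)
        _validate_individuals(self.individuals)
        _validate_fecundity(self.fecundity, self.individuals)

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.individuals["temperature_C"].unique())

    @property
    def n_individuals(self) -> int:
        return self.individuals["individual_id"].nunique()


def _offending(rows) -> str:
    shown = list(rows[:10])
    more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
    return f"rows {shown}{more}"


def _validate_individuals(df: pd.DataFrame) -> None:
    missing = set(INDIVIDUAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"individuals table missing columns: {sorted(missing)}")
    bad_stage = df.index[~df["stage"].isin(STAGES)].tolist()
    if bad_stage:
        raise ValidationError(f"unknown stage values at {_offending(bad_stage)}")
    bad_sex = df.index[~df["sex"].isin(SEXES)].tolist()
    if bad_sex:
        raise ValidationError(f"unknown sex values at {_offending(bad_sex)}")
    dur = pd.to_numeric(df["duration_days"], errors="coerce")
    present = df["duration_days"].notna()
    bad_dur = df.index[present & ~(dur > 0)].tolist()
    if bad_dur:
        raise ValidationError(f"non-positive duration_days at {_offending(bad_dur)}")
    bad_female = df.index[(df["stage"] == "adult_female") & (df["sex"] != "F")].tolist()
    if bad_female:
        raise ValidationError(f"adult_female rows must have sex F at {_offending(bad_female)}")
    bad_male = df.index[(df["stage"] == "adult_male") & (df["sex"] != "M")].tolist()
    if bad_male:
        raise ValidationError(f"adult_male rows must have sex M at {_offending(bad_male)}")


def _validate_fecundity(df: pd.DataFrame, individuals: pd.DataFrame) -> None:
    if df.empty and set(FECUNDITY_COLUMNS) <= set(df.columns):
        return
    missing = set(FECUNDITY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"fecundity table missing columns: {sorted(missing)}")
    eggs = pd.to_numeric(df["eggs"], errors="coerce")
    bad_eggs = df.index[~(eggs >= 0)].tolist()
    if bad_eggs:
        raise ValidationError(f"negative or non-numeric eggs at {_offending(bad_eggs)}")
    bad_age = df.index[~(pd.to_numeric(df["age_day"], errors="coerce") >= 1)].tolist()
    if bad_age:
        raise ValidationError(f"age_day must be >= 1 at {_offending(bad_age)}")
    dup = df.index[df.duplicated(["female_id", "temperature_C", "age_day"])].tolist()
    if dup:
        raise ValidationError(f"duplicate (female_id, temperature, age_day) at {_offending(dup)}")
    females = set(
        individuals.loc[individuals["stage"] == "adult_female", "individual_id"]
    )
    orphans = df.index[~df["female_id"].isin(females)].tolist()
    if orphans:
        raise ValidationError(
            f"fecundity female_id not recorded as adult_female at {_offending(orphans)}"
        )


def read_life_table(individuals_csv, fecundity_csv=None) -> LifeTableObservations:
    """Read life-table observations from CSV file(s).

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (listing row numbers) for invalid values.
    """
    ind = pd.read_csv(individuals_csv)
    for col, typ in [("temperature_C", float), ("duration_days", float)]:
        if col in ind.columns:
            ind[col] = pd.to_numeric(ind[col], errors="coerce")
    if "died_in_stage" in ind.columns:
        ind["died_in_stage"] = ind["died_in_stage"].astype(bool)
    if fecundity_csv is not None:
        fec = pd.read_csv(fecundity_csv)
    else:
        fec = pd.DataFrame(columns=list(FECUNDITY_COLUMNS))
    return LifeTableObservations(individuals=ind, fecundity=fec)


def write_life_table(obs: LifeTableObservations, individuals_csv, fecundity_csv=None) -> None:
    """Write observations back to the documented CSV schemas (UTF-8, '.' decimals)."""
    Path(individuals_csv).parent.mkdir(parents=True, exist_ok=True)
    obs.individuals.to_csv(individuals_csv, index=False)
    if fecundity_csv is not None:
        obs.fecundity.to_csv(fecundity_csv, index=False)


def summarize(obs: LifeTableObservations) -> pd.DataFrame:
    """Per (temperature, stage) summary of development, mortality and fecundity.

    Returns a frame with columns ``temperature_C, stage, n,
    median_dev_days, mean_dev_days, mortality, mean_total_eggs``.
    Mortality is deaths over individuals entering the stage; development
    summaries cover completed individuals only.  Empty cells are omitted
    with a logged warning.
    """
    rows = []
    totals = (
        obs.fecundity.groupby(["temperature_C", "female_id"])["eggs"].sum()
        if not obs.fecundity.empty
        else None
    )
    for (temp, stage), group in obs.individuals.groupby(["temperature_C", "stage"]):
        n = len(group)
        died = int(group["died_in_stage"].sum())
        completed = group.loc[~group["died_in_stage"], "duration_days"].dropna()
        mortality = died / n
        if completed.empty and died < n:
            logger.warning(
                "no completed durations for stage %s at %s C; summary omitted", stage, temp
            )
            continue
        mean_eggs = np.nan
        if stage == "adult_female" and totals is not None and temp in totals.index.get_level_values(0):
            mean_eggs = float(totals.loc[temp].mean())
        rows.append(
            {
                "temperature_C": float(temp),
                "stage": stage,
                "n": n,
                "median_dev_days": float(completed.median()) if not completed.empty else np.nan,
                "mean_dev_days": float(completed.mean()) if not completed.empty else np.nan,
                "mortality": mortality,
                "mean_total_eggs": mean_eggs,
            }
        )
    return pd.DataFrame(rows)


def normalized_times(obs: LifeTableObservations, stage: str) -> pd.DataFrame:
    """Stage durations divided by the per-temperature median.

    Returns columns ``temperature_C, x`` where ``x = t / median(T)``;
    after this normalisation the distribution of x is comparable across
    temperatures (its median is 1 at every temperature).  Individuals
    that died in the stage are excluded.  A stage with no completed
    individuals yields an empty frame.
    """
    df = obs.individuals
    sel = df[(df["stage"] == stage) & (~df["died_in_stage"]) & df["duration_days"].notna()]
    if sel.empty:
        return pd.DataFrame(columns=["temperature_C", "x"])
    out = []
    for temp, group in sel.groupby("temperature_C"):
        med = group["duration_days"].median()
        out.append(
            pd.DataFrame(
                {"temperature_C": temp, "x": group["duration_days"].to_numpy() / med}
            )
        )
    return pd.concat(out, ignore_index=True)


def stage_development_points(summary: pd.DataFrame, stage: str) -> pd.DataFrame:
    """(temperature, rate) pairs for rate-model fitting: 1/median dev time."""
    sel = summary[(summary["stage"] == stage) & summary["median_dev_days"].notna()]
    return pd.DataFrame(
        {
            "temperature_C": sel["temperature_C"].to_numpy(),
            "rate": 1.0 / sel["median_dev_days"].to_numpy(),
        }
    )
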