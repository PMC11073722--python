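"""Published parameter set for the fall armyworm phenology model.

Loads the versioned parameter file shipped with the package (constant
temperature life-table fits for *Spodoptera frugiperda* reared at
20-32 deg C) into a :class:`~fawphen.simulation.PhenologyModel`.  This
model is the default "truth" for the synthetic-data generators and the
default model for the risk-mapping examples.
"""

from __future__ import annotations

import json
from importlib import resources

from .curves import ResponseFunction
from .simulation import PhenologyModel, StageModel

_DATAFILE = "spodoptera_frugiperda.json"


def reference_parameters() -> dict:
    """The raw reference parameter dictionary (JSON contents)."""
    with resources.files("fawphen.data").joinpath(_DATAFILE).open() as fh:
        return json.load(fh)


def reference_model() -> PhenologyModel:
    """The fall armyworm phenology model with the published parameters."""
    d = reference_parameters()
    domain = tuple(d["temp_domain"])

    def fn(spec: dict, family: str) -> ResponseFunction:
        return ResponseFunction(
            name=spec["name"], family=family, params=spec["params"], temp_domain=domain
        )

    stages = {}
    for name, sd in d["stages"].items():
        stages[name] = StageModel(
            name=name,
            development_rate=fn(sd["development_rate"], "development_rate"),
            mortality=fn(sd["mortality"], "mortality"),
            time_slope=float(sd["time_slope"]),
        )
    adult = d["adult"]
    return PhenologyModel(
        egg=stages["egg"],
        larva=stages["larva"],
        pupa=stages["pupa"],
        female_senescence=fn(adult["female_senescence"], "senescence"),
        male_senescence=fn(adult["male_senescence"], "senescence"),
        total_fecundity=fn(adult["total_fecundity"], "total_fecundity"),
        relative_oviposition=fn(adult["relative_oviposition"], "relative_oviposition"),
        sex_ratio=float(d["sex_ratio"]),
        female_time_slope=float(adult["female_time_slope"]),
        male_time_slope=float(adult["male_time_slope"]),
    )
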