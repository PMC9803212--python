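"""Counterfactual scenario predictions with bootstrap uncertainty.

Three named scenarios are predicted from one fitted ensemble:

* ``potential_contemporary`` — contemporary predictors everywhere; the range
  the species could occupy today if introduced predators were absent.
* ``potential_prehuman`` — the five land-cover/climate predictors replaced by
  their pre-human values (the hindcast counterfactual).
* ``observed_contemporary`` — the potential-contemporary predictions
  restricted to the reaches where the species was actually observed,
  treating predators as the reason it is absent everywhere else.

Per-reach summaries (mean, sd, coefficient of variation across ensemble
members) quantify bootstrap prediction uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .brt import BRTEnsemble
from .errors import InvalidArgumentError, SchemaError
from .riverscape import SUBSTITUTED_PREDICTORS, EpochPair

__all__ = [
    "ScenarioSpec",
    "RLOPrediction",
    "standard_scenarios",
    "apply_scenario",
    "predict_scenarios",
    "uncertainty_cv",
]

#: Reaches with mean RLO below this floor get a missing CV instead of an
#: unstable ratio.
CV_MEAN_FLOOR = 1e-6


@dataclass(frozen=True)
class ScenarioSpec:
    """A named predictor substitution plus an optional reach restriction."""

    name: str
    substitution: tuple[str, ...] = ()
    restrict_to: frozenset[int] | None = None


def standard_scenarios(presences: frozenset[int] | set[int]) -> list[ScenarioSpec]:
    """The three canonical scenarios of the driver-partitioning workflow."""
    return [
        ScenarioSpec(name="potential_contemporary"),
        ScenarioSpec(name="potential_prehuman", substitution=SUBSTITUTED_PREDICTORS),
        ScenarioSpec(name="observed_contemporary", restrict_to=frozenset(presences)),
    ]


@dataclass
class RLOPrediction:
    """Per-reach, per-member RLO for one scenario, with summaries."""

    scenario: str
    matrix: pd.DataFrame  # reaches x members, values in (0, 1)
    summary: pd.DataFrame = field(init=False)  # mean_rlo, sd_rlo, cv

    def __post_init__(self) -> None:
        mean = self.matrix.mean(axis=1)
        if self.matrix.shape[1] > 1:
            sd = self.matrix.std(axis=1, ddof=1)
        else:
            sd = pd.Series(0.0, index=self.matrix.index)
        cv = sd / mean.where(mean >= CV_MEAN_FLOOR)
        self.summary = pd.DataFrame({"mean_rlo": mean, "sd_rlo": sd, "cv": cv})


def apply_scenario(pair: EpochPair, spec: ScenarioSpec) -> pd.DataFrame:
    """Contemporary predictors with the substituted columns taken pre-human."""
    for col in spec.substitution:
        if col not in pair.contemporary.columns or col not in pair.prehuman.columns:
            raise SchemaError(f"substitution column {col!r} missing from epoch tables")
    out = pair.contemporary.copy()
    for col in spec.substitution:
        out[col] = pair.prehuman[col]
    return out


def predict_scenarios(
    ensemble: BRTEnsemble,
    pair: EpochPair,
    specs: list[ScenarioSpec],
) -> dict[str, RLOPrediction]:
    """One RLO per reach per ensemble member for each scenario.

    Scenarios sharing a substitution list reuse the same prediction matrix,
    so the observed-contemporary restriction never re-predicts — it only
    filters rows, exactly as the workflow defines it.
    """
    if ensemble.n_members == 0:
        raise InvalidArgumentError("ensemble has no fitted members")
    cache: dict[tuple[str, ...], pd.DataFrame] = {}
    out: dict[str, RLOPrediction] = {}
    for spec in specs:
        key = tuple(spec.substitution)
        if key not in cache:
            cache[key] = ensemble.predict_matrix(apply_scenario(pair, spec))
        mat = cache[key]
        if spec.restrict_to is not None:
            keep = mat.index.intersection(sorted(spec.restrict_to))
            mat = mat.loc[keep]
        out[spec.name] = RLOPrediction(scenario=spec.name, matrix=mat.copy())
    return out


def uncertainty_cv(pred: RLOPrediction) -> pd.Series:
    """Coefficient of variation (sd/mean) per reach; missing below the floor."""
    return pred.summary["cv"]
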