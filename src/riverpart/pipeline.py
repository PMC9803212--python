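"""End-to-end orchestration: simulate -> sample -> fit -> predict -> partition.

A single :func:`run_pipeline` call executes the whole workflow under one
master seed, writes every stage output as plain CSV/JSON into a run
directory, and returns the in-memory objects plus a structured report.  All
stage seeds are derived deterministically from the master seed, so a stored
config reproduces a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brt, sampling
from .exdet import exdet as exdet_table, percent_extrapolating
from .errors import InvalidArgumentError, RiverpartError
from .partition import (
    DriverPartition,
    EffectiveHabitat,
    effective_habitat,
    partition_drivers,
    recovery_report,
)
from .riverscape import (
    PREDICTOR_NAMES,
    SUBSTITUTED_PREDICTORS,
    EpochPair,
    GeneratorConfig,
    OccupancyTruth,
    RiverNetwork,
    build_truth,
    generate_network,
    generate_predictors,
    simulate_presences,
)
from .scenario import RLOPrediction, standard_scenarios, predict_scenarios

__all__ = ["RunConfig", "RunResult", "validate_config", "run_pipeline"]

log = logging.getLogger("riverpart")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from the master seed."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # background sampling
    bandwidth: float | None = None  # None -> Silverman's rule
    density_quantile: float = 0.05
    # boosted-tree settings
    tc: int = 5
    lr: float = 0.01
    bag_fraction: float = 0.75
    min_node: int = 10
    folds: int = 10
    step: int = 50
    max_trees: int = 2000
    patience: int = 5
    # ensemble
    n_sims: int = 20
    holdout: float = 0.2
    bootstrap: bool = False
    # scenarios
    substitution: tuple[str, ...] = SUBSTITUTED_PREDICTORS
    regime: str = "predation"
    # misc
    seed: int = 0
    save_ensemble: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["substitution"] = list(self.substitution)
        d["generator"]["forest_loss"] = list(self.generator.forest_loss)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if isinstance(gen, dict):
            gen = dict(gen)
            if "forest_loss" in gen:
                gen["forest_loss"] = tuple(gen["forest_loss"])
            gen = GeneratorConfig(**gen)
        cfg = cls(generator=gen, **d)
        cfg.substitution = tuple(cfg.substitution)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty when the config is valid)."""
    v: list[str] = []
    g = config.generator
    if g.n_reaches < 1:
        v.append(f"generator.n_reaches must be >= 1, got {g.n_reaches}")
    if not 1 <= g.n_outlets <= max(g.n_reaches, 1):
        v.append(f"generator.n_outlets must be in [1, n_reaches], got {g.n_outlets}")
    if g.mean_length_m <= 0:
        v.append(f"generator.mean_length_m must be > 0, got {g.mean_length_m}")
    if not 0 <= g.conversion_fraction <= 1:
        v.append(f"generator.conversion_fraction must be in [0, 1], got {g.conversion_fraction}")
    if g.refuge_mode not in ("clusters", "covariate", "none"):
        v.append(f"generator.refuge_mode unknown: {g.refuge_mode!r}")
    if g.n_records < 1:
        v.append(f"generator.n_records must be >= 1, got {g.n_records}")
    if config.bandwidth is not None and config.bandwidth <= 0:
        v.append(f"bandwidth must be > 0, got {config.bandwidth}")
    if not 0 <= config.density_quantile < 1:
        v.append(f"density_quantile must be in [0, 1), got {config.density_quantile}")
    if config.lr <= 0:
        v.append(f"lr must be > 0, got {config.lr}")
    if not 0 < config.bag_fraction <= 1:
        v.append(f"bag_fraction must be in (0, 1], got {config.bag_fraction}")
    if config.folds < 2:
        v.append(f"folds must be >= 2, got {config.folds}")
    if config.step < 1:
        v.append(f"step must be >= 1, got {config.step}")
    if config.max_trees < config.step:
        v.append(f"max_trees must be >= step, got {config.max_trees}")
    if not 0 < config.holdout <= 0.5:
        v.append(
            f"holdout must be in (0, 0.5] so a fitting majority remains, "
            f"got {config.holdout}"
        )
    if config.n_sims < 2:
        v.append(f"n_sims must be >= 2, got {config.n_sims}")
    unknown = [c for c in config.substitution if c not in PREDICTOR_NAMES]
    if unknown:
        v.append(f"substitution contains unknown predictor(s): {unknown}")
    if config.regime not in OccupancyTruth.REGIMES:
        v.append(f"regime must be one of {OccupancyTruth.REGIMES}, got {config.regime!r}")
    return v


@dataclass
class RunResult:
    """All in-memory artefacts of one pipeline run."""

    config: RunConfig
    network: RiverNetwork
    pair: EpochPair
    truth: OccupancyTruth
    presences: frozenset[int]
    train: sampling.TrainingSet
    cv_trace: brt.CVTrace
    ensemble: brt.BRTEnsemble
    predictions: dict[str, RLOPrediction]
    eh: dict[str, EffectiveHabitat]
    driver_partition: DriverPartition
    report: dict


class _Stage:
    """Context manager: logs a stage, times it, and names it on failure."""

    def __init__(self, name: str, timings: dict):
        self.name = name
        self.timings = timings

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.timings[self.name] = round(dt, 3)
        if exc is not None:
            raise RiverpartError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, dt)
        return False


def _derive_seeds(master: int) -> dict[str, int]:
    names = ["network", "predictors", "truth", "presences", "background",
             "cv", "ensemble"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig, out_dir=None) -> RunResult:
    """Execute the full workflow; optionally write all artefacts to ``out_dir``."""
    violations = validate_config(config)
    if violations:
        raise InvalidArgumentError("invalid config: " + "; ".join(violations))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)
    timings: dict[str, float] = {}
    g = config.generator

    with _Stage("simulate", timings):
        network = generate_network(
            g.n_reaches, g.n_outlets, g.mean_length_m, g.length_cv,
            seed=seeds["network"],
        )
        pair = generate_predictors(network, g, seed=seeds["predictors"])
        truth = build_truth(pair, network, g, seed=seeds["truth"])
        presences = simulate_presences(
            truth, config.regime, g.n_records, seed=seeds["presences"]
        )

    with _Stage("sample", timings):
        coords = network.coords
        presence_xy = coords.loc[sorted(presences)].to_numpy()
        bw = config.bandwidth or sampling.silverman_bandwidth(presence_xy)
        density = sampling.kernel_density_surface(
            presence_xy, coords.to_numpy(), bw, eval_ids=coords.index.to_numpy()
        )
        train = sampling.select_background(
            presences, density, pair.contemporary,
            density_quantile=config.density_quantile, seed=seeds["background"],
        )

    with _Stage("fit", timings):
        cv_trace = brt.cv_optimal_ntrees(
            train, tc=config.tc, lr=config.lr, bag_fraction=config.bag_fraction,
            min_node=config.min_node, folds=config.folds, step=config.step,
            max_trees=config.max_trees, patience=config.patience,
            seed=seeds["cv"],
        )
        ensemble = brt.fit_ensemble(
            train, n_sims=config.n_sims, holdout=config.holdout,
            tc=config.tc, lr=config.lr, bag_fraction=config.bag_fraction,
            n_trees=cv_trace.optimal_ntrees, min_node=config.min_node,
            seed=seeds["ensemble"], bootstrap=config.bootstrap,
        )

    with _Stage("predict", timings):
        specs = standard_scenarios(presences)
        for i, s in enumerate(specs):
            if s.name == "potential_prehuman":
                specs[i] = dataclasses.replace(s, substitution=config.substitution)
        predictions = predict_scenarios(ensemble, pair, specs)

    with _Stage("exdet", timings):
        reference = pair.contemporary.loc[sorted(presences)]
        exdet_tables = {
            name: exdet_table(
                reference,
                pair.contemporary if name == "potential_contemporary"
                else _substituted(pair, config.substitution),
            )
            for name in ("potential_contemporary", "potential_prehuman")
        }
        extrapolation = {
            name: percent_extrapolating(tbl["combined"])
            for name, tbl in exdet_tables.items()
        }

    with _Stage("partition", timings):
        lengths = network.lengths_m
        eh = {
            name: effective_habitat(pred, lengths)
            for name, pred in predictions.items()
        }
        # restriction of identical predictions to a subset can only shrink EH
        assert (
            eh["observed_contemporary"].values_km
            <= eh["potential_contemporary"].values_km + 1e-9
        ).all()
        part = partition_drivers(
            eh["potential_prehuman"], eh["potential_contemporary"],
            eh["observed_contemporary"],
        )
        recovery = recovery_report(part, truth, lengths)

    report = _build_report(
        config, seeds, timings, cv_trace, ensemble, eh, part, extrapolation,
        truth, lengths, recovery, len(presences),
    )

    if out is not None:
        with _Stage("write", timings):
            _write_outputs(
                out, config, network, pair, presences, truth, train,
                predictions, exdet_tables, ensemble, report,
            )

    return RunResult(
        config=config, network=network, pair=pair, truth=truth,
        presences=presences, train=train, cv_trace=cv_trace,
        ensemble=ensemble, predictions=predictions, eh=eh,
        driver_partition=part, report=report,
    )


def _substituted(pair: EpochPair, substitution) -> pd.DataFrame:
    out = pair.contemporary.copy()
    for col in substitution:
        out[col] = pair.prehuman[col]
    return out


def _build_report(config, seeds, timings, cv_trace, ensemble, eh, part,
                  extrapolation, truth, lengths, recovery, n_presence) -> dict:
    member_auc = np.array([m.auc for m in ensemble.members])
    member_dev = np.array([m.deviance_explained_pct for m in ensemble.members])
    ps = part.summary()
    ratio_of_means = {
        "habitat_loss_pct": 100.0 * (
            1.0 - eh["potential_contemporary"].mean_km / eh["potential_prehuman"].mean_km
        ),
        "predation_loss_pct": 100.0 * (
            1.0 - eh["observed_contemporary"].mean_km / eh["potential_contemporary"].mean_km
        ),
    }
    true_habitat, true_predation = truth.true_loss_percentages(lengths)
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "config": config_dict,
        "config_hash": config_hash,
        "n_simulations": ensemble.n_members,
        "seeds": seeds,
        "n_presence_reaches": n_presence,
        "model": {
            "optimal_ntrees": int(cv_trace.optimal_ntrees),
            "cv_auc": cv_trace.cv_auc,
            "cv_deviance_explained_pct": cv_trace.cv_deviance_explained_pct,
            "ensemble_auc_mean": float(member_auc.mean()),
            "ensemble_auc_sd": float(member_auc.std(ddof=1)),
            "ensemble_deviance_explained_mean": float(member_dev.mean()),
            "ensemble_deviance_explained_sd": float(member_dev.std(ddof=1)),
        },
        "effective_habitat_km": {
            name: {"mean": e.mean_km, "sd": e.sd_km} for name, e in eh.items()
        },
        "partition": ps,
        "partition_ratio_of_means": ratio_of_means,
        "extrapolation": extrapolation,
        "truth": {
            "habitat_loss_pct": true_habitat,
            "predation_loss_pct": true_predation,
        },
        "recovery": recovery.reset_index().to_dict(orient="records"),
        "timings_s": timings,
    }


def _write_outputs(out: Path, config, network, pair, presences, truth, train,
                   predictions, exdet_tables, ensemble, report) -> None:
    config.to_yaml(out / "run_config.yaml")
    network.to_csv(out / "reaches.csv")
    pair.contemporary.rename_axis("reach_id").to_csv(out / "predictors_contemporary.csv")
    pair.prehuman.rename_axis("reach_id").to_csv(out / "predictors_prehuman.csv")
    pd.DataFrame({"reach_id": sorted(presences)}).to_csv(out / "presences.csv", index=False)
    truth.probs.rename_axis("reach_id").to_csv(out / "truth.csv")
    train.to_frame().to_csv(out / "training_set.csv", index=False)
    for name, pred in predictions.items():
        pred.summary.rename_axis("reach_id").to_csv(out / f"rlo_{name}.csv")
    for name, tbl in exdet_tables.items():
        tbl.rename_axis("reach_id").to_csv(out / f"exdet_{name}.csv")
    if config.save_ensemble:
        ensemble.save(out / "ensemble.json")
    with open(out / "partition_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
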