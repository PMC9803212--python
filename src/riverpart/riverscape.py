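"""Synthetic river networks with paired-epoch habitat predictors and known occupancy.

The spatial unit is the *reach*: a confluence-to-confluence river segment
(~700 m on average) linked to a single downstream reach, so the network is a
directed forest draining to one outlet per component.  Each reach carries the
seventeen hydrological, topographic, climatic and land-cover predictors used
to model the relative likelihood of occurrence (RLO) of a riverine specialist
(the whio, *Hymenolaimus malacorhynchos*, is the motivating species).

Two predictor epochs are generated: a *pre-human* epoch with indigenous
forest essentially intact, and a *contemporary* epoch in which a configurable
fraction of lowland reaches has been cleared (forest and riparian shade
reduced, air temperatures raised).  Only the five land-cover/climate
predictors differ between epochs; everything else is shared.

Ground-truth occupancy is defined by a sharp logistic habitat model evaluated
on each epoch's predictors, with an optional predation filter that restricts
the surviving population to refuge reaches.  Presence records are then drawn
in proportion to occupancy, giving every downstream stage of the analysis a
known answer to recover.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    EmptyPresenceError,
    InvalidArgumentError,
)

__all__ = [
    "PREDICTOR_NAMES",
    "NATIONAL_RANGES",
    "SUBSTITUTED_PREDICTORS",
    "Reach",
    "RiverNetwork",
    "EpochPair",
    "OccupancyTruth",
    "GeneratorConfig",
    "generate_network",
    "generate_predictors",
    "temp_seasonality",
    "build_truth",
    "simulate_presences",
]

#: The seventeen reach-scale predictors, in conventional reporting order.
PREDICTOR_NAMES: tuple[str, ...] = (
    "segTempSummer",
    "segTempSeasonality",
    "segSinuosity",
    "segSlope",
    "segSlopeCatchment",
    "Feb",
    "FRE3",
    "segFlowStability",
    "MeanFlow",
    "Order",
    "WidthQ50",
    "segIndigenousForest",
    "usIndigenousForest",
    "segShade",
    "segHabitat",
    "segSediment",
    "segGravelCobble",
)

#: National envelope (min, max) for each predictor; generated values are kept
#: inside these bounds.  segTempSeasonality is computed, not clipped, and its
#: envelope is reported for reference only.
NATIONAL_RANGES: dict[str, tuple[float, float]] = {
    "segTempSummer": (8.28, 25.82),
    "segTempSeasonality": (-7.2, 5.25),
    "segSinuosity": (1.0, 8.89),
    "segSlope": (-0.85, 2.1),
    "segSlopeCatchment": (0.0, 61.8),
    "Feb": (0.22, 1.71),
    "FRE3": (1.81, 40.94),
    "segFlowStability": (-0.1, 0.63),
    "MeanFlow": (0.0, 1327.78),
    "Order": (1, 8),
    "WidthQ50": (0.01, 136.11),
    "segIndigenousForest": (0.0, 1.0),
    "usIndigenousForest": (0.0, 1.0),
    "segShade": (0.0, 0.8),
    "segHabitat": (1.0, 6.9),
    "segSediment": (1.0, 6.79),
    "segGravelCobble": (0.14, 0.83),
}

#: Predictors replaced when hindcasting to the pre-human epoch.
SUBSTITUTED_PREDICTORS: tuple[str, ...] = (
    "segIndigenousForest",
    "usIndigenousForest",
    "segShade",
    "segTempSummer",
    "segTempSeasonality",
)


@dataclass(frozen=True)
class Reach:
    """A confluence-to-confluence river segment."""

    reach_id: int
    downstream_id: int | None
    length_m: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.length_m > 0:
            raise InvalidArgumentError(
                f"reach {self.reach_id}: length_m must be > 0, got {self.length_m}"
            )


class RiverNetwork:
    """A directed forest of reaches draining to one outlet per component.

    Reach identifiers are integers.  Internally reaches are stored in arrays
    indexed by position; the public surface works with reach ids.
    """

    def __init__(self, reaches: Sequence[Reach]):
        if len(reaches) == 0:
            raise InvalidArgumentError("a RiverNetwork needs at least one reach")
        ids = np.array([r.reach_id for r in reaches], dtype=np.int64)
        if len(np.unique(ids)) != len(ids):
            raise InvalidArgumentError("reach_ids must be unique")
        self._ids = ids
        self._pos = {int(i): k for k, i in enumerate(ids)}
        self._lengths = np.array([r.length_m for r in reaches], dtype=float)
        self._xy = np.array([(r.x, r.y) for r in reaches], dtype=float)
        down = np.full(len(ids), -1, dtype=np.int64)
        for k, r in enumerate(reaches):
            if r.downstream_id is not None:
                if r.downstream_id not in self._pos:
                    raise InvalidArgumentError(
                        f"reach {r.reach_id}: downstream_id {r.downstream_id} "
                        "does not exist in the network"
                    )
                if r.downstream_id == r.reach_id:
                    raise InvalidArgumentError(
                        f"reach {r.reach_id} drains into itself"
                    )
                down[k] = self._pos[r.downstream_id]
        self._down = down
        g = nx.DiGraph()
        g.add_nodes_from(range(len(ids)))
        g.add_edges_from((k, d) for k, d in enumerate(down) if d >= 0)
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidArgumentError("downstream links contain a cycle")
        self._children: list[list[int]] = [[] for _ in range(len(ids))]
        for k, d in enumerate(down):
            if d >= 0:
                self._children[d].append(k)
        # depth (link count to the outlet), via a downstream-first sweep
        depth = np.zeros(len(ids), dtype=np.int64)
        for k in reversed(list(nx.topological_sort(g))):
            d = down[k]
            depth[k] = 0 if d < 0 else depth[d] + 1
        self._depth = depth
        #: positions sorted so every reach precedes its downstream reach
        self._upstream_first = np.argsort(-depth, kind="stable")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._ids)

    @property
    def reach_ids(self) -> np.ndarray:
        return self._ids.copy()

    @property
    def lengths_m(self) -> pd.Series:
        return pd.Series(self._lengths, index=self._ids, name="length_m")

    @property
    def coords(self) -> pd.DataFrame:
        return pd.DataFrame(self._xy, index=self._ids, columns=["x", "y"])

    @property
    def outlet_ids(self) -> np.ndarray:
        return self._ids[self._down < 0]

    @property
    def n_components(self) -> int:
        return int((self._down < 0).sum())

    def downstream_id(self, reach_id: int) -> int | None:
        d = self._down[self._pos[reach_id]]
        return None if d < 0 else int(self._ids[d])

    # -- traversal ---------------------------------------------------------
    def upstream_ids(self, reach_id: int, include_self: bool = True) -> set[int]:
        """All reaches whose flow passes through ``reach_id`` (BFS upstream)."""
        start = self._pos[reach_id]
        seen = {start}
        queue = deque([start])
        while queue:
            k = queue.popleft()
            for c in self._children[k]:
                if c not in seen:
                    seen.add(c)
                    queue.append(c)
        if not include_self:
            seen.discard(start)
        return {int(self._ids[k]) for k in seen}

    def upstream_sum(self, values: np.ndarray) -> np.ndarray:
        """For each reach, the sum of ``values`` over its upstream set (incl. self).

        Runs in O(n) via an upstream-first sweep.
        """
        v = np.asarray(values, dtype=float)
        acc = v.copy()
        for k in self._upstream_first:
            d = self._down[k]
            if d >= 0:
                acc[d] += acc[k]
        return acc

    def upstream_length_weighted_mean(self, values: np.ndarray) -> np.ndarray:
        """Length-weighted mean of ``values`` over each reach's upstream set."""
        v = np.asarray(values, dtype=float)
        num = self.upstream_sum(v * self._lengths)
        den = self.upstream_sum(self._lengths)
        return num / den

    def strahler_order(self) -> np.ndarray:
        """Strahler stream order per reach (headwaters are order 1)."""
        order = np.ones(len(self._ids), dtype=np.int64)
        for k in self._upstream_first:
            ch = self._children[k]
            if ch:
                co = sorted((order[c] for c in ch), reverse=True)
                order[k] = co[0] + 1 if len(co) > 1 and co[1] == co[0] else co[0]
        return order

    def distance_to_outlet_m(self) -> np.ndarray:
        """Along-network distance from each reach (inclusive) to its outlet."""
        dist = np.zeros(len(self._ids), dtype=float)
        for k in self._upstream_first[::-1]:  # downstream before upstream
            d = self._down[k]
            dist[k] = self._lengths[k] + (dist[d] if d >= 0 else 0.0)
        return dist

    # -- (de)serialisation -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        down = [None if d < 0 else int(self._ids[d]) for d in self._down]
        return pd.DataFrame(
            {
                "reach_id": self._ids,
                "downstream_id": pd.array(down, dtype="Int64"),
                "length_m": self._lengths,
                "x": self._xy[:, 0],
                "y": self._xy[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiverNetwork":
        reaches = [
            Reach(
                reach_id=int(row.reach_id),
                downstream_id=None if pd.isna(row.downstream_id) else int(row.downstream_id),
                length_m=float(row.length_m),
                x=float(row.x),
                y=float(row.y),
            )
            for row in df.itertuples()
        ]
        return cls(reaches)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiverNetwork":
        return cls.from_frame(pd.read_csv(path, dtype={"downstream_id": "Int64"}))


@dataclass
class EpochPair:
    """Contemporary and pre-human predictor tables over the same reaches.

    Columns outside ``substitution_set`` are identical between epochs by
    construction; the five substituted columns carry the land-cover/climate
    differences between the epochs.
    """

    contemporary: pd.DataFrame
    prehuman: pd.DataFrame
    substitution_set: tuple[str, ...] = SUBSTITUTED_PREDICTORS

    def __post_init__(self) -> None:
        if not self.contemporary.index.equals(self.prehuman.index):
            raise InvalidArgumentError("epoch tables must cover identical reach_ids")
        for col in self.substitution_set:
            if col not in self.contemporary.columns:
                raise InvalidArgumentError(f"substituted column {col!r} missing")


@dataclass
class OccupancyTruth:
    """Known per-reach occupancy under the three generative regimes.

    ``probs`` has one row per reach and columns ``pristine`` (pre-human
    habitat, no predators), ``converted`` (contemporary habitat, no
    predators) and ``predation`` (contemporary habitat with occupancy zeroed
    outside predation refuges).
    """

    probs: pd.DataFrame
    coefficients: dict[str, float]
    refuge_ids: frozenset[int]

    REGIMES = ("pristine", "converted", "predation")

    def true_loss_percentages(self, lengths_m: pd.Series) -> tuple[float, float]:
        """Length-weighted (habitat_loss_pct, predation_loss_pct) ground truth."""
        w = lengths_m.reindex(self.probs.index).to_numpy(dtype=float)
        eh = {r: float(np.sum(self.probs[r].to_numpy() * w)) for r in self.REGIMES}
        habitat = 100.0 * (1.0 - eh["converted"] / eh["pristine"])
        predation = 100.0 * (1.0 - eh["predation"] / eh["converted"])
        return habitat, predation


def _default_suitability_coefs() -> dict[str, float]:
    # Preference for forested, flow-stable, cool, shaded reaches.  Signs are
    # chosen so land conversion (forest/shade down, temperature up) can only
    # lower the habitat score, which guarantees the regime nesting
    # pristine >= converted >= predation reach-wise.
    return {
        "segIndigenousForest": 3.0,
        "usIndigenousForest": 1.5,
        "segShade": 1.5,
        "segTempSummer": -0.30,
        "segFlowStability": 4.0,
        "FRE3": -0.10,
    }


@dataclass
class GeneratorConfig:
    """Settings for the synthetic riverscape.

    Defaults describe a mid-sized desk-scale riverscape: a few thousand
    ~700 m reaches, roughly half the network suitable before human arrival,
    lowland conversion removing about 40% of pristine effective habitat and
    predation refuges retaining about 10% of what remains.
    """

    n_reaches: int = 3000
    n_outlets: int = 4
    mean_length_m: float = 700.0
    length_cv: float = 0.5
    # land conversion (pre-human -> contemporary)
    conversion_fraction: float = 0.67
    conversion_softness: float = 0.08
    forest_loss: tuple[float, float] = (0.85, 1.0)
    summer_warming: float = 1.2
    winter_warming: float = 0.5
    # ground-truth occupancy
    suitability_coefs: dict[str, float] = field(default_factory=_default_suitability_coefs)
    suitability_sharpness: float = 3.0
    suitability_threshold: float = -0.5
    # predation refuges
    refuge_mode: str = "clusters"  # 'clusters' | 'covariate' | 'none'
    refuge_fraction: float = 0.10
    n_refugia: int = 6
    refuge_slope_quantile: float = 0.75
    refuge_forest_min: float = 0.5
    # presence records
    n_records: int = 6000

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def generate_network(
    n_reaches: int,
    n_outlets: int = 3,
    mean_length_m: float = 700.0,
    length_cv: float = 0.5,
    seed: int = 0,
) -> RiverNetwork:
    """Grow a random branching river network by recursive upstream attachment.

    Each new reach attaches upstream of a uniformly chosen existing reach, so
    components stay rooted at their outlets and the result is a forest with
    exactly ``n_outlets`` components.  Reach lengths are log-normal with the
    requested mean and coefficient of variation; reach midpoints follow a
    branching random walk in the plane.
    """
    if n_reaches < 1:
        raise InvalidArgumentError(f"n_reaches must be >= 1, got {n_reaches}")
    if n_outlets < 1 or n_outlets > n_reaches:
        raise InvalidArgumentError(
            f"n_outlets must be in [1, n_reaches]; got {n_outlets} for "
            f"{n_reaches} reaches"
        )
    rng = np.random.default_rng(seed)
    sigma2 = math.log(1.0 + length_cv**2)
    mu = math.log(mean_length_m) - sigma2 / 2.0
    lengths = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_reaches)

    extent = math.sqrt(n_reaches) * mean_length_m * 0.7
    xy = np.zeros((n_reaches, 2))
    downstream = np.full(n_reaches, -1, dtype=np.int64)
    xy[:n_outlets] = rng.uniform(0.0, extent, size=(n_outlets, 2))
    for i in range(n_outlets, n_reaches):
        parent = int(rng.integers(0, i))
        downstream[i] = parent
        theta = rng.uniform(0.0, 2.0 * math.pi)
        step = 0.5 * (lengths[i] + lengths[parent])
        xy[i] = xy[parent] + step * np.array([math.cos(theta), math.sin(theta)])

    reaches = [
        Reach(
            reach_id=i,
            downstream_id=None if downstream[i] < 0 else int(downstream[i]),
            length_m=float(lengths[i]),
            x=float(xy[i, 0]),
            y=float(xy[i, 1]),
        )
        for i in range(n_reaches)
    ]
    return RiverNetwork(reaches)


def temp_seasonality(W: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Winter air temperature normalised with respect to summer temperature.

    Computed as ``((W - mean(W))/sd(W) - (S - mean(S))/sd(S)) * sd(S)`` with
    sample (n-1) standard deviations.  The result is invariant to adding a
    constant to all winter or all summer temperatures.
    """
    W = np.asarray(W, dtype=float)
    S = np.asarray(S, dtype=float)
    if W.shape != S.shape:
        raise InvalidArgumentError("W and S must have the same shape")
    if W.size < 2:
        raise InvalidArgumentError("need at least 2 reaches")
    sw = W.std(ddof=1)
    ss = S.std(ddof=1)
    if sw <= 0 or ss <= 0:
        raise DegenerateInputError("zero variance in winter or summer temperatures")
    return ((W - W.mean()) / sw - (S - S.mean()) / ss) * ss


def _clip(name: str, values: np.ndarray) -> np.ndarray:
    lo, hi = NATIONAL_RANGES[name]
    return np.clip(values, lo, hi)


def _rank_uniform(values: np.ndarray) -> np.ndarray:
    """Map values to (0, 1) by rank; preserves order, kills scale."""
    order = np.argsort(values, kind="stable")
    r = np.empty_like(order, dtype=float)
    r[order] = np.arange(len(values))
    return (r + 0.5) / len(values)


def generate_predictors(
    network: RiverNetwork,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> EpochPair:
    """Generate paired contemporary / pre-human predictor tables.

    Predictors are driven by two latent gradients — *elevation* (rank of the
    along-network distance to the outlet, plus noise) and *wetness* (a smooth
    planar gradient, plus noise) — so that forest, slope, temperature and
    flow stability co-vary as they do along real mountain-to-lowland
    riverscapes.  Land conversion removes most indigenous forest (and its
    riparian shade) and warms air temperatures in a configurable fraction of
    lowland reaches; the pre-human epoch is the unconverted counterfactual.
    """
    cfg = config or GeneratorConfig()
    n = len(network)
    if n < 2:
        raise InvalidArgumentError("need at least 2 reaches to generate predictors")
    rng = np.random.default_rng(seed)

    dist = network.distance_to_outlet_m()
    elev = _rank_uniform(dist + rng.normal(0.0, 0.15 * dist.std() + 1e-9, n))
    xy = network.coords.to_numpy()
    span = xy.max(axis=0) - xy.min(axis=0) + 1e-9
    direction = rng.normal(size=2)
    direction /= np.linalg.norm(direction)
    wet_raw = (xy - xy.min(axis=0)) / span @ direction
    wet = _rank_uniform(wet_raw + rng.normal(0.0, 0.25, n))

    # lowland conversion mask (soft elevation threshold)
    conv_logit = (cfg.conversion_fraction - elev) / max(cfg.conversion_softness, 1e-9)
    converted = rng.random(n) < 1.0 / (1.0 + np.exp(-conv_logit))
    if cfg.conversion_fraction <= 0:
        converted[:] = False

    # land cover
    f_pre = np.clip(0.78 + 0.18 * elev + rng.normal(0.0, 0.08, n), 0.0, 1.0)
    loss = rng.uniform(*cfg.forest_loss, n)
    f_con = np.where(converted, f_pre * (1.0 - loss), f_pre)

    shade_noise = rng.normal(0.0, 0.04, n)
    def shade_of(f: np.ndarray) -> np.ndarray:
        return np.clip(0.8 * f * (0.75 + 0.35 * wet) + shade_noise, 0.0, 0.8)

    # climate
    s_pre = _clip("segTempSummer", 16.3 - 6.0 * (elev - 0.5) + rng.normal(0.0, 0.8, n))
    s_con = _clip("segTempSummer", s_pre + cfg.summer_warming * converted)
    w_pre = s_pre - 8.0 - 2.0 * elev + rng.normal(0.0, 0.6, n)
    w_con = w_pre + cfg.winter_warming * converted

    # shared (epoch-invariant) predictors
    shared = {
        "segSinuosity": _clip("segSinuosity", 1.0 + np.exp(rng.normal(-2.3, 0.7, n))),
        "segSlope": _clip("segSlope", 0.04 + 0.25 * (elev - 0.4) + rng.normal(0.0, 0.08, n)),
        "segSlopeCatchment": _clip(
            "segSlopeCatchment", 28.0 * elev**1.4 + rng.normal(0.0, 2.5, n)
        ),
        "Feb": _clip("Feb", 0.62 + 0.30 * (0.5 - wet) + rng.normal(0.0, 0.12, n)),
        "FRE3": _clip(
            "FRE3", 13.0 + 9.0 * (elev - 0.5) + 7.0 * (wet - 0.5) + rng.normal(0.0, 2.0, n)
        ),
        "segFlowStability": _clip(
            "segFlowStability", 0.17 + 0.35 * (elev - 0.5) + rng.normal(0.0, 0.07, n)
        ),
        "segHabitat": _clip("segHabitat", 3.4 + 1.6 * elev + rng.normal(0.0, 0.45, n)),
        "segSediment": _clip("segSediment", 3.3 + 1.7 * elev + rng.normal(0.0, 0.5, n)),
        "segGravelCobble": _clip(
            "segGravelCobble", 0.5 + 0.12 * (elev - 0.5) + rng.normal(0.0, 0.07, n)
        ),
    }
    upstream_len_km = network.upstream_sum(network.lengths_m.to_numpy()) / 1000.0
    mean_flow = _clip(
        "MeanFlow", 0.045 * upstream_len_km**1.1 * (0.4 + 1.2 * wet)
    )
    shared["MeanFlow"] = mean_flow
    shared["WidthQ50"] = _clip(
        "WidthQ50", 3.2 * np.sqrt(mean_flow) * (0.8 + 0.4 * rng.random(n)) + 0.3
    )
    shared["Order"] = np.minimum(network.strahler_order(), 8)

    def build_table(f: np.ndarray, s: np.ndarray, w: np.ndarray) -> pd.DataFrame:
        cols = dict(shared)
        cols["segIndigenousForest"] = f
        cols["usIndigenousForest"] = network.upstream_length_weighted_mean(f)
        cols["segShade"] = shade_of(f)
        cols["segTempSummer"] = s
        cols["segTempSeasonality"] = temp_seasonality(w, s)
        df = pd.DataFrame(cols, index=pd.Index(network.reach_ids, name="reach_id"))
        return df[list(PREDICTOR_NAMES)]

    contemporary = build_table(f_con, s_con, w_con)
    prehuman = build_table(f_pre, s_pre, w_pre)
    return EpochPair(contemporary=contemporary, prehuman=prehuman)


def _occupancy(df: pd.DataFrame, cfg: GeneratorConfig) -> np.ndarray:
    score = np.zeros(len(df))
    for name, beta in cfg.suitability_coefs.items():
        score += beta * df[name].to_numpy(dtype=float)
    logit = cfg.suitability_sharpness * (score - cfg.suitability_threshold)
    return 1.0 / (1.0 + np.exp(-logit))


def _refuge_mask(
    network: RiverNetwork,
    contemporary: pd.DataFrame,
    p_converted: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(network)
    if cfg.refuge_mode == "none":
        return np.ones(n, dtype=bool)
    if cfg.refuge_mode == "covariate":
        slope = contemporary["segSlopeCatchment"].to_numpy()
        forest = contemporary["segIndigenousForest"].to_numpy()
        thr = np.quantile(slope, cfg.refuge_slope_quantile)
        return (slope >= thr) & (forest > cfg.refuge_forest_min)
    if cfg.refuge_mode != "clusters":
        raise InvalidArgumentError(f"unknown refuge_mode {cfg.refuge_mode!r}")

    # geographic clusters: survivor populations persist in a handful of
    # connected sub-networks of still-suitable habitat (e.g. managed
    # reserves); membership is a property of *where* a reach is, not of its
    # habitat covariates, which is what lets a habitat model generalise
    # beyond the occupied fragments.
    lengths = network.lengths_m.to_numpy()
    eligible = p_converted >= 0.5
    if not eligible.any():
        return np.zeros(n, dtype=bool)
    mass = p_converted * lengths
    target_mass = cfg.refuge_fraction * float(mass.sum())
    pos_ids = network.reach_ids
    id_to_pos = {int(i): k for k, i in enumerate(pos_ids)}
    # undirected adjacency restricted to eligible reaches
    adj: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        d_id = network.downstream_id(int(pos_ids[k]))
        if d_id is not None:
            d = id_to_pos[d_id]
            adj[k].append(d)
            adj[d].append(k)
    elig_pos = np.flatnonzero(eligible)
    n_seeds = min(cfg.n_refugia, len(elig_pos))
    seed_order = list(rng.permutation(elig_pos))
    mask = np.zeros(n, dtype=bool)
    frontiers = [deque([int(seed_order.pop())]) for _ in range(n_seeds)]
    total = 0.0
    while total < target_mass:
        if not any(frontiers):
            # clusters exhausted their connected eligible habitat; seed a
            # fresh one so the configured refuge mass is actually reached
            while seed_order and mask[seed_order[-1]]:
                seed_order.pop()
            if not seed_order:
                break
            frontiers.append(deque([int(seed_order.pop())]))
        for fr in frontiers:
            if not fr or total >= target_mass:
                continue
            k = fr.popleft()
            if mask[k] or not eligible[k]:
                continue
            mask[k] = True
            total += mass[k]
            for nb in adj[k]:
                if not mask[nb] and eligible[nb]:
                    fr.append(nb)
        frontiers = [fr for fr in frontiers if fr]
    return mask


def build_truth(
    pair: EpochPair,
    network: RiverNetwork,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> OccupancyTruth:
    """Ground-truth occupancy probabilities for the three generative regimes.

    Occupancy is a sharp logistic function of the habitat score evaluated on
    each epoch's predictors; the predation regime additionally zeroes
    occupancy outside refuge reaches.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    p_pristine = _occupancy(pair.prehuman, cfg)
    p_converted = _occupancy(pair.contemporary, cfg)
    mask = _refuge_mask(network, pair.contemporary, p_converted, cfg, rng)
    p_predation = p_converted * mask
    probs = pd.DataFrame(
        {"pristine": p_pristine, "converted": p_converted, "predation": p_predation},
        index=pair.contemporary.index,
    )
    refuge_ids = frozenset(int(i) for i in network.reach_ids[mask]) if mask.any() else frozenset()
    return OccupancyTruth(
        probs=probs, coefficients=dict(cfg.suitability_coefs), refuge_ids=refuge_ids
    )


def simulate_presences(
    truth: OccupancyTruth,
    regime: str,
    n_records: int,
    seed: int = 0,
) -> frozenset[int]:
    """Draw presence *records* proportional to occupancy and collapse to reaches.

    Multiple records landing on the same reach collapse to a single presence,
    mimicking the de-duplication applied to real sighting databases.
    """
    if regime not in OccupancyTruth.REGIMES:
        raise InvalidArgumentError(
            f"regime must be one of {OccupancyTruth.REGIMES}, got {regime!r}"
        )
    if n_records < 1:
        raise InvalidArgumentError("n_records must be >= 1")
    p = truth.probs[regime].to_numpy(dtype=float)
    total = p.sum()
    if total <= 0:
        raise EmptyPresenceError(
            f"occupancy under regime {regime!r} is zero everywhere; "
            "no presences can be simulated"
        )
    rng = np.random.default_rng(seed)
    ids = truth.probs.index.to_numpy()
    draws = rng.choice(ids, size=n_records, replace=True, p=p / total)
    return frozenset(int(i) for i in draws)
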