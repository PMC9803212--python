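"""Presence/background training data on a kernel-density-constrained area.

Presence-only occurrence data carry no absences, so model fitting contrasts
presence reaches with an equal number of *background* reaches assumed absent.
Background reaches are drawn only from the geographic neighbourhood of the
presences — operationalised as the region where a Gaussian kernel density of
presence midpoints exceeds a low quantile of the density observed at the
presences themselves — which avoids inflating discrimination statistics with
trivially distant habitat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientBackgroundError, InvalidArgumentError

__all__ = [
    "DensitySurface",
    "TrainingSet",
    "silverman_bandwidth",
    "kernel_density_surface",
    "select_background",
]


@dataclass
class DensitySurface:
    """Kernel density of presence midpoints evaluated at every reach."""

    values: pd.Series  # indexed by reach_id, non-negative
    bandwidth: float


@dataclass
class TrainingSet:
    """Equal presence/background rows with aligned predictors.

    ``response`` is 1 for presence reaches and 0 for background reaches; the
    two reach sets are disjoint and equally sized.
    """

    reach_ids: np.ndarray
    response: np.ndarray
    X: pd.DataFrame

    def __post_init__(self) -> None:
        n1 = int((self.response == 1).sum())
        n0 = int((self.response == 0).sum())
        if n1 != n0:
            raise InvalidArgumentError(
                f"presence/background counts must match ({n1} vs {n0})"
            )
        if len(set(self.reach_ids)) != len(self.reach_ids):
            raise InvalidArgumentError("training reach_ids must be unique")

    def __len__(self) -> int:
        return len(self.response)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, "response", self.response)
        out.insert(0, "reach_id", self.reach_ids)
        return out.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrainingSet":
        return cls(
            reach_ids=df["reach_id"].to_numpy(),
            response=df["response"].to_numpy(dtype=np.int64),
            X=df.drop(columns=["reach_id", "response"]),
        )


def silverman_bandwidth(coords: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 2-d isotropic Gaussian kernel."""
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    sigma = coords.std(axis=0, ddof=1).mean() if n > 1 else 1.0
    return float(max(sigma, 1e-12) * n ** (-1.0 / (d + 4)))


def kernel_density_surface(
    presence_coords: np.ndarray,
    eval_coords: np.ndarray,
    bandwidth: float,
    eval_ids: np.ndarray | None = None,
) -> DensitySurface:
    """Isotropic Gaussian kernel density of presences at each evaluation point.

    The surface is a proper density: summing kernel mass over the plane
    integrates to one.
    """
    P = np.atleast_2d(np.asarray(presence_coords, dtype=float))
    E = np.atleast_2d(np.asarray(eval_coords, dtype=float))
    if len(P) < 1:
        raise InvalidArgumentError("need at least one presence point")
    if not bandwidth > 0:
        raise InvalidArgumentError(f"bandwidth must be > 0, got {bandwidth}")
    h2 = bandwidth**2
    # squared distances eval x presence, blocked to bound memory
    dens = np.zeros(len(E))
    block = max(1, int(2e7 // max(len(P), 1)))
    for start in range(0, len(E), block):
        chunk = E[start : start + block]
        d2 = ((chunk[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
        dens[start : start + len(chunk)] = np.exp(-d2 / (2.0 * h2)).sum(axis=1)
    dens /= len(P) * 2.0 * np.pi * h2
    index = pd.Index(eval_ids if eval_ids is not None else np.arange(len(E)))
    return DensitySurface(values=pd.Series(dens, index=index), bandwidth=float(bandwidth))


def select_background(
    presences: frozenset[int] | set[int],
    density: DensitySurface,
    predictors: pd.DataFrame,
    density_quantile: float = 0.05,
    seed: int = 0,
) -> TrainingSet:
    """Draw one background reach per presence from the constrained area.

    Eligible background reaches are non-presence reaches whose presence-kernel
    density is at least the ``density_quantile`` quantile of the density
    values *at the presence reaches*; the draw is uniform without
    replacement.
    """
    if not 0 <= density_quantile < 1:
        raise InvalidArgumentError(
            f"density_quantile must be in [0, 1), got {density_quantile}"
        )
    presence_ids = np.array(sorted(presences), dtype=np.int64)
    if len(presence_ids) == 0:
        raise InvalidArgumentError("presence set is empty")
    missing = set(presence_ids) - set(predictors.index)
    if missing:
        raise InvalidArgumentError(f"presence reaches missing from predictors: {sorted(missing)[:5]}")
    dens = density.values
    threshold = float(np.quantile(dens.loc[presence_ids].to_numpy(), density_quantile))
    eligible = dens.index[(dens.to_numpy() >= threshold)].difference(presence_ids)
    n_presence = len(presence_ids)
    if len(eligible) < n_presence:
        raise InsufficientBackgroundError(
            f"only {len(eligible)} eligible background reaches for "
            f"{n_presence} presences (short by {n_presence - len(eligible)}); "
            "lower density_quantile or enlarge the network"
        )
    rng = np.random.default_rng(seed)
    background_ids = np.sort(
        rng.choice(eligible.to_numpy(), size=n_presence, replace=False)
    )
    ids = np.concatenate([presence_ids, background_ids])
    response = np.concatenate(
        [np.ones(n_presence, dtype=np.int64), np.zeros(n_presence, dtype=np.int64)]
    )
    X = predictors.loc[ids].reset_index(drop=True)
    return TrainingSet(reach_ids=ids, response=response, X=X)
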