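"""Extrapolation detection (ExDet): univariate and combinational novelty.

A model trained on the environmental conditions at species occurrences may be
asked to predict in places unlike anything it saw.  ExDet quantifies this per
projection point relative to a *reference* predictor matrix (here, the
presence reaches):

* **NT1** (univariate novelty, <= 0): for each covariate, the distance of the
  point below/above the reference range, scaled by the range width, summed
  over covariates.  Zero inside all ranges.
* **NT2** (combinational novelty, >= 0): squared Mahalanobis distance to the
  reference centroid, scaled so the most distant reference point scores 1.
  Values above 1 are novel covariate combinations inside univariate ranges.
* **combined**: NT1 where NT1 < 0, else NT2, so negative = univariate
  novelty, [0, 1] = analogue conditions, > 1 = combinational novelty.
* **MIC** (most influential covariate): the covariate driving the novelty of
  each non-analogue point.

Covariates with zero reference range carry no extrapolation information and
are dropped with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "nt1",
    "nt2",
    "exdet_combined",
    "most_influential_covariate",
    "percent_extrapolating",
    "exdet",
]


def _aligned(reference: pd.DataFrame, projection: pd.DataFrame):
    cols = list(reference.columns)
    missing = [c for c in cols if c not in projection.columns]
    if missing:
        raise InvalidArgumentError(f"projection missing columns: {missing}")
    R = reference[cols].to_numpy(dtype=float)
    P = projection[cols].to_numpy(dtype=float)
    if len(R) < 2:
        raise InvalidArgumentError("reference needs at least 2 rows")
    rng = R.max(axis=0) - R.min(axis=0)
    active = rng > 0
    if not active.all():
        dropped = [c for c, a in zip(cols, active) if not a]
        warnings.warn(f"covariate(s) with zero reference range dropped: {dropped}")
    kept = [c for c, a in zip(cols, active) if a]
    return R[:, active], P[:, active], kept


def nt1(reference: pd.DataFrame, projection: pd.DataFrame) -> pd.Series:
    """Univariate novelty: sum over covariates of the scaled range shortfall."""
    R, P, cols = _aligned(reference, projection)
    ud = _univariate_distances(R, P)
    return pd.Series(ud.sum(axis=1), index=projection.index, name="nt1")


def _univariate_distances(R: np.ndarray, P: np.ndarray) -> np.ndarray:
    lo = R.min(axis=0)
    hi = R.max(axis=0)
    span = hi - lo
    return np.minimum(np.minimum(P - lo, hi - P), 0.0) / span


def _reference_stats(R: np.ndarray):
    mean = R.mean(axis=0)
    cov = np.cov(R, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(cov) / cov.shape[0]
        warnings.warn(f"singular reference covariance; ridge-regularised with eps={eps:.3g}")
        inv = np.linalg.inv(cov + eps * np.eye(cov.shape[0]))
    return mean, inv


def _mahal_sq(X: np.ndarray, mean: np.ndarray, inv: np.ndarray) -> np.ndarray:
    d = X - mean
    return np.einsum("ij,jk,ik->i", d, inv, d)


def nt2(reference: pd.DataFrame, projection: pd.DataFrame) -> pd.Series:
    """Combinational novelty: Mahalanobis distance scaled by the reference max."""
    R, P, cols = _aligned(reference, projection)
    if len(R) <= R.shape[1]:
        warnings.warn(
            "reference has no more rows than covariates; covariance may be unstable"
        )
    mean, inv = _reference_stats(R)
    ref_d = _mahal_sq(R, mean, inv)
    denom = float(ref_d.max())
    vals = _mahal_sq(P, mean, inv) / max(denom, 1e-300)
    return pd.Series(vals, index=projection.index, name="nt2")


def exdet_combined(nt1_values: pd.Series, nt2_values: pd.Series) -> pd.Series:
    """NT1 where univariate novelty exists, otherwise NT2."""
    n1 = np.asarray(nt1_values, dtype=float)
    n2 = np.asarray(nt2_values, dtype=float)
    if n1.shape != n2.shape:
        raise InvalidArgumentError("nt1 and nt2 must be aligned")
    out = np.where(n1 < 0, n1, n2)
    index = nt1_values.index if isinstance(nt1_values, pd.Series) else None
    return pd.Series(out, index=index, name="combined")


def most_influential_covariate(
    reference: pd.DataFrame,
    projection: pd.DataFrame,
    nt1_values: pd.Series | None = None,
    nt2_values: pd.Series | None = None,
) -> pd.Series:
    """The covariate driving the novelty of each non-analogue point.

    For univariate-novel points (NT1 < 0), the covariate with the most
    negative scaled range shortfall.  For combinational-novel points
    (NT2 > 1), the covariate whose removal most reduces the Mahalanobis
    distance.  Analogue points get ``None``.
    """
    if nt1_values is None:
        nt1_values = nt1(reference, projection)
    if nt2_values is None:
        nt2_values = nt2(reference, projection)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R, P, cols = _aligned(reference, projection)
    n1 = nt1_values.to_numpy(dtype=float)
    n2 = nt2_values.to_numpy(dtype=float)
    mic = np.full(len(P), None, dtype=object)

    uni = n1 < 0
    if uni.any():
        ud = _univariate_distances(R, P[uni])
        mic[uni] = np.array(cols, dtype=object)[np.argmin(ud, axis=1)]

    comb = (~uni) & (n2 > 1)
    if comb.any():
        mean, inv = _reference_stats(R)
        full = _mahal_sq(P[comb], mean, inv)
        reductions = np.empty((int(comb.sum()), len(cols)))
        for j in range(len(cols)):
            keep = [k for k in range(len(cols)) if k != j]
            m_j, inv_j = _reference_stats(R[:, keep])
            reductions[:, j] = full - _mahal_sq(P[comb][:, keep], m_j, inv_j)
        mic[comb] = np.array(cols, dtype=object)[np.argmax(reductions, axis=1)]

    return pd.Series(mic, index=projection.index, name="mic")


def percent_extrapolating(combined: pd.Series) -> dict[str, float]:
    """Share of points outside analogue conditions, with a novelty breakdown."""
    c = np.asarray(combined, dtype=float)
    n = len(c)
    if n == 0:
        raise InvalidArgumentError("no points")
    uni = float((c < 0).sum()) / n * 100.0
    comb = float((c > 1).sum()) / n * 100.0
    return {
        "total_pct": uni + comb,
        "univariate_pct": uni,
        "combinational_pct": comb,
    }


def exdet(reference: pd.DataFrame, projection: pd.DataFrame) -> pd.DataFrame:
    """Full ExDet table: nt1, nt2, combined and MIC per projection point."""
    n1 = nt1(reference, projection)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n2 = nt2(reference, projection)
    combined = exdet_combined(n1, n2)
    mic = most_influential_covariate(reference, projection, n1, n2)
    return pd.DataFrame(
        {"nt1": n1, "nt2": n2, "combined": combined, "mic": mic},
        index=projection.index,
    )
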