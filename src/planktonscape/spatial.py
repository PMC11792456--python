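"""Geographic/environmental distances, distance-decay regression, Mantel tests.

Distance-decay fits community dissimilarity on pairwise distance over the
unique (upper-triangle) pairs; because pairs sharing a sample are not
independent, significance comes from Mantel-style simultaneous row/column
permutations rather than from the OLS t-test. The similarity-decay slope is
the exact negation of the dissimilarity slope and both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .diversity import DistanceMatrix

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "haversine_matrix",
    "env_distance_matrix",
    "DecayFit",
    "distance_decay_fit",
    "MantelResult",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, Earth radius 6371.0088 km)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def haversine_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between samples from lat/lon columns."""
    missing = metadata.index[
        metadata["latitude"].isna() | metadata["longitude"].isna()
    ].tolist()
    if missing:
        raise ValueError(f"samples with missing coordinates: {missing}")
    lat = np.radians(metadata["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata["longitude"].to_numpy(dtype=float))
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(metadata.index), values=(d + d.T) / 2)


def env_distance_matrix(
    env: pd.DataFrame, variables: list[str] | None = None, standardize: bool = True
) -> DistanceMatrix:
    """Euclidean distance on (optionally z-scored) environmental variables."""
    if variables is None:
        variables = [c for c in env.columns if c != "sample_id"]
    if not variables:
        raise ValueError("need at least one variable")
    x = env[variables].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("environmental variables must be finite")
    if standardize:
        sd = x.std(axis=0, ddof=0)
        zero = [variables[i] for i in np.where(sd == 0)[0]]
        if zero:
            raise ValueError(f"zero-variance variables cannot be standardized: {zero}")
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(labels=list(env.index), values=d)


@dataclass
class DecayFit:
    predictor: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_pairs: int
    n_permutations: int
    similarity_slope: float


@dataclass
class MantelResult:
    r: float
    p_value: float
    method: str
    n_permutations: int
    seed: int
    alternative: str = "two-sided"


def _check_aligned(d1: DistanceMatrix, d2: DistanceMatrix) -> None:
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share the same labels in the same order")


def distance_decay_fit(
    comm: DistanceMatrix,
    pred: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    predictor: str = "distance",
) -> DecayFit:
    """OLS of community dissimilarity on a predictor distance over unique pairs.

    The permutation p-value applies simultaneous row/column permutations of
    the community matrix (pairs are non-independent); two-sided on the slope.
    """
    _check_aligned(comm, pred)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y_mat = comm.values
    x = pred.condensed()
    y = comm.condensed()
    if np.std(x) == 0:
        raise ValueError("degenerate predictor: all pairwise distances equal")
    res = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    n = comm.n
    xc = x - x.mean()
    sxx = (xc**2).sum()
    obs_slope = res.slope
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(y_mat[np.ix_(perm, perm)], checks=False)
        slope_p = (xc * (yp - yp.mean())).sum() / sxx
        hits += abs(slope_p) >= abs(obs_slope)
    p = (1 + hits) / (1 + n_perm)
    return DecayFit(
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(p),
        n_pairs=len(y),
        n_permutations=n_perm,
        similarity_slope=float(-res.slope),
    )


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Mantel correlation between two distance matrices with a permutation p-value.

    The null distribution permutes rows and columns of ``d1`` simultaneously.
    Two-sided p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm); 'greater' uses
    the right tail.
    """
    _check_aligned(d1, d2)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    v1 = d1.condensed()
    v2 = d2.condensed()
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant distance matrix")
    if method == "spearman":
        v2r = stats.rankdata(v2)
    else:
        v2r = v2

    def corr(a: np.ndarray) -> float:
        aa = stats.rankdata(a) if method == "spearman" else a
        return float(np.corrcoef(aa, v2r)[0, 1])

    r_obs = corr(v1)
    rng = np.random.default_rng(seed)
    m1 = d1.values
    n = d1.n
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(squareform(m1[np.ix_(perm, perm)], checks=False))
        if alternative == "greater":
            hits += r_p >= r_obs
        else:
            hits += abs(r_p) >= abs(r_obs)
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(
        r=r_obs, p_value=float(p), method=method, n_permutations=n_perm, seed=seed,
        alternative=alternative,
    )
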