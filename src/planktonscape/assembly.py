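"""Community assembly inference: Sloan neutral model fit and stochasticity ratio.

The Sloan neutral community model predicts the frequency with which an OTU
is detected across local communities from its regional mean relative
abundance ``p_i``: with per-sample depth ``N_T``, migration rate ``m``, and
detection limit ``d`` (one read, ``d = 1/N_T``, by default),

    f_hat_i = 1 - BetaCDF(d; N_T m p_i, N_T m (1 - p_i)).

``m`` is estimated by least squares of observed occurrence frequencies
against this prediction; the fit's R^2 and a 95% envelope (Wilson binomial
interval around the prediction at n = n_samples) partition OTUs into
above/within/below the neutral expectation.

The modified stochasticity ratio compares each observed pairwise
dissimilarity ``D_ij`` with its mean under a null assembly ``E_ij``:
MST = D/E when the community is more similar than the null (D <= E), else
(1 - D)/(1 - E); values above 0.5 read as stochasticity-dominated assembly.
The default null redraws each sample's library multinomially from the
pooled regional relative abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from .data_io import OTUTable

__all__ = [
    "occurrence_stats",
    "OccurrenceStats",
    "NCMFit",
    "fit_ncm",
    "null_communities",
    "MSTResult",
    "mst",
]


@dataclass
class OccurrenceStats:
    otu_ids: list[str]
    p: np.ndarray  # mean relative abundance across samples
    f: np.ndarray  # fraction of samples where detected
    n_t: float  # mean library size
    n_samples: int


def occurrence_stats(table: OTUTable) -> OccurrenceStats:
    """Mean relative abundance p_i and occurrence frequency f_i per OTU.

    OTUs absent from every sample are excluded with a warning.
    """
    if table.n_samples == 0 or table.n_otus == 0:
        raise ValueError("empty table")
    if table.n_samples < 5:
        warnings.warn("fewer than 5 samples; occurrence frequencies are coarse", stacklevel=2)
    rel = table.relative_abundance()
    present = table.counts.sum(axis=1) > 0
    if not present.all():
        warnings.warn(f"excluding {int((~present).sum())} OTUs absent from all samples",
                      stacklevel=2)
    idx = np.where(present)[0]
    return OccurrenceStats(
        otu_ids=[table.otu_ids[i] for i in idx],
        p=rel[idx].mean(axis=1),
        f=(table.counts[idx] > 0).mean(axis=1),
        n_t=float(table.library_sizes().mean()),
        n_samples=table.n_samples,
    )


@dataclass
class NCMFit:
    m: float
    r2: float
    n_t: float
    d: float
    per_otu: pd.DataFrame = field(repr=False)

    @property
    def fraction_within(self) -> float:
        return float((self.per_otu["partition"] == "within").mean())


def _predicted_frequency(p: np.ndarray, m: float, n_t: float, d: float) -> np.ndarray:
    a = n_t * m * p
    b = n_t * m * (1.0 - p)
    return stats.beta.sf(d, np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def fit_ncm(stats_in: OccurrenceStats, d: float | None = None) -> NCMFit:
    """Fit the Sloan neutral model by least squares over OTUs.

    Minimizes sum_i (f_i - f_hat_i(m))^2 for m in (0, 1]; the 95% envelope is
    the Wilson score interval around f_hat_i at n = n_samples, and each OTU is
    partitioned as above/within/below it.
    """
    p, f = stats_in.p, stats_in.f
    informative = int(((f > 0) & (f < 1)).sum())
    if informative < 10:
        warnings.warn(
            f"only {informative} OTUs with intermediate occurrence; fit may be unstable",
            stacklevel=2,
        )
    n_t = stats_in.n_t
    if d is None:
        d = 1.0 / n_t

    def sse(log_m: float) -> float:
        pred = _predicted_frequency(p, float(np.exp(log_m)), n_t, d)
        return float(((f - pred) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=(np.log(1e-6), 0.0), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"neutral-model fit failed: {res.message}")
    m = float(np.exp(res.x))
    pred = _predicted_frequency(p, m, n_t, d)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else np.nan
    lo, hi = _wilson_interval(pred, stats_in.n_samples)
    partition = np.where(f > hi, "above", np.where(f < lo, "below", "within"))
    per_otu = pd.DataFrame({
        "otu_id": stats_in.otu_ids,
        "p": p,
        "f_observed": f,
        "f_predicted": pred,
        "ci_lower": lo,
        "ci_upper": hi,
        "partition": partition,
    }).set_index("otu_id")
    return NCMFit(m=m, r2=float(r2), n_t=n_t, d=d, per_otu=per_otu)


def _wilson_interval(phat: np.ndarray, n: int, z: float = 1.959963984540054) -> tuple[np.ndarray, np.ndarray]:
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def null_communities(
    table: OTUTable,
    algorithm: str = "abundance-proportional",
    n_iter: int = 100,
    seed: int = 0,
) -> list[np.ndarray]:
    """Null ensembles for the stochasticity ratio.

    ``abundance-proportional`` (default) redraws each sample's observed
    library size multinomially from the pooled regional relative abundances,
    preserving per-sample totals and the regional abundance distribution.
    ``richness-preserving`` shuffles which OTUs occupy each sample while
    keeping its richness, assigning abundances proportionally to the pool.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    totals = table.library_sizes()
    pool = table.counts.sum(axis=1).astype(float)
    pool_p = pool / pool.sum()
    n_otus, n_samples = table.shape
    nulls = []
    if algorithm == "abundance-proportional":
        for _ in range(n_iter):
            null = np.empty((n_otus, n_samples), dtype=np.int64)
            for s in range(n_samples):
                null[:, s] = rng.multinomial(totals[s], pool_p)
            nulls.append(null)
    elif algorithm == "richness-preserving":
        richness = (table.counts > 0).sum(axis=0)
        for _ in range(n_iter):
            null = np.zeros((n_otus, n_samples), dtype=np.int64)
            for s in range(n_samples):
                occ = rng.choice(n_otus, size=richness[s], replace=False, p=pool_p)
                sub_p = pool_p[occ] / pool_p[occ].sum()
                # one guaranteed read per occupant keeps realized richness exact
                null[occ, s] = 1 + rng.multinomial(totals[s] - richness[s], sub_p)
            nulls.append(null)
    else:
        raise ValueError(f"unknown null algorithm {algorithm!r}")
    return nulls


@dataclass
class MSTResult:
    pairwise: np.ndarray  # condensed upper-triangle MST values (NaN where excluded)
    mean: float
    classification: str
    null_algorithm: str
    n_iter: int
    seed: int
    observed_dissimilarity: np.ndarray = field(repr=False, default=None)
    null_mean_dissimilarity: np.ndarray = field(repr=False, default=None)


def _bc_condensed(counts: np.ndarray) -> np.ndarray:
    rel = counts / np.maximum(counts.sum(axis=0, keepdims=True), 1)
    return pdist(rel.T, metric="braycurtis")


def mst(
    table: OTUTable,
    nulls: list[np.ndarray],
    metric: str = "bray_curtis",
    null_algorithm: str = "abundance-proportional",
    n_iter: int | None = None,
    seed: int = 0,
) -> MSTResult:
    """Modified stochasticity ratio from observed vs null pairwise dissimilarity.

    MST_ij = D_ij / E_ij when D_ij <= E_ij, else (1 - D_ij)/(1 - E_ij), with
    E_ij the mean null dissimilarity; pairs with degenerate nulls (E = 0 or 1)
    are excluded with a warning. Classified stochastic when the mean exceeds
    0.5.
    """
    if metric != "bray_curtis":
        raise ValueError("only the Bray-Curtis metric is implemented")
    if not nulls:
        raise ValueError("need at least one null community")
    d_obs = _bc_condensed(table.counts)
    e_null = np.mean([_bc_condensed(n) for n in nulls], axis=0)
    values = np.full_like(d_obs, np.nan)
    degenerate = (e_null <= 0) | (e_null >= 1)
    if degenerate.any():
        warnings.warn(f"excluding {int(degenerate.sum())} pairs with degenerate nulls",
                      stacklevel=2)
    ok = ~degenerate
    low = ok & (d_obs <= e_null)
    high = ok & (d_obs > e_null)
    values[low] = d_obs[low] / e_null[low]
    values[high] = (1 - d_obs[high]) / (1 - e_null[high])
    mean = float(np.nanmean(values))
    return MSTResult(
        pairwise=values,
        mean=mean,
        classification="stochastic" if mean > 0.5 else "deterministic",
        null_algorithm=null_algorithm,
        n_iter=n_iter if n_iter is not None else len(nulls),
        seed=seed,
        observed_dissimilarity=d_obs,
        null_mean_dissimilarity=e_null,
    )
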