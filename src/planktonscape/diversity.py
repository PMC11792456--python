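"""Alpha diversity, Bray-Curtis dissimilarity, NMDS, and group-difference tests.

Shannon-Wiener H = -sum (n_i/N) ln(n_i/N) in nats; Margalef richness
M = (S - 1)/ln N. Bray-Curtis is computed on relative abundances by default
(library sizes may differ); alpha indices always consume raw counts.
The beta-diversity group test is PERMANOVA on the distance matrix (pseudo-F
with a seeded permutation p-value); group comparisons of index values or
environmental variables use classical one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .data_io import OTUTable

__all__ = [
    "shannon_index",
    "margalef_index",
    "alpha_diversity",
    "bray_curtis_matrix",
    "DistanceMatrix",
    "nmds",
    "OrdinationResult",
    "permanova",
    "one_way_anova",
    "GroupTestResult",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values shape must match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    method: str
    df: tuple[int, int] | None = None
    n_permutations: int | None = None


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    n_starts: int
    converged: bool
    seed: int
    labels: list[str] | None = None


def shannon_index(counts: np.ndarray) -> float:
    """Shannon-Wiener diversity H = -sum (n_i/N) ln(n_i/N), zero counts contributing 0."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon index of an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def margalef_index(counts: np.ndarray) -> float:
    """Margalef richness M = (S - 1)/ln N where S = observed taxa, N = total reads."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("Margalef index requires at least 2 individuals (log domain)")
    s = int((counts > 0).sum())
    return float((s - 1) / np.log(n))


def alpha_diversity(table: OTUTable) -> pd.DataFrame:
    """Per-sample Shannon H, Margalef M, observed OTUs S, and total reads N."""
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows.append({
            "sample_id": sid,
            "H": shannon_index(col),
            "M": margalef_index(col),
            "S": int((col > 0).sum()),
            "N": int(col.sum()),
        })
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def bray_curtis_matrix(table: OTUTable, relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: BC = 1 - 2 sum min(x, y) / (sum x + sum y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = table.relative_abundance() if relative else table.counts.astype(float)
    totals = x.sum(axis=0)
    if np.any(totals == 0):
        bad = [table.sample_ids[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"samples with zero total: {bad}")
    from scipy.spatial.distance import pdist

    d = squareform(pdist(x.T, metric="braycurtis"))
    return DistanceMatrix(labels=list(table.sample_ids), values=d)


def _kruskal_stress1(dist: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities."""
    obs = squareform(dist, checks=False)
    emb = squareform(
        np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)), checks=False
    )
    order = np.argsort(obs, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(emb)
    dhat[order] = iso.fit_transform(np.arange(len(order)), emb[order])
    denom = (emb**2).sum()
    if denom == 0:
        return 1.0
    return float(np.sqrt(((emb - dhat) ** 2).sum() / denom))


def _pcoa_init(d: np.ndarray, k: int) -> np.ndarray:
    """Classical-scaling (principal coordinates) start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return coords


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs ``n_starts`` random initializations and keeps the configuration with
    the lowest stress-1; deterministic under ``seed``.
    """
    if not (1 <= k < dist.n):
        raise ValueError("require 1 <= k < n_samples")
    d = np.asarray(dist.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    best: tuple[float, np.ndarray] | None = None
    rng = np.random.default_rng(seed)
    converged = False
    # One start from classical scaling (PCoA), the rest random: the metric
    # start stabilizes the solution and keeps stress nonincreasing in k.
    inits: list[np.ndarray | None] = [_pcoa_init(d, k)] + [None] * (n_starts - 1)
    for init in inits:
        start_seed = int(rng.integers(0, 2**31 - 1))
        mds = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=start_seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(d, init=init)
        s1 = _kruskal_stress1(d, coords)
        if best is None or s1 < best[0]:
            best = (s1, coords)
        converged = converged or mds.n_iter_ < max_iter
    stress, coords = best
    return OrdinationResult(
        coordinates=coords,
        stress=min(stress, 1.0),
        n_starts=n_starts,
        converged=converged,
        seed=seed,
        labels=list(dist.labels),
    )


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    total_ss = d2[np.triu_indices(n, 1)].sum() / n
    within_ss = 0.0
    n_groups = 0
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        n_g = len(idx)
        sub = d2[np.ix_(idx, idx)]
        within_ss += sub[np.triu_indices(n_g, 1)].sum() / n_g
        n_groups += 1
    among_ss = total_ss - within_ss
    df_among = n_groups - 1
    df_within = n - n_groups
    return (among_ss / df_among) / (within_ss / df_within)


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from among/within sums of squared distances;
    p = (1 + #{perm F >= obs F}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    groups = np.asarray(pd.Categorical(np.asarray(groups)).codes)
    if len(groups) != dist.n:
        raise ValueError("groups length must match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")
    d2 = dist.values**2
    obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _pseudo_f(d2, rng.permutation(groups)) >= obs
    p = (1 + hits) / (1 + n_perm)
    return GroupTestResult(
        statistic=float(obs), p_value=float(p), method="PERMANOVA", n_permutations=n_perm
    )


def one_way_anova(values, groups) -> GroupTestResult:
    """Classical one-way ANOVA (F statistic, p from the F distribution)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    if all(np.var(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in all groups")
    f, p = stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = len(values) - len(samples)
    return GroupTestResult(
        statistic=float(f), p_value=float(p), method="one-way ANOVA", df=(df1, df2)
    )
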