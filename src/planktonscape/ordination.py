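"""Gradient-length diagnostics (DCA) and redundancy analysis (RDA).

The detrended-correspondence-analysis step exists only to drive the linear-
vs-unimodal model choice: when the first-axis gradient length is below the
conventional 3 SD (species-turnover) units, a linear constrained ordination
(RDA) of the Hellinger-transformed community matrix is appropriate. The DCA
here uses reciprocal averaging with detrending by segments and no nonlinear
rescaling, so the length is an approximation to the classic SD units —
adequate for the threshold decision it feeds.

RDA regresses the transformed, column-centered community matrix on
standardized environmental predictors and eigen-decomposes the fitted
values; axis percentages are shares of the constrained variance. Overall and
per-variable (marginal) significance use permutation pseudo-F tests, the
marginal ones permuting residuals under the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "GradientLengthResult",
    "dca_gradient_length",
    "RDAResult",
    "rda",
    "PermTestResult",
    "rda_permutation_test",
]


@dataclass
class GradientLengthResult:
    axis1_length: float
    model_choice: str
    threshold: float = 3.0
    n_iterations: int = 0


@dataclass
class RDAResult:
    eigenvalues: np.ndarray
    axis_percent: np.ndarray
    site_scores: np.ndarray
    species_scores: np.ndarray
    biplot_scores: pd.DataFrame
    total_variance: float
    constrained_variance: float
    residual_variance: float
    transform: str
    sample_ids: list[str] = field(default_factory=list)
    otu_ids: list[str] = field(default_factory=list)

    @property
    def constrained_proportion(self) -> float:
        return self.constrained_variance / self.total_variance


@dataclass
class PermTestResult:
    scope: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int


def _ca_axis(
    y: np.ndarray,
    previous: list[np.ndarray],
    axis1: np.ndarray | None,
    n_segments: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, int]:
    """One correspondence-analysis axis by reciprocal averaging.

    ``previous`` axes are removed by weighted orthogonalization; when
    ``axis1`` is given the trial scores are additionally detrended by
    segments along it (the DCA detrending step).
    """
    r = y.sum(axis=1)  # sample totals
    c = y.sum(axis=0)  # species totals
    n = y.shape[0]
    x = np.linspace(-1, 1, n)
    for it in range(1, max_iter + 1):
        u = (y.T @ x) / c
        x_new = (y @ u) / r
        for prev in previous:
            x_new = x_new - (r * prev * x_new).sum() / (r * prev * prev).sum() * prev
        if axis1 is not None:
            x_new = _detrend_by_segments(x_new, axis1, n_segments)
        mean = (r * x_new).sum() / r.sum()
        x_new = x_new - mean
        sd = np.sqrt((r * x_new**2).sum() / r.sum())
        if sd == 0:
            return x_new, it
        x_new = x_new / sd
        if np.abs(x_new - x).max() < tol or np.abs(-x_new - x).max() < tol:
            return x_new, it
        x = x_new
    raise RuntimeError(
        f"reciprocal averaging did not converge after {max_iter} iterations "
        f"(last change {np.abs(x_new - x).max():.3e})"
    )


def _detrend_by_segments(scores: np.ndarray, axis1: np.ndarray, n_segments: int) -> np.ndarray:
    edges = np.linspace(axis1.min(), axis1.max() + 1e-12, n_segments + 1)
    seg = np.clip(np.searchsorted(edges, axis1, side="right") - 1, 0, n_segments - 1)
    out = scores.copy()
    for s in np.unique(seg):
        idx = seg == s
        out[idx] = out[idx] - out[idx].mean()
    return out


def dca_gradient_length(
    Y: np.ndarray,
    n_segments: int = 26,
    threshold: float = 3.0,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> GradientLengthResult:
    """First-axis gradient length in (approximate) SD turnover units.

    ``Y`` is samples x species, nonnegative, with no empty rows or columns.
    The axis is scaled so that the mean within-sample dispersion of species
    scores is one; the reported length is the sample-score range on that
    scale. Complete turnover between samples gives an infinite length
    (within-sample dispersion zero), which correctly selects the unimodal
    model.
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim != 2 or np.any(y < 0):
        raise ValueError("Y must be a nonnegative 2-D matrix (samples x species)")
    if np.any(y.sum(axis=1) == 0) or np.any(y.sum(axis=0) == 0):
        raise ValueError("Y must have no empty rows or columns")
    r = y.sum(axis=1)
    c = y.sum(axis=0)
    x1, it1 = _ca_axis(y, previous=[], axis1=None, n_segments=n_segments, max_iter=max_iter, tol=tol)
    # axis 2 is computed (detrended along axis 1) for completeness/diagnostics
    it2 = 0
    if y.shape[0] > 2:
        try:
            _, it2 = _ca_axis(y, previous=[x1], axis1=x1, n_segments=n_segments,
                              max_iter=max_iter, tol=max(tol, 1e-8))
        except RuntimeError:
            it2 = max_iter  # axis-2 detrending may cycle; axis-1 length is unaffected
    u = (y.T @ x1) / c  # species scores: weighted averages of sample scores
    xs = (y @ u) / r  # sample scores on the species-score scale
    w = y / r[:, None]
    within_var = w @ u**2 - xs**2  # within-sample dispersion of species scores
    alpha2 = (r * within_var).sum() / r.sum()
    if alpha2 <= 1e-12:
        length = np.inf
    else:
        # range of sample scores in units of the mean within-sample sd:
        # the (approximate) SD species-turnover unit
        length = float((xs.max() - xs.min()) / np.sqrt(alpha2))
    choice = "linear" if length < threshold else "unimodal"
    return GradientLengthResult(
        axis1_length=length, model_choice=choice, threshold=threshold, n_iterations=it1 + it2
    )


def hellinger(Y: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-wise relative abundances."""
    y = np.asarray(Y, dtype=float)
    totals = y.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("empty sample rows")
    return np.sqrt(y / totals)


def _transform_community(Y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "hellinger":
        return hellinger(Y)
    if transform == "chord":
        y = np.asarray(Y, dtype=float)
        norms = np.linalg.norm(y, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("empty sample rows")
        return y / norms
    if transform == "none":
        return np.asarray(Y, dtype=float)
    raise ValueError(f"unknown transform {transform!r}")


def _prepare_predictors(X: pd.DataFrame | np.ndarray, standardize: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i + 1}" for i in range(x.shape[1])]
    if standardize:
        sd = x.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [names[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"constant predictor columns: {bad}")
        x = (x - x.mean(axis=0)) / sd
    else:
        x = x - x.mean(axis=0)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name columns involved in the collinearity via QR pivoting
        _, _, piv = sla.qr(x, pivoting=True, mode="economic")
        rank = np.linalg.matrix_rank(x)
        bad = [names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient predictors; collinear columns include {bad}")
    return x, names


def rda(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    transform: str = "hellinger",
    standardize_X: bool = True,
    sample_ids: list[str] | None = None,
    otu_ids: list[str] | None = None,
) -> RDAResult:
    """Redundancy analysis of a community matrix on environmental predictors.

    ``Y`` is samples x OTUs (raw counts; transformed then column-centered),
    ``X`` samples x predictors. Axis percentages are shares of the
    constrained variance; constrained + residual variance equals the total
    variance of the transformed community matrix.
    """
    yt = _transform_community(Y, transform)
    n = yt.shape[0]
    x, names = _prepare_predictors(X, standardize_X)
    if n <= x.shape[1] + 1:
        raise ValueError("need n_samples > n_predictors + 1")
    yc = yt - yt.mean(axis=0)
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    yhat = x @ beta
    u_svd, s, vt = np.linalg.svd(yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    q = min(x.shape[1], int((eig > 1e-12 * max(eig.max(), 1.0)).sum()))
    eig = eig[:q]
    site_scores = u_svd[:, :q] * s[:q]
    species_scores = vt[:q].T
    total_var = float((yc**2).sum() / (n - 1))
    constrained_var = float((yhat**2).sum() / (n - 1))
    percent = 100.0 * eig / eig.sum()
    biplot = pd.DataFrame(
        np.array([
            [np.corrcoef(x[:, j], site_scores[:, a])[0, 1] for a in range(q)]
            for j in range(x.shape[1])
        ]),
        index=names,
        columns=[f"RDA{a + 1}" for a in range(q)],
    )
    return RDAResult(
        eigenvalues=eig,
        axis_percent=percent,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot,
        total_variance=total_var,
        constrained_variance=constrained_var,
        residual_variance=total_var - constrained_var,
        transform=transform,
        sample_ids=list(sample_ids or []),
        otu_ids=list(otu_ids or []),
    )


def _rda_ss(x: np.ndarray, yc: np.ndarray) -> float:
    """Constrained sum of squares of yc projected onto x."""
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    return float(((x @ beta) ** 2).sum())


def rda_permutation_test(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    scope: str = "overall",
    n_perm: int = 999,
    seed: int = 0,
    transform: str = "hellinger",
    standardize_X: bool = True,
) -> PermTestResult | list[PermTestResult]:
    """Monte-Carlo significance for RDA.

    ``scope='overall'`` permutes community rows and compares the overall
    pseudo-F = (constrained SS / q) / (residual SS / (n - q - 1)).
    ``scope='marginal'`` tests each predictor by permuting residuals of the
    reduced model (all other predictors) and returns one result per variable.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    yt = _transform_community(Y, transform)
    yc = yt - yt.mean(axis=0)
    x, names = _prepare_predictors(X, standardize_X)
    n, q = x.shape
    if n <= q + 1:
        raise ValueError("need n_samples > n_predictors + 1")
    total_ss = float((yc**2).sum())
    rng = np.random.default_rng(seed)

    if scope == "overall":
        ss_full = _rda_ss(x, yc)
        f_obs = (ss_full / q) / ((total_ss - ss_full) / (n - q - 1))
        hits = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            ss_p = _rda_ss(x, yp)
            f_p = (ss_p / q) / ((total_ss - ss_p) / (n - q - 1))
            hits += f_p >= f_obs
        return PermTestResult(
            scope="overall",
            statistic=float(f_obs),
            p_value=float((1 + hits) / (1 + n_perm)),
            n_permutations=n_perm,
            seed=seed,
        )

    if scope == "marginal":
        results = []
        ss_full = _rda_ss(x, yc)
        resid_ms_full = (total_ss - ss_full) / (n - q - 1)
        for j, name in enumerate(names):
            x_red = np.delete(x, j, axis=1)
            if x_red.shape[1] > 0:
                beta_red, *_ = np.linalg.lstsq(x_red, yc, rcond=None)
                fit_red = x_red @ beta_red
            else:
                fit_red = np.zeros_like(yc)
            resid_red = yc - fit_red
            ss_red = float((fit_red**2).sum())
            f_obs = (ss_full - ss_red) / resid_ms_full
            hits = 0
            for _ in range(n_perm):
                y_star = fit_red + resid_red[rng.permutation(n)]
                y_star = y_star - y_star.mean(axis=0)
                ss_full_p = _rda_ss(x, y_star)
                ss_red_p = _rda_ss(x_red, y_star) if x_red.shape[1] else 0.0
                resid_ms_p = (float((y_star**2).sum()) - ss_full_p) / (n - q - 1)
                f_p = (ss_full_p - ss_red_p) / resid_ms_p
                hits += f_p >= f_obs
            results.append(
                PermTestResult(
                    scope=f"marginal:{name}",
                    statistic=float(f_obs),
                    p_value=float((1 + hits) / (1 + n_perm)),
                    n_permutations=n_perm,
                    seed=seed,
                )
            )
        return results

    raise ValueError(f"unknown scope {scope!r}; expected 'overall' or 'marginal'")
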