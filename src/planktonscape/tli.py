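"""Trophic level index (TLI) for Chinese lakes and reservoirs.

The composite index TLI(sum) = sum_j W_j * TLI(j) weights five log-linear
sub-indices — chlorophyll a (mg/m3), total phosphorus, total nitrogen
(mg/L), Secchi transparency (m), and permanganate oxygen demand COD_Mn
(mg/L) — by the squared correlation of each parameter with chlorophyll a:
W_j = r_j^2 / sum r^2. The national grading standard maps the 0-100 index
onto oligotrophic / mesotrophic / eutrophic classes, the eutrophic class
splitting into light, middle, and hyper sub-bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TLI_PARAMETERS",
    "DEFAULT_R",
    "TLIWeights",
    "compute_weights",
    "tli_subindex",
    "composite_tli",
    "classify_trophic_status",
    "tli_per_sample",
    "tli_per_site",
    "tli_linear_regressions",
]

#: Sub-index coefficients a, b in TLI(param) = 10 * (a + b * ln(value)).
#: Units: Chl_a mg/m3; SD m; TP, TN, COD_Mn mg/L.
_SUBINDEX_COEFFS = {
    "Chl_a": (2.5, 1.086),
    "TP": (9.436, 1.624),
    "TN": (5.453, 1.694),
    "SD": (5.118, -1.94),
    "COD_Mn": (0.109, 2.661),
}

TLI_PARAMETERS = list(_SUBINDEX_COEFFS)

#: Correlations with the reference parameter Chl a for Chinese lakes and
#: reservoirs (national survey values), in TLI_PARAMETERS order.
DEFAULT_R = np.array([1.0, 0.84, 0.82, -0.83, 0.83])


@dataclass
class TLIWeights:
    """Normalized relative weights W_j proportional to r_j^2."""

    parameters: list[str]
    r: np.ndarray
    r2: np.ndarray = field(init=False)
    W: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if len(self.r) != len(self.parameters):
            raise ValueError("r length must match parameters")
        if len(self.r) < 2:
            raise ValueError("need at least 2 evaluation parameters")
        self.r2 = self.r**2
        total = self.r2.sum()
        if total == 0:
            raise ValueError("all-zero correlation vector")
        self.W = self.r2 / total

    def as_series(self) -> pd.Series:
        return pd.Series(self.W, index=self.parameters, name="W")


def compute_weights(r_vector=DEFAULT_R, parameters: list[str] | None = None) -> TLIWeights:
    """Weights W_j = r_j^2 / sum_j r_j^2 from correlations with Chl a."""
    if parameters is None:
        parameters = list(TLI_PARAMETERS[: len(np.atleast_1d(r_vector))])
    return TLIWeights(parameters=parameters, r=np.atleast_1d(r_vector))


def tli_subindex(parameter: str, value: float) -> float:
    """Log-linear sub-index TLI(parameter) = 10 * (a + b * ln(value))."""
    if parameter not in _SUBINDEX_COEFFS:
        raise KeyError(f"unknown TLI parameter {parameter!r}; expected one of {TLI_PARAMETERS}")
    if value <= 0:
        raise ValueError(f"{parameter} must be > 0 for the TLI logarithm (got {value})")
    a, b = _SUBINDEX_COEFFS[parameter]
    return float(10.0 * (a + b * np.log(value)))


def composite_tli(
    subindices: dict[str, float],
    weights: TLIWeights | None = None,
    renormalize: bool = False,
) -> float:
    """Weighted sum of sub-indices; weights re-normalized over the present subset on request."""
    if weights is None:
        weights = compute_weights()
    w = dict(zip(weights.parameters, weights.W))
    missing = [p for p in weights.parameters if p not in subindices]
    if missing and not renormalize:
        raise ValueError(f"missing sub-indices {missing}; pass renormalize=True to drop them")
    present = [p for p in weights.parameters if p in subindices]
    wsum = sum(w[p] for p in present)
    return float(sum(w[p] / wsum * subindices[p] for p in present))


def classify_trophic_status(tli: float) -> dict:
    """National grading: class label plus eutrophic sub-band when applicable.

    TLI < 30 oligotrophic; 30 <= TLI < 50 mesotrophic; TLI > 50 eutrophic
    (50-60 light, 60-70 middle, > 70 hyper). TLI exactly 50 sits between the
    printed bands and is assigned to Mesotrophic with a boundary flag.
    """
    if not np.isfinite(tli):
        raise ValueError("TLI must be finite")
    boundary = False
    subclass = None
    if tli < 30:
        label = "Oligotrophic"
    elif tli < 50:
        label = "Mesotrophic"
    elif tli == 50:
        label = "Mesotrophic"
        boundary = True
    else:
        label = "Eutrophic"
        if tli <= 60:
            subclass = "Light eutrophic"
        elif tli <= 70:
            subclass = "Middle eutrophic"
        else:
            subclass = "Hyper eutrophic"
    return {"label": label, "subclass": subclass, "boundary": boundary}


def tli_per_sample(env: pd.DataFrame, weights: TLIWeights | None = None) -> pd.DataFrame:
    """Sub-indices and composite TLI for every sample in an environment table."""
    if weights is None:
        weights = compute_weights()
    rows = []
    for sid, row in env.iterrows():
        subs = {p: tli_subindex(p, float(row[p])) for p in weights.parameters}
        total = composite_tli(subs, weights)
        status = classify_trophic_status(total)
        rows.append({
            "sample_id": sid,
            **{f"TLI_{p}": subs[p] for p in weights.parameters},
            "TLI": total,
            "status": status["label"],
            "subclass": status["subclass"],
        })
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def tli_per_site(
    env: pd.DataFrame,
    metadata: pd.DataFrame,
    weights: TLIWeights | None = None,
    aggregate: str = "mean_tli",
) -> pd.DataFrame:
    """One TLI per site.

    ``aggregate='mean_tli'`` computes TLI per sample then averages per site
    (default); ``'mean_concentration'`` averages concentrations per site
    first, then scores the site means.
    """
    if weights is None:
        weights = compute_weights()
    site = metadata.loc[env.index, "site"]
    if aggregate == "mean_tli":
        per_sample = tli_per_sample(env, weights)
        tli = per_sample["TLI"].groupby(site).mean()
    elif aggregate == "mean_concentration":
        means = env[weights.parameters].groupby(site).mean()
        tli = pd.Series({
            s: composite_tli({p: tli_subindex(p, float(v[p])) for p in weights.parameters}, weights)
            for s, v in means.iterrows()
        })
        tli.index.name = "site"
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    out = tli.to_frame("TLI")
    out["status"] = [classify_trophic_status(t)["label"] for t in out["TLI"]]
    out["subclass"] = [classify_trophic_status(t)["subclass"] for t in out["TLI"]]
    return out.sort_index()


def tli_linear_regressions(tli_values, predictors: pd.DataFrame) -> pd.DataFrame:
    """Per-predictor OLS of TLI on each column: slope, intercept, r^2, p.

    Also used for TLI vs diversity indices (Shannon H, Margalef M).
    """
    y = np.asarray(tli_values, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for col in predictors.columns:
        x = np.asarray(predictors[col], dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"constant predictor {col!r}")
        res = stats.linregress(x, y)
        rows.append({
            "predictor": col,
            "slope": res.slope,
            "intercept": res.intercept,
            "r2": res.rvalue**2,
            "p_value": res.pvalue,
            "n": len(y),
        })
    return pd.DataFrame(rows).set_index("predictor")
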