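"""City-level summaries, typology, spatial autocorrelation and regressions.

City GVI distributions are summarised by the mean and (population) standard
deviation of their site GVIs; cities are classified into a 2x2 typology by
comparing each city's pair against the cross-city average pair.  Global
Moran's I with row-standardised spatial weights measures whether greenery
clusters in space.  Location-level GVI is modelled by standardized OLS with
three nested predictor sets (street-level attributes, city controls, region
indicators), plus backward-elimination fits per administrative level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree

__all__ = [
    "MODEL_PREDICTORS",
    "TYPOLOGY_LABELS",
    "MoranResult",
    "RegressionResult",
    "summarize_city",
    "classify_cities",
    "morans_i",
    "fit_location_models",
    "fit_by_level",
    "check_covariate_correlations",
]

#: Nested predictor sets of the three location-level models.
MODEL_PREDICTORS: dict[int, tuple[str, ...]] = {
    1: ("CENTER", "LENGTH"),
    2: ("CENTER", "LENGTH", "SIZE", "LEVEL", "DENSITY", "ECONOMY", "ELEVATION", "WATER"),
    3: (
        "CENTER",
        "LENGTH",
        "SIZE",
        "LEVEL",
        "DENSITY",
        "ECONOMY",
        "ELEVATION",
        "WATER",
        "MIDDLE",
        "WEST",
    ),
}

TYPOLOGY_LABELS = (
    "HighAvgLowStd",
    "LowAvgLowStd",
    "HighAvgHighStd",
    "LowAvgHighStd",
)


def summarize_city(site_gvis: Sequence[float]) -> tuple[float, float]:
    """Mean and population standard deviation of a city's site GVIs."""
    vals = np.asarray(site_gvis, dtype=float)
    if vals.size == 0:
        raise ValueError("city has no sites")
    return float(vals.mean()), float(vals.std(ddof=0))


def classify_cities(summaries: pd.DataFrame) -> pd.Series:
    """Four-type typology from each city's (mean, std) GVI pair.

    The reference pair is the unweighted average of the city means and of
    the city stds.  A city is High-average when its mean exceeds the
    reference mean, High-std when its std exceeds the reference std; ties
    go to the Low class on both axes.
    """
    if not {"mean_gvi", "std_gvi"} <= set(summaries.columns):
        raise ValueError("summaries needs columns mean_gvi and std_gvi")
    if len(summaries) < 2:
        raise ValueError("need at least 2 cities to classify")
    ref_mean = summaries["mean_gvi"].mean()
    ref_std = summaries["std_gvi"].mean()
    high_avg = summaries["mean_gvi"] > ref_mean
    high_std = summaries["std_gvi"] > ref_std
    labels = np.where(
        high_avg,
        np.where(high_std, "HighAvgHighStd", "HighAvgLowStd"),
        np.where(high_std, "LowAvgHighStd", "LowAvgLowStd"),
    )
    return pd.Series(labels, index=summaries.index, name="typology")


# ---------------------------------------------------------------------------
# Moran's I


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_i: float
    z_norm: float
    p_norm: float
    p_sim: float | None = None


def _spatial_weights(points: np.ndarray, weights_spec: Mapping) -> np.ndarray:
    """Row-standardised spatial weight matrix.

    ``weights_spec``: {"kind": "knn", "k": 8} or
    {"kind": "idw", "power": p, "max_neighbors": m}.
    """
    n = len(points)
    kind = weights_spec.get("kind", "knn")
    w = np.zeros((n, n))
    if kind == "knn":
        k = int(weights_spec.get("k", 8))
        k = min(k, n - 1)
        tree = cKDTree(points)
        _, idx = tree.query(points, k=k + 1)
        for i in range(n):
            for j in idx[i][1:]:
                w[i, j] = 1.0
    elif kind == "idw":
        power = float(weights_spec.get("power", 1.0))
        d = np.hypot(
            points[:, 0][:, None] - points[:, 0][None, :],
            points[:, 1][:, None] - points[:, 1][None, :],
        )
        with np.errstate(divide="ignore"):
            w = 1.0 / d**power
        np.fill_diagonal(w, 0.0)
        w[~np.isfinite(w)] = 0.0
    else:
        raise ValueError(f"unknown weights kind {kind!r}")
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return w / rs


def morans_i(
    points: np.ndarray,
    values: Sequence[float],
    weights_spec: Mapping | None = None,
    permutations: int = 0,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with a normality z-score and optional permutation p.

    ``points`` is an (n, 2) coordinate array, ``values`` the attribute.
    Weights default to row-standardised 8-nearest-neighbour.  The expected
    value under no autocorrelation is -1/(n-1); the z-score uses the
    normality-assumption variance.  With ``permutations`` > 0, a one-sided
    pseudo p-value from random relabelling is also returned.
    """
    points = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 8:
        raise ValueError("need at least 8 points for Moran's I")
    if np.ptp(vals) == 0:
        raise ValueError("values are constant; Moran's I undefined")
    w = _spatial_weights(points, weights_spec or {"kind": "knn", "k": 8})

    z = vals - vals.mean()
    s0 = w.sum()

    def _stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ w @ zv) / (zv @ zv))

    i_obs = _stat(z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var_norm = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    z_norm = (i_obs - e_i) / np.sqrt(var_norm)
    from scipy import stats as sps

    p_norm = float(2 * sps.norm.sf(abs(z_norm)))

    p_sim = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for b in range(permutations):
            sims[b] = _stat(rng.permutation(z))
        if i_obs >= e_i:
            p_sim = float((1 + (sims >= i_obs).sum()) / (permutations + 1))
        else:
            p_sim = float((1 + (sims <= i_obs).sum()) / (permutations + 1))
    return MoranResult(i_obs, e_i, float(z_norm), p_norm, p_sim)


# ---------------------------------------------------------------------------
# Regressions


@dataclass
class RegressionResult:
    """Standardized OLS fit: coefficients, p-values, adjusted R-squared."""

    model_id: str
    coefficients: pd.Series
    pvalues: pd.Series
    adj_r2: float
    n: int
    dropped: tuple[str, ...] = ()

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.coefficients, "p_value": self.pvalues}
        )


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for c in df.columns:
        col = df[c].astype(float)
        sd = col.std(ddof=0)
        out[c] = 0.0 if sd == 0 else (col - col.mean()) / sd
    return out


def _standardized_ols(
    records: pd.DataFrame, response: str, predictors: Sequence[str], model_id: str
) -> RegressionResult:
    missing = [p for p in list(predictors) + [response] if p not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    data = records[[response, *predictors]].dropna()
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError(f"only {n} records for {len(predictors)} predictors")
    z = _zscore(data)
    x = sm.add_constant(z[list(predictors)], has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        corr = z[list(predictors)].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {pairs}")
    fit = sm.OLS(z[response], x).fit()
    coefs = fit.params.drop("const")
    pvals = fit.pvalues.drop("const")
    return RegressionResult(model_id, coefs, pvals, float(fit.rsquared_adj), n)


def fit_location_models(records: pd.DataFrame, model: int) -> RegressionResult:
    """Fit one of the three nested location-level GVI models.

    Model 1 uses street-level predictors (CENTER, LENGTH); Model 2 adds the
    city controls; Model 3 adds the region indicators (MIDDLE, WEST).  The
    response column is ``GVI``.  Response and predictors are z-scored, so
    the reported coefficients are standardized.
    """
    if model not in MODEL_PREDICTORS:
        raise ValueError("model must be 1, 2 or 3")
    return _standardized_ols(records, "GVI", MODEL_PREDICTORS[model], f"model{model}")


def fit_by_level(
    records: pd.DataFrame,
    level: int,
    p_threshold: float = 0.05,
    min_records: int = 30,
) -> RegressionResult:
    """Backward-elimination fit of the full model within one administrative level.

    Starting from the Model 3 predictor set (LEVEL itself excluded, being
    constant within a level), zero-variance covariates are dropped, then the
    least significant predictor is removed one at a time until every
    remaining predictor has p <= ``p_threshold``.  Deterministic for
    identical inputs.
    """
    sub = records[records["LEVEL_RAW"] == level] if "LEVEL_RAW" in records.columns else records[
        records["LEVEL"] == level
    ]
    if len(sub) < min_records:
        raise ValueError(
            f"only {len(sub)} records at level {level}; need at least {min_records}"
        )
    predictors = [p for p in MODEL_PREDICTORS[3] if p != "LEVEL"]
    dropped = tuple(
        p for p in predictors if sub[p].astype(float).std(ddof=0) == 0
    )
    predictors = [p for p in predictors if p not in dropped]
    while predictors:
        res = _standardized_ols(sub, "GVI", predictors, f"level{level}")
        worst = res.pvalues.idxmax()
        if res.pvalues[worst] <= p_threshold:
            return RegressionResult(
                res.model_id, res.coefficients, res.pvalues, res.adj_r2, res.n, dropped
            )
        predictors.remove(worst)
    return RegressionResult(
        f"level{level}",
        pd.Series(dtype=float),
        pd.Series(dtype=float),
        0.0,
        len(sub),
        dropped,
    )


def check_covariate_correlations(
    records: pd.DataFrame,
    columns: Sequence[str] | None = None,
    flag_threshold: float = 0.7,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations among covariates, flagging |r| > 0.7."""
    cols = list(columns) if columns is not None else [
        c for c in MODEL_PREDICTORS[3] if c in records.columns
    ]
    if len(cols) < 2:
        raise ValueError("need at least 2 covariates")
    corr = records[cols].astype(float).corr()
    flags = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(cols)
        for b in cols[i + 1 :]
        if abs(corr.loc[a, b]) > flag_threshold
    ]
    return corr, flags
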