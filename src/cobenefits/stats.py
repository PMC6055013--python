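"""Statistical layer: regression through the origin, one-way ANOVA,
city-size and pollution-level segmentation, and aggregate health totals.

The central tool is a no-intercept linear model Y = aX.  Because every
indicator is proportional to the energy saved by a measure, a measure with
zero effort has zero benefit, and a model without intercept is the natural
description of indicator-vs-indicator relations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datamodel import SECTORS, AnalysisDataset

logger = logging.getLogger(__name__)

SeMethod = Literal["classical", "hc1", "cluster"]


@dataclass
class FitResult:
    """Through-origin fit summary: slope with CI, uncentered R², sample size."""

    alpha: float
    alpha_ci: Tuple[float, float]
    r_squared: float
    n: int
    conf_level: float = 0.95
    se: float = float("nan")
    degenerate: bool = False
    flagged_low_r2: bool = False


class ThroughOriginRegression(RegressorMixin, BaseEstimator):
    """Least-squares fit of ``y = alpha * x`` with no intercept.

    The slope is ``alpha = sum(x*y) / sum(x**2)``.  R² uses the uncentered
    total sum of squares ``sum(y**2)`` — the centered convention can leave
    [0, 1] when there is no intercept.

    Parameters
    ----------
    conf_level:
        Two-sided confidence level of the slope interval (default 0.95).
    se_method:
        How the slope's standard error is estimated.

        - ``"classical"``: homoscedastic formula ``sqrt(RSS/(n-1)/sum(x**2))``
          with a t interval on n-1 degrees of freedom;
        - ``"hc1"``: heteroscedasticity-consistent (White) estimator with
          the n/(n-1) small-sample factor;
        - ``"cluster"``: cluster-robust estimator with the Bell-McCaffrey
          CR2 small-sample adjustment and Satterthwaite degrees of
          freedom; pass group labels via ``fit(..., groups=...)``.
          Appropriate when errors are shared within cities, as in the
          synthetic data model, where a handful of cities carrying the
          largest measures dominate the fit and plain cluster standard
          errors undercover.

    Attributes
    ----------
    alpha_ : float
        Fitted slope.
    alpha_ci_ : tuple of float
        Confidence interval for the slope.
    se_ : float
        Standard error of the slope.
    r_squared_ : float
        Uncentered R².
    n_ : int
        Number of observations.
    degenerate_ : bool
        True when no finite interval exists (single observation).
    coef_ : ndarray of shape (1,)
        sklearn-style coefficient array, ``[alpha_]``.
    """

    def __init__(self, conf_level: float = 0.95, se_method: SeMethod = "classical"):
        self.conf_level = conf_level
        self.se_method = se_method

    def fit(self, X, y, groups: Optional[Sequence] = None) -> "ThroughOriginRegression":
        X, y = check_X_y(X, y, ensure_min_samples=1)
        if X.shape[1] != 1:
            raise ValueError("ThroughOriginRegression expects a single feature")
        x = X[:, 0].astype(float)
        y = np.asarray(y, dtype=float)
        n = x.size
        sxx = float(np.sum(x * x))
        if sxx <= 0:
            raise ValueError("degenerate fit: all x values are zero")
        alpha = float(np.sum(x * y) / sxx)
        resid = y - alpha * x
        rss = float(np.sum(resid * resid))
        syy = float(np.sum(y * y))
        self.alpha_ = alpha
        self.coef_ = np.array([alpha])
        self.intercept_ = 0.0
        self.n_ = int(n)
        self.r_squared_ = 1.0 if syy == 0 else 1.0 - rss / syy
        self.degenerate_ = False

        if self.se_method == "classical":
            df = n - 1
            var = rss / df / sxx if df > 0 else np.nan
        elif self.se_method == "hc1":
            df = n - 1
            var = float(np.sum(x * x * resid * resid)) / sxx**2
            var *= n / df if df > 0 else np.nan
        elif self.se_method == "cluster":
            if groups is None:
                raise ValueError("se_method='cluster' requires groups= in fit()")
            labels = pd.Series(np.asarray(groups))
            if len(labels) != n:
                raise ValueError("groups must have one label per observation")
            # CR2: with hat matrix H = x x'/sum(x^2), the per-cluster leverage
            # adjustment (I - H_gg)^{-1/2} reduces to dividing the cluster
            # score sum(x_i r_i) by sqrt(1 - sum_g(x_i^2)/sum(x^2)).
            by = pd.DataFrame({"xr": x * resid, "xx": x * x}).groupby(
                labels, sort=False
            ).sum()
            g = len(by)
            if g < 2:
                df = 0
                var = np.nan
            else:
                a_g = by["xx"].to_numpy() / sxx
                u = by["xr"].to_numpy() / np.sqrt(np.clip(1.0 - a_g, 1e-12, None))
                var = float(np.sum(u * u)) / sxx**2
                # Satterthwaite df: equals G for balanced clusters, drops
                # toward 1 when one cluster dominates sum(x^2).
                df = sxx**2 / float(np.sum(by["xx"].to_numpy() ** 2))
        else:
            raise ValueError(f"unknown se_method {self.se_method!r}")

        if df <= 0 or not np.isfinite(var):
            self.degenerate_ = True
            self.se_ = float("nan")
            self.alpha_ci_ = (float("nan"), float("nan"))
        else:
            se = float(np.sqrt(var))
            tcrit = float(sps.t.ppf(0.5 + self.conf_level / 2.0, df))
            self.se_ = se
            self.alpha_ci_ = (alpha - tcrit * se, alpha + tcrit * se)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "alpha_")
        X = check_array(X)
        return X[:, 0] * self.alpha_

    def result_(self) -> FitResult:
        check_is_fitted(self, "alpha_")
        return FitResult(
            alpha=self.alpha_,
            alpha_ci=self.alpha_ci_,
            r_squared=self.r_squared_,
            n=self.n_,
            conf_level=self.conf_level,
            se=self.se_,
            degenerate=self.degenerate_,
        )


def fit_through_origin(
    x: Iterable[float],
    y: Iterable[float],
    conf_level: float = 0.95,
    se_method: SeMethod = "classical",
    groups: Optional[Sequence] = None,
) -> FitResult:
    """Thin functional wrapper over :class:`ThroughOriginRegression`."""
    x = np.asarray(list(x), dtype=float)
    est = ThroughOriginRegression(conf_level=conf_level, se_method=se_method)
    est.fit(x.reshape(-1, 1), np.asarray(list(y), dtype=float), groups=groups)
    return est.result_()


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    group_sizes: Dict[str, int] = field(default_factory=dict)


def one_way_anova(groups: Mapping[str, Iterable[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Groups with fewer than two values are dropped with a warning; at least
    two groups must remain.
    """
    clean: Dict[str, np.ndarray] = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            warnings.warn(f"ANOVA: dropping group '{label}' with <2 values")
            continue
        clean[label] = arr
    if len(clean) < 2:
        raise ValueError("ANOVA requires at least two groups with >=2 values each")

    all_vals = np.concatenate(list(clean.values()))
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in clean.values())
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in clean.values())
    df_b = len(clean) - 1
    df_w = all_vals.size - len(clean)
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        f = 0.0 if msb == 0 else float("inf")
    else:
        f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(
        f_stat=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        group_sizes={k: int(v.size) for k, v in clean.items()},
    )


@dataclass
class SegmentSpec:
    """Two-way split of the cities by a city-level variable.

    ``rule`` is a numeric threshold or the string ``"median"`` (median over
    distinct cities, not over measures).  Cities strictly above go to
    ``labels[0]``; ties and below go to ``labels[1]``.
    """

    variable: Literal["population", "pm25_level", "nox_level"]
    rule: float | str = "median"
    labels: Tuple[str, str] = ("high", "low")

    def __post_init__(self) -> None:
        if not isinstance(self.rule, str) and not self.rule > 0:
            raise ValueError("numeric threshold must be > 0")


def segment(dataset: AnalysisDataset, spec: SegmentSpec) -> Dict[str, AnalysisDataset]:
    """Partition the measures by their city's value of ``spec.variable``."""
    values = {cid: getattr(c, spec.variable) for cid, c in dataset.cities.items()}
    if isinstance(spec.rule, str):
        if spec.rule != "median":
            raise ValueError(f"unknown rule {spec.rule!r}")
        threshold = float(np.median(list(values.values())))
    else:
        threshold = float(spec.rule)
    above, below = spec.labels
    split = {
        above: [m for m in dataset.measures if values[m.city_id] > threshold],
        below: [m for m in dataset.measures if not values[m.city_id] > threshold],
    }
    return {label: dataset.subset(ms) for label, ms in split.items()}


def sectorwise_fits(
    table: pd.DataFrame,
    x_indicator: str,
    y_indicator: str,
    min_r2: float = 0.4,
    conf_level: float = 0.95,
    se_method: SeMethod = "classical",
    cluster_col: Optional[str] = None,
) -> Dict[str, FitResult]:
    """Through-origin fit of ``y_indicator`` on ``x_indicator``, pooled
    ("all") and per sector.

    Sectors whose R² falls below ``min_r2`` are flagged (not dropped);
    sectors with fewer than two measures come back as degenerate
    placeholders.  ``cluster_col`` names a column of cluster labels
    (typically ``city_id``) when ``se_method="cluster"``.
    """
    out: Dict[str, FitResult] = {}
    pieces = [("all", table)] + [
        (s, table[table["sector"] == s]) for s in SECTORS if (table["sector"] == s).any()
    ]
    for label, sub in pieces:
        if len(sub) < 2:
            out[label] = FitResult(
                alpha=float("nan"),
                alpha_ci=(float("nan"), float("nan")),
                r_squared=float("nan"),
                n=len(sub),
                conf_level=conf_level,
                degenerate=True,
            )
            continue
        groups = sub[cluster_col].to_numpy() if cluster_col else None
        res = fit_through_origin(
            sub[x_indicator], sub[y_indicator],
            conf_level=conf_level, se_method=se_method, groups=groups,
        )
        res.flagged_low_r2 = bool(res.r_squared < min_r2)
        out[label] = res
    return out


def per_capita_summary(
    subsets: Mapping[str, AnalysisDataset],
) -> Dict[str, Tuple[float, float]]:
    """Mean CO2 reduction per measure (t/y) and per measure per capita
    (t/y/person), per subset.  Means are unweighted over measures; the
    per-capita value of a measure divides by its own city's population."""
    out: Dict[str, Tuple[float, float]] = {}
    for label, ds in subsets.items():
        if not ds.measures:
            out[label] = (float("nan"), float("nan"))
            continue
        absolute = [m.co2_reduction or 0.0 for m in ds.measures]
        per_cap = [
            (m.co2_reduction or 0.0) / ds.cities[m.city_id].population
            for m in ds.measures
        ]
        out[label] = (float(np.mean(absolute)), float(np.mean(per_cap)))
    return out


def aggregate_health(
    table: pd.DataFrame, group_by: Literal["all", "sector"] = "all"
) -> pd.DataFrame:
    """Bound-by-bound sums of city-total avoided deaths and years of life
    saved, overall or per sector (sector rows add to the total exactly)."""
    cols = ["pd_low", "pd_central", "pd_high", "yls_low", "yls_central", "yls_high"]
    total = {c: float(table[c].sum()) if len(table) else 0.0 for c in cols}
    rows = [{"group": "all", **total}]
    if group_by == "sector":
        for s in SECTORS:
            sub = table[table["sector"] == s]
            rows.append({"group": s, **{c: float(sub[c].sum()) for c in cols}})
    return pd.DataFrame(rows, columns=["group"] + cols)
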