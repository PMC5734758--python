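"""Smooth-term regression, trends, and AIC-weight variable importance.

The modelling engine mirrors a common survey-analysis setup: Gaussian
additive models in which every covariate enters through a smoother
restricted to three degrees of freedom (k = 3).  A 3-df smooth term is
equivalent to a second-degree polynomial, so the engine realizes each
term as a centered quadratic basis fitted by ordinary least squares.
This keeps every fit exact and auditable while retaining the curvature
the k = 3 smoother is meant to capture.

On top of the engine sit:

- global temporal trends (indicator ~ smooth(year)) with an F-test
  against the intercept-only model and a lag-1 residual autocorrelation
  diagnostic;
- per-site linear trends (OLS slope and two-sided p per site);
- all-subsets multimodel inference: every subset of candidate covariates
  is fitted, Akaike weights w_i = exp(-dAIC_i/2)/sum(...) computed, and
  the relative variable importance (RVI) of a covariate is the summed
  weight of the models containing it.  RVI > 0.9 flags high importance,
  RVI > 0.6 moderate; below 0.6 no relationship shape is reported;
- relationship-shape classification (+ / - / unimodal) from the fitted
  term of the full model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothFit",
    "RVIResult",
    "TrendResult",
    "fit_smooth_model",
    "temporal_trend",
    "per_site_trend",
    "all_subsets_rvi",
    "classify_shape",
    "akaike_weights",
]


@dataclass
class SmoothFit:
    """A Gaussian least-squares fit of y on 3-df smooth terms."""

    covariates: list[str]
    intercept: float
    coef: dict[str, np.ndarray]          # per covariate: (linear, quadratic)
    centers: dict[str, tuple[float, float]]  # (x mean, mean of centered x^2)
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    tss: float
    aic: float
    df_total: int
    n: int

    @property
    def deviance_explained(self) -> float:
        if self.tss <= 0:
            return 0.0
        return float(1.0 - self.rss / self.tss)

    def term(self, covariate: str, x: np.ndarray) -> np.ndarray:
        """Evaluate the fitted smooth contribution of one covariate."""
        b1, b2 = self.coef[covariate]
        mu, c2 = self.centers[covariate]
        xc = np.asarray(x, dtype=float) - mu
        return b1 * xc + b2 * (xc**2 - c2)


def _gaussian_aic(rss: float, n: int, df_total: int) -> float:
    # Profile Gaussian log-likelihood; df_total counts intercept, term
    # coefficients and the variance parameter.
    rss = max(rss, 1e-300)
    ll = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    return float(-2.0 * ll + 2.0 * df_total)


def fit_smooth_model(y, covariates: pd.DataFrame, k: int = 3) -> SmoothFit:
    """Fit y ~ intercept + sum of 3-df smooth terms by least squares.

    Each term uses the centered basis [x - mean, (x - mean)^2 - c] so the
    intercept carries the grand mean and term contributions average to
    ~0.  Raises for near-duplicate covariates (|r| > 0.999) and for
    sample sizes too small to support the requested terms.
    """
    if k != 3:
        raise NotImplementedError("only the 3-df (quadratic-equivalent) smoother is supported")
    y = np.asarray(y, dtype=float)
    n = y.size
    names = list(covariates.columns)
    p = len(names)
    if n < 3 * p + 3:
        raise ValueError(f"n={n} too small for {p} smooth terms (need >= {3 * p + 3})")
    if p >= 2:
        corr = covariates.corr().to_numpy()
        for i, j in itertools.combinations(range(p), 2):
            if abs(corr[i, j]) > 0.999:
                raise ValueError(f"collinear covariates: {names[i]!r} and {names[j]!r}")

    cols = [np.ones(n)]
    centers: dict[str, tuple[float, float]] = {}
    for name in names:
        x = covariates[name].to_numpy(dtype=float)
        mu = x.mean()
        xc = x - mu
        c2 = (xc**2).mean()
        centers[name] = (mu, c2)
        cols.extend([xc, xc**2 - c2])
    design = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_total = 1 + 2 * p + 1
    return SmoothFit(
        covariates=names,
        intercept=float(beta[0]),
        coef={name: beta[1 + 2 * i : 3 + 2 * i].copy() for i, name in enumerate(names)},
        centers=centers,
        fitted=fitted,
        residuals=resid,
        rss=rss,
        tss=tss,
        aic=_gaussian_aic(rss, n, df_total),
        df_total=df_total,
        n=n,
    )


@dataclass
class TrendResult:
    scope: str                      # "global" or "per_site"
    slope: float
    p_value: float
    edf: float = float("nan")
    f_stat: float = float("nan")
    deviance_explained: float = float("nan")
    lag1_autocorr: float = float("nan")


def temporal_trend(series: pd.Series) -> TrendResult:
    """Global smooth trend of an annual indicator series.

    Fits indicator ~ smooth(year) (3 df) and tests it against the
    intercept-only model with an exact Gaussian F-test.  The OLS linear
    slope is reported as the direction summary and the residual lag-1
    autocorrelation as a diagnostic (never auto-corrected).
    """
    series = series.dropna()
    if len(series) < 8:
        raise ValueError("temporal trend needs at least 8 years")
    years = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    n = y.size
    fit = fit_smooth_model(y, pd.DataFrame({"year": years}))
    if fit.tss <= 0:
        return TrendResult("global", 0.0, 1.0, 2.0, 0.0, 0.0, 0.0)
    f = ((fit.tss - fit.rss) / 2.0) / (fit.rss / (n - 3)) if fit.rss > 0 else np.inf
    p = float(stats.f.sf(f, 2, n - 3))
    slope = float(stats.linregress(years, y).slope)
    r = fit.residuals
    denom = float(r @ r)
    lag1 = float((r[:-1] @ r[1:]) / denom) if denom > 0 else float("nan")
    return TrendResult("global", slope, p, 2.0, float(f), fit.deviance_explained, lag1)


def per_site_trend(
    table: pd.DataFrame,
    value_col: str,
    min_years: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS slope and significance of a linear year trend for every site.

    ``table`` is long format with columns site_id, year and ``value_col``.
    Sites with fewer than ``min_years`` non-missing years are flagged
    (NaN slope/p) rather than dropped.
    """
    out = []
    for site, grp in table.groupby("site_id", sort=True):
        grp = grp.dropna(subset=[value_col])
        if grp["year"].nunique() < min_years:
            out.append({"site_id": site, "slope": np.nan, "p_value": np.nan, "significant": False})
            continue
        res = stats.linregress(grp["year"].astype(float), grp[value_col].astype(float))
        out.append(
            {
                "site_id": site,
                "slope": float(res.slope),
                "p_value": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(out)


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Akaike weights exp(-dAIC/2) normalized over a model set."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class RVIResult:
    """All-subsets multimodel inference summary."""

    rvi: dict[str, float]
    model_table: pd.DataFrame           # columns: covariates (tuple), aic, weight
    shapes: dict[str, str]
    full_fit: SmoothFit | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": list(self.rvi),
                "rvi": list(self.rvi.values()),
                "shape": [self.shapes[c] for c in self.rvi],
            }
        )


def classify_shape(
    fit: SmoothFit,
    covariate: str,
    x_range: tuple[float, float] | None = None,
    rvi: float | None = None,
    rvi_threshold: float = 0.6,
    n_grid: int = 101,
) -> str:
    """Classify a fitted term as positive, negative, unimodal or none.

    The term is evaluated on a grid over the observed covariate range:
    monotone increasing -> "positive", monotone decreasing -> "negative",
    an interior maximum -> "unimodal".  Anything else (including an
    interior minimum) and any covariate whose RVI falls below
    ``rvi_threshold`` is reported as "none".
    """
    if covariate not in fit.coef:
        raise KeyError(f"{covariate!r} not in fit")
    if rvi is not None and rvi < rvi_threshold:
        return "none"
    if x_range is None:
        mu, c2 = fit.centers[covariate]
        half = 2.0 * np.sqrt(max(c2, 1e-12))
        x_range = (mu - half, mu + half)
    grid = np.linspace(x_range[0], x_range[1], n_grid)
    f = fit.term(covariate, grid)
    scale = max(np.ptp(f), 1e-12)
    d = np.diff(f)
    tol = 1e-9 * scale
    if np.all(d >= -tol):
        return "positive" if np.any(d > tol) else "none"
    if np.all(d <= tol):
        return "negative"
    sign = np.sign(d[np.abs(d) > tol])
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if len(flips) == 1 and sign[0] > 0 and sign[-1] < 0:
        return "unimodal"
    return "none"


def all_subsets_rvi(
    y,
    candidates: pd.DataFrame,
    k: int = 3,
    max_candidates: int = 12,
    rvi_threshold: float = 0.6,
) -> RVIResult:
    """Fit every subset of candidate covariates and sum Akaike weights.

    The model set contains the intercept-only model and all 2^p - 1
    covariate subsets.  RVI(covariate) = sum of the Akaike weights of
    models containing it.  Relationship shapes come from the full model
    and are reported only for covariates with RVI >= ``rvi_threshold``.
    Subsets too large for the available sample size are skipped with a
    notice.
    """
    names = list(candidates.columns)
    p = len(names)
    if p > max_candidates:
        raise ValueError(f"{p} candidates exceed the {max_candidates} (2^{max_candidates} models) cap")
    y = np.asarray(y, dtype=float)

    records = []
    fits: dict[tuple[str, ...], SmoothFit] = {}
    for r in range(p + 1):
        for subset in itertools.combinations(names, r):
            if y.size < 3 * len(subset) + 3:
                logger.info("skipping subset %s: n too small", subset)
                continue
            if subset:
                fit = fit_smooth_model(y, candidates[list(subset)], k=k)
            else:
                resid = y - y.mean()
                rss = float(resid @ resid)
                fit = SmoothFit(
                    covariates=[], intercept=float(y.mean()), coef={}, centers={},
                    fitted=np.full_like(y, y.mean()), residuals=resid, rss=rss,
                    tss=rss, aic=_gaussian_aic(rss, y.size, 2), df_total=2, n=y.size,
                )
            fits[subset] = fit
            records.append({"covariates": subset, "aic": fit.aic})

    table = pd.DataFrame(records)
    table["weight"] = akaike_weights(table["aic"].to_numpy())
    rvi = {
        name: float(table.loc[[name in s for s in table["covariates"]], "weight"].sum())
        for name in names
    }
    full = fits.get(tuple(names))
    shapes = {}
    for name in names:
        if full is not None and name in full.coef:
            x = candidates[name].to_numpy(dtype=float)
            shapes[name] = classify_shape(
                full, name, (x.min(), x.max()), rvi=rvi[name], rvi_threshold=rvi_threshold
            )
        else:
            shapes[name] = "none"
    return RVIResult(rvi=rvi, model_table=table, shapes=shapes, full_fit=full)
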