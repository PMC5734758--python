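"""Survey data preparation: filters, biomass conversion, aggregation.

Takes long-format haul records (one row per haul x species x length
class, CPUE in individuals per hour) through the standard inclusion
filters used for bottom-trawl time series — haul duration within the
30-minute standard (27-33 min), minimum depth 20 m, sites sampled in at
least 80% of survey years, species present in at least 20% of years —
converts CPUE-at-length to biomass per hour with length-weight
relationships (W = a * L^b), and aggregates hauls into a site-year x
species community matrix.  Environmental covariates (winter means,
seasonality, salinity variability, substrate richness/evenness) are
derived from monthly series and substrate coverage tables, and sparse
point observations can be interpolated to site centroids with a smooth
latitude-longitude surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import ceil

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "filter_hauls",
    "filter_sites_by_coverage",
    "filter_species_by_occurrence",
    "aggregate_species",
    "cpue_to_biomass",
    "build_community_matrix",
    "derive_covariates",
    "interpolate_surface",
]

HAUL_KEY_COLUMNS = ["haul_id", "site_id", "year", "depth_m", "duration_min"]


@dataclass
class CommunityMatrix:
    """Site-year x species biomass-per-hour table with haul counts.

    ``biomass`` is a wide DataFrame indexed by (site_id, year), one
    column per species, cells in g/h (mean across the cell's hauls).
    ``n_hauls`` is a Series on the same index.
    """

    biomass: pd.DataFrame
    n_hauls: pd.Series

    def __post_init__(self) -> None:
        if (self.biomass.to_numpy() < 0).any():
            raise ValueError("community biomasses must be non-negative")
        if (self.n_hauls < 1).any():
            raise ValueError("each retained site-year needs at least one haul")

    @property
    def sites(self) -> pd.Index:
        return self.biomass.index.get_level_values("site_id").unique()

    @property
    def years(self) -> pd.Index:
        return self.biomass.index.get_level_values("year").unique()

    @property
    def species(self) -> pd.Index:
        return self.biomass.columns

    def richness(self) -> pd.Series:
        return (self.biomass > 0).sum(axis=1)

    def presence(self, mode: str = "union") -> pd.DataFrame:
        """Binary site x species occupancy.

        ``union``: species ever present at the site across years;
        ``year``: one layer per site-year (index unchanged).
        """
        if mode == "union":
            return (
                (self.biomass > 0).groupby(level="site_id").any().astype(int)
            )
        if mode == "year":
            return (self.biomass > 0).astype(int)
        raise ValueError(f"unknown presence mode {mode!r}")


def filter_hauls(
    hauls: pd.DataFrame,
    min_duration: float = 27.0,
    max_duration: float = 33.0,
    min_depth: float = 20.0,
) -> pd.DataFrame:
    """Keep hauls with duration in [min, max] minutes and depth >= min_depth.

    Bounds are inclusive.  An empty result raises a warning, not an
    error, so pipelines can report the condition.
    """
    keep = (
        hauls["duration_min"].between(min_duration, max_duration)
        & (hauls["depth_m"] >= min_depth)
    )
    out = hauls.loc[keep].copy()
    if out.empty:
        warnings.warn("haul filter removed every record")
    return out


def _year_threshold(min_fraction: float, n_years: int) -> int:
    # ceil with a guard against float fuzz (e.g. 0.8 * 10 = 8.000000000000002)
    frac = Fraction(min_fraction).limit_denominator(10**6)
    return int(ceil(frac * n_years))


def filter_sites_by_coverage(
    hauls: pd.DataFrame,
    min_fraction: float = 26 / 32,
    n_years: int | None = None,
) -> list:
    """Sites sampled in at least ceil(min_fraction x total years) years.

    ``n_years`` defaults to the number of distinct years in the data.
    Returns the sorted retained site ids.
    """
    if hauls["year"].nunique() < 1:
        raise ValueError("no years present")
    total = int(n_years) if n_years is not None else int(hauls["year"].nunique())
    need = _year_threshold(min_fraction, total)
    counts = hauls.groupby("site_id")["year"].nunique()
    return sorted(counts.index[counts >= need])


def filter_species_by_occurrence(
    matrix: CommunityMatrix,
    min_fraction: float = 7 / 32,
    n_years: int | None = None,
) -> CommunityMatrix:
    """Keep species present (biomass > 0 anywhere) in enough distinct years."""
    if matrix.biomass.empty:
        raise ValueError("community matrix is empty")
    total = int(n_years) if n_years is not None else int(matrix.years.nunique())
    need = _year_threshold(min_fraction, total)
    present = matrix.biomass > 0
    years_present = present.groupby(level="year").any().sum(axis=0)
    keep = years_present.index[years_present >= need]
    if len(keep) == 0:
        raise ValueError("occurrence filter removed every species")
    return CommunityMatrix(biomass=matrix.biomass[keep].copy(), n_hauls=matrix.n_hauls.copy())


def aggregate_species(hauls: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Aggregate ecologically similar species into named groups.

    ``mapping`` maps species -> group id; unmapped species pass through
    unchanged (with a log notice).  CPUEs are summed within group per
    haul and length class.
    """
    unmapped = sorted(set(hauls["species"]) - set(mapping))
    if unmapped and mapping:
        logger.info("species passed through unmapped: %s", ", ".join(map(str, unmapped)))
    out = hauls.copy()
    out["species"] = out["species"].map(lambda s: mapping.get(s, s))
    keys = [c for c in hauls.columns if c not in ("cpue_per_h",)]
    # sum CPUE within haul x group x length; all haul-level fields are keys
    return out.groupby(keys, as_index=False, sort=False)["cpue_per_h"].sum()


def cpue_to_biomass(hauls: pd.DataFrame, lw_params: pd.DataFrame) -> pd.DataFrame:
    """Convert CPUE-at-length to biomass per hour via W = a * L^b.

    ``lw_params`` has columns species, a, b (a in g cm^-b).  Returns one
    row per haul x species with ``biomass_per_h`` in g/h, keeping the
    haul-level fields.  Species without parameters are an error.
    """
    lw = lw_params.set_index("species") if "species" in lw_params.columns else lw_params
    missing = sorted(set(hauls["species"]) - set(lw.index))
    if missing:
        raise KeyError(f"no length-weight parameters for: {', '.join(map(str, missing))}")
    a = hauls["species"].map(lw["a"]).to_numpy(dtype=float)
    b = hauls["species"].map(lw["b"]).to_numpy(dtype=float)
    w = hauls["cpue_per_h"].to_numpy(dtype=float) * a * hauls["length_cm"].to_numpy(dtype=float) ** b
    tmp = hauls.assign(biomass_per_h=w)
    keys = [c for c in HAUL_KEY_COLUMNS if c in hauls.columns] + ["species"]
    return tmp.groupby(keys, as_index=False, sort=False)["biomass_per_h"].sum()


def build_community_matrix(biomass_records: pd.DataFrame) -> CommunityMatrix:
    """Aggregate per-haul biomasses to a site-year community matrix.

    The cell value is the mean biomass per hour across the site-year's
    hauls (hauls where the species is absent contribute zero), keeping
    cells comparable across different sampling effort; haul counts are
    recorded per row for the downstream effort standardization.
    """
    n_hauls = biomass_records.groupby(["site_id", "year"])["haul_id"].nunique()
    n_hauls.name = "n_hauls"
    totals = biomass_records.pivot_table(
        index=["site_id", "year"],
        columns="species",
        values="biomass_per_h",
        aggfunc="sum",
        fill_value=0.0,
    )
    biomass = totals.div(n_hauls, axis=0)
    biomass.columns.name = None
    return CommunityMatrix(biomass=biomass, n_hauls=n_hauls.loc[biomass.index])


_WINTER = (12, 1, 2)
_SUMMER = (6, 7, 8)


def derive_covariates(
    monthly: pd.DataFrame,
    substrate: pd.DataFrame,
    effort: pd.DataFrame | None = None,
    depth: pd.Series | None = None,
) -> pd.DataFrame:
    """Derive per-site environmental covariates.

    Parameters
    ----------
    monthly
        Long table with columns site_id, year, month, sbt, salinity.
        Winter is Dec-Feb, summer Jun-Aug; seasonality = summer mean -
        winter mean; salinity variability = per-year (max - min)
        averaged over years.
    substrate
        Long table site_id, category, fraction (coverage fractions);
        richness counts categories with positive coverage, evenness is
        the Pielou evenness of the fractions.
    effort
        Optional site_id, beam_effort, otter_effort.
    depth
        Optional mean haul depth per site.
    """
    months = set(monthly["month"].unique())
    missing = sorted(set(_WINTER + _SUMMER) - months)
    if missing:
        raise ValueError(f"monthly series missing months: {missing}")

    winter = monthly[monthly["month"].isin(_WINTER)]
    summer = monthly[monthly["month"].isin(_SUMMER)]
    sbt_winter = winter.groupby("site_id")["sbt"].mean()
    sbt_seasonality = summer.groupby("site_id")["sbt"].mean() - sbt_winter
    sal_winter = winter.groupby("site_id")["salinity"].mean()
    per_year = monthly.groupby(["site_id", "year"])["salinity"].agg(lambda s: s.max() - s.min())
    sal_var = per_year.groupby("site_id").mean()

    sub = substrate[substrate["fraction"] > 0]
    richness = sub.groupby("site_id")["category"].nunique()

    def _pielou(fracs: pd.Series) -> float:
        p = fracs.to_numpy(dtype=float)
        p = p / p.sum()
        if p.size <= 1:
            return 0.0
        return float(-(p * np.log(p)).sum() / np.log(p.size))

    evenness = sub.groupby("site_id")["fraction"].apply(_pielou)

    out = pd.DataFrame(
        {
            "sbt_winter": sbt_winter,
            "sbt_seasonality": sbt_seasonality,
            "salinity_winter": sal_winter,
            "salinity_variability": sal_var,
            "substrate_richness": richness,
            "substrate_evenness": evenness,
        }
    )
    if depth is not None:
        out["depth_m"] = depth
    if effort is not None:
        eff = effort.set_index("site_id") if "site_id" in effort.columns else effort
        out = out.join(eff)
    out.index.name = "site_id"
    return out


def interpolate_surface(
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    n_knots: int = 4,
    degree: int = 3,
) -> pd.Series:
    """Smooth latitude-longitude surface fitted to point observations.

    Fits a tensor-product B-spline basis (cubic by default, interior
    knots at coordinate quantiles) to ``observations`` (columns lat, lon,
    value) by least squares, and predicts at site centroids (``sites``
    indexed by site_id with columns lat, lon).  Prediction coordinates
    are clipped to the observed range to avoid extrapolation.
    """
    from scipy.interpolate import BSpline

    obs = observations.dropna(subset=["lat", "lon", "value"])
    if len(obs) < 10:
        raise ValueError("surface interpolation needs at least 10 observations")
    # keep the tensor basis smaller than the sample so the fit smooths
    k_interior = min(n_knots, max(0, int(np.sqrt(len(obs))) - degree - 1))

    def basis(x: np.ndarray, x_obs: np.ndarray):
        lo, hi = x_obs.min(), x_obs.max()
        if hi - lo <= 0:
            raise np.linalg.LinAlgError("degenerate coordinate range")
        interior = np.quantile(x_obs, np.linspace(0, 1, k_interior + 2)[1:-1])
        t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        return BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()

    lat_o, lon_o = obs["lat"].to_numpy(float), obs["lon"].to_numpy(float)
    bx = basis(lat_o, lat_o)
    by = basis(lon_o, lon_o)
    design = np.einsum("ij,ik->ijk", bx, by).reshape(len(obs), -1)
    coef, _, rank, _ = np.linalg.lstsq(design, obs["value"].to_numpy(float), rcond=None)
    # rank deficiency is expected for tensor bases over scattered points;
    # lstsq returns the minimum-norm solution, which is the smooth fit we
    # want — but a design with no usable columns is an error
    if rank == 0:
        raise np.linalg.LinAlgError("rank-deficient interpolation design")

    px = basis(sites["lat"].to_numpy(float), lat_o)
    py = basis(sites["lon"].to_numpy(float), lon_o)
    pred = np.einsum("ij,ik->ijk", px, py).reshape(len(sites), -1) @ coef
    return pd.Series(pred, index=sites.index, name="value")
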