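"""Taxonomic and trait-based biodiversity indicators.

Four indicators are computed per site-year community:

- SRic: species richness (count of species with positive biomass);
- SEve: Pielou's evenness of relative biomasses, H / ln(S);
- TRic: trait richness — convex-hull volume of the community's species in
  the shared trait space, standardized by the species-pool hull volume so
  it lies in [0, 1];
- TEve: trait evenness — regularity of biomass distribution along the
  minimum spanning tree of the community in trait space (the FEve
  construction: branch lengths divided by the summed biomass of their
  endpoints, truncated at the 1/(S-1) regular share).

Indicators that are undefined for small communities (SEve at S=1, TRic at
S <= m, TEve at S < 3) are carried as NaN so spatial and temporal means
exclude rather than silently absorb them.  Because the number of hauls
behind a community varies, every indicator can additionally be
standardized for sampling effort by removing a smooth haul-count effect
while preserving the grand mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .traitspace import TraitSpace, hull_volume

logger = logging.getLogger(__name__)

__all__ = [
    "species_richness",
    "pielou_evenness",
    "convex_hull_volume",
    "trait_richness",
    "trait_evenness",
    "compute_indicator_table",
    "effort_standardize",
]


def species_richness(biomass: np.ndarray | pd.Series) -> int:
    """Number of species with strictly positive biomass."""
    b = np.asarray(biomass, dtype=float)
    return int(np.sum(b > 0))


def pielou_evenness(biomass: np.ndarray | pd.Series) -> float:
    """Pielou's evenness J = -sum(p ln p) / ln S over positive biomasses.

    Returns NaN for empty or single-species communities (ln 1 = 0).
    """
    b = np.asarray(biomass, dtype=float)
    b = b[b > 0]
    s = b.size
    if s <= 1:
        return float("nan")
    p = b / b.sum()
    return float(-(p * np.log(p)).sum() / np.log(s))


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume of the convex hull of m-dimensional points (area when m=2).

    NaN when the point set is degenerate (fewer than m+1 points, or
    affinely dependent)."""
    return hull_volume(points)


def trait_richness(biomass: pd.Series, space: TraitSpace) -> float:
    """Standardized trait richness: community hull volume / pool hull volume.

    Presence-only: biomass values act solely as a presence mask.  NaN when
    the community has m or fewer species (no m-dimensional hull).
    """
    present = biomass.index[np.asarray(biomass, dtype=float) > 0]
    pts = space.community_points(present)
    if pts.shape[0] <= space.m:
        return float("nan")
    v = hull_volume(pts)
    return v / space.pool_hull_volume


def _mst_edges(points: np.ndarray) -> list[tuple[int, int, float]]:
    """Minimum-spanning-tree edges over Euclidean distances.

    Ties are resolved deterministically by perturbation-free Kruskal order
    on the condensed distance matrix, which scipy applies consistently for
    identical input; input order is the (lexicographically sorted) species
    order of the caller.
    """
    d = squareform(pdist(points))
    mst = minimum_spanning_tree(d).tocoo()
    return [(int(i), int(j), float(w)) for i, j, w in zip(mst.row, mst.col, mst.data)]


def trait_evenness(biomass: pd.Series, space: TraitSpace) -> float:
    """Trait evenness (FEve) of biomass along the trait-space MST.

    For each MST branch l joining species i and j with Euclidean length
    ``dist_l`` in the m-axis space, the abundance-weighted "evenness" of
    the branch is ``EW_l = dist_l / (w_i + w_j)`` with w the relative
    biomasses; ``PEW_l = EW_l / sum(EW)``.  With S species (S-1 branches),

        TEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))

    which is 1 for a perfectly regular, equally weighted tree and tends to
    0 as biomass or branch structure concentrates.  NaN for S < 3.
    """
    b = biomass[np.asarray(biomass, dtype=float) > 0].astype(float)
    # lexicographic species order fixes MST tie-breaking
    b = b.sort_index()
    s = len(b)
    if s < 3:
        return float("nan")
    pts = space.community_points(b.index)
    w = (b / b.sum()).to_numpy()
    edges = _mst_edges(pts)
    ew = np.array([dist / (w[i] + w[j]) for i, j, dist in edges])
    pew = ew / ew.sum()
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


def compute_indicator_table(community, space: TraitSpace) -> pd.DataFrame:
    """Per site-year indicator records for a community matrix.

    Parameters
    ----------
    community
        A :class:`~trawldiv.survey.CommunityMatrix` (or any object with
        ``biomass`` wide DataFrame indexed by (site_id, year) and an
        ``n_hauls`` Series on the same index).
    space
        Shared trait space covering every species column.

    Returns a DataFrame with columns site_id, year, n_hauls, SRic, SEve,
    TRic, TEve.  Undefined values propagate as NaN.
    """
    biomass = community.biomass
    missing = [s for s in biomass.columns if s not in space.species]
    if missing:
        raise KeyError(f"species absent from trait space: {missing}")
    rows = []
    for (site, year), row in biomass.iterrows():
        rows.append(
            {
                "site_id": site,
                "year": year,
                "n_hauls": int(community.n_hauls.loc[(site, year)]),
                "SRic": species_richness(row),
                "SEve": pielou_evenness(row),
                "TRic": trait_richness(row, space),
                "TEve": trait_evenness(row, space),
            }
        )
    return pd.DataFrame(rows)


def effort_standardize(
    table: pd.DataFrame,
    columns: tuple[str, ...] = ("SRic", "SEve", "TRic", "TEve"),
    min_records: int = 20,
) -> pd.DataFrame:
    """Remove a smooth sampling-effort effect from each indicator.

    Fits ``indicator ~ smooth(n_hauls)`` with the 3-df quadratic smoother
    and replaces each value by ``grand mean + residual``, so standardized
    values are (linearly) uncorrelated with haul count while the overall
    mean — and hence the indicator's units — is preserved.  Appends
    ``<col>_std`` columns.  With constant haul counts there is nothing to
    remove and values pass through unchanged.
    """
    from .drivers import fit_smooth_model

    if len(table) < min_records:
        raise ValueError(f"effort standardization needs >= {min_records} records")
    out = table.copy()
    n_hauls = table["n_hauls"].astype(float)
    constant = n_hauls.nunique() <= 1
    if constant:
        logger.info("n_hauls constant; effort standardization is the identity")
    for col in columns:
        vals = table[col].astype(float)
        ok = vals.notna()
        std = vals.copy()
        if not constant and ok.sum() >= min_records:
            fit = fit_smooth_model(
                vals[ok].to_numpy(), pd.DataFrame({"n_hauls": n_hauls[ok]})
            )
            std.loc[ok] = vals[ok].mean() + fit.residuals
        out[f"{col}_std"] = std
    return out
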