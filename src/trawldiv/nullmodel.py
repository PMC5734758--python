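"""Fixed-marginals null model for trait richness.

Compares each site's observed trait richness (TRic) with a null
distribution built from randomized species assemblages drawn from the
observed pool while holding both site richness (row sums) and species
prevalence (column sums) fixed.  Sites whose communities are less
trait-diverse than the null expectation point to environmental
filtering (trait underdispersion); more diverse points to limiting
similarity (overdispersion).

Randomization uses the curveball algorithm: repeated "trades" between
random site pairs that reshuffle the species unique to each site.
Trades preserve both marginals exactly and the chain samples the
fixed-fixed ensemble uniformly.  Each permutation runs its own
independently seeded chain from the observed matrix, so results are
reproducible and permutations are exchangeable.

Classification of a site follows the quantile of its observed TRic
among the simulated values (mid-rank convention): inside the
interquartile range neither process dominates; below/above the IQR
suggests filtering/limiting; outside the central 95% range the
departure is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traitspace import TraitSpace, hull_volume

logger = logging.getLogger(__name__)

__all__ = [
    "NullResult",
    "randomize_presence",
    "null_distribution",
    "classify_dispersion",
    "richness_banding",
]

CLASSES = ["under_significant", "under", "neither", "over", "over_significant"]


def _rows_to_sets(mat: np.ndarray) -> list[set[int]]:
    return [set(np.nonzero(row)[0].tolist()) for row in mat]


def _curveball_trades(rows: list[set[int]], n_steps: int, rng: np.random.Generator) -> int:
    """Run n_steps curveball trades in place; returns number that changed."""
    n = len(rows)
    changed = 0
    pairs = rng.integers(0, n, size=(n_steps, 2))
    for i, j in pairs:
        if i == j:
            continue
        ri, rj = rows[i], rows[j]
        only_i = ri - rj
        only_j = rj - ri
        ka, kb = len(only_i), len(only_j)
        if ka == 0 or kb == 0:
            continue
        tradeable = list(only_i | only_j)
        perm = rng.permutation(len(tradeable))
        new_i = {tradeable[p] for p in perm[:ka]}
        if new_i != only_i:
            changed += 1
        rows[i] = (ri - only_i) | new_i
        rows[j] = (rj - only_j) | (set(tradeable) - new_i)
    return changed


def randomize_presence(
    matrix: pd.DataFrame | np.ndarray,
    seed: int | None = None,
    n_steps: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame | np.ndarray:
    """One curveball randomization of a binary presence matrix.

    Preserves every row and column sum exactly.  ``n_steps`` defaults to
    5x the number of filled cells (burn-in long enough for the chain to
    forget the observed configuration).  A matrix whose marginals force
    a unique configuration is returned unchanged with a notice.
    """
    arr = np.asarray(matrix, dtype=int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    if rng is None:
        rng = np.random.default_rng(seed)
    fill = int(arr.sum())
    if n_steps is None:
        n_steps = 5 * fill
    rows = _rows_to_sets(arr)
    changed = _curveball_trades(rows, n_steps, rng)
    if changed == 0 and _is_forced(rows):
        logger.info("marginals force a unique configuration; matrix returned unchanged")
    out = np.zeros_like(arr)
    for i, s in enumerate(rows):
        out[i, list(s)] = 1
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def _is_forced(rows: list[set[int]]) -> bool:
    # no trade is possible iff every row pair is nested
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if rows[i] - rows[j] and rows[j] - rows[i]:
                return False
    return True


def classify_dispersion(observed: float, simulated: np.ndarray) -> tuple[str, float, float]:
    """Dispersion class, quantile and residual of observed vs null draws.

    The quantile is the mid-rank of the observed value within the pooled
    sample of observed + simulated, scaled to [0, 1]:
    q = (#below + ties/2 + 1/2) / (n + 1).  Under exchangeability q is
    uniform with mean 1/2, and an observed value sitting exactly at the
    k/(n+1) plotting position of the simulated sample gets exactly that
    quantile, making the inclusive-IQR boundaries sharp.  Classes:
    q < 0.025 under_significant; q < 0.25 under; 0.25 <= q <= 0.75
    neither (inclusive IQR); q <= 0.975 over; else over_significant.
    The residual is observed minus the simulated mean.
    """
    sim = np.asarray(simulated, dtype=float)
    sim = sim[np.isfinite(sim)]   # degenerate-hull draws carry no rank information
    if sim.size == 0:
        raise ValueError("simulated distribution is empty")
    q = (np.sum(sim < observed) + 0.5 * np.sum(sim == observed) + 0.5) / (sim.size + 1)
    if q < 0.025:
        cls = "under_significant"
    elif q < 0.25:
        cls = "under"
    elif q <= 0.75:
        cls = "neither"
    elif q <= 0.975:
        cls = "over"
    else:
        cls = "over_significant"
    return cls, float(q), float(observed - sim.mean())


@dataclass
class NullResult:
    """Per-site null-model summary plus the raw simulated TRic draws."""

    table: pd.DataFrame          # site_id, observed, mean_sim, sd_sim, quantile, class, residual
    simulated: np.ndarray        # (n_sites, n_perm) TRic draws
    sites: list

    @property
    def n_perm(self) -> int:
        return self.simulated.shape[1]


def _tric_for_rows(
    rows: list[set[int]], coords: np.ndarray, m: int, pool_volume: float
) -> np.ndarray:
    out = np.empty(len(rows))
    for i, s in enumerate(rows):
        if len(s) <= m:
            out[i] = np.nan
        else:
            out[i] = hull_volume(coords[sorted(s)]) / pool_volume
    return out


def null_distribution(
    presence: pd.DataFrame,
    space: TraitSpace,
    n_perm: int = 999,
    seed: int | None = None,
    n_steps: int | None = None,
) -> NullResult:
    """Per-site null distributions of TRic under fixed-fixed randomization.

    For each of ``n_perm`` permutations an independently seeded curveball
    chain randomizes the presence matrix and TRic is recomputed for every
    site.  Sites whose observed TRic is undefined (richness <= m) are
    excluded and logged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    missing = [s for s in presence.columns if s not in space.species]
    if missing:
        raise KeyError(f"species absent from trait space: {missing}")
    arr = presence.to_numpy(dtype=int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    coords = space.coordinates.loc[presence.columns].iloc[:, : space.m].to_numpy()

    base_rows = _rows_to_sets(arr)
    observed = _tric_for_rows(base_rows, coords, space.m, space.pool_hull_volume)
    keep = np.isfinite(observed)
    dropped = [site for site, ok in zip(presence.index, keep) if not ok]
    if dropped:
        logger.info("sites excluded (TRic undefined, richness <= m): %s", dropped)

    fill = int(arr.sum())
    steps = 5 * fill if n_steps is None else int(n_steps)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    sims = np.empty((len(base_rows), n_perm))
    for p in range(n_perm):
        rng = np.random.default_rng(children[p])
        rows = [set(s) for s in base_rows]
        _curveball_trades(rows, steps, rng)
        sims[:, p] = _tric_for_rows(rows, coords, space.m, space.pool_hull_volume)

    records = []
    kept_sites = [site for site, ok in zip(presence.index, keep) if ok]
    kept_idx = np.nonzero(keep)[0]
    for site, i in zip(kept_sites, kept_idx):
        cls, q, resid = classify_dispersion(observed[i], sims[i])
        records.append(
            {
                "site_id": site,
                "observed": observed[i],
                "mean_sim": float(np.mean(sims[i])),
                "sd_sim": float(np.std(sims[i], ddof=1)) if n_perm > 1 else np.nan,
                "quantile": q,
                "dispersion_class": cls,
                "residual": resid,
            }
        )
    return NullResult(
        table=pd.DataFrame(records), simulated=sims[kept_idx], sites=kept_sites
    )


def richness_banding(
    result: NullResult,
    richness: pd.Series,
    percentiles: tuple[float, ...] = (2.5, 25.0, 75.0, 97.5),
) -> pd.DataFrame:
    """Null-distribution percentile bands as smooth functions of richness.

    Pools each site's simulated TRic draws into per-site percentiles and
    smooths each percentile against species richness with the 3-df
    smoother, giving the 50% (25/75) and 95% (2.5/97.5) bands plotted
    under observed TRic-vs-SRic relationships.  Requires >= 5 distinct
    richness levels.
    """
    from .drivers import fit_smooth_model

    sric = richness.loc[result.sites].to_numpy(dtype=float)
    if len(np.unique(sric)) < 5:
        raise ValueError("richness banding needs >= 5 distinct richness levels")
    raw = {p: np.percentile(result.simulated, p, axis=1) for p in percentiles}
    grid = np.unique(sric)
    out = {"SRic": grid}
    for p, vals in raw.items():
        fit = fit_smooth_model(vals, pd.DataFrame({"sric": sric}))
        out[f"p{p:g}"] = fit.intercept + fit.term("sric", grid)
    return pd.DataFrame(out)
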