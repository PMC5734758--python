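"""Multidimensional trait space construction.

Mixed-type species trait tables are turned into a Gower dissimilarity
matrix, embedded into Euclidean axes by principal coordinates analysis
(PCoA), and truncated to the low-dimensional space in which convex-hull
trait richness and MST-based trait evenness are computed.  The convex
hull of the full species pool in that space provides the denominator
that standardizes trait richness to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "TraitSpace",
    "gower_distance",
    "pcoa",
    "select_axes",
    "build_trait_space",
    "hull_volume",
]


def _split_trait_columns(
    traits: pd.DataFrame,
    continuous: list[str] | None,
    categorical: list[str] | None,
) -> tuple[list[str], list[str]]:
    if continuous is None:
        continuous = [c for c in traits.columns if pd.api.types.is_numeric_dtype(traits[c])]
    if categorical is None:
        categorical = [c for c in traits.columns if c not in continuous]
    return list(continuous), list(categorical)


def gower_distance(
    traits: pd.DataFrame,
    weights: dict[str, float] | None = None,
    *,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    log_continuous: bool = True,
) -> pd.DataFrame:
    """Pairwise Gower dissimilarity over a mixed-type trait table.

    Per trait, the contribution for a species pair is ``|x_i - x_j| / range``
    for continuous traits (optionally after a natural-log transform, since
    e.g. fecundity and body size span orders of magnitude) and a 0/1
    mismatch indicator for categorical traits.  The Gower dissimilarity is
    the weighted mean of the per-trait contributions, which keeps it in
    [0, 1].

    Parameters
    ----------
    traits
        Trait table indexed by species.  Numeric columns are treated as
        continuous, all others as categorical, unless given explicitly.
    weights
        Optional per-trait weights (default: equal).
    log_continuous
        Log-transform continuous traits before range-normalizing.
        Requires strictly positive values.

    Returns
    -------
    Square symmetric DataFrame of dissimilarities in [0, 1] with a zero
    diagonal, indexed by species.

    Notes
    -----
    A continuous trait with zero range carries no information and is
    excluded with a warning rather than producing 0/0.
    """
    if len(traits) < 2:
        raise ValueError("gower_distance requires at least 2 species")
    cont, cat = _split_trait_columns(traits, continuous, categorical)
    if weights is None:
        weights = {}
    n = len(traits)
    num = np.zeros((n, n))
    wsum = 0.0

    for col in cont:
        x = traits[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"trait {col!r} contains missing or non-finite values")
        if log_continuous:
            if np.any(x <= 0):
                raise ValueError(f"trait {col!r} must be strictly positive for log transform")
            x = np.log(x)
        rng = x.max() - x.min()
        if rng == 0:
            warnings.warn(f"continuous trait {col!r} has zero range; excluded from Gower distance")
            continue
        w = float(weights.get(col, 1.0))
        num += w * np.abs(x[:, None] - x[None, :]) / rng
        wsum += w

    for col in cat:
        levels = traits[col]
        if levels.isna().any():
            raise ValueError(f"trait {col!r} contains missing values")
        codes = pd.factorize(levels)[0]
        w = float(weights.get(col, 1.0))
        num += w * (codes[:, None] != codes[None, :]).astype(float)
        wsum += w

    if wsum == 0:
        raise ValueError("no usable traits left after exclusions")
    d = num / wsum
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


def _cailliez_constant(d: np.ndarray) -> float:
    # Smallest c such that d_ij + c (i != j) is Euclidean: largest real
    # eigenvalue of the 2n x 2n companion problem (Cailliez 1983).
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b1 = -0.5 * j @ d2 @ j
    b2 = -0.5 * j @ d @ j
    upper = np.hstack([np.zeros((n, n)), 2.0 * b1])
    lower = np.hstack([-np.eye(n), -4.0 * b2])
    ev = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(ev.real))


def pcoa(
    dist: pd.DataFrame | np.ndarray,
    correction: str = "sqrt",
    *,
    eig_tol: float = 1e-9,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates analysis of a dissimilarity matrix.

    Double-centers ``-0.5 * D**2``, eigen-decomposes, and returns species
    coordinates scaled by the square roots of the (non-increasing)
    eigenvalues.  Non-Euclidean dissimilarities produce negative
    eigenvalues; these are handled by ``correction``:

    - ``"none"``: keep only axes with positive eigenvalues;
    - ``"sqrt"``: embed the square roots of the dissimilarities (a metric
      transform that is Euclidean for Gower-type dissimilarities);
    - ``"lingoes"``: add ``2*c`` to all squared off-diagonal dissimilarities,
      ``c = |smallest eigenvalue|``;
    - ``"cailliez"``: add a constant to all off-diagonal dissimilarities.
    """
    d = np.asarray(dist, dtype=float).copy()
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(d.shape[0])
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)

    if correction == "sqrt":
        d = np.sqrt(d)
    elif correction == "lingoes":
        lam_min = _min_eigenvalue(d)
        if lam_min < 0:
            d2 = d**2
            d2[off] += -2.0 * lam_min
            d = np.sqrt(d2)
    elif correction == "cailliez":
        lam_min = _min_eigenvalue(d)
        if lam_min < 0:
            c = _cailliez_constant(d)
            if c > 0:
                d[off] += c
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    pos = eigval > eig_tol * max(abs(eigval[0]), 1.0)
    if not pos.any():
        raise ValueError("no positive eigenvalues; degenerate distance matrix")
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=index, columns=cols), eigval


def _min_eigenvalue(d: np.ndarray) -> float:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    return float(np.linalg.eigvalsh((b + b.T) / 2.0)[0])


def select_axes(
    n_available: int,
    community_richness: pd.Series | np.ndarray,
    m_max: int = 4,
) -> int:
    """Number of trait-space axes usable by every hull computation.

    A convex hull in ``m`` dimensions needs at least ``m + 1`` species, so
    ``m`` is capped at ``s_min - 1`` where ``s_min`` is the smallest
    richness among communities rich enough to enter the trait-richness
    calculation (richness >= 3; poorer communities are flagged, not fatal).
    ``m >= 2`` is always enforced.
    """
    rich = np.asarray(community_richness, dtype=float)
    usable = rich[rich >= 3]
    if usable.size == 0:
        warnings.warn("no community with >= 3 species; falling back to m = 2")
        s_min = 3
    else:
        s_min = int(usable.min())
    return max(2, min(int(m_max), s_min - 1, int(n_available)))


def hull_volume(points: np.ndarray) -> float:
    """Convex hull volume (area in 2-D); NaN for degenerate point sets."""
    pts = np.asarray(points, dtype=float)
    m = pts.shape[1]
    if pts.shape[0] < m + 1:
        return float("nan")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        # affinely dependent (collinear/coplanar) point sets have no
        # m-dimensional hull; flag rather than joggle
        return float("nan")


@dataclass
class TraitSpace:
    """Species embedded on PCoA axes derived from Gower dissimilarities.

    ``coordinates`` holds all retained positive axes; hull and MST
    computations use the first ``m`` of them.  ``pool_hull_volume`` is the
    convex-hull volume of the entire species pool in that m-dimensional
    space and is the TRic standardization denominator.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    correction: str
    m: int
    pool_hull_volume: float = field(init=False)

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("trait space needs at least 2 axes")
        if self.m > self.coordinates.shape[1]:
            raise ValueError("m exceeds the number of available axes")
        self.pool_hull_volume = hull_volume(self.points)
        if not np.isfinite(self.pool_hull_volume) or self.pool_hull_volume <= 0:
            raise ValueError("species pool hull is degenerate in the selected space")

    @property
    def species(self) -> pd.Index:
        return self.coordinates.index

    @property
    def points(self) -> np.ndarray:
        """Pool coordinates restricted to the first m axes."""
        return self.coordinates.iloc[:, : self.m].to_numpy()

    def community_points(self, species: pd.Index | list) -> np.ndarray:
        missing = [s for s in species if s not in self.coordinates.index]
        if missing:
            raise KeyError(f"species absent from trait space: {missing}")
        return self.coordinates.loc[list(species)].iloc[:, : self.m].to_numpy()


def build_trait_space(
    traits: pd.DataFrame,
    *,
    weights: dict[str, float] | None = None,
    correction: str = "sqrt",
    log_continuous: bool = True,
    m: int | None = None,
    m_max: int = 4,
    community_richness: pd.Series | np.ndarray | None = None,
) -> TraitSpace:
    """Gower distances -> PCoA -> axis selection, in one shared basis.

    If ``m`` is not given it is chosen by :func:`select_axes` from the
    richness distribution of the communities that will be scored (or just
    ``m_max`` when no communities are supplied).
    """
    dist = gower_distance(traits, weights, log_continuous=log_continuous)
    coords, eigval = pcoa(dist, correction=correction)
    if m is None:
        if community_richness is not None:
            m = select_axes(coords.shape[1], community_richness, m_max=m_max)
        else:
            m = min(m_max, coords.shape[1])
    return TraitSpace(coordinates=coords, eigenvalues=eigval, correction=correction, m=int(m))
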