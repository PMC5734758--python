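"""Synthetic bottom-trawl survey generator with known ground truth.

Emulates the structure of a quarter-one bottom-trawl survey over a grid
of statistical rectangles: a demersal species pool with mixed-type
ecological traits and length-weight parameters, smooth environmental
gradients across sites, communities assembled under a labelled process
(neutral, environmental filtering, or limiting similarity), and
haul-level CPUE-at-length records whose expected biomass matches the
assembled communities.

Species are organized along a latent "fast-slow" niche axis: continuous
life-history traits load on it, categorical trait levels are drawn with
probabilities centered on it, and the environmental optimum of each
species tracks it.  Environmental filtering on the optimum therefore
selects trait-similar species (underdispersion), while
limiting-similarity assembly rejects candidates closer than a Gower
distance threshold to any resident (overdispersion) — giving downstream
null-model tests a known answer.

All draws come from a single seeded generator, so every output is
bit-reproducible given the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .survey import CommunityMatrix
from .traitspace import gower_distance

__all__ = [
    "TRAIT_LEVELS",
    "CONTINUOUS_TRAITS",
    "CATEGORICAL_TRAITS",
    "generate_species_pool",
    "generate_sites",
    "assemble_communities",
    "generate_hauls",
]

# Categorical level sets for the four non-continuous traits.
TRAIT_LEVELS: dict[str, list[str]] = {
    "body_shape": ["gadoid-like", "flat", "elongated", "short/deep", "eel-like"],
    "diet": ["benthivore", "piscivore", "planktivore", "bentho-piscivore", "plankto-piscivore"],
    "spawning_behavior": ["Ob", "Og", "Op", "Os", "Ov", "V"],
    "caudal_fin_shape": ["truncated", "continuous", "forked", "rounded", "emarginate", "heterocercal"],
}
CONTINUOUS_TRAITS = ["body_size", "age_at_maturity", "fecundity", "egg_size"]
CATEGORICAL_TRAITS = list(TRAIT_LEVELS)
TRAIT_COLUMNS = CONTINUOUS_TRAITS + CATEGORICAL_TRAITS

# (log-mean, log-sd, loading on the latent niche axis)
_CONTINUOUS_PARAMS = {
    "body_size": (np.log(40.0), 0.60, 0.85),       # cm
    "age_at_maturity": (np.log(3.0), 0.45, 0.85),  # yr
    "fecundity": (np.log(1.0e5), 1.40, 0.70),      # eggs per female per season
    "egg_size": (np.log(1.1), 0.45, -0.60),        # mm
}


def generate_species_pool(
    n_species: int = 77,
    seed: int | None = None,
    *,
    assortment: float = 2.0,
    n_guilds: int = 10,
    guild_sd: float = 0.25,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a species pool with traits, length-weight and niche fields.

    Species belong to one of ``n_guilds`` trait guilds whose centers are
    spread along a latent fast-slow niche axis; within-guild scatter is
    ``guild_sd``.  This mirrors the trait redundancy of real demersal
    assemblages, where taxonomically related species (gadoids, flatfish,
    elasmobranchs, ...) share trait syndromes.  Continuous traits are
    log-normal with loadings on the latent axis; categorical levels are
    multinomial draws whose probabilities shift along the axis with
    strength ``assortment`` (0 = independent).  ``env_optimum`` is the
    latent axis position plus noise; ``niche_breadth`` is log-normal
    around 0.5 (on the standardized environmental axis).
    """
    if n_species < 5:
        raise ValueError("n_species must be >= 5; trait space is degenerate otherwise")
    if rng is None:
        rng = np.random.default_rng(seed)
    # guild centers at evenly spaced normal quantiles; membership thins
    # toward the extremes, so outlying trait syndromes are rare
    from scipy.stats import norm

    centers = norm.ppf((np.arange(n_guilds) + 0.5) / n_guilds)
    p_guild = norm.pdf(centers)
    p_guild = p_guild / p_guild.sum()
    guild = rng.choice(n_guilds, size=n_species, p=p_guild)
    u = centers[guild] + guild_sd * rng.standard_normal(n_species)

    data: dict[str, np.ndarray | list] = {}
    for name, (mu, sd, load) in _CONTINUOUS_PARAMS.items():
        z = rng.standard_normal(n_species)
        data[name] = np.exp(mu + sd * (load * u + np.sqrt(1.0 - load**2) * z))

    # rank position of each species on the latent axis, in (0, 1)
    pos = (pd.Series(u).rank().to_numpy() - 0.5) / n_species
    for name, levels in TRAIT_LEVELS.items():
        k = len(levels)
        centers = pos * (k - 1)
        kernel_sd = (k - 1) / (1.0 + 2.0 * max(assortment, 1e-9))
        logits = -((np.arange(k)[None, :] - centers[:, None]) ** 2) / (2.0 * kernel_sd**2)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        draws = [rng.choice(k, p=probs[i]) for i in range(n_species)]
        data[name] = [levels[j] for j in draws]

    data["lw_a"] = np.exp(rng.normal(np.log(0.01), 0.25, n_species))
    data["lw_b"] = rng.uniform(2.8, 3.2, n_species)
    data["env_optimum"] = u + rng.normal(0.0, 0.15, n_species)
    data["niche_breadth"] = np.exp(rng.normal(np.log(0.5), 0.15, n_species))
    data["guild"] = guild

    index = pd.Index([f"sp{i:03d}" for i in range(n_species)], name="species")
    return pd.DataFrame(data, index=index)


_DEFAULT_GRADIENTS = {"noise_sd": 1.0, "year_start": 1983}


def generate_sites(
    n_sites: int = 119,
    n_years: int = 32,
    gradient_config: dict | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Site covariate table on a grid with smooth gradients plus noise.

    Covariates mimic a temperate shelf sea: depth increasing northward,
    winter bottom temperature and seasonality with opposing latitudinal
    gradients, salinity structure, a phytoplankton color index, substrate
    richness (1..6 categories) and evenness, and two fishing-effort
    fields concentrated in the shallow south (beam) and deeper north
    (otter).  ``noise_sd`` scales the Gaussian noise on every covariate;
    at 0 the covariates equal the gradient surfaces exactly.  The
    standardized winter-temperature field doubles as the environmental
    axis ``env`` that species optima live on.

    The survey years are recorded in ``df.attrs["years"]``.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    cfg = dict(_DEFAULT_GRADIENTS)
    if gradient_config:
        cfg.update(gradient_config)
    ns = float(cfg["noise_sd"])
    if rng is None:
        rng = np.random.default_rng(seed)

    ncol = int(np.ceil(np.sqrt(n_sites)))
    nrow = int(np.ceil(n_sites / ncol))
    idx = np.arange(n_sites)
    row, col = idx // ncol, idx % ncol
    lat = 51.0 + 10.5 * (row / max(nrow - 1, 1))
    lon = -3.0 + 11.0 * (col / max(ncol - 1, 1))
    u = (lat - 51.0) / 10.5   # 0 = south, 1 = north
    v = (lon + 3.0) / 11.0

    def noise(sd: float) -> np.ndarray:
        return rng.normal(0.0, sd * ns, n_sites)

    depth = 30.0 + 120.0 * u + 10.0 * np.sin(3.0 * v) + noise(5.0)
    sbt_winter = 8.5 - 4.5 * u + 1.2 * np.sin(2.0 * v) + noise(0.3)
    sbt_seasonality = 2.0 + 7.0 * (1.0 - u) + noise(0.4)
    salinity_winter = 32.0 + 3.0 * u + noise(0.2)
    salinity_variability = 0.3 + 2.2 * (1.0 - u) + noise(0.15)
    pci = np.clip(1.0 + 1.5 * v * (1.0 - u) + 0.5 * np.sin(4.0 * u) + noise(0.2), 0.0, None)

    # substrate: 1..6 categories present, geometric coverage shares
    k_sub = 1 + np.floor(5.9999 * (0.5 + 0.5 * np.sin(2.2 * u + 1.3 * v))).astype(int)
    richness = np.clip(k_sub, 1, 6)
    evenness = np.zeros(n_sites)
    for i in range(n_sites):
        shares = 0.55 ** np.arange(richness[i], dtype=float)
        if ns > 0:
            shares = shares * np.exp(rng.normal(0.0, 0.3 * ns, richness[i]))
        shares /= shares.sum()
        if richness[i] == 1:
            evenness[i] = 0.0
        else:
            evenness[i] = float(-(shares * np.log(shares)).sum() / np.log(richness[i]))

    beam_effort = np.clip(3000.0 * (1.0 - u) ** 2 + noise(150.0), 0.0, None)
    otter_effort = np.clip(1500.0 * u * (0.7 + 0.6 * v) + noise(100.0), 0.0, None)

    env = (sbt_winter - sbt_winter.mean()) / max(sbt_winter.std(), 1e-12)

    df = pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(n_sites)],
            "lat": lat,
            "lon": lon,
            "depth_m": depth,
            "sbt_winter": sbt_winter,
            "sbt_seasonality": sbt_seasonality,
            "salinity_winter": salinity_winter,
            "salinity_variability": salinity_variability,
            "pci": pci,
            "substrate_richness": richness,
            "substrate_evenness": evenness,
            "beam_effort": beam_effort,
            "otter_effort": otter_effort,
            "env": env,
        }
    ).set_index("site_id")
    year0 = int(cfg["year_start"])
    df.attrs["years"] = list(range(year0, year0 + int(n_years)))
    return df


def default_target_richness(n_species: int) -> tuple[int, int]:
    """Survey-like per-site richness range (8-16), clamped to small pools."""
    hi = min(16, n_species)
    lo = min(8, hi)
    return lo, hi


def _limiting_threshold(dist: np.ndarray, strength: float, cap: float = 0.85) -> float:
    """Gower-distance quantile threshold; scale-free across trait sets."""
    level = min(cap, 1.0 - 2.0 ** (-float(strength)))
    off = dist[~np.eye(dist.shape[0], dtype=bool)]
    return float(np.quantile(off, level))


def _select_species(
    process: str,
    strength: float,
    target: int,
    env_value: float,
    pool: pd.DataFrame,
    dist: np.ndarray | None,
    threshold: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(pool)
    if process == "neutral" or strength == 0:
        return rng.choice(n, size=target, replace=False)
    if process == "filtering":
        opt = pool["env_optimum"].to_numpy()
        nb = pool["niche_breadth"].to_numpy()
        logw = -strength * (env_value - opt) ** 2 / (2.0 * nb**2)
        w = np.exp(logw - logw.max())
        return rng.choice(n, size=target, replace=False, p=w / w.sum())
    if process == "limiting":
        # random-order sequential packing; restart on stall since a greedy
        # maximal packing can be smaller than the maximum one
        best: list[int] = []
        for _ in range(20):
            order = rng.permutation(n)
            residents = [int(order[0])]
            for cand in order[1:]:
                if len(residents) >= target:
                    break
                if dist[cand, residents].min() >= threshold:
                    residents.append(int(cand))
            if len(residents) > len(best):
                best = residents
            if len(best) >= target:
                break
        return np.array(best)
    raise ValueError(f"unknown process {process!r}")


def assemble_communities(
    pool: pd.DataFrame,
    sites: pd.DataFrame,
    process: str = "neutral",
    strength: float = 0.0,
    target_richness: int | tuple[int, int] = (8, 16),
    seed: int | None = None,
    *,
    dominance: float = 0.5,
    years: list[int] | None = None,
    biomass_total: float = 20000.0,
    biomass_cv: float = 0.3,
    presence_prob: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Assemble site communities under a labelled process.

    - ``neutral``: species drawn uniformly without replacement;
    - ``filtering``: sampling weights ``exp(-(env - optimum)^2 /
      (2 * breadth^2)) ** strength`` — a Gaussian niche sharpened by the
      process strength;
    - ``limiting``: sequential assembly that rejects any candidate whose
      minimum Gower distance to the residents falls below a pool-quantile
      threshold increasing with strength (so all resident pairs are at
      least the threshold apart by construction).

    ``strength = 0`` reduces every process to neutral.  Per-species
    biomasses follow a geometric series with dominance parameter
    ``dominance`` (0 = perfectly even), randomly ranked, then perturbed
    per year by log-normal noise of coefficient of variation
    ``biomass_cv`` and thinned by ``presence_prob``.

    Returns the community matrix (rows indexed by site-year) and a truth
    table recording the process label and realized richness per site.
    """
    if process not in {"neutral", "filtering", "limiting"}:
        raise ValueError(f"process must be neutral/filtering/limiting, got {process!r}")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if not 0.0 <= dominance < 1.0:
        raise ValueError("dominance must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = (target_richness, target_richness) if np.isscalar(target_richness) else target_richness
    if hi > len(pool):
        raise ValueError(f"target richness {hi} exceeds pool size {len(pool)}")

    dist = None
    threshold = 0.0
    if process == "limiting" and strength > 0:
        dist = gower_distance(pool[TRAIT_COLUMNS]).to_numpy()
        threshold = _limiting_threshold(dist, strength)

    if years is None:
        years = list(sites.attrs.get("years", [0]))
    species = pool.index
    sigma = np.sqrt(np.log1p(biomass_cv**2))

    site_rows, truth_rows = {}, []
    for site_id, site in sites.iterrows():
        target = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
        chosen = _select_species(
            process, strength, target, float(site.get("env", 0.0)), pool, dist, threshold, rng
        )
        ranks = rng.permutation(len(chosen))
        shares = (1.0 - dominance) ** ranks
        shares /= shares.sum()
        base = biomass_total * shares
        dominant = int(np.argmax(base))
        for year in years:
            b = np.zeros(len(species))
            present = rng.random(len(chosen)) < presence_prob
            present[dominant] = True
            mult = (
                np.exp(rng.normal(-0.5 * sigma**2, sigma, len(chosen)))
                if biomass_cv > 0
                else np.ones(len(chosen))
            )
            b[chosen[present]] = (base * mult)[present]
            site_rows[(site_id, year)] = b
        truth_rows.append(
            {
                "site_id": site_id,
                "assembly_process": process if strength > 0 else "neutral",
                "process_strength": float(strength),
                "env": float(site.get("env", 0.0)),
                "target_richness": target,
                "realized_richness": int(len(chosen)),
                "limiting_threshold": threshold if process == "limiting" else np.nan,
            }
        )

    biomass = pd.DataFrame.from_dict(site_rows, orient="index", columns=species)
    biomass.index = pd.MultiIndex.from_tuples(biomass.index, names=["site_id", "year"])
    n_hauls = pd.Series(1, index=biomass.index, name="n_hauls")
    return CommunityMatrix(biomass=biomass, n_hauls=n_hauls), pd.DataFrame(truth_rows)


_DEFAULT_EFFORT = {
    "mean_hauls": 2.0,
    "duration_mean": 30.0,
    "duration_sd": 2.0,
    "haul_cv": 0.25,
    "min_class_prob": 0.01,
}


def _length_classes(body_size: float, lw_a: float, lw_b: float, min_prob: float):
    """Integer length classes, probabilities and expected weight per fish.

    Lengths are log-normal around a species mean of 0.45 x asymptotic
    body size (sd(log) = 0.2), discretized to 1 cm classes; classes with
    negligible probability are dropped and the rest renormalized.
    """
    mean_l = max(0.45 * body_size, 2.0)
    sdlog = 0.2
    mulog = np.log(mean_l)
    lo = max(1, int(np.floor(np.exp(mulog - 3 * sdlog))))
    hi = int(np.ceil(np.exp(mulog + 3 * sdlog)))
    edges = np.arange(lo, hi + 2, dtype=float)
    from scipy.stats import lognorm

    cdf = lognorm.cdf(edges, s=sdlog, scale=np.exp(mulog))
    probs = np.diff(cdf)
    lengths = edges[:-1]
    keep = probs > min_prob * probs.max()
    lengths, probs = lengths[keep], probs[keep]
    probs = probs / probs.sum()
    unit_weight = float((probs * lw_a * lengths**lw_b).sum())
    return lengths, probs, unit_weight


def generate_hauls(
    communities: CommunityMatrix,
    sites: pd.DataFrame,
    pool: pd.DataFrame,
    effort_config: dict | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate haul-level CPUE-at-length records from community biomasses.

    Hauls per site-year are ``1 + Poisson(mean_hauls - 1)``; durations are
    Normal(30, 2) minutes and depths follow the site covariate.  For each
    species present, total CPUE is the community biomass divided by the
    expected weight per individual (from W = a L^b over the species'
    length distribution), spread over length classes and perturbed by a
    mean-one log-normal haul effect — so the expected aggregate biomass
    recovered via W = a L^b matches the community biomass exactly.
    """
    cfg = dict(_DEFAULT_EFFORT)
    if effort_config:
        cfg.update(effort_config)
    if cfg["mean_hauls"] < 1:
        raise ValueError("mean hauls per site-year must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    sigma = np.sqrt(np.log1p(cfg["haul_cv"] ** 2))
    length_info = {
        sp: _length_classes(
            float(pool.at[sp, "body_size"]),
            float(pool.at[sp, "lw_a"]),
            float(pool.at[sp, "lw_b"]),
            cfg["min_class_prob"],
        )
        for sp in communities.biomass.columns
    }

    cols: dict[str, list] = {c: [] for c in (
        "haul_id", "site_id", "year", "lat", "lon", "depth_m",
        "duration_min", "species", "length_cm", "cpue_per_h",
    )}
    for (site_id, year), row in communities.biomass.iterrows():
        site = sites.loc[site_id]
        present = row[row > 0]
        n_hauls = 1 + rng.poisson(max(cfg["mean_hauls"] - 1.0, 0.0))
        for h in range(n_hauls):
            duration = max(rng.normal(cfg["duration_mean"], cfg["duration_sd"]), 5.0)
            depth = max(float(site["depth_m"]) + rng.normal(0.0, 1.0), 5.0)
            haul_id = f"{site_id}-{year}-h{h:02d}"
            for sp, biomass in present.items():
                lengths, probs, unit_w = length_info[sp]
                n_total = biomass / unit_w
                haul_factor = np.exp(rng.normal(-0.5 * sigma**2, sigma))
                cpue = n_total * probs * haul_factor
                k = len(lengths)
                cols["haul_id"].extend([haul_id] * k)
                cols["site_id"].extend([site_id] * k)
                cols["year"].extend([year] * k)
                cols["lat"].extend([float(site["lat"])] * k)
                cols["lon"].extend([float(site["lon"])] * k)
                cols["depth_m"].extend([depth] * k)
                cols["duration_min"].extend([duration] * k)
                cols["species"].extend([sp] * k)
                cols["length_cm"].extend(lengths.tolist())
                cols["cpue_per_h"].extend(cpue.tolist())
    return pd.DataFrame(cols)
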