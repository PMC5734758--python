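"""Calibration and recovery experiments on synthetic ground truth.

These are the package's standard validation studies: they exercise the
full stack (generator -> trait space -> indicators -> null model /
model-selection engine) under conditions where the right answer is known,
and return the summary statistics that the test suite asserts and the
acceptance script reports.

Problem sizes are chosen to give stable rates on a single CPU: 500 sites
with 199 permutations for the neutral calibration, 200 sites per
assembly-process scenario, and 50 replicates of n = 300 for driver
recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic
from .drivers import all_subsets_rvi
from .nullmodel import null_distribution
from .synthetic import TRAIT_COLUMNS
from .traitspace import build_trait_space

__all__ = [
    "neutral_calibration",
    "process_recovery",
    "rvi_recovery",
    "SCENARIOS",
]

# "strong" assembly-process scenarios: strengths at which the generating
# mechanism dominates community composition (filtering: effective niche
# breadth ~ breadth/sqrt(20); limiting: Gower threshold at the ~0.57 pool
# quantile, near the packing limit for the target richness)
SCENARIOS = {
    "filtering": {"strength": 20.0, "target_richness": (8, 12)},
    "limiting": {"strength": 1.2, "target_richness": (6, 9)},
}


def _scenario_null(process: str, strength: float, target, n_sites: int, n_perm: int, seed: int):
    ss = np.random.SeedSequence(seed)
    s_pool, s_sites, s_comm, s_null = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    pool = synthetic.generate_species_pool(77, seed=s_pool)
    sites = synthetic.generate_sites(n_sites, 1, seed=s_sites)
    communities, truth = synthetic.assemble_communities(
        pool, sites, process, strength, target,
        seed=s_comm, biomass_cv=0.0, presence_prob=1.0,
    )
    space = build_trait_space(pool[TRAIT_COLUMNS], m=4)
    result = null_distribution(communities.presence("union"), space, n_perm, seed=s_null)
    return result, truth


def neutral_calibration(n_sites: int = 500, n_perm: int = 199, seed: int = 0) -> dict:
    """Null-model calibration under neutral assembly.

    With communities drawn uniformly from the pool, the observed matrix is
    exchangeable with its fixed-marginals randomizations, so the per-site
    quantiles should be uniform and ~5% of sites should fall outside the
    central 95% band.  Returns the outside-95% fraction and the p-value of
    a Kolmogorov-Smirnov uniformity test on the quantiles.
    """
    result, _ = _scenario_null("neutral", 0.0, (8, 16), n_sites, n_perm, seed)
    q = result.table["quantile"].to_numpy()
    outside = float(((q < 0.025) | (q > 0.975)).mean())
    ks_p = float(stats.kstest(q, "uniform").pvalue)
    return {"outside_95_fraction": outside, "ks_pvalue": ks_p, "n_sites": len(q)}


def process_recovery(process: str, n_sites: int = 200, n_perm: int = 199, seed: int = 0) -> dict:
    """Fraction of sites classified toward the generating process.

    ``filtering`` communities should be trait-underdispersed (quantile
    below the IQR), ``limiting`` communities overdispersed.
    """
    cfg = SCENARIOS[process]
    result, truth = _scenario_null(
        process, cfg["strength"], cfg["target_richness"], n_sites, n_perm, seed
    )
    counts = result.table["dispersion_class"].value_counts()
    n = len(result.table)
    under = float((counts.get("under", 0) + counts.get("under_significant", 0)) / n)
    over = float((counts.get("over", 0) + counts.get("over_significant", 0)) / n)
    return {
        "under_fraction": under,
        "over_fraction": over,
        "n_classified": n,
        "n_sites": n_sites,
        "min_realized_richness": int(truth["realized_richness"].min()),
    }


def rvi_recovery(
    n_replicates: int = 50,
    n_obs: int = 300,
    n_candidates: int = 5,
    effect_to_noise: float = 2.0,
    seed: int = 0,
) -> dict:
    """Driver recovery by all-subsets Akaike-weight variable importance.

    Each replicate draws independent standard-normal candidates; the
    response is driven linearly by the first with effect/noise sd ratio
    ``effect_to_noise``.  Reports how often the true driver reaches
    RVI >= 0.9, how often a null driver stays below 0.6 (per
    driver-replicate), and the worst Akaike-weight normalization error.
    """
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n_candidates)]
    true_hits = 0
    null_below = 0
    n_null_cases = 0
    max_weight_err = 0.0
    for _ in range(n_replicates):
        x = pd.DataFrame(rng.standard_normal((n_obs, n_candidates)), columns=names)
        y = effect_to_noise * x["x0"].to_numpy() + rng.standard_normal(n_obs)
        res = all_subsets_rvi(y, x)
        true_hits += res.rvi["x0"] >= 0.9
        for name in names[1:]:
            n_null_cases += 1
            null_below += res.rvi[name] < 0.6
        max_weight_err = max(max_weight_err, abs(res.model_table["weight"].sum() - 1.0))
    return {
        "true_recovery_rate": true_hits / n_replicates,
        "null_below_rate": null_below / n_null_cases,
        "max_weight_sum_error": float(max_weight_err),
        "n_replicates": n_replicates,
    }
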