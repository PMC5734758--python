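import numpy as np
import pandas as pd
import pytest

import trawldiv as td
from trawldiv.synthetic import TRAIT_COLUMNS


@pytest.fixture(scope="session")
def pool():
    return td.generate_species_pool(30, seed=1)


@pytest.fixture(scope="session")
def sites():
    return td.generate_sites(20, 6, seed=2)


@pytest.fixture(scope="session")
def community(pool, sites):
    cm, _ = td.assemble_communities(pool, sites, "neutral", 0.0, (8, 12), seed=3)
    return cm


@pytest.fixture(scope="session")
def space(pool, community):
    return td.build_trait_space(
        pool[TRAIT_COLUMNS], community_richness=community.richness()
    )


@pytest.fixture(scope="session")
def mixed_traits():
    """Small mixed-type trait table with a known layout."""
    rng = np.random.default_rng(7)
    n = 12
    return pd.DataFrame(
        {
            "body_size": np.exp(rng.normal(3.5, 0.6, n)),
            "age_at_maturity": np.exp(rng.normal(1.1, 0.4, n)),
            "fecundity": np.exp(rng.normal(11.0, 1.2, n)),
            "egg_size": np.exp(rng.normal(0.1, 0.4, n)),
            "body_shape": rng.choice(["gadoid-like", "flat", "elongated"], n).tolist(),
            "diet": rng.choice(["benthivore", "piscivore"], n).tolist(),
            "spawning_behavior": rng.choice(["Ob", "Op", "V"], n).tolist(),
            "caudal_fin_shape": rng.choice(["forked", "rounded"], n).tolist(),
        },
        index=pd.Index([f"sp{i:02d}" for i in range(n)], name="species"),
    )
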