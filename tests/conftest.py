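import numpy as np
import pandas as pd
import pytest

import illusiongame as ig


@pytest.fixture(scope="session")
def config():
    return ig.DesignConfig()


@pytest.fixture(scope="session")
def manifest(config):
    return ig.build_full_design(config, participant_seed=20251002)


@pytest.fixture(scope="session")
def small_sim(manifest):
    """30 clean simulated participants plus the latent truth table."""
    pop = ig.PopulationConfig(n_participants=30, seed=101)
    people, truth = ig.sample_population(pop)
    trials = ig.simulate_study(people, manifest, seed=102)
    return trials, truth


@pytest.fixture(scope="session")
def small_clean(small_sim):
    trials, truth = small_sim
    kept, report = ig.clean(trials)
    return kept, truth, report


def make_factor_table(n, loadings, seed, share=0.7,
                      illusions=ig.ILLUSIONS):
    """Synthetic 20-column score table with a known general factor."""
    rng = np.random.default_rng(seed)
    g = rng.normal(size=n)
    cols = {}
    for ill in illusions:
        lam = loadings[ill] if isinstance(loadings, dict) else loadings
        l2 = share * lam
        cols[f"{ill}_strength"] = lam * g + np.sqrt(1 - lam**2) * rng.normal(size=n)
        cols[f"{ill}_interaction"] = l2 * g + np.sqrt(1 - l2**2) * rng.normal(size=n)
    table = pd.DataFrame(cols, index=pd.RangeIndex(n, name="participant"))
    return table, g
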