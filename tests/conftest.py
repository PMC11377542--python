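import numpy as np
import pytest

import alscreen as als


@pytest.fixture(scope="session")
def synthetic_screen():
    """One compact active-learning campaign on a 50k synthetic library.

    Session-scoped: the campaign, its replay and an equal-budget random
    baseline are shared by the end-to-end tests.
    """
    spec = als.SyntheticLibrarySpec(n_compounds=50_000, binder_fraction=0.01, seed=7)
    records, truth = als.generate_library(spec)
    oracle = als.make_synthetic_oracle(
        truth.reference_fps, depth=12.0, noise_sd=1.0, seed=7
    )
    config = als.compact_profile(seed=7, max_iterations=4)
    result = als.run_campaign(records, oracle, config, rescore=True)
    return {
        "records": records,
        "truth": truth,
        "oracle": oracle,
        "config": config,
        "result": result,
    }


@pytest.fixture(scope="session")
def tiny_library():
    """2,000-compound synthetic library for fast loop unit tests."""
    spec = als.SyntheticLibrarySpec(
        n_compounds=2_000, binder_fraction=0.02, n_binder_clusters=3, seed=11
    )
    return als.generate_library(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
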