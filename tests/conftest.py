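import numpy as np
import pytest

import fluxmod as fm


@pytest.fixture(scope="session")
def study():
    """The default synthetic study: universe, annotations, environments, truth."""
    return fm.generate(fm.SynthConfig())


@pytest.fixture(scope="session")
def uniformity_fixture():
    """Small universe with exactly 12 swappable reactions and an enumerable
    viable set (two nutrient chains, redundant core/alternative routes,
    distractor padding); used as the exhaustive MCMC oracle."""
    config = fm.SynthConfig(
        n_nutrients=2, pathway_length=2, core_length=2, n_redundant_routes=1,
        n_distractors=4, n_deep_chains=0, with_branch=False, with_cycle=False,
        n_cofactors=0, seed=11,
    )
    universe, annotations, environments, truth = fm.generate(config)
    assert int(universe.swappable.sum()) == 12
    return universe, annotations, environments, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
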