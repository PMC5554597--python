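import pytest

import ecoknn as ek


@pytest.fixture
def microweb():
    """The four-predator worked-example web (species 0, 6, 28, 70)."""
    return ek.table3_microweb()


@pytest.fixture(scope="session")
def niche_web():
    """A mid-sized nested niche-model web with diet-correlated traits."""
    web = ek.generate_niche_web(ek.NicheParams(n_species=120, connectance=0.12, seed=7))
    ek.attach_synthetic_traits(web, noise=0.05, seed=7)
    return web


@pytest.fixture(scope="session")
def clone_web():
    """Predator clone groups with identical within-group, disjoint diets."""
    return ek.make_clone_web(n_groups=5, group_size=6, diet_size=4, seed=2)
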