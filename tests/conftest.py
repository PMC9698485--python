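import hypothesis
import pytest

import pocketmif as pm

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return pm.load_params()


@pytest.fixture(scope="session")
def toy():
    """A small mixed-chemistry pocket plus its definition."""
    return pm.make_toy_pocket(pm.FixtureSpec(seed=1, n_residues=10))


@pytest.fixture(scope="session")
def tiny():
    """A very small pocket whose grids stay under ~2000 points at coarse
    spacing (brute-force-oracle scale)."""
    return pm.make_toy_pocket(
        pm.FixtureSpec(seed=3, n_residues=5, pocket_radius=4.0))
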