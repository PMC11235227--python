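"""Shared fixtures: small synthetic slides and bag sets, generated once."""

import numpy as np
import pytest

import tissuemil as tm
from tissuemil.fusion import quality_weights_from_s2


@pytest.fixture(scope="session")
def small_slide():
    cfg = tm.SlideConfig(
        height=256, width=256, n_tubules=1, n_glomeruli=1, n_vessels=1
    )
    return tm.make_slide(cfg, seed=1)


@pytest.fixture(scope="session")
def vessel_slide():
    """One vessel with outer radius 50 px and lumen radius 25 px."""
    cfg = tm.SlideConfig(
        height=256,
        width=256,
        n_tubules=0,
        n_glomeruli=0,
        n_vessels=1,
        vessel_radius=(50.0, 50.0),
        vessel_lumen_frac=0.25,
        nuclei_per_compartment=(0, 0),
    )
    return tm.make_slide(cfg, seed=5)


@pytest.fixture(scope="session")
def clean_bags():
    """200 separable bags: effect size 3, no contamination."""
    return tm.make_bags(tm.BagSetConfig(n_bags=200, effect_size=3.0, seed=11))


@pytest.fixture(scope="session")
def contaminated_bags():
    """30% corrupted instances with high sigma2; g filled from sigma2."""
    bs = tm.make_bags(
        tm.BagSetConfig(n_bags=200, effect_size=3.0, contamination=0.3, seed=21)
    )
    for b in bs:
        b.g = quality_weights_from_s2(b.sigma2)
    return bs


@pytest.fixture(scope="session")
def ordinal_bags():
    """Three-class instance-count bags (<7, 7-9, >=10 signal instances)."""
    return tm.make_bags(
        tm.BagSetConfig(n_bags=200, effect_size=3.0, n_classes=3, seed=31)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
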