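import numpy as np
import pytest

from leafseal.synthetic import LeafSimConfig, simulate_leaf


@pytest.fixture(scope="session")
def straight_leaf_noiseless():
    """Short straight leaf with known plateaus, no tracking noise."""
    cfg = LeafSimConfig(
        shape_profile="straight",
        leaf_length_mm=45.5,
        segment_plateaus={"apex": -0.03, "incision": -0.10, "base": -0.04},
        tau_min=10.0,
        duration_min=60.0,
    )
    return cfg, simulate_leaf(cfg)


@pytest.fixture(scope="session")
def recurved_leaf_noiseless():
    """Recurved leaf (circular-arc midline), no tracking noise."""
    cfg = LeafSimConfig(
        shape_profile="recurved",
        leaf_length_mm=27.4,
        curvature_radius_mm=40.0,
        segment_plateaus={"apex": -0.03, "incision": -0.05, "base": -0.03},
        tau_min=10.0,
        duration_min=60.0,
    )
    return cfg, simulate_leaf(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
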