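"""Shared fixtures: a desk-scale phantom configuration and derived volumes.

Tests run on a 96³ grid with a proportionally smaller liver than the default
configuration so the whole suite stays fast; the geometry rules (2 mm vessel
floor, second-ramification trees, ~9% blood pool) are identical.
"""

import numpy as np
import pytest

from hepavol import (
    PerturbationConfig,
    PhantomConfig,
    generate_phantom,
    perturb_segmentation,
)

TEST_TARGET_DSC = {"liver": 0.97, "hepatic_veins": 0.66, "portal_veins": 0.67}


def small_phantom_config(**overrides) -> PhantomConfig:
    base = dict(
        grid_shape=(96, 96, 96),
        liver_axes=(38.0, 28.0, 22.0),
        trunk_radius_mm=2.4,
        lesion_radius_range=(6.0, 12.0),
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return small_phantom_config()


@pytest.fixture(scope="session")
def phantom(small_config):
    """One deterministic right-hepatectomy phantom shared across tests."""
    return generate_phantom(small_config, seed=11)


@pytest.fixture(scope="session")
def cirrhotic_phantom():
    return generate_phantom(
        small_phantom_config(condition="cirrhosis", resection="extended_right"), seed=5
    )


@pytest.fixture(scope="session")
def perturbed(phantom):
    """Simulated automated segmentation of the shared phantom."""
    cfg = PerturbationConfig(target_dsc=dict(TEST_TARGET_DSC), seed=101)
    return perturb_segmentation(phantom.truth, cfg, trees=phantom.trees)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240615)
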