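"""Shared fixtures: fixture recipes, properties and (expensive) fits.

Session scope is used for everything that costs simulations so the suite
re-uses one noise-free campaign fit and one noisy fit across modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from fbgtwin.calibration import fit
from fbgtwin.simulator import ModelParameters, simulate
from fbgtwin.synthetic_data import (
    default_material_properties,
    default_sigmas,
    default_true_params,
    equipment_properties,
    make_campaign,
    make_recipe,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props():
    return default_material_properties()


@pytest.fixture(scope="session")
def equip():
    return equipment_properties("pilot")


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def target_recipe():
    return make_recipe("pilot", "target")


@pytest.fixture(scope="session")
def sigmas():
    return default_sigmas("pilot")


@pytest.fixture(scope="session")
def target_trajectory(target_recipe, true_params, props, equip):
    return simulate(target_recipe, true_params, props, equip)


@pytest.fixture(scope="session")
def clean_campaign():
    """Noise-free, jitter-free A/B/C/D campaign."""
    return make_campaign(noise_sd=0.0, time_jitter_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_campaign():
    """Campaign at the default noise conditions (0.1 LOD%, 30 s jitter)."""
    return make_campaign(noise_sd=0.1, time_jitter_sd=30.0, seed=11)


@pytest.fixture(scope="session")
def noisy_fit(noisy_campaign):
    """Two-batch fit of the noisy campaign; provides a realistic covariance."""
    c = noisy_campaign
    return fit([c.batches["A"], c.batches["B"]], props=c.props,
               equip={"A": c.equip_pilot, "B": c.equip_pilot})
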