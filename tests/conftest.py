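"""Shared fixtures: acquisition configs and a small simulated phantom."""

import numpy as np
import pytest

from hvmudi.clutter_svd import blockwise_filter, power_image
from hvmudi.core_io import compound
from hvmudi.phantom import (
    ClutterSpec,
    NoiseSpec,
    microtube_scene,
    reference_acquisition_config,
    simulate_iq,
)


@pytest.fixture(scope="session")
def reference_config():
    """40 MHz, PRF 3500 Hz, 7 angles −3..+3° (FR = 500 Hz)."""
    return reference_acquisition_config()


@pytest.fixture(scope="session")
def small_phantom(reference_config):
    """96×96, 100-frame microtube simulation at 7.2 mm/s (seed 3)."""
    scene = microtube_scene(7.2e-3, 96, 96, reference_config)
    ensemble, truth = simulate_iq(
        scene, ClutterSpec(), NoiseSpec(), reference_config,
        n_frames=100, seed=3, shape=(96, 96),
    )
    return ensemble, truth


@pytest.fixture(scope="session")
def small_phantom_power(small_phantom):
    """Blockwise-filtered power image of the small phantom."""
    ensemble, truth = small_phantom
    series = compound(ensemble)
    filtered, records = blockwise_filter(series, block_size=48, overlap=0.8)
    return power_image(filtered), truth, records


@pytest.fixture(scope="session")
def clean_phantom(reference_config):
    """Clutter-free, near-noiseless microtube simulation for closed-form checks."""
    scene = microtube_scene(7.2e-3, 64, 64, reference_config)
    ensemble, truth = simulate_iq(
        scene,
        ClutterSpec(amplitude_db_above_blood=-300.0),
        NoiseSpec(snr_db=120.0),
        reference_config,
        n_frames=100,
        seed=5,
        shape=(64, 64),
    )
    return ensemble, truth
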