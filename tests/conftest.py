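"""Shared fixtures: small calibrated systems and fast pulling protocols."""

import numpy as np
import pytest

import pullfe as pf


@pytest.fixture(scope="session")
def default_config():
    return pf.load_config()


@pytest.fixture(scope="session")
def apo_landscape(default_config):
    """Apo-like landscape calibrated to a breaking ΔF of -2.5 kJ/mol."""
    return pf.calibrate_depth(
        default_config.systems["apo"].landscape, -2.5, 300.0
    )


@pytest.fixture(scope="session")
def holo_landscape(default_config):
    """Holo-like landscape calibrated to a breaking ΔF of +1.9 kJ/mol."""
    return pf.calibrate_depth(
        default_config.systems["holo"].landscape, 1.9, 300.0
    )


@pytest.fixture(scope="session")
def fast_protocol():
    """8x pulling speed: cheap ensembles for unit tests."""
    return pf.PullingProtocol(velocity=8 * 1.75e-4, save_stride=500)


@pytest.fixture(scope="session")
def flat_landscape():
    """Free particle: no wells, thresholds only partition the domain."""
    return pf.ToyLandscape(wells=())


@pytest.fixture(scope="session")
def small_apo_ensemble(apo_landscape, fast_protocol):
    """48 replicas pulled at 8x speed on the calibrated apo landscape."""
    return pf.simulate_ensemble(apo_landscape, fast_protocol, 48, 4242)
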