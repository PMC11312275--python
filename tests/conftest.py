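"""Shared fixtures: small phantoms and the recovery-protocol geometry."""

import numpy as np
import pytest

from pancedge.imgio import ROIBox
from pancedge.phantoms import PhantomSpec, centered_roi, make_phantom


@pytest.fixture(scope="session")
def default_roi() -> ROIBox:
    return centered_roi((64, 64), (40, 40))


@pytest.fixture(scope="session")
def recovery_roi() -> ROIBox:
    """Wide ROI used when the baseline spline must stay stiff (knot spacing 40 px)."""
    return ROIBox(top=64, left=8, height=48, width=160)


@pytest.fixture(scope="session")
def flat_phantom():
    """Noise-free, perfectly smooth horizontal border."""
    spec = PhantomSpec(perturbation_rms=0.0, noise_sigma=0.0, seed=0)
    image, truth = make_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def rough_phantom():
    """Reference rough phantom under the default imaging conditions."""
    spec = PhantomSpec(perturbation_rms=1.5, seed=2)
    image, truth = make_phantom(spec)
    return spec, image, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
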