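"""Shared fixtures: small phantoms and their pipeline products.

The expensive fixtures are session-scoped so the synthetic field is
generated and analyzed once: ``phantom_default`` is the default-geometry
1 mm² field (used for segmentation-fidelity and density checks) and
``small_phantom`` a 0.35 mm field for fast end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import imic
from imic.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(width_px=1380, height_px=1380, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_phantom, small_config):
    stack, truth, regions = small_phantom
    return imic.analyze_stack(stack, regions, seed=small_config.seed)


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    # default geometry: 1 mm^2 field at the default density / size laws
    return PhantomConfig(seed=7)


@pytest.fixture(scope="session")
def default_phantom(default_config):
    return generate_phantom(default_config)


def make_disk_labelmap(
    shape=(200, 200), centers=((60, 60), (60, 140)), radius=18
) -> np.ndarray:
    """Label map with one disk per center, labels 1..n."""
    out = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for i, (r, c) in enumerate(centers, start=1):
        out[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = i
    return out
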