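"""Shared fixtures: small, fast synthetic objects for the unit suites."""

from __future__ import annotations

import numpy as np
import pytest

from axoncyto import rve, synth
from axoncyto.containers import TractStats


@pytest.fixture(scope="session")
def cc_params() -> TractStats:
    return rve.tract_preset("cc")


@pytest.fixture(scope="session")
def small_phantom():
    """A 256×256 clean phantom at 30% myelin with its ground truth."""
    cfg = synth.Phantom2DConfig(
        width=256, height=256, myelin_fraction=0.30, glia_blob_count=1, seed=42
    )
    return synth.generate_phantom_image(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    """A 256×256 phantom with impulse noise and illumination gradient."""
    cfg = synth.Phantom2DConfig(
        width=256, height=256, myelin_fraction=0.30, glia_blob_count=1,
        impulse_noise_fraction=0.05, illumination_gradient_amplitude=0.20,
        seed=43,
    )
    return synth.generate_phantom_image(cfg)


@pytest.fixture(scope="session")
def small_rve(cc_params):
    """A compact corpus-callosum RVE (6 μm box, a handful of axons)."""
    return rve.generate_rve(
        rve.RVEConfig(tract_params=cc_params, box=(6.0, 6.0, 6.0), seed=3)
    )


@pytest.fixture(scope="session")
def small_volume(small_rve):
    return synth.voxelize_tubes(small_rve.tubes, small_rve.box)


def straight_tube(radius=0.5, length=4.0, center=(2.0, 2.0), axon_id=1):
    """An axis-aligned circular tube for analytic oracles."""
    z = np.arange(0.0, length + 1e-9, 0.15)
    n = z.size
    return rve.AxonTube(
        axon_id=axon_id,
        z=z,
        centers=np.tile(np.asarray(center, dtype=float), (n, 1)),
        a=np.full(n, radius),
        b=np.full(n, radius),
        theta=np.zeros(n),
        ellipticity=0.0,
    )
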