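"""Shared fixtures: small synthetic datasets and cached model presses."""

from __future__ import annotations

import numpy as np
import pytest

from frictouch.mechanics import default_params, simulate_press
from frictouch.synth import GeneratorConfig, gen_press_trial


@pytest.fixture(scope="session")
def disk_field_axes():
    """A 64x64 grid on [-1, 1]^2 with an inscribed disk mask."""
    ax = np.linspace(-1.0, 1.0, 64)
    gx, gy = np.meshgrid(ax, ax)
    mask = gx**2 + gy**2 <= 0.9**2
    return ax, gx, gy, mask


@pytest.fixture(scope="session")
def small_trial_pair():
    """A low/high-friction synthetic trial pair at reduced image size.

    Smaller frames keep tracking fast while preserving the full
    statistical structure (radial growth, onset referencing, speckle).
    """
    out = {}
    for alpha in (3.0, 1e-3):
        cfg = GeneratorConfig(
            seed=42,
            alpha_um=alpha,
            image_size=256,
            contact_radius_max_mm=2.2,
            frame_rate=12.0,
        )
        out[alpha] = gen_press_trial(cfg)
    return out


@pytest.fixture(scope="session")
def press_cache():
    """Lazily computed equilibrium presses of the fingertip model.

    One press per friction coefficient is expensive; every test (and
    the acceptance checks) shares the same converged results.
    """
    cache: dict[float, object] = {}

    def get(mu: float, **overrides):
        key = (mu, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = simulate_press(default_params(mu=mu, **overrides))
        return cache[key]

    return get
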