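"""Shared fixtures: small rendered scenes with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from angioquant.synthetic import BeadPlan, SceneSpec, SproutPlan, render_scene


def clean_bead_spec(radius: float = 60.0, sprouts=(0.0, 120.0, 240.0),
                    size: int = 320, noise: float = 0.0,
                    shading: float = 0.0, **kw) -> SceneSpec:
    """One centered bead with simple radial sprouts, defaults noise-free."""
    c = size / 2.0
    plan = tuple(SproutPlan(angle_deg=a, trunk_length=55.0) for a in sprouts)
    return SceneSpec(kind="fba", height=size, width=size,
                     beads=(BeadPlan(cy=c, cx=c, radius=radius, sprouts=plan),),
                     noise_sigma=noise, shading_amplitude=shading,
                     texture_density=0.0, **kw)


@pytest.fixture(scope="session")
def single_bead():
    """Noise-free single-bead render plus its ground truth."""
    return render_scene(clean_bead_spec())


@pytest.fixture(scope="session")
def noisy_blank():
    """A structure-free image: background, shading and speckle only."""
    spec = SceneSpec(kind="fba", height=320, width=320, beads=(),
                     noise_sigma=0.04, shading_amplitude=0.2,
                     texture_density=0.0)
    img, _ = render_scene(spec)
    return img


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
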