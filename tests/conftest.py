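"""Shared fixtures: deterministic RNGs, canonical outlines and small datasets."""

from dataclasses import replace

import numpy as np
import pytest

from molarmark import (
    GroovePoints,
    Outline,
    default_templates,
    derive_landmarks,
    generate_crown,
    make_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def circle_outline():
    """Regular 360-gon approximating the unit circle, centered at the origin."""
    theta = np.deg2rad(np.arange(360.0))
    return Outline(np.column_stack([np.cos(theta), np.sin(theta)]))


@pytest.fixture
def circle_grooves(circle_outline):
    """Groove points on the 360-gon at anatomically plausible azimuths:
    g6 mesial (180 deg), g7 lingual (90), g8 distolingual (22), g9
    distobuccal (-22), g10 buccal (-90)."""
    v = circle_outline.vertices
    pts = np.array([v[180], v[90], v[22], v[338], v[270]])
    return GroovePoints(pts, circle_outline)


@pytest.fixture
def symmetric_template():
    """Mirror-symmetric crown template (about the MD axis), zero noise."""
    return replace(
        default_templates()[0],
        cusp_lobe_amplitudes=(0.16, 0.15, 0.13, 0.15, 0.16),
        cusp_angular_positions=tuple(
            np.deg2rad([135.0, 45.0, 0.0, -45.0, -135.0])
        ),
        noise_sd=0.0,
    )


@pytest.fixture
def crown_specimen():
    """One deterministic noisy crown from the first default template."""
    return generate_crown(default_templates()[0], 42, sex="F", specimen_id="fix1")


@pytest.fixture
def crown_config(crown_specimen):
    return derive_landmarks(
        crown_specimen.outline, crown_specimen.groove, specimen_id="fix1"
    )


@pytest.fixture(scope="session")
def small_dataset():
    """5 templates x 6 specimens: enough for DFA/PCA mechanics tests."""
    return make_dataset(n_per_template=6, seed=7)


def random_star_polygon(rng, n_vertices=None, r_min=0.5, r_max=1.5):
    """Radial polygon with random radii at jittered evenly spaced angles.

    Angular gaps stay below pi, so the polygon always contains the origin and
    is star-shaped from it.
    """
    n = n_vertices or int(rng.integers(8, 60))
    theta = 2 * np.pi * np.arange(n) / n + rng.uniform(0, 0.8 * 2 * np.pi / n, n)
    r = rng.uniform(r_min, r_max, n)
    return Outline(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
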