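"""Shared fixtures: small phantoms and geometric helpers.

Phantom generation is the expensive part of the suite, so the standard
phantom (and derived guidance fractions) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from cordprop.image_io import Contour, ImageVolume, StructureSet
from cordprop.masking import build_body_mask
from cordprop.phantom import DeformationSpec, PhantomSpec, generate_fraction, generate_phantom


def square(side: float, centre=(0.0, 0.0)) -> np.ndarray:
    h = side / 2
    cx, cy = centre
    return np.array(
        [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
    )


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=101)


@pytest.fixture(scope="session")
def phantom(default_spec):
    """(kvct, cord structure set, true body mask) for the default phantom."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def body_mask(phantom):
    kvct, _, _ = phantom
    return build_body_mask(kvct)


@pytest.fixture(scope="session")
def identity_fraction(default_spec, phantom):
    """Guidance fraction with zero deformation (identity ground truth)."""
    kvct, _, _ = phantom
    return generate_fraction(kvct, default_spec, 0)


@pytest.fixture(scope="session")
def shifted_spec() -> PhantomSpec:
    return PhantomSpec(
        seed=202, deformation=DeformationSpec(translation=(5.0, -3.0, 6.0))
    )


@pytest.fixture(scope="session")
def shifted_phantom(shifted_spec):
    kvct, cord, mask_truth = generate_phantom(shifted_spec)
    mvct, truth, truth_contours, dose = generate_fraction(kvct, shifted_spec, 0)
    return kvct, cord, mvct, truth, truth_contours, dose


@pytest.fixture()
def tiny_volume() -> ImageVolume:
    rng = np.random.default_rng(0)
    voxels = rng.integers(-1000, 2000, size=(5, 8, 7)).astype(np.int16)
    return ImageVolume(voxels, (1.5, 2.0, 2.5), (-10.0, -20.0, 5.0), frame="tiny")


@pytest.fixture()
def circle_structure() -> StructureSet:
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    pts = np.column_stack([4.0 * np.cos(theta), 4.0 * np.sin(theta)])
    contours = [Contour(float(z), pts.copy()) for z in np.arange(0, 30, 3.0)]
    return StructureSet("cord", contours, frame="tiny")
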