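"""Shared fixtures: canonical shapes and the default synthetic dataset."""

import numpy as np
import pytest

from leafcat import synthetic_leaves as sl
from leafcat import contour_extraction as ce
from leafcat import fourier_descriptor as fd
from leafcat import morphospace as ms
from leafcat.contour import Contour


@pytest.fixture(scope="session")
def circle_contour():
    """Unit circle sampled at 256 equally spaced points, CCW."""
    theta = 2 * np.pi * np.arange(256) / 256
    return Contour(np.column_stack([np.cos(theta), np.sin(theta)]))


@pytest.fixture(scope="session")
def square_contour():
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture(scope="session")
def leaf_fixtures():
    """20 varied leaf contours (all families/margins), resampled to 512."""
    specs = sl.reconstruction_fixture(seed=11, n_contours=20)
    return [ce.resample_contour(sl.generate_leaf(s, 512), 512) for s in specs]


@pytest.fixture(scope="session")
def default_dataset():
    """The 6-class, 20-per-class dataset at default generator noise."""
    return sl.generate_dataset(n_per_class=20, seed=0)


@pytest.fixture(scope="session")
def default_phi(default_dataset):
    contours = [ce.resample_contour(c, 512) for c in default_dataset.contours]
    descs = [fd.describe(c) for c in contours]
    return ms.harmonic_matrix(descs, default_dataset.sample_ids)
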