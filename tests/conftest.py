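"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import waterpet as wp
from waterpet.aif import fine_time_base, frame_average_curve, sample_aif

#: Small field of view used throughout the suite: same 3.27-mm voxels and mm
#: geometry as the clinical default, smaller grid for speed.
TEST_SHAPE = (64, 64, 64)


@pytest.fixture(scope="session")
def grid():
    return wp.build_frame_grid()


@pytest.fixture(scope="session")
def aif():
    return wp.AIFModel()


@pytest.fixture(scope="session")
def aif_curves(grid, aif):
    """(fine time base, fine AIF, frame-averaged AIF)."""
    t_fine = fine_time_base(grid)
    ca_fine = sample_aif(aif, t_fine)
    return t_fine, ca_fine, frame_average_curve(ca_fine, t_fine, grid)


@pytest.fixture(scope="session")
def clean_phantom(grid, aif):
    """Noise-free default-geometry phantom on the small grid."""
    spec = wp.PhantomSpec(grid_shape=TEST_SHAPE, noise_scale=0.0)
    image, truth = wp.generate_phantom(spec, aif=aif, grid=grid)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_analysis(clean_phantom):
    """Motion-free territorial analysis of the clean phantom."""
    from waterpet.study import MotionStudy

    _, image, truth = clean_phantom
    return MotionStudy.analyse(image, truth)


@pytest.fixture(scope="session")
def catalogue(grid, clean_phantom):
    _, image, truth = clean_phantom
    pk = wp.peak_frame(image.tac(truth.myocardium_mask))
    return wp.build_catalogue(grid, pk)
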