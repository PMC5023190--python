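"""Shared phantom fixtures.

The expensive pieces — rendering and tracking — are session-scoped so each
phantom is segmented once and reused by the unit, property and acceptance
tests.  Noise levels put the phantoms in the regime of a good
contrast-enhanced MRA acquisition (contrast/noise = 20).
"""

from __future__ import annotations

import numpy as np
import pytest

from pavol import segmentation as sg
from pavol.phantom import TubeSpec, render_tube

CONTRAST = 90.0  # a1 - a0
NOISE_SD = CONTRAST / 20.0  # SNR 20


def run_pipeline(vol, seed_point):
    """track -> refine -> centroid centerline -> diameter profile -> QC."""
    seg = sg.track(vol, seed_point)
    seg = sg.refine(vol, seg)
    seg = sg.centroid_centerline(vol, seg)
    seg = sg.diameter_profile(seg)
    return sg.flag_blowouts(seg)


@pytest.fixture(scope="session")
def straight_spec():
    return TubeSpec.straight(
        start=(0, 0, 0), direction=(0, 0, 1), length=60.0, radius=5.0,
        a0=10.0, a1=10.0 + CONTRAST, psf_sigma=1.0, noise_sd=NOISE_SD, seed=7,
    )


@pytest.fixture(scope="session")
def straight_volume(straight_spec):
    vol, truth = render_tube(straight_spec)
    return vol, truth


@pytest.fixture(scope="session")
def straight_tracked(straight_volume):
    vol, _ = straight_volume
    return run_pipeline(vol, (0.3, 0.2, 30.0))


@pytest.fixture(scope="session")
def straight_tracked_shifted_seed(straight_volume):
    """Same tube tracked from a seed 2 mm away (along the axis and slightly
    off-center) — the seed-placement reproducibility probe."""
    vol, _ = straight_volume
    return run_pipeline(vol, (-0.4, 0.3, 31.9))


@pytest.fixture(scope="session")
def arc_spec():
    return TubeSpec.arc(
        start=(0, 0, 0), direction=(0, 0, 1), binormal=(0, 1, 0),
        curvature_radius=30.0, length=np.pi / 2 * 30.0, radius=4.0,
        a0=10.0, a1=10.0 + CONTRAST, psf_sigma=1.0, noise_sd=NOISE_SD, seed=3,
    )


@pytest.fixture(scope="session")
def arc_volume(arc_spec):
    vol, truth = render_tube(arc_spec)
    return vol, truth


@pytest.fixture(scope="session")
def arc_tracked(arc_spec, arc_volume):
    vol, _ = arc_volume
    return run_pipeline(vol, arc_spec.centerline(arc_spec.length / 2)[0])


@pytest.fixture(scope="session")
def clean_tube():
    """Small noiseless tube for cheap fit-level tests."""
    spec = TubeSpec.straight(
        start=(0, 0, 0), direction=(0, 0, 1), length=30.0, radius=5.0,
        a0=10.0, a1=100.0, psf_sigma=1.0, noise_sd=0.0,
    )
    vol, truth = render_tube(spec)
    return spec, vol, truth
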