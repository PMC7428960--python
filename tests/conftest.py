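"""Shared fixtures: small, fast phantom cubes for unit tests.

Unit tests run on a reduced 96 x 224 x 96 grid (4 um axial sampling) so a
full render-plus-segmentation cycle takes well under a second; the
acceptance suite exercises the full-size default geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaquant import LesionTruthSpec, PhantomSpec, make_truth, render_volume


def small_spec(**overrides) -> PhantomSpec:
    """A reduced-grid phantom spec for fast unit tests."""
    kwargs = dict(
        grid_nx=96,
        grid_ny=96,
        depth_nz=224,
        extent_xy_mm=7.0,
        axial_um_per_px=4.0,
        speckle_looks=None,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def single_lesion(**overrides) -> LesionTruthSpec:
    kwargs = dict(center_xy_mm=(3.5, 3.5), base_radius_mm=1.25)
    kwargs.update(overrides)
    return LesionTruthSpec(**kwargs)


@pytest.fixture(scope="session")
def noiseless_lesion_phantom():
    spec = small_spec(ga_lesions=[single_lesion()])
    truth = make_truth(spec)
    return spec, truth, render_volume(truth, spec)


@pytest.fixture(scope="session")
def speckled_lesion_phantom():
    spec = small_spec(ga_lesions=[single_lesion()], speckle_looks=4.0, seed=11)
    truth = make_truth(spec)
    return spec, truth, render_volume(truth, spec)


@pytest.fixture(scope="session")
def noiseless_clean_phantom():
    spec = small_spec()
    truth = make_truth(spec)
    return spec, truth, render_volume(truth, spec)


def rms(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(a))))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * float((a & b).sum()) / float(a.sum() + b.sum())
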