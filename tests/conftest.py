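import logging

import numpy as np
import pytest

from mitonode import Calibration, ROI, apply_photoconversion, build_scene, render_movie
from mitonode.simulate import OpticsModel, SceneParams

logging.getLogger("mitonode").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def calibration():
    return Calibration()


@pytest.fixture(scope="session")
def constriction_scene():
    """A 12-slice z-stack scene with 60% of ER crossings constricted."""
    return build_scene(SceneParams.constriction_stack(), seed=21)


@pytest.fixture(scope="session")
def constriction_stack(constriction_scene):
    return render_movie(constriction_scene, seed=321)


@pytest.fixture(scope="session")
def puncta_scene():
    return build_scene(SceneParams.puncta_movie(), seed=4)


@pytest.fixture(scope="session")
def puncta_stack(puncta_scene):
    return render_movie(puncta_scene, seed=104)


def converted_scene(seed):
    scene = build_scene(SceneParams.photoconversion_movie(), seed=seed)
    pts = scene.filaments[0].points
    mid = pts[len(pts) // 2]
    roi = ROI(origin=(int(mid[0] / 0.1) - 10, int(mid[1] / 0.1) - 10), size=(2.0, 2.0))
    return apply_photoconversion(scene, roi)


@pytest.fixture(scope="session")
def photoconversion_scene():
    return converted_scene(seed=3)


@pytest.fixture(scope="session")
def photoconversion_stack(photoconversion_scene):
    return render_movie(photoconversion_scene, seed=503)


@pytest.fixture(scope="session")
def noise_free_optics():
    return OpticsModel(poisson_noise=False, gaussian_read_noise_sd=0.0)
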