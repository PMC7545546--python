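import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_landmarks():
    """Symmetric neutral-looking landmark set, teardrops horizontal."""
    from cupversion import PelvicLandmarks

    return PelvicLandmarks(
        symphysis=(256.0, 286.0),
        scj=(256.0, 256.0),
        teardrop_l=(316.0, 256.0),
        teardrop_r=(196.0, 256.0),
    )


@pytest.fixture
def measure_synthetic():
    """Project a scene and push its annotation through the measurement chain."""
    from cupversion import CupScene, PelvicPose, project_scene
    from cupversion.io import FilmAnnotation, measure_annotation

    def _run(anteversion, inclination, theta=0.0, phi=0.0, side="right",
             noise_sigma=0.0, seed=0, **kwargs):
        scene = CupScene(
            true_anteversion=anteversion,
            true_inclination=inclination,
            pelvic_pose=PelvicPose(theta=theta, phi=phi),
            side=side,
            noise_sigma=noise_sigma,
            seed=seed,
            **kwargs,
        )
        film = project_scene(scene)
        ann = FilmAnnotation(
            film_id="synthetic",
            side=side,
            landmarks=film.landmarks,
            rim_points=film.rim_points,
            apparent_retroversion=film.apparent_retroversion,
        )
        return measure_annotation(ann), film

    return _run
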