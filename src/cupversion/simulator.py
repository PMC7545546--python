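"""Forward projection of a cup and pelvic landmarks onto a synthetic film.

The simulator is the ground-truth oracle for every measurement operation:
it places a circular cup rim at a known anatomical anteversion and
inclination, puts the pelvic landmarks at known 3D offsets, applies a known
pelvic pose (tilt then axial rotation), and projects everything onto the
film plane.  The projected rim's exact ellipse is computed analytically, so
measurement code can be validated against known truth; optional Gaussian
noise on the annotation points mimics human clicking error.

Geometry
--------
All 3D positions live in the *measured-side frame*: e1 toward the measured
acetabulum along the transverse axis, e2 superior, e3 anterior.  The film
is the e1-e2 plane; the default projection is orthographic along e3 (a
point-source perspective mode is available via ``source_distance``).  Image
coordinates are raster pixels (y down); on an AP film the patient's left
side appears on the viewer's right, so e1 maps to +x for a left hip and -x
for a right hip.  One length unit = one pixel.

The cup-opening axis for anteversion ``av`` and inclination ``w`` is

    n = (cos av * sin w,  -cos av * cos w,  sin av)

so at identity pose the projected ellipse has axis ratio ``sin av`` and its
major axis makes the angle ``w`` with the trans-teardrop line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .ellipse_fit import fit_ellipse
from .geometry import Ellipse2D
from .landmarks import PelvicLandmarks, PelvicPose, pose_matrix

__all__ = [
    "LandmarkModel3D",
    "CupScene",
    "SyntheticFilm",
    "project_scene",
    "generate_cohort",
    "generate_repeated_cohort",
    "DEFAULT_RANGES",
]

#: Default sampling ranges for synthetic cohorts (degrees).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "anteversion": (5.0, 60.0),
    "inclination": (30.0, 60.0),
    "tilt": (-15.0, 15.0),
    "rotation": (-10.0, 10.0),
}


@dataclass(frozen=True)
class LandmarkModel3D:
    """3D landmark positions in the measured-side frame, origin at the
    teardrop midpoint.  Lengths in pixels (1 px = 1 length unit).

    Defaults approximate adult AP-pelvis geometry at typical magnification:
    teardrops 120 px apart on the transverse axis; symphysis upper pole on
    the midline, 30 px inferior and 40 px anterior to the teardrop plane;
    SCJ ``neutral_v`` px superior to the symphysis pole and posterior by
    the depth that makes the 3D symphysis-SCJ distance equal ``ssd``.
    """

    teardrop_halfspan: float = 60.0
    symphysis: tuple[float, float, float] = (0.0, -30.0, 40.0)
    ssd: float = 100.0
    neutral_v: float = 30.0

    def __post_init__(self) -> None:
        if self.ssd <= 0 or self.teardrop_halfspan <= 0:
            raise ValueError("ssd and teardrop_halfspan must be positive")
        if abs(self.neutral_v) > self.ssd:
            raise ValueError("|neutral_v| cannot exceed ssd")

    @property
    def scj(self) -> tuple[float, float, float]:
        depth = math.sqrt(self.ssd**2 - self.neutral_v**2)
        sx, sy, sz = self.symphysis
        return (sx, sy + self.neutral_v, sz - depth)


@dataclass(frozen=True)
class CupScene:
    """Ground-truth description of one synthetic film."""

    true_anteversion: float
    true_inclination: float
    cup_radius: float = 25.0
    cup_center: tuple[float, float, float] = (55.0, 20.0, 10.0)
    pelvic_pose: PelvicPose = PelvicPose()
    landmark_model: LandmarkModel3D = LandmarkModel3D()
    side: str = "right"
    noise_sigma: float = 0.0
    seed: int = 0
    n_rim_points: int = 64
    rim_arc_deg: float = 360.0
    image_center: tuple[float, float] = (256.0, 256.0)
    source_distance: Optional[float] = None  # None = orthographic

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_anteversion < 90.0:
            raise ValueError("true_anteversion must be in [0, 90)")
        if not 0.0 <= self.true_inclination < 90.0:
            raise ValueError("true_inclination must be in [0, 90)")
        if self.cup_radius <= 0:
            raise ValueError("cup_radius must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def cup_axis(self) -> np.ndarray:
        """Unit cup-opening axis in the reference (un-posed) frame."""
        av = math.radians(self.true_anteversion)
        w = math.radians(self.true_inclination)
        return np.array(
            [math.cos(av) * math.sin(w), -math.cos(av) * math.cos(w), math.sin(av)]
        )


@dataclass(frozen=True)
class SyntheticFilm:
    """Projected annotation of one scene, plus analytic ground truth."""

    landmarks: PelvicLandmarks
    rim_points: np.ndarray
    true_ellipse: Ellipse2D
    apparent_retroversion: bool
    scene: CupScene

    def to_annotation(self, film_id: str = "synthetic") -> dict:
        """Annotation dict in the standard measurement-input schema."""
        lm = self.landmarks
        return {
            "film_id": film_id,
            "side": self.scene.side,
            "apparent_retroversion": bool(self.apparent_retroversion),
            "landmarks": {
                "symphysis": list(lm.symphysis),
                "scj": list(lm.scj),
                "teardrop_l": list(lm.teardrop_l),
                "teardrop_r": list(lm.teardrop_r),
            },
            "cup": {"rim_points": self.rim_points.tolist()},
        }


def _to_image(points3d: np.ndarray, scene: CupScene) -> np.ndarray:
    """Project 3D points (measured-side frame) to image pixels.

    Orthographic by default; with ``source_distance`` D set, a point source
    sits D units anterior to the film plane (e3 = D) and rays diverge.
    """
    p = np.atleast_2d(points3d)
    sx = 1.0 if scene.side == "left" else -1.0
    x = sx * p[:, 0]
    y = -p[:, 1]
    if scene.source_distance is not None:
        d = float(scene.source_distance)
        z = p[:, 2]
        if np.any(z >= d):
            raise ValueError("points at or behind the X-ray source")
        mag = d / (d - z)
        x, y = x * mag, y * mag
    return np.column_stack([x + scene.image_center[0], y + scene.image_center[1]])


def _analytic_ellipse(scene: CupScene, rot: np.ndarray) -> Ellipse2D:
    """Exact ellipse of the orthographically projected rim circle.

    A circle of radius r with unit normal n projects to an ellipse with
    semi-major r (perpendicular to the projected normal) and semi-minor
    r*|n . e3|.
    """
    n_film = rot @ scene.cup_axis()
    center = _to_image(rot @ np.asarray(scene.cup_center, dtype=float), scene)[0]
    a = scene.cup_radius
    b = a * abs(float(n_film[2]))
    sx = 1.0 if scene.side == "left" else -1.0
    q = np.array([sx * n_film[0], -n_film[1]])  # projected normal, image coords
    if np.hypot(*q) < 1e-12:
        ori = 0.0
    else:
        major = np.array([-q[1], q[0]])
        ori = math.degrees(math.atan2(major[1], major[0])) % 180.0
    return Ellipse2D(center=(float(center[0]), float(center[1])), a=a, b=b,
                     orientation_deg=ori)


def project_scene(scene: CupScene) -> SyntheticFilm:
    """Project a scene onto the film and package the annotation.

    The pelvic pose is applied about the teardrop midpoint (rotation center
    cancels out of all relative measurements); rim points are sampled at
    uniform parametric angle over ``rim_arc_deg`` of the rim circle.
    Gaussian noise of ``noise_sigma`` pixels, seeded from ``scene.seed``,
    is added to every annotation coordinate (landmarks and rim points),
    never to the analytic ``true_ellipse``.
    """
    rot = pose_matrix(scene.pelvic_pose)
    lm = scene.landmark_model
    hs = lm.teardrop_halfspan
    td_measured = np.array([hs, 0.0, 0.0])
    td_other = np.array([-hs, 0.0, 0.0])
    landmarks3d = np.array([lm.symphysis, lm.scj, td_measured, td_other])

    n = scene.cup_axis()
    # orthonormal basis of the rim plane
    p1 = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(p1) < 1e-12:
        p1 = np.array([1.0, 0.0, 0.0])
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(n, p1)
    tau = np.radians(np.linspace(0.0, scene.rim_arc_deg, scene.n_rim_points,
                                 endpoint=scene.rim_arc_deg < 360.0))
    rim3d = (
        np.asarray(scene.cup_center, dtype=float)
        + scene.cup_radius * (np.outer(np.cos(tau), p1) + np.outer(np.sin(tau), p2))
    )

    lm_img = _to_image(landmarks3d @ rot.T, scene)
    rim_img = _to_image(rim3d @ rot.T, scene)
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        lm_img = lm_img + rng.normal(0.0, scene.noise_sigma, lm_img.shape)
        rim_img = rim_img + rng.normal(0.0, scene.noise_sigma, rim_img.shape)

    if scene.source_distance is None:
        true_ellipse = _analytic_ellipse(scene, rot)
    else:
        # perspective: no simple closed form; fit a dense exact projection
        dense = np.radians(np.linspace(0.0, 360.0, 360, endpoint=False))
        ring = (
            np.asarray(scene.cup_center, dtype=float)
            + scene.cup_radius * (np.outer(np.cos(dense), p1) + np.outer(np.sin(dense), p2))
        )
        true_ellipse, _ = fit_ellipse(_to_image(ring @ rot.T, scene))

    n_film = rot @ n
    measured, other = (lm_img[2], lm_img[3])
    td_l, td_r = (measured, other) if scene.side == "left" else (other, measured)
    landmarks = PelvicLandmarks(
        symphysis=tuple(lm_img[0]),
        scj=tuple(lm_img[1]),
        teardrop_l=tuple(td_l),
        teardrop_r=tuple(td_r),
    )
    return SyntheticFilm(
        landmarks=landmarks,
        rim_points=rim_img,
        true_ellipse=true_ellipse,
        apparent_retroversion=bool(n_film[2] < 0),
        scene=scene,
    )


def _check_ranges(ranges: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    merged = dict(DEFAULT_RANGES)
    merged.update(ranges or {})
    for key, (lo, hi) in merged.items():
        if hi < lo:
            raise ValueError(f"empty range for {key!r}: ({lo}, {hi})")
    return merged


def generate_cohort(
    n_films: int,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
    side: str = "right",
    **scene_kwargs,
) -> tuple[list[SyntheticFilm], pd.DataFrame]:
    """Sample ``n_films`` scenes uniformly from the ranges and project them.

    Fully reproducible from ``seed``: scene parameters and per-film noise
    streams all derive from a single generator.  Returns the films together
    with a truth table pairing each film id with its generating parameters.
    """
    if n_films < 1:
        raise ValueError("n_films must be >= 1")
    rng = np.random.default_rng(seed)
    merged = _check_ranges(ranges or {})
    films, rows = [], []
    for i in range(n_films):
        params = {k: float(rng.uniform(*merged[k])) for k in merged}
        scene = CupScene(
            true_anteversion=params["anteversion"],
            true_inclination=params["inclination"],
            pelvic_pose=PelvicPose(theta=params["tilt"], phi=params["rotation"]),
            side=side,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
            **scene_kwargs,
        )
        film = project_scene(scene)
        films.append(film)
        rows.append(
            {
                "film_id": f"film_{i:04d}",
                "side": side,
                "true_anteversion": scene.true_anteversion,
                "true_inclination": scene.true_inclination,
                "theta": scene.pelvic_pose.theta,
                "phi": scene.pelvic_pose.phi,
                "noise_sigma": noise_sigma,
                "apparent_retroversion": film.apparent_retroversion,
            }
        )
    return films, pd.DataFrame(rows)


def generate_repeated_cohort(
    n_patients: int,
    films_per_patient: int,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    noise_sigma: float = 1.0,
    side: str = "right",
    **scene_kwargs,
) -> tuple[list[SyntheticFilm], pd.DataFrame]:
    """Repeated films per patient: fixed cup, fresh pose and noise per film.

    Emulates serial radiographs of a stable implant — each patient keeps one
    true (anteversion, inclination) but is positioned anew for every film.
    The truth table adds ``patient_id`` and ``measurement_index`` columns,
    ready for repeated-SD analysis.
    """
    if n_patients < 1 or films_per_patient < 1:
        raise ValueError("n_patients and films_per_patient must be >= 1")
    rng = np.random.default_rng(seed)
    merged = _check_ranges(ranges or {})
    films, rows = [], []
    for j in range(n_patients):
        av = float(rng.uniform(*merged["anteversion"]))
        incl = float(rng.uniform(*merged["inclination"]))
        for i in range(films_per_patient):
            scene = CupScene(
                true_anteversion=av,
                true_inclination=incl,
                pelvic_pose=PelvicPose(
                    theta=float(rng.uniform(*merged["tilt"])),
                    phi=float(rng.uniform(*merged["rotation"])),
                ),
                side=side,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
                **scene_kwargs,
            )
            film = project_scene(scene)
            films.append(film)
            rows.append(
                {
                    "film_id": f"p{j:03d}_f{i:02d}",
                    "patient_id": f"p{j:03d}",
                    "measurement_index": i,
                    "side": side,
                    "true_anteversion": av,
                    "true_inclination": incl,
                    "theta": scene.pelvic_pose.theta,
                    "phi": scene.pelvic_pose.phi,
                    "noise_sigma": noise_sigma,
                    "apparent_retroversion": film.apparent_retroversion,
                }
            )
    return films, pd.DataFrame(rows)
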