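"""Pelvic landmarks, patient-pose estimation, and standardized anteversion.

A planar anteversion read off a single AP film depends on how the patient
was positioned: pelvic tilt (rotation about the transverse, trans-teardrop
axis) and axial rotation (about the craniocaudal axis) change the projected
rim ellipse.  Three midline/paired landmarks let the pose be estimated and
removed:

* upper pole of the pubic symphysis (SP),
* center of the sacrococcygeal junction (SCJ),
* the bilateral teardrops, defining the trans-teardrop line.

The SP→SCJ segment has a calibrated 3D length ``ssd``.  Its projected
displacements ``h`` (along the trans-teardrop line, positive toward the
measured acetabulum) and ``v`` (perpendicular, superior positive) encode the
pose: ``v`` varies with tilt, ``h`` with axial rotation.  Given the pose,
the cup axis reconstructed from the planar anteversion ``u`` and
inclination ``w`` is rotated back into the standardized reference position
and the anteversion recomputed there — the standardized (Liaw's)
anteversion.

Conventions
-----------
All 3D work happens in the *measured-side frame*: e1 toward the measured
acetabulum along the transverse axis, e2 superior, e3 anterior (out of the
film toward the X-ray source).  Pelvic tilt ``theta`` is a rotation about
e1 applied first (positive tilts the superior direction anteriorly); axial
rotation ``phi`` about e2 is applied second.  Angles in degrees throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    DegenerateEllipseError,
    Ellipse2D,
    inclination as _inclination,
    radiographic_anteversion,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MissingLandmarkError",
    "InconsistentLandmarksError",
    "NoPoseSolutionError",
    "PelvicLandmarks",
    "PlanarMeasurement",
    "PelvicPose",
    "StandardizationConfig",
    "MeasurementRecord",
    "pelvic_axis",
    "trans_teardrop_line",
    "teardrop_frame",
    "displacements",
    "estimate_pelvic_pose",
    "standardized_anteversion",
    "measure_film",
    "rot_transverse",
    "rot_craniocaudal",
]


class MissingLandmarkError(ValueError):
    """A required landmark is absent from the annotation."""

    def __init__(self, landmark: str):
        self.landmark = landmark
        super().__init__(f"missing landmark: {landmark!r}")


class InconsistentLandmarksError(ValueError):
    """Landmark geometry contradicts the calibrated ssd (h^2+v^2 > ssd^2)."""


class NoPoseSolutionError(ValueError):
    """No pelvic pose reproduces the observed displacements."""


_LANDMARK_NAMES = ("symphysis", "scj", "teardrop_l", "teardrop_r")


@dataclass(frozen=True)
class PelvicLandmarks:
    """2D image coordinates (pixels, y down) of the four pelvic landmarks."""

    symphysis: tuple[float, float]
    scj: tuple[float, float]
    teardrop_l: tuple[float, float]
    teardrop_r: tuple[float, float]

    def __post_init__(self) -> None:
        for name in _LANDMARK_NAMES:
            value = getattr(self, name)
            if value is None:
                raise MissingLandmarkError(name)
            p = (float(value[0]), float(value[1]))
            if not all(math.isfinite(c) for c in p):
                raise MissingLandmarkError(name)
            object.__setattr__(self, name, p)
        if self.teardrop_l == self.teardrop_r:
            raise InconsistentLandmarksError(
                "teardrops coincide; trans-teardrop line undefined"
            )


@dataclass(frozen=True)
class PelvicPose:
    """Pelvic tilt ``theta`` and axial rotation ``phi`` in degrees.

    Both are rotations away from the standardized reference position,
    expressed in the measured-side frame; each must lie in (-90, 90).
    """

    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta", "phi"):
            val = float(getattr(self, name))
            if not -90.0 < val < 90.0:
                raise ValueError(f"{name} must be in (-90, 90) degrees, got {val}")
            object.__setattr__(self, name, val)

    @property
    def is_identity(self) -> bool:
        return self.theta == 0.0 and self.phi == 0.0


@dataclass(frozen=True)
class PlanarMeasurement:
    """Per-film planar quantities feeding the standardization.

    u, w in degrees; h, v, ssd share one length unit (pixels unless a
    calibrated spacing was applied).  ``side`` is the measured hip.
    """

    u: float
    w: float
    h: float
    v: float
    ssd: float
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not 0.0 <= self.u <= 90.0 or not 0.0 <= self.w <= 90.0:
            raise ValueError("u and w must lie in [0, 90] degrees")
        if self.h**2 + self.v**2 > self.ssd**2 * (1.0 + 1e-9):
            raise InconsistentLandmarksError(
                f"h^2 + v^2 = {self.h**2 + self.v**2:.3f} exceeds ssd^2 = "
                f"{self.ssd**2:.3f}; landmark geometry inconsistent with ssd"
            )


@dataclass(frozen=True)
class StandardizationConfig:
    """Configuration of the pose model.

    ssd : calibrated 3D symphysis-to-SCJ length (length units; default 100
        matches the synthetic landmark model).
    neutral_v : projected v in the standardized reference position (same
        units).  The reference pose is the one in which SCJ sits in the
        midsagittal plane (h = 0) at this height above the symphysis pole.
    tilt_branch : 'min' picks the tilt solution of smallest magnitude (small
        tilts are the common clinical case); 'alternate' picks the other one.
    units : unit label for h/v/ssd, bookkeeping only.
    """

    ssd: float = 100.0
    neutral_v: float = 30.0
    tilt_branch: str = "min"
    units: str = "px"

    def __post_init__(self) -> None:
        if self.ssd <= 0:
            raise ValueError("ssd must be positive")
        if abs(self.neutral_v) > self.ssd:
            raise ValueError("|neutral_v| cannot exceed ssd")
        if self.tilt_branch not in ("min", "alternate"):
            raise ValueError("tilt_branch must be 'min' or 'alternate'")


@dataclass(frozen=True)
class MeasurementRecord:
    """Full per-film measurement output with intermediates."""

    film_id: str
    side: str
    ellipse: Ellipse2D
    radiographic_anteversion: float
    inclination: float
    h: float
    v: float
    ssd: float
    pose: PelvicPose
    standardized_anteversion: float
    fit_residual_rms: float = float("nan")
    provenance: str = ""


# --- rotations -------------------------------------------------------------

def rot_transverse(theta_deg: float) -> np.ndarray:
    """Rotation about e1 (transverse axis) by ``theta`` degrees."""
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_craniocaudal(phi_deg: float) -> np.ndarray:
    """Rotation about e2 (craniocaudal axis) by ``phi`` degrees."""
    p = math.radians(phi_deg)
    c, s = math.cos(p), math.sin(p)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def pose_matrix(pose: PelvicPose) -> np.ndarray:
    """Reference-frame -> film-frame rotation: tilt first, then axial."""
    return rot_craniocaudal(pose.phi) @ rot_transverse(pose.theta)


# --- landmark geometry -----------------------------------------------------

def pelvic_axis(landmarks: PelvicLandmarks) -> np.ndarray:
    """Unit vector of the radiographic pelvic axis, SCJ toward SP."""
    d = np.subtract(landmarks.symphysis, landmarks.scj, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise InconsistentLandmarksError(
            "symphysis and sacrococcygeal junction coincide; pelvic axis undefined"
        )
    return d / n


def trans_teardrop_line(landmarks: PelvicLandmarks) -> tuple[np.ndarray, np.ndarray]:
    """Trans-teardrop line as (point, unit direction) through both teardrops."""
    p = np.asarray(landmarks.teardrop_l, dtype=float)
    d = np.subtract(landmarks.teardrop_r, landmarks.teardrop_l, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:  # unreachable through the constructor, kept for raw inputs
        raise InconsistentLandmarksError("teardrops coincide")
    return p, d / n


def teardrop_frame(landmarks: PelvicLandmarks, side: str) -> tuple[np.ndarray, np.ndarray]:
    """In-image basis (e1, e2) of the measured-side frame.

    e1 points along the trans-teardrop line from the contralateral teardrop
    toward the measured-side teardrop; e2 is its in-image perpendicular with
    the superior direction positive (image y grows downward, so e2 has
    negative y).
    """
    if side == "left":
        d = np.subtract(landmarks.teardrop_l, landmarks.teardrop_r, dtype=float)
    elif side == "right":
        d = np.subtract(landmarks.teardrop_r, landmarks.teardrop_l, dtype=float)
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    e1 = d / np.linalg.norm(d)
    e2 = np.array([-e1[1], e1[0]])
    if e2[1] > 0:  # superior must be positive
        e2 = -e2
    return e1, e2


def displacements(
    landmarks: PelvicLandmarks, side: str, pixel_spacing: float = 1.0
) -> tuple[float, float]:
    """Signed displacements (h, v) of the SCJ relative to the symphysis pole.

    h is measured along the trans-teardrop direction, positive when the SCJ
    lies between the symphysis pole and the measured acetabulum (flipping
    ``side`` flips h's sign); v is measured along the in-image perpendicular,
    positive when the SCJ is above (superior to) the symphysis pole.
    ``pixel_spacing`` converts pixels to physical units when known.
    """
    e1, e2 = teardrop_frame(landmarks, side)
    d = np.subtract(landmarks.scj, landmarks.symphysis, dtype=float)
    return float(np.dot(d, e1)) * pixel_spacing, float(np.dot(d, e2)) * pixel_spacing


# --- pose estimation -------------------------------------------------------

def estimate_pelvic_pose(
    h: float,
    v: float,
    ssd: float,
    neutral_v: float,
    tilt_branch: str = "min",
) -> PelvicPose:
    """Invert the projection of the SP→SCJ segment to a pelvic pose.

    In the reference position the 3D SP→SCJ vector is
    ``(0, neutral_v, -d)`` with depth ``d = sqrt(ssd^2 - neutral_v^2)``
    (the SCJ lies posterior to the symphysis).  After tilt ``theta`` and
    axial rotation ``phi`` its projection shows

        v = neutral_v*cos(theta) + d*sin(theta)
        h = sin(phi) * (neutral_v*sin(theta) - d*cos(theta))

    so ``theta`` follows from v alone and ``phi`` from h given theta.  Two
    tilt solutions exist; ``tilt_branch='min'`` keeps the one of smallest
    magnitude.
    """
    if ssd <= 0:
        raise ValueError("ssd must be positive")
    if h * h + v * v > ssd * ssd * (1.0 + 1e-9):
        raise InconsistentLandmarksError(
            f"h^2 + v^2 = {h*h + v*v:.3f} exceeds ssd^2 = {ssd*ssd:.3f}"
        )
    if abs(neutral_v) > ssd:
        raise ValueError("|neutral_v| cannot exceed ssd")
    depth = math.sqrt(max(0.0, ssd * ssd - neutral_v * neutral_v))
    delta = math.asin(neutral_v / ssd)
    s = math.asin(max(-1.0, min(1.0, v / ssd)))
    candidates = [s - delta, math.pi - s - delta]
    # wrap into (-pi, pi]
    candidates = [(t + math.pi) % (2.0 * math.pi) - math.pi for t in candidates]
    candidates.sort(key=abs)
    theta = candidates[0] if tilt_branch == "min" else candidates[1]
    if not -math.pi / 2 < theta < math.pi / 2:
        raise NoPoseSolutionError(
            f"no tilt solution in (-90, 90) degrees on branch {tilt_branch!r}"
        )
    q = neutral_v * math.sin(theta) - depth * math.cos(theta)
    if q == 0.0:
        if abs(h) > 1e-12:
            raise NoPoseSolutionError(
                "observed h nonzero but the SP-SCJ segment lies in the film plane"
            )
        phi = 0.0
    else:
        r = h / q
        if abs(r) > 1.0 + 1e-9:
            raise NoPoseSolutionError(
                f"|h| = {abs(h):.3f} exceeds the projected segment depth {abs(q):.3f}"
            )
        phi = math.asin(max(-1.0, min(1.0, r)))
    return PelvicPose(theta=math.degrees(theta), phi=math.degrees(phi))


# --- standardization -------------------------------------------------------

def _cup_axis_film(
    u_deg: float,
    w_deg: float,
    axis_direction: Optional[Sequence[float]] = None,
    apparent_retroversion: bool = False,
) -> np.ndarray:
    """Cup-opening axis unit vector in the film (measured-side) frame.

    The in-plane component is perpendicular to the rim's major axis and is
    taken to point toward the measured acetabulum (infero-lateral for the
    usual cup quadrant); the out-of-plane component is ``sin u`` anterior
    unless the cup appears retroverted on the film, in which case it points
    posterior.  ``axis_direction``, when given, is the measured major-axis
    direction as (e1, e2) components and overrides the w-based quadrant
    convention.
    """
    u = math.radians(u_deg)
    if axis_direction is None:
        w = math.radians(w_deg)
        p1, p2 = math.sin(w), -math.cos(w)
    else:
        m = np.asarray(axis_direction, dtype=float)
        n = np.linalg.norm(m)
        if n == 0:
            raise ValueError("axis_direction must be nonzero")
        m = m / n
        p1, p2 = m[1], -m[0]
        if p1 < 0 or (p1 == 0 and p2 > 0):
            p1, p2 = -p1, -p2
    z = math.sin(u) * (-1.0 if apparent_retroversion else 1.0)
    c = math.cos(u)
    return np.array([c * p1, c * p2, z])


def standardized_anteversion(
    pm: PlanarMeasurement,
    pose: PelvicPose,
    axis_direction: Optional[Sequence[float]] = None,
    apparent_retroversion: bool = False,
) -> float:
    """Anteversion re-expressed in the standardized pelvic position, degrees.

    Reconstructs the cup axis from the planar anteversion ``u`` and
    inclination ``w`` in film coordinates, removes the pelvic pose by the
    inverse rotation (axial rotation undone first, then tilt), and returns
    ``arcsin`` of the axis's anteroposterior component.  Equals ``pm.u``
    when the pose is the identity.
    """
    n_film = _cup_axis_film(pm.u, pm.w, axis_direction, apparent_retroversion)
    n_ref = rot_transverse(-pose.theta) @ (rot_craniocaudal(-pose.phi) @ n_film)
    comp = abs(float(n_ref[2]))
    if comp > 1.0 + 1e-9:
        raise ArithmeticError(f"axis component {comp} exceeds unit norm")
    return math.degrees(math.asin(min(1.0, comp)))


def measure_film(
    landmarks: PelvicLandmarks,
    ellipse: Ellipse2D,
    side: str,
    config: StandardizationConfig = StandardizationConfig(),
    film_id: str = "",
    apparent_retroversion: bool = False,
    fit_residual_rms: float = float("nan"),
    pixel_spacing: float = 1.0,
    provenance: str = "",
) -> MeasurementRecord:
    """End-to-end measurement of one annotated film.

    Computes the radiographic anteversion and inclination from the rim
    ellipse, the landmark displacements, the pelvic pose, and the
    standardized anteversion; all intermediates are kept in the record.
    """
    u = radiographic_anteversion(ellipse)
    _, tt_dir = trans_teardrop_line(landmarks)
    w = _inclination(ellipse, tt_dir)
    h, v = displacements(landmarks, side, pixel_spacing)
    pose = estimate_pelvic_pose(h, v, config.ssd, config.neutral_v, config.tilt_branch)
    pm = PlanarMeasurement(u=u, w=w, h=h, v=v, ssd=config.ssd, side=side)
    e1, e2 = teardrop_frame(landmarks, side)
    m_img = ellipse.major_axis_direction()
    axis_dir = (float(np.dot(m_img, e1)), float(np.dot(m_img, e2)))
    std = standardized_anteversion(pm, pose, axis_dir, apparent_retroversion)
    logger.debug(
        "film %s: u=%.3f w=%.3f h=%.3f v=%.3f theta=%.3f phi=%.3f std=%.3f",
        film_id, u, w, h, v, pose.theta, pose.phi, std,
    )
    return MeasurementRecord(
        film_id=film_id,
        side=side,
        ellipse=ellipse,
        radiographic_anteversion=u,
        inclination=w,
        h=h,
        v=v,
        ssd=config.ssd,
        pose=pose,
        standardized_anteversion=std,
        fit_residual_rms=fit_residual_rms,
        provenance=provenance,
    )
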