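"""Planar ellipse geometry and the two planar anteversion formulas.

The projected rim of a hemispherical acetabular cup on an anteroposterior
(AP) radiograph is an ellipse.  Two equivalent planar anteversion readings
are derived from it:

* **radiographic (McLaren) anteversion** ``arcsin(short axis / long axis)``;
* **Liaw's trigonometric anteversion** ``arcsin(tan βp)``, where βp is the
  angle at a major-axis endpoint between the major axis and the chord to the
  adjacent minor-axis endpoint, so ``tan βp = b/a``.

Both are reported in degrees.  Image coordinates follow the raster
convention: x grows rightward, y grows downward; ellipse orientation is the
angle of the major axis against the image x-axis, reduced to [0, 180).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateEllipseError",
    "Ellipse2D",
    "radiographic_anteversion",
    "beta_p",
    "liaw_anteversion",
    "render_ellipse_polygon",
    "inclination",
    "acute_angle_between",
]


class DegenerateEllipseError(ValueError):
    """Raised when an ellipse has zero major axis and an axis ratio is needed."""


@dataclass(frozen=True)
class Ellipse2D:
    """Geometric ellipse in image (pixel) coordinates.

    Parameters
    ----------
    center : (float, float)
        Ellipse center ``(cx, cy)`` in pixels.
    a : float
        Semi-major axis length, pixels. Must satisfy ``a >= b >= 0``;
        if called with ``b > a`` the constructor swaps the axes and rotates
        the orientation by 90 deg so the invariant holds.
    b : float
        Semi-minor axis length, pixels.
    orientation_deg : float
        Angle of the major axis against the image x-axis, degrees,
        normalized to [0, 180).
    """

    center: tuple[float, float] = (0.0, 0.0)
    a: float = 1.0
    b: float = 1.0
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        a, b, ori = float(self.a), float(self.b), float(self.orientation_deg)
        if a < 0 or b < 0:
            raise ValueError(f"semi-axes must be non-negative, got a={a}, b={b}")
        if b > a:
            a, b = b, a
            ori += 90.0
        ori %= 180.0
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "orientation_deg", ori)

    @property
    def axis_ratio(self) -> float:
        """Minor/major axis ratio ``b/a`` (equals short axis / long axis)."""
        if self.a == 0:
            raise DegenerateEllipseError("ellipse has zero major axis")
        return self.b / self.a

    def major_axis_direction(self) -> np.ndarray:
        """Unit vector along the major axis in image coordinates."""
        t = math.radians(self.orientation_deg)
        return np.array([math.cos(t), math.sin(t)])


def radiographic_anteversion(ellipse: Ellipse2D) -> float:
    """McLaren's radiographic anteversion, degrees in [0, 90].

    ``anteversion = arcsin(short axis / long axis)``; the full-axis ratio
    equals the semi-axis ratio ``b/a``.
    """
    return math.degrees(math.asin(ellipse.axis_ratio))


def beta_p(ellipse: Ellipse2D) -> float:
    """Angle βp, degrees in [0, 45].

    βp is the angle between the major axis and the segment joining a
    major-axis endpoint to the adjacent minor-axis endpoint, i.e.
    ``arctan(b/a)``.
    """
    return math.degrees(math.atan(ellipse.axis_ratio))


def liaw_anteversion(beta_p_deg: float) -> float:
    """Liaw's trigonometric anteversion ``arcsin(tan βp)``, degrees in [0, 90].

    Raises
    ------
    ValueError
        If ``beta_p_deg`` lies outside [0, 45]: tan βp would exceed 1,
        which means the measured minor axis was longer than the major axis.
    """
    if not 0.0 <= beta_p_deg <= 45.0:
        raise ValueError(
            f"beta_p must be in [0, 45] degrees, got {beta_p_deg!r} "
            "(minor axis longer than major axis?)"
        )
    if beta_p_deg == 45.0:  # tan 45 deg = 1 analytically; avoid rounding at the boundary
        return 90.0
    return math.degrees(math.asin(min(1.0, math.tan(math.radians(beta_p_deg)))))


def render_ellipse_polygon(ellipse: Ellipse2D, n_segments: int = 64) -> np.ndarray:
    """Render the ellipse as a closed ``n_segments``-sided polygon.

    Vertices are sampled at uniform parametric angle ``2*pi*k/n`` on the
    canonical ellipse, then rotated by the orientation and translated to the
    center; the closing segment joins the last vertex back to the first.
    The default of 64 segments matches the drawing scheme used clinically,
    where the rim overlay is a 64-sided polygon whose vertices come from the
    position and lengths of the long and short axes.

    Returns
    -------
    ndarray of shape (n_segments, 2)
        Ordered vertices (closed implicitly: vertex n-1 connects to vertex 0).
    """
    n = int(n_segments)
    if n < 3:
        raise ValueError(f"a polygon needs at least 3 segments, got {n}")
    tau = 2.0 * np.pi * np.arange(n) / n
    t = math.radians(ellipse.orientation_deg)
    c, s = math.cos(t), math.sin(t)
    x = ellipse.a * np.cos(tau)
    y = ellipse.b * np.sin(tau)
    return np.column_stack(
        [
            ellipse.center[0] + c * x - s * y,
            ellipse.center[1] + s * x + c * y,
        ]
    )


def acute_angle_between(d1: np.ndarray, d2: np.ndarray) -> float:
    """Acute angle in degrees, [0, 90], between two 2D directions."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot measure an angle against a zero vector")
    cosang = abs(float(np.dot(d1, d2)) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, cosang)))


def inclination(ellipse: Ellipse2D, line_direction: np.ndarray) -> float:
    """Cup inclination (abduction) angle, degrees in [0, 90].

    The acute angle between the ellipse major axis (the long axis of the
    cup's projected rim) and the pelvic horizontal, conventionally the
    trans-teardrop line.

    Parameters
    ----------
    ellipse : Ellipse2D
        Projected cup rim.
    line_direction : array-like, shape (2,)
        Direction vector of the trans-teardrop line in image coordinates.
    """
    if ellipse.a == 0:
        raise DegenerateEllipseError("ellipse has zero major axis")
    return acute_angle_between(ellipse.major_axis_direction(), line_direction)
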