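"""Direct least-squares ellipse fitting to annotated cup-rim points.

Clinically the rim ellipse is matched to the cup by eye; here it is
recovered reproducibly from >= 5 clicked rim points with the numerically
stable direct least-squares method of Halir & Flusser (1998), which
minimizes the algebraic distance subject to the ellipse constraint
``4AC - B^2 = 1``.  The constraint guarantees an ellipse (never a
hyperbola or parabola) even for noisy partial arcs, which matter because
the femoral head obscures part of the rim on most films.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import Ellipse2D

logger = logging.getLogger(__name__)

__all__ = ["ConicCoefficients", "EllipseFitError", "fit_ellipse", "conic_to_geometric"]

_MIN_POINTS = 5
_SPAN_WARN_DEG = 120.0


class EllipseFitError(ValueError):
    """Input points do not determine an ellipse."""


@dataclass(frozen=True)
class ConicCoefficients:
    """Conic ``A x^2 + B x y + C y^2 + D x + E y + F = 0``.

    Coefficients are defined up to scale; the constructor normalizes so
    that ``A + C = 1`` whenever ``A + C != 0``.  An ellipse requires the
    discriminant ``B^2 - 4AC < 0``.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def __post_init__(self) -> None:
        trace = self.A + self.C
        if trace != 0.0:
            for name in "ABCDEF":
                object.__setattr__(self, name, float(getattr(self, name)) / trace)

    @property
    def discriminant(self) -> float:
        return self.B**2 - 4.0 * self.A * self.C

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Algebraic residual of the conic at (x, y)."""
        return (
            self.A * x**2 + self.B * x * y + self.C * y**2
            + self.D * x + self.E * y + self.F
        )


def _halir_flusser(x: np.ndarray, y: np.ndarray) -> ConicCoefficients:
    # Partitioned design matrices: quadratic and linear parts.
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate point configuration") from exc
    m = s1 + s2 @ t
    # Premultiply by inv(C1) for the constraint 4AC - B^2 = 1.
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    eigval, eigvec = np.real(eigval), np.real(eigvec)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.where((cond > 0) & np.isfinite(eigval))[0]
    if good.size == 0:
        raise EllipseFitError("no ellipse satisfies the constraint for these points")
    a1 = eigvec[:, good[0]]
    a2 = t @ a1
    return ConicCoefficients(a1[0], a1[1], a1[2], a2[0], a2[1], a2[2])


def _angular_span_deg(x: np.ndarray, y: np.ndarray, e: Ellipse2D) -> float:
    """Arc span of the points as seen from the fitted ellipse center."""
    ang = np.sort(np.mod(np.degrees(np.arctan2(y - e.center[1], x - e.center[0])), 360.0))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
    return 360.0 - float(gaps.max())


def fit_ellipse(points: np.ndarray) -> tuple[Ellipse2D, float]:
    """Fit an ellipse to >= 5 rim points.

    Points are centered and scaled before fitting for numerical
    conditioning, and the conic is mapped back afterwards.  A warning is
    logged when the points span less than 120 degrees of arc around the
    fitted center, where fit variance grows sharply.

    Returns
    -------
    (Ellipse2D, float)
        The fitted ellipse and the RMS algebraic-distance residual
        (approximate orthogonal distance, pixels).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EllipseFitError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if pts.shape[0] < _MIN_POINTS:
        raise EllipseFitError(
            f"need at least {_MIN_POINTS} points to fit an ellipse, got {pts.shape[0]}"
        )
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-10) < 2:
        raise EllipseFitError("points are collinear")
    mean = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale == 0:
        raise EllipseFitError("points are coincident")
    xs = (pts[:, 0] - mean[0]) / scale
    ys = (pts[:, 1] - mean[1]) / scale
    conic_n = _halir_flusser(xs, ys)
    # Undo the normalization x = (X - mx)/s, y = (Y - my)/s.
    A, B, C, D, E, F = (getattr(conic_n, k) for k in "ABCDEF")
    mx, my, s = mean[0], mean[1], scale
    conic = ConicCoefficients(
        A,
        B,
        C,
        s * D - 2 * A * mx - B * my,
        s * E - 2 * C * my - B * mx,
        A * mx**2 + B * mx * my + C * my**2 - s * D * mx - s * E * my + s * s * F,
    )
    ellipse = conic_to_geometric(conic)
    residual = _rms_distance(pts, ellipse)
    span = _angular_span_deg(pts[:, 0], pts[:, 1], ellipse)
    if span < _SPAN_WARN_DEG:
        logger.warning(
            "rim points span only %.0f degrees of arc; fit variance grows sharply "
            "below %.0f degrees", span, _SPAN_WARN_DEG,
        )
    return ellipse, residual


def conic_to_geometric(conic: ConicCoefficients) -> Ellipse2D:
    """Convert conic coefficients to geometric ellipse parameters.

    Center from the stationary point of the quadratic form; semi-axes and
    orientation from the eigen-decomposition of ``[[A, B/2], [B/2, C]]``.
    """
    if conic.discriminant >= 0:
        raise EllipseFitError(
            f"conic is not an ellipse (discriminant {conic.discriminant:.3g} >= 0)"
        )
    A, B, C, D, E, F = (getattr(conic, k) for k in "ABCDEF")
    q = np.array([[A, B / 2.0], [B / 2.0, C]])
    center = np.linalg.solve(2.0 * q, [-D, -E])
    # Constant term of the conic translated to its center.
    f0 = F + (D * center[0] + E * center[1]) / 2.0
    eigval, eigvec = np.linalg.eigh(q)
    with np.errstate(invalid="ignore"):
        axes_sq = -f0 / eigval
    if np.any(axes_sq <= 0):
        raise EllipseFitError("conic has no real ellipse points")
    axes = np.sqrt(axes_sq)
    # eigh sorts ascending, so the major axis pairs with the first eigenvector.
    order = np.argsort(axes)[::-1]
    a, b = float(axes[order[0]]), float(axes[order[1]])
    major_vec = eigvec[:, order[0]]
    ori = math.degrees(math.atan2(major_vec[1], major_vec[0])) % 180.0
    return Ellipse2D(center=(float(center[0]), float(center[1])), a=a, b=b,
                     orientation_deg=ori)


def _rms_distance(pts: np.ndarray, e: Ellipse2D) -> float:
    """RMS of approximate point-to-ellipse distances (radial, pixels)."""
    t = math.radians(e.orientation_deg)
    c, s = math.cos(t), math.sin(t)
    dx = pts[:, 0] - e.center[0]
    dy = pts[:, 1] - e.center[1]
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    r = np.hypot(xr, yr)
    ang = np.arctan2(yr, xr)
    # radius of the ellipse along each point's direction
    denom = np.hypot(e.b * np.cos(ang), e.a * np.sin(ang))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_e = np.where(denom > 0, e.a * e.b / denom, 0.0)
    return float(np.sqrt(np.mean((r - r_e) ** 2)))
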