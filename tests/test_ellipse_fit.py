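"""Direct least-squares ellipse fit and conic conversion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cupversion import (
    ConicCoefficients,
    Ellipse2D,
    EllipseFitError,
    conic_to_geometric,
    fit_ellipse,
    render_ellipse_polygon,
)


def _assert_ellipse_close(e1: Ellipse2D, e2: Ellipse2D, rtol=1e-6, atol_center=None):
    atol_center = atol_center if atol_center is not None else rtol * max(e2.a, 1.0)
    assert e1.center[0] == pytest.approx(e2.center[0], abs=atol_center)
    assert e1.center[1] == pytest.approx(e2.center[1], abs=atol_center)
    assert e1.a == pytest.approx(e2.a, rel=rtol)
    assert e1.b == pytest.approx(e2.b, rel=rtol)
    if e2.b < e2.a:  # orientation undefined for circles
        diff = abs(e1.orientation_deg - e2.orientation_deg) % 180.0
        assert min(diff, 180.0 - diff) < max(rtol * 180.0, 1e-4)


class TestConicToGeometric:
    def test_unit_circle(self):
        e = conic_to_geometric(ConicCoefficients(1, 0, 1, 0, 0, -1))
        assert e.center == pytest.approx((0.0, 0.0))
        assert e.a == pytest.approx(1.0) and e.b == pytest.approx(1.0)

    def test_axis_aligned(self):
        e = conic_to_geometric(ConicCoefficients(0.25, 0, 1, 0, 0, -1))
        assert e.a == pytest.approx(2.0)
        assert e.b == pytest.approx(1.0)
        assert e.orientation_deg == pytest.approx(0.0)

    def test_hyperbola_rejected(self):
        with pytest.raises(EllipseFitError):
            conic_to_geometric(ConicCoefficients(1, 0, -1, 0, 0, -1))


class TestFitEllipse:
    def test_exact_recovery(self):
        truth = Ellipse2D(center=(200, 150), a=100, b=50, orientation_deg=30)
        fitted, residual = fit_ellipse(render_ellipse_polygon(truth, 64))
        _assert_ellipse_close(fitted, truth, rtol=1e-6)
        assert residual < 1e-6

    def test_too_few_points(self):
        pts = render_ellipse_polygon(Ellipse2D(a=10, b=5), 64)[:4]
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)

    def test_collinear_points(self):
        pts = np.column_stack([np.linspace(0, 10, 8), np.linspace(0, 5, 8)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)

    def test_noisy_recovery_within_2_percent(self, rng):
        truth = Ellipse2D(center=(200, 150), a=100, b=50, orientation_deg=30)
        pts = render_ellipse_polygon(truth, 64) + rng.normal(0, 1.0, (64, 2))
        fitted, _ = fit_ellipse(pts)
        assert fitted.a == pytest.approx(truth.a, rel=0.02)
        assert fitted.b == pytest.approx(truth.b, rel=0.02)
        assert fitted.center[0] == pytest.approx(truth.center[0], abs=2.0)
        assert fitted.center[1] == pytest.approx(truth.center[1], abs=2.0)

    def test_bias_shrinks_with_noise(self, rng):
        """Semi-axis bias goes to zero as the click noise vanishes."""
        truth = Ellipse2D(center=(0, 0), a=100, b=60, orientation_deg=10)
        base = render_ellipse_polygon(truth, 64)
        biases = []
        for sigma in (1.0, 0.1, 0.01):
            err = []
            for _ in range(30):
                fitted, _ = fit_ellipse(base + rng.normal(0, sigma, base.shape))
                err.append(abs(fitted.a - truth.a) + abs(fitted.b - truth.b))
            biases.append(np.mean(err))
        assert biases[2] < biases[1] < biases[0]
        assert biases[2] < 0.01

    def test_partial_arc_still_an_ellipse(self):
        """Points over a 150-degree arc (femoral-head occlusion) fit fine."""
        truth = Ellipse2D(center=(50, 80), a=40, b=25, orientation_deg=50)
        tau = np.radians(np.linspace(0, 150, 40))
        import math

        t = math.radians(truth.orientation_deg)
        c, s = math.cos(t), math.sin(t)
        x = truth.a * np.cos(tau)
        y = truth.b * np.sin(tau)
        pts = np.column_stack(
            [truth.center[0] + c * x - s * y, truth.center[1] + s * x + c * y]
        )
        fitted, _ = fit_ellipse(pts)
        _assert_ellipse_close(fitted, truth, rtol=1e-5)

    @given(
        cx=st.floats(-500, 500),
        cy=st.floats(-500, 500),
        a=st.floats(10, 200),
        ratio=st.floats(0.2, 0.95),
        ori=st.floats(0, 179),
    )
    def test_fit_render_round_trip(self, cx, cy, a, ratio, ori):
        truth = Ellipse2D(center=(cx, cy), a=a, b=a * ratio, orientation_deg=ori)
        fitted, _ = fit_ellipse(render_ellipse_polygon(truth, 64))
        _assert_ellipse_close(fitted, truth, rtol=1e-6)

    def test_translation_rotation_equivariance(self):
        truth = Ellipse2D(center=(0, 0), a=30, b=12, orientation_deg=20)
        pts = render_ellipse_polygon(truth, 64)
        shift = np.array([123.0, -45.0])
        ang = np.radians(33.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        fitted, _ = fit_ellipse(pts @ rot.T + shift)
        expected_center = rot @ np.array(truth.center) + shift
        assert fitted.center[0] == pytest.approx(expected_center[0], abs=1e-9)
        assert fitted.center[1] == pytest.approx(expected_center[1], abs=1e-9)
        assert fitted.a == pytest.approx(truth.a, rel=1e-9)
        assert fitted.b == pytest.approx(truth.b, rel=1e-9)
        assert fitted.orientation_deg == pytest.approx(
            (truth.orientation_deg + 33.0) % 180.0, abs=1e-6
        )


def test_against_independent_fitter(rng):
    """Cross-check the direct fit against scikit-image's EllipseModel."""
    skimage = pytest.importorskip("skimage.measure")
    truth = Ellipse2D(center=(120, 90), a=70, b=40, orientation_deg=25)
    pts = render_ellipse_polygon(truth, 64) + rng.normal(0, 0.5, (64, 2))
    ours, _ = fit_ellipse(pts)
    model = skimage.EllipseModel.from_estimate(pts)
    assert model
    xc, yc = model.center
    sa, sb = model.axis_lengths
    ref_a, ref_b = max(sa, sb), min(sa, sb)
    assert ours.center[0] == pytest.approx(xc, abs=0.5)
    assert ours.center[1] == pytest.approx(yc, abs=0.5)
    assert ours.a == pytest.approx(ref_a, rel=0.01)
    assert ours.b == pytest.approx(ref_b, rel=0.01)
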