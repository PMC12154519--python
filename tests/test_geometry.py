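"""Camera geometry: projection, FOV, aperture ray tracing, analytic oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pinholesim import materials
from pinholesim.geometry import (
    CameraConfig,
    DetectorSpec,
    PinholeSpec,
    ShieldSpec,
    active_fov,
    analytic_point_sensitivity,
    aperture_path_length,
    default_camera,
    effective_diameter,
    minification_factor,
    project_through_pinhole,
)


class TestMinification:
    @pytest.mark.parametrize(
        "b_obj,b_det,expected", [(100, 20, 5.0), (125, 20, 6.25), (20, 20, 1.0)]
    )
    def test_ratio(self, b_obj, b_det, expected):
        assert minification_factor(b_obj, b_det) == pytest.approx(expected)

    def test_camera_overload(self):
        assert minification_factor(default_camera()) == pytest.approx(5.0)

    def test_invalid_distances(self):
        with pytest.raises(ValueError):
            minification_factor(0.0, 20.0)
        with pytest.raises(ValueError):
            CameraConfig(pinhole_to_detector_mm=-1.0)


class TestActiveFov:
    def test_default_nominal_fov_is_250mm(self):
        fov = active_fov(default_camera())
        assert fov.nominal_side_mm == pytest.approx(250.0)
        assert fov.detector_side_mm == pytest.approx(250.0)

    def test_fov_over_detector_side_equals_minification(self):
        cam = default_camera()
        fov = active_fov(cam)
        assert fov.detector_side_mm / cam.detector.active_side_mm == pytest.approx(
            minification_factor(cam)
        )

    def test_unity_minification(self):
        cam = CameraConfig(object_to_pinhole_mm=20.0)
        assert active_fov(cam).detector_side_mm == pytest.approx(50.0)

    def test_narrow_cone_limits_fov(self):
        # trigonometric oracle: 2 * 100 * tan(10 deg)
        cam = CameraConfig(pinhole=PinholeSpec(acceptance_angle_deg=20.0))
        fov = active_fov(cam)
        assert fov.limited_by == "acceptance_cone"
        assert fov.side_mm == pytest.approx(2 * 100 * np.tan(np.radians(10.0)))


class TestProjection:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0, 0, 100), (0, 0)),
            ((20, 0, 100), (-4, 0)),
            ((125, 0, 100), (-25, 0)),  # exactly the detector edge: 250 mm FOV
        ],
    )
    def test_examples(self, point, expected):
        uv = project_through_pinhole(np.array(point, dtype=float), default_camera())
        assert uv == pytest.approx(expected)

    def test_behind_pinhole_rejected(self):
        with pytest.raises(ValueError):
            project_through_pinhole([0.0, 0.0, -1.0], default_camera())

    @given(
        x1=st.floats(-100, 100), y1=st.floats(-100, 100),
        x2=st.floats(-100, 100), y2=st.floats(-100, 100),
        a=st.floats(-2, 2), z=st.floats(20, 400),
    )
    def test_linear_in_xy_and_magnification_recovered(self, x1, y1, x2, y2, a, z):
        """Projection is linear at fixed z; any point pair recovers b_det/z."""
        cam = default_camera()
        p1 = np.array([x1, y1, z])
        p2 = np.array([x2, y2, z])
        u1 = project_through_pinhole(p1, cam)
        u2 = project_through_pinhole(p2, cam)
        combo = project_through_pinhole(p1 + a * (p2 - p1), cam)
        assert combo == pytest.approx(u1 + a * (u2 - u1), abs=1e-9)
        delta = np.linalg.norm(p2[:2] - p1[:2])
        if delta > 1e-6:
            mag = np.linalg.norm(u2 - u1) / delta
            assert mag == pytest.approx(cam.pinhole_to_detector_mm / z, rel=1e-9)


def _raymarch_path(origin, direction, pinhole, shield, step=1e-3):
    """Independent brute-force oracle: 1 um marching through the aperture solid."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    T = max(shield.thickness_mm, pinhole.effective_channel_mm)
    hc = pinhole.effective_channel_mm / 2.0
    r0 = pinhole.diameter_mm / 2.0
    slope = np.tan(np.radians(pinhole.acceptance_angle_deg / 2.0))
    t = np.arange(0.0, 300.0, step)
    p = o[None, :] + t[:, None] * d[None, :]
    z = p[:, 2]
    rho = np.hypot(p[:, 0], p[:, 1])
    opening = r0 + np.clip(np.abs(z) - hc, 0.0, None) * slope
    return float(np.sum((np.abs(z) <= T / 2.0) & (rho > opening)) * step)


class TestAperturePathLength:
    def test_on_axis_ray_is_clear(self):
        ph, sh = PinholeSpec(), ShieldSpec()
        assert aperture_path_length([0, 0, 100], [0, 0, -1], ph, sh)[0] == 0.0

    def test_flat_shield_normal_incidence(self):
        ph, sh = PinholeSpec(), ShieldSpec()
        path = aperture_path_length([30.0, 0, 100], [0, 0, -1], ph, sh)[0]
        assert path == pytest.approx(sh.thickness_mm)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_raymarch_oracle(self, seed):
        ph, sh = PinholeSpec(), ShieldSpec()
        rng = np.random.default_rng(seed)
        for _ in range(15):
            o = np.array([rng.uniform(-8, 8), rng.uniform(-8, 8), 100.0])
            tgt = np.array([rng.uniform(-6, 6), rng.uniform(-6, 6), -20.0])
            d = tgt - o
            d /= np.linalg.norm(d)
            ana = aperture_path_length(o, d, ph, sh)[0]
            assert ana == pytest.approx(_raymarch_path(o, d, ph, sh), abs=2e-3)

    def test_grazing_ray_small_positive(self):
        ph, sh = PinholeSpec(), ShieldSpec()
        # just outside the channel wall, nearly axial
        o = np.array([0.65, 0.0, 100.0])
        d = np.array([0.0, 0.0, -1.0])
        path = aperture_path_length(o, d, ph, sh)[0]
        assert 0 < path < sh.thickness_mm
        assert path == pytest.approx(_raymarch_path(o, d, ph, sh), abs=2e-3)

    def test_rotational_symmetry(self):
        ph, sh = PinholeSpec(), ShieldSpec()
        o = np.array([3.0, 0.0, 100.0])
        d = np.array([-0.03, 0.004, -1.0])
        d /= np.linalg.norm(d)
        base = aperture_path_length(o, d, ph, sh)[0]
        for ang in np.linspace(0.3, 5.8, 7):
            c, s = np.cos(ang), np.sin(ang)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            rotated = aperture_path_length(R @ o, R @ d, ph, sh)[0]
            assert rotated == pytest.approx(base, abs=1e-9)

    def test_knife_edge_thinner_than_channel(self):
        sh = ShieldSpec()
        o = np.array([0.7, 0.0, 100.0])
        d = np.array([0.0, 0.0, -1.0])
        knife = aperture_path_length(o, d, PinholeSpec(edge_profile="knife_edge"), sh)[0]
        channel = aperture_path_length(o, d, PinholeSpec(), sh)[0]
        assert knife < channel


class TestEffectiveDiameter:
    def test_opaque_limit_recovers_bare_diameter(self):
        assert effective_diameter(PinholeSpec(), 1e9) == pytest.approx(1.2, abs=1e-6)

    def test_closed_aperture_limit(self):
        ph = PinholeSpec(acceptance_angle_deg=1e-6)
        mu = materials.linear_attenuation_mm("tungsten", 113.0)
        assert effective_diameter(ph, mu) == pytest.approx(1.2, abs=1e-6)

    def test_penetration_enlarges_and_is_monotone_in_energy(self):
        ph = PinholeSpec()
        mu113 = materials.linear_attenuation_mm("tungsten", 112.95)
        mu208 = materials.linear_attenuation_mm("tungsten", 208.37)
        d113 = effective_diameter(ph, mu113)
        d208 = effective_diameter(ph, mu208)
        assert d113 > 1.2
        assert d208 > d113  # less attenuation -> wider effective aperture


class TestAnalyticSensitivity:
    def test_on_axis_value(self):
        g = analytic_point_sensitivity(default_camera(), [0, 0, 100], d_eff_mm=1.2)
        assert g == pytest.approx(1.44 / 160000)

    def test_inverse_square_ratio(self):
        cam = default_camera()
        g100 = analytic_point_sensitivity(cam, [0, 0, 100])
        g125 = analytic_point_sensitivity(cam, [0, 0, 125])
        assert g125 / g100 == pytest.approx(0.64)

    def test_on_axis_has_unit_obliquity(self):
        cam = default_camera()
        g_axis = analytic_point_sensitivity(cam, [0, 0, 100])
        g_off = analytic_point_sensitivity(cam, [50, 0, 100])
        cos3 = (100 / np.hypot(50, 100)) ** 3
        assert g_off / g_axis == pytest.approx(cos3)

    def test_behind_plane_rejected(self):
        with pytest.raises(ValueError):
            analytic_point_sensitivity(default_camera(), [0, 0, -5])


class TestDetectorGrid:
    def test_pixel_grid_fits_active_side(self):
        det = DetectorSpec()
        assert det.n_pixels == 41
        assert det.sensitive_span_mm == pytest.approx(49.0)
        with pytest.raises(ValueError):
            DetectorSpec(n_pixels=42)

    def test_locate_center_and_septa(self):
        det = DetectorSpec()
        i, j, hit = det.locate(0.0, 0.0)
        assert hit and i == 20 and j == 20
        # mid-septum between pixels 20 and 21
        _, _, hit_septum = det.locate(0.6, 0.0)
        assert not hit_septum
        _, _, hit_outside = det.locate(25.0, 0.0)
        assert not hit_outside
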