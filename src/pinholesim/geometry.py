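"""Physical camera description and exact pinhole-geometry operations.

Coordinate convention (fixed for bit-reproducibility): the pinhole centre is
the origin, the pinhole axis is z, the object sits at z > 0 and the detector
plane at z = -b_det.  A point (x, y, z) projects through the aperture centre
to (u, v) = (-x*b_det/z, -y*b_det/z): the image is inverted and minified by
b_obj/b_det (1:5 for the default 100 mm / 20 mm configuration).

The aperture is a solid of revolution in the tungsten front plate: a
cylindrical channel of the pinhole diameter and channel height (1 mm
default), flanked by two cones opening at the acceptance angle until they
reach the plate faces; a knife-edge profile is the channel-height -> 0
limit.  ``aperture_path_length`` returns the exact tungsten thickness a
ray traverses in this solid, which drives edge penetration and shield leakage
in the Monte Carlo engine; the closed-form ``analytic_point_sensitivity``
(d_eff^2 cos^3(theta) / 16 h^2) is the independent oracle the engine is tested
against.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

__all__ = [
    "PinholeSpec",
    "DetectorSpec",
    "ShieldSpec",
    "CameraConfig",
    "FovResult",
    "default_camera",
    "minification_factor",
    "active_fov",
    "project_through_pinhole",
    "aperture_path_length",
    "effective_diameter",
    "analytic_point_sensitivity",
    "camera_hash",
]


@dataclass(frozen=True)
class PinholeSpec:
    """Pinhole aperture: 1.2 mm diameter, 94 degree acceptance angle.

    ``channel_height_mm`` defaults to 1 mm.  A channel as long as the full
    5 mm plate would collimate the bore to atan(d/h) ~ 13.5 degrees and shrink
    the usable field to ~48 mm, which is inconsistent with this camera's
    250 mm field of view and its wide-angle acceptance cones; see the methods
    note.  ``edge_profile='knife_edge'`` forces a zero-height channel.
    """

    diameter_mm: float = 1.2
    acceptance_angle_deg: float = 94.0
    channel_height_mm: float = 1.0
    edge_profile: Literal["channel_edge", "knife_edge"] = "channel_edge"

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("pinhole diameter must be positive")
        if not (0.0 < self.acceptance_angle_deg < 180.0):
            raise ValueError("acceptance angle must be in (0, 180) degrees")
        if self.channel_height_mm < 0:
            raise ValueError("channel height must be >= 0")
        if self.edge_profile not in ("channel_edge", "knife_edge"):
            raise ValueError(f"unknown edge profile {self.edge_profile!r}")

    @property
    def effective_channel_mm(self) -> float:
        return 0.0 if self.edge_profile == "knife_edge" else self.channel_height_mm


@dataclass(frozen=True)
class DetectorSpec:
    """Pixelated scintillator: 41 x 41 crystals of 1 x 1 x 5 mm, 0.2 mm septa.

    Crystals are laid out on a grid of cells of size ``pitch = crystal + septa``
    with each crystal centred in its cell, so pixel centres sit at
    (i + 0.5) * pitch from the detector corner; the sensitive span is
    n*pitch - septa = 49.0 mm inside the 50 mm active side.
    """

    active_side_mm: float = 50.0
    crystal_size_mm: float = 1.0
    septa_mm: float = 0.2
    crystal_thickness_mm: float = 5.0
    n_pixels: int = 41
    optical_guide_mm: float = 1.0
    material: str = "gagg"

    def __post_init__(self):
        if min(self.active_side_mm, self.crystal_size_mm, self.crystal_thickness_mm) <= 0:
            raise ValueError("detector dimensions must be positive")
        if self.septa_mm < 0 or self.n_pixels < 1:
            raise ValueError("invalid septa width or pixel count")
        if self.n_pixels * self.pitch_mm - self.septa_mm > self.active_side_mm + 1e-9:
            raise ValueError("pixel grid does not fit the active side")

    @property
    def pitch_mm(self) -> float:
        return self.crystal_size_mm + self.septa_mm

    @property
    def sensitive_span_mm(self) -> float:
        """Outer crystal-edge to outer crystal-edge distance (49.0 mm default)."""
        return self.n_pixels * self.pitch_mm - self.septa_mm

    def pixel_centers(self) -> np.ndarray:
        """1-D pixel-centre coordinates (mm), centred on the detector axis."""
        half = self.n_pixels * self.pitch_mm / 2.0
        return (np.arange(self.n_pixels) + 0.5) * self.pitch_mm - half

    def locate(self, u, v):
        """Map detector-plane coordinates to pixel indices.

        Returns ``(i, j, hit)`` where ``hit`` is False for positions on septa
        or outside the crystal grid.  ``i`` indexes v (rows), ``j`` indexes u
        (columns), both 0-based from the negative-coordinate corner.
        """
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        half = self.n_pixels * self.pitch_mm / 2.0
        s_u, s_v = u + half, v + half
        j = np.floor(s_u / self.pitch_mm).astype(np.int64)
        i = np.floor(s_v / self.pitch_mm).astype(np.int64)
        fu = s_u - j * self.pitch_mm
        fv = s_v - i * self.pitch_mm
        lo, hi = self.septa_mm / 2.0, self.pitch_mm - self.septa_mm / 2.0
        hit = (
            (i >= 0) & (i < self.n_pixels) & (j >= 0) & (j < self.n_pixels)
            & (fu >= lo) & (fu < hi) & (fv >= lo) & (fv < hi)
        )
        return i, j, hit


@dataclass(frozen=True)
class ShieldSpec:
    """Tungsten housing: 5 mm walls, 70 x 70 x 100 mm outer box."""

    thickness_mm: float = 5.0
    outer_mm: tuple[float, float, float] = (70.0, 70.0, 100.0)

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValueError("shield thickness must be positive")


@dataclass(frozen=True)
class CameraConfig:
    pinhole: PinholeSpec = field(default_factory=PinholeSpec)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    shield: ShieldSpec = field(default_factory=ShieldSpec)
    pinhole_to_detector_mm: float = 20.0
    object_to_pinhole_mm: float = 100.0

    def __post_init__(self):
        if self.pinhole_to_detector_mm <= 0 or self.object_to_pinhole_mm <= 0:
            raise ValueError("distances must be positive")

    @property
    def plate_thickness_mm(self) -> float:
        """Thickness of the aperture plate the ray-tracer uses."""
        return max(self.shield.thickness_mm, self.pinhole.effective_channel_mm)


def default_camera() -> CameraConfig:
    return CameraConfig()


def camera_hash(camera: CameraConfig) -> str:
    """Short stable digest of the full camera description."""
    payload = json.dumps(asdict(camera), sort_keys=True, default=float)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def minification_factor(camera_or_b_obj, b_det: float | None = None) -> float:
    """Object-to-image minification ratio b_obj / b_det (5 for the default)."""
    if isinstance(camera_or_b_obj, CameraConfig):
        b_obj = camera_or_b_obj.object_to_pinhole_mm
        b_det = camera_or_b_obj.pinhole_to_detector_mm
    else:
        b_obj = camera_or_b_obj
    if b_obj is None or b_det is None or b_obj <= 0 or b_det <= 0:
        raise ValueError("both distances must be positive")
    return b_obj / b_det


@dataclass(frozen=True)
class FovResult:
    side_mm: float
    limited_by: Literal["detector", "acceptance_cone"]
    detector_side_mm: float
    cone_side_mm: float

    @property
    def nominal_side_mm(self) -> float:
        """The conventional 'active FOV': detector side times minification.

        For this camera class the quoted field of view is the detector-limited
        one (250 mm for the default configuration); a hard acceptance-angle
        cut narrower than that only vignettes the field softly, because rays
        slightly outside the cone still penetrate the thin aperture edge.
        """
        return self.detector_side_mm


def active_fov(camera: CameraConfig) -> FovResult:
    """Side of the square field of view at the object plane.

    The detector side scaled by the minification, additionally truncated by
    the acceptance-angle cone 2 * b_obj * tan(a/2) when the cone is narrower;
    the binding constraint is reported, and both candidate sides are exposed.
    """
    m = minification_factor(camera)
    det_side = camera.detector.active_side_mm * m
    half_angle = np.radians(camera.pinhole.acceptance_angle_deg / 2.0)
    cone_side = 2.0 * camera.object_to_pinhole_mm * np.tan(half_angle)
    if cone_side < det_side:
        return FovResult(float(cone_side), "acceptance_cone", float(det_side), float(cone_side))
    return FovResult(float(det_side), "detector", float(det_side), float(cone_side))


def project_through_pinhole(points, camera: CameraConfig) -> np.ndarray:
    """Ideal pinhole projection of object points to the detector plane.

    ``points`` is (..., 3) in object space with z the distance from the
    pinhole plane; returns (..., 2) detector coordinates
    (u, v) = (-x, -y) * b_det / z.  Rays invert through the aperture centre.
    """
    p = np.asarray(points, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("points must have a trailing dimension of 3")
    z = p[..., 2]
    if np.any(z <= 0):
        raise ValueError("points must lie in front of the pinhole (z > 0)")
    scale = camera.pinhole_to_detector_mm / z
    return np.stack([-p[..., 0] * scale, -p[..., 1] * scale], axis=-1)


def _measure_neg(a, b, c, lo: float, hi: float) -> np.ndarray:
    """Length of {z in [lo, hi] : a z^2 + b z + c <= 0}, elementwise.

    Used piecewise to find where a ray runs inside the aperture opening.
    """
    a = np.asarray(a, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), a.shape)
    c = np.broadcast_to(np.asarray(c, dtype=float), a.shape)
    span = hi - lo
    out = np.zeros(a.shape)
    if span <= 0:
        return out
    tiny = 1e-14

    lin = np.abs(a) < tiny
    const = lin & (np.abs(b) < tiny)
    # constant case
    out = np.where(const & (c <= 0), span, out)
    # linear case: b z + c <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        zstar = -c / np.where(np.abs(b) < tiny, np.nan, b)
    lpos = lin & ~const & (b > 0)  # z <= zstar
    lneg = lin & ~const & (b < 0)  # z >= zstar
    out = np.where(lpos, np.clip(np.minimum(hi, zstar) - lo, 0, span), out)
    out = np.where(lneg, np.clip(hi - np.maximum(lo, zstar), 0, span), out)

    quad = ~lin
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = b * b - 4.0 * a * c
        sq = np.sqrt(np.clip(disc, 0.0, None))
        r1 = (-b - sq) / (2.0 * a)
        r2 = (-b + sq) / (2.0 * a)
    rlo, rhi = np.minimum(r1, r2), np.maximum(r1, r2)
    # opening upward: inside between the roots
    up = quad & (a > 0) & (disc > 0)
    out = np.where(up, np.clip(np.minimum(hi, rhi) - np.maximum(lo, rlo), 0, span), out)
    # opening downward: inside outside the roots (or everywhere if no roots)
    dn = quad & (a < 0)
    dn_none = dn & (disc <= 0)
    out = np.where(dn_none, span, out)
    dn_roots = dn & (disc > 0)
    left = np.clip(np.minimum(hi, rlo) - lo, 0, span)
    right = np.clip(hi - np.maximum(lo, rhi), 0, span)
    out = np.where(dn_roots, np.minimum(left + right, span), out)
    return out


def aperture_path_length(
    origins, directions, pinhole: PinholeSpec, shield: ShieldSpec
) -> np.ndarray:
    """Tungsten path length (mm) of rays through the aperture plate.

    The plate occupies |z| <= T/2 with T = max(shield thickness, channel
    height).  The opening radius is r0 = d/2 inside the channel and grows as
    r0 + (|z| - h/2) tan(a/2) in the flanking cones.  Rays passing cleanly
    through the opening return 0; rays clipping the edge return the exact
    chord through tungsten; rays far from the aperture return the full
    (oblique) plate crossing.  Origins on the detector side of the plate are
    not meaningful and rays must not run parallel to the plate.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    o, d = np.broadcast_arrays(o, d)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    d = d / norm

    T = max(shield.thickness_mm, pinhole.effective_channel_mm)
    H = T / 2.0
    hc = min(pinhole.effective_channel_mm, T) / 2.0
    r0 = pinhole.diameter_mm / 2.0
    u_slope = np.tan(np.radians(pinhole.acceptance_angle_deg / 2.0))

    dz = d[..., 2]
    steep = np.abs(dz) > 1e-9
    dz_safe = np.where(steep, dz, 1.0)
    gx, gy = d[..., 0] / dz_safe, d[..., 1] / dz_safe
    px = o[..., 0] - o[..., 2] * gx
    py = o[..., 1] - o[..., 2] * gy

    a = gx * gx + gy * gy
    b = 2.0 * (px * gx + py * gy)
    c0 = px * px + py * py

    # quick reject: a ray whose closest approach to the aperture axis inside
    # the slab exceeds the widest opening radius never sees air
    r_max = r0 + max(0.0, H - hc) * u_slope
    with np.errstate(divide="ignore", invalid="ignore"):
        z_star = np.where(a > 0, -b / (2.0 * np.maximum(a, 1e-300)), 0.0)
    z_star = np.clip(z_star, -H, H)
    rho2_min = (a * z_star + b) * z_star + c0
    near = rho2_min <= (r_max + 1e-9) ** 2

    air = np.zeros(a.shape)
    if np.any(near):
        an, bn, cn = a[near], b[near], c0[near]
        # channel piece: rho^2 - r0^2 <= 0 on [-hc, hc]
        air_n = _measure_neg(an, bn, cn - r0 * r0, -hc, hc)
        if H > hc + 1e-12:
            alpha = r0 - u_slope * hc
            aa = an - u_slope * u_slope
            cc = cn - alpha * alpha
            # cone toward object: R = alpha + u z on [hc, H]
            air_n = air_n + _measure_neg(aa, bn - 2.0 * alpha * u_slope, cc, hc, H)
            # cone toward detector: R = alpha - u z on [-H, -hc]
            air_n = air_n + _measure_neg(aa, bn + 2.0 * alpha * u_slope, cc, -H, -hc)
        air[near] = air_n

    # extent of the slab actually crossed by the ray (origin may sit inside)
    z0 = o[..., 2]
    top = np.minimum(H, np.maximum(z0, -H))
    extent = np.where(dz < 0, top + H, H - np.minimum(np.maximum(z0, -H), H))
    w_z = np.clip(extent - air, 0.0, None)
    path = np.where(steep, w_z / np.abs(dz_safe), np.where(w_z > 0, np.inf, 0.0))
    return path if path.shape else float(path)


def effective_diameter(pinhole: PinholeSpec, mu_tungsten_mm: float) -> float:
    """Sensitivity-effective pinhole diameter with edge penetration.

    Classical form d_eff = sqrt(d * (d + (2/mu) tan(a/2))): the resolution- and
    sensitivity-weighted diameter of a knife-edge aperture in a material with
    linear attenuation ``mu`` (per mm).  Used by the analytic oracle only; the
    Monte Carlo engine models penetration explicitly via the path length.
    """
    if mu_tungsten_mm <= 0:
        raise ValueError("attenuation coefficient must be positive")
    d = pinhole.diameter_mm
    return float(
        np.sqrt(d * (d + (2.0 / mu_tungsten_mm) * np.tan(np.radians(pinhole.acceptance_angle_deg / 2.0))))
    )


def analytic_point_sensitivity(
    camera: CameraConfig, point, d_eff_mm: float | None = None
) -> float:
    """Geometric detection fraction of a point source through the aperture.

    Returns d_eff^2 cos^3(theta) / (16 h^2): the accepted solid angle over
    4 pi, where h is the perpendicular distance of the point from the pinhole
    plane and theta its off-axis angle.  With ``d_eff_mm`` omitted the bare
    pinhole diameter is used (ideal opaque aperture).
    """
    p = np.asarray(point, dtype=float)
    h = p[2]
    if h <= 0:
        raise ValueError("point must be in front of the pinhole plane")
    if d_eff_mm is None:
        d_eff_mm = camera.pinhole.diameter_mm
    cos_theta = h / np.linalg.norm(p)
    return float(d_eff_mm**2 * cos_theta**3 / (16.0 * h**2))
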