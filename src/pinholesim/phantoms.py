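"""Synthetic activity phantoms: every source geometry the evaluation uses.

All phantoms live in the camera frame (pinhole at the origin, object z > 0,
distances along +z).  A :class:`SourceModel` is a set of analytic primitives
(points, boxes, rods, spheres, ellipsoids) each carrying an activity in MBq,
or a voxelised activity volume, plus optional attenuating water regions the
transport engine integrates through.  Generators reproduce the study
conditions: an 80 MBq 250 x 250 x 10 mm flood box, a 286 x 286 x 15 mm
Derenzo-like slab with rod groups of 29/18.6/15.7/13/11.5/10 mm diameter at
18.5 MBq per rod, 1000 MBq point sources at 0-100 mm offsets, two 12.4 mm
370 MBq spheres at 100/125 mm depth in a 200 mm 37 MBq water box, and a
rat-like four-region phantom with 17 mm tumour-liver and 9 mm bladder-tumour
surface separations.

Voxel phantoms use a deliberately plain on-disk format: raw little-endian
float32 in z-y-x order plus a JSON sidecar declaring dimensions, voxel size,
origin and value semantics ("activity" in MBq/voxel or "mu" in mm^-1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "SourceModel",
    "VoxelVolume",
    "PointSource",
    "BoxSource",
    "SphereSource",
    "CylinderSource",
    "EllipsoidSource",
    "VoxelSource",
    "AttenuationRegion",
    "BoxRegion",
    "SphereRegion",
    "make_flood_phantom",
    "make_derenzo_phantom",
    "make_point_source",
    "make_two_sphere_phantom",
    "make_rat_like_phantom",
    "load_voxel_phantom",
]


# --------------------------------------------------------------------------
# activity primitives


@dataclass(frozen=True)
class PointSource:
    position_mm: tuple[float, float, float]
    activity_mbq: float

    def __post_init__(self):
        _check_activity(self.activity_mbq)

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.position_mm, dtype=float)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.broadcast_to(self.centroid, (n, 3)).copy()


@dataclass(frozen=True)
class BoxSource:
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    activity_mbq: float

    def __post_init__(self):
        _check_activity(self.activity_mbq)
        if min(self.size_mm) <= 0:
            raise ValueError("box dimensions must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float)

    def sample(self, n, rng):
        half = np.asarray(self.size_mm) / 2.0
        return self.centroid + rng.uniform(-half, half, size=(n, 3))


@dataclass(frozen=True)
class SphereSource:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    activity_mbq: float

    def __post_init__(self):
        _check_activity(self.activity_mbq)
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float)

    def sample(self, n, rng):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = (self.diameter_mm / 2.0) * rng.random(n) ** (1.0 / 3.0)
        return self.centroid + v * r[:, None]


@dataclass(frozen=True)
class CylinderSource:
    """Rod with its axis along z (the depth direction)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    length_mm: float
    activity_mbq: float

    def __post_init__(self):
        _check_activity(self.activity_mbq)
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("rod dimensions must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float)

    def sample(self, n, rng):
        r = (self.diameter_mm / 2.0) * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        z = rng.uniform(-self.length_mm / 2.0, self.length_mm / 2.0, n)
        return self.centroid + np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class EllipsoidSource:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    activity_mbq: float
    name: str = ""

    def __post_init__(self):
        _check_activity(self.activity_mbq)
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float)

    def sample(self, n, rng):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.random(n) ** (1.0 / 3.0)
        return self.centroid + v * r[:, None] * np.asarray(self.semi_axes_mm)


def _check_activity(a: float) -> None:
    if a < 0:
        raise ValueError("activity must be >= 0 MBq")


# --------------------------------------------------------------------------
# voxel volume


@dataclass
class VoxelVolume:
    """A regular grid of per-voxel values in z-y-x order.

    ``values[iz, iy, ix]`` covers the cube whose minimum corner is
    ``origin + (ix, iy, iz) * voxel_size`` (origin is the volume's minimum
    corner in camera coordinates, mm).
    """

    values: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float]
    kind: Literal["activity", "mu"] = "activity"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("voxel volume must be 3-D (z, y, x)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.values < 0):
            raise ValueError("voxel values must be >= 0")

    @property
    def dims(self) -> tuple[int, int, int]:
        nz, ny, nx = self.values.shape
        return nx, ny, nz

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def save(self, data_path: str | Path, meta_path: str | Path) -> None:
        arr = np.ascontiguousarray(self.values, dtype="<f4")
        Path(data_path).write_bytes(arr.tobytes())
        meta = {
            "dims_xyz": list(self.dims),
            "voxel_size_mm": self.voxel_size_mm,
            "origin_mm": list(self.origin_mm),
            "kind": self.kind,
            "dtype": "<f4",
            "order": "zyx",
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, data_path: str | Path, meta_path: str | Path) -> "VoxelVolume":
        meta = json.loads(Path(meta_path).read_text())
        nx, ny, nz = (int(v) for v in meta["dims_xyz"])
        raw = Path(data_path).read_bytes()
        expected = nx * ny * nz * 4
        if len(raw) != expected:
            raise ValueError(
                f"voxel file holds {len(raw)} bytes but metadata implies {expected}"
            )
        values = np.frombuffer(raw, dtype="<f4").reshape(nz, ny, nx)
        return cls(
            values=values.copy(),
            voxel_size_mm=float(meta["voxel_size_mm"]),
            origin_mm=tuple(float(v) for v in meta.get("origin_mm", (0, 0, 0))),
            kind=meta.get("kind", "activity"),
        )

    def line_integral(self, origins, directions, t_max, step: float | None = None):
        """Integral of voxel values along rays from t=0 to t_max (value*mm).

        Nearest-voxel lookup with a marching step of half the voxel size
        (midpoint rule); used for voxelised attenuation maps.
        """
        o = np.atleast_2d(np.asarray(origins, dtype=float))
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        t_max = np.atleast_1d(np.asarray(t_max, dtype=float))
        if step is None:
            step = self.voxel_size_mm / 2.0
        n_steps = int(np.ceil(np.max(t_max) / step)) if t_max.size else 0
        total = np.zeros(o.shape[0])
        if n_steps == 0:
            return total
        nz, ny, nx = self.values.shape
        org = np.asarray(self.origin_mm)
        for k in range(n_steps):
            t_mid = (k + 0.5) * step
            live = t_mid < t_max
            if not live.any():
                break
            p = o[live] + t_mid * d[live]
            idx = np.floor((p - org) / self.voxel_size_mm).astype(np.int64)
            ok = (
                (idx[:, 0] >= 0) & (idx[:, 0] < nx)
                & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
                & (idx[:, 2] >= 0) & (idx[:, 2] < nz)
            )
            vals = np.zeros(ok.shape)
            sel = idx[ok]
            vals[ok] = self.values[sel[:, 2], sel[:, 1], sel[:, 0]]
            total[live] += vals * step
        return total


@dataclass(frozen=True)
class VoxelSource:
    volume: VoxelVolume

    @property
    def activity_mbq(self) -> float:
        return self.volume.total

    @property
    def centroid(self) -> np.ndarray:
        nz, ny, nx = self.volume.values.shape
        w = self.volume.values
        tot = w.sum()
        if tot == 0:
            return np.asarray(self.volume.origin_mm, dtype=float)
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        org = np.asarray(self.volume.origin_mm)
        vs = self.volume.voxel_size_mm
        cx = (w * (xx + 0.5)).sum() / tot
        cy = (w * (yy + 0.5)).sum() / tot
        cz = (w * (zz + 0.5)).sum() / tot
        return org + np.array([cx, cy, cz]) * vs

    def sample(self, n, rng):
        w = self.volume.values.ravel()
        tot = w.sum()
        if tot <= 0:
            raise ValueError("cannot sample from a zero-activity volume")
        cdf = np.cumsum(w) / tot
        flat = np.searchsorted(cdf, rng.random(n), side="right")
        nz, ny, nx = self.volume.values.shape
        iz, rem = np.divmod(flat, ny * nx)
        iy, ix = np.divmod(rem, nx)
        org = np.asarray(self.volume.origin_mm)
        vs = self.volume.voxel_size_mm
        corner = org + np.column_stack([ix, iy, iz]) * vs
        return corner + rng.random((n, 3)) * vs


# --------------------------------------------------------------------------
# attenuation regions (convex; ray intersection returns a [t0, t1] interval)


class AttenuationRegion:
    material: str

    def intersect(self, origins, directions):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class BoxRegion(AttenuationRegion):
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    material: str = "water"

    def intersect(self, origins, directions):
        # slab method; +-inf from zero direction components propagates the
        # right in/out answer for axis-parallel rays
        o = np.atleast_2d(origins) - np.asarray(self.center_mm)
        d = np.atleast_2d(directions)
        half = np.asarray(self.size_mm) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / d
            t1 = (-half - o) * inv
            t2 = (half - o) * inv
        t1 = np.nan_to_num(t1, nan=-np.inf)
        t2 = np.nan_to_num(t2, nan=np.inf)
        t_in = np.minimum(t1, t2).max(axis=1)
        t_out = np.maximum(t1, t2).min(axis=1)
        return t_in, t_out


@dataclass(frozen=True)
class SphereRegion(AttenuationRegion):
    center_mm: tuple[float, float, float]
    diameter_mm: float
    material: str = "water"

    def intersect(self, origins, directions):
        o = np.atleast_2d(origins) - np.asarray(self.center_mm)
        d = np.atleast_2d(directions)
        b = np.sum(o * d, axis=1)
        c = np.sum(o * o, axis=1) - (self.diameter_mm / 2.0) ** 2
        disc = b * b - c
        sq = np.sqrt(np.clip(disc, 0.0, None))
        t_in = np.where(disc > 0, -b - sq, np.inf)
        t_out = np.where(disc > 0, -b + sq, -np.inf)
        return t_in, t_out


# --------------------------------------------------------------------------
# the source model


@dataclass
class SourceModel:
    """An activity distribution plus optional attenuating regions.

    ``primitives`` may mix analytic primitives and :class:`VoxelSource`.
    ``attenuation_regions`` are convex water (or other material) bodies;
    overlapping regions of the same material are handled up to pairwise
    overlaps (generators never produce triple overlaps).  ``attenuation_map``
    optionally supplies a voxelised mu volume instead.
    """

    primitives: tuple = ()
    attenuation_regions: tuple = ()
    attenuation_map: VoxelVolume | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_activity_mbq(self) -> float:
        return float(sum(p.activity_mbq for p in self.primitives))

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw emission positions, each primitive weighted by its activity."""
        if n == 0:
            return np.empty((0, 3))
        acts = np.array([p.activity_mbq for p in self.primitives])
        total = acts.sum()
        if total <= 0:
            raise ValueError("cannot sample positions from a zero-activity source")
        counts = rng.multinomial(n, acts / total)
        chunks = [p.sample(c, rng) for p, c in zip(self.primitives, counts) if c > 0]
        return np.concatenate(chunks, axis=0)

    def rasterize(self, voxel_size_mm: float, padding_mm: float = 0.0) -> VoxelVolume:
        """Voxelise the analytic activity distribution (centre-in-primitive test).

        Each primitive's activity is split evenly over the voxels whose
        centres fall inside it (a point source claims its nearest voxel), so
        the voxel total matches the analytic total exactly.
        """
        pts = np.array([p.centroid for p in self.primitives])
        half = np.array(
            [_primitive_halfextent(p) for p in self.primitives]
        )
        lo = (pts - half).min(axis=0) - padding_mm
        hi = (pts + half).max(axis=0) + padding_mm
        dims = np.maximum(np.ceil((hi - lo) / voxel_size_mm).astype(int), 1)
        nx, ny, nz = dims
        vol = np.zeros((nz, ny, nx), dtype=np.float64)
        xs = lo[0] + (np.arange(nx) + 0.5) * voxel_size_mm
        ys = lo[1] + (np.arange(ny) + 0.5) * voxel_size_mm
        zs = lo[2] + (np.arange(nz) + 0.5) * voxel_size_mm
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        centers = np.stack([xx, yy, zz], axis=-1)
        for p in self.primitives:
            if isinstance(p, PointSource):
                idx = np.clip(
                    np.floor((p.centroid - lo) / voxel_size_mm).astype(int), 0, dims - 1
                )
                vol[idx[2], idx[1], idx[0]] += p.activity_mbq
                continue
            mask = _primitive_contains(p, centers)
            nvox = int(mask.sum())
            if nvox == 0:
                idx = np.clip(
                    np.floor((p.centroid - lo) / voxel_size_mm).astype(int), 0, dims - 1
                )
                vol[idx[2], idx[1], idx[0]] += p.activity_mbq
            else:
                vol[mask] += p.activity_mbq / nvox
        return VoxelVolume(vol, voxel_size_mm, tuple(lo), kind="activity")


def _primitive_halfextent(p) -> np.ndarray:
    if isinstance(p, PointSource):
        return np.zeros(3)
    if isinstance(p, BoxSource):
        return np.asarray(p.size_mm) / 2.0
    if isinstance(p, SphereSource):
        return np.full(3, p.diameter_mm / 2.0)
    if isinstance(p, CylinderSource):
        r = p.diameter_mm / 2.0
        return np.array([r, r, p.length_mm / 2.0])
    if isinstance(p, EllipsoidSource):
        return np.asarray(p.semi_axes_mm)
    raise TypeError(f"cannot rasterise primitive {type(p).__name__}")


def _primitive_contains(p, points) -> np.ndarray:
    rel = points - p.centroid
    if isinstance(p, BoxSource):
        return np.all(np.abs(rel) <= np.asarray(p.size_mm) / 2.0, axis=-1)
    if isinstance(p, SphereSource):
        return np.sum(rel**2, axis=-1) <= (p.diameter_mm / 2.0) ** 2
    if isinstance(p, CylinderSource):
        return (np.hypot(rel[..., 0], rel[..., 1]) <= p.diameter_mm / 2.0) & (
            np.abs(rel[..., 2]) <= p.length_mm / 2.0
        )
    if isinstance(p, EllipsoidSource):
        return np.sum((rel / np.asarray(p.semi_axes_mm)) ** 2, axis=-1) <= 1.0
    raise TypeError(type(p).__name__)


# --------------------------------------------------------------------------
# generators


def make_flood_phantom(activity_mbq: float = 80.0, distance_mm: float = 100.0) -> SourceModel:
    """Uniform 250 x 250 x 10 mm flood box with its front face at ``distance``.

    Covers the whole 250 mm active FOV; the simulated flood uses 80 MBq, the
    experimental variant 37 MBq.
    """
    center = (0.0, 0.0, distance_mm + 5.0)
    box = BoxSource(center, (250.0, 250.0, 10.0), activity_mbq)
    att = BoxRegion(center, (250.0, 250.0, 10.0))
    return SourceModel((box,), (att,), meta={"phantom": "flood", "distance_mm": distance_mm})


def make_point_source(
    offset_mm: float = 0.0,
    activity_mbq: float = 1000.0,
    distance_mm: float = 100.0,
    water_sphere_diameter_mm: float = 2.0,
) -> SourceModel:
    """Point source at a horizontal offset, wrapped in a 2 mm water sphere."""
    pos = (offset_mm, 0.0, distance_mm)
    regions = ()
    if water_sphere_diameter_mm > 0:
        regions = (SphereRegion(pos, water_sphere_diameter_mm),)
    return SourceModel(
        (PointSource(pos, activity_mbq),),
        regions,
        meta={"phantom": "point", "offset_mm": offset_mm, "distance_mm": distance_mm},
    )


def make_derenzo_phantom(
    rod_diameters_mm: Sequence[float] = (29.0, 18.6, 15.7, 13.0, 11.5, 10.0),
    slab_mm: tuple[float, float, float] = (286.0, 286.0, 15.0),
    activity_per_rod_mbq: float = 18.5,
    distance_mm: float = 100.0,
    start_radius_factor: float = 2.0,
) -> SourceModel:
    """Six-sector Derenzo-like hot-rod phantom.

    Each diameter group occupies a 60-degree sector with rods in triangular
    packing: centre-to-centre spacing twice the diameter (edge gap equal to
    the diameter), rows of 1, 2, 3, ... rods at increasing radius starting at
    ``start_radius_factor * diameter`` from the phantom centre, growing while
    rods stay inside both the sector wedge and the slab.  Rods span the full
    slab thickness.  The layout is deterministic and recorded in ``meta``.
    """
    if any(d <= 0 for d in rod_diameters_mm):
        raise ValueError("rod diameters must be positive")
    sx, sy, sz = slab_mm
    half_side = min(sx, sy) / 2.0
    zc = distance_mm + sz / 2.0
    rods: list[CylinderSource] = []
    groups = []
    n_groups = len(rod_diameters_mm)
    for g, dia in enumerate(rod_diameters_mm):
        phi = math.radians(90.0 + 360.0 * g / n_groups)  # sector axis direction
        radial = np.array([math.cos(phi), math.sin(phi)])
        tangent = np.array([-math.sin(phi), math.cos(phi)])
        wedge_half = math.pi / n_groups
        rows = []
        r = start_radius_factor * dia
        j = 0
        while True:
            offsets = (np.arange(j + 1) - j / 2.0) * 2.0 * dia
            centers = r * radial + offsets[:, None] * tangent
            in_slab = np.all(np.abs(centers) + dia / 2.0 <= half_side, axis=1)
            half_width = (j * dia) + dia / 2.0
            in_wedge = math.atan2(half_width, r) <= wedge_half
            if not (in_slab.all() and in_wedge):
                break
            rows.append([tuple(c) for c in centers])
            for cx, cy in centers:
                rods.append(
                    CylinderSource((cx, cy, zc), dia, sz, activity_per_rod_mbq)
                )
            j += 1
            r += math.sqrt(3.0) * dia
        if not rows:
            raise ValueError(
                f"rod group of diameter {dia} mm does not fit its sector"
            )
        groups.append(
            {"diameter_mm": dia, "sector_angle_deg": math.degrees(phi), "rows": rows}
        )
    att = BoxRegion((0.0, 0.0, zc), slab_mm)
    return SourceModel(
        tuple(rods),
        (att,),
        meta={
            "phantom": "derenzo",
            "distance_mm": distance_mm,
            "slab_mm": tuple(slab_mm),
            "groups": groups,
        },
    )


def make_two_sphere_phantom(
    sphere_diameter_mm: float = 12.4,
    depths_mm: tuple[float, float] = (100.0, 125.0),
    sphere_activity_mbq: float = 370.0,
    bg_box_mm: tuple[float, float, float] = (200.0, 200.0, 200.0),
    bg_activity_mbq: float = 37.0,
    lateral_offsets_mm: tuple[float, float] = (25.0, -25.0),
    distance_mm: float = 100.0,
) -> SourceModel:
    """Two identical hot spheres at different depths in a warm water box.

    The box front face sits at ``distance_mm``; sphere centres at the stated
    depths, laterally offset so their projections do not overlap.  The
    returned meta orders spheres (near, far) by depth.
    """
    if depths_mm[0] == depths_mm[1]:
        raise ValueError("the two sphere depths must be distinct")
    box_center = (0.0, 0.0, distance_mm + bg_box_mm[2] / 2.0)
    order = np.argsort(depths_mm)
    spheres = []
    sphere_meta = []
    for k in order:
        center = (float(lateral_offsets_mm[k]), 0.0, float(depths_mm[k]))
        if abs(center[0]) + sphere_diameter_mm / 2.0 > bg_box_mm[0] / 2.0:
            raise ValueError("sphere does not fit laterally inside the box")
        if center[2] + sphere_diameter_mm / 2.0 > distance_mm + bg_box_mm[2]:
            raise ValueError("sphere deeper than the box")
        spheres.append(SphereSource(center, sphere_diameter_mm, sphere_activity_mbq))
        sphere_meta.append({"center_mm": center, "diameter_mm": sphere_diameter_mm})
    prims: list = list(spheres)
    if bg_activity_mbq > 0:
        prims.append(BoxSource(box_center, bg_box_mm, bg_activity_mbq))
    regions = (
        BoxRegion(box_center, bg_box_mm),
        SphereRegion(sphere_meta[0]["center_mm"], sphere_diameter_mm),
        SphereRegion(sphere_meta[1]["center_mm"], sphere_diameter_mm),
    )
    return SourceModel(
        tuple(prims),
        regions,
        meta={"phantom": "two_sphere", "spheres": sphere_meta, "distance_mm": distance_mm},
    )


# semi-axes (mm) of the rat-like regions; stand-ins for organ shapes
_RAT_REGIONS = {
    "left_tumor": (6.0, 5.0, 5.0),
    "liver": (12.0, 10.0, 8.0),
    "bladder": (7.0, 6.0, 6.0),
    "right_tumor": (6.0, 5.0, 5.0),
}


def make_rat_like_phantom(
    region_activities: Mapping[str, float] | None = None,
    separations_mm: tuple[float, float] = (17.0, 9.0),
    distance_mm: float = 100.0,
) -> SourceModel:
    """Four ellipsoidal hot regions in a rat-sized water body.

    A synthetic stand-in for a fillable rat phantom: left tumour, liver,
    bladder and right tumour along the body axis with the stated
    surface-to-surface separations (tumour-liver, bladder-tumour), each
    region 18.5 MBq by default, body bottom surface 100 mm from the pinhole.
    Pass a subset of region names to build fewer regions.
    """
    if any(s <= 0 for s in separations_mm):
        raise ValueError("separations must be positive")
    acts = dict(region_activities) if region_activities is not None else {
        name: 18.5 for name in _RAT_REGIONS
    }
    unknown = set(acts) - set(_RAT_REGIONS)
    if unknown:
        raise ValueError(f"unknown region names: {sorted(unknown)}")
    sep_tl, sep_bt = separations_mm
    ax = {k: _RAT_REGIONS[k] for k in _RAT_REGIONS}
    # place centres along x so that surface gaps match the separations
    x_lt = -45.0
    x_liver = x_lt + ax["left_tumor"][0] + sep_tl + ax["liver"][0]
    x_bladder = x_liver + ax["liver"][0] + 25.0 + ax["bladder"][0]
    x_rt = x_bladder + ax["bladder"][0] + sep_bt + ax["right_tumor"][0]
    centers = {
        "left_tumor": x_lt,
        "liver": x_liver,
        "bladder": x_bladder,
        "right_tumor": x_rt,
    }
    body_len = 2.0 * max(abs(x_lt), abs(x_rt)) + 60.0
    zc = distance_mm + 20.0  # body box is 40 mm thick, bottom at distance_mm
    prims = tuple(
        EllipsoidSource((centers[name], 0.0, zc), ax[name], acts[name], name=name)
        for name in _RAT_REGIONS
        if name in acts
    )
    body = BoxRegion((0.0, 0.0, zc), (body_len, 70.0, 40.0))
    return SourceModel(
        prims,
        (body,),
        meta={
            "phantom": "rat_like",
            "centers_x_mm": centers,
            "separations_mm": tuple(separations_mm),
            "distance_mm": distance_mm,
        },
    )


def load_voxel_phantom(
    data_path: str | Path,
    meta_path: str | Path,
    attenuation: tuple[str | Path, str | Path] | None = None,
) -> SourceModel:
    """Build a SourceModel from a raw-volume activity map (+ optional mu map)."""
    vol = VoxelVolume.load(data_path, meta_path)
    if vol.kind != "activity":
        raise ValueError("the primary volume must carry activity values")
    att = None
    if attenuation is not None:
        att = VoxelVolume.load(*attenuation)
        if att.kind != "mu":
            raise ValueError("the attenuation volume must carry mu values")
    return SourceModel(
        (VoxelSource(vol),),
        (),
        attenuation_map=att,
        meta={"phantom": "voxel"},
    )
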