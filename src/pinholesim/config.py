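"""Configuration files: YAML (JSON-compatible) camera / phantom / protocol specs.

A run configuration has up to four sections::

    camera:
      pinhole:   {diameter_mm: 1.2, acceptance_angle_deg: 94, channel_height_mm: 1}
      detector:  {active_side_mm: 50, crystal_size_mm: 1, septa_mm: 0.2, ...}
      shield:    {thickness_mm: 5}
      pinhole_to_detector_mm: 20
      object_to_pinhole_mm: 100
    phantom:
      type: derenzo            # flood | derenzo | point | two_sphere | rat_like | voxel
      ...generator keyword arguments...
    protocol:
      duration_s: 7.0          # or n_primaries
      windows: [{peaks: [112.95, 208.37], half_width: 0.35}]
      direction_sampling: cone
      seed: 1
    output:
      prefix: out/run1

Unknown keys raise immediately with the offending section named, so a typo
cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import yaml

from .emission import EnergyWindow, make_energy_window
from .geometry import CameraConfig, DetectorSpec, PinholeSpec, ShieldSpec
from .phantoms import (
    SourceModel,
    load_voxel_phantom,
    make_derenzo_phantom,
    make_flood_phantom,
    make_point_source,
    make_rat_like_phantom,
    make_two_sphere_phantom,
)
from .transport import AcquisitionProtocol

__all__ = [
    "RunConfig",
    "load_run_config",
    "camera_from_dict",
    "camera_to_dict",
    "phantom_from_dict",
    "protocol_from_dict",
]


def _build(cls, section: dict | None, name: str):
    section = dict(section or {})
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section {name!r}")
    if "outer_mm" in section and isinstance(section["outer_mm"], list):
        section["outer_mm"] = tuple(section["outer_mm"])
    return cls(**section)


def camera_from_dict(d: dict | None) -> CameraConfig:
    d = dict(d or {})
    known = {"pinhole", "detector", "shield", "pinhole_to_detector_mm", "object_to_pinhole_mm"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section 'camera'")
    return CameraConfig(
        pinhole=_build(PinholeSpec, d.get("pinhole"), "camera.pinhole"),
        detector=_build(DetectorSpec, d.get("detector"), "camera.detector"),
        shield=_build(ShieldSpec, d.get("shield"), "camera.shield"),
        pinhole_to_detector_mm=d.get("pinhole_to_detector_mm", 20.0),
        object_to_pinhole_mm=d.get("object_to_pinhole_mm", 100.0),
    )


def camera_to_dict(camera: CameraConfig) -> dict:
    return dataclasses.asdict(camera)


_PHANTOM_BUILDERS = {
    "flood": make_flood_phantom,
    "derenzo": make_derenzo_phantom,
    "point": make_point_source,
    "two_sphere": make_two_sphere_phantom,
    "rat_like": make_rat_like_phantom,
}


def phantom_from_dict(d: dict) -> SourceModel:
    d = dict(d)
    kind = d.pop("type", None)
    if kind == "voxel":
        att = d.pop("attenuation", None)
        return load_voxel_phantom(
            d.pop("data"), d.pop("meta"), attenuation=tuple(att) if att else None
        )
    builder = _PHANTOM_BUILDERS.get(kind)
    if builder is None:
        raise ValueError(
            f"unknown phantom type {kind!r}; choose from "
            f"{sorted(_PHANTOM_BUILDERS) + ['voxel']}"
        )
    for key, val in d.items():
        if isinstance(val, list):
            d[key] = tuple(val)
    return builder(**d)


def _window_from_dict(w) -> EnergyWindow:
    if isinstance(w, dict) and "peaks" in w:
        return make_energy_window(w["peaks"], w.get("half_width", 0.35))
    if isinstance(w, dict) and "intervals" in w:
        return EnergyWindow(tuple(tuple(iv) for iv in w["intervals"]))
    raise ValueError(f"cannot interpret window spec {w!r}")


def protocol_from_dict(d: dict | None) -> AcquisitionProtocol:
    d = dict(d or {})
    if "windows" in d:
        d["windows"] = tuple(_window_from_dict(w) for w in d["windows"])
    fields = {f.name for f in dataclasses.fields(AcquisitionProtocol)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section 'protocol'")
    return AcquisitionProtocol(**d)


@dataclasses.dataclass
class RunConfig:
    camera: CameraConfig
    phantom: SourceModel | None
    protocol: AcquisitionProtocol | None
    output_prefix: str | None
    raw: dict


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"camera", "phantom", "protocol", "output"}
    if unknown:
        raise ValueError(f"unknown top-level section(s) {sorted(unknown)}")
    camera = camera_from_dict(raw.get("camera"))
    phantom = phantom_from_dict(raw["phantom"]) if "phantom" in raw else None
    protocol = protocol_from_dict(raw["protocol"]) if "protocol" in raw else None
    output = (raw.get("output") or {}).get("prefix")
    return RunConfig(camera, phantom, protocol, output, raw)
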