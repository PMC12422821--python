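"""Image and table IO: multi-page TIFF fields with JSON sidecars, plate maps.

A field is stored as one multi-page TIFF (one page per channel) next to a JSON
sidecar ``<stem>.json`` holding the channel roles, pixel size and identifiers.
Plate maps are YAML mapping well ids to condition/serum-state/dose/replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile
import yaml

CHANNEL_ROLES = (
    "dna", "edu", "gH2AX", "p21", "laminB1", "hmgb1", "brightfield_sabgal",
)


class FormatError(ValueError):
    """Raised when an on-disk field or plate map is malformed."""


@dataclass
class FieldImage:
    """One acquired field: a (C, H, W) uint16 stack plus channel metadata."""

    pixels: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float
    field_id: str
    well_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise FormatError("pixels must be a (channels, H, W) array")
        if "dna" not in self.channel_roles:
            raise FormatError("field is missing the mandatory 'dna' channel role")
        n_ch = self.pixels.shape[0]
        for role, idx in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise FormatError(f"unknown channel role {role!r}")
            if not 0 <= idx < n_ch:
                raise FormatError(f"channel index {idx} for {role!r} out of range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D image for a channel role."""
        if role not in self.channel_roles:
            raise KeyError(f"channel role {role!r} not present in field {self.field_id}")
        return self.pixels[self.channel_roles[role]]

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_field(field_image: FieldImage, path: str | Path) -> Path:
    """Write a field as multi-page TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(field_image.pixels, dtype=np.uint16),
                     photometric="minisblack")
    meta = {
        "channel_roles": field_image.channel_roles,
        "pixel_size_um": field_image.pixel_size_um,
        "field_id": field_image.field_id,
        "well_id": field_image.well_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_field(path: str | Path) -> FieldImage:
    """Read a field written by :func:`write_field`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"missing JSON sidecar {sidecar.name} (channel_roles / pixel_size_um "
            f"metadata) next to {path.name}"
        )
    meta = json.loads(sidecar.read_text())
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    return FieldImage(
        pixels=pixels,
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
        pixel_size_um=float(meta["pixel_size_um"]),
        field_id=str(meta["field_id"]),
        well_id=str(meta["well_id"]),
    )


def iter_plate_fields(plate_dir: str | Path) -> Iterable[FieldImage]:
    """Yield all fields under a plate directory, sorted by file name."""
    plate_dir = Path(plate_dir)
    for tiff in sorted(plate_dir.rglob("*.tiff")) + sorted(plate_dir.rglob("*.tif")):
        yield read_field(tiff)


@dataclass(frozen=True)
class WellInfo:
    condition: str
    dose_uM: float = 0.0
    serum_state: str = "FS"
    replicate: int = 1
    experiment_id: str = "E1"

    def __post_init__(self) -> None:
        if self.dose_uM < 0:
            raise FormatError("dose_uM must be >= 0")
        if self.serum_state not in ("FS", "SS"):
            raise FormatError("serum_state must be 'FS' or 'SS'")


@dataclass
class PlateMap:
    """Well id -> experimental annotation for one plate."""

    wells: dict[str, WellInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.wells)) != len(self.wells):  # dict keys are unique; guard for ctor misuse
            raise FormatError("duplicate well ids in plate map")

    def __getitem__(self, well_id: str) -> WellInfo:
        return self.wells[well_id]

    def __contains__(self, well_id: str) -> bool:
        return well_id in self.wells

    def __len__(self) -> int:
        return len(self.wells)

    def well_ids(self) -> list[str]:
        return sorted(self.wells)

    def conditions(self) -> list[str]:
        return sorted({w.condition for w in self.wells.values()})

    @classmethod
    def from_dict(cls, mapping) -> "PlateMap":
        """Build from {well_id: entry} or an iterable of (well_id, entry) pairs."""
        items = mapping.items() if isinstance(mapping, Mapping) else mapping
        wells = {}
        for well_id, entry in items:
            if well_id in wells:
                raise FormatError(f"duplicate well id {well_id!r}")
            wells[str(well_id)] = WellInfo(
                condition=str(entry["condition"]),
                dose_uM=float(entry.get("dose_uM", 0.0)),
                serum_state=str(entry.get("serum_state", "FS")),
                replicate=int(entry.get("replicate", 1)),
                experiment_id=str(entry.get("experiment_id", "E1")),
            )
        return cls(wells=wells)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateMap":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping) or "wells" not in raw:
            raise FormatError("plate map YAML must contain a top-level 'wells' mapping")
        return cls.from_dict(raw["wells"])

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "wells": {
                wid: {
                    "condition": w.condition,
                    "dose_uM": w.dose_uM,
                    "serum_state": w.serum_state,
                    "replicate": w.replicate,
                    "experiment_id": w.experiment_id,
                }
                for wid, w in self.wells.items()
            }
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def assemble_well(fields: list[FieldImage], grid: tuple[int, int]) -> FieldImage:
    """Concatenate fields of one well into a single large field.

    Tiles are laid out row-major on a ``rows x cols`` grid with no overlap or
    registration; tile (i, j) local pixel (r, c) maps to global
    (i*H + r, j*W + c).
    """
    rows, cols = grid
    if rows * cols != len(fields):
        raise ValueError(f"grid {rows}x{cols} does not match {len(fields)} fields")
    well_ids = {f.well_id for f in fields}
    if len(well_ids) != 1:
        raise ValueError(f"fields belong to multiple wells: {sorted(well_ids)}")
    shapes = {f.pixels.shape for f in fields}
    if len(shapes) != 1:
        raise ValueError(f"fields have mismatched shapes: {sorted(shapes)}")
    roles = fields[0].channel_roles
    for f in fields[1:]:
        if f.channel_roles != roles:
            raise ValueError("fields have mismatched channel roles")

    band_list = []
    for i in range(rows):
        row_fields = fields[i * cols:(i + 1) * cols]
        band_list.append(np.concatenate([f.pixels for f in row_fields], axis=2))
    mosaic = np.concatenate(band_list, axis=1)
    return FieldImage(
        pixels=mosaic,
        channel_roles=dict(roles),
        pixel_size_um=fields[0].pixel_size_um,
        field_id=f"{fields[0].well_id}_mosaic",
        well_id=fields[0].well_id,
    )
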