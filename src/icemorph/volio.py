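"""Volume containers and I/O.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based, with half-open index ranges;
* voxels are isotropic; the physical voxel size (µm) always comes from the
  caller or a config file, never from TIFF metadata (resolution tags written
  by tomography exporters are unreliable);
* label volumes use the phase codes :data:`AIR`, :data:`ICE_OUTSIDE`,
  :data:`ICE_INSIDE`, :data:`STARCH`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "AIR",
    "ICE_OUTSIDE",
    "ICE_INSIDE",
    "STARCH",
    "PHASE_NAMES",
    "PHASE_CODES",
    "GreyVolume",
    "LabelVolume",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "crop_subvolume",
]

#: Phase codes of a :class:`LabelVolume`.
AIR = 0
ICE_OUTSIDE = 1
ICE_INSIDE = 2
STARCH = 3

PHASE_NAMES = {AIR: "air", ICE_OUTSIDE: "ice_outside", ICE_INSIDE: "ice_inside", STARCH: "starch"}
PHASE_CODES = {v: k for k, v in PHASE_NAMES.items()}


class VolumeFormatError(ValueError):
    """Raised when a volume on disk violates the format contract."""


def _check_volume(data: np.ndarray, voxel_size: float) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all axes must be >= 1, got shape {data.shape}")
    if not voxel_size > 0:
        raise ValueError(f"voxel_size must be > 0, got {voxel_size}")


@dataclass
class GreyVolume:
    """A 3D grey-level tomogram with isotropic physical voxel size in µm."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_volume(self.data, self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A per-voxel phase-code volume (air=0, ice-outside=1, ice-inside=2, starch=3)."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_volume(self.data, self.voxel_size)
        bad = np.setdiff1d(np.unique(self.data), list(PHASE_NAMES))
        if bad.size:
            raise ValueError(f"undefined phase codes present: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, phase: int | str) -> np.ndarray:
        """Binary mask of one phase; `phase` may be a code or a phase name."""
        code = PHASE_CODES[phase] if isinstance(phase, str) else int(phase)
        if code not in PHASE_NAMES:
            raise ValueError(f"unknown phase {phase!r}")
        return self.data == code


def read_volume(path: str | Path, voxel_size: float, *, labels: bool = False):
    """Read a multi-page TIFF stack (or a directory of single-page TIFFs).

    The z axis is the page index, ascending; for a directory, pages are taken
    in lexicographic filename order. ``voxel_size`` is attached from the
    argument — TIFF metadata is deliberately ignored.
    """
    path = Path(path)
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not pages:
            raise VolumeFormatError(f"no TIFF pages found in directory {path}")
        slices = [tifffile.imread(p) for p in pages]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise VolumeFormatError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    else:
        try:
            data = tifffile.imread(path)
        except (OSError, tifffile.TiffFileError) as exc:
            raise VolumeFormatError(f"cannot read TIFF volume {path}: {exc}") from exc
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected 3D stack, got shape {data.shape}")
    cls = LabelVolume if labels else GreyVolume
    return cls(data, voxel_size)


def write_volume(volume: GreyVolume | LabelVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF, pages in ascending z."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if isinstance(volume, LabelVolume):
        data = data.astype(np.uint8)
    tifffile.imwrite(path, data)
    return path


def crop_subvolume(volume, center: tuple[int, int, int], size: int):
    """Extract the axis-aligned cube of edge ``size`` voxels centered at ``center``.

    Half-open index ranges; for even sizes the center voxel is the lower-middle
    one of the cropped cube. Raises ``IndexError`` if the cube does not fit —
    there is no silent clipping.
    """
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    starts = [int(c) - (size - 1) // 2 for c in center]
    stops = [s + size for s in starts]
    for ax, (lo, hi) in enumerate(zip(starts, stops)):
        if lo < 0 or hi > volume.data.shape[ax]:
            raise IndexError(
                f"crop [{lo}:{hi}) on axis {ax} exceeds volume shape {volume.data.shape}"
            )
    sub = volume.data[starts[0]:stops[0], starts[1]:stops[1], starts[2]:stops[2]]
    return type(volume)(sub.copy(), volume.voxel_size)
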