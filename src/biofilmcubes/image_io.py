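"""Reading and writing image stacks, binary masks and cube tables.

All volumes carry explicit physical voxel spacing in micrometres.  The axis
convention is fixed as ``(channel, z, y, x)`` for multi-channel stacks and
``(z, y, x)`` for masks; the physical coordinate of a voxel is
``(index + 0.5) * spacing`` per axis (voxel-centre convention).

TIFF is the only image dialect.  Intensities are stored and returned without
any rescaling so that raw fluorescence values survive a round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "BinaryMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_cube_table",
    "write_cube_table",
    "CUBE_TABLE_REQUIRED_COLUMNS",
]

_DESCRIPTION_KEY = "biofilmcubes"


@dataclass
class ImageStack:
    """Multi-channel 3D intensity volume.

    Attributes
    ----------
    voxels
        Array of shape ``(n_channels, nz, ny, nx)``; non-negative intensities.
    spacing_um
        Physical voxel spacing ``(z, y, x)`` in micrometres.
    channel_names
        One name per channel, same order as the channel axis.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"stack must be 4-D (channel, z, y, x); got shape {self.voxels.shape}"
            )
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing_um must be 3 positive values; got {self.spacing_um}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def is_isotropic(self) -> bool:
        z, y, x = self.spacing_um
        return np.isclose(z, y) and np.isclose(y, x)

    def channel(self, name: str) -> np.ndarray:
        """Return the 3-D volume of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.voxels[idx]


@dataclass
class BinaryMask:
    """Isotropic foreground/background volume (z, y, x), boolean."""

    voxels: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3-D (z, y, x); got shape {self.voxels.shape}")
        self.spacing_um = float(self.spacing_um)
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


def _make_description(meta: dict) -> str:
    # prefixed so generic TIFF readers treat it as an opaque comment
    return _DESCRIPTION_KEY + " " + json.dumps(meta)


def _parse_description(desc: str | None) -> dict | None:
    if not desc or not desc.startswith(_DESCRIPTION_KEY + " "):
        return None
    try:
        payload = json.loads(desc[len(_DESCRIPTION_KEY) + 1 :])
    except (TypeError, ValueError):
        return None
    return payload if isinstance(payload, dict) else None


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF, pages z-major within channel.

    Spacing and channel names are recorded in the image description tag and in
    the TIFF resolution tags (x/y), so a round trip through
    :func:`read_stack` restores them.
    """
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "spacing_um": list(stack.spacing_um),
        "channel_names": stack.channel_names,
        "shape": list(stack.voxels.shape),
    }
    sz, sy, sx = stack.spacing_um
    # resolution tags are pixels per unit; use centimetres (1e4 um).
    tifffile.imwrite(
        path,
        stack.voxels.reshape((-1,) + stack.voxels.shape[2:]),
        description=_make_description(meta),
        resolution=(1e4 / sx, 1e4 / sy),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )
    return path


def read_stack(
    paths: str | Path | Sequence[str | Path],
    spacing_um: tuple[float, float, float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read one multi-channel TIFF, or one single-channel TIFF per channel.

    Integer pixel types are preserved without rescaling.  Spacing must either
    be supplied explicitly or be present in the file's description metadata
    (as written by :func:`write_stack`); there is no silent default.
    """
    if isinstance(paths, (str, Path)):
        path_list = [Path(paths)]
    else:
        path_list = [Path(p) for p in paths]

    volumes: list[np.ndarray] = []
    meta: dict | None = None
    for p in path_list:
        with tifffile.TiffFile(p) as tif:
            arr = tif.asarray()
            this_meta = _parse_description(tif.pages[0].description)
        if meta is None:
            meta = this_meta
        if arr.ndim == 2:
            arr = arr[None]
        volumes.append(arr)

    if len(volumes) == 1:
        arr = volumes[0]
        if meta is not None and "shape" in meta:
            arr = arr.reshape(meta["shape"])
        if arr.ndim == 3:
            arr = arr[None]
        voxels = arr
    else:
        shapes = {v.shape for v in volumes}
        if len(shapes) != 1:
            raise ValueError(
                f"channel files have mismatched shapes: {sorted(shapes)}"
            )
        if any(v.ndim != 3 for v in volumes):
            raise ValueError("per-channel files must each hold a single 3-D volume")
        voxels = np.stack(volumes, axis=0)

    if spacing_um is None:
        if meta is None or "spacing_um" not in meta:
            raise ValueError(
                "voxel spacing not supplied and not present in TIFF metadata; "
                "pass spacing_um explicitly"
            )
        spacing_um = tuple(meta["spacing_um"])
    if channel_names is None:
        if meta is not None and "channel_names" in meta:
            channel_names = meta["channel_names"]
        else:
            channel_names = [f"channel{i}" for i in range(voxels.shape[0])]
    if len(channel_names) != voxels.shape[0]:
        raise ValueError(
            f"{len(channel_names)} channel names for {voxels.shape[0]} channels"
        )
    return ImageStack(voxels=voxels, spacing_um=spacing_um, channel_names=list(channel_names))


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit multi-page TIFF with values {0, 255}."""
    path = Path(path)
    meta = {
        "axes": "ZYX",
        "spacing_um": [mask.spacing_um] * 3,
        "kind": "mask",
        "shape": list(mask.voxels.shape),
    }
    tifffile.imwrite(
        path,
        (mask.voxels.astype(np.uint8) * 255),
        description=_make_description(meta),
        resolution=(1e4 / mask.spacing_um, 1e4 / mask.spacing_um),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )
    return path


def read_mask(path: str | Path, spacing_um: float | None = None) -> BinaryMask:
    """Read a binary mask written by :func:`write_mask` (nonzero = foreground)."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = _parse_description(tif.pages[0].description)
    if arr.ndim == 2:
        arr = arr[None]
    if spacing_um is None:
        if meta is None or "spacing_um" not in meta:
            raise ValueError(
                "voxel spacing not supplied and not present in TIFF metadata"
            )
        spacing = meta["spacing_um"]
        if not np.allclose(spacing, spacing[0]):
            raise ValueError(f"mask spacing must be isotropic; got {spacing}")
        spacing_um = float(spacing[0])
    return BinaryMask(voxels=arr > 0, spacing_um=spacing_um)


#: Columns every cube table must carry; per-channel mean-intensity columns are
#: named ``mean_<channel>`` and positivity columns ``positive_<channel>``.
CUBE_TABLE_REQUIRED_COLUMNS = (
    "gz",
    "gy",
    "gx",
    "occupancy_vox",
    "com_z_um",
    "com_y_um",
    "com_x_um",
)


def write_cube_table(cubes: pd.DataFrame, path: str | Path) -> Path:
    """Write a cube table as CSV with header; >= 6 significant digits survive."""
    _check_cube_schema(cubes)
    path = Path(path)
    cubes.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def read_cube_table(path: str | Path) -> pd.DataFrame:
    """Read a cube table CSV, validating the required schema."""
    cubes = pd.read_csv(path)
    _check_cube_schema(cubes)
    return cubes


def _check_cube_schema(cubes: pd.DataFrame) -> None:
    missing = [c for c in CUBE_TABLE_REQUIRED_COLUMNS if c not in cubes.columns]
    if missing:
        raise ValueError(f"cube table is missing required columns: {missing}")
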