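"""Cube-based quantification of a segmented biofilm volume.

The merged biomass mask is dissected into a non-overlapping grid of cubes
(default side 5 voxels, roughly one to a few micrometres depending on the
voxel size).  Each occupied cube is the unit of measurement: its raw
(unprocessed) per-channel mean fluorescence, its centre of mass, and the
local cell density — the occupied volume fraction inside a ball of 3 um
radius around the centre of mass.  On top of the cube table the module
derives biofilm surface height and roughness maps, z and density profiles,
constitutive-normalized expression ratios, per-channel positivity labels and
TIMER orange/green ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import BinaryMask, ImageStack

__all__ = [
    "Profile",
    "Profile2D",
    "SurfaceMap",
    "dissect",
    "local_density",
    "annotate_local_density",
    "height_map",
    "roughness_map",
    "density_z_profile",
    "normalize_channel",
    "expression_vs_density",
    "expression_z_profile",
    "classify_cubes",
    "timer_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class Profile:
    """Binned 1-D profile: per-bin mean value and count (NaN where empty)."""

    bin_edges: np.ndarray
    values: np.ndarray
    n_per_bin: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class Profile2D:
    """2-D joint histogram (counts) over two binned quantities."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n_total: int


@dataclass
class SurfaceMap:
    """Per-column biofilm height and windowed roughness over the top view.

    ``height_um[y, x]`` is the physical z of the topmost foreground voxel
    centre (NaN where the column holds no biomass); ``roughness_um`` is the
    windowed standard deviation of the height field, filled by
    :func:`roughness_map`.
    """

    height_um: np.ndarray
    spacing_um: float
    roughness_um: np.ndarray | None = None


def _block_sums(volume: np.ndarray, side: int) -> np.ndarray:
    """Sum a 3-D array over a grid of side**3 blocks (zero-padded at far ends)."""
    nz, ny, nx = volume.shape
    pad = [(0, (-n) % side) for n in (nz, ny, nx)]
    v = np.pad(volume, pad, mode="constant", constant_values=0)
    gz, gy, gx = (s // side for s in v.shape)
    return (
        v.reshape(gz, side, gy, side, gx, side)
        .sum(axis=(1, 3, 5))
    )


def dissect(
    mask: BinaryMask,
    raw: ImageStack,
    cube_side_vox: int = 5,
    min_occupancy: int = 1,
) -> pd.DataFrame:
    """Dissect a binary mask into a cube grid and measure raw intensities.

    The grid is anchored at the index origin; partial cubes at the far
    borders are retained with their true voxel counts.  For each cube with
    ``occupancy >= min_occupancy`` the table records the grid index, the
    foreground-voxel count, the centre of mass of the foreground voxels
    (physical um, voxel-centre convention) and, per channel, the mean raw
    intensity over the cube's foreground voxels only — intensity is a
    property of the segmented biomass, not of the empty volume around it.
    """
    if cube_side_vox < 1:
        raise ValueError("cube side must be >= 1 voxel")
    if raw.shape_zyx != mask.voxels.shape:
        raise ValueError(
            f"mask shape {mask.voxels.shape} != raw shape {raw.shape_zyx}"
        )
    if cube_side_vox > max(mask.voxels.shape):
        raise ValueError("cube side exceeds every volume axis")

    side = cube_side_vox
    m = mask.voxels.astype(np.float64)
    occ = _block_sums(m, side)
    keep = occ >= max(min_occupancy, 1)
    gz, gy, gx = np.nonzero(keep)
    occupancy = occ[keep].astype(int)

    s = mask.spacing_um
    nz, ny, nx = mask.voxels.shape
    zc = (np.arange(nz, dtype=np.float64) + 0.5) * s
    yc = (np.arange(ny, dtype=np.float64) + 0.5) * s
    xc = (np.arange(nx, dtype=np.float64) + 0.5) * s
    com = {}
    for name, coords in (
        ("com_z_um", zc[:, None, None]),
        ("com_y_um", yc[None, :, None]),
        ("com_x_um", xc[None, None, :]),
    ):
        sums = _block_sums(m * coords, side)
        com[name] = sums[keep] / occupancy

    data = {
        "gz": gz,
        "gy": gy,
        "gx": gx,
        "occupancy_vox": occupancy,
        **com,
    }
    for ci, ch in enumerate(raw.channel_names):
        sums = _block_sums(m * raw.voxels[ci].astype(np.float64), side)
        data[f"mean_{ch}"] = sums[keep] / occupancy
    return pd.DataFrame(data)


def local_density(
    mask: BinaryMask,
    point_um: tuple[float, float, float],
    radius_um: float = 3.0,
) -> float:
    """Occupied volume fraction inside a ball around a physical point.

    The fraction counts voxel centres within Euclidean distance
    ``radius_um`` of the point; the denominator includes only centres inside
    the image bounds, so densities at the substratum or image edge are not
    systematically underestimated.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    s = mask.spacing_um
    shape = np.asarray(mask.voxels.shape)
    p = np.asarray(point_um, dtype=np.float64)
    if (p < 0).any() or (p > shape * s).any():
        raise ValueError(f"point {tuple(p)} lies outside the volume bounds")
    lo = np.maximum(np.floor((p - radius_um) / s - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((p + radius_um) / s - 0.5).astype(int) + 1, shape)
    zz = (np.arange(lo[0], hi[0]) + 0.5) * s - p[0]
    yy = (np.arange(lo[1], hi[1]) + 0.5) * s - p[1]
    xx = (np.arange(lo[2], hi[2]) + 0.5) * s - p[2]
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    in_ball = d2 <= radius_um**2
    n_total = int(in_ball.sum())
    if n_total == 0:
        return 0.0
    sub = mask.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    n_fg = int((sub & in_ball).sum())
    return n_fg / n_total


def annotate_local_density(
    cubes: pd.DataFrame, mask: BinaryMask, radius_um: float = 3.0
) -> pd.DataFrame:
    """Add a ``local_density`` column (density at each cube's centre of mass)."""
    dens = np.empty(len(cubes))
    pts = cubes[["com_z_um", "com_y_um", "com_x_um"]].to_numpy()
    for i, p in enumerate(pts):
        dens[i] = local_density(mask, tuple(p), radius_um)
    out = cubes.copy()
    out["local_density"] = dens
    return out


def height_map(mask: BinaryMask) -> SurfaceMap:
    """Per (y, x) column, the physical z of the topmost foreground voxel centre.

    z = 0 is the substratum (attachment surface); empty columns are NaN.
    """
    vox = mask.voxels
    nz = vox.shape[0]
    any_fg = vox.any(axis=0)
    # index of topmost foreground voxel: argmax over reversed z
    top_idx = nz - 1 - np.argmax(vox[::-1], axis=0)
    height = (top_idx + 0.5) * mask.spacing_um
    height = np.where(any_fg, height, np.nan)
    return SurfaceMap(height_um=height, spacing_um=mask.spacing_um)


def roughness_map(surface: SurfaceMap, window_px: int = 11) -> SurfaceMap:
    """Windowed standard deviation of the height field (sample SD, ddof=1).

    Roughness is undefined (NaN) wherever the centred window holds fewer than
    two defined heights.  Adding a constant to all heights leaves the map
    unchanged.
    """
    if window_px % 2 == 0 or window_px < 3:
        raise ValueError("window must be odd and >= 3")
    h = surface.height_um
    defined = np.isfinite(h)
    if not defined.any():
        return SurfaceMap(
            height_um=h, spacing_um=surface.spacing_um, roughness_um=np.full_like(h, np.nan)
        )
    # centre on the global mean: SD is shift-invariant and the cancellation
    # in s2 - s1^2/n is far better behaved near zero
    offset = h[defined].mean()
    h0 = np.where(defined, h - offset, 0.0)
    size = (window_px, window_px)
    # truncated windows at the borders: zero padding contributes nothing
    n = ndimage.uniform_filter(defined.astype(np.float64), size=size, mode="constant")
    s1 = ndimage.uniform_filter(h0, size=size, mode="constant")
    s2 = ndimage.uniform_filter(h0 * h0, size=size, mode="constant")
    area = window_px * window_px
    n = np.rint(n * area)
    s1 = s1 * area
    s2 = s2 * area
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1 * s1 / n) / (n - 1)
    var = np.where(n >= 2, np.maximum(var, 0.0), np.nan)
    return SurfaceMap(
        height_um=surface.height_um,
        spacing_um=surface.spacing_um,
        roughness_um=np.sqrt(var),
    )


def density_z_profile(cubes: pd.DataFrame, z_bin_um: float = 2.0) -> Profile:
    """Mean local density of cubes binned by centre-of-mass height."""
    if z_bin_um <= 0:
        raise ValueError("bin width must be positive")
    if "local_density" not in cubes.columns:
        raise ValueError("cubes must be annotated with local_density first")
    if cubes.empty:
        edges = np.array([0.0, z_bin_um])
        return Profile(edges, np.array([np.nan]), np.array([0]))
    z = cubes["com_z_um"].to_numpy()
    n_bins = max(int(np.ceil(z.max() / z_bin_um)), 1)
    edges = np.arange(n_bins + 1) * z_bin_um
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=cubes["local_density"].to_numpy(), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Profile(edges, values, counts)


def normalize_channel(
    cubes: pd.DataFrame,
    channel: str,
    reference: str,
    floor: float = 0.0,
) -> pd.Series:
    """Per-cube ratio of a reporter to a reference (constitutive) channel.

    Cubes whose reference intensity is at or below ``floor`` are excluded and
    the exclusion count is logged.  The returned Series is indexed by the
    surviving cube rows.
    """
    for name in (channel, reference):
        if f"mean_{name}" not in cubes.columns:
            raise KeyError(f"channel {name!r} not measured in this cube table")
    ref = cubes[f"mean_{reference}"]
    keep = ref > floor
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "normalize_channel(%s/%s): excluded %d cubes with reference <= %g",
            channel,
            reference,
            n_excluded,
            floor,
        )
    return cubes.loc[keep, f"mean_{channel}"] / ref[keep]


def _hist2d(x: np.ndarray, y: np.ndarray, x_bins, y_bins) -> Profile2D:
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=[x_bins, y_bins])
    return Profile2D(x_edges=x_edges, y_edges=y_edges, counts=counts, n_total=len(x))


def expression_vs_density(
    cubes: pd.DataFrame,
    channel: str,
    reference: str,
    density_bins=20,
    value_bins=20,
    floor: float = 0.0,
) -> Profile2D:
    """Joint histogram of (local density, normalized expression) over cubes."""
    if cubes.empty:
        raise ValueError("empty cube table")
    ratio = normalize_channel(cubes, channel, reference, floor=floor)
    dens = cubes.loc[ratio.index, "local_density"].to_numpy()
    return _hist2d(dens, ratio.to_numpy(), density_bins, value_bins)


def expression_z_profile(
    cubes: pd.DataFrame,
    channel: str,
    reference: str,
    z_bins=20,
    value_bins=20,
    floor: float = 0.0,
) -> Profile2D:
    """Joint histogram of (height, normalized expression) over cubes."""
    if cubes.empty:
        raise ValueError("empty cube table")
    ratio = normalize_channel(cubes, channel, reference, floor=floor)
    z = cubes.loc[ratio.index, "com_z_um"].to_numpy()
    return _hist2d(z, ratio.to_numpy(), z_bins, value_bins)


def classify_cubes(
    cubes: pd.DataFrame,
    per_channel_masks: dict[str, BinaryMask],
    cube_side_vox: int = 5,
    min_overlap_vox: int = 1,
) -> pd.DataFrame:
    """Label each cube positive for every channel whose individual mask it overlaps.

    A cube is positive for a channel iff at least ``min_overlap_vox`` of its
    voxels are foreground in that channel's pre-merge mask; cubes may be
    positive for zero, one or several channels.  Adds one boolean
    ``positive_<channel>`` column per mask.
    """
    out = cubes.copy()
    shapes = {m.voxels.shape for m in per_channel_masks.values()}
    if len(shapes) > 1:
        raise ValueError(f"per-channel mask shapes differ: {sorted(shapes)}")
    for ch, mask in per_channel_masks.items():
        overlap = _block_sums(mask.voxels.astype(np.float64), cube_side_vox)
        idx = (cubes["gz"].to_numpy(), cubes["gy"].to_numpy(), cubes["gx"].to_numpy())
        if (idx[0].size and (
            idx[0].max() >= overlap.shape[0]
            or idx[1].max() >= overlap.shape[1]
            or idx[2].max() >= overlap.shape[2]
        )):
            raise ValueError(
                f"cube grid indices exceed mask {ch!r} cube grid "
                f"{overlap.shape}; shape mismatch with the dissected mask"
            )
        out[f"positive_{ch}"] = overlap[idx] >= min_overlap_vox
    return out


def timer_ratio(
    cubes: pd.DataFrame,
    orange: str = "timer_orange",
    green: str = "timer_green",
    floor: float = 0.0,
) -> pd.Series:
    """Per-cube TIMER orange/green intensity ratio (growth-rate readout).

    Slowly growing cells accumulate the slow-maturing orange form, so higher
    ratios indicate slower growth.  Cubes with green intensity at or below
    ``floor`` are excluded and logged, as in :func:`normalize_channel`.
    """
    return normalize_channel(cubes, orange, green, floor=floor)
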