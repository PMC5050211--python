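"""Preprocessing and segmentation of confocal stacks.

The chain mirrors standard volumetric biofilm processing: the stack is first
up-sampled along z to isotropic voxels, denoised with a small averaging
(box) filter, then segmented per channel by 3-class Otsu thresholding on a
256-bin histogram of the full volume.  Class 1 is background; classes 2 and 3
together form the biomass foreground.  In dual-reporter mode each channel is
segmented individually and the masks are merged (voxelwise union) before the
volume is dissected into cubes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, ImageStack

__all__ = [
    "OtsuResult",
    "DegenerateHistogramError",
    "upsample_to_isotropic",
    "smooth",
    "otsu_thresholds",
    "otsu3_thresholds",
    "segment",
    "merge_masks",
]


class DegenerateHistogramError(ValueError):
    """Raised when a volume has too few distinct values to threshold."""


@dataclass(frozen=True)
class OtsuResult:
    """Thresholds maximizing between-class variance for a 3-class split.

    ``t1 < t2`` are upper bin edges: class 1 is ``value <= t1``, class 2 is
    ``t1 < value <= t2``, class 3 is ``value > t2``.
    """

    t1: float
    t2: float
    class_counts: tuple[int, int, int]
    between_class_variance: float


def upsample_to_isotropic(stack: ImageStack) -> ImageStack:
    """Resample the z axis so all voxel side lengths equal the y/x spacing.

    Linear interpolation between voxel centres; the physical extent of the
    volume is preserved to within one output voxel.  Already-isotropic input
    is returned unchanged.
    """
    sz, sy, sx = stack.spacing_um
    if not np.isclose(sy, sx):
        raise ValueError(
            f"unsupported geometry: y and x spacings differ ({sy} vs {sx} um)"
        )
    if np.isclose(sz, sy):
        return stack
    target = sy
    nz = stack.voxels.shape[1]
    nz_out = int(round(nz * sz / target))
    # start-aligned resampling: output slice j interpolates the input at
    # fractional index j * target / sz (standard zoom convention), so a
    # slice inserted midway between two input planes is their exact mean
    frac_idx = np.arange(nz_out) * (target / sz)
    frac_idx = np.clip(frac_idx, 0.0, nz - 1.0)
    lo = np.floor(frac_idx).astype(int)
    hi = np.minimum(lo + 1, nz - 1)
    w = (frac_idx - lo)[None, :, None, None]
    vox = stack.voxels.astype(np.float64)
    out = vox[:, lo] * (1.0 - w) + vox[:, hi] * w
    return ImageStack(
        voxels=out,
        spacing_um=(target, sy, sx),
        channel_names=list(stack.channel_names),
    )


def smooth(stack: ImageStack, kernel_radius_vox: int = 1) -> ImageStack:
    """Reduce noise with a uniform (box) mean filter of side ``2r + 1``.

    Reflect padding at the borders avoids darkening at the substratum plane
    where the biofilm touches the image edge.
    """
    if kernel_radius_vox < 0:
        raise ValueError("kernel radius must be >= 0")
    if kernel_radius_vox == 0:
        return stack
    size = 2 * kernel_radius_vox + 1
    out = np.empty(stack.voxels.shape, dtype=np.float64)
    for c in range(stack.voxels.shape[0]):
        ndimage.uniform_filter(
            stack.voxels[c].astype(np.float64), size=size, mode="reflect", output=out[c]
        )
    return ImageStack(
        voxels=out, spacing_um=stack.spacing_um, channel_names=list(stack.channel_names)
    )


def _class_stats(counts: np.ndarray, centers: np.ndarray):
    """Cumulative weight and first moment used by the Otsu maximizer."""
    w = counts / counts.sum()
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cm = np.concatenate([[0.0], np.cumsum(w * centers)])
    return cw, cm


def otsu_thresholds(
    counts: np.ndarray,
    bin_edges: np.ndarray,
    classes: int = 3,
) -> OtsuResult | float:
    """Maximize between-class variance for a 2- or 3-class split of a histogram.

    Thresholds are upper bin edges of the lower classes.  Exhaustive search
    over all admissible boundary pairs; ties broken toward the
    lexicographically smallest thresholds.  For ``classes == 2`` a single
    float threshold is returned.
    """
    counts = np.asarray(counts, dtype=np.float64)
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if classes not in (2, 3):
        raise ValueError("only 2- or 3-class splits are supported")
    nonempty = int((counts > 0).sum())
    if nonempty < classes:
        raise DegenerateHistogramError(
            f"histogram has only {nonempty} nonempty bins; need >= {classes}"
        )
    nbins = counts.size
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    cw, cm = _class_stats(counts, centers)
    mu_total = cm[-1]

    def seg_var(a: int, b: int) -> float:
        # between-class contribution w * mu^2 of bins [a, b)
        w = cw[b] - cw[a]
        if w <= 0:
            return 0.0
        m = cm[b] - cm[a]
        return m * m / w

    if classes == 2:
        best = (-np.inf, None)
        for k in range(nbins - 1):
            v = seg_var(0, k + 1) + seg_var(k + 1, nbins)
            if v > best[0]:
                best = (v, k)
        return float(bin_edges[best[1] + 1])

    best_v = -np.inf
    best_pair: tuple[int, int] | None = None
    # boundaries after bins k1 and k2, 0 <= k1 < k2 <= nbins - 2
    for k1 in range(nbins - 2):
        v1 = seg_var(0, k1 + 1)
        for k2 in range(k1 + 1, nbins - 1):
            v = v1 + seg_var(k1 + 1, k2 + 1) + seg_var(k2 + 1, nbins)
            if v > best_v:
                best_v = v
                best_pair = (k1, k2)
    assert best_pair is not None
    k1, k2 = best_pair
    t1 = float(bin_edges[k1 + 1])
    t2 = float(bin_edges[k2 + 1])
    n = counts
    c1 = int(round(n[: k1 + 1].sum()))
    c2 = int(round(n[k1 + 1 : k2 + 1].sum()))
    c3 = int(round(n[k2 + 1 :].sum()))
    return OtsuResult(
        t1=t1,
        t2=t2,
        class_counts=(c1, c2, c3),
        between_class_variance=float(best_v - mu_total * mu_total),
    )


def otsu3_thresholds(counts: np.ndarray, bin_edges: np.ndarray) -> OtsuResult:
    """3-class Otsu thresholds of a histogram (see :func:`otsu_thresholds`)."""
    result = otsu_thresholds(counts, bin_edges, classes=3)
    assert isinstance(result, OtsuResult)
    return result


def segment(
    stack: ImageStack,
    channel: str,
    n_bins: int = 256,
) -> tuple[BinaryMask, OtsuResult]:
    """Segment one channel: 3-class Otsu, classes 2 + 3 as foreground.

    Thresholds are computed on a ``n_bins``-bin histogram over the observed
    min-max of the full volume.  The caller is expected to have up-sampled
    and smoothed the stack; a warning is emitted if the spacing is still
    anisotropic.  Volumes with fewer than 3 distinct values raise
    :class:`DegenerateHistogramError` rather than silently thresholding.
    """
    vol = stack.channel(channel)
    if not stack.is_isotropic:
        warnings.warn(
            f"segmenting an anisotropic stack (spacing {stack.spacing_um}); "
            "run upsample_to_isotropic first",
            stacklevel=2,
        )
    vmin = float(vol.min())
    vmax = float(vol.max())
    n_distinct = len(np.unique(vol)) if vol.size <= 4_000_000 else 3
    if vmax <= vmin or n_distinct < 3:
        raise DegenerateHistogramError(
            f"channel {channel!r} has fewer than 3 distinct values; "
            "cannot form 3 classes"
        )
    counts, edges = np.histogram(vol, bins=n_bins, range=(vmin, vmax))
    result = otsu3_thresholds(counts, edges)
    mask = vol > result.t1
    return BinaryMask(voxels=mask, spacing_um=stack.spacing_um[1]), result


def merge_masks(masks: list[BinaryMask]) -> BinaryMask:
    """Voxelwise union of per-channel masks (equal shapes and spacings)."""
    if not masks:
        raise ValueError("no masks to merge")
    shapes = {m.voxels.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")
    spacings = {m.spacing_um for m in masks}
    if len(spacings) != 1 and not np.allclose(list(spacings), masks[0].spacing_um):
        raise ValueError(f"mask spacings differ: {sorted(spacings)}")
    union = reduce(np.logical_or, (m.voxels for m in masks))
    return BinaryMask(voxels=union, spacing_um=masks[0].spacing_um)
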