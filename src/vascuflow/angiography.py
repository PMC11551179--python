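"""Angiogram computation from repeated B-scans, and vessel segmentation.

The angiogram estimator is complex inter-repeat decorrelation: after
correcting each repeat pair for a global bulk phase (tissue motion), the
mean magnitude of consecutive complex differences is taken per voxel.
Moving blood decorrelates between repeats and lights up; static tissue
cancels.

Segmentation here is a thresholding baseline (adaptive threshold, small
component removal, morphological closing).  Deep-learning masks produced
elsewhere are consumed through the same :class:`SegmentationMask` type,
receiving only the closing step.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import ball, closing, remove_small_objects

from .octsim import BScanSeries
from .volumes import AngiogramVolume, SegmentationMask, VoxelGrid

__all__ = ["compute_angiogram", "segment_vessels"]


def compute_angiogram(series: BScanSeries, grid: VoxelGrid | None = None) -> AngiogramVolume:
    """Inter-repeat decorrelation contrast from a repeated B-scan series."""
    data = np.asarray(series.data)
    n_rep = data.shape[0]
    if n_rep < 2:
        raise ValueError("angiography needs at least 2 repeated B-scans")
    if grid is None:
        grid = VoxelGrid(shape=data.shape[1:], voxel_size=series.protocol.pixel_size)
    acc = np.zeros(data.shape[1:], dtype=np.float64)
    for r in range(n_rep - 1):
        a, b = data[r], data[r + 1]
        # bulk-phase correction: global phase maximizing <a, b e^{i phi}>
        phi = np.angle(np.vdot(b, a))
        acc += np.abs(a - b * np.exp(1j * phi))
    acc /= n_rep - 1
    return AngiogramVolume(data=acc.astype(np.float32), grid=grid)


def segment_vessels(
    angio: AngiogramVolume,
    threshold: float | None = None,
    min_size: int = 27,
    closing_radius: int = 1,
    external_mask: SegmentationMask | None = None,
) -> SegmentationMask:
    """Binary vessel mask from an angiogram (thresholding baseline).

    ``threshold=None`` uses Otsu's threshold on the angiogram intensities.
    Raising the threshold never grows the foreground.  When an
    ``external_mask`` is supplied (e.g. a released deep-learning
    segmentation) it bypasses thresholding and receives only the
    morphological closing pass.
    """
    if external_mask is not None:
        closed = _close(external_mask.data, closing_radius)
        return SegmentationMask(closed, external_mask.grid, provenance="external")

    a = np.asarray(angio.data)
    if not np.all(np.isfinite(a)):
        raise ValueError("angiogram must be finite")
    if threshold is None:
        if np.ptp(a) == 0:
            threshold = np.inf  # featureless angiogram has no foreground
        else:
            threshold = float(threshold_otsu(a))
    fg = a > threshold
    if min_size > 1 and fg.any():
        fg = remove_small_objects(fg, max_size=min_size - 1)
    fg = _close(fg, closing_radius)
    if not fg.any():
        warnings.warn("segmentation produced an empty mask", stacklevel=2)
    return SegmentationMask(fg, angio.grid, provenance="internal-threshold")


def _close(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius < 1:
        return mask.copy()
    # pad so closing is not clipped at the volume faces
    pad = radius + 1
    padded = np.pad(mask, pad)
    closed = closing(padded, ball(radius))
    sl = (slice(pad, -pad),) * mask.ndim
    return closed[sl]


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap between two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
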