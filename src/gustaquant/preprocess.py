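"""Image conditioning: rolling-ball background subtraction, median
filtering, and Otsu binarization on the pooled stack histogram.

The chain mirrors the standard ImageJ recipe for confocal stacks of
immunolabeled tissue — ``Subtract Background`` (rolling ball, 50 px),
``Median`` (radius 2), ``Auto Threshold`` (Otsu, stack histogram) — with
every convention pinned down so results are bit-reproducible:

* the rolling ball is a per-slice grey-scale morphological opening with a
  ball-shaped (non-flat) structuring element; the opening is the background
  estimate and is subtracted from the slice;
* the median filter acts per slice over a disk neighbourhood with
  reflective edge handling;
* the Otsu threshold is computed once from the histogram pooled over all
  z-slices of a channel, the smallest threshold attaining the maximal
  between-class variance wins ties, and foreground is strictly greater
  than the threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import BinaryMask, ImageStack

__all__ = [
    "ball_structuring_element",
    "disk_footprint",
    "subtract_background",
    "median_filter",
    "otsu_threshold_value",
    "otsu_binarize",
    "binarize_channel",
]


def ball_structuring_element(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height map of a ball of given radius.

    Returns the boolean disk footprint and the (non-positive) structuring
    heights ``sqrt(r^2 - d^2) - r`` used for the grey-scale opening; the
    vertical offset of the heights is immaterial to the opening.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    footprint = d2 <= r**2
    heights = np.zeros_like(d2, dtype=float)
    heights[footprint] = np.sqrt(r**2 - d2[footprint]) - r
    return footprint, heights


def disk_footprint(radius_px: int) -> np.ndarray:
    """Boolean disk ``x^2 + y^2 <= r^2`` used by the median filter."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy**2 + xx**2 <= r**2


def _ball_opening(volume: np.ndarray, radius_px: int) -> np.ndarray:
    """Grey-scale opening of each z-slice by the ball structuring element.

    Exact erosion-then-dilation with the non-flat ball heights and
    reflective edge handling, computed as a shift-and-reduce over the
    footprint offsets with all slices batched (the per-slice result is
    identical to looping slices independently).
    """
    r = int(radius_px)
    footprint, heights = ball_structuring_element(r)
    heights = heights + r  # apex r; vertical offset cancels in the opening
    offs = np.argwhere(footprint)
    offsets = [(int(dy) - r, int(dx) - r, float(heights[dy, dx])) for dy, dx in offs]

    vol = volume.astype(float)
    _, ny, nx = vol.shape

    def _reduce(arr: np.ndarray, erode: bool) -> np.ndarray:
        padded = np.pad(arr, ((0, 0), (r, r), (r, r)), mode="symmetric")
        out = np.full_like(arr, np.inf if erode else -np.inf)
        for dy, dx, h in offsets:
            if erode:
                view = padded[:, r + dy : r + dy + ny, r + dx : r + dx + nx]
                np.minimum(out, view - h, out=out)
            else:
                view = padded[:, r - dy : r - dy + ny, r - dx : r - dx + nx]
                np.maximum(out, view + h, out=out)
        return out

    eroded = _reduce(vol, erode=True)
    return _reduce(eroded, erode=False)


def subtract_background(stack: ImageStack, radius_px: int = 50) -> ImageStack:
    """Rolling-ball background subtraction, per channel and per z-slice.

    The background is the grey-scale opening of each slice by a ball of
    ``radius_px``; the result is the top-hat ``slice - background``, which
    is non-negative and voxelwise no larger than the input.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    _, _, ny, nx = stack.voxels.shape
    if radius_px > ny and radius_px > nx:
        raise ValueError(
            f"rolling-ball radius {radius_px} exceeds both in-plane "
            f"dimensions ({ny} x {nx})"
        )
    out = np.empty_like(stack.voxels, dtype=float)
    for c in range(stack.n_channels):
        vol = stack.voxels[c].astype(float)
        background = _ball_opening(vol, radius_px)
        out[c] = np.clip(vol - background, 0.0, None)
    if np.issubdtype(stack.voxels.dtype, np.integer):
        out = np.rint(out).astype(stack.voxels.dtype)
    return stack.with_voxels(out)


def median_filter(stack: ImageStack, radius_px: int = 2) -> ImageStack:
    """Per-slice 2D median over a disk neighbourhood, reflective edges."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    footprint = disk_footprint(radius_px)
    out = np.empty_like(stack.voxels)
    for c in range(stack.n_channels):
        for z in range(stack.voxels.shape[1]):
            out[c, z] = ndimage.median_filter(
                stack.voxels[c, z], footprint=footprint, mode="reflect"
            )
    return stack.with_voxels(out)


def _histogram_edges(data: np.ndarray, bit_depth: int, n_bins: int) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        # span the declared bit-depth range; width 1 grey level at n_bins=2**bd
        return np.linspace(0.0, float(2**bit_depth), n_bins + 1)
    return np.linspace(float(data.min()), float(data.max()), n_bins + 1)


def otsu_threshold_value(
    data: np.ndarray, bit_depth: int = 8, n_bins: int = 256
) -> float:
    """Otsu threshold of a pooled histogram.

    Every boundary between two consecutive occupied-range bins is a
    candidate; the between-class variance ``w0*w1*(mu0 - mu1)^2`` over bin
    centres is maximized and ties break toward the smallest candidate.
    For integer data the returned value is the largest grey level of the
    background class, so ``data > threshold`` reproduces the bin split
    exactly; for float data it is the winning bin's upper edge. Raises on
    constant input (no threshold separates anything).
    """
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError("cannot threshold empty data")
    if float(data.min()) == float(data.max()):
        raise ValueError("channel is constant: no Otsu threshold exists")
    edges = _histogram_edges(data, bit_depth, n_bins)
    counts, _ = np.histogram(data.ravel(), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = counts.astype(float)
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    mu_total = (counts * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (mu_total - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    best = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer
    if np.issubdtype(data.dtype, np.integer):
        # highest integer in the background class (one below the next edge)
        return float(np.ceil(edges[best + 1]) - 1.0)
    return float(edges[best + 1])


def otsu_binarize(
    stack: ImageStack, channel: str, n_bins: int = 256
) -> BinaryMask:
    """Binarize one channel with a single stack-histogram Otsu threshold.

    The histogram pools all z-slices, so the threshold is invariant to any
    permutation of slice order; foreground is strictly above threshold.
    """
    data = stack.channel(channel)
    t = otsu_threshold_value(data, bit_depth=stack.bit_depth, n_bins=n_bins)
    mask = data > t
    return BinaryMask(
        voxels=mask,
        source_channel=channel,
        threshold=t,
        voxel_size=stack.voxel_size,
        provenance={"method": "otsu_stack_histogram", "n_bins": n_bins},
    )


def binarize_channel(
    stack: ImageStack,
    channel: str,
    background_radius_px: int = 50,
    median_radius_px: int = 2,
    n_bins: int = 256,
) -> BinaryMask:
    """Full conditioning chain for one channel.

    Applies, in the fixed order, rolling-ball background subtraction,
    median filtering, and stack-histogram Otsu binarization; the mask's
    provenance records every parameter.
    """
    single = ImageStack(
        stack.channel(channel)[None],
        stack.voxel_size,
        (channel,),
        stack.bit_depth,
    )
    sub = subtract_background(single, radius_px=background_radius_px)
    med = median_filter(sub, radius_px=median_radius_px)
    mask = otsu_binarize(med, channel, n_bins=n_bins)
    mask.provenance.update(
        {
            "background_radius_px": background_radius_px,
            "median_radius_px": median_radius_px,
            "pipeline": "subtract_background>median_filter>otsu_binarize",
        }
    )
    return mask
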