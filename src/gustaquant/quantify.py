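"""Per-taste-bud volumetric measurements.

Three quantities drive the group comparisons:

* **innervation density** ``D`` — the fraction of a taste-bud ROI's voxels
  positive for a nerve-fiber marker (labeled volume / total volume,
  pooled over all optical sections the ROI spans);
* **colocalization fraction** ``F`` — of the fiber voxels positive for a
  pan-innervation marker (e.g. P2X3) inside the bud, the fraction also
  positive for a second marker (e.g. a 5-HT3A-GFP reporter):
  ``F = |A ∩ B ∩ ROI| / |B ∩ ROI|``;
* **cell-profile counts** — marker-positive profiles with a nucleus,
  counted on single planes drawn from the lower, middle and upper
  quadrants of each bud's z-extent.

All fractions are computed on voxel counts (units cancel); volumes are
also reported in µm³ from the anisotropic voxel size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import BinaryMask, ImageStack, ROISet
from . import preprocess

__all__ = [
    "innervation_density",
    "coloc_fraction",
    "quadrant_planes",
    "count_profiles",
]


def _check_geometry(mask: BinaryMask, rois: ROISet) -> None:
    if mask.shape != rois.labels.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match ROI shape "
            f"{rois.labels.shape}"
        )
    if tuple(mask.voxel_size) != tuple(rois.voxel_size):
        raise ValueError("mask and ROI voxel sizes differ")


def innervation_density(mask: BinaryMask, rois: ROISet) -> pd.DataFrame:
    """Labeled-volume fraction per bud, with per-section records.

    Returns one row per bud with columns ``bud``, ``label``, ``channel``,
    ``total_voxels``, ``labeled_voxels``, ``total_um3``, ``labeled_um3``
    and ``density`` (labeled/total), plus a ``sections`` column holding a
    per-optical-section table (z, area, labeled area, mean of the mask).
    """
    _check_geometry(mask, rois)
    vol = np.prod(mask.voxel_size)
    rows = []
    for label in rois.region_labels:
        region = rois.mask_for(label)
        n_total = int(region.sum())
        if n_total == 0:  # unreachable by ROISet contract, kept defensive
            raise ValueError(f"ROI {rois.names[label]!r} is empty")
        inside = mask.voxels & region
        n_pos = int(inside.sum())
        zs = np.unique(np.nonzero(region)[0])
        sections = pd.DataFrame(
            {
                "z": zs,
                "area_voxels": [int(region[z].sum()) for z in zs],
                "labeled_voxels": [int(inside[z].sum()) for z in zs],
            }
        )
        sections["mean_labeled"] = (
            sections["labeled_voxels"] / sections["area_voxels"]
        )
        rows.append(
            {
                "bud": rois.names[label],
                "label": label,
                "channel": mask.source_channel,
                "total_voxels": n_total,
                "labeled_voxels": n_pos,
                "total_um3": n_total * vol,
                "labeled_um3": n_pos * vol,
                "density": n_pos / n_total,
                "sections": sections,
            }
        )
    return pd.DataFrame(rows)


def coloc_fraction(
    mask_a: BinaryMask, mask_b: BinaryMask, rois: ROISet
) -> pd.DataFrame:
    """Two-channel co-occupancy per bud: ``F = |A∩B∩ROI| / |B∩ROI|``.

    ``mask_a`` is the reporter channel (numerator restriction), ``mask_b``
    the reference fiber channel (denominator). Buds with no reference
    voxels get ``F = NaN`` with ``undefined = True`` — never a silent 0.
    Also reports ``|A∩ROI|``, ``|B∩ROI|`` and ``|(A∪B)∩ROI|``.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share shape")
    _check_geometry(mask_b, rois)
    rows = []
    for label in rois.region_labels:
        region = rois.mask_for(label)
        a = mask_a.voxels & region
        b = mask_b.voxels & region
        n_b = int(b.sum())
        n_ab = int((a & b).sum())
        rows.append(
            {
                "bud": rois.names[label],
                "label": label,
                "a_voxels": int(a.sum()),
                "b_voxels": n_b,
                "ab_voxels": n_ab,
                "union_voxels": int((a | b).sum()),
                "fraction": (n_ab / n_b) if n_b else np.nan,
                "undefined": n_b == 0,
            }
        )
    return pd.DataFrame(rows)


def quadrant_planes(z_indices: np.ndarray) -> tuple[int, int, int]:
    """Planes at the 25/50/75 % depth quantiles of a bud's z-extent.

    Quantile positions are floor-rounded onto the bud's own z-planes.
    """
    zs = np.sort(np.unique(z_indices))
    if len(zs) < 3:
        raise ValueError("ROI must span at least 3 z-planes")
    picks = tuple(zs[int(np.floor(q * (len(zs) - 1)))] for q in (0.25, 0.5, 0.75))
    return picks


def count_profiles(
    stack: ImageStack,
    rois: ROISet,
    marker_channel: str,
    nucleus_channel: str,
    min_area_px: int = 20,
    background_radius_px: int = 50,
    median_radius_px: int = 2,
) -> pd.DataFrame:
    """Count marker-positive cell profiles with a nucleus on quadrant planes.

    For each bud, single planes at 25/50/75 % of the z-extent are
    extracted; on each, connected components (8-connectivity) of the
    binarized marker channel inside the ROI with area ≥ ``min_area_px``
    and at least one nucleus-positive pixel count as one cell profile.
    Sampling a plane per quadrant avoids re-counting cells that persist
    through consecutive optical sections.

    Returns one row per bud per sampled plane plus the per-bud total in
    ``total`` (repeated on each row for convenience).
    """
    def _binarize_or_empty(channel: str) -> np.ndarray:
        try:
            return preprocess.binarize_channel(
                stack,
                channel,
                background_radius_px=background_radius_px,
                median_radius_px=median_radius_px,
            ).voxels
        except ValueError as err:
            if "constant" not in str(err):
                raise
            # constant (signal-free) channel: nothing to count
            return np.zeros(stack.shape_zyx, dtype=bool)

    marker = _binarize_or_empty(marker_channel)
    nucleus = _binarize_or_empty(nucleus_channel)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity in-plane
    rows = []
    for label in rois.region_labels:
        region = rois.mask_for(label)
        zs = np.nonzero(region)[0]
        planes = quadrant_planes(zs)
        counts = []
        for quadrant, z in zip(("lower", "middle", "upper"), planes):
            roi2d = region[z]
            marker2d = marker[z] & roi2d
            nuc2d = nucleus[z] & roi2d
            labeled, n_comp = ndimage.label(marker2d, structure=structure)
            n_profiles = 0
            for comp in range(1, n_comp + 1):
                comp_mask = labeled == comp
                if comp_mask.sum() < min_area_px:
                    continue
                if (comp_mask & nuc2d).any():
                    n_profiles += 1
            counts.append(n_profiles)
            rows.append(
                {
                    "bud": rois.names[label],
                    "label": label,
                    "quadrant": quadrant,
                    "z": int(z),
                    "count": n_profiles,
                }
            )
        for row in rows[-3:]:
            row["total"] = int(sum(counts))
    return pd.DataFrame(rows)
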