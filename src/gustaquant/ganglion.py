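"""Geniculate-ganglion cell scoring.

Whole-mount ganglia are imaged at ~1 µm axial spacing; the analysis works
on maximal z-projections of 10 µm substacks. Per cell ROI and channel the
mean fluorescence is measured, background-subtracted and normalized per
image, and cells are called positive or negative against a per-channel
threshold derived from the intensity histogram: a 1- vs 2-component
Gaussian mixture is fitted (EM, k-means initialization, fixed seed),
modality chosen by BIC, and for a bimodal histogram the threshold is any
value more than 2 SD above the median of the lower peak's assigned
values. Marker-combination proportions are then tabulated per group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .datatypes import ImageStack, ROISet, ThresholdModel

__all__ = [
    "project_substacks",
    "measure_cells",
    "normalize_intensities",
    "determine_threshold",
    "score_cells",
]


def project_substacks(stack: ImageStack, thickness_um: float = 10.0) -> list[ImageStack]:
    """Maximal z-projections of consecutive non-overlapping substacks.

    Substacks are ``ceil(thickness / z_step)`` slices thick; a trailing
    remainder of at least half the substack thickness becomes its own
    substack, a shorter one merges into the previous substack. Each
    projection is returned as a single-slice ImageStack.
    """
    z_step = stack.voxel_size[2]
    nz = stack.voxels.shape[1]
    if thickness_um < z_step:
        raise ValueError("substack thickness must cover at least one slice")
    per = int(np.ceil(thickness_um / z_step))
    if nz < 1:
        raise ValueError("stack has no slices")
    n_full = nz // per
    remainder = nz - n_full * per
    bounds: list[tuple[int, int]] = [(i * per, (i + 1) * per) for i in range(n_full)]
    if remainder:
        if remainder >= per / 2 or not bounds:
            bounds.append((n_full * per, nz))
        else:
            start, _ = bounds[-1]
            bounds[-1] = (start, nz)
    projections = []
    for start, stop in bounds:
        proj = stack.voxels[:, start:stop].max(axis=1, keepdims=True)
        projections.append(
            ImageStack(proj, stack.voxel_size, stack.channel_names, stack.bit_depth)
        )
    return projections


def measure_cells(projection: ImageStack, cell_rois: ROISet) -> pd.DataFrame:
    """Mean intensity per cell ROI and channel on one projection.

    Returns one row per cell with a ``mean_<channel>`` column per channel.
    """
    if cell_rois.labels.shape != projection.shape_zyx:
        raise ValueError("cell ROIs must match the projection geometry")
    rows = []
    for label in cell_rois.region_labels:
        region = cell_rois.mask_for(label)
        row = {"cell": cell_rois.names[label], "label": label}
        for name in projection.channel_names:
            row[f"mean_{name}"] = float(projection.channel(name)[region].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_intensities(
    table: pd.DataFrame,
    projection: ImageStack,
    cell_rois: ROISet,
    percentile: float = 99.0,
) -> pd.DataFrame:
    """Background-subtract and normalize cell intensities per image.

    Per channel: the background is the median of all non-ROI pixels of
    the projection; it is subtracted from each cell's mean (clipped at
    0), and the result is divided by the ``percentile``-th percentile of
    the background-subtracted cell values of that image. The constants
    used are recorded as DataFrame attrs. Multiplying every pixel by a
    positive constant leaves the normalized values unchanged.
    """
    outside = cell_rois.labels == 0
    out = table.copy()
    constants = {}
    for name in projection.channel_names:
        background = float(np.median(projection.channel(name)[outside]))
        shifted = np.clip(out[f"mean_{name}"].to_numpy() - background, 0.0, None)
        scale = float(np.percentile(shifted, percentile))
        if scale == 0:
            raise ValueError(
                f"channel {name!r} is blank after background subtraction"
            )
        out[f"norm_{name}"] = shifted / scale
        constants[name] = {"background": background, "scale": scale}
    out.attrs["normalization"] = constants
    return out


def determine_threshold(
    values,
    channel: str,
    seed: int = 0,
    use_fitted_sigma: bool = False,
    max_iter: int = 500,
) -> ThresholdModel:
    """Positivity threshold for one channel from normalized intensities.

    Fits 1- and 2-component Gaussian mixtures (EM with k-means
    initialization, deterministic given ``seed``) and keeps the lower-BIC
    model. Bimodal: each value is assigned to its maximum-responsibility
    component and ``T = median + 2·SD`` of the lower component's values
    (or of its fitted sigma with ``use_fitted_sigma``). Unimodal: ``T =
    mean + 2·SD`` of the single fit, flagged as extrapolated since the
    rule is designed for separated peaks.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ValueError("need at least 20 intensity values to fit")
    if np.ptp(x) == 0.0:
        v = float(x[0, 0])
        return ThresholdModel(
            channel=channel,
            modality="unimodal",
            weights=(1.0,),
            means=(v,),
            sds=(0.0,),
            lower_median=v,
            lower_sd=0.0,
            threshold=v,
            extrapolated=True,
            n_values=x.shape[0],
        )

    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            init_params="kmeans",
            n_init=1,
            max_iter=max_iter,
            random_state=seed,
        ).fit(x)
        if not gm.converged_:
            raise RuntimeError(
                f"EM did not converge for {channel!r} with {k} component(s) "
                f"after {max_iter} iterations (lower bound "
                f"{gm.lower_bound_:.4g})"
            )
        fits[k] = (gm, gm.bic(x))

    modality = "bimodal" if fits[2][1] < fits[1][1] else "unimodal"
    gm = fits[2][0] if modality == "bimodal" else fits[1][0]
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(gm.covariances_.ravel()[i])) for i in order)
    weights = tuple(float(gm.weights_[i]) for i in order)

    if modality == "bimodal":
        assign = gm.predict(x)
        lower_comp = order[0]
        lower_vals = x[assign == lower_comp, 0]
        if lower_vals.size == 0:  # degenerate fit: fall back to smaller mean
            lower_vals = np.array([means[0]])
        m_low = float(np.median(lower_vals))
        s_low = float(sds[0]) if use_fitted_sigma else float(
            np.std(lower_vals, ddof=1) if lower_vals.size > 1 else 0.0
        )
        threshold = m_low + 2.0 * s_low
        extrapolated = False
    else:
        m_low = means[0]
        s_low = sds[0]
        threshold = m_low + 2.0 * s_low
        extrapolated = True

    return ThresholdModel(
        channel=channel,
        modality=modality,
        weights=weights,
        means=means,
        sds=sds,
        lower_median=m_low,
        lower_sd=s_low,
        threshold=threshold,
        extrapolated=extrapolated,
        n_values=x.shape[0],
    )


def score_cells(
    table: pd.DataFrame,
    models: dict[str, ThresholdModel],
    group_column: str | None = None,
    channels: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-channel thresholds and tabulate label combinations.

    Positivity is strict: ``normalized intensity > T`` (a cell exactly at
    threshold is negative). ``channels`` defaults to every normalized
    channel in the table, each of which must then have a model. Returns
    the scored table (``pos_<channel>`` flags and a ``combination``
    string like ``"GFP+P2X3-"``) and a summary with percent positive per
    channel and percent of cells per combination, split by
    ``group_column`` when given; the combination percentages partition
    100 % within each group.
    """
    if channels is None:
        channels = sorted(
            c.removeprefix("norm_")
            for c in table.columns
            if c.startswith("norm_")
        )
    else:
        channels = sorted(channels)
    missing = [c for c in channels if c not in models]
    if missing:
        raise ValueError(f"no threshold model for channel(s): {missing}")
    scored = table.copy()
    for name in channels:
        col = f"norm_{name}"
        if col not in scored.columns:
            raise ValueError(f"table lacks normalized column {col!r}")
        scored[f"pos_{name}"] = scored[col] > models[name].threshold
    scored["combination"] = [
        "".join(f"{c}{'+' if row[f'pos_{c}'] else '-'}" for c in channels)
        for _, row in scored.iterrows()
    ]

    groups = (
        scored.groupby(group_column, observed=True)
        if group_column
        else [("all", scored)]
    )
    rows = []
    for group, sub in groups:
        n = len(sub)
        entry = {"group": group, "n_cells": n}
        for name in channels:
            entry[f"pct_{name}_positive"] = 100.0 * sub[f"pos_{name}"].mean()
        rows.append(entry)
        for combo, count in sub["combination"].value_counts().items():
            rows.append(
                {
                    "group": group,
                    "n_cells": n,
                    "combination": combo,
                    "pct_of_cells": 100.0 * count / n,
                }
            )
    return scored, pd.DataFrame(rows)
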