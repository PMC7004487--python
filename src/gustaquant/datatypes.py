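"""Core in-memory containers shared across the pipeline.

Images are held as plain numpy arrays wrapped with the physical metadata
(voxel size, channel names, bit depth) that the volumetric measurements
need; tabular results are pandas DataFrames so they round-trip to tidy CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ImageStack",
    "BinaryMask",
    "ROISet",
    "Stimulus",
    "TraceRecording",
    "StandardCurve",
    "ThresholdModel",
    "StatResult",
]


@dataclass
class ImageStack:
    """Multichannel 3D image with physical voxel dimensions.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative intensities, one volume per channel.
    voxel_size : (float, float, float)
        Physical voxel edge lengths ``(x, y, z)`` in micrometres.
    channel_names : sequence of str
        One name per channel, e.g. ``("SNAP25", "GFP", "P2X3", "DAPI")``.
    bit_depth : int
        Declared dynamic range; intensities must fit in ``[0, 2**bit_depth)``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.channel_names = tuple(self.channel_names)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be indexed (channel, z, y, x)")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError("all image dimensions must be >= 1")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if self.voxels.size and float(self.voxels.max()) >= 2**self.bit_depth:
            raise ValueError(
                f"intensities exceed declared {self.bit_depth}-bit range"
            )

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, Y, X) volume for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.voxels[idx]

    def voxel_volume_um3(self) -> float:
        x, y, z = self.voxel_size
        return x * y * z

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, self.voxel_size, self.channel_names, self.bit_depth)


@dataclass
class BinaryMask:
    """Boolean (Z, Y, X) mask with the provenance of its thresholding."""

    voxels: np.ndarray
    source_channel: str
    threshold: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a (z, y, x) volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROISet:
    """Named regions as an integer label volume.

    Label 0 is background; every positive label is one region. ``names``
    maps label -> region name. ``kind`` distinguishes taste-bud ROIs from
    single-cell ROIs (the two granularities the measurements use).
    """

    labels: np.ndarray
    names: dict[int, str]
    kind: str = "bud"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ROI labels must be integer")
        present = set(np.unique(self.labels)) - {0}
        declared = set(self.names)
        if any(l <= 0 for l in declared):
            raise ValueError("region labels must be positive")
        missing = declared - present
        if missing:
            raise ValueError(f"empty ROI region(s): {sorted(missing)}")
        undeclared = present - declared
        if undeclared:
            raise ValueError(f"unnamed label(s) present: {sorted(undeclared)}")

    @property
    def region_labels(self) -> list[int]:
        return sorted(self.names)

    def mask_for(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class Stimulus:
    """One stimulus application: label, onset (s) and duration (s)."""

    label: str
    onset: float
    duration: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class TraceRecording:
    """Uniformly sampled signal with its stimulus schedule.

    ``kind`` is ``"nerve"`` for baseline-normalized integrated whole-nerve
    activity or ``"calcium"`` for a dimensionless fura-2 340/380 ratio.
    """

    values: np.ndarray
    sampling_rate: float
    stimuli: tuple[Stimulus, ...]
    kind: str = "nerve"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stimuli = tuple(self.stimuli)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.values.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        onsets = [s.onset for s in self.stimuli]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        for a, b in zip(self.stimuli, self.stimuli[1:]):
            if b.onset < a.offset:
                raise ValueError(
                    f"stimulus windows overlap: {a.label!r} and {b.label!r}"
                )
        span = len(self.values) / self.sampling_rate
        for s in self.stimuli:
            if s.onset < 0 or s.offset > span + 1e-9:
                raise ValueError(
                    f"stimulus {s.label!r} window outside recording span"
                )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate


@dataclass
class StandardCurve:
    """Linear luminescence calibration: RLU = intercept + slope * [ATP]."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("a valid assay requires a positive slope")

    def to_concentration(self, rlu: np.ndarray) -> np.ndarray:
        return (np.asarray(rlu, dtype=float) - self.intercept) / self.slope


@dataclass
class ThresholdModel:
    """Per-channel positivity threshold from a Gaussian-mixture fit.

    For a bimodal intensity histogram the threshold is two SDs above the
    median of the values assigned to the lower component; for a unimodal
    one it falls back to mean + 2 SD of the single fit (flagged).
    """

    channel: str
    modality: str                       # "unimodal" | "bimodal"
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    lower_median: float
    lower_sd: float
    threshold: float
    extrapolated: bool = False
    n_values: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("unimodal", "bimodal"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("component weights must sum to 1")
        if list(self.means) != sorted(self.means):
            raise ValueError("component means must be ordered")


@dataclass
class StatResult:
    """A test outcome in the shape results tables report them.

    ``posthoc`` is a DataFrame with one row per pairwise comparison
    (columns: pair labels, statistic, raw p, adjusted p, method).
    """

    test: str
    statistic: float
    df: object
    p_value: float
    n_per_group: dict
    posthoc: object = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")
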