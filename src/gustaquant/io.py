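"""File formats: OME-TIFF stacks, label/mask TIFFs with JSON sidecars,
trace and plate CSVs. Writers are deterministic (no timestamps) so a
pipeline run with a fixed seed is byte-reproducible."""

from __future__ import annotations

import json
import uuid
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import BinaryMask, ImageStack, ROISet, Stimulus, TraceRecording

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_rois",
    "read_rois",
    "write_trace",
    "read_trace",
    "write_json",
]


def write_json(obj, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_stack(stack: ImageStack, path: Path | str) -> None:
    """Write a multichannel stack as OME-TIFF with channel names."""
    tifffile.imwrite(
        str(path),
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            # content-independent deterministic UUID: byte-identical reruns
            "UUID": "urn:uuid:"
            + str(uuid.uuid5(uuid.NAMESPACE_URL, f"gustaquant/{Path(path).name}")),
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeX": stack.voxel_size[0],
            "PhysicalSizeY": stack.voxel_size[1],
            "PhysicalSizeZ": stack.voxel_size[2],
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )
    sidecar = {
        "channel_names": list(stack.channel_names),
        "voxel_size_um_xyz": list(stack.voxel_size),
        "bit_depth": stack.bit_depth,
    }
    write_json(sidecar, str(path) + ".json")


def read_stack(path: Path | str) -> ImageStack:
    voxels = tifffile.imread(str(path))
    if voxels.ndim == 3:
        voxels = voxels[None]
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ImageStack(
        voxels,
        tuple(meta["voxel_size_um_xyz"]),
        tuple(meta["channel_names"]),
        meta["bit_depth"],
    )


def write_mask(mask: BinaryMask, path: Path | str) -> None:
    """0/255 8-bit TIFF plus JSON provenance sidecar."""
    tifffile.imwrite(str(path), mask.voxels.astype(np.uint8) * 255)
    write_json(
        {
            "source_channel": mask.source_channel,
            "threshold": mask.threshold,
            "voxel_size_um_xyz": list(mask.voxel_size),
            "provenance": mask.provenance,
        },
        str(path) + ".json",
    )


def read_mask(path: Path | str) -> BinaryMask:
    voxels = tifffile.imread(str(path)) > 0
    meta = json.loads(Path(str(path) + ".json").read_text())
    return BinaryMask(
        voxels,
        meta["source_channel"],
        meta["threshold"],
        tuple(meta["voxel_size_um_xyz"]),
        meta["provenance"],
    )


def write_rois(rois: ROISet, path: Path | str) -> None:
    tifffile.imwrite(str(path), rois.labels.astype(np.int32))
    write_json(
        {
            "names": {str(k): v for k, v in rois.names.items()},
            "kind": rois.kind,
            "voxel_size_um_xyz": list(rois.voxel_size),
        },
        str(path) + ".json",
    )


def read_rois(path: Path | str) -> ROISet:
    labels = tifffile.imread(str(path))
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ROISet(
        labels,
        {int(k): v for k, v in meta["names"].items()},
        meta["kind"],
        tuple(meta["voxel_size_um_xyz"]),
    )


def write_trace(trace: TraceRecording, path: Path | str) -> None:
    """Trace as (time_s, value) CSV plus a JSON stimulus schedule."""
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False
    )
    write_json(
        {
            "kind": trace.kind,
            "sampling_rate_hz": trace.sampling_rate,
            "stimuli": [
                {"label": s.label, "onset_s": s.onset, "duration_s": s.duration}
                for s in trace.stimuli
            ],
        },
        str(path) + ".json",
    )


def read_trace(path: Path | str) -> TraceRecording:
    table = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return TraceRecording(
        values=table["value"].to_numpy(),
        sampling_rate=meta["sampling_rate_hz"],
        stimuli=tuple(
            Stimulus(s["label"], s["onset_s"], s["duration_s"])
            for s in meta["stimuli"]
        ),
        kind=meta["kind"],
    )
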