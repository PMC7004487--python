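"""Synthetic ground-truth data for every pipeline stage.

No raw images or recordings ship with the package, so each input the
pipeline consumes is emulated with fully known ground truth:

* taste-bud stacks — ellipsoidal bud ROIs containing elongate cells
  (columns with spherical nuclei) and tubular intragemmal nerve fibers
  simulated as persistent random-walk tubes clipped to the bud, with a
  controllable voxel overlap fraction between the two fiber channels;
* geniculate-ganglion fields — round cells whose per-channel intensities
  are drawn from a two-component (negative/positive) Gaussian mixture;
* integrated nerve and fura-2 ratio traces on a 30 s stimulus / 40 s
  rinse schedule, with first-order rise/decay kinetics, drift and noise;
* luciferase plate readings from a linear RLU-vs-[ATP] relation.

All generators are deterministic given their seed, and every stored true
fraction or amplitude is recomputable from the stored masks and traces
(tests never re-derive truth from rendered images).

Rendering follows a standard confocal forward model: structures are
painted at their intensity levels over a background with a linear
gradient, blurred with an anisotropic Gaussian PSF, then corrupted with
mixed Poisson–Gaussian noise of configurable gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import ImageStack, ROISet, Stimulus, TraceRecording

__all__ = [
    "BudSimParams",
    "BudGroundTruth",
    "generate_bud_stack",
    "GanglionSimParams",
    "generate_ganglion_field",
    "TraceSimParams",
    "generate_nerve_trace",
    "generate_calcium_trace",
    "generate_atp_plate",
    "default_schedule",
]

BUD_CHANNELS = ("SNAP25", "GFP", "P2X3", "DAPI")


# --------------------------------------------------------------------------
# taste-bud stacks


@dataclass
class BudSimParams:
    """Conditions for the taste-bud stack generator.

    Geometry is in µm (converted through ``voxel_size``); intensities are
    grey levels of an 8-bit image. Defaults emulate a 0.2 × 0.2 × 1 µm
    confocal acquisition of a 12–16 µm section through fungiform-scale
    buds at moderate signal-to-noise.
    """

    stack_shape: tuple[int, int, int] = (16, 128, 256)   # (Z, Y, X)
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 1.0)  # (x, y, z) um
    n_buds: int = 2
    cells_per_bud: Mapping[str, int] = field(
        default_factory=lambda: {"type_ii": 5, "type_iii": 3}
    )
    bud_semiaxes_um: tuple[float, float, float] = (6.0, 10.0, 10.0)  # (z, y, x)
    cell_radius_um: float = 2.0
    cell_gap_um: float = 0.8        # minimum clearance between cell surfaces
    nucleus_radius_um: float = 1.6
    fiber_density: Mapping[str, float] | float = 0.20  # target labeled fraction
    channel_overlap_fraction: float = 0.6  # fraction of P2X3+ voxels also GFP+
    fiber_radius_um: float = 0.4
    fiber_step_um: float = 0.4
    fiber_persistence: float = 0.8
    intensity: Mapping[str, float] = field(
        default_factory=lambda: {
            "SNAP25": 150.0,
            "GFP": 160.0,
            "P2X3": 160.0,
            "DAPI": 150.0,
        }
    )
    background: float = 20.0
    gradient_amplitude: float = 8.0
    noise_sd: float = 6.0
    poisson_gain: float = 1.0            # 0 disables shot noise
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.1, 0.1)  # (z, y, x)
    seed: int = 0

    def fiber_densities(self) -> dict[str, float]:
        """Per-fiber-channel density targets (a bare float applies to both)."""
        if isinstance(self.fiber_density, (int, float)):
            return {"P2X3": float(self.fiber_density), "GFP": float(self.fiber_density)}
        dens = {"P2X3": 0.0, "GFP": 0.0}
        dens.update({k: float(v) for k, v in self.fiber_density.items()})
        return dens

    def validate(self) -> None:
        if any(d < 1 for d in self.stack_shape):
            raise ValueError("stack_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        dens = self.fiber_densities()
        f = self.channel_overlap_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError("channel_overlap_fraction must lie in [0, 1]")
        for name, d in dens.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"fiber_density[{name!r}] must lie in [0, 1]")
        if f * dens["P2X3"] > dens["GFP"] + 1e-9:
            raise ValueError(
                "channel_overlap_fraction demands more shared voxels than "
                "the GFP fiber_density allows"
            )
        union = dens["P2X3"] + dens["GFP"] - f * dens["P2X3"]
        if union > 0.75:
            raise ValueError(
                "combined fiber density above 0.75 is infeasible for a tube "
                "packing of the bud volume"
            )
        if self.n_buds < 1:
            raise ValueError("need at least one bud")

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        x, y, z = self.voxel_size
        return (z, y, x)


@dataclass
class BudGroundTruth:
    """Exact truth for one simulated bud stack.

    ``fiber_masks`` are the noiseless per-channel fiber voxel sets;
    ``innervation`` and ``overlap`` store the fractions computed from
    those masks (identical to a recount, by construction). The nucleus
    label volume assigns each cell's nucleus voxels its cell id, which is
    what per-plane profile-count truths are read from.
    """

    rois: ROISet
    cells: pd.DataFrame
    nucleus_labels: np.ndarray
    fiber_masks: dict[str, np.ndarray]
    innervation: pd.DataFrame
    overlap: pd.DataFrame
    params: BudSimParams

    def true_profile_count(self, bud_label: int, z: int) -> int:
        """Type III cells of a bud whose nucleus intersects plane ``z``."""
        in_bud = self.cells["bud_label"] == bud_label
        t3 = self.cells.loc[in_bud & (self.cells["cell_type"] == "type_iii")]
        plane = self.nucleus_labels[z]
        present = np.unique(plane[plane > 0])
        return int(t3["cell_id"].isin(present).sum())


def _sphere_offsets(radius_um: float, voxel_zyx: Sequence[float]) -> np.ndarray:
    """Voxel offsets within an anisotropic physical sphere."""
    ext = [max(int(np.floor(radius_um / v)), 0) for v in voxel_zyx]
    zz, yy, xx = np.mgrid[
        -ext[0] : ext[0] + 1, -ext[1] : ext[1] + 1, -ext[2] : ext[2] + 1
    ]
    d2 = (
        (zz * voxel_zyx[0]) ** 2
        + (yy * voxel_zyx[1]) ** 2
        + (xx * voxel_zyx[2]) ** 2
    )
    sel = d2 <= radius_um**2
    return np.stack([zz[sel], yy[sel], xx[sel]], axis=1)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center_zyx: Sequence[float],
    semiaxes_um: Sequence[float],
    voxel_zyx: Sequence[float],
) -> np.ndarray:
    zz, yy, xx = np.indices(shape)
    d = (
        ((zz - center_zyx[0]) * voxel_zyx[0] / semiaxes_um[0]) ** 2
        + ((yy - center_zyx[1]) * voxel_zyx[1] / semiaxes_um[1]) ** 2
        + ((xx - center_zyx[2]) * voxel_zyx[2] / semiaxes_um[2]) ** 2
    )
    return d <= 1.0


def _grow_fiber_mask(
    allowed: np.ndarray,
    n_target: int,
    params: BudSimParams,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Random-walk tubes inside the allowed region until ``n_target`` voxels.

    Returns the labeled voxels in the order they were first reached; the
    trailing excess of the final tube stamp is trimmed so the count is
    exact (one-voxel quantization of the target fraction).
    """
    vz = params.voxel_size_zyx
    offsets = _sphere_offsets(params.fiber_radius_um, vz)
    shape = allowed.shape
    inside = np.argwhere(allowed)
    if len(inside) < n_target:
        raise RuntimeError("fiber density target exceeds the allowed region")
    taken = np.zeros(shape, dtype=bool)
    ordered: list[tuple[int, int, int]] = []
    guard = 0
    while len(ordered) < n_target:
        guard += 1
        if guard > 10_000:
            raise RuntimeError(
                "fiber growth stalled: density target infeasible for this bud"
            )
        start = inside[rng.integers(len(inside))]
        pos = start.astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        steps = int(rng.integers(30, 120))
        for _ in range(steps):
            center = np.round(pos).astype(int)
            coords = center[None, :] + offsets
            ok = (
                (coords >= 0).all(axis=1)
                & (coords[:, 0] < shape[0])
                & (coords[:, 1] < shape[1])
                & (coords[:, 2] < shape[2])
            )
            coords = coords[ok]
            sel = allowed[coords[:, 0], coords[:, 1], coords[:, 2]] & ~taken[
                coords[:, 0], coords[:, 1], coords[:, 2]
            ]
            for c in coords[sel]:
                taken[c[0], c[1], c[2]] = True
                ordered.append((int(c[0]), int(c[1]), int(c[2])))
            if len(ordered) >= n_target:
                break
            wobble = rng.normal(size=3)
            wobble /= np.linalg.norm(wobble)
            direction = params.fiber_persistence * direction + (
                1 - params.fiber_persistence
            ) * wobble
            direction /= np.linalg.norm(direction)
            step_vox = direction * params.fiber_step_um / np.asarray(vz)
            nxt = pos + step_vox
            probe = np.round(nxt).astype(int)
            if (
                (probe < 0).any()
                or (probe >= np.asarray(shape)).any()
                or not allowed[probe[0], probe[1], probe[2]]
            ):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                continue
            pos = nxt
    return ordered[:n_target]


def _place_cells(
    bud_center: np.ndarray,
    params: BudSimParams,
    rng: np.random.Generator,
) -> list[dict]:
    """Dart-throw cell positions inside one bud with in-plane separation."""
    vz = params.voxel_size_zyx
    sz, sy, sx = params.bud_semiaxes_um
    min_sep_um = 2.0 * params.cell_radius_um + params.cell_gap_um
    placed: list[dict] = []
    for cell_type, count in params.cells_per_bud.items():
        for _ in range(count):
            sep = min_sep_um
            for _attempt in range(4000):
                if _attempt and _attempt % 500 == 0:
                    sep *= 0.9  # relax separation for crowded buds
                # uniform in the inner ~78 % of the bud's in-plane ellipse
                ang = rng.uniform(0, 2 * np.pi)
                rad = 0.78 * np.sqrt(rng.uniform())
                dy_um = rad * sy * np.sin(ang)
                dx_um = rad * sx * np.cos(ang)
                clash = any(
                    np.hypot(dy_um - c["dy_um"], dx_um - c["dx_um"]) < sep
                    for c in placed
                )
                if not clash:
                    break
            else:
                raise RuntimeError(
                    "could not place all cells: bud too crowded for the "
                    "requested cells_per_bud"
                )
            nz_um = rng.uniform(-0.3 * sz, 0.3 * sz)  # nucleus depth jitter
            placed.append(
                {
                    "cell_type": cell_type,
                    "dy_um": dy_um,
                    "dx_um": dx_um,
                    "nucleus_dz_um": nz_um,
                    "center": np.array(
                        [
                            bud_center[0],
                            bud_center[1] + dy_um / vz[1],
                            bud_center[2] + dx_um / vz[2],
                        ]
                    ),
                }
            )
    return placed


def generate_bud_stack(params: BudSimParams) -> tuple[ImageStack, BudGroundTruth]:
    """Render a multichannel taste-bud stack with exact ground truth.

    Channels are ``SNAP25`` (Type III cell-body marker), ``GFP`` and
    ``P2X3`` (fiber channels; GFP+ voxels are a subset of P2X3+ voxels
    covering ``channel_overlap_fraction`` of them) and ``DAPI`` (all
    nuclei). Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.stack_shape)
    vz = params.voxel_size_zyx
    nz, ny, nx = shape

    # bud centers spaced along x
    sz, sy, sx = params.bud_semiaxes_um
    rx_px = sx / vz[2]
    if params.n_buds * 2 * rx_px > nx:
        raise ValueError("stack too narrow for the requested number of buds")
    centers = [
        np.array([nz / 2.0, ny / 2.0, (i + 0.5) * nx / params.n_buds])
        for i in range(params.n_buds)
    ]

    labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    fiber_b = np.zeros(shape, dtype=bool)
    fiber_a = np.zeros(shape, dtype=bool)
    snap25 = np.zeros(shape, dtype=bool)
    dapi = np.zeros(shape, dtype=bool)

    names = {}
    cell_rows = []
    innervation_rows = []
    overlap_rows = []
    nucleus_offsets = _sphere_offsets(params.nucleus_radius_um, vz)
    cell_id = 0

    for i, center in enumerate(centers):
        label = i + 1
        names[label] = f"bud_{label}"
        bud = _ellipsoid_mask(shape, center, (sz, sy, sx), vz)
        if labels[bud].any():
            raise RuntimeError("bud ROIs overlap; widen the stack")
        labels[bud] = label
        n_bud = int(bud.sum())

        # ---- fibers: P2X3 tubes, a shared GFP+P2X3 subset, GFP-only tubes
        dens = params.fiber_densities()
        n_b_target = int(round(dens["P2X3"] * n_bud))
        n_a_target = int(round(dens["GFP"] * n_bud))
        if n_b_target > 0:
            ordered = _grow_fiber_mask(bud, n_b_target, params, rng)
            idx = tuple(np.array(ordered).T)
            fiber_b[idx] = True
            n_shared = int(round(params.channel_overlap_fraction * n_b_target))
            if n_shared > 0:
                idx_a = tuple(np.array(ordered[:n_shared]).T)
                fiber_a[idx_a] = True
        else:
            n_shared = 0
        n_a_only = max(n_a_target - n_shared, 0)
        if n_a_only > 0:
            ordered_a = _grow_fiber_mask(bud & ~fiber_b, n_a_only, params, rng)
            idx_a_only = tuple(np.array(ordered_a).T)
            fiber_a[idx_a_only] = True
        b_in = fiber_b & bud
        a_in = fiber_a & bud
        nb, na = int(b_in.sum()), int((a_in & b_in).sum())
        innervation_rows += [
            {"bud_label": label, "channel": "P2X3", "fraction": nb / n_bud},
            {"bud_label": label, "channel": "GFP", "fraction": int(a_in.sum()) / n_bud},
        ]
        overlap_rows.append(
            {"bud_label": label, "fraction": (na / nb) if nb else np.nan}
        )

        # ---- cells
        for cell in _place_cells(center, params, rng):
            cell_id += 1
            cz, cy, cx = cell["center"]
            # elongate cell: vertical column clipped to the bud
            zz, yy, xx = np.indices(shape)
            col = (
                ((yy - cy) * vz[1]) ** 2 + ((xx - cx) * vz[2]) ** 2
                <= params.cell_radius_um**2
            ) & bud
            if cell["cell_type"] == "type_iii":
                snap25 |= col
            ncz = cz + cell["nucleus_dz_um"] / vz[0]
            ncenter = np.round([ncz, cy, cx]).astype(int)
            coords = ncenter[None, :] + nucleus_offsets
            ok = (
                (coords >= 0).all(axis=1)
                & (coords[:, 0] < nz)
                & (coords[:, 1] < ny)
                & (coords[:, 2] < nx)
            )
            coords = coords[ok]
            dapi[coords[:, 0], coords[:, 1], coords[:, 2]] = True
            nucleus_labels[coords[:, 0], coords[:, 1], coords[:, 2]] = cell_id
            cell_rows.append(
                {
                    "cell_id": cell_id,
                    "bud_label": label,
                    "cell_type": cell["cell_type"],
                    "z": float(ncz),
                    "y": float(cy),
                    "x": float(cx),
                    "nucleus_voxels": int(len(coords)),
                }
            )

    # ---- render
    structure_masks = {
        "SNAP25": snap25,
        "GFP": fiber_a,
        "P2X3": fiber_b,
        "DAPI": dapi,
    }
    yy2, xx2 = np.mgrid[0:ny, 0:nx]
    gradient = params.gradient_amplitude * (yy2 / max(ny - 1, 1) + xx2 / max(nx - 1, 1)) / 2.0
    sigma_px = tuple(s / v for s, v in zip(params.psf_sigma_um, vz))
    channels = []
    for name in BUD_CHANNELS:
        img = np.full(shape, params.background, dtype=float)
        img += gradient[None, :, :]
        img[structure_masks[name]] = params.background + params.intensity[name]
        if any(s > 0 for s in sigma_px):
            img = ndimage.gaussian_filter(img, sigma=sigma_px)
        if params.poisson_gain > 0:
            img = rng.poisson(img / params.poisson_gain) * params.poisson_gain
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=shape)
        channels.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))

    stack = ImageStack(
        np.stack(channels),
        params.voxel_size,
        BUD_CHANNELS,
        bit_depth=8,
    )
    rois = ROISet(labels, names, kind="bud", voxel_size=params.voxel_size)
    truth = BudGroundTruth(
        rois=rois,
        cells=pd.DataFrame(cell_rows),
        nucleus_labels=nucleus_labels,
        fiber_masks={"P2X3": fiber_b, "GFP": fiber_a},
        innervation=pd.DataFrame(innervation_rows),
        overlap=pd.DataFrame(overlap_rows),
        params=params,
    )
    return stack, truth


# --------------------------------------------------------------------------
# ganglion fields


@dataclass
class GanglionSimParams:
    """Conditions for the ganglion-field generator.

    Intensities are drawn in normalized units from a two-component
    Gaussian mixture shared across channels; per-channel
    ``positive_fraction`` sets the mixing weight of the upper (positive)
    component. The rendered field spans ``n_substacks`` axial blocks of
    ``substack_thickness_um`` at 1 µm slice spacing.
    """

    n_cells: int = 500
    positive_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"GFP": 0.4, "P2X3": 0.9, "SNAP25": 0.95}
    )
    lower_mean: float = 0.2
    lower_sd: float = 0.05
    upper_mean: float = 0.8
    upper_sd: float = 0.05
    n_substacks: int = 3
    substack_thickness_um: float = 10.0
    field_shape_yx: tuple[int, int] = (512, 512)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0)
    cell_radius_um: float = 5.0
    background: float = 20.0
    gain: float = 200.0
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name, frac in self.positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"positive_fraction[{name!r}] outside [0, 1]")
        if not self.lower_mean < self.upper_mean:
            raise ValueError("component means must be ordered lower < upper")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.positive_fraction) + ("DAPI",)


def draw_cell_intensities(
    params: GanglionSimParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-cell true classes and normalized intensities.

    One row per cell with, per channel, ``true_pos_<ch>`` (the Bernoulli
    class draw) and ``value_<ch>`` (the Gaussian intensity from that
    class's component, clipped into [0, 1.2]).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_cells
    table = {"cell_id": np.arange(1, n + 1)}
    for ch, frac in params.positive_fraction.items():
        pos = rng.random(n) < frac
        vals = np.where(
            pos,
            rng.normal(params.upper_mean, params.upper_sd, n),
            rng.normal(params.lower_mean, params.lower_sd, n),
        )
        table[f"true_pos_{ch}"] = pos
        table[f"value_{ch}"] = np.clip(vals, 0.0, 1.2)
    return pd.DataFrame(table)


def generate_ganglion_field(
    params: GanglionSimParams,
) -> tuple[ImageStack, pd.DataFrame, list[ROISet]]:
    """Render a ganglion field with known per-cell classes.

    Returns the multichannel stack, the ground-truth cell table
    (positions, substack assignment, true classes and intensities) and
    one cell-ROI label set per substack projection (disk ROIs at the
    truth positions, slightly eroded to dodge edge blur). With
    ``n_cells = 0`` the truth table is empty and the stack is valid
    background.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = draw_cell_intensities(params, rng)

    z_step = params.voxel_size[2]
    per = int(np.ceil(params.substack_thickness_um / z_step))
    nz = per * params.n_substacks
    ny, nx = params.field_shape_yx
    r_px = params.cell_radius_um / params.voxel_size[0]
    min_sep = 2.3 * r_px

    substack = rng.integers(0, params.n_substacks, params.n_cells)
    ys = np.empty(params.n_cells)
    xs = np.empty(params.n_cells)
    zs = np.empty(params.n_cells, dtype=int)
    placed: dict[int, list[tuple[float, float]]] = {
        s: [] for s in range(params.n_substacks)
    }
    for i in range(params.n_cells):
        s = int(substack[i])
        sep = min_sep
        for _attempt in range(3000):
            if _attempt and _attempt % 400 == 0:
                sep *= 0.92  # relax separation in crowded substacks
            y = rng.uniform(r_px + 1, ny - r_px - 1)
            x = rng.uniform(r_px + 1, nx - r_px - 1)
            if all(np.hypot(y - py, x - px) >= sep for py, px in placed[s]):
                break
        else:
            raise RuntimeError(
                "could not place all ganglion cells without overlap; "
                "reduce n_cells or enlarge the field"
            )
        placed[s].append((y, x))
        ys[i], xs[i] = y, x
        zs[i] = s * per + int(rng.integers(1, per - 1)) if per > 2 else s * per
    truth["substack"] = substack
    truth["y"] = ys
    truth["x"] = xs
    truth["z"] = zs
    truth["true_pos_DAPI"] = True
    truth["value_DAPI"] = 0.8

    def _local_disk(y: float, x: float, radius: float):
        y0, y1 = max(int(y - radius) - 1, 0), min(int(y + radius) + 2, ny)
        x0, x1 = max(int(x - radius) - 1, 0), min(int(x + radius) + 2, nx)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        return (slice(y0, y1), slice(x0, x1)), (yy - y) ** 2 + (xx - x) ** 2 <= radius**2

    channels = params.channels
    stacks = np.full((len(channels), nz, ny, nx), params.background, dtype=float)
    for i in range(params.n_cells):
        (sy_, sx_), disk = _local_disk(ys[i], xs[i], r_px)
        z0 = max(int(zs[i]) - 2, (substack[i]) * per)
        z1 = min(int(zs[i]) + 3, (substack[i] + 1) * per)
        for c, ch in enumerate(channels):
            level = params.background + truth.loc[i, f"value_{ch}"] * params.gain
            for z in range(z0, z1):
                plane = stacks[c, z, sy_, sx_]
                plane[disk] = np.maximum(plane[disk], level)
                stacks[c, z, sy_, sx_] = plane
    stacks = ndimage.gaussian_filter(stacks, sigma=(0, 0.3, 1.0, 1.0))
    if params.noise_sd > 0:
        stacks = stacks + rng.normal(0.0, params.noise_sd, size=stacks.shape)
    stacks = np.clip(np.rint(stacks), 0, 65535).astype(np.uint16)
    stack = ImageStack(stacks, params.voxel_size, channels, bit_depth=16)

    roi_sets = []
    r_roi = max(r_px - 2.0, 2.0)
    for s in range(params.n_substacks):
        labels2d = np.zeros((1, ny, nx), dtype=np.int32)
        names = {}
        for i in np.flatnonzero(substack == s):
            (sy_, sx_), disk = _local_disk(ys[i], xs[i], r_roi)
            labels2d[0, sy_, sx_][disk] = int(truth.loc[i, "cell_id"])
            names[int(truth.loc[i, "cell_id"])] = f"cell_{truth.loc[i, 'cell_id']}"
        roi_sets.append(
            ROISet(labels2d, names, kind="cell", voxel_size=params.voxel_size)
        )
    return stack, truth, roi_sets


# --------------------------------------------------------------------------
# traces


def default_schedule(
    labels: Sequence[str],
    first_onset_s: float = 30.0,
    stimulus_s: float = 30.0,
    rinse_s: float = 40.0,
) -> tuple[Stimulus, ...]:
    """30 s stimulus / 40 s rinse schedule starting at ``first_onset_s``."""
    return tuple(
        Stimulus(label, first_onset_s + i * (stimulus_s + rinse_s), stimulus_s)
        for i, label in enumerate(labels)
    )


@dataclass
class TraceSimParams:
    """Conditions for the trace generators.

    ``amplitudes`` maps stimulus label to steady-state response above
    baseline (integrated-signal units for nerve, ratio units for
    calcium). ``rise_tau_s``/``decay_tau_s`` of 0 give step kinetics.
    Defaults: 10 Hz integrated nerve sampling; fura-2 ratio sampling at
    1 Hz (full 340/380 pairs); 30 s stimulation with 40 s rinse.
    """

    sampling_rate: float = 10.0
    duration_s: float | None = None
    baseline_level: float = 1.0
    drift_slope: float = 0.0          # signal units per second
    amplitudes: Mapping[str, float] = field(default_factory=lambda: {"stim": 0.5})
    rise_tau_s: float = 0.0
    decay_tau_s: float = 2.0
    schedule: tuple[Stimulus, ...] | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def resolved_schedule(self, first_onset_s: float) -> tuple[Stimulus, ...]:
        if self.schedule is not None:
            return tuple(self.schedule)
        return default_schedule(list(self.amplitudes), first_onset_s=first_onset_s)

    def validate(self) -> None:
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def _response_component(
    t: np.ndarray, stim: Stimulus, amplitude: float, rise_tau: float, decay_tau: float
) -> np.ndarray:
    on = (t >= stim.onset) & (t < stim.offset)
    after = t >= stim.offset
    g = np.zeros_like(t)
    if rise_tau > 0:
        g[on] = 1.0 - np.exp(-(t[on] - stim.onset) / rise_tau)
        end_level = 1.0 - np.exp(-stim.duration / rise_tau)
    else:
        g[on] = 1.0
        end_level = 1.0
    if decay_tau > 0:
        g[after] = end_level * np.exp(-(t[after] - stim.offset) / decay_tau)
    return amplitude * g


def _synthesize(
    params: TraceSimParams, kind: str, first_onset_s: float
) -> tuple[TraceRecording, dict[str, float]]:
    params.validate()
    schedule = params.resolved_schedule(first_onset_s)
    if kind == "calcium" and schedule and schedule[0].onset < 15.0:
        raise ValueError(
            "calcium schedule must leave at least 15 s of baseline before "
            "the first stimulus"
        )
    rng = np.random.default_rng(params.seed)
    if params.duration_s is not None:
        duration = params.duration_s
    else:
        tail = 40.0
        duration = (schedule[-1].offset + tail) if schedule else 60.0
    n = int(round(duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    values = params.baseline_level + params.drift_slope * t
    amplitudes = dict(params.amplitudes)
    for stim in schedule:
        amp = amplitudes.get(stim.label, 0.0)
        values = values + _response_component(
            t, stim, amp, params.rise_tau_s, params.decay_tau_s
        )
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=n)
    values = np.clip(values, 0.0, None)
    trace = TraceRecording(
        values=values, sampling_rate=params.sampling_rate, stimuli=schedule, kind=kind
    )
    return trace, amplitudes


def generate_nerve_trace(
    params: TraceSimParams,
) -> tuple[TraceRecording, dict[str, float]]:
    """Integrated whole-nerve trace plus the true steady-state amplitudes.

    Noiseless with step kinetics, the trace sits exactly at
    ``baseline + amplitude`` throughout each stimulus window. The signal
    is clipped at zero (an integrated record is non-negative).
    """
    return _synthesize(params, kind="nerve", first_onset_s=30.0)


def generate_calcium_trace(
    params: TraceSimParams,
) -> tuple[TraceRecording, dict[str, float]]:
    """Fura-2 ratio trace plus true ΔR per stimulus.

    The schedule must leave ≥ 15 s of pre-stimulus baseline (the
    baseline-window convention needs it); the returned amplitudes are the
    true ΔR values.
    """
    return _synthesize(params, kind="calcium", first_onset_s=30.0)


# --------------------------------------------------------------------------
# ATP plates


def generate_atp_plate(
    slope: float,
    intercept: float,
    true_concentrations_nM: Mapping[str, Sequence[float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    standard_concentrations_nM: Sequence[float] = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0),
) -> pd.DataFrame:
    """Simulate a 96-well luminescence plate.

    ``true_concentrations_nM`` maps condition name to the per-preparation
    true [ATP]; preparations are paired across conditions by position.
    Standards are emitted under condition ``"standard"`` with their known
    concentrations. ``RLU = intercept + slope·conc + N(0, noise_sd)``.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in standard_concentrations_nM:
        if conc < 0:
            raise ValueError("standard concentrations must be non-negative")
        rows.append(
            {
                "condition": "standard",
                "preparation": f"std_{conc:g}",
                "concentration_nM_true": float(conc),
                "rlu": intercept + slope * conc,
            }
        )
    for condition, concs in true_concentrations_nM.items():
        for i, conc in enumerate(concs):
            if conc < 0:
                raise ValueError("sample concentrations must be non-negative")
            rows.append(
                {
                    "condition": condition,
                    "preparation": f"prep_{i + 1}",
                    "concentration_nM_true": float(conc),
                    "rlu": intercept + slope * conc,
                }
            )
    plate = pd.DataFrame(rows)
    if noise_sd > 0:
        plate["rlu"] = plate["rlu"] + rng.normal(0.0, noise_sd, size=len(plate))
    plate["rlu"] = plate["rlu"].clip(lower=0.0)
    plate["well"] = [f"W{i + 1:02d}" for i in range(len(plate))]
    return plate
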