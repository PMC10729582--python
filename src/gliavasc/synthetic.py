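"""Synthetic multi-channel confocal fields of view with full ground truth.

Every FOV mimics the study's acquisition settings: a vessel channel
(lectin/STL-like) containing a network of smooth tubular vessels, a
microglia channel (IBA1-like) with bright somata and dimmer tapering
branch trees (a configurable fraction of somata planted touching a
vessel), and an optional plasma-protein (IgG-like) channel with diffuse
perivascular leakage blobs.  Intensities follow an 8-bit convention
(0-255) so the fixed IgG threshold of 25 is meaningful, and rasterization
happens in physical um coordinates so anisotropic voxel sizes (e.g.
1.25 x 1.25 x 1 um^3 stacks) are handled exactly.

Ground truth is defined on the generative geometry first (polyline
centerlines and branch trees) and on the noise-free rendered masks second,
so that per-cell truth (soma size, endpoint count, branch lengths, hull,
planted VAM flag) is unambiguous.  Per-FOV RNG streams derive from a
master seed plus the FOV index, making multi-FOV datasets reproducible
bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from gliavasc.exceptions import ConfigurationError, PlacementError
from gliavasc.morpho import hull_and_ramification

__all__ = [
    "FovConfig",
    "GroundTruth",
    "Fov",
    "ARCHETYPES",
    "VOXEL_RODENT_STACK_UM",
    "VOXEL_SINGLE_CELL_UM",
    "generate_vessels",
    "generate_microglia",
    "generate_leakage",
    "add_noise",
    "generate_fov",
    "render_tubes",
    "sample_archetype_features",
]

#: Acquisition presets (zyx, um): overview z-stacks and high-NA single-cell mode.
VOXEL_RODENT_STACK_UM = (1.0, 1.25, 1.25)
VOXEL_SINGLE_CELL_UM = (0.3, 0.16, 0.16)

# Rendered intensity conventions (8-bit scale).  Somata are much brighter
# than processes, as in IBA1 stainings, so a global Otsu threshold isolates
# somata while the Triangle threshold (histogram-foot) captures the full
# arbor for single-cell analysis.
_BG = 4.0
_VESSEL_PEAK = 200.0
_SOMA_PEAK = 215.0
_SOMA_RIM = 170.0
_BRANCH_PEAK = 45.0
_BRANCH_TIP = 30.0


@dataclass(frozen=True)
class FovConfig:
    """Generative parameters of one synthetic field of view.

    ``shape`` and ``voxel_size`` are per-axis (zyx order for 3D, yx for
    2D), voxel size in um.  Radii and lengths are um.  ``vam_fraction`` of
    the cells are planted with their soma touching a vessel;
    ``leakage_fraction`` is the target fraction of the FOV above the IgG
    threshold.  Noise is Gaussian read noise (``noise_sigma``) plus
    optional Poisson shot noise.
    """

    shape: tuple[int, ...] = (20, 144, 144)
    voxel_size: tuple[float, ...] = (1.0, 1.25, 1.25)
    n_vessels: int = 3
    vessel_radius_range: tuple[float, float] = (2.0, 3.5)
    n_cells: int = 8
    soma_radius_range: tuple[float, float] = (5.0, 6.5)
    branches_per_cell: tuple[int, int] = (3, 5)
    branch_length_range: tuple[float, float] = (12.0, 25.0)
    vam_fraction: float = 0.3
    leakage_fraction: float = 0.1
    noise_sigma: float = 5.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) not in (2, 3) or len(self.voxel_size) != len(self.shape):
            raise ConfigurationError("shape must be 2D or 3D with matching voxel_size")
        if any(s <= 0 for s in self.shape) or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("shape and voxel_size must be strictly positive")
        if self.n_vessels < 0 or self.n_cells < 0:
            raise ConfigurationError("counts must be >= 0")
        for lo, hi in (
            self.vessel_radius_range,
            self.soma_radius_range,
            self.branch_length_range,
        ):
            if lo <= 0 or hi < lo:
                raise ConfigurationError("ranges must be positive with lo <= hi")
        if not (0 <= self.branches_per_cell[0] <= self.branches_per_cell[1]):
            raise ConfigurationError("branches_per_cell must be a non-negative range")
        if not 0.0 <= self.vam_fraction <= 1.0:
            raise ConfigurationError("vam_fraction must lie in [0, 1]")
        if not 0.0 <= self.leakage_fraction <= 1.0:
            raise ConfigurationError("leakage_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * np.asarray(self.voxel_size)


@dataclass
class GroundTruth:
    """Everything the generator knows about one FOV."""

    vessel_mask: np.ndarray | None = None
    vessel_centerlines: list = field(default_factory=list)
    vessel_radii: list = field(default_factory=list)
    cells: pd.DataFrame | None = None
    cell_labels: np.ndarray | None = None
    soma_labels: np.ndarray | None = None
    branch_lengths: dict = field(default_factory=dict)
    true_leakage_fraction: float = 0.0


@dataclass
class Fov:
    fov_id: str
    config: FovConfig
    channels: dict            # channel name -> noisy array (float32, 0..255)
    clean_channels: dict      # channel name -> noise-free array
    truth: GroundTruth


def _fov_rngs(config: FovConfig, fov_index: int) -> dict:
    base = np.random.SeedSequence(entropy=config.seed, spawn_key=(fov_index,))
    names = ("vessels", "cells", "leakage", "noise_vessel", "noise_iba1", "noise_igg")
    return {n: np.random.default_rng(ss) for n, ss in zip(names, base.spawn(len(names)))}


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length steps."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return points
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0:
        return points[:1]
    n = max(int(math.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.stack(
        [np.interp(t, arclen, points[:, d]) for d in range(points.shape[1])], axis=1
    )


def _arc_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def render_tubes(
    centerlines: list[np.ndarray],
    radii: list[float],
    shape: tuple[int, ...],
    voxel_size: tuple[float, ...],
    peak: float = _VESSEL_PEAK,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize tubes around um-space polylines.

    Returns ``(intensity, mask)``: the intensity has a parabolic radial
    profile vanishing at the tube radius, and the mask is the rendered
    support (distance to the centerline <= radius).
    """
    vs = np.asarray(voxel_size, dtype=float)
    intensity = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    for line, r in zip(centerlines, radii):
        pts = _resample_polyline(np.asarray(line, dtype=float), step=float(vs.min()) / 2)
        seeds = np.zeros(shape, dtype=bool)
        idx = np.round(pts / vs).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
        if not inside.any():
            continue
        seeds[tuple(idx[inside].T)] = True
        d = distance_transform_edt(~seeds, sampling=vs)
        tube = d <= r
        mask |= tube
        profile = peak * np.sqrt(np.clip(1.0 - (d / r) ** 2, 0.0, 1.0))
        np.maximum(intensity, profile, out=intensity)
    return intensity, mask


def _random_centerline(
    config: FovConfig, rng: np.random.Generator, radius: float = 0.0
) -> np.ndarray:
    """A smooth random curve entering at one in-plane border and crossing the FOV.

    In 3D the curve stays at least one tube radius (plus margin) away from
    the axial faces, as vessels in an acquired stack are framed inside it.
    """
    extent = config.extent_um
    d = config.ndim
    zlo = zhi = None
    if d == 3:
        zlo = radius + 2.0
        zhi = extent[0] - radius - 2.0
        if zhi <= zlo:
            zlo = zhi = extent[0] / 2.0
    axis = int(rng.integers(d - 2, d))  # one of the two in-plane axes
    side = rng.integers(2)
    pos = rng.uniform(0.15, 0.85, d) * extent
    if d == 3:
        pos[0] = rng.uniform(zlo, zhi) if zhi > zlo else zlo
    pos[axis] = 0.0 if side == 0 else extent[axis]
    direction = rng.normal(size=d)
    direction[axis] = (1.0 if side == 0 else -1.0) * (1.0 + abs(direction[axis]))
    if d == 3:
        direction[0] *= 0.2  # vessels run mostly in-plane
    direction /= np.linalg.norm(direction)
    step = 1.0
    pts = [pos.copy()]
    for _ in range(int(3 * extent.max())):
        wiggle = rng.normal(size=d) * 0.10
        if d == 3:
            wiggle[0] *= 0.3
        direction = direction + wiggle
        direction /= np.linalg.norm(direction)
        pos = pos + step * direction
        if d == 3:  # keep the tube inside the axial extent
            pos[0] = float(np.clip(pos[0], zlo, zhi))
            if pos[0] in (zlo, zhi):
                direction[0] = 0.0
        pts.append(pos.copy())
        if np.any(pos < -2.0) or np.any(pos > extent + 2.0):
            break
    return np.asarray(pts)


def generate_vessels(
    config: FovConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render the vessel channel and its ground truth."""
    if any(s == 0 for s in config.shape):
        raise ConfigurationError("zero-sized shape")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lines, radii = [], []
    for _ in range(config.n_vessels):
        r = float(rng.uniform(*config.vessel_radius_range))
        lines.append(_random_centerline(config, rng, radius=r))
        radii.append(r)
    intensity, mask = render_tubes(lines, radii, config.shape, config.voxel_size)
    truth = GroundTruth(vessel_mask=mask, vessel_centerlines=lines, vessel_radii=radii)
    return intensity, truth


def _stamp_ball(
    array: np.ndarray,
    center_um: np.ndarray,
    radius: float,
    value: float,
    vs: np.ndarray,
    mask: np.ndarray | None = None,
) -> None:
    """Paint ``value`` into all voxels within ``radius`` um of a point."""
    shape = np.asarray(array.shape)
    lo = np.maximum(np.floor((center_um - radius) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + radius) / vs).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(lo[d], hi[d]) * vs[d] - center_um[d] for d in range(len(shape))],
        indexing="ij",
    )
    d2 = sum(g**2 for g in grids)
    sel = d2 <= radius**2
    window = tuple(slice(lo[d], hi[d]) for d in range(len(shape)))
    region = array[window]
    np.maximum(region, np.where(sel, value, -np.inf), out=region, where=sel)
    if mask is not None:
        mask[window] |= sel


def _soma_profile(
    channel: np.ndarray, center_um: np.ndarray, radius: float, vs: np.ndarray
) -> np.ndarray:
    """Render one soma ball with a bright center; returns its exact mask."""
    shape = np.asarray(channel.shape)
    lo = np.maximum(np.floor((center_um - radius) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + radius) / vs).astype(int) + 1, shape)
    grids = np.meshgrid(
        *[np.arange(lo[d], hi[d]) * vs[d] - center_um[d] for d in range(len(shape))],
        indexing="ij",
    )
    d2 = sum(g**2 for g in grids)
    sel = d2 <= radius**2
    prof = _SOMA_PEAK - (_SOMA_PEAK - _SOMA_RIM) * d2 / radius**2
    window = tuple(slice(lo[d], hi[d]) for d in range(len(shape)))
    region = channel[window]
    np.maximum(region, np.where(sel, prof, 0.0), out=region)
    full = np.zeros(channel.shape, dtype=bool)
    full[window] = sel
    return full


def _branch_directions(n: int, ndim: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random unit directions with pairwise angular separation."""
    min_sep = min(1.0, 0.7 * 2 * math.pi / max(n, 1)) if ndim == 2 else 0.7
    dirs: list[np.ndarray] = []
    for _ in range(n):
        best = None
        for _attempt in range(60):
            v = rng.normal(size=ndim)
            if ndim == 3:
                v[0] *= 0.35  # arbors spread mostly in-plane
            v /= np.linalg.norm(v)
            sep = min((math.acos(np.clip(v @ u, -1, 1)) for u in dirs), default=math.pi)
            if best is None or sep > best[0]:
                best = (sep, v)
            if sep >= min_sep:
                break
        dirs.append(best[1])
    return dirs


def _grow_branch(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A gently curving polyline of the requested arc length (1 um steps)."""
    pts = [start.copy()]
    w = direction.copy()
    pos = start.copy()
    n_steps = max(int(round(length)), 1)
    for _ in range(n_steps):
        w = w + 0.10 * rng.normal(size=w.size) + 0.05 * direction
        w /= np.linalg.norm(w)
        pos = pos + w  # 1 um step
        pts.append(pos.copy())
    return np.asarray(pts)


def _place_cells(
    config: FovConfig,
    vessel_truth: GroundTruth | None,
    rng: np.random.Generator,
    fov_id: str,
) -> list[dict]:
    """Choose soma centers/radii and VAM flags, respecting separations."""
    extent = config.extent_um
    vs = np.asarray(config.voxel_size, dtype=float)
    # each cell is vascular-associated independently with prob. vam_fraction,
    # so FOV-level VAM frequencies vary as they would across real fields
    n_vam_target = int(rng.binomial(config.n_cells, config.vam_fraction))
    if config.vam_fraction > 0 and (
        vessel_truth is None
        or vessel_truth.vessel_mask is None
        or not vessel_truth.vessel_mask.any()
    ):
        if n_vam_target > 0:
            raise ConfigurationError(
                "vam_fraction > 0 requires a non-empty vessel ground truth"
            )
    if vessel_truth is not None and vessel_truth.vessel_mask is not None and vessel_truth.vessel_mask.any():
        vessel_dist = distance_transform_edt(~vessel_truth.vessel_mask, sampling=vs)
    else:
        vessel_dist = np.full(config.shape, np.inf)

    # candidate voxel pools (um positions)
    all_idx = np.argwhere(np.ones(config.shape, dtype=bool))
    pos_um = all_idx * vs
    margin = config.soma_radius_range[1] + 1.0
    margins = np.full(config.ndim, margin)
    if config.ndim == 3:  # thin stacks: somata may clip at the axial faces
        margins[0] = max(min(margin, extent[0] / 2 - vs[0]), 0.0)
    in_margin = np.all((pos_um >= margins) & (pos_um <= extent - margins), axis=1)
    dist_flat = vessel_dist[tuple(all_idx.T)]

    placed: list[dict] = []

    def ok(center, r):
        return all(
            np.linalg.norm(center - p["center"]) >= r + p["radius"] + 4.0
            for p in placed
        )

    for i in range(config.n_cells):
        want_vam = i < n_vam_target
        r = float(rng.uniform(*config.soma_radius_range))
        if want_vam:
            pool = np.flatnonzero(in_margin & (dist_flat > 0) & (dist_flat < 0.5 * r))
        else:
            pool = np.flatnonzero(in_margin & (dist_flat > r + 6.0))
        if pool.size == 0:
            raise PlacementError(f"FOV {fov_id}: no admissible position for cell {i}")
        success = False
        for _ in range(500):
            center = pos_um[rng.choice(pool)].astype(float)
            if ok(center, r):
                success = True
                break
        if not success:
            raise PlacementError(
                f"FOV {fov_id}: could not place cell {i} without overlap"
            )
        placed.append({"center": center, "radius": r, "is_vam": want_vam})
    return placed


def generate_microglia(
    config: FovConfig,
    vessel_truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
    fov_id: str = "fov0",
) -> tuple[np.ndarray, GroundTruth]:
    """Render the microglia channel: bright somata plus branch trees.

    A ``vam_fraction`` subset of cells is placed with its soma overlapping
    the vessel mask; the remaining somata keep a clear gap (> 6 um) to
    every vessel.  All generative truth -- soma geometry, branch polylines
    and their arc lengths, leaf (endpoint) counts, hull and ramification
    index of the rendered mask, planted VAM flags -- is recorded.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    vs = np.asarray(config.voxel_size, dtype=float)
    channel = np.full(config.shape, _BG, dtype=np.float64)
    cell_labels = np.zeros(config.shape, dtype=np.int32)
    soma_labels = np.zeros(config.shape, dtype=np.int32)
    placed = _place_cells(config, vessel_truth, rng, fov_id)

    records = []
    branch_lengths: dict[int, list[float]] = {}
    for i, cell in enumerate(placed, start=1):
        center, r = cell["center"], cell["radius"]
        soma_mask = _soma_profile(channel, center, r, vs)
        cell_mask = soma_mask.copy()
        n_b = int(rng.integers(config.branches_per_cell[0], config.branches_per_cell[1] + 1))
        lengths = []
        for direction in _branch_directions(n_b, config.ndim, rng):
            L = float(rng.uniform(*config.branch_length_range))
            start = center + direction * (0.95 * r)
            poly = _grow_branch(start, direction, L, rng)
            lengths.append(_arc_length(poly))
            pts = _resample_polyline(poly, step=0.5)
            for t, p in zip(np.linspace(0, 1, len(pts)), pts):
                radius = 1.1 - 0.5 * t
                value = _BRANCH_PEAK - (_BRANCH_PEAK - _BRANCH_TIP) * t
                _stamp_ball(channel, p, radius, value, vs, mask=cell_mask)
        cell_labels[cell_mask] = i
        soma_labels[soma_mask] = i

        soma_size = float(soma_mask.sum() * np.prod(vs))
        footprint = soma_mask.any(axis=0) if config.ndim == 3 else soma_mask
        soma_area = float(footprint.sum() * vs[-1] * vs[-2])
        centroid = np.mean(np.argwhere(soma_mask), axis=0) * vs
        cell_size, hull_size, ri = hull_and_ramification(cell_mask, tuple(vs))
        records.append(
            {
                "cell_id": i,
                "is_vam": bool(cell["is_vam"]),
                "soma_radius_um": r,
                "soma_size": soma_size,
                "soma_footprint_um2": soma_area,
                **{f"centroid_{ax}": c for ax, c in zip("zyx"[-config.ndim:], centroid)},
                "n_branches": n_b,
                "n_endpoints": n_b,  # each branch ends in one leaf
                "max_branch_length": max(lengths) if lengths else 0.0,
                "total_branch_length": float(sum(lengths)),
                "cell_size": cell_size,
                "hull_size": hull_size,
                "ramification_index": ri,
            }
        )
        branch_lengths[i] = lengths

    truth = GroundTruth(
        vessel_mask=None if vessel_truth is None else vessel_truth.vessel_mask,
        vessel_centerlines=[] if vessel_truth is None else vessel_truth.vessel_centerlines,
        vessel_radii=[] if vessel_truth is None else vessel_truth.vessel_radii,
        cells=pd.DataFrame(records),
        cell_labels=cell_labels,
        soma_labels=soma_labels,
        branch_lengths=branch_lengths,
    )
    return channel, truth


def generate_leakage(
    config: FovConfig,
    vessel_truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Render the IgG channel: perivascular blobs above the leakage threshold.

    Blobs are added until the fraction of the FOV strictly above intensity
    25 reaches the configured target (overshoot bounded by one blob's
    area).  If the perivascular zone saturates first, a warning is issued
    and the achieved fraction is recorded.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    vs = np.asarray(config.voxel_size, dtype=float)
    channel = np.full(config.shape, 3.0, dtype=np.float64)
    target = config.leakage_fraction
    if target == 0:
        return channel, 0.0
    if (
        vessel_truth is not None
        and vessel_truth.vessel_mask is not None
        and vessel_truth.vessel_mask.any()
    ):
        vessel_dist = distance_transform_edt(~vessel_truth.vessel_mask, sampling=vs)
        zone = (vessel_dist > 0.5) & (vessel_dist < 12.0)
        if not zone.any():
            zone = vessel_dist > 0.5
    else:
        zone = np.ones(config.shape, dtype=bool)
    zone_idx = np.argwhere(zone)
    threshold = 25.0

    def achieved() -> float:
        return float((channel > threshold).mean())

    stale = 0
    for _ in range(20000):
        frac = achieved()
        if frac >= target:
            break
        center = zone_idx[rng.integers(len(zone_idx))] * vs
        r = float(rng.uniform(3.0, 6.0))
        peak = float(rng.uniform(60.0, 160.0))
        sigma = r / 1.8
        before = frac
        _stamp_gaussian_blob(channel, center, r, peak, sigma, vs)
        if achieved() <= before + 1e-12:
            stale += 1
            if stale > 200:
                warnings.warn(
                    "leakage target unreachable given vessel placement; "
                    f"achieved {achieved():.4f} of target {target:.4f}"
                )
                break
        else:
            stale = 0
    else:
        warnings.warn(
            f"leakage painting hit the iteration cap; achieved {achieved():.4f}"
        )
    return channel, achieved()


def _stamp_gaussian_blob(channel, center_um, radius, peak, sigma, vs) -> None:
    shape = np.asarray(channel.shape)
    reach = 2.2 * radius
    lo = np.maximum(np.floor((center_um - reach) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + reach) / vs).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(lo[d], hi[d]) * vs[d] - center_um[d] for d in range(len(shape))],
        indexing="ij",
    )
    d2 = sum(g**2 for g in grids)
    prof = peak * np.exp(-d2 / (2.0 * sigma**2))
    window = tuple(slice(lo[d], hi[d]) for d in range(len(shape)))
    np.maximum(channel[window], prof, out=channel[window])


def add_noise(
    channel: np.ndarray,
    sigma: float,
    poisson: bool = False,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Gaussian read noise plus optional Poisson shot noise, clipped to 8-bit."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0 and not poisson:
        return np.asarray(channel, dtype=np.float32).copy()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = np.asarray(channel, dtype=np.float64)
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return np.clip(out, 0.0, 255.0).astype(np.float32)


def generate_fov(config: FovConfig, fov_index: int = 0, fov_id: str | None = None) -> Fov:
    """Generate one complete FOV: vessel, microglia, and IgG channels + truth."""
    fov_id = fov_id or f"fov{fov_index}"
    rngs = _fov_rngs(config, fov_index)
    vessel_clean, vessel_truth = generate_vessels(config, rngs["vessels"])
    iba1_clean, truth = generate_microglia(config, vessel_truth, rngs["cells"], fov_id)
    igg_clean, leak = generate_leakage(config, vessel_truth, rngs["leakage"])
    truth.true_leakage_fraction = leak
    # mild optical blur on the vessel channel only smooths staircase artifacts
    vessel_clean = gaussian_filter(vessel_clean, sigma=0.5)
    clean = {"vessel": vessel_clean, "iba1": iba1_clean, "igg": igg_clean}
    noisy = {
        name: add_noise(arr, config.noise_sigma, config.poisson, rngs[f"noise_{name}"])
        for name, arr in clean.items()
    }
    return Fov(
        fov_id=fov_id,
        config=config,
        channels=noisy,
        clean_channels={k: v.astype(np.float32) for k, v in clean.items()},
        truth=truth,
    )


#: Morphology archetypes spanning the ramified-to-amoeboid continuum.
#: Values are typical feature means (2D-mode units: sizes um^2, lengths um).
ARCHETYPES = {
    "ramified": dict(
        soma_size=110.0, n_endpoints=14.0, n_branchpoints=9.0,
        max_branch_length=38.0, total_branch_length=240.0,
        cell_size=950.0, hull_size=8200.0, ramification_index=0.115,
    ),
    "hypertrophic": dict(
        soma_size=190.0, n_endpoints=9.0, n_branchpoints=6.0,
        max_branch_length=28.0, total_branch_length=150.0,
        cell_size=1250.0, hull_size=5200.0, ramification_index=0.24,
    ),
    "bushy": dict(
        soma_size=240.0, n_endpoints=5.0, n_branchpoints=3.0,
        max_branch_length=16.0, total_branch_length=70.0,
        cell_size=1100.0, hull_size=2600.0, ramification_index=0.42,
    ),
    "amoeboid": dict(
        soma_size=300.0, n_endpoints=1.0, n_branchpoints=0.0,
        max_branch_length=6.0, total_branch_length=8.0,
        cell_size=900.0, hull_size=1200.0, ramification_index=0.75,
    ),
}


def sample_archetype_features(
    n_per_archetype: int,
    rng: np.random.Generator | int | None = None,
    cv: float = 0.10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample single-cell feature vectors from the four morphology archetypes.

    Each feature is the archetype mean perturbed by multiplicative
    lognormal noise with coefficient of variation ``cv``.  Returns the
    feature DataFrame and the archetype label per row.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows, labels = [], []
    for name, means in ARCHETYPES.items():
        for _ in range(n_per_archetype):
            noise = rng.lognormal(mean=0.0, sigma=cv, size=len(means))
            rows.append({k: v * z for (k, v), z in zip(means.items(), noise)})
            labels.append(name)
    return pd.DataFrame(rows), np.asarray(labels)
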