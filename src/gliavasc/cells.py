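"""Microglia soma / single-cell segmentation and IgG-leakage quantification.

Somata are detected on the IBA1-like channel by automatic global
thresholding (by default the widest-gap cut of the three-class Otsu split,
which isolates the bright soma class; two-class Otsu and Triangle are also
available) followed by connected components and a physical size filter
(strictly > 60 um^2 by default).  Single cells are the
foreground components containing exactly one soma; components containing
two or more somata are "touching" and excluded from single-cell
morphometrics.  IgG extravasation is quantified with a fixed intensity
threshold of 25 (8-bit scale) and a strict > 5 um^2 size filter, reported
as percent of the field of view.

All size filters use strict inequalities.  In 3D, "area" filters are
applied to the component's footprint projected onto the xy plane (the
convention for anisotropic stacks whose z-extent is thin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle

from gliavasc.exceptions import DegenerateDistributionError, InconsistencyError


def _threshold_otsu3_upper(channel: np.ndarray) -> float:
    """Soma-isolating automatic threshold from the three-class Otsu split.

    IBA1-like fields have up to three intensity populations -- background,
    processes, somata.  Of the two Otsu cut points, the one spanning the
    widest inter-class mean gap separates the bright soma class from the
    rest: with a process class present that is the upper cut; in
    process-free (amoeboid) fields the three-class split subdivides the
    soma class itself and the lower cut is the soma/background boundary.
    Degenerate histograms fall back to the two-class threshold.
    """
    from gliavasc.vessels import otsu3_thresholds

    v = np.asarray(channel, dtype=np.float64).ravel()
    try:
        thr = otsu3_thresholds(v)
    except DegenerateDistributionError:
        return float(threshold_otsu(np.asarray(channel)))
    lo_class = v[v <= thr.low]
    mid_class = v[(v > thr.low) & (v <= thr.high)]
    hi_class = v[v > thr.high]
    if mid_class.size == 0 or hi_class.size == 0 or lo_class.size == 0:
        return thr.high
    gap_low = mid_class.mean() - lo_class.mean()
    gap_high = hi_class.mean() - mid_class.mean()
    return thr.low if gap_low >= gap_high else thr.high

__all__ = [
    "SegmentationParams",
    "CellRecord",
    "SomaSegmentation",
    "SingleCellExtraction",
    "segment_somata",
    "extract_single_cells",
    "quantify_igg",
]

_THRESHOLD_METHODS = {
    "otsu": threshold_otsu,
    "otsu3_upper": _threshold_otsu3_upper,
    "triangle": threshold_triangle,
}


@dataclass(frozen=True)
class SegmentationParams:
    soma_min_area: float = 60.0          # um^2, strict >
    threshold_method: str = "otsu3_upper"  # soma detection: otsu3_upper | otsu | triangle
    cell_threshold_method: str = "triangle"  # single-cell masks: captures dim processes
    single_cell_min_size: int = 2000     # pixels, strict >, 2D human mode only
    igg_threshold: float = 25.0          # 8-bit intensity, strict >
    igg_min_area: float = 5.0            # um^2, strict >

    def __post_init__(self):
        if self.soma_min_area <= 0 or self.igg_min_area <= 0:
            raise ValueError("area filters must be positive")
        for m in (self.threshold_method, self.cell_threshold_method):
            if m not in _THRESHOLD_METHODS:
                raise ValueError(f"unknown threshold method {m!r}")
        if not 0 <= self.igg_threshold <= 255:
            raise ValueError("igg_threshold must lie in the 8-bit range")


@dataclass
class CellRecord:
    """One segmented microglia: full mask, soma mask, and soma geometry."""

    cell_id: int
    mask: np.ndarray
    soma_mask: np.ndarray
    soma_centroid_um: tuple[float, ...]
    soma_size: float  # um^2 in 2D, um^3 in 3D
    soma_footprint_um2: float  # xy-projected area; equals soma_size in 2D


@dataclass
class SomaSegmentation:
    labels: np.ndarray           # relabeled 1..n after the size filter
    count: int
    areas_um2: np.ndarray        # xy-footprint area per retained soma
    sizes: np.ndarray            # um^2 (2D) / um^3 (3D) per retained soma
    threshold: float


@dataclass
class SingleCellExtraction:
    cells: list
    n_foreground_components: int
    n_touching_excluded: int
    n_size_excluded: int


def _footprint_area(mask: np.ndarray, voxel_size) -> float:
    """Physical area of the mask's xy projection (identity in 2D)."""
    vs = np.asarray(voxel_size, dtype=float)
    if mask.ndim == 3:
        mask = mask.any(axis=0)
    return float(mask.sum() * vs[-1] * vs[-2])


def _physical_size(mask: np.ndarray, voxel_size) -> float:
    return float(mask.sum() * np.prod(np.asarray(voxel_size, dtype=float)))


def segment_somata(
    channel: np.ndarray,
    voxel_size: tuple[float, ...],
    params: SegmentationParams | None = None,
) -> SomaSegmentation:
    """Detect microglia somata: automatic threshold, components, size filter.

    Components whose xy-footprint area is strictly greater than
    ``soma_min_area`` (um^2) are retained.  A blank channel yields zero
    somata, not an error.
    """
    params = params or SegmentationParams()
    channel = np.asarray(channel, dtype=np.float64)
    if not np.isfinite(channel).all():
        raise ValueError("soma channel contains non-finite values")
    if channel.max() == channel.min():
        return SomaSegmentation(
            labels=np.zeros(channel.shape, dtype=np.int32),
            count=0,
            areas_um2=np.array([]),
            sizes=np.array([]),
            threshold=float(channel.max()),
        )
    thr = float(_THRESHOLD_METHODS[params.threshold_method](channel))
    binary = channel > thr
    structure = ndi.generate_binary_structure(channel.ndim, channel.ndim)
    labels, n = ndi.label(binary, structure=structure)
    out = np.zeros_like(labels, dtype=np.int32)
    areas, sizes = [], []
    next_id = 0
    for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        area = _footprint_area(comp, voxel_size)
        if area > params.soma_min_area:
            next_id += 1
            out[sl][comp] = next_id
            areas.append(area)
            sizes.append(_physical_size(comp, voxel_size))
    return SomaSegmentation(
        labels=out,
        count=next_id,
        areas_um2=np.asarray(areas),
        sizes=np.asarray(sizes),
        threshold=thr,
    )


def extract_single_cells(
    channel: np.ndarray,
    soma_seg: SomaSegmentation,
    voxel_size: tuple[float, ...],
    params: SegmentationParams | None = None,
    mode: str = "rodent",
) -> SingleCellExtraction:
    """Extract single-cell masks around detected somata.

    The channel is thresholded with the ``cell_threshold_method`` (Triangle
    by default -- dim distal processes sit near the histogram foot, which
    Triangle preserves and Otsu cuts; the 2D human mode always uses
    Triangle) and each foreground component is assigned to the soma it
    contains.  Components with >= 2 somata are flagged touching and
    excluded; in human mode components of <= ``single_cell_min_size``
    pixels are also excluded.
    """
    params = params or SegmentationParams()
    if mode not in ("rodent", "human"):
        raise ValueError("mode must be 'rodent' or 'human'")
    channel = np.asarray(channel, dtype=np.float64)
    method = threshold_triangle if mode == "human" else _THRESHOLD_METHODS[
        params.cell_threshold_method
    ]
    thr = float(method(channel))
    binary = channel > thr
    binary |= soma_seg.labels > 0  # a soma is foreground by definition
    structure = ndi.generate_binary_structure(channel.ndim, channel.ndim)
    comp_labels, n_comp = ndi.label(binary, structure=structure)

    vs = np.asarray(voxel_size, dtype=float)
    cells: list[CellRecord] = []
    n_touching = 0
    n_size = 0
    for soma_id in range(1, soma_seg.count + 1):
        soma_mask = soma_seg.labels == soma_id
        owners = np.unique(comp_labels[soma_mask])
        owners = owners[owners > 0]
        if owners.size == 0:
            raise InconsistencyError(
                f"soma {soma_id} lies outside every foreground component"
            )

    counted = set()
    for comp_sl, comp_id in zip(ndi.find_objects(comp_labels), range(1, n_comp + 1)):
        comp = comp_labels == comp_id
        somata = np.unique(soma_seg.labels[comp])
        somata = somata[somata > 0]
        if somata.size == 0:
            continue
        if somata.size >= 2:
            n_touching += 1
            counted.update(int(s) for s in somata)
            continue
        if mode == "human" and comp.sum() <= params.single_cell_min_size:
            n_size += 1
            continue
        soma_id = int(somata[0])
        soma_mask = soma_seg.labels == soma_id
        centroid = tuple(np.mean(np.argwhere(soma_mask), axis=0) * vs)
        cells.append(
            CellRecord(
                cell_id=soma_id,
                mask=comp,
                soma_mask=soma_mask,
                soma_centroid_um=centroid,
                soma_size=_physical_size(soma_mask, voxel_size),
                soma_footprint_um2=_footprint_area(soma_mask, voxel_size),
            )
        )
    return SingleCellExtraction(
        cells=cells,
        n_foreground_components=n_comp,
        n_touching_excluded=n_touching,
        n_size_excluded=n_size,
    )


def quantify_igg(
    channel: np.ndarray,
    voxel_size: tuple[float, ...],
    params: SegmentationParams | None = None,
) -> float:
    """IgG extravasation as percent of the field of view.

    Pixels strictly above the fixed threshold (default 25) form candidate
    leakage; components whose physical area is <= 5 um^2 are dropped as
    speckle; the retained fraction of the FOV is returned in percent.
    """
    params = params or SegmentationParams()
    channel = np.asarray(channel, dtype=np.float64)
    if not np.isfinite(channel).all():
        raise ValueError("IgG channel contains non-finite values")
    binary = channel > params.igg_threshold
    if not binary.any():
        return 0.0
    structure = ndi.generate_binary_structure(channel.ndim, channel.ndim)
    labels, n = ndi.label(binary, structure=structure)
    retained = 0
    for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        if _footprint_area(comp, voxel_size) > params.igg_min_area:
            retained += int(comp.sum())
    return 100.0 * retained / channel.size
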