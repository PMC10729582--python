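"""Vascular-associated microglia (VAM) classification and densities.

A microglia is vascular-associated when its soma is attached to a labeled
vessel.  Attachment is operationalized as the minimum Euclidean distance
from any soma voxel to the vessel mask (computed on the anisotropic
distance transform) being at most ``attach_distance``; the default is one
voxel diagonal, i.e. direct contact up to discretization.  Densities are
standardized to cells per mm^2 of the xy field-of-view footprint.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

__all__ = ["classify_vam", "vam_table", "density_per_mm2"]


def default_attach_distance(voxel_size) -> float:
    """One voxel diagonal in um -- 'direct contact' on the grid."""
    vs = np.asarray(voxel_size, dtype=float)
    return float(np.sqrt(np.sum(vs**2)))


def classify_vam(
    soma_labels: np.ndarray,
    vessel_mask: np.ndarray,
    voxel_size: tuple[float, ...],
    attach_distance: float | None = None,
) -> pd.DataFrame:
    """Per-cell VAM flags and soma-vessel gaps.

    Returns a DataFrame with columns ``cell_id``, ``is_vam``, ``gap_um``.
    An empty vessel mask yields all-false flags (with a warning) and
    infinite gaps.
    """
    soma_labels = np.asarray(soma_labels)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if soma_labels.shape != vessel_mask.shape:
        raise ValueError("soma labels and vessel mask must share one grid")
    if attach_distance is None:
        attach_distance = default_attach_distance(voxel_size)
    ids = np.unique(soma_labels)
    ids = ids[ids > 0]
    if not vessel_mask.any():
        warnings.warn("vessel mask is empty; no cell can be vascular-associated")
        return pd.DataFrame(
            {"cell_id": ids, "is_vam": False, "gap_um": np.inf}
        )
    dist = distance_transform_edt(~vessel_mask, sampling=voxel_size)
    gaps = np.array(
        [float(dist[soma_labels == i].min()) for i in ids]
    )
    return pd.DataFrame(
        {"cell_id": ids, "is_vam": gaps <= attach_distance, "gap_um": gaps}
    )


def density_per_mm2(count: int, shape, voxel_size) -> float:
    """Cells per mm^2 of xy footprint (3D stacks use their xy projection area)."""
    vs = np.asarray(voxel_size, dtype=float)
    shape = tuple(shape)
    area_um2 = shape[-1] * vs[-1] * shape[-2] * vs[-2]
    if area_um2 <= 0:
        raise ValueError("FOV area must be positive")
    return count / (area_um2 / 1.0e6)


def vam_table(per_cell: pd.DataFrame, shape, voxel_size) -> pd.Series:
    """FOV-level VAM summary from the per-cell classification table."""
    n_cells = len(per_cell)
    n_vam = int(per_cell["is_vam"].sum())
    freq = n_vam / n_cells if n_cells else float("nan")
    return pd.Series(
        {
            "n_cells": n_cells,
            "n_vam": n_vam,
            "vam_frequency": freq,
            "microglia_density_mm2": density_per_mm2(n_cells, shape, voxel_size),
            "vam_density_mm2": density_per_mm2(n_vam, shape, voxel_size),
        }
    )
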