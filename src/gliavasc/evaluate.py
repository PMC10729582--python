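"""Evaluation helpers: comparing pipeline output against ground truth.

Segmentation label ids are assigned in raster order and do not correspond
to generator cell ids, so per-cell comparisons match somata to truth
records by nearest soma centroid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["dice", "match_somata_to_truth", "vam_accuracy"]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def _truth_centroids(truth_cells: pd.DataFrame, ndim: int) -> np.ndarray:
    cols = [f"centroid_{ax}" for ax in "zyx"[-ndim:]]
    return truth_cells[cols].to_numpy(dtype=float)


def match_somata_to_truth(
    soma_labels: np.ndarray,
    truth_cells: pd.DataFrame,
    voxel_size,
) -> pd.DataFrame:
    """Match each segmented soma to its nearest ground-truth cell.

    Returns one row per segmented soma: ``soma_label``, ``truth_index``
    (row index into the truth table), and ``centroid_distance_um``.
    """
    vs = np.asarray(voxel_size, dtype=float)
    ids = np.unique(soma_labels)
    ids = ids[ids > 0]
    tc = _truth_centroids(truth_cells, soma_labels.ndim)
    rows = []
    for lab in ids:
        c = np.mean(np.argwhere(soma_labels == lab), axis=0) * vs
        d = np.linalg.norm(tc - c, axis=1)
        j = int(np.argmin(d))
        rows.append(
            {"soma_label": int(lab), "truth_index": truth_cells.index[j],
             "centroid_distance_um": float(d[j])}
        )
    return pd.DataFrame(rows)


def vam_accuracy(
    vam_flags: pd.DataFrame,
    soma_labels: np.ndarray,
    truth_cells: pd.DataFrame,
    voxel_size,
) -> float:
    """Fraction of cells whose recovered VAM flag matches the planted one."""
    match = match_somata_to_truth(soma_labels, truth_cells, voxel_size)
    merged = vam_flags.merge(match, left_on="cell_id", right_on="soma_label")
    planted = truth_cells.loc[merged["truth_index"], "is_vam"].to_numpy(dtype=bool)
    return float(np.mean(merged["is_vam"].to_numpy(dtype=bool) == planted))
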