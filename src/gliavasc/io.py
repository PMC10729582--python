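"""Reading and writing multi-channel TIFF FOVs with physical metadata.

One FOV is one multi-channel TIFF (channels labeled iba1 / vessel / igg)
plus a JSON sidecar carrying the voxel size in um and, for synthetic data,
the full generator configuration.  The in-plane pixel size is additionally
stored in the TIFF resolution tags.  Ground truth travels as CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from gliavasc.synthetic import Fov, FovConfig

__all__ = ["write_fov", "read_fov", "read_channels"]

CHANNEL_ORDER = ("iba1", "vessel", "igg")


def write_fov(fov: Fov, directory: str | Path) -> Path:
    """Write one FOV: TIFF + sidecar JSON + ground-truth CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([fov.channels[c] for c in CHANNEL_ORDER])
    tiff_path = directory / f"{fov.fov_id}.tif"
    vs = fov.config.voxel_size
    # resolution tags are pixels per um in-plane
    tifffile.imwrite(
        tiff_path,
        stack.astype(np.float32),
        resolution=(1.0 / vs[-1], 1.0 / vs[-2]),
        metadata={"axes": "CZYX" if stack.ndim == 4 else "CYX"},
    )
    sidecar = {
        "fov_id": fov.fov_id,
        "channels": list(CHANNEL_ORDER),
        "voxel_size_um": list(vs),
        "config": dataclasses.asdict(fov.config),
    }
    (directory / f"{fov.fov_id}.json").write_text(json.dumps(sidecar, indent=2))
    if fov.truth.cells is not None:
        fov.truth.cells.to_csv(directory / f"{fov.fov_id}_cells_truth.csv", index=False)
    return tiff_path


def read_channels(tiff_path: str | Path) -> tuple[dict, tuple[float, ...]]:
    """Load the channel dict and voxel size for one written FOV."""
    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    channels = {name: stack[i] for i, name in enumerate(sidecar["channels"])}
    return channels, tuple(sidecar["voxel_size_um"])


def read_fov(tiff_path: str | Path) -> Fov:
    """Reload a written synthetic FOV (channels + config; truth tables stay on disk)."""
    tiff_path = Path(tiff_path)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    channels, _ = read_channels(tiff_path)
    cfg = sidecar["config"]
    for key in ("shape", "voxel_size", "vessel_radius_range", "soma_radius_range",
                "branches_per_cell", "branch_length_range"):
        cfg[key] = tuple(cfg[key])
    config = FovConfig(**cfg)
    from gliavasc.synthetic import GroundTruth

    return Fov(
        fov_id=sidecar["fov_id"],
        config=config,
        channels=channels,
        clean_channels={},
        truth=GroundTruth(),
    )
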