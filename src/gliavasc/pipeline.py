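"""End-to-end orchestration: generate -> segment -> measure -> associate -> cluster -> stats.

A run is described by one declarative YAML/dict config (all module
parameters pre-filled with the study defaults: Frangi scales 1-5, gamma
fraction 0.4, soma filter > 60 um^2, IgG threshold 25 / > 5 um^2, k = 4
clusters).  The run writes per-FOV and pooled CSV tables plus a JSON
manifest with the fully resolved config, software version, per-file SHA-256
digests, and any warnings.  Runs with identical configs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gliavasc._version import __version__
from gliavasc.cells import SegmentationParams, extract_single_cells, quantify_igg, segment_somata
from gliavasc.cluster import cluster_morphologies
from gliavasc.exceptions import ConfigurationError
from gliavasc.morpho import FEATURE_NAMES, compute_features
from gliavasc.stats import holm_sidak, welch_t
from gliavasc.synthetic import FovConfig, generate_fov
from gliavasc.vam import classify_vam, vam_table
from gliavasc.vessels import FrangiParams, segment_vessels

__all__ = ["GroupSpec", "RunConfig", "RunManifest", "validate_config", "run_pipeline"]

_FOV_KEYS = {f.name for f in dataclasses.fields(FovConfig)}
_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationParams)}
_FRANGI_KEYS = {f.name for f in dataclasses.fields(FrangiParams)}
_CLUSTER_DEFAULTS = {"k": 4, "seed": 42, "n_neighbors": 15, "min_dist": 0.1, "embed": True}
_VAM_DEFAULTS = {"attach_distance": None}
_MORPH_DEFAULTS = {"prune_um": 1.0}


@dataclass
class GroupSpec:
    name: str
    n_fovs: int = 4
    fov_overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = 0
    mode: str = "rodent-3D"  # rodent-3D | human-2D
    groups: list = field(default_factory=lambda: [GroupSpec("control"), GroupSpec("hypertensive")])
    fov: dict = field(default_factory=dict)            # base FovConfig overrides
    segmentation: dict = field(default_factory=dict)   # SegmentationParams overrides
    frangi: dict = field(default_factory=dict)         # FrangiParams overrides
    vam: dict = field(default_factory=lambda: dict(_VAM_DEFAULTS))
    clustering: dict = field(default_factory=lambda: dict(_CLUSTER_DEFAULTS))
    morphometrics: dict = field(default_factory=lambda: dict(_MORPH_DEFAULTS))

    def fov_config(self, group: GroupSpec) -> FovConfig:
        params = {**self.fov, **group.fov_overrides, "seed": self.seed}
        if self.mode == "human-2D" and "shape" not in params:
            params["shape"] = (256, 256)
            params["voxel_size"] = (1.25, 1.25)
        for key in ("shape", "voxel_size", "vessel_radius_range", "soma_radius_range",
                    "branches_per_cell", "branch_length_range"):
            if key in params:
                params[key] = tuple(params[key])
        return FovConfig(**params)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)

    def frangi_params(self) -> FrangiParams:
        p = dict(self.frangi)
        if "scales" in p:
            p["scales"] = tuple(p["scales"])
        return FrangiParams(**p)


@dataclass
class RunManifest:
    config: dict
    version: str
    digests: dict
    warnings: list


def _check_keys(block: dict, allowed: set, name: str, errors: list) -> None:
    for key in block:
        if key not in allowed:
            errors.append(f"{name}: unknown key {key!r}")


def validate_config(raw: dict | str | Path | None) -> RunConfig:
    """Normalize a raw config (dict, YAML text, or path) into a RunConfig.

    Every unknown key is an error (no silent ignoring); all errors are
    aggregated into one ConfigurationError.  An empty config yields the
    all-defaults run.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        path = Path(raw)
        text = path.read_text() if path.exists() else str(raw)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")

    errors: list[str] = []
    top_allowed = {"seed", "mode", "groups", "fov", "segmentation", "frangi",
                   "vam", "clustering", "morphometrics"}
    _check_keys(raw, top_allowed, "config", errors)
    mode = raw.get("mode", "rodent-3D")
    if mode not in ("rodent-3D", "human-2D"):
        errors.append(f"mode: unknown mode {mode!r}")

    groups = []
    seen = set()
    for i, g in enumerate(raw.get("groups", [{"name": "control"}, {"name": "hypertensive"}])):
        if not isinstance(g, dict):
            errors.append(f"groups[{i}]: must be a mapping")
            continue
        _check_keys(g, {"name", "n_fovs", "fov"}, f"groups[{i}]", errors)
        name = g.get("name", f"group{i}")
        if name in seen:
            errors.append(f"groups[{i}]: duplicate group name {name!r} (FOV ids collide)")
        seen.add(name)
        fov_over = g.get("fov", {})
        _check_keys(fov_over, _FOV_KEYS - {"seed"}, f"groups[{i}].fov", errors)
        groups.append(GroupSpec(name=name, n_fovs=int(g.get("n_fovs", 4)),
                                fov_overrides=fov_over))

    for block, allowed in (("fov", _FOV_KEYS - {"seed"}), ("segmentation", _SEG_KEYS),
                           ("frangi", _FRANGI_KEYS), ("vam", set(_VAM_DEFAULTS)),
                           ("clustering", set(_CLUSTER_DEFAULTS)),
                           ("morphometrics", set(_MORPH_DEFAULTS))):
        _check_keys(raw.get(block, {}) or {}, allowed, block, errors)

    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        mode=mode,
        groups=groups,
        fov=raw.get("fov", {}) or {},
        segmentation=raw.get("segmentation", {}) or {},
        frangi=raw.get("frangi", {}) or {},
        vam={**_VAM_DEFAULTS, **(raw.get("vam", {}) or {})},
        clustering={**_CLUSTER_DEFAULTS, **(raw.get("clustering", {}) or {})},
        morphometrics={**_MORPH_DEFAULTS, **(raw.get("morphometrics", {}) or {})},
    )
    if not errors:
        # materialize parameter objects so range errors surface here too
        try:
            cfg.segmentation_params()
            cfg.frangi_params()
            for g in cfg.groups:
                cfg.fov_config(g)
        except (ConfigurationError, ValueError, TypeError) as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict | str | Path | None, outdir: str | Path) -> RunManifest:
    """Execute the full pipeline on a synthetic dataset and write the report.

    Stages per FOV: generate channels -> Frangi vessel segmentation ->
    soma detection -> VAM classification -> IgG quantification ->
    single-cell extraction -> morphometrics.  Pooled: feature
    standardization + Ward clustering (+ UMAP), cluster frequencies per
    group, and Welch tests on FOV-level VAM frequency between groups.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg_params = config.segmentation_params()
    frangi_params = config.frangi_params()
    mode = "human" if config.mode == "human-2D" else "rodent"
    prune_um = float(config.morphometrics["prune_um"])

    fov_rows, cell_rows = [], []
    caught: list[str] = []
    fov_index = 0
    for group in config.groups:
        fov_cfg = config.fov_config(group)
        for j in range(group.n_fovs):
            fov_id = f"{group.name}_fov{j}"
            with _warnings.catch_warnings(record=True) as wlist:
                _warnings.simplefilter("always")
                fov = generate_fov(fov_cfg, fov_index=fov_index, fov_id=fov_id)
                try:
                    vessel_seg = segment_vessels(fov.channels["vessel"], frangi_params)
                    soma_seg = segment_somata(fov.channels["iba1"], fov_cfg.voxel_size, seg_params)
                    vam_cells = classify_vam(
                        soma_seg.labels, vessel_seg.mask, fov_cfg.voxel_size,
                        attach_distance=config.vam["attach_distance"],
                    )
                    fov_summary = vam_table(vam_cells, fov_cfg.shape, fov_cfg.voxel_size)
                    igg_percent = quantify_igg(fov.channels["igg"], fov_cfg.voxel_size, seg_params)
                    extraction = extract_single_cells(
                        fov.channels["iba1"], soma_seg, fov_cfg.voxel_size, seg_params, mode=mode
                    )
                    for cell in extraction.cells:
                        feats = compute_features(cell, fov_cfg.voxel_size, prune_um=prune_um)
                        row = {"group": group.name, "fov_id": fov_id, "cell_id": cell.cell_id}
                        row.update({k: getattr(feats, k) for k in FEATURE_NAMES})
                        cell_rows.append(row)
                except Exception as exc:
                    raise RuntimeError(
                        f"stage failure in FOV {fov_id}: {exc}"
                    ) from exc
            caught.extend(f"{fov_id}: {w.message}" for w in wlist)
            fov_rows.append(
                {
                    "group": group.name,
                    "fov_id": fov_id,
                    "soma_count": soma_seg.count,
                    "igg_percent": igg_percent,
                    "n_touching_excluded": extraction.n_touching_excluded,
                    **fov_summary.to_dict(),
                }
            )
            fov_index += 1

    fov_df = pd.DataFrame(fov_rows)
    cells_df = pd.DataFrame(cell_rows)
    outputs: dict[str, Path] = {}

    fov_path = outdir / "fov_summary.csv"
    fov_df.to_csv(fov_path, index=False)
    outputs["fov_summary"] = fov_path
    cells_path = outdir / "cells.csv"
    cells_df.to_csv(cells_path, index=False)
    outputs["cells"] = cells_path

    ccfg = config.clustering
    if len(cells_df) >= max(int(ccfg["k"]), 2) + 1:
        features = cells_df[list(FEATURE_NAMES)]
        # drop features that are constant across this dataset (cannot be z-scored)
        keep = [c for c in features.columns if features[c].nunique() > 1]
        result = cluster_morphologies(
            features[keep],
            metadata=cells_df[["group"]],
            k=int(ccfg["k"]),
            n_neighbors=int(ccfg["n_neighbors"]),
            min_dist=float(ccfg["min_dist"]),
            seed=int(ccfg["seed"]),
            embed=bool(ccfg["embed"]),
        )
        labels_df = cells_df[["group", "fov_id", "cell_id"]].copy()
        labels_df["cluster"] = result.labels
        if result.embedding is not None:
            labels_df["umap_1"] = result.embedding[:, 0]
            labels_df["umap_2"] = result.embedding[:, 1]
        lab_path = outdir / "cluster_labels.csv"
        labels_df.to_csv(lab_path, index=False)
        outputs["cluster_labels"] = lab_path
        freq_path = outdir / "cluster_frequencies.csv"
        result.frequency_tables["group"].to_csv(freq_path)
        outputs["cluster_frequencies"] = freq_path

    stats_rows = []
    names = [g.name for g in config.groups]
    pair_results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = fov_df.loc[fov_df["group"] == names[i], "vam_frequency"].dropna()
            b = fov_df.loc[fov_df["group"] == names[j], "vam_frequency"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                try:
                    res = welch_t(a, b)
                except ValueError as exc:
                    caught.append(f"welch {names[i]} vs {names[j]}: {exc}")
                    continue
                pair_results.append((f"{names[i]} vs {names[j]}", res))
    if pair_results:
        adjusted = holm_sidak([r.p for _, r in pair_results])
        for (label, res), padj in zip(pair_results, adjusted):
            stats_rows.append(
                {"test": "welch_t", "variable": "vam_frequency", "comparison": label,
                 "statistic": res.statistic, "df": res.df, "p": res.p, "p_adjusted": padj}
            )
    stats_path = outdir / "stats.csv"
    stats_cols = ["test", "variable", "comparison", "statistic", "df", "p", "p_adjusted"]
    pd.DataFrame(stats_rows, columns=stats_cols).to_csv(stats_path, index=False)
    outputs["stats"] = stats_path

    manifest = RunManifest(
        config=_resolved_config_dict(config),
        version=__version__,
        digests={name: _sha256(path) for name, path in sorted(outputs.items())},
        warnings=sorted(set(caught)),
    )
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, default=str)
    )
    return manifest


def _resolved_config_dict(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    out["groups"] = [dataclasses.asdict(g) for g in config.groups]
    out["resolved"] = {
        "segmentation": dataclasses.asdict(config.segmentation_params()),
        "frangi": dataclasses.asdict(config.frangi_params()),
        "fov_per_group": {
            g.name: dataclasses.asdict(config.fov_config(g)) for g in config.groups
        },
    }
    return out
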