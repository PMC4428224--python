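"""End-to-end pipeline: config, stage orchestration, reproducible outputs.

A YAML/JSON config names exactly one input mode — per-subject node time
series (TSV), 4D NIfTI volumes plus a node table and RSN maps, or
precomputed connectome matrices — along with the group label file, the
screening thresholds, and an output directory. ``run_pipeline`` executes
parcellation -> connectivity -> block summaries -> group comparison ->
edgewise consistency -> MVPA/behavior, writing every stage's tables plus a
run manifest (config hash, seed, package version, output checksums). A rerun
with the same config and seed is bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocks import (block_metadata, coordinates_table, enumerate_blocks,
                     mean_connectivity_table, summarize_blocks)
from .compare import compare_blocks, write_comparison_tables
from .connectivity import (SubjectConnectome, build_connectome,
                           connectome_from_voxels, detrend_series,
                           extract_sphere_timeseries, standardize_series)
from .consistency import consistency_tables
from .mvpa import (behavior_block_correlations, correlate_dimensional_scores,
                   fit_classifier_cv)
from .parcellation import Parcellation, assign_modules, prune

logger = logging.getLogger(__name__)

STAGES = ("parcellate", "connect", "summarize", "compare", "consistency",
          "mvpa", "correlate")


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds. Exactly one input mode is set."""

    output_dir: str = "modconn_out"
    group_file: str | None = None
    behavior_file: str | None = None
    # input mode 1: directory of per-subject time x node TSVs
    timeseries_dir: str | None = None
    # input mode 2: 4D NIfTI per subject + node table + RSN z maps
    nifti_files: dict[str, str] | None = None
    node_table: str | None = None
    rsn_maps: dict[str, str] | None = None
    # input mode 3: directory of precomputed connectome TSVs
    connectome_dir: str | None = None
    # parcellation with module labels (modes 1 and 3)
    parcellation_file: str | None = None

    z_threshold: float = 3.0
    d_threshold: float = 0.5
    retention_threshold: float = 0.05
    consistency_threshold: float = 0.33
    r_threshold: float = 0.5
    n_folds: int = 4
    radius_mm: float = 5.0
    poly_order: int = 2
    min_module_size: int = 2
    seed: int = 0
    group_names: tuple[str, str] = ("G1", "G2")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        modes = [self.timeseries_dir is not None,
                 self.nifti_files is not None,
                 self.connectome_dir is not None]
        if sum(modes) != 1:
            raise ValueError("exactly one input mode must be set "
                             "(timeseries_dir | nifti_files | connectome_dir)")
        for name in ("z_threshold", "d_threshold", "retention_threshold",
                     "consistency_threshold", "r_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.group_file is None:
            raise ValueError("group_file is required")
        self.group_names = tuple(self.group_names)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        if cfg.extra:
            logger.warning("unrecognized config keys: %s",
                           sorted(cfg.extra))
        return cfg

    def content_hash(self) -> str:
        # output_dir is where results land, not what they are: keep it out
        # of the hash so reruns into different directories stay comparable
        payload = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_groups(path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"subject_id", "group"} <= set(df.columns):
        raise ValueError("group file needs subject_id and group columns")
    return df.set_index("subject_id")["group"].astype(int)


def _load_parcellation(config: PipelineConfig) -> Parcellation:
    if config.parcellation_file is None:
        raise ValueError("parcellation_file required for this input mode")
    parc = Parcellation.from_csv(config.parcellation_file,
                                 radius_mm=config.radius_mm)
    return parc


def _parcellate_from_maps(config: PipelineConfig) -> Parcellation:
    import nibabel as nib

    nodes = pd.read_csv(config.node_table)
    from .parcellation import sample_sphere_statistic

    z = {}
    for module, path in config.rsn_maps.items():
        img = nib.load(path)
        z[module] = [sample_sphere_statistic(img, row[["x", "y", "z"]].to_numpy(float),
                                             config.radius_mm)
                     for _, row in nodes.iterrows()]
    node_z = pd.DataFrame(z, index=nodes["node_id"])
    labels = assign_modules(node_z, config.z_threshold)
    nodes = nodes.assign(module=labels.to_numpy(),
                         max_z=node_z.max(axis=1).to_numpy())
    parc, report = prune(nodes, config.min_module_size,
                         radius_mm=config.radius_mm)
    logger.info("parcellation: %d input, %d unassigned, %d retained",
                report.n_input, report.n_unassigned, report.n_retained)
    return parc


def _connect_timeseries(config: PipelineConfig, parc: Parcellation,
                        groups: pd.Series) -> list[SubjectConnectome]:
    tsdir = Path(config.timeseries_dir)
    node_ids = parc.nodes["node_id"].tolist()
    connectomes = []
    for sid in groups.index:
        path = tsdir / f"{sid}_timeseries.tsv"
        if not path.exists():
            raise FileNotFoundError(f"time series for subject {sid!r}: {path}")
        ts = pd.read_csv(path, sep="\t")
        missing = set(node_ids) - set(ts.columns)
        if missing:
            raise ValueError(f"subject {sid!r} lacks node columns "
                             f"{sorted(missing)[:5]}...")
        X = ts[node_ids].to_numpy(dtype=float)
        X = standardize_series(detrend_series(X, config.poly_order))
        connectomes.append(build_connectome(X, sid, tuple(node_ids)))
    return connectomes


def _connect_nifti(config: PipelineConfig, parc: Parcellation,
                   groups: pd.Series) -> list[SubjectConnectome]:
    import nibabel as nib

    centers = parc.nodes[["x", "y", "z"]].to_numpy(dtype=float)
    node_ids = tuple(parc.nodes["node_id"])
    connectomes = []
    for sid in groups.index:
        if sid not in config.nifti_files:
            raise FileNotFoundError(f"no NIfTI listed for subject {sid!r}")
        img = nib.load(config.nifti_files[sid])
        voxel_sets = extract_sphere_timeseries(img, centers, config.radius_mm)
        connectomes.append(connectome_from_voxels(voxel_sets, sid, node_ids,
                                                  config.poly_order))
    return connectomes


def _load_connectomes(config: PipelineConfig,
                      groups: pd.Series) -> list[SubjectConnectome]:
    cdir = Path(config.connectome_dir)
    out = []
    for sid in groups.index:
        path = cdir / f"{sid}_connectome.tsv"
        if not path.exists():
            raise FileNotFoundError(f"connectome for subject {sid!r}: {path}")
        out.append(SubjectConnectome.from_tsv(path, sid))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig,
                 stop_after: str = "correlate") -> dict:
    """Execute the pipeline through ``stop_after`` and write stage outputs.

    Returns a dict of in-memory results (parcellation, connectomes,
    summaries, tables, MVPA results, manifest path).
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; one of {STAGES}")
    last = STAGES.index(stop_after)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    groups = _load_groups(config.group_file)
    results["groups"] = groups

    # -- parcellate ---------------------------------------------------------
    logger.info("stage parcellate")
    try:
        if config.nifti_files is not None:
            parc = _parcellate_from_maps(config)
        else:
            parc = _load_parcellation(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'parcellate' failed: {exc}") from exc
    parc.to_csv(out / "parcellation_labels.csv")
    results["parcellation"] = parc
    if last < 1:
        return _finish(results, config, out)

    # -- connect ------------------------------------------------------------
    logger.info("stage connect")
    try:
        if config.timeseries_dir is not None:
            connectomes = _connect_timeseries(config, parc, groups)
        elif config.nifti_files is not None:
            connectomes = _connect_nifti(config, parc, groups)
        else:
            connectomes = _load_connectomes(config, groups)
    except Exception as exc:
        raise RuntimeError(f"stage 'connect' failed: {exc}") from exc
    for c in connectomes:
        c.to_tsv(out / f"{c.subject_id}_connectome.tsv")
    results["connectomes"] = connectomes
    if last < 2:
        return _finish(results, config, out)

    # -- summarize ----------------------------------------------------------
    logger.info("stage summarize")
    try:
        block_index = enumerate_blocks(parc)
        summaries = summarize_blocks(connectomes, block_index)
    except Exception as exc:
        raise RuntimeError(f"stage 'summarize' failed: {exc}") from exc
    coords = coordinates_table(summaries)
    coords.rename_axis("subject_id").to_csv(out / "coordinates.csv",
                                            float_format="%.8f")
    mean_connectivity_table(summaries).rename_axis("subject_id").to_csv(
        out / "block_mean_connectivity.csv", float_format="%.8f")
    with open(out / "block_metadata.json", "w") as fh:
        json.dump(block_metadata(summaries, block_index, groups), fh, indent=1)
    results.update(block_index=block_index, summaries=summaries,
                   coordinates=coords)
    if last < 3:
        return _finish(results, config, out)

    # -- compare ------------------------------------------------------------
    logger.info("stage compare")
    try:
        comparison = compare_blocks(summaries, groups, config.d_threshold,
                                    config.group_names)
    except Exception as exc:
        raise RuntimeError(f"stage 'compare' failed: {exc}") from exc
    write_comparison_tables(comparison, out)
    results["comparison"] = comparison
    if last < 4:
        return _finish(results, config, out)

    # -- consistency --------------------------------------------------------
    logger.info("stage consistency")
    try:
        effects, cons = consistency_tables(
            connectomes, groups, block_index, config.d_threshold,
            config.retention_threshold, config.consistency_threshold,
            modulewise=comparison)
    except Exception as exc:
        raise RuntimeError(f"stage 'consistency' failed: {exc}") from exc
    for cls, table in cons.items():
        table.to_csv(out / f"consistency_{cls}.csv", index=False,
                     float_format="%.6f")
    results.update(edge_effects=effects, consistency=cons)
    if last < 5:
        return _finish(results, config, out)

    # -- mvpa ---------------------------------------------------------------
    logger.info("stage mvpa")
    behavior = None
    if config.behavior_file is not None:
        behavior = pd.read_csv(config.behavior_file,
                               index_col="subject_id").reindex(coords.index)
    try:
        mvpa = {"connectivity": fit_classifier_cv(
            coords, groups, config.n_folds, config.seed,
            feature_set="connectivity")}
        if behavior is not None:
            mvpa["behavior"] = fit_classifier_cv(
                behavior, groups, config.n_folds, config.seed,
                feature_set="behavior")
            combined = pd.concat([coords, behavior], axis=1)
            mvpa["combined"] = fit_classifier_cv(
                combined, groups, config.n_folds, config.seed,
                feature_set="combined")
    except Exception as exc:
        raise RuntimeError(f"stage 'mvpa' failed: {exc}") from exc
    for name, res in mvpa.items():
        res.to_json(out / f"mvpa_{name}.json")
    results["mvpa"] = mvpa
    if last < 6:
        return _finish(results, config, out)

    # -- correlate ----------------------------------------------------------
    logger.info("stage correlate")
    try:
        if behavior is not None:
            corr = behavior_block_correlations(coords, behavior,
                                               config.r_threshold)
            corr.to_csv(out / "behavior_correlations.csv", index=False,
                        float_format="%.6f")
            results["behavior_correlations"] = corr
            if "behavior" in mvpa:
                r, p = correlate_dimensional_scores(
                    mvpa["connectivity"].dimensional_scores,
                    mvpa["behavior"].dimensional_scores)
                scatter = pd.DataFrame({
                    "connectivity_score": mvpa["connectivity"].dimensional_scores,
                    "behavior_score": mvpa["behavior"].dimensional_scores,
                })
                scatter.rename_axis("subject_id").to_csv(
                    out / "score_scatter.csv", float_format="%.8f")
                with open(out / "score_correlation.json", "w") as fh:
                    json.dump({"r": r, "p": p}, fh, indent=1)
                results["score_correlation"] = (r, p)
        else:
            logger.info("no behavior file; correlate stage skipped")
    except Exception as exc:
        raise RuntimeError(f"stage 'correlate' failed: {exc}") from exc
    return _finish(results, config, out)


def _finish(results: dict, config: PipelineConfig, out: Path) -> dict:
    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "modconn",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "outputs": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
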