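"""Synthetic multi-subject connectivity data with planted group effects.

The generator emulates the data regime of a two-group resting-state study:
two groups of subjects (default 12 + 12), a node system partitioned into
canonical modules, and per-subject node time series drawn from a multivariate
normal whose correlation matrix is block structured — one correlation value
per module pair (and per module, within). Group differences are planted in
the *population* block correlations, so modulewise effect sizes are
controlled by ``delta_corr`` and the number of timepoints rather than by
ad-hoc per-subject noise. Behavior scores are linear functions of selected
block strengths plus Gaussian noise.

Time series are temporally white by default (an optional AR(1) coefficient
adds serial correlation); the downstream analysis consumes only correlation
matrices, for which whiteness is the minimal sufficient structure.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import CANONICAL_MODULES, Parcellation

logger = logging.getLogger(__name__)

#: Module sizes of the reference 209-node, 9-module system.
REFERENCE_MODULE_SIZES: tuple[int, ...] = (14, 6, 16, 21, 29, 29, 38, 30, 26)


def default_between_corr(n_modules: int, positive: float = 0.12,
                         negative: float = -0.12) -> np.ndarray:
    """Sign-mixed default module-pair correlations.

    Modules are split into an early-sensory/default-mode system (first four
    canonical modules) and a task-positive system (the rest); pairs within a
    system correlate positively, pairs across systems negatively — a crude
    but standard cartoon of resting-state anticorrelation that yields both
    positive- and negative-mean blocks.
    """
    half = min(4, n_modules)
    system = np.array([0] * half + [1] * (n_modules - half))
    B = np.where(system[:, None] == system[None, :], positive, negative)
    np.fill_diagonal(B, 0.0)
    return B.astype(float)


@dataclass
class SimulationDesign:
    """Study-design parameters for the synthetic generator.

    ``planted_effects`` entries are ``(module_a, module_b, delta_corr,
    group_direction)``: the favored group (1 or 2) has its population
    correlation in that block shifted by ``delta_corr``. ``behavior_couplings``
    entries are ``(module_a, module_b, loading, noise_sd)``: each defines one
    behavior measure equal to ``loading`` times the subject's block coordinate
    plus Gaussian noise.
    """

    n_subjects_per_group: int = 12
    n_modules: int = 9
    nodes_per_module: tuple[int, ...] = REFERENCE_MODULE_SIZES
    n_timepoints: int = 200
    base_within_corr: float = 0.45
    base_between_corr: np.ndarray | None = None
    planted_effects: list[tuple[str, str, float, int]] = field(default_factory=list)
    voxels_per_node: int = 1
    voxel_noise_sd: float = 0.5
    behavior_couplings: list[tuple[str, str, float, float]] = field(default_factory=list)
    ar1: float = 0.0
    psd_repair_tolerance: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.nodes_per_module = tuple(int(k) for k in self.nodes_per_module)
        if len(self.nodes_per_module) != self.n_modules:
            raise ValueError("nodes_per_module length must equal n_modules")
        if any(k <= 0 for k in self.nodes_per_module):
            raise ValueError("every module must have at least one node")
        if self.n_subjects_per_group < 1 or self.n_timepoints < 3:
            raise ValueError("need >=1 subject per group and >=3 timepoints")
        if self.base_between_corr is None:
            self.base_between_corr = default_between_corr(self.n_modules)
        self.base_between_corr = np.asarray(self.base_between_corr, dtype=float)
        if self.base_between_corr.shape != (self.n_modules, self.n_modules):
            raise ValueError("base_between_corr must be n_modules x n_modules")
        if not np.allclose(self.base_between_corr, self.base_between_corr.T):
            raise ValueError("base_between_corr must be symmetric")

    @property
    def module_names(self) -> tuple[str, ...]:
        if self.n_modules <= len(CANONICAL_MODULES):
            return CANONICAL_MODULES[: self.n_modules]
        return tuple(f"M{i + 1}" for i in range(self.n_modules))

    def module_index(self, name: str) -> int:
        try:
            return self.module_names.index(name)
        except ValueError:
            raise KeyError(f"unknown module {name!r}") from None

    def group_target_corr(self, group: int) -> np.ndarray:
        """Module-level target correlation matrix (K x K) for group 1 or 2.

        The diagonal holds the within-module off-diagonal correlation.
        """
        K = self.n_modules
        M = self.base_between_corr.copy()
        np.fill_diagonal(M, self.base_within_corr)
        for mod_a, mod_b, delta, direction in self.planted_effects:
            if direction not in (1, 2):
                raise ValueError("group_direction must be 1 or 2")
            if direction == group:
                a, b = self.module_index(mod_a), self.module_index(mod_b)
                M[a, b] += delta
                M[b, a] = M[a, b]
        if np.any(np.abs(M) >= 1.0):
            raise ValueError("target correlations must stay inside (-1, 1)")
        return M


@dataclass
class GroundTruth:
    """What was planted: per-group module-level target correlations, the
    affected blocks with their signed directions, and behavior loadings."""

    module_names: tuple[str, ...]
    target_corr_group1: np.ndarray
    target_corr_group2: np.ndarray
    planted_blocks: list[tuple[str, str, float, int]]
    behavior_loadings: list[tuple[str, str, float, float]]

    def to_json(self, path) -> None:
        payload = {
            "module_names": list(self.module_names),
            "target_corr_group1": self.target_corr_group1.tolist(),
            "target_corr_group2": self.target_corr_group2.tolist(),
            "planted_blocks": [list(p) for p in self.planted_blocks],
            "behavior_loadings": [list(b) for b in self.behavior_loadings],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_parcellation(design: SimulationDesign) -> Parcellation:
    """Synthetic node table: module labels in canonical order plus
    deterministic pseudo-MNI coordinates drawn from the design seed."""
    rng = np.random.default_rng(np.random.SeedSequence(design.seed,
                                                       spawn_key=(0,)))
    names = design.module_names
    rows = []
    n = 0
    for m, k in zip(names, design.nodes_per_module):
        center = rng.uniform(-60, 60, size=3)
        for _ in range(k):
            xyz = center + rng.normal(scale=12.0, size=3)
            rows.append((f"n{n:03d}", *np.round(xyz, 1), m))
            n += 1
    nodes = pd.DataFrame(rows, columns=["node_id", "x", "y", "z", "module"])
    return Parcellation(nodes, module_order=names)


def _node_target_matrix(design: SimulationDesign, group: int) -> np.ndarray:
    M = design.group_target_corr(group)
    labels = np.repeat(np.arange(design.n_modules), design.nodes_per_module)
    R = M[labels[:, None], labels[None, :]]
    np.fill_diagonal(R, 1.0)
    return R


def nearest_psd_correlation(R: np.ndarray, tolerance: float = 0.01,
                            eps: float = 1e-10) -> np.ndarray:
    """Repair a near-PSD correlation matrix by eigenvalue clipping.

    Negative eigenvalues are clipped to ``eps``, the matrix is rebuilt and
    rescaled to unit diagonal. Raises if any entry moves by more than
    ``tolerance``.
    """
    w, V = np.linalg.eigh(R)
    if w.min() >= 0:
        return R
    logger.warning("target correlation matrix not PSD (min eigenvalue %.3g); "
                   "clipping", w.min())
    w = np.clip(w, eps, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    shift = np.abs(R2 - R).max()
    if shift > tolerance:
        raise ValueError(f"PSD repair moved a correlation by {shift:.4f} "
                         f"(> tolerance {tolerance})")
    return R2


def _subject_rng(design: SimulationDesign, subject_index: int) -> np.random.Generator:
    # one child stream per subject, keyed by index: adding subjects never
    # perturbs existing subjects' draws
    return np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(1, subject_index)))


def generate_group_timeseries(
    design: SimulationDesign,
    parcellation: Parcellation | None = None,
) -> tuple[dict[str, np.ndarray], pd.Series, GroundTruth]:
    """Draw per-subject node time series for both groups.

    Returns ``(series, groups, truth)`` where ``series`` maps subject id to a
    (time x node) array, ``groups`` maps subject id to group label 1 or 2,
    and ``truth`` records the planted structure. Identical design and seed
    give bit-identical output.
    """
    if parcellation is None:
        parcellation = generate_parcellation(design)
    n_nodes = parcellation.n_nodes
    chol = {}
    truth_targets = {}
    for g in (1, 2):
        R = _node_target_matrix(design, g)
        R = nearest_psd_correlation(R, design.psd_repair_tolerance)
        chol[g] = np.linalg.cholesky(R + 1e-12 * np.eye(n_nodes))
        truth_targets[g] = design.group_target_corr(g)

    series: dict[str, np.ndarray] = {}
    labels = {}
    n = design.n_subjects_per_group
    for s in range(2 * n):
        group = 1 if s < n else 2
        rng = _subject_rng(design, s)
        white = rng.standard_normal((design.n_timepoints, n_nodes))
        if design.ar1:
            phi = design.ar1
            for t in range(1, design.n_timepoints):
                white[t] += phi * white[t - 1]
            white *= np.sqrt(1 - phi ** 2)
        sid = f"sub-{s + 1:02d}"
        series[sid] = white @ chol[group].T
        labels[sid] = group
    truth = GroundTruth(
        module_names=design.module_names,
        target_corr_group1=truth_targets[1],
        target_corr_group2=truth_targets[2],
        planted_blocks=list(design.planted_effects),
        behavior_loadings=list(design.behavior_couplings),
    )
    return series, pd.Series(labels, name="group"), truth


def generate_voxel_timeseries(node_series: np.ndarray, voxels_per_node: int,
                              voxel_noise_sd: float, seed: int) -> np.ndarray:
    """Expand one node's latent series into a (time x voxel) matrix.

    Every voxel is the shared latent series plus independent Gaussian noise,
    so the first principal component of the voxel set points along the
    latent series.
    """
    if voxels_per_node < 1:
        raise ValueError("voxels_per_node must be >= 1")
    x = np.asarray(node_series, dtype=float).reshape(-1, 1)
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=voxel_noise_sd, size=(x.shape[0], voxels_per_node))
    return x + noise


def behavior_from_coordinates(coordinates: pd.DataFrame,
                              loadings: dict[str, float],
                              noise_sd: float,
                              rng: np.random.Generator) -> pd.Series:
    """score_s = sum_b loading_b * coordinate_{s,b} + N(0, noise_sd)."""
    score = np.zeros(len(coordinates))
    for block, loading in loadings.items():
        score += loading * coordinates[block].to_numpy(dtype=float)
    score += rng.normal(scale=noise_sd, size=len(coordinates))
    return pd.Series(score, index=coordinates.index)


def generate_behavior_scores(coordinates: pd.DataFrame,
                             couplings: list[tuple[str, float, float]],
                             seed: int,
                             names: list[str] | None = None) -> pd.DataFrame:
    """One behavior measure per coupling ``(block_label, loading, noise_sd)``.

    ``coordinates`` is the subject x block table; unknown block labels raise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    cols = {}
    for i, (block, loading, noise_sd) in enumerate(couplings):
        if block not in coordinates.columns:
            raise KeyError(f"coupled block {block!r} not in coordinate table")
        name = names[i] if names else f"measure_{i + 1}"
        cols[name] = behavior_from_coordinates(coordinates, {block: loading},
                                               noise_sd, rng)
    return pd.DataFrame(cols, index=coordinates.index)


def noise_sd_for_target_r(loading: float, coord_sd: float, r: float) -> float:
    """Noise level making the population score–coordinate correlation |r|."""
    if not 0 < abs(r) <= 1:
        raise ValueError("target r must be in (0, 1]")
    return abs(loading) * coord_sd * np.sqrt(1.0 / r ** 2 - 1.0)


def write_dataset(outdir, series: dict[str, np.ndarray], groups: pd.Series,
                  parcellation: Parcellation, truth: GroundTruth,
                  behavior: pd.DataFrame | None = None) -> None:
    """Write a generated dataset as plain text (TSV/CSV/JSON)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    node_ids = parcellation.nodes["node_id"].tolist()
    for sid, mat in series.items():
        pd.DataFrame(mat, columns=node_ids).to_csv(
            out / f"{sid}_timeseries.tsv", sep="\t", index=False,
            float_format="%.6f")
    groups.rename_axis("subject_id").to_frame().to_csv(out / "groups.csv")
    parcellation.to_csv(out / "parcellation.csv")
    truth.to_json(out / "ground_truth.json")
    if behavior is not None:
        behavior.rename_axis("subject_id").to_csv(out / "behavior.csv",
                                                  float_format="%.6f")
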