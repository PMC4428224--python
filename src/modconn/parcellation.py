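"""Node-to-module assignment and pruning.

Each network node is a small sphere in MNI space (10 mm diameter by
convention). Nodes are assigned to canonical resting-state network (RSN)
modules by winner-take-all over a set of RSN z-statistic maps: a node joins
the module whose map has the largest z value at the node's location, provided
that value exceeds a threshold (default z > 3); otherwise it stays
unassigned. Unassigned nodes and undersized modules (e.g. a module holding a
single node) are pruned before any block-level analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical ordered module set: medial / occipital-pole / lateral visual,
#: default mode, sensorimotor, auditory, executive control, right and left
#: frontoparietal networks.
CANONICAL_MODULES: tuple[str, ...] = (
    "Med Vis", "OP Vis", "Lat Vis", "DMN", "SM", "Aud", "EC", "FPR", "FPL",
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Parcellation:
    """An ordered node table with module membership.

    ``nodes`` has columns ``node_id``, ``x``, ``y``, ``z`` (MNI mm) and
    ``module``; rows are sorted by module in canonical order (module order is
    the order labels appear in ``module_order``), nodes within a module keep
    their input order. ``radius_mm`` is the node sphere radius.
    """

    nodes: pd.DataFrame
    module_order: tuple[str, ...] = CANONICAL_MODULES
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        missing = {"node_id", "module"} - set(self.nodes.columns)
        if missing:
            raise ValueError(f"node table lacks columns {sorted(missing)}")
        bad = set(self.nodes["module"]) - set(self.module_order)
        if bad:
            raise ValueError(f"module labels outside canonical set: {sorted(bad)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def modules(self) -> tuple[str, ...]:
        """Modules actually present, in canonical order."""
        present = set(self.nodes["module"])
        return tuple(m for m in self.module_order if m in present)

    def module_sizes(self) -> dict[str, int]:
        counts = self.nodes["module"].value_counts()
        return {m: int(counts[m]) for m in self.modules}

    def node_indices(self, module: str) -> np.ndarray:
        """Positional indices (into the canonical node order) of a module."""
        return np.flatnonzero((self.nodes["module"] == module).to_numpy())

    def sorted_canonical(self) -> "Parcellation":
        order = {m: i for i, m in enumerate(self.module_order)}
        idx = sorted(range(len(self.nodes)),
                     key=lambda i: (order[self.nodes["module"].iat[i]], i))
        return Parcellation(self.nodes.iloc[idx].reset_index(drop=True),
                            self.module_order, self.radius_mm)

    def to_csv(self, path) -> None:
        self.nodes.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Parcellation":
        return cls(pd.read_csv(path), **kwargs).sorted_canonical()


@dataclass
class PruneReport:
    n_input: int
    n_unassigned: int
    dropped_modules: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0


def assign_modules(
    node_z: pd.DataFrame | np.ndarray,
    z_threshold: float = 3.0,
    map_names: tuple[str, ...] | None = None,
) -> pd.Series:
    """Winner-take-all module assignment from node-by-map z statistics.

    Parameters
    ----------
    node_z
        Matrix of z statistics, one row per node and one column per candidate
        RSN map. Column names (or ``map_names``) must be canonical module
        labels; their canonical order, not their column order, decides ties.
    z_threshold
        A node is assigned only if its best map exceeds this value.

    Returns
    -------
    A Series of module labels, ``"unassigned"`` where no map wins.
    """
    if isinstance(node_z, pd.DataFrame):
        maps = tuple(node_z.columns)
        z = node_z.to_numpy(dtype=float)
        index = node_z.index
    else:
        if map_names is None:
            raise ValueError("map_names required for array input")
        maps = tuple(map_names)
        z = np.asarray(node_z, dtype=float)
        index = pd.RangeIndex(z.shape[0])
    if np.isnan(z).any():
        i, j = np.argwhere(np.isnan(z))[0]
        raise ValueError(f"NaN z-statistic for node {index[i]!r} in map {maps[j]!r}")

    # evaluate maps in canonical order so argmax resolves ties canonically
    canon = [m for m in CANONICAL_MODULES if m in maps] + \
            [m for m in maps if m not in CANONICAL_MODULES]
    col = {m: maps.index(m) for m in maps}
    zc = z[:, [col[m] for m in canon]]
    best = np.argmax(zc, axis=1)
    best_z = zc[np.arange(len(zc)), best]
    labels = np.where(best_z > z_threshold,
                      np.array(canon, dtype=object)[best], UNASSIGNED)

    ties = (zc == best_z[:, None]).sum(axis=1) > 1
    for i in np.flatnonzero(ties & (best_z > z_threshold)):
        tied = [canon[j] for j in np.flatnonzero(zc[i] == best_z[i])]
        logger.warning("node %r: tie between maps %s resolved to %r by canonical order",
                       index[i], tied, labels[i])
    return pd.Series(labels, index=index, name="module")


def sample_sphere_statistic(volume, center_mm, radius_mm: float,
                            stat: str = "mean") -> float:
    """Read a statistic image inside a sphere around an MNI coordinate.

    ``volume`` is a nibabel spatial image (3D). Voxels whose mm-center lies
    within ``radius_mm`` of ``center_mm`` are pooled with ``stat`` ("mean" or
    "peak"); voxels outside the array are ignored. If the sphere is so small
    that no voxel center falls inside it, the single voxel containing the
    center is used. A sphere entirely outside the image raises.
    """
    data = np.asanyarray(volume.dataobj, dtype=float)
    affine = volume.affine
    idx = _sphere_voxel_indices(data.shape, affine, np.asarray(center_mm, float),
                                float(radius_mm))
    vals = data[idx[:, 0], idx[:, 1], idx[:, 2]]
    if stat == "mean":
        return float(vals.mean())
    if stat == "peak":
        return float(vals.max())
    raise ValueError(f"unknown sphere statistic {stat!r}")


def _sphere_voxel_indices(shape, affine, center_mm: np.ndarray,
                          radius_mm: float) -> np.ndarray:
    """Voxel ijk indices whose mm centers fall inside a sphere (n x 3)."""
    inv = np.linalg.inv(affine)
    cvox = (inv @ np.append(center_mm, 1.0))[:3]
    # bounding box in voxel space, padded by the radius over the voxel size
    zooms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    lo = np.floor(cvox - radius_mm / zooms - 1).astype(int)
    hi = np.ceil(cvox + radius_mm / zooms + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(shape[:3]) - 1)
    if np.any(lo > hi):
        raise ValueError(f"sphere at {center_mm} mm lies entirely outside the image")
    ii, jj, kk = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(lo, hi)),
                             indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = (affine @ np.column_stack([ijk, np.ones(len(ijk))]).T).T[:, :3]
    inside = ((mm - center_mm) ** 2).sum(axis=1) <= radius_mm ** 2
    if inside.any():
        return ijk[inside]
    # tiny sphere: fall back to the containing voxel
    nearest = np.round(cvox).astype(int)
    if np.any(nearest < 0) or np.any(nearest >= np.array(shape[:3])):
        raise ValueError(f"sphere at {center_mm} mm lies entirely outside the image")
    return nearest[None, :]


def prune(
    nodes: pd.DataFrame,
    min_module_size: int = 2,
    module_order: tuple[str, ...] = CANONICAL_MODULES,
    radius_mm: float = 5.0,
) -> tuple[Parcellation, PruneReport]:
    """Drop unassigned nodes and undersized modules.

    ``nodes`` needs ``node_id`` and ``module`` columns (``module`` may contain
    ``"unassigned"``). Returns the retained parcellation in canonical order
    plus a report. Raises if fewer than two modules survive, since no
    between-module blocks would exist.
    """
    report = PruneReport(n_input=len(nodes),
                         n_unassigned=int((nodes["module"] == UNASSIGNED).sum()))
    kept = nodes[nodes["module"] != UNASSIGNED]
    sizes = kept["module"].value_counts()
    small = sizes[sizes < min_module_size]
    report.dropped_modules = {m: int(small[m]) for m in small.index}
    if report.dropped_modules:
        logger.info("pruning undersized modules: %s", report.dropped_modules)
    kept = kept[~kept["module"].isin(small.index)].reset_index(drop=True)
    report.n_retained = len(kept)
    if kept["module"].nunique() < 2:
        raise ValueError("fewer than 2 modules survive pruning; "
                         "no between-module blocks possible")
    parc = Parcellation(kept, module_order, radius_mm).sorted_canonical()
    return parc, report
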