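"""Module-module blocks and their SVD summaries.

The strict upper triangle of the node x node connectivity matrix is
partitioned into module-module blocks: one block per module (within-module
edges) plus one per unordered module pair (between-module edges) — K within
plus K(K-1)/2 between blocks for K modules. Each block's edges, stacked
across subjects into an (m_i x n_subjects) matrix and row-demeaned, are
summarized by the first singular pair: the left vector gives per-edge
loadings, and the right vector (scaled by the singular value) gives one
principal-component coordinate per subject — a compact per-subject summary
of the block's connectivity pattern. The block's mean connectivity keeps the
sign context that the SVD summary discards.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import SubjectConnectome
from .parcellation import Parcellation

logger = logging.getLogger(__name__)

BLOCK_SEP = " - "


def block_label(module_a: str, module_b: str) -> str:
    return f"{module_a}{BLOCK_SEP}{module_b}"


@dataclass(frozen=True)
class Block:
    module_a: str
    module_b: str
    edges: np.ndarray  # (m, 2) node index pairs, i < j, canonical order

    @property
    def label(self) -> str:
        return block_label(self.module_a, self.module_b)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def within(self) -> bool:
        return self.module_a == self.module_b


@dataclass(frozen=True)
class BlockIndex:
    """Ordered blocks partitioning the strict upper triangle of the graph."""

    blocks: tuple[Block, ...]
    n_nodes: int

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.blocks)

    def __getitem__(self, key) -> Block:
        if isinstance(key, str):
            for b in self.blocks:
                if b.label == key:
                    return b
            raise KeyError(key)
        return self.blocks[key]

    def total_edges(self) -> int:
        return sum(b.n_edges for b in self.blocks)


@dataclass(frozen=True)
class BlockSummary:
    """First-singular-pair summary of one block across subjects."""

    label: str
    left_vector: np.ndarray        # unit-norm edge loadings (m,)
    coordinates: pd.Series         # per-subject PC score (right vector * sigma1)
    variance_explained: float
    mean_connectivity: pd.Series   # per-subject block mean edge correlation


def enumerate_blocks(parcellation: Parcellation) -> BlockIndex:
    """List all within- and between-module blocks in canonical order.

    Edge order inside a block: within-module blocks take pairs (i, j), i < j,
    in node order; between-module blocks pair every node of the first module
    with every node of the second. Blocks are ordered (a, a), (a, b>a), ...
    by canonical module index.
    """
    mods = parcellation.modules
    if len(mods) < 2:
        raise ValueError("need at least 2 modules to enumerate blocks")
    idx = {m: parcellation.node_indices(m) for m in mods}
    blocks = []
    for ai, a in enumerate(mods):
        for b in mods[ai:]:
            if a == b:
                ia = idx[a]
                pairs = [(int(ia[p]), int(ia[q]))
                         for p in range(len(ia)) for q in range(p + 1, len(ia))]
            else:
                pairs = [(min(int(i), int(j)), max(int(i), int(j)))
                         for i in idx[a] for j in idx[b]]
            blocks.append(Block(a, b, np.array(pairs, dtype=int).reshape(-1, 2)))
    bi = BlockIndex(tuple(blocks), parcellation.n_nodes)
    n = parcellation.n_nodes
    assert bi.total_edges() == n * (n - 1) // 2
    return bi


def block_edge_matrix(connectomes: list[SubjectConnectome],
                      block: Block) -> np.ndarray:
    """Stack one block's edge values across subjects: (m_i x n_subjects)."""
    node_ids = connectomes[0].node_ids
    for c in connectomes[1:]:
        if c.node_ids != node_ids:
            raise ValueError(f"node order mismatch between subjects "
                             f"{connectomes[0].subject_id!r} and {c.subject_id!r}")
    i, j = block.edges[:, 0], block.edges[:, 1]
    return np.column_stack([c.matrix[i, j] for c in connectomes])


def block_svd_summary(edge_matrix: np.ndarray,
                      subject_ids: list[str] | None = None,
                      label: str = "") -> BlockSummary:
    """First singular pair of the row-demeaned edge x subject matrix.

    Coordinates are the first right singular vector scaled by the first
    singular value (principal-component scores); because row-demeaning makes
    the all-ones vector a right null vector, the coordinates sum to zero.
    The sign is fixed so coordinates correlate positively with the
    per-subject block mean connectivity; an exactly-zero correlation falls
    back to a positive first nonzero edge loading (logged).
    """
    X = np.asarray(edge_matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    m, n = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean_conn = X.mean(axis=0)
    Xd = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xd):
        raise ValueError("no variation across subjects in this block")
    U, s, Vt = np.linalg.svd(Xd, full_matrices=False)
    u, sigma, v = U[:, 0], s[0], Vt[0]
    coords = sigma * v
    align = float(np.dot(coords - coords.mean(), mean_conn - mean_conn.mean()))
    if align < 0:
        u, coords = -u, -coords
    elif align == 0:
        nz = np.flatnonzero(u)
        logger.warning("block %s: coordinates uncorrelated with block mean; "
                       "sign fixed by first nonzero loading", label or "?")
        if nz.size and u[nz[0]] < 0:
            u, coords = -u, -coords
    var_expl = float(sigma ** 2 / np.sum(s ** 2))
    if subject_ids is None:
        subject_ids = [f"sub-{k + 1:02d}" for k in range(n)]
    return BlockSummary(label=label, left_vector=u,
                        coordinates=pd.Series(coords, index=subject_ids),
                        variance_explained=var_expl,
                        mean_connectivity=pd.Series(mean_conn, index=subject_ids))


def block_mean_connectivity(connectomes: list[SubjectConnectome], block: Block,
                            groups: pd.Series | None = None):
    """Per-subject block mean edge correlation, plus per-group means/signs.

    Returns ``(per_subject, group_means, dominant_signs)``; the latter two
    are None when ``groups`` is not given.
    """
    M = block_edge_matrix(connectomes, block)
    per_subject = pd.Series(M.mean(axis=0),
                            index=[c.subject_id for c in connectomes])
    if groups is None:
        return per_subject, None, None
    g = groups.reindex(per_subject.index)
    group_means = per_subject.groupby(g).mean()
    dominant = {k: int(np.sign(v)) for k, v in group_means.items()}
    return per_subject, group_means, dominant


def summarize_blocks(connectomes: list[SubjectConnectome],
                     block_index: BlockIndex) -> dict[str, BlockSummary]:
    """SVD summary for every block, keyed by block label."""
    sids = [c.subject_id for c in connectomes]
    out = {}
    for block in block_index:
        M = block_edge_matrix(connectomes, block)
        out[block.label] = block_svd_summary(M, sids, label=block.label)
    return out


def coordinates_table(summaries: dict[str, BlockSummary]) -> pd.DataFrame:
    """Subject x block table of principal-component coordinates."""
    return pd.DataFrame({lbl: s.coordinates for lbl, s in summaries.items()})


def mean_connectivity_table(summaries: dict[str, BlockSummary]) -> pd.DataFrame:
    """Subject x block table of block mean connectivities."""
    return pd.DataFrame({lbl: s.mean_connectivity for lbl, s in summaries.items()})


def block_metadata(summaries: dict[str, BlockSummary],
                   block_index: BlockIndex,
                   groups: pd.Series | None = None) -> dict:
    """JSON-ready per-block metadata: size, variance explained, mean signs."""
    meta = {}
    for block in block_index:
        s = summaries[block.label]
        entry = {
            "n_edges": int(block.n_edges),
            "within_module": block.within,
            "variance_explained": s.variance_explained,
        }
        if groups is not None:
            gm = s.mean_connectivity.groupby(
                groups.reindex(s.mean_connectivity.index)).mean()
            entry["group_mean_connectivity"] = {str(k): float(v)
                                                for k, v in gm.items()}
            entry["dominant_sign"] = {str(k): int(np.sign(v))
                                      for k, v in gm.items()}
        meta[block.label] = entry
    return meta
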