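"""Edgewise effect-size screening and within-block consistency.

Every unique edge gets a Cohen's d between the groups. Edges are first
stratified by the sign of their group-average connectivity — analyzed only
when positive in both groups or negative in both groups; sign-mixed edges
are excluded. Within each module-module block, the direction balance of the
suprathreshold edges (|d| >= 0.5 by default) is condensed into a
McNemar-style consistency metric (N1 - N2) / (N1 + N2), where N1 and N2
count edges favoring each group. The metric is only computed in blocks
retaining at least 5% of their (sign-class) edges above threshold, so that
conclusions never rest on a handful of edges; |consistency| >= 0.33 — at
least twice as many edges favoring one group as the other — marks a block
as highly consistent.
"""
from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd

from .blocks import BlockIndex
from .compare import cohens_d
from .connectivity import SubjectConnectome

logger = logging.getLogger(__name__)

SIGN_CLASSES = ("positive", "negative", "mixed")


def group_mean_matrices(connectomes: list[SubjectConnectome],
                        groups: pd.Series) -> dict:
    """Average connectivity matrix per group, keyed by group label."""
    sids = [c.subject_id for c in connectomes]
    g = groups.reindex(sids)
    out = {}
    for level in sorted(pd.unique(g)):
        mats = [c.matrix for c, lv in zip(connectomes, g) if lv == level]
        out[level] = np.mean(mats, axis=0)
    return out


def classify_edge_signs(group1_mean: np.ndarray,
                        group2_mean: np.ndarray) -> np.ndarray:
    """Per-edge sign class from the two group-average matrices.

    "positive" where both means are > 0, "negative" where both are < 0,
    "mixed" otherwise (exact zeros count as mixed and are logged). Returns a
    full node x node object array; only the strict upper triangle matters.
    """
    a = np.asarray(group1_mean, dtype=float)
    b = np.asarray(group2_mean, dtype=float)
    if a.shape != b.shape:
        raise ValueError("group mean matrices must be conformable")
    cls = np.full(a.shape, "mixed", dtype=object)
    cls[(a > 0) & (b > 0)] = "positive"
    cls[(a < 0) & (b < 0)] = "negative"
    iu = np.triu_indices_from(a, k=1)
    zeros = int(((a[iu] == 0) | (b[iu] == 0)).sum())
    if zeros:
        logger.info("%d edges with an exactly-zero group mean classed mixed",
                    zeros)
    return cls


def edgewise_effects(connectomes: list[SubjectConnectome], groups: pd.Series,
                     block_index: BlockIndex,
                     d_threshold: float = 0.5) -> pd.DataFrame:
    """Cohen's d for every unique edge, with block and sign-class labels.

    Returns one row per upper-triangle edge: ``node_i``, ``node_j``,
    ``block``, ``sign_class``, ``cohens_d``, ``suprathreshold``. d is group 1
    minus group 2 (lower group label first).
    """
    sids = [c.subject_id for c in connectomes]
    g = groups.reindex(sids)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    stack = np.stack([c.matrix for c in connectomes])  # (S, n, n)
    m1 = (g == levels[0]).to_numpy()
    m2 = (g == levels[1]).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    mean1, mean2 = stack[m1].mean(axis=0), stack[m2].mean(axis=0)
    var1 = stack[m1].var(axis=0, ddof=1)
    var2 = stack[m2].var(axis=0, ddof=1)
    s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean1 - mean2) / np.sqrt(s2)
    sign_cls = classify_edge_signs(mean1, mean2)

    rows = []
    node_ids = connectomes[0].node_ids
    for block in block_index:
        i, j = block.edges[:, 0], block.edges[:, 1]
        for ii, jj in zip(i, j):
            dij = float(d[ii, jj])
            rows.append((node_ids[ii], node_ids[jj], block.label,
                         sign_cls[ii, jj], dij,
                         bool(np.isfinite(dij) and abs(dij) >= d_threshold)))
    return pd.DataFrame(rows, columns=["node_i", "node_j", "block",
                                       "sign_class", "cohens_d",
                                       "suprathreshold"])


def consistency_metric(n1: int, n2: int) -> float:
    """(N1 - N2) / (N1 + N2): +1/-1 full directional consistency, 0 none."""
    if n1 < 0 or n2 < 0:
        raise ValueError("edge counts must be nonnegative")
    if n1 + n2 == 0:
        raise ValueError("consistency undefined with no suprathreshold edges")
    return (n1 - n2) / (n1 + n2)


def block_consistency(edge_effects: pd.DataFrame, block_index: BlockIndex,
                      sign_class: str,
                      d_threshold: float = 0.5,
                      retention_threshold: float = 0.05,
                      consistency_threshold: float = 0.33,
                      modulewise: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-block directional consistency for one sign class.

    The retention denominator is the number of the block's edges belonging
    to ``sign_class`` (the analysis runs separately per class); the fraction
    is compared to ``retention_threshold`` in exact rational arithmetic.
    Blocks below retention carry no metric (NaN). If a modulewise comparison
    table is given, ``modulewise_overlap`` flags blocks that also passed the
    modulewise screen with matching sign class and direction.
    """
    if sign_class not in ("positive", "negative"):
        raise ValueError("sign_class must be 'positive' or 'negative'")
    ret_frac = Fraction(retention_threshold).limit_denominator(10 ** 6)
    mw = None
    if modulewise is not None:
        mw = modulewise.set_index("block")
    rows = []
    for block in block_index:
        sub = edge_effects[(edge_effects["block"] == block.label)
                           & (edge_effects["sign_class"] == sign_class)]
        n_eligible = len(sub)
        supra = sub[sub["suprathreshold"]
                    & (sub["cohens_d"].abs() >= d_threshold)]
        n1 = int((supra["cohens_d"] > 0).sum())
        n2 = int((supra["cohens_d"] < 0).sum())
        n_supra = n1 + n2
        retained = (n_eligible > 0
                    and Fraction(n_supra, n_eligible) >= ret_frac)
        if retained and n_supra > 0:
            cons = consistency_metric(n1, n2)
            highly = abs(cons) >= consistency_threshold
        else:
            cons, highly = np.nan, False
            if not retained:
                logger.debug("block %s (%s): %d/%d suprathreshold, below "
                             "retention — metric skipped", block.label,
                             sign_class, n_supra, n_eligible)
        overlap = False
        if mw is not None and block.label in mw.index and highly:
            row = mw.loc[block.label]
            overlap = (bool(row["selected"])
                       and row["sign_class"] == sign_class
                       and np.sign(row["cohens_d"]) == np.sign(cons))
        rows.append({
            "block": block.label,
            "sign_class": sign_class,
            "n_eligible": n_eligible,
            "n_g1_gt_g2": n1,
            "n_g2_gt_g1": n2,
            "retained_fraction": (n_supra / n_eligible) if n_eligible else np.nan,
            "retained": bool(retained),
            "consistency": cons,
            "highly_consistent": bool(highly),
            "modulewise_overlap": bool(overlap),
        })
    return pd.DataFrame(rows)


def consistency_tables(connectomes: list[SubjectConnectome], groups: pd.Series,
                       block_index: BlockIndex,
                       d_threshold: float = 0.5,
                       retention_threshold: float = 0.05,
                       consistency_threshold: float = 0.33,
                       modulewise: pd.DataFrame | None = None,
                       ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Edgewise effects plus one consistency table per sign class."""
    effects = edgewise_effects(connectomes, groups, block_index, d_threshold)
    tables = {cls: block_consistency(effects, block_index, cls, d_threshold,
                                     retention_threshold,
                                     consistency_threshold, modulewise)
              for cls in ("positive", "negative")}
    return effects, tables
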