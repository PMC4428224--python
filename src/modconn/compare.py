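"""Modulewise group comparison: effect sizes and rank-sum tests.

Groups are compared on the per-block principal-component coordinates with
Cohen's d (classical pooled-SD formula, group 1 minus group 2); blocks with
at least a medium effect (|d| >= 0.5 by default) are flagged. A two-sided
Wilcoxon rank-sum test supplies exploratory uncorrected p-values — no
multiple-comparison correction is applied, and outputs say so.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import BlockSummary

logger = logging.getLogger(__name__)

UNCORRECTED_NOTE = "p-values are uncorrected for multiple comparisons"


def cohens_d(x, y) -> float:
    """Standardized mean difference (mean(x) - mean(y)) / pooled SD.

    Pooled SD uses the classical (n1 + n2 - 2)-denominator formula without
    small-sample correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def rank_sum_test(x, y, exact: bool | None = None) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution when the combined sample is small
    (n1 + n2 <= 20) and tie-free, otherwise the normal approximation with
    tie correction. ``exact`` forces one mode.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if exact is None:
        exact = (len(pooled) <= 20) and not has_ties
    if exact and has_ties:
        raise ValueError("exact rank-sum p-value undefined with ties")
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(min(res.pvalue, 1.0))


def direction_label(d: float, dominant_sign: int,
                    group_names: tuple[str, str] = ("G1", "G2")) -> str:
    """Human-readable direction of a block difference.

    Coordinates are sign-aligned with block mean connectivity, so d > 0 means
    group 1 sits higher on the block's connectivity scale. For
    positive-connectivity blocks the label reads "G1>G2" / "G2>G1". For
    negative blocks the label names the group with the *stronger negative*
    connectivity: d < 0 (group 1 lower, i.e. more negative) reads "G1->G2-".
    """
    g1, g2 = group_names
    if dominant_sign >= 0:
        return f"{g1}>{g2}" if d > 0 else f"{g2}>{g1}"
    return f"{g1}->{g2}-" if d < 0 else f"{g2}->{g1}-"


def block_sign_class(group_means: pd.Series) -> str:
    """positive / negative / mixed according to both group means' signs."""
    vals = group_means.to_numpy(dtype=float)
    if np.all(vals > 0):
        return "positive"
    if np.all(vals < 0):
        return "negative"
    return "mixed"


def compare_blocks(summaries: dict[str, BlockSummary], groups: pd.Series,
                   d_threshold: float = 0.5,
                   group_names: tuple[str, str] = ("G1", "G2")) -> pd.DataFrame:
    """Per-block Cohen's d, rank-sum p, direction and selection flag.

    ``groups`` maps subject id to group label 1 or 2 (1 is the first-named
    group). Rows are returned for every block with columns ``block``,
    ``cohens_d``, ``p_uncorrected``, ``sign_class``, ``dominant_sign``,
    ``direction``, ``selected``; ``selected`` is |d| >= d_threshold.
    """
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    counts = groups.value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for lbl, s in summaries.items():
        g = groups.reindex(s.coordinates.index)
        if g.isna().any():
            missing = s.coordinates.index[g.isna()].tolist()
            raise ValueError(f"unlabeled subjects: {missing}")
        x = s.coordinates[g == levels[0]].to_numpy()
        y = s.coordinates[g == levels[1]].to_numpy()
        d = cohens_d(x, y)
        p = rank_sum_test(x, y)
        gm = s.mean_connectivity.groupby(g).mean()
        sign_class = block_sign_class(gm)
        dom = int(np.sign(gm.mean())) or 1
        rows.append({
            "block": lbl,
            "cohens_d": d,
            "p_uncorrected": p,
            "sign_class": sign_class,
            "dominant_sign": dom,
            "direction": direction_label(d, 1 if sign_class == "positive" else
                                         (-1 if sign_class == "negative" else dom),
                                         group_names),
            "selected": bool(abs(d) >= d_threshold),
        })
    out = pd.DataFrame(rows)
    out.attrs["note"] = UNCORRECTED_NOTE
    return out


def split_by_sign(comparison: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Selected blocks split into positive / negative report sections."""
    sel = comparison[comparison["selected"]]
    return {cls: sel[sel["sign_class"] == cls].reset_index(drop=True)
            for cls in ("positive", "negative")}


def write_comparison_tables(comparison: pd.DataFrame, outdir,
                            prefix: str = "modulewise") -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cols = ["block", "cohens_d", "direction", "p_uncorrected"]
    for cls, table in split_by_sign(comparison).items():
        path = out / f"{prefix}_comparison_{cls}.csv"
        with open(path, "w") as fh:
            fh.write(f"# {UNCORRECTED_NOTE}\n")
            table[cols].to_csv(fh, index=False, float_format="%.6f")
    with open(out / f"{prefix}_comparison_all.csv", "w") as fh:
        fh.write(f"# {UNCORRECTED_NOTE}\n")
        comparison.to_csv(fh, index=False, float_format="%.6f")
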