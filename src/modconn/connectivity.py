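"""Per-subject node time series and Pearson connectivity matrices.

The per-node representative time series is the first left singular vector of
the (time x voxel) matrix of detrended, standardized voxel series — the
temporal pattern carrying the largest share of the node's variance. The
subject's connectome is the full, unthresholded matrix of Pearson
correlations between node representative series: symmetric, unit diagonal,
with both positive and negative weights.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectConnectome:
    """Symmetric node x node Pearson correlation matrix for one subject."""

    subject_id: str
    matrix: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if len(self.node_ids) != m.shape[0]:
            raise ValueError("node_ids length must match matrix size")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("connectome matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("connectome diagonal must be 1")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.node_ids,
                     columns=self.node_ids).to_csv(path, sep="\t",
                                                   float_format="%.8f")

    @classmethod
    def from_tsv(cls, path, subject_id: str) -> "SubjectConnectome":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(subject_id, df.to_numpy(dtype=float), tuple(df.columns))


def detrend_series(series: np.ndarray, poly_order: int = 2) -> np.ndarray:
    """Regress Legendre polynomials of degree 0..poly_order out of each column.

    Time is rescaled to [-1, 1]; residuals are orthogonal to the polynomial
    design (least squares). Removes slow scanner drift plus the mean.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    T = x.shape[0]
    if T <= poly_order + 1:
        raise ValueError(f"need more than {poly_order + 1} timepoints to "
                         f"detrend with order {poly_order}")
    t = np.linspace(-1.0, 1.0, T)
    design = np.polynomial.legendre.legvander(t, poly_order)
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    return resid[:, 0] if squeeze else resid


def standardize_series(series: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Demean each column and scale it to unit (sample) variance."""
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    # numerically constant columns: sd indistinguishable from rounding noise
    bad = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mu)))
    if bad.size:
        raise ValueError(f"constant series in column(s) {bad.tolist()}; "
                         "cannot standardize")
    z = (x - mu) / sd
    return z[:, 0] if squeeze else z


def prewhiten_ar1(series: np.ndarray) -> np.ndarray:
    """Optional temporal pre-whitening: remove a fitted AR(1) component.

    Estimates the lag-1 autocorrelation of each column and returns the
    innovation series x_t - phi * x_{t-1} (first sample kept as is). Offered
    for sensitivity analysis; Pearson correlation is unaffected by the
    default variance-normalization reading of "whitening".
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    xc = x - x.mean(axis=0)
    num = (xc[1:] * xc[:-1]).sum(axis=0)
    den = (xc ** 2).sum(axis=0)
    phi = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = x.copy()
    out[1:] -= phi * x[:-1]
    return out[:, 0] if squeeze else out


def extract_node_series(voxel_matrix: np.ndarray) -> np.ndarray:
    """Representative series of a node: first left singular vector.

    The sign is fixed so the representative correlates positively with the
    mean voxel series; if that correlation is numerically zero (e.g. voxels
    cancel pairwise) the sign of the largest-magnitude voxel loading is used
    and the fallback is logged. Output is rescaled to unit sample variance.
    """
    X = np.asarray(voxel_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.any(X):
        raise ValueError("all-zero voxel matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    u = U[:, 0]
    mean_voxel = X.mean(axis=1)
    align = float(u @ mean_voxel)
    if abs(align) > 1e-12 * max(1.0, np.abs(mean_voxel).max()) * len(u):
        if align < 0:
            u = -u
    else:
        loading = Vt[0]
        j = int(np.argmax(np.abs(loading)))
        logger.warning("mean voxel series ~0; SVD sign fixed by largest "
                       "loading (voxel %d)", j)
        if loading[j] < 0:
            u = -u
    return standardize_series(u)


def build_connectome(node_series: np.ndarray | pd.DataFrame,
                     subject_id: str = "",
                     node_ids: tuple[str, ...] | None = None) -> SubjectConnectome:
    """Pearson correlation matrix between node representative series."""
    if isinstance(node_series, pd.DataFrame):
        node_ids = tuple(node_series.columns)
        X = node_series.to_numpy(dtype=float)
    else:
        X = np.asarray(node_series, dtype=float)
        if node_ids is None:
            node_ids = tuple(f"n{i:03d}" for i in range(X.shape[1]))
    if X.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant node series at column(s) {bad.tolist()}")
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return SubjectConnectome(subject_id, R, node_ids)


def extract_sphere_timeseries(img4d, centers_mm: np.ndarray,
                              radius_mm: float) -> list[np.ndarray]:
    """Voxel time series for each node sphere from a 4D NIfTI image.

    Returns one (time x voxel) matrix per center, using the image affine to
    locate voxels whose centers fall inside each node sphere.
    """
    from .parcellation import _sphere_voxel_indices

    data = np.asanyarray(img4d.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D image")
    out = []
    for center in np.atleast_2d(centers_mm):
        ijk = _sphere_voxel_indices(data.shape[:3], img4d.affine,
                                    np.asarray(center, float), radius_mm)
        out.append(data[ijk[:, 0], ijk[:, 1], ijk[:, 2], :].T)
    return out


def connectome_from_voxels(voxel_sets: list[np.ndarray], subject_id: str = "",
                           node_ids: tuple[str, ...] | None = None,
                           poly_order: int = 2,
                           ar1_prewhiten: bool = False) -> SubjectConnectome:
    """Full voxel-level path: detrend, standardize, SVD-summarize, correlate."""
    reps = []
    for X in voxel_sets:
        X = standardize_series(detrend_series(X, poly_order), ddof=1)
        if ar1_prewhiten:
            X = prewhiten_ar1(X)
        reps.append(extract_node_series(X))
    return build_connectome(np.column_stack(reps), subject_id, node_ids)
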