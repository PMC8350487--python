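"""Build an FDR-thresholded, normalized association matrix from node time series.

The preprocessing chain mirrors standard resting-state network construction:
node-wise Pearson correlation, Fisher z transform, removal of negative links
(their graph-theoretic interpretation is contested), Benjamini-Hochberg FDR
pruning of the weakest links at q = 0.005, and a global min-max normalization
so every surviving link weight lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TimeSeriesMatrix",
    "AssociationMatrix",
    "correlation_matrix",
    "fisher_z",
    "remove_negatives",
    "fdr_threshold",
    "minmax_normalize",
    "association_matrix",
    "read_timeseries_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

#: correlations are clipped to +/-(1 - _ATANH_CLIP) before atanh
_ATANH_CLIP = 1e-7


@dataclass
class TimeSeriesMatrix:
    """BOLD-like signals, one column per node, one row per timepoint."""

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (timepoints x nodes) array")
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(self.values.shape[1])]
        if len(self.node_ids) != self.values.shape[1]:
            raise ValueError("node_ids length does not match node count")
        if self.values.shape[0] < 3:
            raise ValueError("at least 3 timepoints are required")
        if self.values.shape[1] < 2:
            raise ValueError("at least 2 nodes are required")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains missing/non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationMatrix:
    """Symmetric node-by-node association weights with a zero diagonal."""

    r: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("association matrix must be square")
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(self.r.shape[0])]
        if len(self.node_ids) != self.r.shape[0]:
            raise ValueError("node_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.r.shape[0]

    def copy_with(self, r: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(r=np.array(r, dtype=float), node_ids=list(self.node_ids))


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def correlation_matrix(ts: TimeSeriesMatrix | np.ndarray | pd.DataFrame) -> AssociationMatrix:
    """Pearson correlation between every pair of node time series.

    The diagonal is set to 0 by convention (self-connectivity is meaningless
    for the stepwise chains downstream).
    """
    if isinstance(ts, pd.DataFrame):
        ts = TimeSeriesMatrix(ts.to_numpy(float), [str(c) for c in ts.columns])
    elif not isinstance(ts, TimeSeriesMatrix):
        ts = TimeSeriesMatrix(np.asarray(ts, dtype=float))

    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.node_ids[i] for i in dead[:5])
        raise ValueError(f"zero-variance node(s): {names}")

    r = np.corrcoef(ts.values, rowvar=False)
    r = (r + r.T) / 2.0  # corrcoef is not bit-exact symmetric
    np.fill_diagonal(r, 0.0)
    return AssociationMatrix(r=r, node_ids=list(ts.node_ids))


def fisher_z(a: AssociationMatrix) -> AssociationMatrix:
    """Entrywise Fisher transform z = atanh(r); correlations are clipped to
    +/-(1 - 1e-7) first so perfect correlations do not map to infinity."""
    r = np.clip(a.r, -(1 - _ATANH_CLIP), 1 - _ATANH_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return a.copy_with(z)


def remove_negatives(a: AssociationMatrix) -> AssociationMatrix:
    """Zero out negative links."""
    return a.copy_with(np.where(a.r < 0, 0.0, a.r))


def fdr_threshold(
    a: AssociationMatrix,
    n_timepoints: int,
    q: float = 0.005,
    transformed: bool = False,
) -> AssociationMatrix:
    """Remove the weakest links by Benjamini-Hochberg FDR at level ``q``.

    A two-sided p-value is attached to each upper-triangle link through the
    t transform of its correlation, t = r * sqrt((m - 2) / (1 - r^2)) with
    m timepoints.  BH runs on the upper triangle only; the surviving set is
    mirrored to keep the matrix symmetric.

    Parameters
    ----------
    transformed
        Set True when the matrix entries are Fisher z values (the chain
        applies the transform before thresholding); p-values are then
        computed from r = tanh(z).
    """
    if n_timepoints <= 3:
        raise ValueError("FDR thresholding needs more than 3 timepoints")
    n = a.n
    iu = np.triu_indices(n, k=1)
    vals = a.r[iu]
    r = np.tanh(vals) if transformed else np.clip(vals, -1.0, 1.0)
    df = n_timepoints - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.zeros_like(a.r)
    kept = np.where(reject, vals, 0.0)
    out[iu] = kept
    out = out + out.T
    return a.copy_with(out)


def minmax_normalize(m: np.ndarray) -> np.ndarray:
    """Min-max normalize over off-diagonal entries; diagonal forced to 0.

    Raises on a constant off-diagonal (degenerate normalization).
    """
    m = np.asarray(m, dtype=float)
    mask = _offdiag_mask(m.shape[0])
    lo = m[mask].min()
    hi = m[mask].max()
    if hi - lo <= 0:
        raise ValueError("constant off-diagonal matrix: min-max normalization is degenerate")
    out = (m - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def association_matrix(
    ts: TimeSeriesMatrix | np.ndarray | pd.DataFrame, q: float = 0.005
) -> AssociationMatrix:
    """Full chain: correlation -> Fisher z -> negatives removed -> FDR -> min-max."""
    if isinstance(ts, pd.DataFrame):
        m = ts.shape[0]
    elif isinstance(ts, TimeSeriesMatrix):
        m = ts.n_timepoints
    else:
        m = np.asarray(ts).shape[0]
    a = correlation_matrix(ts)
    a = fisher_z(a)
    a = remove_negatives(a)
    a = fdr_threshold(a, n_timepoints=m, q=q, transformed=True)
    return a.copy_with(minmax_normalize(a.r))


# ---------------------------------------------------------------------------
# TSV plumbing


def read_timeseries_tsv(path) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(df.to_numpy(float), [str(c) for c in df.columns])


def write_matrix_tsv(a: AssociationMatrix, path) -> None:
    pd.DataFrame(a.r, index=a.node_ids, columns=a.node_ids).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AssociationMatrix(df.to_numpy(float), [str(c) for c in df.columns])
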