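"""Subject-level correlation networks and group difference networks.

Each subject-condition yields a symmetric region-by-region Pearson
correlation matrix (94 x 94 for the AAL2 cerebrum).  Group comparisons
are made edge-wise on Fisher-z-transformed correlations; edges whose
two-sided p-value beats a threshold form the *difference network*, and a
region's degree in that network counts its significantly altered
connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .errors import (
    DesignMismatchError,
    InsufficientSubjectsError,
    InvalidThresholdError,
    TooFewVolumesError,
    ZeroVarianceChannelError,
)
from .preprocess import ROITimeSeries

__all__ = [
    "ConnectivityMatrix",
    "DifferenceNetwork",
    "correlation_matrix",
    "to_fisher_z",
    "edgewise_stats",
    "difference_network",
    "top_degree_nodes",
    "triu_index",
]


def triu_index(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, row-major (i < j)."""
    return np.triu_indices(n_rois, k=1)


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region connectivity on the r or Fisher-z scale."""

    values: np.ndarray
    scale: str  # "r" or "z"
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("r", "z"):
            raise ValueError(f"scale must be 'r' or 'z', got {self.scale!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        i, j = triu_index(self.n_rois)
        return self.values[i, j]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.roi_labels, columns=self.roi_labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, scale: str = "r") -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), scale, [str(c) for c in df.columns])


@dataclass
class DifferenceNetwork:
    """Edges surviving an edge-wise significance screen, with node degree."""

    adjacency: np.ndarray
    edge_stats: np.ndarray
    degree: np.ndarray
    design: str  # "paired" or "unpaired"
    p_threshold: float
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.degree = np.asarray(self.degree, dtype=int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def degree_table(self) -> pd.DataFrame:
        return pd.DataFrame({"roi": self.roi_labels, "degree": self.degree})


def correlation_matrix(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI time courses."""
    if ts.n_volumes < 3:
        raise TooFewVolumesError("correlation needs at least 3 volumes")
    sd = ts.values.std(axis=0)
    dead = np.nonzero(sd == 0.0)[0]
    if dead.size:
        names = ", ".join(ts.roi_labels[k] for k in dead[:5])
        raise ZeroVarianceChannelError(f"constant ROI time course(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, "r", list(ts.roi_labels))


def to_fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z transform of a correlation matrix (diagonal set to 0)."""
    if cm.scale == "z":
        return cm
    z = stats.fisher_r_to_z(cm.values)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, "z", list(cm.roi_labels))


def _stack_edges(group: list[ConnectivityMatrix], use_fisher_z: bool) -> np.ndarray:
    mats = [to_fisher_z(m) if use_fisher_z else m for m in group]
    return np.vstack([m.upper_triangle() for m in mats])


def edgewise_stats(
    group1: list[ConnectivityMatrix],
    group2: list[ConnectivityMatrix],
    design: str = "unpaired",
    use_fisher_z: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-edge t statistics for group1 vs group2 (positive t = group1 higher;
    for the paired design the differences are group1 - group2).

    Matrices on the r scale are Fisher-transformed first (the standard
    convention, applied before *all* edge-wise tests here for
    consistency); pass ``use_fisher_z=False`` to test raw correlations.
    Returns a symmetric t matrix (diagonal 0) and the test df.
    """
    if design not in ("paired", "unpaired"):
        raise DesignMismatchError(f"unknown design {design!r}")
    if len(group1) < 2 or len(group2) < 2:
        raise InsufficientSubjectsError("need at least 2 subjects per group")
    if design == "paired" and len(group1) != len(group2):
        raise DesignMismatchError(
            f"paired design needs aligned groups: {len(group1)} vs {len(group2)}"
        )
    n_rois = group1[0].n_rois
    x = _stack_edges(group1, use_fisher_z)
    y = _stack_edges(group2, use_fisher_z)
    if design == "paired":
        t, df = stats.paired_t_stats(x - y)
    else:
        t, df = stats.pooled_t_stats(x, y)
    t_matrix = np.zeros((n_rois, n_rois))
    i, j = triu_index(n_rois)
    t_matrix[i, j] = t
    t_matrix[j, i] = t
    return t_matrix, df


def difference_network(
    t_matrix: np.ndarray,
    df: float,
    p_threshold: float = 0.05,
    roi_labels: list[str] | None = None,
    design: str = "unpaired",
) -> DifferenceNetwork:
    """Binary network of edges whose two-sided p beats the threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise InvalidThresholdError(f"p_threshold must be in (0, 1), got {p_threshold}")
    t_matrix = np.asarray(t_matrix, dtype=float)
    n = t_matrix.shape[0]
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t_matrix), df)
    adjacency = p < p_threshold
    np.fill_diagonal(adjacency, False)
    adjacency &= adjacency.T
    degree = adjacency.sum(axis=1).astype(int)
    labels = roi_labels or [f"ROI{i + 1:03d}" for i in range(n)]
    return DifferenceNetwork(adjacency, t_matrix, degree, design, p_threshold, labels)


def top_degree_nodes(net: DifferenceNetwork, k: int) -> list[tuple[str, int]]:
    """The k highest-degree regions, ties broken by label order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        range(len(net.degree)), key=lambda i: (-net.degree[i], net.roi_labels[i])
    )
    return [(net.roi_labels[i], int(net.degree[i])) for i in order[:k]]
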