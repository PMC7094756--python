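"""The network-based statistic (NBS).

Edge-wise t statistics on Fisher-z connectivity are thresholded at a
*primary* threshold; connected components of the surviving
(suprathreshold) links are found by breadth-first search; and each
component's extent (link count) is referred to a permutation null of the
*maximal* component size, which controls the family-wise error rate at
the component level.  Permutation schemes: random reassignment of
subjects to groups (unpaired design) or per-subject condition swaps,
equivalently sign flips of the paired z differences (paired design).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats as sps

from . import stats
from .connectivity import ConnectivityMatrix, to_fisher_z, triu_index
from .errors import DesignMismatchError, InsufficientSubjectsError
from .stats import empirical_p, paired_t_stats, pooled_t_stats

__all__ = [
    "NBSConfig",
    "NBSComponent",
    "NBSResult",
    "suprathreshold_graph",
    "connected_components",
    "run_nbs",
]

_PERM_CHUNK = 256


@dataclass(frozen=True)
class NBSConfig:
    """Settings for one NBS run.

    The primary threshold may be given directly as a t value
    (``primary_threshold_t``) or as a two-sided p value converted via the
    design's degrees of freedom (``primary_threshold_p``, the default
    0.001 of common NBS practice).  ``sign`` selects which tail of the
    edge-wise t defines a suprathreshold link; directional runs
    (positive / negative) are reported separately.
    """

    primary_threshold_p: float | None = 0.001
    primary_threshold_t: float | None = None
    n_permutations: int = 5000
    alpha: float = 0.05
    design: str = "unpaired"  # or "paired"
    sign: str = "positive"  # "positive" | "negative" | "two_sided"
    seed: int = 0
    component_measure: str = "extent"
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.design not in ("paired", "unpaired"):
            raise DesignMismatchError(f"unknown design {self.design!r}")
        if self.sign not in ("positive", "negative", "two_sided"):
            raise ValueError(f"unknown sign {self.sign!r}")
        if self.component_measure != "extent":
            raise ValueError("only the extent (link count) measure is supported")
        if self.primary_threshold_t is None and self.primary_threshold_p is None:
            raise ValueError("one of primary_threshold_{t,p} is required")
        if self.primary_threshold_t is not None and self.primary_threshold_t <= 0:
            raise ValueError("primary_threshold_t must be positive")
        if self.n_permutations < 1 and not self.exhaustive:
            raise ValueError("n_permutations must be >= 1")

    def resolve_threshold(self, df: float) -> float:
        """The primary threshold as a positive t value."""
        if self.primary_threshold_t is not None:
            return float(self.primary_threshold_t)
        return float(sps.t.isf(self.primary_threshold_p / 2.0, df))


@dataclass
class NBSComponent:
    """One connected component of suprathreshold links."""

    edges: list[tuple[int, int]]
    nodes: frozenset[int]
    size: int
    p_fwe: float = float("nan")


@dataclass
class NBSResult:
    components: list[NBSComponent]
    null_max_sizes: np.ndarray
    config: NBSConfig
    t_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]
    threshold_t: float = float("nan")
    df: float = float("nan")
    roi_labels: list[str] = field(default_factory=list)

    def significant(self, alpha: float | None = None) -> list[NBSComponent]:
        a = self.config.alpha if alpha is None else alpha
        return [c for c in self.components if c.p_fwe < a]


def _supra_mask(t: np.ndarray, threshold: float, sign: str) -> np.ndarray:
    if sign == "positive":
        return t > threshold
    if sign == "negative":
        return t < -threshold
    return np.abs(t) > threshold


def suprathreshold_graph(
    t_matrix: np.ndarray, threshold: float, sign: str = "two_sided"
) -> np.ndarray:
    """Boolean adjacency of edges whose t beats the primary threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(t_matrix, dtype=float)
    adj = _supra_mask(t, threshold, sign)
    adj = adj & adj.T
    np.fill_diagonal(adj, False)
    return adj


def _components_from_edges(
    ii: np.ndarray, jj: np.ndarray
) -> list[tuple[list[tuple[int, int]], frozenset[int]]]:
    """Connected components of an edge list via breadth-first search."""
    adj: dict[int, list[int]] = {}
    for i, j in zip(ii.tolist(), jj.tolist()):
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    seen: set[int] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        members = set()
        while queue:
            node = queue.pop(0)
            members.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        edges = [
            (min(i, j), max(i, j))
            for i, j in zip(ii.tolist(), jj.tolist())
            if i in members
        ]
        comps.append((sorted(set(edges)), frozenset(members)))
    return comps


def connected_components(adjacency: np.ndarray) -> list[NBSComponent]:
    """Maximal connected components of a link set (BFS; isolated nodes excluded).

    Component size is the number of links.  Components are returned
    size-descending, ties broken by smallest member node.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    if not (adjacency == adjacency.T).all():
        raise ValueError("adjacency must be symmetric")
    ii, jj = np.nonzero(np.triu(adjacency, k=1))
    comps = [
        NBSComponent(edges, nodes, len(edges))
        for edges, nodes in _components_from_edges(ii, jj)
    ]
    comps.sort(key=lambda c: (-c.size, min(c.nodes)))
    return comps


def _max_component_size(ii: np.ndarray, jj: np.ndarray) -> int:
    """Maximal component extent of an edge list (0 when empty)."""
    if ii.size == 0:
        return 0
    return max(len(edges) for edges, _ in _components_from_edges(ii, jj))


def _paired_sign_matrix(config: NBSConfig, n: int) -> np.ndarray:
    if config.exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration is limited to <= 20 pairs")
        return np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    rng = np.random.default_rng(config.seed)
    return rng.choice((1.0, -1.0), size=(config.n_permutations, n))


def run_nbs(
    group1: list[ConnectivityMatrix],
    group2: list[ConnectivityMatrix],
    config: NBSConfig,
) -> NBSResult:
    """Full NBS run: observed components plus the permutation FWE null.

    ``group1``/``group2`` are per-subject connectivity matrices (r or z
    scale; r is Fisher-transformed).  For the paired design the lists
    must be subject-aligned and t is computed on group1 - group2
    differences.  Each component's ``p_fwe`` is the add-one empirical
    p-value of its extent against the null of maximal component sizes.
    Deterministic given ``config.seed``.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise InsufficientSubjectsError("need at least 2 subjects per group")
    if config.design == "paired" and len(group1) != len(group2):
        raise DesignMismatchError("paired design needs subject-aligned groups")
    n_rois = group1[0].n_rois
    roi_labels = list(group1[0].roi_labels)
    iu, ju = triu_index(n_rois)
    x = np.vstack([to_fisher_z(m).upper_triangle() for m in group1])
    y = np.vstack([to_fisher_z(m).upper_triangle() for m in group2])

    if config.design == "paired":
        d = x - y
        t_obs, df = paired_t_stats(d)
    else:
        t_obs, df = pooled_t_stats(x, y)
    threshold = config.resolve_threshold(df)

    # Observed components.
    obs_mask = _supra_mask(t_obs, threshold, config.sign)
    t_matrix = np.zeros((n_rois, n_rois))
    t_matrix[iu, ju] = t_obs
    t_matrix[ju, iu] = t_obs
    components = connected_components(
        suprathreshold_graph(t_matrix, threshold, config.sign)
        if obs_mask.any()
        else np.zeros((n_rois, n_rois), dtype=bool)
    )

    # Permutation null of the maximal component size.
    if config.design == "paired":
        n = x.shape[0]
        n_distinct = 2**n
        signs = _paired_sign_matrix(config, n)
        m_perms = signs.shape[0]
        ss = (d**2).sum(axis=0)  # invariant under sign flips
        null = np.zeros(m_perms, dtype=int)
        for lo in range(0, m_perms, _PERM_CHUNK):
            s = signs[lo : lo + _PERM_CHUNK]
            means = (s @ d) / n
            var = np.maximum(ss - n * means**2, 0.0) / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = means / np.sqrt(var / n)
            t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
            mask = _supra_mask(t_perm, threshold, config.sign)
            for row in range(s.shape[0]):
                k = np.nonzero(mask[row])[0]
                null[lo + row] = _max_component_size(iu[k], ju[k])
    else:
        n1, n2 = x.shape[0], y.shape[0]
        n_all = n1 + n2
        n_distinct = comb(n_all, n1)
        pooled = np.vstack([x, y])
        pooled_sq = pooled**2
        m_perms = config.n_permutations
        rng = np.random.default_rng(config.seed)
        null = np.zeros(m_perms, dtype=int)
        tot_s = pooled.sum(axis=0)
        tot_q = pooled_sq.sum(axis=0)
        for lo in range(0, m_perms, _PERM_CHUNK):
            chunk = min(_PERM_CHUNK, m_perms - lo)
            sel = np.zeros((chunk, n_all))
            for row in range(chunk):
                sel[row, rng.permutation(n_all)[:n1]] = 1.0
            s1 = sel @ pooled
            q1 = sel @ pooled_sq
            m1 = s1 / n1
            m2 = (tot_s - s1) / n2
            v1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1)
            v2 = np.maximum(tot_q - q1 - n2 * m2**2, 0.0) / (n2 - 1)
            sv = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = (m1 - m2) / np.sqrt(sv * (1.0 / n1 + 1.0 / n2))
            t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
            mask = _supra_mask(t_perm, threshold, config.sign)
            for row in range(chunk):
                k = np.nonzero(mask[row])[0]
                null[lo + row] = _max_component_size(iu[k], ju[k])

    if n_distinct < 1.0 / config.alpha:
        warnings.warn(
            f"only {n_distinct} distinct permutations exist; "
            f"FWE control at alpha={config.alpha} is not attainable",
            stacklevel=2,
        )

    for c in components:
        c.p_fwe = empirical_p(c.size, null)
    return NBSResult(
        components=components,
        null_max_sizes=null,
        config=config,
        t_matrix=t_matrix,
        threshold_t=threshold,
        df=df,
        roi_labels=roi_labels,
    )
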