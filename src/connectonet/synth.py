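"""Synthetic cohorts with known connectivity structure.

No raw resting-state data accompany the study design this package
implements, so every downstream stage is exercised on generated cohorts
whose ground truth is known: two groups of subjects (optionally with a
pre/post condition pair each), ROI time series drawn from a target
correlation matrix, and a *planted* connected component of edges whose
correlation is shifted by a known delta in the affected group or
condition.  Temporal realism is limited to what the analysis assumes:
AR(1)-autocorrelated noise, a shared low-frequency drift below the
band-pass cutoff, and random-walk rigid-body motion parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as spsig

from .errors import EdgeOutOfRangeError, NotPositiveDefiniteError
from .preprocess import MotionParams, ROITimeSeries

__all__ = [
    "CohortDesign",
    "SyntheticCohort",
    "SubjectRecord",
    "plant_component",
    "generate_timeseries",
    "generate_motion",
    "generate_cohort",
]

#: Eigenvalue floor used when repairing a planted matrix to positive definite.
PD_FLOOR = 1e-6

#: Target frequency (Hz) of the shared drift; deliberately below the
#: 0.01 Hz band-pass cutoff so cleaning must demonstrably remove it.
DRIFT_HZ = 0.005


def drift_frequency_hz(n_volumes: int, tr_seconds: float) -> float:
    """The generator's drift frequency for a given window.

    The nearest DFT bin to the 0.005 Hz target: an integer number of
    cycles per window, so the rectangular band-pass removes the drift
    exactly rather than smearing it across bins (spectral-leakage
    realism is a non-goal of the generator).
    """
    window = n_volumes * tr_seconds
    k = max(1, round(DRIFT_HZ * window))
    return k / window


def _edges_connected(edges: tuple[tuple[int, int], ...]) -> bool:
    """True when the edge set induces a single connected graph."""
    if not edges:
        return True
    nodes = {n for e in edges for n in e}
    adj: dict[int, set[int]] = {n: set() for n in nodes}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = set()
    stack = [next(iter(nodes))]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj[n] - seen)
    return seen == nodes


@dataclass(frozen=True)
class CohortDesign:
    """Generative description of a study cohort.

    Defaults mirror the emulated study design: 28 controls vs 24
    dependent chewers, 94 AAL2 regions, 240 retained volumes at
    TR = 2 s.  ``paired=True`` gives every subject a pre and post
    condition with the planted effect applied to the post condition of
    both groups (the acute contrast); ``paired=False`` applies the
    effect to group 2 only (the chronic contrast).
    """

    n_group1: int = 28
    n_group2: int = 24
    n_rois: int = 94
    n_volumes: int = 240
    tr_seconds: float = 2.0
    paired: bool = False
    planted_edges: tuple[tuple[int, int], ...] = ()
    effect_delta_r: float = 0.0
    base_correlation: float = 0.1
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.0
    motion_magnitude_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("both groups need at least one subject")
        if not 0.0 <= self.base_correlation < 1.0:
            raise ValueError("base_correlation must be in [0, 1)")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.drift_amplitude < 0 or self.motion_magnitude_mm < 0:
            raise ValueError("amplitudes must be non-negative")
        edges = tuple(tuple(sorted(e)) for e in self.planted_edges)
        object.__setattr__(self, "planted_edges", edges)
        for i, j in edges:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois) or i == j:
                raise EdgeOutOfRangeError(f"edge ({i}, {j}) out of range")
        if not _edges_connected(edges):
            raise ValueError("planted_edges must induce a connected graph")

    def base_matrix(self) -> np.ndarray:
        """Compound-symmetric background correlation matrix."""
        c = self.base_correlation
        m = np.full((self.n_rois, self.n_rois), c)
        np.fill_diagonal(m, 1.0)
        return m

    def effect_matrix(self) -> np.ndarray:
        """Base matrix with the planted component added and PD-repaired."""
        return plant_component(
            self.base_matrix(), self.planted_edges, self.effect_delta_r
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        if "planted_edges" in d:
            d["planted_edges"] = tuple(tuple(e) for e in d["planted_edges"])
        return cls(**d)


@dataclass
class SubjectRecord:
    subject_id: str
    group_label: str
    condition_label: str
    series: ROITimeSeries
    motion: MotionParams


@dataclass
class SyntheticCohort:
    """Generated subjects plus the ground truth that produced them."""

    subjects: list[SubjectRecord]
    truth: CohortDesign

    def write(self, out_dir: str | Path) -> Path:
        """Write per-subject TSVs, a manifest, and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in self.subjects:
            stem = f"{rec.subject_id}_{rec.condition_label}"
            ts_path = out / f"{stem}_ts.tsv"
            mot_path = out / f"{stem}_motion.tsv"
            rec.series.to_tsv(ts_path)
            rec.motion.to_tsv(mot_path)
            rows.append(
                "\t".join(
                    [
                        rec.subject_id,
                        rec.group_label,
                        rec.condition_label,
                        ts_path.name,
                        mot_path.name,
                    ]
                )
            )
        header = "subject_id\tgroup\tcondition\tts_path\tmotion_path"
        (out / "manifest.tsv").write_text("\n".join([header, *rows]) + "\n")
        self.truth.to_json(out / "truth.json")
        return out


def _repair_pd(m: np.ndarray, floor: float = PD_FLOOR, max_iter: int = 50) -> np.ndarray:
    """Nearest-ish PD correlation repair: eigenvalue clipping + diagonal rescale."""
    a = (m + m.T) / 2.0
    for _ in range(max_iter):
        w = np.linalg.eigvalsh(a)
        if w.min() >= floor * (1.0 - 1e-9):
            return a
        w, v = np.linalg.eigh(a)
        w = np.clip(w, floor * 1.05, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
    raise NotPositiveDefiniteError(
        "could not repair matrix to positive definite with unit diagonal"
    )


def plant_component(
    base: np.ndarray,
    edges: tuple[tuple[int, int], ...],
    delta: float,
) -> np.ndarray:
    """Add ``delta`` to the listed edges of a correlation matrix, then repair.

    The edge set is the alternative hypothesis the network-based
    statistic is designed to detect: an interconnected subnetwork of
    altered correlations.  When the shifted matrix is already positive
    definite it is returned untouched apart from the planted entries;
    otherwise eigenvalues are clipped at 1e-6 and the diagonal rescaled
    to 1 (bounded distortion of the remaining edges).
    """
    base = np.asarray(base, dtype=float)
    n = base.shape[0]
    if delta == 0.0 or not edges:
        return base.copy()
    out = base.copy()
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise EdgeOutOfRangeError(f"edge ({i}, {j}) out of range for n={n}")
        out[i, j] += delta
        out[j, i] += delta
        if abs(out[i, j]) >= 1.0:
            raise EdgeOutOfRangeError(
                f"planted correlation {out[i, j]:.3f} at ({i}, {j}) leaves (-1, 1)"
            )
    return _repair_pd(out)


def generate_timeseries(
    target: np.ndarray,
    n_volumes: int,
    ar1: float = 0.0,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    tr_seconds: float = 2.0,
    roi_labels: list[str] | None = None,
) -> ROITimeSeries:
    """Multivariate series whose innovations have correlation ``target``.

    Innovations are Gaussian with covariance ``target``; each channel is
    then filtered by the same AR(1) recursion (which preserves the
    cross-correlation structure of the stationary series), and a shared
    sub-band sinusoidal drift is added.  Deterministic given ``seed``.
    """
    target = np.asarray(target, dtype=float)
    w = np.linalg.eigvalsh(target)
    if w.min() <= 0:
        raise NotPositiveDefiniteError("target correlation matrix is not PD")
    rng = np.random.default_rng(seed)
    n_rois = target.shape[0]
    burn = 100 if ar1 > 0 else 0
    chol = np.linalg.cholesky(target)
    innov = rng.standard_normal((n_volumes + burn, n_rois)) @ chol.T
    if ar1 > 0:
        series = spsig.lfilter([1.0], [1.0, -ar1], innov, axis=0)[burn:, :]
    else:
        series = innov
    if drift_amplitude > 0:
        t = np.arange(n_volumes) * tr_seconds
        phase = rng.uniform(0, 2 * np.pi)
        freq = drift_frequency_hz(n_volumes, tr_seconds)
        drift = drift_amplitude * np.sin(2 * np.pi * freq * t + phase)
        series = series + drift[:, None]
    labels = roi_labels or [f"ROI{i + 1:03d}" for i in range(n_rois)]
    return ROITimeSeries(series, tr_seconds, labels)


def generate_motion(n_volumes: int, magnitude_mm: float, seed: int = 0) -> MotionParams:
    """Random-walk rigid-body parameters.

    Translation steps have SD ``magnitude_mm``; rotation steps have SD
    ``magnitude_mm / 80`` radians so that, over the conventional 80 mm
    sphere, rotations contribute displacements on the same scale as
    translations and mean FD is linear in the magnitude.
    """
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes, 6))
    steps[0, :] = 0.0
    steps[:, :3] *= magnitude_mm
    steps[:, 3:] *= magnitude_mm / 80.0
    return MotionParams(np.cumsum(steps, axis=0))


def generate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Draw a full cohort from a design.

    Per-subject seeds are spawned deterministically from ``design.seed``.
    Unpaired: group 1 from the base matrix, group 2 from the planted
    matrix.  Paired: both groups' pre condition from the base matrix and
    post condition from the planted matrix.
    """
    base = design.base_matrix()
    effect = design.effect_matrix()
    root = np.random.SeedSequence(design.seed)
    subjects: list[SubjectRecord] = []
    group_sizes = (("g1", design.n_group1), ("g2", design.n_group2))
    conditions = ("pre", "post") if design.paired else ("rest",)
    n_series = sum(n for _, n in group_sizes) * len(conditions)
    children = iter(root.spawn(2 * n_series))
    for group, n_subj in group_sizes:
        for s in range(n_subj):
            subject_id = f"{group}s{s + 1:02d}"
            for cond in conditions:
                if design.paired:
                    target = effect if cond == "post" else base
                else:
                    target = effect if group == "g2" else base
                ts_seed = next(children)
                mot_seed = next(children)
                series = generate_timeseries(
                    target,
                    design.n_volumes,
                    ar1=design.ar1_coefficient,
                    drift_amplitude=design.drift_amplitude,
                    seed=ts_seed,
                    tr_seconds=design.tr_seconds,
                )
                motion = generate_motion(
                    design.n_volumes, design.motion_magnitude_mm, seed=mot_seed
                )
                subjects.append(
                    SubjectRecord(subject_id, group, cond, series, motion)
                )
    return SyntheticCohort(subjects, design)
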