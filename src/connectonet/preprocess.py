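"""Time-series-level cleaning of ROI signals.

The pipeline mirrors the standard resting-state fMRI convention for
region-averaged BOLD signals: linear detrend, ideal (frequency-domain)
band-pass at 0.01-0.08 Hz, and nuisance regression against the
Friston-24 motion expansion plus optional tissue signals.  Frame-level
quality is summarised by Jenkinson's framewise displacement (FD) and
DVARS, with optional scrubbing (frame censoring) before connectivity.

Only signal-level steps live here; volume-level operations (slice
timing, realignment, spatial normalisation, smoothing) are out of scope
because they require image volumes, not ROI tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .errors import (
    AllFramesCensoredError,
    DimensionMismatchError,
    InvalidBandError,
    TooFewVolumesError,
)

__all__ = [
    "ROITimeSeries",
    "MotionParams",
    "FrameQuality",
    "linear_detrend",
    "bandpass",
    "friston24",
    "nuisance_regress",
    "fd_jenkinson",
    "dvars",
    "default_dvars_threshold",
    "scrub",
    "clean",
    "frame_quality",
]

#: Minimum frames that must survive scrubbing for a usable correlation.
MIN_SURVIVING_FRAMES = 10


@dataclass
class ROITimeSeries:
    """One subject-condition's signal matrix (volumes x regions)."""

    values: np.ndarray
    tr_seconds: float
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (volumes x regions) matrix")
        if self.values.shape[0] < 2:
            raise TooFewVolumesError("need at least 2 volumes")
        if len(self.roi_labels) != self.values.shape[1]:
            raise DimensionMismatchError(
                f"{len(self.roi_labels)} labels for {self.values.shape[1]} regions"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "ROITimeSeries":
        return ROITimeSeries(values, self.tr_seconds, list(self.roi_labels))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.roi_labels).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, tr_seconds: float) -> "ROITimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), tr_seconds, [str(c) for c in df.columns])


@dataclass
class MotionParams:
    """Rigid-body realignment parameters per volume.

    Columns: x, y, z translations (mm), then rotations about x, y, z
    (radians).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise DimensionMismatchError("motion must be (volumes x 6)")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotionParams":
        return cls(np.loadtxt(path, delimiter="\t", ndmin=2))


@dataclass
class FrameQuality:
    """Per-frame motion/artifact indices and the censoring mask."""

    fd: np.ndarray
    dvars: np.ndarray
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.fd.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)

    def summary(self) -> dict:
        return {
            "mean_fd_mm": float(self.fd.mean()),
            "mean_dvars": float(self.dvars.mean()),
            "n_censored": int(self.censored.sum()),
            "n_frames": int(self.fd.size),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def linear_detrend(ts: ROITimeSeries) -> ROITimeSeries:
    """Remove each channel's least-squares intercept and linear trend."""
    if ts.n_volumes < 3:
        raise TooFewVolumesError("detrending needs at least 3 volumes")
    return ts.with_values(spsig.detrend(ts.values, axis=0, type="linear"))


def bandpass(
    ts: ROITimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> ROITimeSeries:
    """Ideal frequency-domain band-pass.

    DFT coefficients with frequency in [low_hz, high_hz] are retained and
    all others (including DC) zeroed, conjugate-symmetrically, so the
    output is real and the filter is exactly idempotent.  This is the
    rectangular-filter convention of the common resting-state toolboxes,
    which makes in-band/out-of-band behaviour bin-exact.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 <= low_hz < high_hz <= nyquist):
        raise InvalidBandError(
            f"need 0 <= low < high <= Nyquist ({nyquist:g} Hz); "
            f"got [{low_hz}, {high_hz}]"
        )
    n = ts.n_volumes
    coeffs = np.fft.rfft(ts.values, axis=0)
    freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    coeffs[~keep, :] = 0.0
    return ts.with_values(np.fft.irfft(coeffs, n=n, axis=0))


def friston24(motion: MotionParams) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Columns: the 6 parameters, the 6 parameters lagged one frame
    (zero-filled at t = 0), and the element-wise squares of both.
    """
    m = motion.values
    lag = np.vstack([np.zeros((1, 6)), m[:-1, :]])
    return np.hstack([m, lag, m**2, lag**2])


def nuisance_regress(ts: ROITimeSeries, regressors: np.ndarray) -> ROITimeSeries:
    """Residualise every channel against [intercept | regressors] by OLS.

    Rank-deficient designs are handled by the minimum-norm least-squares
    solution; residuals are orthogonal to every regressor column either
    way.  An empty regressor matrix simply demeans the series.
    """
    regressors = np.asarray(regressors, dtype=float)
    if regressors.size == 0:
        regressors = np.empty((ts.n_volumes, 0))
    if regressors.ndim != 2 or regressors.shape[0] != ts.n_volumes:
        raise DimensionMismatchError(
            f"regressors have {regressors.shape[0]} rows for "
            f"{ts.n_volumes} volumes"
        )
    design = np.hstack([np.ones((ts.n_volumes, 1)), regressors])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ beta)


def _rigid_affine(params: np.ndarray) -> np.ndarray:
    """4x4 rigid-body transform from 6 parameters (SPM order T*Rx*Ry*Rz)."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    r_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    r_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    r_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = r_x @ r_y @ r_z
    m[:3, 3] = (tx, ty, tz)
    return m


def fd_jenkinson(motion: MotionParams, sphere_radius_mm: float = 80.0) -> np.ndarray:
    """Jenkinson framewise displacement.

    For consecutive frames with rigid transforms M_t, M_{t-1}, let
    [A | b] = M_t M_{t-1}^{-1} - I.  FD(t) is the RMS displacement of
    points uniformly distributed in a ball of radius R centred at the
    origin: sqrt((R^2 / 5) tr(A^T A) + b^T b).  FD(0) = 0.  R defaults
    to 80 mm, the conventional head-sized sphere.
    """
    m = motion.values
    fd = np.zeros(m.shape[0])
    r2 = sphere_radius_mm**2
    prev = _rigid_affine(m[0])
    for t in range(1, m.shape[0]):
        cur = _rigid_affine(m[t])
        diff = cur @ np.linalg.inv(prev) - np.eye(4)
        a = diff[:3, :3]
        b = diff[:3, 3]
        fd[t] = np.sqrt(r2 / 5.0 * np.trace(a.T @ a) + b @ b)
        prev = cur
    return fd


def dvars(ts: ROITimeSeries) -> np.ndarray:
    """Root-mean-square (across regions) of the frame-to-frame signal change.

    First frame is 0 by convention.
    """
    d = np.diff(ts.values, axis=0)
    out = np.zeros(ts.n_volumes)
    out[1:] = np.sqrt((d**2).mean(axis=1))
    return out


def default_dvars_threshold(dvars_values: np.ndarray) -> float:
    """Median + 1.5 x IQR of the (nonzero-frame) DVARS trace."""
    v = np.asarray(dvars_values, dtype=float)[1:]
    q1, q3 = np.percentile(v, [25, 75])
    return float(np.median(v) + 1.5 * (q3 - q1))


def scrub(
    ts: ROITimeSeries, quality: FrameQuality, dvars_threshold: float
) -> tuple[ROITimeSeries, FrameQuality]:
    """Censor frames whose DVARS exceeds the threshold.

    Censored frames are removed from the series used for correlation (no
    interpolation); the mask is recorded in the returned FrameQuality.
    """
    if dvars_threshold <= 0:
        raise AllFramesCensoredError("non-positive threshold censors everything")
    censored = quality.dvars > dvars_threshold
    keep = ~censored
    if keep.sum() < MIN_SURVIVING_FRAMES:
        raise AllFramesCensoredError(
            f"only {int(keep.sum())} frames survive scrubbing "
            f"(need >= {MIN_SURVIVING_FRAMES})"
        )
    out_quality = FrameQuality(quality.fd, quality.dvars, censored)
    return ts.with_values(ts.values[keep, :]), out_quality


def frame_quality(ts: ROITimeSeries, motion: MotionParams | None = None) -> FrameQuality:
    """FD + DVARS for a series (FD is zero when no motion is supplied)."""
    if motion is not None and motion.n_volumes != ts.n_volumes:
        raise DimensionMismatchError("motion rows must match series volumes")
    fd = fd_jenkinson(motion) if motion is not None else np.zeros(ts.n_volumes)
    return FrameQuality(fd, dvars(ts))


def clean(
    ts: ROITimeSeries,
    motion: MotionParams | None = None,
    nuisance: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> ROITimeSeries:
    """Full signal-level pipeline: detrend -> band-pass -> nuisance regression.

    The nuisance design is the Friston-24 expansion of ``motion`` (when
    given) stacked with any extra ``nuisance`` columns (e.g. white-matter
    and CSF signals).  Regressors are used as supplied, unfiltered; only
    the series itself is band-passed.
    """
    out = linear_detrend(ts)
    out = bandpass(out, low_hz, high_hz)
    blocks = []
    if motion is not None:
        if motion.n_volumes != ts.n_volumes:
            raise DimensionMismatchError("motion rows must match series volumes")
        blocks.append(friston24(motion))
    if nuisance is not None and np.asarray(nuisance).size:
        blocks.append(np.asarray(nuisance, dtype=float))
    if blocks:
        out = nuisance_regress(out, np.hstack(blocks))
    return out
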