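"""Frame-level quality filtering and seed-FC map estimation.

Motion scrubbing follows the rule used throughout the pipeline: a frame whose
framewise displacement (FD) exceeds 0.4 mm is censored together with the
preceding frame and the two following frames. Quality control keeps a session
only if at least 50 frames survive censoring and the mean FD over all frames is
at most 0.3 mm. Seed-FC maps are Pearson correlations between the seed-network
mean signal and every target feature over the kept frames. For test-retest
analyses, sessions are truncated to round(K/M * n_frame_min) frames each so
that averages over M sessions hold the total frame count at K session
equivalents.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSeries",
    "scrub_frames",
    "qc_pass",
    "seed_fc_map",
    "truncate_and_average",
    "read_frame_series",
    "write_frame_series",
]

FD_THRESHOLD_MM = 0.4
QC_MIN_FRAMES = 50
QC_MAX_MEAN_FD_MM = 0.3


@dataclasses.dataclass
class FrameSeries:
    """One scan session: seed mean signal, target signals, and per-frame FD (mm)."""

    seed_signal: np.ndarray  # (T,)
    target_signals: np.ndarray  # (T, F)
    fd: np.ndarray  # (T,)

    def __post_init__(self):
        self.seed_signal = np.asarray(self.seed_signal, dtype=float).ravel()
        self.target_signals = np.asarray(self.target_signals, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float).ravel()
        T = self.seed_signal.shape[0]
        if T < 1:
            raise ValueError("empty frame series")
        if self.target_signals.shape[0] != T or self.fd.shape[0] != T:
            raise ValueError(
                f"frame count mismatch: seed {T}, targets {self.target_signals.shape[0]}, "
                f"fd {self.fd.shape[0]}"
            )

    @property
    def n_frames(self) -> int:
        return self.seed_signal.shape[0]

    def truncated(self, n_frames: int) -> "FrameSeries":
        """First ``n_frames`` frames (deterministic, order-preserving)."""
        if n_frames > self.n_frames:
            raise ValueError(f"cannot truncate {self.n_frames} frames to {n_frames}")
        return FrameSeries(
            self.seed_signal[:n_frames], self.target_signals[:n_frames], self.fd[:n_frames]
        )


def scrub_frames(fd, threshold: float = FD_THRESHOLD_MM) -> np.ndarray:
    """Keep-mask after motion censoring.

    An exceedance (fd > threshold) at frame j removes frames j-1, j, j+1, j+2
    (clipped at the series bounds). Returns a boolean vector of the input length.
    """
    fd = np.asarray(fd, dtype=float).ravel()
    if fd.size == 0:
        raise ValueError("empty FD vector")
    if not np.isfinite(fd).all() or (fd < 0).any():
        raise ValueError("FD must be finite and non-negative")
    keep = np.ones(fd.size, dtype=bool)
    for j in np.flatnonzero(fd > threshold):
        keep[max(j - 1, 0) : j + 3] = False
    return keep


def qc_pass(
    keep_mask,
    fd,
    min_frames: int = QC_MIN_FRAMES,
    max_mean_fd: float = QC_MAX_MEAN_FD_MM,
) -> bool:
    """True iff >= ``min_frames`` frames survive censoring and mean FD <= ``max_mean_fd``.

    Mean FD is taken over all frames of the session, not only the kept ones.
    """
    keep_mask = np.asarray(keep_mask, dtype=bool).ravel()
    fd = np.asarray(fd, dtype=float).ravel()
    if keep_mask.size != fd.size:
        raise ValueError("mask and FD length differ")
    return bool(keep_mask.sum() >= min_frames and fd.mean() <= max_mean_fd)


def seed_fc_map(series: FrameSeries, keep_mask=None) -> np.ndarray:
    """Pearson correlation of the kept seed frames with each kept target feature.

    Zero-variance targets yield NaN (propagated as missing downstream); a
    zero-variance seed is an error since no feature would be defined.
    """
    if keep_mask is None:
        keep_mask = np.ones(series.n_frames, dtype=bool)
    keep_mask = np.asarray(keep_mask, dtype=bool).ravel()
    if keep_mask.size != series.n_frames:
        raise ValueError("keep mask length does not match frame count")
    if keep_mask.sum() < 3:
        raise ValueError(f"only {int(keep_mask.sum())} kept frames; need >= 3")
    x = series.seed_signal[keep_mask]
    Y = series.target_signals[keep_mask]
    xc = x - x.mean()
    nx = np.linalg.norm(xc)
    if nx == 0:
        raise ValueError("zero-variance seed signal over kept frames")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    ny = np.linalg.norm(Yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / (nx * ny)
    r[ny == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def session_frame_count(M: int, K: int, n_frame_min: int) -> int:
    """Frames per session so that M sessions total K session-equivalents of data.

    Nearest-integer rounding (half to even); e.g. n_frame_min=238 gives 79
    frames for (M=3, K=1) and 159 for (M=3, K=2).
    """
    if not (1 <= K <= M):
        raise ValueError(f"need 1 <= K <= M, got K={K}, M={M}")
    n = int(np.rint(K / M * n_frame_min))
    if n < 3:
        raise ValueError(f"truncated frame count {n} < 3 (M={M}, K={K}, n_frame_min={n_frame_min})")
    return n


def truncate_and_average(
    sessions: Sequence[FrameSeries],
    M: int,
    K: int,
    n_frame_min: int,
    scrub: bool = True,
    fd_threshold: float = FD_THRESHOLD_MM,
) -> np.ndarray:
    """Average seed-FC map over ``M`` truncated sessions.

    Each of the first M sessions is truncated to round(K/M * n_frame_min)
    frames, a per-session seed-FC map is computed, and the maps are averaged
    elementwise. Motion censoring, when enabled, is applied before truncation
    (configurable order is handled by the caller pre-scrubbing).
    """
    if M > len(sessions):
        raise ValueError(f"M={M} sessions requested but only {len(sessions)} available")
    if n_frame_min > min(s.n_frames for s in sessions[:M]):
        raise ValueError("n_frame_min exceeds the shortest session")
    n = session_frame_count(M, K, n_frame_min)
    maps = []
    for s in sessions[:M]:
        if scrub:
            keep = scrub_frames(s.fd, threshold=fd_threshold)
            s = FrameSeries(s.seed_signal[keep], s.target_signals[keep], s.fd[keep])
            if s.n_frames < n:
                raise ValueError("too few frames remain after censoring for this truncation")
        st = s.truncated(n)
        maps.append(seed_fc_map(st))
    return np.nanmean(np.vstack(maps), axis=0)


def write_frame_series(series: FrameSeries, path) -> None:
    """One TSV per session: frame rows; columns seed, target features, fd."""
    df = pd.DataFrame(series.target_signals, columns=[f"f{i}" for i in range(series.target_signals.shape[1])])
    df.insert(0, "seed", series.seed_signal)
    df["fd"] = series.fd
    df.to_csv(path, sep="\t", index=False)


def read_frame_series(path) -> FrameSeries:
    df = pd.read_csv(path, sep="\t")
    for col in ("seed", "fd"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    targets = df.drop(columns=["seed", "fd"])
    return FrameSeries(df["seed"].to_numpy(), targets.to_numpy(), df["fd"].to_numpy())
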