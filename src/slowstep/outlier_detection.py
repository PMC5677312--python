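"""Sliding-window Mahalanobis outlier pre-detection of candidate ground contacts.

A ground contact at slow cadence produces a short, prominent burst in the
``(ag, aHx)`` plane.  For every interior sample the Mahalanobis statistic of
the 2-D point at the window center is computed against the sample mean and
covariance of a symmetric window whose duration is one full step period at the
maximum target cadence (``60 / c_max`` seconds, 1.5 s for 40 steps/min).
Samples whose statistic exceeds the threshold are flagged; contiguous flagged
runs are collapsed and a refractory period suppresses duplicates so that one
ground contact yields one time-aligned candidate.

The threshold (default 3) is interpreted on the *squared* Mahalanobis scale,
matching the convention of the common statistics-toolbox function of that
name; the plain distance is available through ``stat_kind``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .signal_model import DerivedSignals

#: Condition number above which the window covariance is ridge-regularized.
COND_LIMIT = 1e12
#: Ridge scale, relative to the mean diagonal entry of the covariance.
RIDGE_SCALE = 1e-9

#: Default candidate-to-truth matching tolerance in seconds.
DEFAULT_MATCH_TOL_S = 0.2


@dataclass
class OutlierConfig:
    """Parameters of the pre-detection stage.

    ``window_s`` defaults to one step period at ``c_max`` (60/40 = 1.5 s);
    ``refractory_s`` defaults to half of that, which cannot merge two distinct
    steps because at ``c_max`` steps are at least one window apart.
    """

    c_max: float = 40.0
    c_min: float = 30.0
    window_s: float | None = None
    threshold: float = 3.0
    refractory_s: float | None = None
    stat_kind: str = "squared"

    def __post_init__(self) -> None:
        if self.c_min > self.c_max:
            raise InputError("c_min must not exceed c_max")
        if self.window_s is None:
            self.window_s = 60.0 / self.c_max
        if self.window_s <= 0:
            raise InputError("window_s must be positive")
        if self.refractory_s is None:
            self.refractory_s = self.window_s / 2.0
        if self.threshold <= 0:
            raise InputError("threshold must be positive")
        if self.stat_kind not in ("squared", "distance"):
            raise InputError(f"unknown stat_kind '{self.stat_kind}'")

    def window_samples(self, sample_rate: float) -> int:
        """Window length in samples, rounded to the nearest odd count."""
        n = int(round(self.window_s * sample_rate))
        if n % 2 == 0:
            n += 1
        return max(n, 3)


@dataclass(frozen=True)
class Candidate:
    """A consolidated outlier hypothesized to contain a ground contact."""

    index: int
    time: float
    stat: float


def mahalanobis_stat(point, window, stat_kind: str = "squared") -> float:
    """Mahalanobis statistic of ``point`` against a window of samples.

    The window includes the point itself.  Returns the quadratic form
    ``(x - mu)' Sigma^{-1} (x - mu)`` with the sample (n-1) covariance, or its
    square root for ``stat_kind='distance'``.  Near-singular covariances are
    ridge-regularized; an exactly constant window yields 0 for a point equal
    to the mean and infinity otherwise.
    """
    x = np.asarray(point, dtype=float)
    w = np.asarray(window, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
        x = np.atleast_1d(x)
    if len(w) < 3:
        raise InputError("window must contain at least 3 samples")
    mu = w.mean(axis=0)
    dev = x - mu
    cov = np.atleast_2d(np.cov(w, rowvar=False, ddof=1))
    tr = float(np.trace(cov))
    if tr == 0.0:
        d2 = 0.0 if np.allclose(dev, 0.0) else np.inf
    else:
        if np.linalg.cond(cov) > COND_LIMIT:
            cov = cov + RIDGE_SCALE * tr / cov.shape[0] * np.eye(cov.shape[0])
        d2 = float(dev @ np.linalg.solve(cov, dev))
        d2 = max(d2, 0.0)
    return float(np.sqrt(d2)) if stat_kind == "distance" else d2


def scan_outliers(
    signals: DerivedSignals, config: OutlierConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flag every interior sample whose Mahalanobis statistic exceeds the threshold.

    Returns ``(indices, stats)`` for the flagged samples, indices being
    absolute sample positions.  Border samples without a full centered window
    are skipped.  The statistic is affine-invariant, so jointly rescaling both
    channels leaves the flagged set unchanged.
    """
    if config is None:
        config = OutlierConfig()
    x = np.column_stack([signals.ag, signals.ahx])
    n = len(x)
    w = config.window_samples(signals.sample_rate)
    if n < w:
        raise InputError(f"signal has {n} samples but the window needs {w}")
    half = (w - 1) // 2

    windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=0)  # (m, 2, w)
    mu = windows.mean(axis=2)  # (m, 2)
    dev_w = windows - mu[:, :, None]
    # sample covariance entries per window
    s11 = np.einsum("mk,mk->m", dev_w[:, 0, :], dev_w[:, 0, :]) / (w - 1)
    s22 = np.einsum("mk,mk->m", dev_w[:, 1, :], dev_w[:, 1, :]) / (w - 1)
    s12 = np.einsum("mk,mk->m", dev_w[:, 0, :], dev_w[:, 1, :]) / (w - 1)

    tr = s11 + s22
    disc = np.sqrt(np.maximum((s11 - s22) ** 2 + 4.0 * s12**2, 0.0))
    lmin = (tr - disc) / 2.0
    lmax = (tr + disc) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(lmin > 0, lmax / np.where(lmin > 0, lmin, 1.0), np.inf)
    needs_ridge = (cond > COND_LIMIT) & (tr > 0)
    ridge = RIDGE_SCALE * tr / 2.0
    s11 = np.where(needs_ridge, s11 + ridge, s11)
    s22 = np.where(needs_ridge, s22 + ridge, s22)
    det = s11 * s22 - s12**2

    center = x[half : n - half]
    dx = center[:, 0] - mu[:, 0]
    dy = center[:, 1] - mu[:, 1]
    quad = dx**2 * s22 - 2.0 * dx * dy * s12 + dy**2 * s11
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(det > 0, quad / np.where(det > 0, det, 1.0), np.inf)
    # exactly constant window: the center point is the mean -> statistic 0
    d2 = np.where((tr == 0) & (dx == 0) & (dy == 0), 0.0, d2)
    d2 = np.maximum(d2, 0.0)
    stat = np.sqrt(d2) if config.stat_kind == "distance" else d2

    flagged = np.nonzero(stat > config.threshold)[0]
    return flagged + half, stat[flagged]


def consolidate_candidates(
    indices: np.ndarray,
    stats: np.ndarray,
    sample_rate: float,
    config: OutlierConfig | None = None,
) -> list[Candidate]:
    """Collapse flagged samples into one time-aligned candidate per ground contact.

    Contiguous runs of flagged samples collapse to the run's strongest sample
    (earliest index on ties); candidates closer than the refractory period then
    keep only the larger statistic.  Output is time-sorted with pairwise
    spacing >= ``refractory_s``.
    """
    if config is None:
        config = OutlierConfig()
    indices = np.asarray(indices, dtype=int)
    stats = np.asarray(stats, dtype=float)
    if len(indices) == 0:
        return []
    if np.any(np.diff(indices) <= 0):
        raise InputError("flagged indices must be sorted and unique")

    # collapse contiguous runs to their argmax
    run_starts = np.concatenate([[0], np.nonzero(np.diff(indices) > 1)[0] + 1])
    run_ends = np.concatenate([run_starts[1:], [len(indices)]])
    peaks_idx, peaks_stat = [], []
    for a, b in zip(run_starts, run_ends):
        k = a + int(np.argmax(stats[a:b]))  # argmax takes the earliest on ties
        peaks_idx.append(int(indices[k]))
        peaks_stat.append(float(stats[k]))

    # refractory suppression: strongest first, earlier index on ties
    order = sorted(range(len(peaks_idx)), key=lambda i: (-peaks_stat[i], peaks_idx[i]))
    min_gap = config.refractory_s * sample_rate
    kept: list[int] = []
    for i in order:
        if all(abs(peaks_idx[i] - peaks_idx[j]) >= min_gap for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: peaks_idx[i])
    return [
        Candidate(index=peaks_idx[i], time=peaks_idx[i] / sample_rate, stat=peaks_stat[i])
        for i in kept
    ]


def match_to_truth(
    candidate_times: Sequence[float],
    truth_times: Sequence[float],
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-neighbor one-to-one matching of candidates to truth times.

    Pairs within ``tol_s`` are taken in order of increasing time difference;
    ties are broken toward the earlier truth, then the earlier candidate, so
    the matching is deterministic.  Returns ``(matched pairs, unmatched
    candidate indices, missed truth indices)``.
    """
    cand = np.asarray(candidate_times, dtype=float)
    truth = np.asarray(truth_times, dtype=float)
    pairs = [
        (abs(c - tt), j, i)
        for i, c in enumerate(cand)
        for j, tt in enumerate(truth)
        if abs(c - tt) <= tol_s
    ]
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, j, i in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        matches.append((i, j))
    matches.sort()
    unmatched = [i for i in range(len(cand)) if i not in used_c]
    missed = [j for j in range(len(truth)) if j not in used_t]
    return matches, unmatched, missed


def candidates_to_frame(candidates: Sequence[Candidate]) -> pd.DataFrame:
    """Candidates as a ``index,time,stat`` table, ready for CSV export."""
    return pd.DataFrame(
        {
            "index": [c.index for c in candidates],
            "time": [c.time for c in candidates],
            "stat": [c.stat for c in candidates],
        }
    )
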