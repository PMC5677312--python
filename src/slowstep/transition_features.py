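"""Std-band state discretization and transition-matrix featurization.

Each candidate ground contact is characterized by the 240 ms of signal around
it (13 samples at 50 Hz, N = 6 per side).  Within that window every sample is
assigned one of 8 states according to its deviation from the window mean in
multiples of the window standard deviation, with band edges at 0, +-0.5, +-1.0
and +-1.5 std and closed upper bounds (a deviation of exactly 0 falls in S4).
The 8x8 matrix of consecutive-state transition probabilities (row-normalized
counts; empty rows stay zero) is serialized row-major to a 64-vector that
feeds the autoencoder.

Because states are defined relative to the window's own mean and standard
deviation, the feature is invariant to positive affine transforms of the
signal — this is what makes it insensitive to participant weight and sensor
gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BoundaryError, InputError
from .outlier_detection import Candidate
from .signal_model import DerivedSignals


@dataclass
class FeatureConfig:
    """Window half-length (samples per side) and state-band layout."""

    half_window_samples: int = 6
    n_states: int = 8
    band_edges: tuple[float, ...] = (0.5, 1.0, 1.5)
    std_ddof: int = 1  # sample standard deviation; 0 for the population variant

    def __post_init__(self) -> None:
        if self.half_window_samples < 2:
            raise InputError("half_window_samples must be >= 2")
        if self.n_states != 2 * (len(self.band_edges) + 1):
            raise InputError(
                f"band_edges imply {2 * (len(self.band_edges) + 1)} states, "
                f"not n_states={self.n_states}"
            )
        if list(self.band_edges) != sorted(self.band_edges) or self.band_edges[0] <= 0:
            raise InputError("band_edges must be positive and increasing")

    @property
    def window_len(self) -> int:
        return 2 * self.half_window_samples + 1


@dataclass
class StateSequence:
    """Discretized window: states in ``1..n_states`` plus the window moments."""

    states: np.ndarray
    m: float
    std: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)


@dataclass
class TransitionFeature:
    """Row-normalized transition matrix and its row-major vectorization."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise InputError("transition matrix must be square")

    @property
    def vector(self) -> np.ndarray:
        """Length ``n_states**2`` row-major concatenation of the matrix rows."""
        return self.matrix.reshape(-1)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "TransitionFeature":
        vec = np.asarray(vec, dtype=float)
        n = int(round(np.sqrt(len(vec))))
        if n * n != len(vec):
            raise InputError("vector length is not a perfect square")
        return cls(matrix=vec.reshape(n, n))


def extract_window(signal, center: int, n_half: int) -> np.ndarray:
    """The ``2*n_half + 1`` samples centered at ``center``; bounds are strict."""
    signal = np.asarray(signal, dtype=float)
    if center - n_half < 0 or center + n_half >= len(signal):
        raise BoundaryError(
            f"window [{center - n_half}, {center + n_half}] exceeds "
            f"signal bounds [0, {len(signal) - 1}]"
        )
    return signal[center - n_half : center + n_half + 1]


def discretize_states(window, config: FeatureConfig | None = None) -> StateSequence:
    """Map each sample to a std-band state relative to the window's own moments.

    Band inequalities have closed upper bounds: sample ``x`` is in state ``k``
    iff ``edge[k-1] < x - m <= edge[k]`` with edges ``(-inf, -1.5s, -s, -0.5s,
    0, 0.5s, s, 1.5s, inf)``.  A zero-variance window maps every sample to the
    state just below the mean (S4 of 8: deviation 0 satisfies "<= 0").
    """
    if config is None:
        config = FeatureConfig()
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise InputError("window must be non-empty")
    m = float(w.mean())
    std = float(w.std(ddof=config.std_ddof)) if w.size > config.std_ddof else 0.0
    k = config.n_states // 2
    if std == 0.0:
        states = np.full(w.shape, k, dtype=int)
    else:
        pos = std * np.asarray(config.band_edges)
        edges = np.concatenate([-pos[::-1], [0.0], pos])
        states = np.digitize(w - m, edges, right=True) + 1
    return StateSequence(states=states, m=m, std=std)


def transition_matrix(
    states: StateSequence | np.ndarray, n_states: int = 8
) -> TransitionFeature:
    """Estimate transition probabilities from the consecutive-state pairs.

    Counts every ``j -> k`` over adjacent samples, then divides each row by its
    total count; rows with no outgoing transitions remain all-zero (preserving
    sparsity and keeping entries in [0, 1]).
    """
    s = states.states if isinstance(states, StateSequence) else np.asarray(states, dtype=int)
    if len(s) < 2:
        raise InputError("need at least 2 states to count transitions")
    if np.any(s < 1) or np.any(s > n_states):
        raise InputError(f"states must lie in 1..{n_states}")
    counts = np.zeros((n_states, n_states), dtype=float)
    np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    return TransitionFeature(matrix=probs)


def candidate_features(
    signals: DerivedSignals,
    candidate: Candidate | int,
    config: FeatureConfig | None = None,
) -> tuple[TransitionFeature, TransitionFeature]:
    """Per-channel transition features for the window around a candidate.

    Each channel is discretized against its own window mean and standard
    deviation, which normalizes away participant- and placement-dependent
    amplitude differences.  Raises :class:`BoundaryError` if the window does
    not fit; callers drop such candidates.
    """
    if config is None:
        config = FeatureConfig()
    center = candidate.index if isinstance(candidate, Candidate) else int(candidate)
    n = config.half_window_samples
    feats = []
    for channel in (signals.ag, signals.ahx):
        window = extract_window(channel, center, n)
        states = discretize_states(window, config)
        feats.append(transition_matrix(states, config.n_states))
    return feats[0], feats[1]


def features_to_frame(
    times: Sequence[float],
    feats_ag: Sequence[TransitionFeature],
    feats_ahx: Sequence[TransitionFeature],
    n_states: int = 8,
) -> pd.DataFrame:
    """Features as a flat table: candidate time plus ``<chan>_t_j_k`` columns."""
    cols: dict[str, list] = {"time": list(times)}
    for name, feats in (("ag", feats_ag), ("ahx", feats_ahx)):
        mat = np.array([f.vector for f in feats]) if feats else np.empty((0, n_states**2))
        for j in range(n_states):
            for k in range(n_states):
                cols[f"{name}_t_{j + 1}_{k + 1}"] = list(mat[:, j * n_states + k])
    return pd.DataFrame(cols)
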