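"""End-to-end slow-walk step detector: both feature variants plus the decision rule.

Two detector variants share the outlier pre-detection front end and differ in
what the per-channel autoencoders see:

* ``raw_accel`` — the min-max-scaled 13-sample acceleration window itself;
* ``transition_matrix`` — the 64-vector serialization of the 8x8 std-band
  transition matrix of that window.

Training isolates candidates that the pre-detection stage aligned to labeled
ground contacts inside the slow-walk segments (30 and 40 steps/min) and fits
one autoencoder per channel on their inputs.  At detection time every outlier
candidate in the full session is reconstructed by both models and scored with
the Pearson correlation between autoencoder input and output; a candidate is
accepted as a slow-walk step only when *both* channel similarities exceed the
threshold.  All candidates are returned with their similarities so threshold
sweeps can be replayed without re-scanning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import autoencoder as ae
from .errors import BoundaryError, InputError, InsufficientDataError
from .outlier_detection import (
    Candidate,
    DEFAULT_MATCH_TOL_S,
    OutlierConfig,
    consolidate_candidates,
    match_to_truth,
    scan_outliers,
)
from .signal_model import AccelSession, DerivedSignals, SLOW_WALK_LABELS, derive_signals
from .transition_features import FeatureConfig, candidate_features, extract_window

logger = logging.getLogger("slowstep")

VARIANTS = ("raw_accel", "transition_matrix")
DEFAULT_THRESHOLD_GRID = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
MIN_TRAINING_CANDIDATES = 10


@dataclass
class DetectorModel:
    """Trained detector: one autoencoder per channel plus the stage configs."""

    variant: str
    model_ag: ae.AutoencoderModel
    model_ahx: ae.AutoencoderModel
    outlier_config: OutlierConfig
    feature_config: FeatureConfig
    similarity_threshold: float = 0.6
    decision: str = "and"  # "mean" averages the two channel similarities

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InputError(f"unknown variant '{self.variant}'")
        if self.decision not in ("and", "mean"):
            raise InputError(f"unknown decision rule '{self.decision}'")


@dataclass(frozen=True)
class Detection:
    """One scored candidate: similarities for both channels and the verdict."""

    time: float
    sim_ag: float
    sim_ahx: float
    accepted: bool


def pearson(x, y) -> float:
    """Pearson correlation; defined as 0 when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InputError("pearson needs two equal-length vectors of length >= 2")
    sx = x - x.mean()
    sy = y - y.mean()
    nx = float(np.sqrt(np.sum(sx**2)))
    ny = float(np.sqrt(np.sum(sy**2)))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(sx, sy) / (nx * ny))


def _candidate_inputs(
    signals: DerivedSignals,
    center: int,
    variant: str,
    feature_config: FeatureConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled per-channel input vectors for one candidate (may raise BoundaryError)."""
    if variant == "raw_accel":
        n = feature_config.half_window_samples
        return (
            extract_window(signals.ag, center, n),
            extract_window(signals.ahx, center, n),
        )
    feat_ag, feat_ahx = candidate_features(signals, center, feature_config)
    return feat_ag.vector, feat_ahx.vector


def _session_candidates(
    session: AccelSession, outlier_config: OutlierConfig
) -> tuple[DerivedSignals, list[Candidate]]:
    signals = derive_signals(session)
    idx, stats = scan_outliers(signals, outlier_config)
    return signals, consolidate_candidates(idx, stats, session.sample_rate, outlier_config)


def train_detector(
    sessions: Iterable[AccelSession],
    variant: str = "transition_matrix",
    outlier_config: OutlierConfig | None = None,
    feature_config: FeatureConfig | None = None,
    seed: int = 0,
    similarity_threshold: float = 0.6,
    match_tol_s: float = DEFAULT_MATCH_TOL_S,
    epochs: int = ae.DEFAULT_EPOCHS,
    decision: str = "and",
) -> DetectorModel:
    """Fit both channel autoencoders on truth-aligned slow-walk candidates.

    Per session: scan for outlier candidates, keep those matching a labeled
    ground contact inside a walk30/walk40 segment (within ``match_tol_s``),
    and collect their per-channel inputs.  Candidates whose feature window
    crosses the session boundary are dropped.
    """
    if variant not in VARIANTS:
        raise InputError(f"unknown variant '{variant}'")
    outlier_config = outlier_config or OutlierConfig()
    feature_config = feature_config or FeatureConfig()
    rows_ag: list[np.ndarray] = []
    rows_ahx: list[np.ndarray] = []
    for session in sessions:
        signals, candidates = _session_candidates(session, outlier_config)
        slow_truth = session.truth_in_labels(SLOW_WALK_LABELS)
        matches, _, _ = match_to_truth(
            [c.time for c in candidates], slow_truth, match_tol_s
        )
        for cand_i, _truth_j in matches:
            try:
                in_ag, in_ahx = _candidate_inputs(
                    signals, candidates[cand_i].index, variant, feature_config
                )
            except BoundaryError:
                logger.warning(
                    "dropping training candidate at %.3fs: window out of bounds",
                    candidates[cand_i].time,
                )
                continue
            rows_ag.append(in_ag)
            rows_ahx.append(in_ahx)
    if len(rows_ag) < MIN_TRAINING_CANDIDATES:
        raise InsufficientDataError(
            f"only {len(rows_ag)} truth-matched training candidates "
            f"(need >= {MIN_TRAINING_CANDIDATES})"
        )
    X_ag = np.asarray(rows_ag)
    X_ahx = np.asarray(rows_ahx)
    if variant == "raw_accel":
        scaler_ag = ae.fit_scaler(X_ag)
        scaler_ahx = ae.fit_scaler(X_ahx)
        X_ag = ae.apply_scaler(scaler_ag, X_ag)
        X_ahx = ae.apply_scaler(scaler_ahx, X_ahx)
    else:
        scaler_ag = scaler_ahx = None
    seed_ag, seed_ahx = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(2) % (2**31)
    )
    logger.info(
        "training %s detector on %d candidates (input dim %d)",
        variant, len(X_ag), X_ag.shape[1],
    )
    model_ag = ae.train(X_ag, seed=seed_ag, epochs=epochs, scaler=scaler_ag)
    model_ahx = ae.train(X_ahx, seed=seed_ahx, epochs=epochs, scaler=scaler_ahx)
    return DetectorModel(
        variant=variant,
        model_ag=model_ag,
        model_ahx=model_ahx,
        outlier_config=outlier_config,
        feature_config=feature_config,
        similarity_threshold=similarity_threshold,
        decision=decision,
    )


def is_accepted(sim_ag: float, sim_ahx: float, threshold: float, decision: str = "and") -> bool:
    if decision == "mean":
        return (sim_ag + sim_ahx) / 2.0 > threshold
    return sim_ag > threshold and sim_ahx > threshold


def detect(model: DetectorModel, session: AccelSession) -> list[Detection]:
    """Score every outlier candidate in the session; keep rejected ones too."""
    signals, candidates = _session_candidates(session, model.outlier_config)
    detections: list[Detection] = []
    for cand in candidates:
        try:
            in_ag, in_ahx = _candidate_inputs(
                signals, cand.index, model.variant, model.feature_config
            )
        except BoundaryError:
            logger.warning("skipping candidate at %.3fs: window out of bounds", cand.time)
            continue
        x_ag = ae.apply_scaler(model.model_ag.scaler, in_ag)
        x_ahx = ae.apply_scaler(model.model_ahx.scaler, in_ahx)
        sim_ag = pearson(x_ag, ae.reconstruct(model.model_ag, x_ag))
        sim_ahx = pearson(x_ahx, ae.reconstruct(model.model_ahx, x_ahx))
        detections.append(
            Detection(
                time=cand.time,
                sim_ag=sim_ag,
                sim_ahx=sim_ahx,
                accepted=is_accepted(
                    sim_ag, sim_ahx, model.similarity_threshold, model.decision
                ),
            )
        )
    return detections


def accepted_times(
    detections: Sequence[Detection], threshold: float, decision: str = "and"
) -> np.ndarray:
    """Re-apply the decision rule to cached similarities at a new threshold."""
    return np.asarray(
        [d.time for d in detections if is_accepted(d.sim_ag, d.sim_ahx, threshold, decision)]
    )


def sweep_thresholds(
    model: DetectorModel,
    sessions: Sequence[AccelSession],
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    detections_per_session: Sequence[Sequence[Detection]] | None = None,
    count_all_steps: bool = False,
) -> pd.DataFrame:
    """Pooled recall/precision/F table over a threshold grid.

    Similarities are computed once per session and the decision rule replayed
    per threshold; counts are pooled over sessions before the metrics are
    formed.  Pass ``detections_per_session`` to reuse cached similarities.
    """
    from .evaluation import f_score, score_detections  # local import: avoids a cycle

    if detections_per_session is None:
        detections_per_session = [detect(model, s) for s in sessions]
    rows = []
    for thr in thresholds:
        tp = fp = Tp = 0
        for session, dets in zip(sessions, detections_per_session):
            report = score_detections(
                accepted_times(dets, thr, model.decision),
                session.step_truth,
                session.segments,
                count_all_steps=count_all_steps,
            )
            tp += report.tp
            fp += report.fp
            Tp += report.Tp
        recall = tp / Tp if Tp else 0.0
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        rows.append(
            {
                "threshold": thr,
                "recall": recall,
                "precision": precision,
                "f_score": f_score(recall, precision),
                "tp": tp,
                "fp": fp,
                "Tp": Tp,
            }
        )
    return pd.DataFrame(rows)


def detections_to_frame(detections: Sequence[Detection]) -> pd.DataFrame:
    """Detections as a ``time,sim_ag,sim_aHx,accepted`` table."""
    return pd.DataFrame(
        {
            "time": [d.time for d in detections],
            "sim_ag": [d.sim_ag for d in detections],
            "sim_aHx": [d.sim_ahx for d in detections],
            "accepted": [d.accepted for d in detections],
        }
    )


def save_detector(model: DetectorModel, path) -> Path:
    """Serialize the detector (both autoencoders plus configs) to one JSON bundle."""
    from dataclasses import asdict

    doc = {
        "variant": model.variant,
        "similarity_threshold": model.similarity_threshold,
        "decision": model.decision,
        "outlier_config": asdict(model.outlier_config),
        "feature_config": {
            "half_window_samples": model.feature_config.half_window_samples,
            "n_states": model.feature_config.n_states,
            "band_edges": list(model.feature_config.band_edges),
            "std_ddof": model.feature_config.std_ddof,
        },
        "model_ag": ae.model_to_dict(model.model_ag),
        "model_aHx": ae.model_to_dict(model.model_ahx),
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_detector(path) -> DetectorModel:
    doc = json.loads(Path(path).read_text())
    fc = doc["feature_config"]
    return DetectorModel(
        variant=doc["variant"],
        model_ag=ae.model_from_dict(doc["model_ag"]),
        model_ahx=ae.model_from_dict(doc["model_aHx"]),
        outlier_config=OutlierConfig(**doc["outlier_config"]),
        feature_config=FeatureConfig(
            half_window_samples=fc["half_window_samples"],
            n_states=fc["n_states"],
            band_edges=tuple(fc["band_edges"]),
            std_ddof=fc["std_ddof"],
        ),
        similarity_threshold=doc["similarity_threshold"],
        decision=doc["decision"],
    )
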