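"""Metrics, false-positive attribution and the leave-one-subject-out harness.

The detector is scored against the target class — ground contacts inside the
30 and 40 steps/min walking segments.  Accepted detections are matched
one-to-one to target truths within a tolerance; matched detections are true
positives, every other accepted detection is a false positive attributed to
the activity segment containing it (so a moderate-pace step counted by the
detector is, by default, a false positive for the slow-walk class; the
``count_all_steps`` flag flips to the generic step-counting convention where
any genuine step counts).  Recall, precision and F follow the usual
definitions: ``recall = tp/Tp``, ``precision = tp/(tp+fp)``,
``F = 2PR/(P+R)``.

The leave-one-subject-out harness trains on all participants but one,
evaluates on the held-out participant's *full* session (all activities) and
reports per-fold, fold-averaged and count-pooled threshold sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedMetricError
from .outlier_detection import DEFAULT_MATCH_TOL_S, match_to_truth
from .signal_model import AccelSession, STEP_LABELS, SLOW_WALK_LABELS, Segment
from .step_detector import (
    DEFAULT_THRESHOLD_GRID,
    DetectorModel,
    Detection,
    accepted_times,
    detect,
    train_detector,
)

logger = logging.getLogger("slowstep")

#: Activity classes over which the false-positive distribution is reported.
FP_ACTIVITY_CLASSES = ("sit", "circles30", "slide30", "walk60")


def f_score(recall: float, precision: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= recall <= 1 and 0 <= precision <= 1):
        raise InputError("recall and precision must lie in [0, 1]")
    if recall + precision == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Counts, metrics and the false-positive distribution for one evaluation."""

    tp: int
    fp: int
    Tp: int
    recall: float
    precision: float
    f_score: float
    #: Percentage of non-standing false positives per activity class.
    fp_by_activity: dict[str, float]
    #: False positives inside standing segments, reported apart from the
    #: percentage distribution (standing is not one of the confusable classes).
    fp_stand: int = 0
    missed: int = 0
    per_participant: dict[str, "EvalReport"] | None = None

    def to_dict(self) -> dict:
        doc = {
            "tp": self.tp,
            "fp": self.fp,
            "Tp": self.Tp,
            "recall": self.recall,
            "precision": self.precision,
            "f_score": self.f_score,
            "fp_by_activity": self.fp_by_activity,
            "fp_stand": self.fp_stand,
            "missed": self.missed,
        }
        if self.per_participant:
            doc["per_participant"] = {
                k: v.to_dict() for k, v in self.per_participant.items()
            }
        return doc


def _segment_label_at(segments: Sequence[Segment], time: float) -> str:
    for seg in segments:
        if seg.start <= time < seg.end:
            return seg.label
    return "stand"  # outside any segment: treat as idle


def score_detections(
    accepted: Sequence[float],
    step_truth: Sequence[float],
    segments: Sequence[Segment],
    tol_s: float = DEFAULT_MATCH_TOL_S,
    count_all_steps: bool = False,
) -> EvalReport:
    """Score accepted detection times against the ground truth.

    ``Tp`` counts truth steps of the target class only; matching is one-to-one
    within ``tol_s``.  Accounting is exhaustive: ``tp + missed == Tp`` and
    every accepted detection is either a tp or an fp.
    """
    accepted = np.sort(np.asarray(accepted, dtype=float))
    truth = np.asarray(step_truth, dtype=float)
    target_labels = STEP_LABELS if count_all_steps else SLOW_WALK_LABELS
    target_truth = np.asarray(
        [t for t in truth if _segment_label_at(segments, t) in target_labels]
    )
    Tp = len(target_truth)
    if Tp == 0:
        raise UndefinedMetricError("no target-class truth steps: recall is undefined")
    matches, unmatched_cand, missed_truth = match_to_truth(accepted, target_truth, tol_s)
    tp = len(matches)
    fp_times = [accepted[i] for i in unmatched_cand]
    fp = len(fp_times)
    fp_labels = [_segment_label_at(segments, t) for t in fp_times]
    fp_stand = sum(1 for lab in fp_labels if lab == "stand")
    dist_counts = {cls: 0 for cls in FP_ACTIVITY_CLASSES}
    for lab in fp_labels:
        if lab != "stand":
            dist_counts[lab] = dist_counts.get(lab, 0) + 1
    n_dist = sum(dist_counts.values())
    fp_by_activity = {
        cls: (100.0 * c / n_dist if n_dist else 0.0) for cls, c in dist_counts.items()
    }
    recall = tp / Tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return EvalReport(
        tp=tp,
        fp=fp,
        Tp=Tp,
        recall=recall,
        precision=precision,
        f_score=f_score(recall, precision),
        fp_by_activity=fp_by_activity,
        fp_stand=fp_stand,
        missed=len(missed_truth),
    )


@dataclass
class FoldResult:
    """One leave-one-out fold: the held-out participant and its cached scores."""

    participant_id: str
    model: DetectorModel
    session: AccelSession
    detections: list[Detection]
    sweep: pd.DataFrame


@dataclass
class LosoResult:
    """All folds plus fold-averaged and count-pooled sweep tables."""

    folds: list[FoldResult]
    averaged: pd.DataFrame
    pooled: pd.DataFrame
    variant: str

    def best_row(self, table: str = "pooled") -> pd.Series:
        """Sweep row with the highest F (largest threshold on ties)."""
        df = self.pooled if table == "pooled" else self.averaged
        best = df[df.f_score == df.f_score.max()]
        return best.iloc[-1]

    def score_at(
        self, threshold: float, count_all_steps: bool = False
    ) -> EvalReport:
        """Pooled report (with fp distribution) at one threshold, from cached sims."""
        per_fold: dict[str, EvalReport] = {}
        tp = fp = Tp = fp_stand = missed = 0
        dist_counts = {cls: 0 for cls in FP_ACTIVITY_CLASSES}
        for fold in self.folds:
            rep = score_detections(
                accepted_times(fold.detections, threshold, fold.model.decision),
                fold.session.step_truth,
                fold.session.segments,
                count_all_steps=count_all_steps,
            )
            per_fold[fold.participant_id] = rep
            tp += rep.tp
            fp += rep.fp
            Tp += rep.Tp
            fp_stand += rep.fp_stand
            missed += rep.missed
            n_dist = rep.fp - rep.fp_stand
            for cls, pct in rep.fp_by_activity.items():
                dist_counts[cls] = dist_counts.get(cls, 0) + pct * n_dist / 100.0
        n_dist_total = sum(dist_counts.values())
        recall = tp / Tp if Tp else 0.0
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        return EvalReport(
            tp=tp,
            fp=fp,
            Tp=Tp,
            recall=recall,
            precision=precision,
            f_score=f_score(recall, precision),
            fp_by_activity={
                cls: (100.0 * c / n_dist_total if n_dist_total else 0.0)
                for cls, c in dist_counts.items()
            },
            fp_stand=fp_stand,
            missed=missed,
            per_participant=per_fold,
        )


def leave_one_out(
    cohort: Sequence[AccelSession],
    variant: str = "transition_matrix",
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    seed: int = 0,
    count_all_steps: bool = False,
    **train_kwargs,
) -> LosoResult:
    """Leave-one-subject-out evaluation over a cohort of sessions.

    For each participant the detector is trained on everyone else's slow-walk
    candidates and evaluated on the held-out participant's full session.  The
    averaged table is the mean of the fold metric columns; the pooled table
    recomputes metrics from summed counts (both conventions are emitted since
    either could be the one behind a published summary table).
    """
    from .step_detector import sweep_thresholds  # local import: avoids a cycle

    ids = [s.participant_id for s in cohort]
    if len(ids) != len(set(ids)):
        raise InputError("participant ids must be unique")
    if len(cohort) < 2:
        raise InputError("leave-one-out needs at least 2 participants")
    folds: list[FoldResult] = []
    for held_out in cohort:
        training = [s for s in cohort if s.participant_id != held_out.participant_id]
        assert all(s.participant_id != held_out.participant_id for s in training)
        model = train_detector(training, variant=variant, seed=seed, **train_kwargs)
        detections = detect(model, held_out)
        sweep = sweep_thresholds(
            model,
            [held_out],
            thresholds,
            detections_per_session=[detections],
            count_all_steps=count_all_steps,
        )
        logger.info(
            "fold %s: %d candidates, best F %.3f",
            held_out.participant_id, len(detections), sweep.f_score.max(),
        )
        folds.append(
            FoldResult(
                participant_id=held_out.participant_id,
                model=model,
                session=held_out,
                detections=detections,
                sweep=sweep,
            )
        )
    averaged = (
        pd.concat([f.sweep[["threshold", "recall", "precision", "f_score"]] for f in folds])
        .groupby("threshold", as_index=False)
        .mean()
    )
    pooled_counts = (
        pd.concat([f.sweep[["threshold", "tp", "fp", "Tp"]] for f in folds])
        .groupby("threshold", as_index=False)
        .sum()
    )
    pooled_counts["recall"] = pooled_counts.tp / pooled_counts.Tp
    denom = (pooled_counts.tp + pooled_counts.fp).replace(0, np.nan)
    pooled_counts["precision"] = (pooled_counts.tp / denom).fillna(0.0)
    pooled_counts["f_score"] = [
        f_score(r, p) for r, p in zip(pooled_counts.recall, pooled_counts.precision)
    ]
    return LosoResult(folds=folds, averaged=averaged, pooled=pooled_counts, variant=variant)


def format_sweep_table(df: pd.DataFrame) -> str:
    """Aligned-column text rendering of a sweep table (Sim Thr / R / P / F)."""
    lines = ["Sim Thr  Recall  Precision  F Score"]
    for _, row in df.iterrows():
        lines.append(
            f"{row.threshold:7.2f}  {row.recall:6.2f}  {row.precision:9.2f}  {row.f_score:7.2f}"
        )
    return "\n".join(lines)
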