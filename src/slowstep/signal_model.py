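"""Sensor-session data model and derivation of the two working channels.

A recording session consists of synchronized tri-axial accelerometer and
gravity-sensor streams sampled at a nominal 50 Hz, annotated with activity
segments and manually labeled ground-contact times.  The preprocessing chain
removes the gravity vector from the raw accelerometer output, projects the
residual motion acceleration onto the gravity direction (the signed vertical
channel ``ag``) and keeps the first device-frame component of what is left in
the horizontal plane (``aHx``).  The pair ``(ag, aHx)`` is the input to every
downstream stage.

The vertical projection makes the pipeline independent of how the device sits
in the pocket; ``aHx`` is used raw in the device frame, with no re-orientation.
Sign convention: ``ag`` is positive when the motion acceleration points along
the gravity vector (downward).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, InputError

#: Activity labels a session may carry.
ACTIVITY_LABELS = ("stand", "walk60", "walk30", "walk40", "slide30", "sit", "circles30")

#: Target-class activities: slow walking at 30 and 40 steps per minute.
SLOW_WALK_LABELS = ("walk30", "walk40")

#: Activities whose ground contacts are genuine steps (any cadence).
STEP_LABELS = ("walk30", "walk40", "walk60", "circles30")

#: Valid gravity-sensor magnitude range (m/s^2) for a calibrated session.
GRAVITY_MAG_RANGE = (9.0, 10.6)

_CSV_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "grav_x", "grav_y", "grav_z", "label"]


class Segment(NamedTuple):
    """Half-open activity interval ``[start, end)`` in seconds."""

    start: float
    end: float
    label: str


@dataclass
class AccelSession:
    """One participant's recording: raw sensor streams plus annotations.

    Timestamps are seconds from session start; sample ``i`` sits at
    ``i / sample_rate``.  ``step_truth`` holds the ground-contact times of all
    stepping activities (slow walk, moderate walk, circles); sliding contacts
    are kept apart in ``slide_contacts`` because they are not steps.
    """

    sample_rate: float
    t: np.ndarray
    acc: np.ndarray
    grav: np.ndarray
    segments: list[Segment]
    step_truth: np.ndarray
    participant_id: str
    slide_contacts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.grav = np.asarray(self.grav, dtype=float)
        self.segments = [Segment(*s) for s in self.segments]
        self.step_truth = np.sort(np.asarray(self.step_truth, dtype=float))
        self.slide_contacts = np.sort(np.asarray(self.slide_contacts, dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`InputError` on violation."""
        n = self.n_samples
        if not (len(self.acc) == len(self.grav) == n):
            raise InputError("t, acc and grav must have equal lengths")
        if self.acc.shape != (n, 3) or self.grav.shape != (n, 3):
            raise InputError("acc and grav must be (n, 3) arrays")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InputError("timestamps must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.sample_rate) > 1e-6):
            raise InputError("timestamps must be uniformly spaced at 1/sample_rate")
        mags = np.linalg.norm(self.grav, axis=1)
        lo, hi = GRAVITY_MAG_RANGE
        if np.any(mags < lo) or np.any(mags > hi):
            raise InputError(
                f"gravity magnitude outside [{lo}, {hi}] m/s^2: "
                f"range [{mags.min():.3f}, {mags.max():.3f}]"
            )
        for ts in self.step_truth:
            if not any(seg.start <= ts < seg.end for seg in self.segments):
                raise InputError(f"step truth time {ts:.3f}s lies in no segment")

    def segment_at(self, time: float) -> Segment | None:
        """Segment containing ``time``, or None."""
        for seg in self.segments:
            if seg.start <= time < seg.end:
                return seg
        return None

    def truth_in_labels(self, labels: Sequence[str]) -> np.ndarray:
        """Ground-contact times falling inside segments with the given labels."""
        keep = []
        for ts in self.step_truth:
            seg = self.segment_at(ts)
            if seg is not None and seg.label in labels:
                keep.append(ts)
        return np.asarray(keep, dtype=float)


@dataclass
class DerivedSignals:
    """The two working channels: signed vertical ``ag`` and horizontal ``ahx``."""

    ag: np.ndarray
    ahx: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.ag = np.asarray(self.ag, dtype=float)
        self.ahx = np.asarray(self.ahx, dtype=float)
        if len(self.ag) != len(self.ahx):
            raise InputError("ag and ahx must have equal lengths")

    @property
    def n_samples(self) -> int:
        return len(self.ag)


def _as_vectors(x, name: str) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InputError(f"{name} must be a 3-vector or an (n, 3) sequence")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr, single


def remove_gravity(acc, grav) -> np.ndarray:
    """Gravity-free motion acceleration: elementwise ``a = acc - grav``."""
    a, single_a = _as_vectors(acc, "acc")
    g, single_g = _as_vectors(grav, "grav")
    if len(a) != len(g):
        raise InputError(f"length mismatch: acc has {len(a)} samples, grav has {len(g)}")
    out = a - g
    return out[0] if (single_a and single_g) else out


def _check_gravity_norms(g: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(g, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("zero-magnitude gravity sample")
    return norms


def project_vertical(a, grav):
    """Signed vertical acceleration ``ag = (a . g) / ||g||`` per sample.

    Positive when the motion acceleration points along the gravity vector.
    Invariant to rescaling of the gravity vector.
    """
    av, single_a = _as_vectors(a, "a")
    g, single_g = _as_vectors(grav, "grav")
    if len(av) != len(g):
        raise InputError("length mismatch between a and grav")
    norms = _check_gravity_norms(g)
    ag = np.einsum("ij,ij->i", av, g) / norms
    return float(ag[0]) if (single_a and single_g) else ag


def horizontal_component(a, grav):
    """First device-frame component of the horizontal residual ``aH = a - ag_vec``."""
    av, single_a = _as_vectors(a, "a")
    g, single_g = _as_vectors(grav, "grav")
    if len(av) != len(g):
        raise InputError("length mismatch between a and grav")
    norms = _check_gravity_norms(g)
    ag = np.einsum("ij,ij->i", av, g) / norms
    ah = av - ag[:, None] * (g / norms[:, None])
    ahx = ah[:, 0]
    return float(ahx[0]) if (single_a and single_g) else ahx


def derive_signals(session: AccelSession) -> DerivedSignals:
    """Run the preprocessing chain on a session; length is preserved."""
    a = remove_gravity(session.acc, session.grav)
    ag = project_vertical(a, session.grav)
    ahx = horizontal_component(a, session.grav)
    return DerivedSignals(ag=ag, ahx=ahx, sample_rate=session.sample_rate)


# ---------------------------------------------------------------------------
# Session file I/O: CSV stream + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".steps.json")


def write_session(session: AccelSession, path) -> Path:
    """Write a session as CSV (one row per sample) plus a ``.steps.json`` sidecar."""
    path = Path(path)
    labels = np.empty(session.n_samples, dtype=object)
    labels[:] = ""
    for seg in session.segments:
        mask = (session.t >= seg.start - 1e-12) & (session.t < seg.end - 1e-12)
        labels[mask] = seg.label
    df = pd.DataFrame(
        {
            "t": session.t,
            "acc_x": session.acc[:, 0],
            "acc_y": session.acc[:, 1],
            "acc_z": session.acc[:, 2],
            "grav_x": session.grav[:, 0],
            "grav_y": session.grav[:, 1],
            "grav_z": session.grav[:, 2],
            "label": labels,
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")
    sidecar = {
        "participant_id": session.participant_id,
        "sample_rate": session.sample_rate,
        "step_truth": [round(float(x), 9) for x in session.step_truth],
        "slide_contacts": [round(float(x), 9) for x in session.slide_contacts],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path) -> AccelSession:
    """Read a session written by :func:`write_session`; lossless to 1e-9."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse session CSV {path}: {exc}") from exc
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"session CSV {path} is missing column '{col}'")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"session CSV {path} has non-monotone timestamps")
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar file {side}")
    meta = json.loads(side.read_text())
    for key in ("participant_id", "sample_rate", "step_truth"):
        if key not in meta:
            raise FormatError(f"sidecar {side} is missing key '{key}'")
    rate = float(meta["sample_rate"])
    labels = df["label"].astype(str).to_numpy()
    segments: list[Segment] = []
    start_i = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start_i]:
            segments.append(
                Segment(float(t[start_i]), float(t[i - 1] + 1.0 / rate), str(labels[start_i]))
            )
            start_i = i
    return AccelSession(
        sample_rate=rate,
        t=t,
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
        grav=df[["grav_x", "grav_y", "grav_z"]].to_numpy(dtype=float),
        segments=segments,
        step_truth=np.asarray(meta["step_truth"], dtype=float),
        participant_id=str(meta["participant_id"]),
        slide_contacts=np.asarray(meta.get("slide_contacts", []), dtype=float),
    )
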