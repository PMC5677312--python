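"""Generator of labeled virtual gait sessions for training and benchmarking.

Each virtual participant records the fixed activity protocol: 5 s of standing
interleaved with 60 s activity blocks — moderate walk (60 steps/min), the two
target-class slow walks (30 and 40 steps/min), sliding at 30 steps/min,
10 sit-down/stand-up repetitions, and walking in circles at 30 steps/min —
sampled at 50 Hz.

Ground contacts are modeled as exponentially damped sinusoid bursts injected
into the clean ``ag``/``aHx`` channels, which are then corrupted with white
noise and inverted through the preprocessing equations (``grav = (0,0,9.81)``,
``acc = grav + ag*ẑ + aHx*x̂``) so that the forward chain recovers them.  The
confusable structure of the protocol is built in: sliding keeps the full
horizontal burst but attenuates the vertical one; sitting moves the vertical
channel slowly with minimal horizontal activity; circling modulates the
horizontal burst amplitude with the heading angle.  Walking and circling
contacts are recorded as step truth (slow-walk ones being the target class);
sliding contacts are stored under a separate key because they are not steps.

The generator emulates burst timing, relative channel amplitudes and
additive sensor noise — not biomechanical gait dynamics or in-pocket device
rotation, which real recordings would add.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InputError
from .signal_model import AccelSession, Segment

GRAVITY = 9.81
DEFAULT_SAMPLE_RATE = 50.0


@dataclass
class GaitParams:
    """Amplitudes, rates and noise level of the virtual recordings.

    Defaults put the default pipeline in an informative regime: step bursts
    well above the noise floor, sliding close enough to slow walking to
    generate genuine confusions, and sitting clearly distinct.
    """

    step_amp_ag: float = 3.0        # vertical burst amplitude, m/s^2
    step_amp_ahx: float = 1.5       # horizontal burst amplitude, m/s^2
    burst_freq: float = 12.0        # damped-sinusoid frequency, Hz
    burst_decay: float = 0.05       # envelope time constant, s
    noise_std: float = 0.15         # white sensor noise, m/s^2
    slide_vertical_factor: float = 0.25  # vertical attenuation while sliding
    sit_excursion: float = 2.5      # sit/stand half-sine amplitude, m/s^2
    circle_heading_rate: float = 0.6  # rad/s while circling
    participant_scale: float = 1.0  # per-participant amplitude multiplier
    cadence_jitter: float = 0.03    # fractional step-interval jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.step_amp_ag, self.step_amp_ahx, self.sit_excursion) < 0:
            raise InputError("amplitudes must be non-negative")
        if self.noise_std <= 0:
            raise InputError("noise_std must be positive")


class ProtocolSegment(NamedTuple):
    label: str
    duration_s: float
    cadence_spm: float | None = None
    repetitions: int | None = None


def default_protocol() -> list[ProtocolSegment]:
    """The 13-segment recording protocol: 5 s standing between 60 s activities."""
    stand = ProtocolSegment("stand", 5.0)
    return [
        stand,
        ProtocolSegment("walk60", 60.0, cadence_spm=60),
        stand,
        ProtocolSegment("walk30", 60.0, cadence_spm=30),
        stand,
        ProtocolSegment("walk40", 60.0, cadence_spm=40),
        stand,
        ProtocolSegment("slide30", 60.0, cadence_spm=30),
        stand,
        ProtocolSegment("sit", 40.0, repetitions=10),
        stand,
        ProtocolSegment("circles30", 60.0, cadence_spm=30),
        stand,
    ]


def step_burst(t_rel, params: GaitParams, vertical: bool = True) -> np.ndarray:
    """Damped-sinusoid ground-contact burst, zero before onset.

    ``amp * exp(-t/decay) * sin(2*pi*freq*t)`` for ``t >= 0``; the peak falls
    within ~20 ms of onset and the envelope is negligible after five decay
    constants.
    """
    t = np.asarray(t_rel, dtype=float)
    amp = params.step_amp_ag if vertical else params.step_amp_ahx
    out = np.where(
        t >= 0,
        amp * np.exp(-np.maximum(t, 0.0) / params.burst_decay)
        * np.sin(2.0 * np.pi * params.burst_freq * t),
        0.0,
    )
    return out if out.shape else float(out)


def _step_onsets(
    duration: float, cadence_spm: float, rng: np.random.Generator, jitter: float
) -> list[float]:
    """Jittered step-onset times within one activity segment."""
    interval = 60.0 / cadence_spm
    onsets = []
    t = interval / 2.0
    while t < duration - 0.3:  # leave room for the burst tail
        onsets.append(t)
        t += interval * (1.0 + jitter * rng.standard_normal())
    return onsets


def _add_burst(
    channel: np.ndarray,
    onset_idx: int,
    amp_scale: float,
    params: GaitParams,
    rate: float,
) -> None:
    n_burst = int(round(6.0 * params.burst_decay * rate))
    stop = min(onset_idx + n_burst, len(channel))
    t_rel = np.arange(stop - onset_idx) / rate
    envelope = np.exp(-t_rel / params.burst_decay) * np.sin(
        2.0 * np.pi * params.burst_freq * t_rel
    )
    channel[onset_idx:stop] += amp_scale * envelope


def _half_sine(channel: np.ndarray, start_idx: int, amp: float, dur_s: float, rate: float) -> None:
    n = int(round(dur_s * rate))
    stop = min(start_idx + n, len(channel))
    t_rel = np.arange(stop - start_idx) / rate
    channel[start_idx:stop] += amp * np.sin(np.pi * t_rel / dur_s)


def synth_session(
    protocol: Sequence[ProtocolSegment] | None = None,
    params: GaitParams | None = None,
    participant_id: str = "P1",
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> AccelSession:
    """Build one labeled virtual session following the protocol.

    The clean channels are assembled segment by segment, white noise is added,
    and the raw sensor streams are reconstituted by inverting the gravity
    compensation with a fixed device frame (``ẑ`` along gravity, ``x̂``
    horizontal).  Deterministic for a given ``params.seed``.
    """
    protocol = list(protocol) if protocol is not None else default_protocol()
    params = params or GaitParams()
    rng = np.random.default_rng(params.seed)
    rate = sample_rate
    scale = params.participant_scale

    seg_samples = [int(round(p.duration_s * rate)) for p in protocol]
    n_total = sum(seg_samples)
    ag = np.zeros(n_total)
    ahx = np.zeros(n_total)
    segments: list[Segment] = []
    step_truth: list[float] = []
    slide_contacts: list[float] = []

    i0 = 0
    for block, n_seg in zip(protocol, seg_samples):
        seg_start = i0 / rate
        seg_end = (i0 + n_seg) / rate
        segments.append(Segment(seg_start, seg_end, block.label))
        if block.label in ("walk60", "walk30", "walk40", "slide30", "circles30"):
            onsets = _step_onsets(block.duration_s, block.cadence_spm, rng, params.cadence_jitter)
            for onset in onsets:
                onset_idx = i0 + int(round(onset * rate))
                t_abs = onset_idx / rate
                amp_var = 1.0 + 0.1 * rng.standard_normal()  # step-to-step variability
                amp_ag = params.step_amp_ag * scale * amp_var
                amp_ahx = params.step_amp_ahx * scale * amp_var
                if block.label == "slide30":
                    amp_ag *= params.slide_vertical_factor
                    slide_contacts.append(t_abs)
                else:
                    step_truth.append(t_abs)
                if block.label == "circles30":
                    heading = params.circle_heading_rate * (t_abs - seg_start)
                    amp_ahx *= np.cos(heading)
                _add_burst(ag, onset_idx, amp_ag, params, rate)
                _add_burst(ahx, onset_idx, amp_ahx, params, rate)
        elif block.label == "sit":
            reps = block.repetitions or 10
            rep_period = block.duration_s / reps
            for r in range(reps):
                t0 = i0 + int(round((r * rep_period + 0.2) * rate))
                amp = params.sit_excursion * scale
                # sit down: downward excursion; stand up: mirrored, 1 s each
                _half_sine(ag, t0, amp, 1.0, rate)
                _half_sine(ag, t0 + int(round(1.5 * rate)), -amp, 1.0, rate)
                _half_sine(ahx, t0, 0.05 * amp, 1.0, rate)
                _half_sine(ahx, t0 + int(round(1.5 * rate)), -0.05 * amp, 1.0, rate)
        # stand: noise only
        i0 += n_seg

    if params.noise_std > 0:
        ag = ag + rng.normal(0.0, params.noise_std, n_total)
        ahx = ahx + rng.normal(0.0, params.noise_std, n_total)

    grav = np.tile([0.0, 0.0, GRAVITY], (n_total, 1))
    acc = grav.copy()
    acc[:, 2] += ag   # vertical channel along the gravity unit vector
    acc[:, 0] += ahx  # horizontal channel along the device x axis
    return AccelSession(
        sample_rate=rate,
        t=np.arange(n_total) / rate,
        acc=acc,
        grav=grav,
        segments=segments,
        step_truth=np.asarray(step_truth),
        participant_id=participant_id,
        slide_contacts=np.asarray(slide_contacts),
    )


def synth_cohort(
    n_participants: int = 3,
    base_params: GaitParams | None = None,
    seed: int = 0,
    protocol: Sequence[ProtocolSegment] | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> list[AccelSession]:
    """Generate a cohort of virtual participants with varied amplitude scales.

    Per-participant amplitude scales are drawn uniformly from [0.7, 1.3]
    around the base parameters (emulating body-build and pocket-fit
    differences) with independent sub-seeds, all derived from ``seed``.
    """
    if n_participants < 2:
        raise InputError("a cohort needs at least 2 participants")
    base = base_params or GaitParams()
    ss = np.random.SeedSequence(seed)
    scale_rng = np.random.default_rng(ss.generate_state(1)[0] % (2**31))
    sub_seeds = ss.generate_state(n_participants + 1)[1:] % (2**31)
    cohort = []
    for i in range(n_participants):
        scale = float(scale_rng.uniform(0.7, 1.3))
        p = replace(
            base,
            participant_scale=base.participant_scale * scale,
            seed=int(sub_seeds[i]),
        )
        cohort.append(
            synth_session(protocol, p, participant_id=f"P{i + 1}", sample_rate=sample_rate)
        )
    return cohort
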