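# Methods

## Signal model

A session is a pair of synchronized 50 Hz streams — accelerometer output
**a**c and gravity vector **g** (both m/s², device frame) — with activity
segment labels and manually labeled ground-contact times. Gravity removal,
vertical projection and the horizontal residual follow

    a = a_c − g,    a_g = (a · g)/‖g‖,    a_H = a − a_g ĝ,

and only the first horizontal component a_Hx is kept, matching the working
channels of the detection algorithm. The decomposition is exact
(a_g ĝ + a_H = a to machine precision) and a_g is invariant to rescaling of
the gravity vector; the sign convention makes a_g positive along **g**
(downward). No re-orientation, filtering or resampling is applied — the
gravity projection is the only orientation compensation. Sessions at rates
other than 50 Hz are accepted: all window lengths are specified in seconds
and converted to samples, rounded to the nearest odd count so windows stay
centered.

Timestamps are seconds from session start (sample *i* at *i*/rate). Session
files are plain CSV (`t,acc_x,acc_y,acc_z,grav_x,grav_y,grav_z,label`) with
a JSON sidecar holding participant id, sample rate and ground-contact times;
write→read round-trips are lossless to 1e-9. Validation requires strictly
uniform timestamps (±1e-6 s) and gravity magnitudes within 9.0–10.6 m/s².

## Outlier pre-detection

For each interior sample t_c the statistic

    md(t_c) = (x − μ)ᵀ Σ⁻¹ (x − μ),   x = (a_g(t_c), a_Hx(t_c)),

is computed with μ, Σ the sample mean and (n−1)-covariance of the window of
duration T_out = 60/c_max s centered at t_c (1.5 s → 75 samples at 50 Hz).
Samples with md > 3 are flagged. The threshold is interpreted on the
*squared* Mahalanobis scale — the convention of the common statistics
toolbox function of that name — with the plain distance available as a
configuration switch.

Numerical choices:

- Near-singular windows (condition number > 1e12, e.g. standing still) get a
  ridge of 1e-9 · tr(Σ)/2 on the diagonal; an exactly constant window yields
  statistic 0 when the center equals the mean.
- One ground contact raises several consecutive samples, so contiguous
  flagged runs collapse to the run's strongest sample (earliest on ties) and
  a refractory period of T_out/2 = 0.75 s suppresses the weaker of any pair
  closer than that (earlier index on ties). At the 40 spm cadence ceiling
  steps are ≥ 1.5 s apart, so the refractory period cannot merge two
  distinct steps.
- Candidate-to-truth matching is greedy nearest-neighbor, one-to-one, within
  ±0.2 s — shorter than half the feature window plus labeling jitter — with
  deterministic tie-breaks (earlier truth, then earlier candidate).

Note that for white noise the squared statistic of a 2-D sample against its
own window is approximately chi-square with 2 degrees of freedom, so the
threshold of 3 flags roughly a fifth of idle samples; the refractory period
thins these to about one candidate per 0.75 s of idle signal, and rejecting
them is the job of the similarity stage, not the pre-detector.

## Transition-matrix features

The 2N+1 = 13 samples (240 ms at 50 Hz) around a candidate are discretized
per channel against that window's own mean m and standard deviation σ
(sample, n−1; a population-σ switch exists). States follow the band
inequalities with closed upper bounds: S1 for deviation ≤ −1.5σ, S2 for
(−1.5σ, −σ], …, S4 for (−0.5σ, 0], …, S8 for > 1.5σ; an exact-zero deviation
lands in S4, and a zero-variance window maps every sample to S4. The 8×8
transition matrix counts the 12 consecutive-state pairs; each row with any
outgoing transitions is divided by its row total, and rows with none stay
all-zero — with only 12 transitions over 64 cells most rows are empty, and
zeros preserve sparsity while keeping autoencoder inputs in [0, 1] (making
rows uniform instead would inject mass the window never exhibited). The
matrix is flattened row-major to a 64-vector.

Because each channel is normalized by its own window moments, the feature is
invariant under positive affine transforms of the signal — the property that
compensates participant weight, build and sensor gain. Candidates whose
window crosses a session boundary are dropped rather than padded (padding
would fabricate transitions).

## Autoencoder and decision rule

Each channel has a single-hidden-layer sigmoid autoencoder with 5 hidden
units, x′ = σ(W′ σ(Wx + b) + b′), trained to minimize the mean squared
reconstruction error over the training candidates (optional L2 weight decay,
default 0). Training is full-batch steepest descent with a backtracking line
search (halve the step until the loss does not increase, then let it grow by
1.25×), at most 5000 epochs, stopping when the per-epoch improvement falls
below 1e-9. This optimizer is deliberately simple: it is deterministic given
the seed, its loss trace is non-increasing by construction, and at the
64-input/5-hidden scale it reaches the capacity-limited loss floor — longer
training was verified to change the reconstruction loss only marginally
without moving the detector's operating point. Weights initialize from a
symmetric uniform range scaled by 1/√fan-in with a seeded generator; biases
start at zero.

Transition features already live in [0, 1] and pass through an identity
scaler. For the raw-acceleration variant (13-sample windows per channel) a
per-dimension min-max scaler is fit on the training windows and applied with
clamping to [0, 1]; constant dimensions map to 0.5. A consequence worth
knowing: training windows are peak-aligned by the pre-detector, so the
center dimensions of the scaler sit far from idle-noise values, and scaled
noise windows acquire a stereotyped clipped pattern that correlates with
almost any reconstruction — the main reason the raw variant's precision
collapses at permissive thresholds while the transition variant's does not.

A candidate is accepted when the Pearson correlation between autoencoder
input and output exceeds the similarity threshold on **both** channels (a
mean-of-similarities rule is available as an ablation switch; Pearson is
defined as 0 for constant vectors). One threshold is shared by both
channels. All candidates are retained with their similarities so threshold
sweeps replay the decision rule without re-scanning.

Training a detector isolates candidates matched (±0.2 s) to labeled ground
contacts inside the 30/40 spm walking segments; fewer than 10 matches is an
error. Channel seeds derive from the user seed via a seed sequence, so the
whole artifact is reproducible bit-exactly from configuration plus seed.

## Evaluation

Tp counts ground contacts inside walk30/walk40 segments only; accepted
detections are matched one-to-one within ±0.2 s; matched = tp, everything
else = fp, attributed to the segment containing it. A detection matching a
60 spm step is therefore a false positive by default — the detector is
scored as a slow-walk discriminator — while a `count_all_steps` flag treats
any stepping-activity contact as positive for the generic step-counting use
case. The false-positive distribution is reported as percentages over the
four confusable activity classes (sit, circles, slide, walk60); false
positives inside standing segments are counted in fp and reported apart
rather than folded into that distribution. Accounting is exhaustive:
tp + missed = Tp and accepted = tp + fp, asserted per session.

The leave-one-subject-out harness trains on all participants but one and
evaluates on the held-out participant's full session, for every participant.
Sweep tables are emitted three ways — per fold, fold-averaged, and pooled
(metrics recomputed from summed counts) — because a published summary could
follow either convention; the operating point is the pooled row with the
highest F (largest threshold on ties).

A worked-example caveat the test suite pins down: recomputing F from
precision/recall values already rounded to two decimals does not always
reproduce a table's printed F — three of twelve published-style rows differ
by exactly 0.01, an input-rounding artifact rather than a computational
disagreement.

## Synthetic gait generator

The generator emulates the recording protocol used to exercise the
detector: 5 s standing blocks interleaved with 60 s activity blocks —
walking at 60, 30 and 40 spm, sliding at 30 spm, 10 sit-down/stand-up
repetitions (40 s), and walking in circles at 30 spm — for each virtual
participant.

Ground contacts are damped sinusoid bursts, amp · e^(−t/τ) · sin(2πft) with
f = 12 Hz and τ = 50 ms, so the burst peaks ~17 ms after onset and dies
within a quarter second. Defaults: vertical amplitude 3.0 m/s², horizontal
1.5 m/s², white noise σ = 0.15 m/s² per channel, 3% cadence jitter and 10%
per-step amplitude variability — step bursts stand ~14σ above the noise
floor, comfortably detectable yet leaving the sweep tables unsaturated. The
confusion structure is built in: sliding keeps the full horizontal burst but
scales the vertical one by 0.25 (the foot never leaves the ground, yet the
pocket still picks up some vertical activity); sitting is a 2.5 m/s²,
1 s half-sine excursion pair on the vertical channel with 5% of that
horizontally; circling multiplies the horizontal amplitude by cos(heading)
at 0.6 rad/s. Channels are then inverted through the preprocessing
equations (grav = (0,0,9.81), acc = grav + a_g ẑ + a_Hx x̂) so the forward
chain recovers them exactly up to noise. Walking and circling contacts enter
the ground truth (slow-walk ones as the target class); sliding contacts are
stored separately since they are not steps. Cohorts draw per-participant
amplitude scales uniformly from [0.7, 1.3] with independent sub-seeds.

What the generator does **not** emulate: biomechanical gait dynamics
(double-support timing, heel-to-toe rollout), in-pocket device rotation,
correlated or non-stationary sensor noise, and gravity-estimate drift.
Passing the synthetic benchmark therefore demonstrates that the pipeline's
stages compose correctly and that its discrimination structure behaves as
designed (slide confuses the horizontal channel, sit does not confuse the
operating point's vertical patterns, moderate-pace steps are the dominant
confusion) — it does not certify accuracy on human recordings. One known
consequence of the white-noise idealization: idle stretches produce chance
outlier candidates whose features occasionally survive moderate similarity
thresholds in both channels at once, so small false-positive counts can
appear even in activity segments, such as sitting, whose genuine movements
the detector rejects reliably.

## Problem sizes

The default benchmark — the package's own choice of scale — is 3 virtual
participants × 375 s sessions (18,750 samples each), giving 210 target-class
ground contacts and roughly 350 outlier candidates per session;
leave-one-subject-out training sets contain ~140 matched slow-walk
candidates per fold. Both detector variants train and evaluate in well under
a minute on one CPU at this scale.
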