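# slowstep

Step detection at very low walking cadences (30–40 steps per minute) from a
single body-worn tri-axial accelerometer with a companion gravity sensor.

Commodity pedometers and accelerometer step counters underestimate steps
badly at slow cadences — precisely the regime that matters when monitoring
physical activity in people with mobility-limiting conditions. `slowstep`
implements a detector specialized for that regime, together with a synthetic
gait-session generator and a leave-one-subject-out evaluation harness, so the
whole pipeline can be trained, run and benchmarked without any real
recordings.

## Method

The raw streams are the accelerometer output **a**c and the gravity vector
**g**, sampled at 50 Hz. Preprocessing removes gravity and splits the motion
acceleration into two channels:

    a   = a_c − g
    a_g = (a · g) / ‖g‖          (signed vertical acceleration)
    a_H = a − a_g ĝ ;  a_Hx = first horizontal component

The detector chains three stages over the pair (a_g, a_Hx):

1. **Outlier pre-detection.** For every sample, the squared Mahalanobis
   statistic of the 2-D point at the center of a 1.5 s sliding window
   (one step period at the 40 spm cadence ceiling) is computed against the
   window's sample mean and covariance. Samples with statistic > 3 are
   flagged; runs are collapsed and a 0.75 s refractory period leaves one
   time-aligned candidate per ground contact.
2. **Transition-matrix features.** The 240 ms (13 samples, N = 6 per side)
   around each candidate is discretized into 8 states by deviation from the
   window mean in multiples of the window standard deviation (band edges 0,
   ±0.5σ, ±σ, ±1.5σ). The 8×8 row-normalized matrix of consecutive-state
   transition counts, flattened row-major to a 64-vector, is the candidate's
   feature — invariant to amplitude and offset, hence to participant build
   and sensor gain. A baseline variant feeds the min-max-scaled raw
   13-sample windows instead.
3. **Autoencoder similarity.** One single-hidden-layer sigmoid autoencoder
   (5 hidden units), x′ = f₂(W′ f₁(Wx + b) + b′), is trained per channel on
   candidates aligned to labeled slow-walk ground contacts. A candidate is
   accepted as a slow-walk step when the Pearson correlation between input
   and reconstruction exceeds a similarity threshold on *both* channels.

Evaluation targets the slow-walk class: recall = tp/Tp, precision =
tp/(tp+fp), F = 2PR/(P+R), with false positives attributed to the activity
segment containing them, swept over similarity thresholds 0.4–0.9.

## Worked example

Train and evaluate the transition-matrix detector on the default virtual
cohort (three participants, leave-one-subject-out):

```python
from slowstep import synth_cohort, leave_one_out
from slowstep.evaluation import format_sweep_table

cohort = synth_cohort(3, seed=42)
result = leave_one_out(cohort, variant="transition_matrix", seed=42)
print(format_sweep_table(result.pooled))
best = result.best_row()
report = result.score_at(float(best.threshold))
print(f"best F = {best.f_score:.3f} at similarity threshold {best.threshold:.1f}")
```

prints

```
Sim Thr  Recall  Precision  F Score
   0.40    0.92       0.37     0.52
   0.50    0.86       0.42     0.57
   0.60    0.71       0.44     0.55
   0.70    0.54       0.45     0.49
   0.80    0.33       0.50     0.40
   0.90    0.10       0.50     0.17
best F = 0.566 at similarity threshold 0.5
```

Reading the table: at threshold 0.5 the detector recovers 86% of the 210
slow-walk ground contacts in the held-out sessions while 58% of its accepted
detections are confusions — mostly moderate-pace (60 spm) steps, which are
genuine steps outside the 30–40 spm target class, followed by circling steps
and sliding contacts. Raising the threshold trades recall for precision
monotonically.

The same pipeline is available from the shell:

```sh
slowstep simulate --out cohort/ --seed 42
slowstep loso --session cohort/session_P1.csv --session cohort/session_P2.csv \
              --session cohort/session_P3.csv --out results/
slowstep train --session cohort/session_P1.csv --session cohort/session_P2.csv \
               --out model.json
slowstep detect --model model.json --session cohort/session_P3.csv --out det.csv
slowstep evaluate --model model.json --session cohort/session_P3.csv
```

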