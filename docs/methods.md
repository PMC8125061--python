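# Methods

## Signal model and scope

The package operates on R-R interval (RRI) streams in milliseconds — the
tachogram — never on raw ECG. It targets the three ectopic mechanisms that
dominate in people without cardiovascular disease:

* **PVC**: the interval before the ectopic beat shortens by some height
  `H` and the next interval lengthens by the same amount (compensatory
  pause). Total elapsed time is conserved.
* **PAC**: one interval shortens by `H` with no compensation; the beat
  clock genuinely shifts by `H`.
* **RDE** (R-wave detection error): a missed R peak merges two adjacent
  intervals into one roughly doubled interval.

Isolated events only: successive extrasystoles and successive detection
errors are out of scope, which matches their rarity in healthy adults and
keeps every repair local to a 4-beat window.

## Detection (AED)

A window of four consecutive RRIs is centered by its own mean and passed
through a 4–3–4 autoencoder (sigmoid hidden, identity output). The anomaly
score is the Euclidean reconstruction error `RE = ‖x − x̂‖`.

*Why per-window centering.* Subtracting the window's own mean makes the
score invariant to between-subject baseline heart-rate differences, so one
trained model generalises across subjects. The cost is that centered
windows always sum to zero (an effectively 3-dimensional input), so a
3-unit linear bottleneck could in principle reconstruct anything; the
sigmoid nonlinearity is what bounds reconstruction amplitude and makes
large ectopic excursions irreproducible, hence detectable. A fixed input
scale of 100 ms (stored on the model) keeps physiological windows inside
the responsive range of the sigmoid; without it, millisecond-scale inputs
saturate the hidden layer at initialisation and training stalls.

*Thresholds.* `RE̅` is the maximum RE over held-out normal windows, so the
detector produces zero positives on its own calibration data by
construction ("normal" is `RE ≤ RE̅`; a strict inequality would flag the
maximising calibration window itself). The typing limits `r̅1, r̅2` are
empirical 0.5%/99.5% percentiles of held-out normal RRIs — percentiles
rather than Gaussian `μ ± zσ` limits because RRI distributions are skewed.

*Typing tree.* For an anomalous beat `t` (one-beat latency; `r_{t+1}` is
needed):

```
r_t > r̅2:  RDE   if r_{t-1} ≥ r̅1        (one lone doubled interval)
           PVC   if r_{t-1} < r̅1        (short-then-long: late-anchored PVC)
r_t < r̅1:  PVC   if r_{t+1} > r̅2
           PAC   if r̅1 ≤ r_{t+1} ≤ r̅2
           OTHER if r_{t+1} < r̅1        (successive short intervals)
otherwise: OTHER
```

The `r_{t-1}` refinement exists because a small-`H` PVC sometimes first
trips the RE ceiling on the window ending at its *lengthened* interval; a
doubled-interval test alone would then mislabel it RDE. In simulation this
single predicate moves type accuracy from ~83% to ~100% without affecting
RDE detection, and the event is re-anchored at `t−1` so the repair window
still holds the ectopic interval in its second slot.

*Event de-duplication.* One event perturbs intervals `t` and `t+1`, which
appear in windows ending up to `t+4`; after an ectopic label the next 4
beats are suppressed, so one physiological event yields exactly one label.

## Repair (DAEM)

Detected PVC/PAC beats are repaired on `x = [r_{t-1}, r_t, r_{t+1},
r_{t+2}]` (ectopic interval second): center by the window mean, map through
the type-specific 4–2–4 ReLU denoising autoencoder, restore the mean, then
spread the residual time gap `d = Σx̂ − Σx` evenly (`x̃ = x̂ − d/4`). The
final step enforces exact conservation of the window's elapsed time, which
keeps the repaired stream synchronised with real time — essential for
streaming consumers — and is asserted on every modification record.

Training pairs are built by injecting synthetic events into clean data
(clean targets, contaminated inputs), both sides centered by the
*contaminated* window's mean so training matches inference exactly. A
consequence of time conservation: a PAC can never be repaired perfectly,
because restoring the clean window would require recovering the `H` ms the
premature beat removed from the timeline; the compensation step spreads
that deficit as `H/4` per interval. This is why PAC repair ratios are
intrinsically worse than PVC's, on surrogate data as in practice.

RDE and "other arrhythmia" beats are reported but not auto-repaired in the
streaming pipeline (splicing a split interval changes the beat count
mid-stream). An opt-in `repair_rde` splits the merged interval using the
dedicated 4–8–4 model's predictions for its two halves, rescaled to sum
exactly to the merged interval.

## Training

Full-batch Adam, 2000 epochs, learning rate 1e-2, Glorot-uniform
initialisation, L2 weight penalty λ = 1e-4 (weights only, not biases), all
seeded; training fails loudly if the held-out cost does not improve. The
learning rate was set by convergence on the tiny 4-unit-scale networks: at
1e-3 the cost is still an order of magnitude from its plateau after 2000
epochs. Analytic gradients are verified against central differences at
1e-5 relative tolerance in the test suite. Hidden sizes are fixed per
role: detection 3 (sigmoid), PVC/PAC repair 2 (ReLU), RDE repair 8
(sigmoid).

## Surrogate data

`simulate_normal_rri` emulates an adult sinus tachogram:

```
rri_j = mean + lf·sin(2π·0.10·t_j) + hf·sin(2π·0.25·t_j) + ε_j
```

with `t_j` the cumulative beat time in seconds, defaults mean = 800 ms,
lf = 30 ms (baroreflex band), hf = 20 ms (respiratory sinus arrhythmia),
white noise ε ~ N(0, 20² ms²), floored at 300 ms. Contamination injects
events at 1/1200 beats (the healthy-adult extrasystole rate) with heights
U(100, 370) ms — the physiological range that keeps the simulated QT
interval healthy — and a minimum 4-beat separation. The ground-truth log
is exact: replaying it on the clean series reproduces the contaminated
series bit-for-bit, which the tests use as an oracle.

What the surrogate does *not* capture: 1/f baseline wander, sleep-stage
nonstationarity, respiratory amplitude modulation, and the nonlinear
dynamics of real HRV. Beat-to-beat detail is white, which matters for the
baseline comparison below. Passing tests on this surrogate demonstrate the
mechanics of detection and repair under controlled truth, not clinical
performance.

## Evaluation conventions

* Detection matches are greedy one-to-one within ±1 beat (PVC alters two
  adjacent intervals, so anchoring can differ by one beat legitimately).
* Sensitivity = matched/true events; FP rate = unmatched detections per
  recorded hour; classification accuracy is computed among matched
  detections.
* `C_RMSE = 100 · RMSE(clean, modified) / RMSE(clean, contaminated)`,
  evaluated over the 4-beat event windows; below 100% means repair helped.
* The repeated experiment re-simulates, re-trains and re-scores per
  repetition with derived seeds; reported values are means over
  repetitions. Default problem sizes — 3 repetitions, 3 000 training
  beats, 20 000 validation and test beats — give stable headline numbers
  while keeping a full study run around half a minute on one CPU.
* Normal-data safety is assessed by running the full detect-and-repair
  pipeline on clean records and averaging |modified − original| over all
  beats; false positives are rare, so the mean alternation is far below
  the 5 ms error budget that clinical HRV analysis tolerates. Forcing the
  repair network onto clean windows instead alters them by ~14 ms on this
  surrogate — the rank-2 bottleneck cannot reproduce 20 ms white
  beat-to-beat detail — which is why safety is defined at the pipeline
  level where repair is gated by detection.

## Baselines

* **SSA**: the principal 3-dimensional subspace of the column-centered
  Hankel embedding of normal data (SVD), scored by residual distance,
  thresholded with the same max-on-validation protocol as the autoencoder.
  Column centering uses the training means, so — unlike the per-window
  centered autoencoder — SSA inherits sensitivity to baseline differences
  between calibration and test subjects; the detector comparison therefore
  draws each test subject's mean RRI from U(760, 840) ms to emulate
  inter-subject variation, and SSA shows the higher false-positive rate.
* **PLS / LWPLS**: regression of clean windows on contaminated windows;
  LWPLS fits a Gaussian-weighted local PLS per query (bandwidth defaulting
  to the median pairwise window distance) and discards it after use. Both
  get their component count (and LWPLS its bandwidth multiplier) selected
  on tuning data, mirroring the per-method tuning of the original
  comparison protocol.

**Known limitation.** On this surrogate the tuned linear regressors
slightly *beat* the denoising autoencoder at window repair (median C_RMSE
≈ 6% vs ≈ 10%): with white Gaussian beat-to-beat detail, window content is
full-rank and a rank-4 linear map is near-optimal, while the repair
network is capped at 2 hidden units. The autoencoder's documented
advantage arises on real RRI data, whose detail is autocorrelated and
nonlinear so that low-rank linear maps lose more; the surrogate
deliberately does not model that structure. Both numbers are computed and
reported by the acceptance script rather than adjudicated away.

## Numerical choices and degenerate inputs

* RRIs are float64 ms; series validate positivity and beat-time
  consistency at construction, and CSV round-trips are exact.
* Window length is frozen at 4 everywhere (detector input, repair window,
  Hankel embedding); the `d/4` compensation constant is literal.
* HRV: 3-minute sliding windows on cumulative time; population SD for
  SDNN; 4 Hz cubic-spline resampling and a Welch periodogram with LF
  0.04–0.15 Hz, HF 0.15–0.40 Hz; all conventions live in one config block.
* Constant windows center to zero and score RE = 0; constant predictor
  columns are rejected by PLS; LWPLS falls back to the stored weighted
  mean when the local problem degenerates, and to global PLS when all
  weights underflow.
* Model files are schema-versioned JSON; loading a truncated or
  wrong-version file raises.
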