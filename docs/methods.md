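# Methods

## Problem and pipeline

`myowrist` implements a torque **intensity-and-direction** decoder for the
wrist: from four channels of surface EMG (ECR, ED, PL, FCU) it predicts
which of a discrete set of isometric effort classes the user is producing —
rest, or one of four directions (flexion, extension, ulnar and radial
deviation) at a torque level expressed as a fraction of that direction's
maximum voluntary contraction (MVC). Two class maps are supported: the full
*nineteen*-class map (levels every 10 % MVC, up to 50 % for
flexion/extension and 40 % for the deviations) and its *thirteen*-class
reduction (every 20 %), which trades torque granularity for accuracy.

The stages, in execution order:

1. **Synthesis** (`synthetic_data`) — stepped isometric protocol runs with
   a matching sEMG surrogate (below), or real recordings via `core_io`.
2. **Features** (`features`) — 256-sample (250 ms) windows stepped by 128
   samples (125 ms); per channel: rms, Burg AR(4) coefficients, waveform
   length → 24 features per window.
3. **Labeling** (`labeling`) — MVC calibration from max-effort trials;
   torque fractions map to the nearest configured level (boundaries midway
   between levels, midpoint ties to the lower level); chronological
   30-per-class test holdout.
4. **Classification** (`classification`) — per-feature scaling of the
   training range to [−1, 1]; one-vs-one RBF-SVM; (C, γ) by stratified
   8-fold cross-validated grid search, ties toward smaller C then smaller γ.
5. **Streaming control** (`realtime_control`) — a causal sliding-window
   loop emitting one decision per 125 ms of new samples; decisions map to
   signed torque setpoints driving a PID-controlled first-order actuator
   plant standing in for a wrist exoskeleton.

## The sEMG surrogate

Each channel is amplitude-modulated band-limited Gaussian noise: white
noise filtered to 20–500 Hz (linear-phase FIR, 257 taps, rescaled by the
exact white-noise gain so the sample standard deviation is unbiased),
multiplied by an envelope

    std(t) [mV] = baseline_noise + gain × activation(t),

with `baseline_noise = 0.01 mV` (electrode/thermal floor) and
`gain = 1 mV` at full activation. Every feature the classifier consumes is
an amplitude or spectral-shape statistic, so this minimal surrogate carries
exactly the structure the pipeline assumes — and nothing else. It does
**not** model motor-unit action potentials, electrode crosstalk, fatigue,
or inter-subject variability; passing tests therefore demonstrate the
pipeline's correctness and its behavior on data with the assumed
statistical structure, not clinical performance on human subjects.

**Activation map.** Per-muscle activation is linear in effort:
`activation = weight × level / top_level`, clipped to [0, 1], with weights
from the muscles' anatomical roles — primary mover 1.0, main synergist
0.6, remaining muscles 0.1:

| direction | ECR | ED | PL | FCU |
|-----------|-----|----|----|-----|
| flexion   | 0.1 | 0.1| 1.0| 0.6 |
| extension | 0.6 | 1.0| 0.1| 0.1 |
| ulnar     | 0.1 | 0.1| 0.6| 1.0 |
| radial    | 1.0 | 0.6| 0.1| 0.1 |

**Effort tracking drift.** A subject cannot hold a commanded torque
exactly. The effective level is the commanded staircase plus slow zero-mean
Gaussian drift (std 0.02 × MVC, correlation time 2 s, Gaussian-smoothed
white noise), shared between the torque trace and the EMG envelopes so
muscle activity and torque waver together. This drift is what makes windows
near the 5 %-MVC-wide decision boundaries of the nineteen-class map
genuinely ambiguous and reproduces the characteristic adjacent-level
confusion pattern; the thirteen-class map's boundaries are twice as far
apart, which is why its accuracy is higher at matched settings. The torque
sensor additionally adds white noise (1 % of MVC).

**Protocols.** Ascending and descending staircases (10 s holds joined by
1 s linear ramps, steps of 10 % MVC) alternated three times per direction
give six plateau instances per (direction, level); the central 6 s of each
plateau becomes one excerpt, yielding the canonical bookkeeping: 47 windows
per excerpt, 6 × 47 = 282 windows per class, 5358 rows for nineteen
classes, and 4788 × 24 / 3276 × 24 training matrices after the 30-per-class
holdout. Rest excerpts are taken from the flexion rig's rest plateaus.
Default MVC torques are plausible wrist values: flexion 10, extension 7,
ulnar 6, radial 5 N·m.

## Numerical and design choices

* **AR estimator: Burg** (via `statsmodels`), reported in the predictor
  sign convention (`y(t) = Σ aᵢ y(t−i) + ε`). Burg is stable on 256-sample
  windows where Yule–Walker is noticeably biased. Constant (silent)
  windows have no AR representation: the batch and streaming paths
  substitute zeros for the four AR features and log a warning, keeping
  pipelines alive on dead channels; rms and waveform length remain exact.
* **No pre-filtering** of the EMG beyond what the acquisition provides;
  features are computed on raw samples.
* **Scaling to [−1, 1]** per feature, fitted on training data only;
  zero-range features map to 0; out-of-range test values are not clipped.
* **Grid**: C ∈ {1, 10, 20, …, 100}, γ ∈ {0.1, 0.3, …, 1.5}, 8-fold
  stratified CV. The lattice spans two decades of regularization and the
  useful RBF-width range for [−1, 1]-scaled features with the plausible
  optimum region (C ≈ 45–90, γ ≈ 0.7–1.0) strictly interior; a finer
  lattice multiplies search cost without moving the selected model on this
  family of feature distributions. CV ties resolve to the smallest C, then
  the smallest γ (least complex model); fold assignment is shuffled under
  the run seed, so a fixed seed fixes the chosen pair exactly.
* **One-vs-one** multiclass voting (libsvm's native strategy); voting ties
  resolve toward the lowest class id.
* **Class boundaries** sit midway between adjacent configured levels; exact
  midpoints (distances compared after rounding to 9 decimals, so float
  noise cannot flip a tie) go to the lower level — the conservative choice
  for an assistive device. Rest is simply level 0 in every direction's
  ladder, equivalent to a 5 %-MVC rest band in the nineteen-class map.
* **Steadiness screen** in `label_excerpts`: excerpts whose torque standard
  deviation exceeds 5 % of MVC straddle a ramp and are excluded (a steady
  hold under default noise sits near 3 %).
* **Plant**: first-order lag (τ = 0.4 s) with output saturation
  (±12 N·m default) under PI control (kp = 1, ki = 2, kd = 0), advanced at
  the 125 ms decision period with a frozen-integrator anti-windup. The
  continuous-time closed-loop poles are ≈ −1.4 and −3.6 s⁻¹: zero
  steady-state error and settling well inside a plateau. The real device's
  current-sensing feedback is abstracted to direct force feedback.
* **No debouncing** of the decision stream by default; an optional
  majority-of-3 filter exists but is off, so reported streaming behavior is
  the classifier's raw output.
* **Timing is simulated, not wall-clock**: the 125 ms cadence and the
  ≤ 250 ms decision age are structural properties of the sample-indexed
  loop, asserted in simulated time.

## Problem sizes in tests

Unit tests run a miniature study (2–3 iterations per class, 4–5 s holds,
3–4 s excerpts) so the whole non-acceptance suite completes in well under a
minute; the acceptance tests and `scripts/acceptance.py` run the full-size
study (6 iterations, 10 s holds, 6 s excerpts) for both class maps. The
19-versus-13-class accuracy comparison uses a matched reduced grid
(C ∈ {1, 10, 50, 100}, γ ∈ {0.1, 0.5, 1.0}) for both arms — the comparison
needs matched, not exhaustive, settings.

## Known limitations

* The surrogate's class structure lives almost entirely in the amplitude
  features; the AR features are informative only about the (fixed) band
  shape and act as nuisance dimensions, which is harsher than real EMG,
  where spectral shape also shifts with force.
* At 10 % MVC the flexion and ulnar activation patterns overlap under
  noise, so rare low-level direction confusions occur; real co-contraction
  patterns are richer and may separate better or worse.
* Labels derive from the commanded plateau (the measured mean torque of a
  steady hold rounds to the same level), mirroring training-by-protocol;
  subjects who track poorly would blur class boundaries further.
* The plant is a one-pole caricature of an exoskeleton: no backlash, cable
  friction, or torque-dependent dynamics.
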