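# Methods

This note documents the models inside `graspsense`, the choices behind
their defaults, and what the synthetic evaluation does and does not show.

## 1. Drivetrain plant

The multi-joint under-actuated hand is reduced to a **single output-shaft
coordinate** `ϑ` (deg, 0 = fully open, mechanical range 0–110 deg). This is
deliberate: the stiffness classifier only ever sees shaft-level signals
(current, reference angle, encoder angle), so finger-level kinematics add
nothing observable.

### Control structure

A cascade mirrors typical embedded hand controllers:

* outer loop (position, PD): `ε_pos = ϑ_ref − ϑ_out`, output scaled by a
  proportional factor into a current reference
  `i_ref = g·(kp_pos·ε_pos + kd_pos·ε̇_pos)`, clipped at the driver's
  current limit;
* inner loop (current, PI): `ε_i = i_ref − i_out`,
  `V = kp_cur·ε_i + ki_cur·∫ε_i dt`, clipped at the supply voltage, with
  **conditional-integration anti-windup** (the integrator freezes while the
  voltage saturates);
* electrical dynamics: first-order lag of `i_out` toward `V/R` with time
  constant 5 ms — this is intentionally simpler than a full inductance
  model but preserves the one feature that matters downstream, the
  current **rise-time asymmetry** between soft and rigid contacts;
* mechanics: `J·ϑ̈ = kt·i_out − b·ϑ̇ − τ_contact(ϑ, ϑ̇)`.

Integration is fixed-step **semi-implicit Euler at 1 kHz** (current first,
then velocity, then position), matching a typical embedded control rate. A
per-step guard raises `SimulationDiverged` if the state leaves the finite
range; position is clamped to the mechanical range with velocity zeroing at
the stops.

### Objects

A grasped object is a **unilateral rotational spring-damper** engaged past
its contact angle (40 deg in the shipped catalog):
`τ_contact = k·max(0, ϑ − ϑ_c) + c·max(0, ϑ̇)` for `k > 0`, and identically
zero for void "objects". Damping acts only while closing into the object so
the contact can never pull the fingers inward.

### Steady-state check

For a held reference past contact, the equilibrium is algebraic: with
servo stiffness `s = kt·g·kp_pos` (N·m/deg),

```
ϑ_ss = (s·ϑ_ref + k·ϑ_c) / (s + k),      i_ss = g·kp_pos·(ϑ_ref − ϑ_ss).
```

`steady_state_grasp` implements this closed form; the test suite requires
the time-domain integrator to land within 2 % of it across a five-point
stiffness grid, and the same grid establishes that steady current is
monotone in spring rate — the physical basis of the whole method.

### Reference generators

* **sinusoidal** — `A·(1 − cos 2πft)/2` (default `A` = 90 deg,
  `f` = 0.25 Hz): a smooth close-and-reopen bench cycle.
* **emg_like** — proportional-speed control from a muscle-like excitation:
  rectified, 3 Hz low-pass-filtered Gaussian noise modulates a nominal
  closing speed of 30 deg/s·`drive_level`; after the amplitude plateau the
  reference keeps **creeping at 2 deg/s** (EMG residuals never fully
  vanish). That creep is what keeps `ϑ_ref` growing after contact while
  `ϑ_out` plateaus — the separability mechanism between void and object
  closures.

### Default parameters

All plant numbers (`configs/hannes_like.yaml`) are synthetic. The working
points they produce at a 90-deg command: void closures peak below ~85 mA
(gate at 300 mA), soft objects settle at roughly 420–520 mA, rigid objects
at 780–820 mA, with transients overlapping across classes. Spring rates
follow a parallel-spring catalog (unit springs S1 = 2.0e-4, S2 = 2.0e-3,
S3 = 3.0e-3, S4 = 1.25e-4 N·m/deg; combinations sum), so "4xS2" etc. are
physically coherent. The current limit (2 A) and voltage limit (12 V) are
never reached in the shipped scenarios but are enforced everywhere.

## 2. Dataset construction

The acquisition protocol (`configs/table2.yaml`) performs 80 closures over
13 rows: 10 void (sinusoidal), 10+10 rigid dynamometer (sinusoidal + EMG),
and 5 closures per spring combination per reference kind. Per-closure
seeds are spawned deterministically from one master seed, and the commanded
amplitude is jittered (sd 3 deg) to emulate trial-to-trial command
variability. Traces are decimated from the 1 kHz control rate to 100 Hz
feature rows — a typical logging rate that keeps the dataset at 32 000
rows.

**Labeling (300 mA rule).** Labels are per sample: any sample with current
below 300 mA is void (0) — including the pre-contact phase of object
closures, which is physically indistinguishable from a void closure — and
samples at or above the gate take the object's class (1 rigid, 2 soft).
The boundary value 300 mA itself goes to the object class ("below 300 mA"
defines void). A `per_closure` mode that labels whole closures by their
object is available behind a flag, since labeling granularity is a genuine
protocol ambiguity.

**Splitting.** 80 % train / 20 % validation assigned at the **closure**
level (never sample level, to avoid temporal leakage), stratified by
stiffness class with at least one validation closure per class. Feature
z-scoring (mean/sd) is fitted on training rows only and travels with the
model.

## 3. One-vs-All non-linear logistic regression

Three binary models, one per class, each computing
`P(1|x) = g(wᵀφ(z) + b)` where `z` is the z-scored raw triple
(current, `ϑ_ref`, `ϑ_out`) and `φ` the polynomial expansion without
constant term. The printed model is linear in its features; the
*non-linearity* is realized by the expansion. **Degree 2 is the default**
(9 terms: 3 linear + 3 squares + 3 cross products) because the soft/rigid
boundary in (current, position) space is curved; degree 1 recovers plain
logistic regression and remains available.

**Training.** Full-batch gradient descent on the cross-entropy
`J = −(1/m)Σ[y ln p + (1−y) ln(1−p)]` (optional L2, default off), zero
initialization, learning rate 0.1 on normalized features, at most 5 000
iterations, stopping when the relative decrease of `J` falls below 1e-8.
The `J` trajectory is recorded and must be non-increasing under the default
configuration; growth beyond 10× the initial cost raises a
learning-rate error. Probabilities are clamped to [1e-12, 1−1e-12] inside
the log only.

**Thresholds.** Each binary gets its own decision threshold `TH`, chosen
on the validation split by exhaustive grid search over
{0.05, 0.06, …, 0.95} maximizing that class's binary F1; ties break toward
the value nearest 0.5. A shared-threshold mode (mean of the three) exists
behind a flag since per-class vs shared tuning is an open design point.

**Multi-class decision.** For a sample, classes with `p_k ≥ TH_k` are
candidates and the largest margin `p_k − TH_k` wins; with no candidate the
largest probability wins; exact ties go to the lower class index. For a
whole closure, the decision is a **majority vote over the final 0.5 s** of
the trace (the steady-grasp regime the protocol emphasizes), with vote
ties resolved toward the class consistent with higher grasp current
(rigid > soft > void).

Models serialize to JSON (weights, biases, thresholds, normalization,
training metadata) and round-trip exactly.

## 4. Feedback encoding and calibration

The vibromotor runs at a 200 Hz carrier; amplitude is a PWM duty. The four
conditions: NoFB and AFB never activate the motor; 1FB encodes any object
at the 30 % intensity and void as silence; 2FB encodes rigid at 100 %,
soft at 30 %, void as silence. Intensity fractions map onto the user's
calibrated band as `duty = pwm_min + f·(pwm_max − pwm_min)` — the
percentages are fractions *of the calibrated range*, since the band is
what the calibration exists for; an `absolute` mode (`duty = 100·f`) is
provided for strictness comparisons.

The band comes from an ascending **method-of-limits** staircase: duty
rises from 0 in 4–5 % steps; the first duty reported perceptible becomes
`pwm_min`, the first reported strong becomes `pwm_max`. A subject never
reporting "strong" saturates the band at 100 % (flagged with a warning); a
collapsed band raises an error. Deterministic and seeded-stochastic
(logistic psychometric) simulated subjects are included.

## 5. Closed-loop evaluation

A session presents 3 rigid and 3 soft objects three times each plus 3 void
closures — 21 trials in seeded random order. Each trial simulates a
closure (EMG-like reference), classifies it, encodes the feedback, and
queries a **simulated responder**:

* NoFB — uniform guess over the three classes;
* AFB — motor sound reveals void vs object with accuracy 0.9; rigid/soft
  is a coin flip;
* 1FB — vibration presence reveals the classifier's void decision exactly;
  rigid vs soft is guessed from the physical vibration-onset latency cue
  with accuracy 0.6 (soft contacts raise current later, so the vibration
  starts later);
* 2FB — the duty level is decoded, confusing rigid and soft with
  probability 0.05.

Response times are lognormal per condition (medians 3.5 / 3.7 / 4.3 /
2.8 s, σ = 0.3 in log space). Every responder number is an invented
default chosen to exercise the qualitative ordering
2FB > 1FB > AFB > NoFB — not to reproduce any human measurement.

Scoring uses 3×3 confusion matrices and F1 in percent. **Macro averaging
is the default** (robust to the 9/9/3 session imbalance); micro (equal to
accuracy for single-label data) and per-class values are computed
alongside, and classes absent from both truth and prediction are excluded
from the macro mean. Chance level is 100/3 ≈ 33.3 %.

For Monte-Carlo studies over hundreds of sessions, `run_study` first
builds a **pre-classified closure pool** (12 independent seeded closures
per object, each run once through the per-closure classifier) and sessions
draw from it; simulating every trial of every session individually repeats
identical physics at ~100× the cost for no statistical benefit at these
pool sizes. `run_closed_loop_session` without a pool still simulates each
trial, and is the reference path.

## 6. Problem sizes and numerical choices

Defaults throughout: 4 s closures at 1 kHz control rate; 80-closure
training acquisitions (32 000 rows at 100 Hz); 200 sessions per condition
(500 for the chance-level check) in closed-loop studies. Threshold grid
step 0.01; gradient-descent tolerance 1e-8; steady-state oracle tolerance
2 % on settled cases (very soft springs, below ~2e-4 N·m/deg, need longer
than 4 s to settle and are excluded from oracle grids).

## 7. Limitations

* The plant is a one-DOF abstraction with linear friction and massless
  unilateral springs; no tendon mechanics, per-finger contact
  distribution, thermal effects, or backlash. Passing tests show the
  *method* works when the physics matches the assumed regime structure —
  not that a physical hand meets it.
* The 300 mA gate is exact in simulation; on hardware, sensor noise blurs
  the label boundary and per-sample scores would drop accordingly.
* The responder is a caricature of human psychophysics: cue accuracies are
  fixed, with no learning, fatigue, or attention effects; closed-loop
  scores therefore validate the harness and the encoding logic, not human
  performance magnitudes.
* Training data and test data come from the same generative family;
  distribution shift (object size/shape variety, different users) is out
  of scope.
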