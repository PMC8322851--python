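# Methods

This note documents the models and procedures implemented in
`myoface`, the defaults chosen where the design was open, and what the
synthetic data can and cannot show.

## Signal model of the synthetic generator

Surface EMG during a sustained contraction is well approximated by an
interference pattern: zero-mean Gaussian noise whose power lives in a
band, amplitude-modulated by muscle activation. The generator uses
exactly that surrogate:

* **Carrier** — white Gaussian noise band-passed to 20–450 Hz
  (4th-order Butterworth) and rescaled so that a unit gain corresponds
  to unit burst RMS.
* **Envelope** — a raised-cosine on/off ramp of 100 ms around each
  3 s action (50 ms ramps for online streams); the per-channel
  amplitude is the movement's cross-talk gain.
* **Background** — a common-mode mains sinusoid (50 Hz, amplitude
  0.01) with random phase, plus white baseline noise (sd 0.02), in the
  same arbitrary mV-scale units as the bursts.

The cross-talk gain matrix is the generator's central fidelity claim.
Only its qualitative structure is constrained by the observed
recordings — main-channel assignment (forehead→LEb, left/right eye
corner→LEBO/REBO, masseter→Bk, left/right mouth corner→TML/TMR),
amplitude ordering Bk > LEb > TML ≈ TMR > LEBO ≈ REBO, the clench
bleeding into every channel, the eyebrow lift into none, and the
specific minor couplings (REBO→ch1, TML→ch2+ch4, TMR→ch3, Bk weakly
into ch5/ch6). The magnitudes (main gains 1.0 / 0.6 / 0.4 / 0.15;
cross-talk 10–30 % of the source's main gain) are package defaults
chosen once to realise that ordering; they are fully exposed in
`CrosstalkProfile` and in the YAML run config.

The mains amplitude default (0.01, i.e. half the baseline noise sd)
keeps the REST-segment RMS within a few percent of the baseline noise
level, so the quiescent signal is noise-dominated as in a decently
shielded recording; the notch stage removes what remains.

**Protocol timing.** A round presents the six movements once each in a
seeded random order: 5 s rest, prompt, 0.5 s reaction latency, 3 s
action. The 0.5 s latency is a modelling choice (the prompt cannot
coincide with the onset, or the analysis epoch 1.5–2.65 s after the
prompt would clip the burst tail); the epoch then sits in the
burst plateau and the pre-prompt 350 ms sits in rest, which is what
makes the printed window arithmetic meaningful.

**What the generator does not model** — and hence what passing tests
do *not* show about real recordings: motor-unit structure,
within-class amplitude variability and trends (fatigue), electrode
lift/impedance drift, movement artefacts, inter-subject variability,
and imperfect user compliance. The default profile is *cleanly
separable by construction*; near-perfect cross-validation accuracy on
it verifies the pipeline's plumbing, not the difficulty of the
classification problem. Published accuracies on real subjects
(mid-90s %) live on private recordings and are not reproduced here.

## Preprocessing

An IIR mains notch (Q = 30; the quality factor is unreported upstream,
30 is a conventional biosignal choice) followed by a 10–450 Hz
Butterworth band-pass of design order 2, both realised as second-order
sections. Filtering is **causal by default**: the online stage has no
future samples, and offline training must see the same signal the
decoder will see; a zero-phase forward-backward mode exists for
offline exploration only. `StreamingPreprocessor` carries the SOS
state between chunks, so chunked output equals whole-signal output to
machine precision — this equality is asserted in the tests.

## Windowing

200 ms windows, 50 ms step, half-open `[start, start + 200 ms)`. Per
prompt: the active span 1,500–2,650 ms after the prompt gives
`floor((1150−200)/50)+1 = 20` windows labelled with the prompted
movement, and the 350 ms before the prompt gives 4 REST windows. The
REST windows are taken before *every* prompt (24 per 6-prompt round);
that convention is forced by the total count arithmetic
(20 rounds × (120 + 24) = 2,880). Prompts whose spans leave the
recording are skipped with a warning rather than truncated.

## Features

Definitions are in the README. Numerical decisions:

* **VAR** defaults to the textbook sample variance (full sum,
  denominator N−1). The upstream description truncates the sum at
  N−1 terms; that truncated form is not a named statistic and is
  judged a typographical slip, but `var_as_printed=True` reproduces
  it exactly.
* **ZC** uses the strict product test `−x_i·x_{i+1} > 0`: exact zeros
  never count, and no amplitude threshold is applied.
* **ARC** is fitted by Yule-Walker on the biased (divide-by-N)
  autocovariance of the demeaned window — deterministic and always
  stable — via `statsmodels`; a least-squares covariance method is
  selectable (`ar_method="lstsq"`). The three coefficients are the
  features; the innovation variance is not. Constant windows have no
  AR structure and return zeros.
* Design-matrix columns are channel-major, feature-minor
  (`ch1_var, ch1_rms, ch1_mac, ch2_var, …`), so each channel's block
  is contiguous; the order is frozen in the feature-table header.

## Model evaluation

All twelve classifiers run with library defaults, a shared integer
seed, and a standardising scaler in front (no hyperparameters are
reported upstream; the scaler is required for the scale-sensitive
members — MLP, SVM, logistic regression — to train on raw feature
magnitudes). Cross-validation is **stratified** 5-fold with seeded
shuffling: exact per-class 80/20 splits (320/80 per movement, 384/96
REST on the full acquisition) are only achievable under
stratification, which is how the printed per-class counts pin the
design down. Classes smaller than k are rejected.

The single-feature ranking averages each feature's CV accuracy over
the registry models and sorts ascending, breaking ties by the declared
feature order. The reduction curve removes features one at a time in a
given order (the reported order lists "WAV", which is read as MAV —
no WAV feature exists in the feature set), recording the retained
set, the CV accuracy of a gradient-boosting model and the wall-clock
cost of computing the retained features; under the reported order the
three survivors are {VAR, RMS, MAC}, the elected (EF) set.

Paired t-tests compare assembly modes per model. Degenerate inputs
take limiting values: all-zero differences give p = 1 (the samples are
indistinguishable), a non-zero constant shift gives p = 0 (the t
statistic diverges).

The permutation test on task times exchanges group labels and counts
arrangements whose absolute mean difference reaches the observed one.
When `C(n_a+n_b, n_a) ≤ 10⁶` it enumerates exactly (so small-group
p-values are rational numbers like 2/252); otherwise it draws 10,000
seeded permutations and applies the add-one correction
`(b+1)/(m+1)`, bounding the p-value in `[1/(m+1), 1]`.

## The two-stage decoder

Stage 0 requires `debounce_windows` (default 5 ≈ 250 ms at the 50 ms
step) consecutive identical non-REST predictions before accepting a
selector; the upstream description asks only for "about 1 s" of
recognisable action, so the threshold is configurable. The selector
maps REBO→X, LEBO→Y, TMR→Z, TML→gripper and starts a 5 s deadline.
LEb then selects the positive direction, Bk the negative (+X is the
user's left, −Y is forward); axis motion is hold-to-move and stops
after `rest_stop_windows` of REST (default = the debounce length) —
shorter REST gaps inside a held action are bridged, because a single
misclassified window would otherwise stutter the arm. A held direction
action refreshes its own deadline ("the last non-resting action is
itself"), so long moves never expire mid-run.

The gripper is momentary and self-latching. Direction convention:
LEb→Close, Bk→Open, following the operational broadcast table; the
surrounding prose states the opposite convention, and
`swap_gripper_direction=True` flips it. Gripper commands are honoured
only when the end effector is over the desktop rectangle below the
10 cm safety height; otherwise a refusal event is logged and the
decoder returns to stage 0. Exhaustive enumeration over
(stage, pending axis, label) shows exactly 8 commands and 12 broadcast
strings are reachable.

## Arm and task simulation

The end effector is a point moving at 3 cm/s along one axis per
command inside the cuboid workspace X [20,120], Y [−70,100],
Z [5,120] cm. The +Y desktop edge may be overhung by up to 30 cm
(mouth zone) — but only through a "mouth window" (x ∈ [55,85],
z ∈ [60,100] cm, both configurable; only the 30 cm overhang itself is
fixed upstream). X/Z moves that would strand the arm in the overhang
outside that window are blocked rather than clamped, so the simulated
effector never jumps. Scenarios draw the cup uniformly on the
30 × 15 cm saucer centred at (90, 45, 0) (inset by the 3.75 cm cup
radius) and the gripper start at (x_i, −45, z_i) with x_i, z_i uniform
in the workspace ranges.

Grasping uses a 5 cm capture radius (≈ cup radius + soft-gripper
clearance, which is not quantified upstream) at or below the 13 cm cup
height; "drinking" is holding the cup in the mouth zone for ≥ 1 s.
Task time runs from the first gripper motion to the cup's release back
on the saucer. The scripted (virtual-button) policy moves one axis at
a time, so its duration is the Manhattan path length over 3 cm/s plus
the ~1.3 s of dwell and gripper pulses — within 5 % for any scenario.

## Closed loop

The closed-loop driver ties the pieces together at the decoder's 50 ms
tick: a scripted intent policy (standing in for the user, with the
same visual and audio feedback — it watches the simulated arm and
hears the broadcasts) chooses a facial movement; the streaming
generator synthesises 50 ms of signal with filter state carried across
ticks; the streaming preprocessor filters it; the newest 200 ms window
is classified from the elected features; the decoder turns predictions
into commands; the arm integrates them. The policy stops a held
direction movement one `lead_cm` (default 1 cm) before the target to
compensate the decoder's stop latency (window flush plus REST
hysteresis, ≈ 0.4 s ≈ 1.2 cm at 3 cm/s); the remaining overshoot is
well inside the grasp radius and zone tolerances. Everything is
seeded, so a closed-loop run replays bit-identically.

## Problem sizes and defaults

The test suite and the acceptance script run the acquisition at its
natural scale — 20 rounds, 2,880 windows, ~52 s of 6-channel signal at
1,000 Hz per round — and cross-validate the gradient-boosting model on
the 18-column elected-feature matrix; broader sweeps (all 12 models ×
all modes, full reduction curves on the full acquisition) are
exercised in the unit tests on smaller window subsets, since they are
O(models × features × folds) classifier fits and add nothing beyond
plumbing coverage at full scale. One closed-loop drinking task
(~200 simulated seconds, ~4,000 ticks) runs per suite.

## Known limitations

* Synthetic separability overstates real-world accuracy (see above).
* The intent policy is an idealised user: no reaction-time jitter, no
  wrong movements, perfect plan knowledge. Decoder robustness to a
  *noisy* user is only probed indirectly through misclassified
  transition windows.
* The arm model has no dynamics, no joint limits and no collision
  geometry; the cup cannot tip or spill.
* EDF export writes a minimal EDF+C file (16-bit, 1 s records, one
  annotation channel); it is validated against MNE's reader but not
  against the full zoo of EDF consumers.
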