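# myoface

A facial-EMG (fEMG) face-computer interface pipeline: from raw
six-channel facial-muscle signals to the commands that drive a robotic
arm through a drinking task — with a built-in synthetic signal
generator so the whole loop runs, and is tested, without any hardware.

People who have lost limb function (high paraplegia, upper-limb
amputation) cannot use buttons, joysticks or touch screens. Facial
muscles usually remain under fine voluntary control, and surface
electrodes over the forehead, eye corners, masseter and mouth corners
pick up distinct activity for distinct movements. This package
implements an interface built on six such movements — lift eyebrows
(LEb), slow left/right single eye blinks (LEBO/REBO), a chewing-like
clench ("bick", Bk), and tilting the mouth left/right (TML/TMR) — plus
REST, and maps them onto eight Cartesian arm commands
(±X, ±Y, ±Z, open/close gripper).

## What is inside

| module | role |
| --- | --- |
| `myoface.synth` | seeded synthetic fEMG: amplitude-modulated band-limited (20–450 Hz) noise with a movement-by-channel cross-talk gain matrix, 50 Hz mains and baseline noise; prompted-round protocol and online streams |
| `myoface.preprocess` | IIR mains notch + 10–450 Hz second-order Butterworth band-pass, identical for batch and streamed chunks |
| `myoface.segmentation` | 200 ms windows at a 50 ms step: 20 active windows from 1.5–2.65 s after each prompt, 4 REST windows from the 350 ms before it |
| `myoface.features` | the eight time-domain window features MAV, RMS, MC, MAC, MAX, ZC, VAR and order-3 AR coefficients (ARC); SF/AF/EF design matrices |
| `myoface.model_eval` | 12-classifier registry (LR, NB, DT, linear SVM, MLP, Ridge, RF, QDA, AdaBoost, GBC, LDA, LightGBM), stratified 5-fold CV, single-feature ranking, sequential feature-removal curve, paired t-tests, exact/Monte-Carlo permutation test |
| `myoface.decoder` | two-stage finite-state intent decoder: a debounced selector movement picks an axis (REBO→X, LEBO→Y, TMR→Z, TML→gripper), then LEb/Bk pick the direction; hold-to-move axes, self-latching gripper with a z < 10 cm over-desktop safety guard, audio-broadcast text events |
| `myoface.armsim` | 3 cm/s point model of the end effector in a [20,120]×[−70,100]×[5,120] cm workspace with a 30 cm mouth overhang; randomized cup/saucer drinking-task scenarios |
| `myoface.pipeline` | offline training and the closed loop: scripted intent → streamed synthesis → filters → elected features → classifier → decoder → arm |
| `myoface.io` / `myoface.cli` | CSV/EDF recording I/O, YAML run config, model persistence, and the `myoface` command line |

For a 200 ms window `x_1..x_N` the features are

    MAV = (1/N) Σ|x_i|            RMS = sqrt((1/N) Σ x_i²)
    MC  = (1/N) Σ (x_{i+1}−x_i)   MAC = (1/N) Σ |x_{i+1}−x_i|
    MAX = max x_i                 ZC  = #{i : −x_i·x_{i+1} > 0}
    VAR = sample variance         ARC = (a_1,a_2,a_3) of x_i = Σ_k a_k x_{i−k} + e_i

computed per channel, and assembled as SF (one feature type, 6
columns), AF (all features, 60 columns) or EF (the elected triple
{VAR, RMS, MAC}, 18 columns).

## Worked example

```python
import myoface as mf

profile = mf.default_crosstalk_profile()
recs = mf.generate_dataset(profile, mf.ProtocolConfig(n_rounds=20, seed=0))
windows = [w for i, r in enumerate(recs)
           for w in mf.segment_recording(mf.preprocess(r), round_index=i)]
print(f"{len(windows)} labelled windows")

ef = mf.assemble(windows, "EF")
scores = mf.run_cv(ef, {"GBC": mf.make_registry(0)["GBC"]}, k=5, seed=0)["GBC"]
print(f"GBC + elected features, 5-fold CV: {scores.mean:.3f} +/- {scores.std:.3f}")

clf = mf.train_classifier(ef, "GBC", seed=0)
scenario = mf.make_scenario(3)
result = mf.run_closed_loop(clf, profile, scenario, seed=11)
print(f"drinking task completed: {result.task.completed}, "
      f"time {result.task.elapsed_s / 60:.2f} min, "
      f"online window accuracy {result.prediction_accuracy:.3f}")
```

prints

```
2880 labelled windows
GBC + elected features, 5-fold CV: 1.000 +/- 0.000
drinking task completed: True, time 2.88 min, online window accuracy 0.979
```

A 20-round prompted acquisition yields 6 movements × 20 windows + 24
REST windows per round = 2,880 design-matrix rows. The gradient
boosting classifier on the elected features separates the default
synthetic profile essentially perfectly (real recordings are harder —
see `docs/methods.md`), and the trained model then drives the
simulated arm through the full reach–drink–return task in under three
minutes, classifying 97.9 % of the streamed windows as the movement
the scripted user intended.

The same steps are available from the shell:

```
myoface simulate --rounds 20 --seed 1 --out data/
myoface features --data data/ --mode EF --out ef.csv
myoface train --features ef.csv --model GBC --out model.joblib
myoface drink --policy fci --model model.joblib --seed 3 --log task.json
```

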