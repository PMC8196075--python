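# strugglescope

Analysis pipeline for restraint-stress struggle behavior and fiber
photometry. During restraint, rodents make brief escape attempts ("struggle
bouts"). `strugglescope` scores those bouts automatically from tracked
body-point trajectories, converts two-channel fluorescence-sensor
recordings into standardized activity traces and detected transients,
aligns signal to behavior, and quantifies how the size of the neural
response scales with the vigor of the behavior. It is aimed at behavioral
neuroscientists who record pose-estimation output (DeepLabCut-style tables)
together with fiber photometry.

## What it computes

**Behavior.** Per-frame speed of each tracked point (head fiber, tail tip)
is thresholded adaptively: a frame is *mobile* when its speed exceeds
`mean(S) + k·sd(S)`, where `S` is the bottom `q`-quantile of that point's
session speeds (head: q = 0.95, k = 1; tail: q = 0.99, k = 3). A bout opens
at an immobile→mobile transition and closes after > 0.7 s of all-point
immobility; bouts are typed head-only / tail-only / full-body.

**Photometry.** With an isosbestic reference channel, the reference is fit
to the signal by OLS and

ΔF/F(t) = (F₄₇₀(t) − fitted F₄₀₅(t)) / fitted F₄₀₅(t).

Residual drift is removed with airPLS (adaptive iteratively reweighted
penalized least squares; λ = 5·10⁴), the corrected trace is standardized to
a session Z score, and transients are maximal runs with Z ≥ 2.91, each with
max peak (Z) and area (Z·s); frequency is transients per second.

**Alignment.** Traces are time-locked to bout onsets; each row is Z-scored
against its own −5…−3 s baseline, so retained rows have baseline mean 0 and
sd 1 by construction. Per-bout AUC and max peak are computed over 0–5 s
after onset (independent of bout length), with an optional −3–0 s pre
window and a +10 s lock-offset control.

**Statistics.** Pearson r (with t-based p and the OLS slope ± 95% CI) of
AUC against bout duration; Welch and paired t tests; an exact two-sided
binomial test of the proportion of bouts with positive AUC; the
Benjamini–Krieger–Yekutieli two-stage step-up FDR procedure; and
day-1-normalized transient frequencies for multi-day designs.

A synthetic-data module (`strugglescope.synthetic`) generates pose and
photometry sessions from a known generative model — Poisson bouts with
gamma durations, double-exponential transients whose amplitude is β ×
duration, bleaching, shared motion artifact, multi-day habituation and
drug-day designs — so every stage can be validated against ground truth.

## Worked example

```python
import numpy as np
from strugglescope.synthetic import simulate_session, BehaviorSimParams, PhotometrySimParams
from strugglescope.pipeline import analyze_session, RunConfig

sess = simulate_session(BehaviorSimParams(session_s=600, seed=1),
                        PhotometrySimParams(session_s=600, seed=1))
report = analyze_session(sess.pose, sess.recording, RunConfig(bout_type="any"))
print(report.stats["n_bouts_total"], "bouts,",
      report.stats["n_transients"], "transients,",
      f"{report.stats['transient_frequency_hz']:.3f} Hz")
c = report.stats["auc_duration"]
print(f"r = {c['r']:.2f}, p = {c['p']:.1e}, slope = {c['slope']:.2f} Z*s per s")
```

prints

```
9 bouts, 74 transients, 0.123 Hz
r = 0.83, p = 5.5e-03, slope = 6.87 Z*s per s
```

i.e. in this 10-minute simulated session the pipeline found 9 struggle
bouts and 74 supra-threshold runs (large transients fragment into several
threshold crossings as their decay rides the 2.91 line), and the
post-onset AUC grows by ≈ 7 Z·s for every extra second of struggling —
recovering the behavior–signal coupling the generator built in.

The same chain is available from the shell:

```bash
strugglescope simulate --out sim/ --seed 1
strugglescope run-session --pose sim/subject01_day1_pose.csv \
    --photometry sim/subject01_day1_photometry.csv --out out/
strugglescope run-session ... --offset-s 10 --out out_control/   # offset control
```

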