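# Methods

This note documents the models, parameters and numerical choices behind
`strugglescope`, and what the synthetic-data validation does and does not
establish about real recordings.

## Behavioral scoring

Speeds are per-frame Euclidean displacements in pixels/frame (frame 0 is
defined to have speed 0); the frame rate is carried as metadata and no
pixel-to-millimeter calibration is applied. The mobility threshold for a
point is `mean(S) + k·sd(S)` over the subset `S` of session speeds at or
below the linear-interpolation `q`-quantile, with the n−1 sd denominator;
a frame is mobile when its speed is *strictly* greater than the threshold.
"One sd above the bottom 95%" is read as mean-plus-sd *of the
bottom-quantile subset* (rather than quantile-plus-sd); both quantities
are exposed through `compute_mobility_threshold` if a user wants the other
convention. Because the threshold is a functional of the session's own
speed distribution, it is equivariant under rescaling of the camera
geometry, which is the point of a normalized rather than raw pixel
threshold.

Bout segmentation merges mobile episodes separated by all-immobile runs of
at most the gap parameter (0.7 s; at 10 fps a bout terminates only after
≥ 8 consecutive all-immobile frames, the strict reading of "> 0.7 s").
Duration includes the onset frame (`offset − onset + 1/fps`); the offset is
the last mobile frame, not the end of the closing immobile run. Bouts cut
off by the session end are kept but flagged `truncated`. A bout is
`full_body` when head and tail each have at least one mobile frame anywhere
inside it — the movements need not be simultaneous.

## Photometry

Processing order for dual-channel (isosbestic) recordings: OLS fit of the
reference to the signal over the whole session → ΔF/F = (signal −
fitted reference)/fitted reference → airPLS drift removal on ΔF/F →
session-level Z standardization → threshold transient detection.
Single-channel sensors skip the regression and use the airPLS baseline of
the raw signal as F₀. The printed forms of the ΔF/F and peri-event
equations in some acquisition-system documentation contain spurious
divisions; the implemented forms are the standard subtractive ones.

airPLS follows the published algorithm: a weighted Whittaker smoother
`(W + λDᵀD) z = W y` (solved as a symmetric banded system, O(n) per
iteration), with weights zeroed where `y ≥ z`, set to `exp(i·|r|/s)` where
`y < z` (`s` = summed magnitude of negative residuals), and both endpoints
anchored at the largest such weight. Iteration stops when
`s < 0.001·Σ|y|` or after 50 iterations. Defaults: λ = 5·10⁴, first-order
differences. The reweighting exponent is clipped at 50 to avoid overflow
as `s → 0`. Two numerical caveats are worth knowing. First, the smoother
has a boundary layer of about √λ samples, so on short traces with strong
drift the endpoints are tracked less tightly than the interior; at session
scale (≥ 10⁴ samples) drift-only signals are recovered to well under 1%.
Second, on zero-mean noisy traces the stopping rule rarely fires and the
baseline settles below the noise band (only negative residuals keep
weight); this offsets the corrected trace by a constant that the
subsequent standardization removes.

Transients are maximal runs of samples with Z ≥ 2.91 (a configurable
outlier criterion, not a hard-coded constant), reported with max peak and
trapezoidal area; no minimum duration is imposed by default, so a large
transient whose decay crosses the threshold repeatedly yields several
runs. Frequency is count/duration. The session-level Z denominator
includes the transients themselves, so dense high-amplitude activity
raises the effective detection threshold in noise units — the recovery
tests quantify both sides of this (≥ 90% detection, ≤ 10% spurious under
5-Z injections on a unit noise floor).

## Peri-event analysis

Rows are extracted on the recording's own sample grid by nearest-sample
mapping (no interpolation), over −5…+10 s around onset, and standardized
against the −5…−3 s baseline with the n−1 sd. Rows whose window leaves the
recording, or whose baseline sd is zero, are flagged with a reason and
excluded from metrics but never silently dropped. AUC is the signed
trapezoidal integral (exact for piecewise-linear rows and additive over
adjacent windows); max peak is signed, so purely negative deflections
(GABA-sensor-like) yield negative peaks. Bouts whose windows overlap a
neighboring bout's activity are retained. The +10 s offset control shifts
every onset before extraction. One consequence of the window layout: with
a 1.5 s decay kernel, the shifted baseline (5–7 s after the true onset)
still holds a small duration-coupled residual of the bout's own transient,
so offset AUCs carry a slight negative bias and a weak negative
correlation with duration (about −0.1 on average in the validation runs)
rather than exactly zero. The destruction of the locked coupling (> 90%
loss of mean AUC, correlation collapse) is unaffected.

## Statistics

Pearson r uses the t transform for its two-sided p; the slope CI is the
t-based 95% interval from OLS of AUC on duration. Welch's t uses the
Satterthwaite df. The positive-AUC test is the exact minimum-likelihood
two-sided binomial against 0.5. The two-stage step-up FDR procedure runs
Benjamini–Hochberg at q′ = q/(1+q), estimates the null count m0 from the
non-rejections, and reruns BH at q′·m/m0; it is verified against an
independent step-by-step oracle and against statsmodels' implementation,
and its two-stage rejections provably contain the BH rejections at level
q′. Mixed-effects and multi-group ANOVA procedures are deliberately not
reimplemented; the pipeline exports tidy long-format tables for standard
tools.

## Synthetic data: what it emulates, and what it does not

Bout onsets are homogeneous Poisson (1/min over a 30-min session),
durations gamma (shape 4, scale 0.5 s; mean 2 s), types categorical
(head/tail/full-body = 0.5/0.2/0.3); events that collide within 0.8 s are
merged and counted. Immobile tracking noise is quantized hold (p = 0.3)
plus near-constant-length sway (1 px/frame, CV 4%): a bottom-quantile
mean+k·sd threshold sits near the 84th percentile of any single-scale
symmetric jitter distribution, so a regime with quantized stillness and
metronome-like micromotion is the one in which a percentile+sd rule can
separate idle from struggle at all — on real data that regularity comes
from respiration-locked micromotion and sub-pixel tracker quantization,
and sessions where idle jitter is broadband Gaussian would need different
(q, k).

Struggling points take isotropic Gaussian steps (sd 5 px/frame). The
photometry channels are `bleach·(1+C)·(1+a) + noise` (signal) and
`bleach·(1+a) + noise` (reference): per-channel single-exponential
bleaching with different time constants (600 vs 800 s) but similar decay
shape, and a shared *fractional* motion artifact `a` (smoothed Gaussian,
sd 1%). The fractional (multiplicative) form matters: a single OLS slope
cancels a shared artifact only when the two channels' artifact gain ratio
matches their bleach-trajectory slope, which holds for shared fractional
light loss but not for an additive artifact of fixed gain. The indicator
`C` sums unit-peak double-exponential kernels (rise 0.1 s, decay 1.5 s);
each bout triggers one with probability 0.95 and amplitude β·duration +
N(0, 0.5) in Z units (β = 2.5 Z/s; Z units are multiples of the nominal
ΔF/F noise floor, 0.005), plus spontaneous 4-Z events at 0.01 Hz.
Multi-day designs scale β by δ^(day−1) (habituation) and, on a drug day,
multiply the bout and spontaneous-transient rates (default 1.5×); a sign
flip emulates negatively-deflecting sensors.

Not emulated: nonstationary bout rates within a session, correlated
(pink/flicker) photometry noise, indicator saturation and nonlinear
ΔF/F-to-spiking relations, tracking identity swaps or occlusions, and
hemodynamic contamination. Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under this generative model, not
that the thresholds are optimal for any particular rig.

## Validation problem sizes

Recovery runs use 10 seeds of single 30-min sessions (bouts), 10 × 10-min
sessions (transients), and, for correlation-based checks, bouts pooled
across 6–8 simulated subjects per seed (~150–200 bouts) — mirroring how
per-day bout correlations pool animals, and the smallest n at which a
|r| < 0.15 null band is statistically meaningful (sd(r) ≈ 1/√n). The null
calibration uses 100 seeds; the FDR null uses 2000 replicates of m = 50.
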