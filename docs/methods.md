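# Methods

This note documents the models, numerical choices and known limitations of
the `pareidolia` package: a pipeline for synthesizing face/flower-in-pink-noise
stimuli, building divided-visual-field detection schedules, simulating
observers, and analyzing the resulting trial logs with equal-variance signal
detection theory (SDT).

## Stimulus synthesis

**Pink noise.** Noise fields are built in the frequency domain: a
deterministic 1/f amplitude envelope (f = radial spatial frequency) with
i.i.d. uniform random phase, zero DC, inverted with a real FFT and affinely
mapped to the requested mean luminance (default 128 on the 8-bit scale) and
RMS contrast. Because the envelope is deterministic, the radially averaged
log-amplitude spectrum has slope −1 by construction; the measured slope of a
400×400 field fits at ≈ −0.99 (the residual comes from radial binning on a
square grid).

**Signal images.** Two schematic identities per category are drawn
procedurally (synthetic stand-ins for the face/orchid photographs, which are
not redistributable): a face outline with eyes/nose/mouth (150×110 px) and an
orchid-like flower with petals and stalk (150×120 px). Preparation resizes to
a 150-px height (bilinear) and offset-matches the mean luminance to a common
reference, so all four signals share the same mean.

**Composition.** Each composite starts from a signal image placed at one of
8 lateralized locations (4 elevations per side of the vertical midline, the
footprint wholly within its half-field); a companion noise field is matched
to the signal-in-noise image's mean and RMS contrast; the two are combined
pixel-wise with exactly `round(noise_fraction · N)` positions (seeded uniform
draw without replacement) taking the noise value. Noise-pixel proportions are
44–50% for faces and 38–44% for flowers, 16 images per identity per level,
giving 128 signal composites per category plus one unique paired noise-only
field each (256 noise-only in total).

**Filtering and normalization.** All images pass an isotropic band-pass
filter whose gain is Gaussian in log2 radial frequency, equal to 1 at
1.5 cycles/degree and exactly 0.5 one half-octave below and above
(half-height frequency ratio exactly 2 — the literal meaning of "octave
bandwidth at half-height"). A Gaussian in *linear* frequency cannot place
half-height at both geometric points, which is why the log-frequency form is
used. The DC term is removed by the filter and restored by re-centring on the
input mean. Spatial frequency uses the stimulus-intrinsic scale
400 px / 4.2° = 95.24 px/deg, under which the centre frequency is 6.3
cycles/image. After filtering, contrast is rescaled to the target RMS
(std/mean of linear luminance, default 0.30) and quantized to 8 bits last;
clipping affects ≪ 1% of pixels and is logged per image. Every emitted
image's measured RMS contrast must lie in [0.25, 0.35] or generation aborts
naming the offending image.

## Trial design

Blocks are 256 trials with every unique image appearing once, shuffled per
seed. Experiment 1 uses a 1:1 signal:noise ratio (128 + 128); Experiment 2
uses 1:3 (64 + 192). The Experiment-2 signal subset is drawn balanced over
identity × noise level × hemifield (16 cells × 4), and the extra noise-only
images it needs are generated as additional unique fields — both choices keep
the published counts and the one-presentation-per-image rule intact while
filling in details the design itself leaves open. Counterbalancing fills the
8 cells of block order × response mapping × responding hand as evenly as
possible (exact at n = 8, within one subject otherwise). Eight practice
trials are flagged and excluded from analysis. Schedules can be built
*abstractly* (same composition, no pixel rendering) for simulation studies
where only the trial structure matters.

## Simulated observers

**SDT observer.** Evidence on each trial is a unit-variance normal centred at
−d′/2 (noise) or +d′/2 (signal); the response is "present" iff evidence
exceeds the criterion c for that category × hemifield. The symmetric
placement makes d′ = z(HR) − z(FAR) and c = −(z(HR)+z(FAR))/2 exactly
unbiased at the population level, which is what makes the estimator-recovery
targets meaningful. A block-level d′ can optionally be spread over noise
levels linearly in signal strength (1 − noise fraction), mean-preserving.
Lapses (≤ 5%) produce a uniform random response. RT is lognormal with a mild
slowing when evidence falls near the criterion; only its correct-trial mean
is consumed downstream, so this is a pragmatic stand-in, not a process model.

**DDM observer.** A Wiener process with diffusion s = 0.1 accumulates from a
start point z = a·start_bias(hemifield) between absorbing boundaries 0
("absent") and a ("present"); drift is drift_scale · (1 − noise fraction) on
signal trials and 0 on noise trials; RT is first-passage time plus a
non-decision time t0. Hemifield response bias is carried by the start point
(a drift-bias variant would be an alternative; the start-point form is the
conventional way to model baseline response bias). Closed forms for the
absorption probability and the unbiased mean decision time are provided as
oracles. Simulation uses Euler–Maruyama at dt = 1 ms with walks capped at 5 s
(forced guess, flagged, excluded from RT means). Discretely monitored walks
under-detect boundary crossings, which biases choice probability upward by
≈ 0.01 at typical parameters; the boundaries are therefore pulled inward by
the continuity correction 0.5826·s·√dt, after which the simulator matches the
closed forms within Monte-Carlo error (measured p = 0.8801 vs 0.8808 and mean
decision time 0.1901 s vs 0.1904 s at 50k trials, v = 0.2, a = 0.1, z = a/2).

**Traits and coupling.** The four O-LIFE schizotypy subscales are drawn from
binomial distributions bounded by the subscale maxima (12/11/10/10), with
success probabilities chosen to give undergraduate-typical means (≈ 3.6, 4.4,
2.5, 3.5). The coupled criterion (default: Unusual Experiences → face-block
criterion, target r = −0.559) is built from a per-subject standardized
deviation w = r·z_trait + √(1−r²)·u shared across hemifields, so the
population correlation equals the target both per hemifield and for the
hemifield-averaged criterion that the correlation analysis uses. An
independent per-hemifield residual would inflate the field-averaged
correlation (to ≈ 0.69 at a 0.559 target) by averaging away half the noise.

## Analysis

Rates use the log-linear correction (count + 0.5)/(n + 1) applied uniformly
to every cell — not only to degenerate ones — which keeps rates strictly
inside (0, 1) and avoids selection effects. d′ and c use the standard normal
quantile (relative error far below 1e-10 on the working range). RT means are
over correct trials only; incorrect-trial means are reported alongside as a
speed–accuracy audit; forced-guess DDM trials count for rates but not RT.
The repeated-measures ANOVA (statsmodels AnovaRM; partial η² =
F·df1/(F·df1 + df2)) needs no sphericity correction because all factors have
two levels; exactly degenerate designs (zero per-subject contrast) are
reported as F = 0, p = 1 rather than the indeterminate 0/0 ratio. Pearson
correlations of traits with d′/c use a Bonferroni-adjusted α (0.05/4 =
0.0125); regressions report VIF = 1/(1−R²_j) and tolerance = 1/VIF per
covariate. Bayesian model comparison is deliberately out of scope: the
package is frequentist-only.

## Recovery scenarios

Named scenarios pin the generative truths to the observed group statistics:
`exp1-baseline` (26 subjects, face d′ 0.277 ± 0.45, flower 0.791 ± 0.49,
criterion LVF 0.329 ± 0.48, RVF 0.09 ± 0.45, UnEx coupling −0.559),
`exp2-baseline` (29 subjects, 1:3 ratio, CogDis→flower coupling +0.437) and a
`null` scenario for calibration. A recovery run simulates replicate cohorts
end-to-end (cohort → schedules → responses → rate tables → d′/c), then
reports bias, RMSE and 95%-CI coverage of the group means against the
injected truths. At 200 replicates the estimator shrinkage from the uniform
log-linear correction is visible but small (≈ −0.01 to −0.02 on d′ and c at
the default trial counts), well inside the ±0.05 recovery tolerance. Default
problem sizes (200 replicates, 26–29 subjects, 512 trials per subject) were
chosen so a full recovery run completes in about a minute on one CPU.

## What the generator does and does not emulate

The synthetic cohorts reproduce the *statistical structure* the analysis
assumes — between-subject spread of sensitivity and bias, hemifield-specific
criteria, trait–bias coupling, realistic trial counts — so passing recovery
tests shows the estimation pipeline is calibrated and unbiased under the
model. They do not emulate sequential effects (fatigue, learning, response
streaks), criterion drift within a block, the empirical RT distributions of
the keyboard task, or any true generative link between schizotypy and
perception; agreement of recovered values with published group means is
evidence about the pipeline, not about human observers. The schematic signal
images preserve geometry and contrast statistics, not photographic content,
so absolute detectability at a given noise level is not comparable to the
original stimuli.
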