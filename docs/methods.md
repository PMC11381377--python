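# Methods

This note documents the models, conventions and deliberate design
choices behind `mitrain`, in the spirit of a methods appendix: what each
stage assumes, which knobs matter, and what the synthetic tests do and
do not demonstrate about real EEG.

## Signal model and preprocessing

Trials are 4-s, 256-Hz, 21-channel matrices in microvolts, channels
ordered as the montage lists them (FC row, C row, CP row, left→right).
Incoming data are assumed already referenced (the acquisition reference
is not modelled); all stages resolve electrodes by montage label, never
by position.

Filtering is an overall **order-8 Butterworth band-pass (0.1–30 Hz)**
cascaded with an **order-8 band-stop (48–52 Hz)**.  "Order 8" is the
transfer-function order (four conjugate pole pairs per edge).  The
default application is zero-phase (forward–backward), which doubles the
effective attenuation and keeps the 0.5–2.5 s training window free of
group delay; a causal single-pass mode mirrors what a real-time loop
would see.  Both modes are part of the filter spec echoed into every
output manifest.  Epochs are half-open sample windows
`[⌊start·fs⌋, ⌊end·fs⌋)`, so (0.5, 2.5) s is exactly rows 128..639 and
the three feedback segments hold 256/512/768 samples.

## Prompt feedback

The envelope transform (i) re-references — default is the common
average over the 21 montage electrodes, with a nearest-neighbour
surface-Laplacian alternative, since a "local average" is not uniquely
defined; (ii) band-passes to **8–30 Hz** (mu+beta) before taking the
analytic-signal magnitude — without this narrowing, slow drifts inside
the 0.1–30 Hz band would dominate the envelope; (iii) subtracts each
channel's mean envelope over the full 4-s window.  The preparation
phase is not recorded in this paradigm, so no pre-cue baseline exists;
using the within-window mean guarantees both deviation signs occur,
which the map-selection rule requires.  The generator leaves the first
0.5 s of the MI window unmodulated so that, relative to this baseline,
contralateral deviations come out negative (ERD) and ipsilateral ones
positive (ERS).

Map selection iterates over the three segments with a per-iteration
metric reset (a stale metric would otherwise leak into segments matching
neither branch), strict `>` comparison (earliest best segment wins
ties), both-hemisphere candidates barring later single-hemisphere ones,
and K=2 as the empty default.  TopoVal extrema are taken over the
sign-restricted subsets only, so each electrode contributes a ratio in
(0, 1] and each score lies in [0, 18]; a TopoVal tie counts as `good`.

**Known property: the verdict is optimistically biased under the
null.**  Because the representative map is chosen to maximise the true
class's correctly-signed electrode count *before* the TopoVal
comparison, pure-noise trials earn `good` well above chance (~60% with
the realistic generator, ~80% for independent random segments).  The
label enters twice — once in selection, once in scoring — and only a
label-blind selection would restore a 0.5 null rate.  This is inherent
to the selection rule (whose stated purpose is encouragement), not an
implementation artifact; the test suite measures it rather than
assuming chance-level behaviour.

## EOG gating

The blink feature is the **peak absolute amplitude** of the 2-s epoch
(blinks are biphasic and the deflection polarity depends on wiring).
Outlier pruning uses strict inequalities against the *input* median
(boundary features survive), and only blink-labelled trials feed
calibration.  Pruning is a single pass: removing an outlier can shift
the survivors' own median enough that a second pass would prune again
(e.g. features [1, 20, 41, 41]), so the rule is deliberately not
iterated.  Gating is strict (`peak > threshold`) and removes trials
without relabelling or cleaning them.

In the generator, confirmation-phase blinks — deliberate "discard this
trial" signals — are drawn 1.5× more vigorous than the casual cued
blinks of the EOG run.  Some such separation is a *requirement* of the
threshold design, not a convenience: the threshold is the mean of the
EOG-run features, and any i.i.d. amplitude distribution shared by both
runs would leave roughly half of all deliberate blinks below it.

## Artifact rejection

Per-channel variances use the unbiased (N−1) estimator on mean-removed
samples.  Channels where more than 10% of trials have variance below
0.5 µV² are screened out once, before the loop (flat or disconnected
channels would drag the pooled percentiles down); screened channels are
excluded from the variance screen only — all 21 channels still feed
decoding.  The loop pools the retained-channel variances, computes
`P90 + 3·(P90 − P10)` with **linear-interpolation percentiles** (the
convention is recorded in output manifests because worked examples
depend on it), removes trials whose *maximum* retained-channel variance
strictly exceeds the threshold (a single saturated channel should doom
a trial), and stops at the first pass that removes nothing — which also
makes the procedure idempotent.

A percentile rule of this form assumes artifacts are a minority of the
*pooled variance entries*.  Artifacts confined to one to three channels
(electrode pops, movement) keep the pooled contamination low even at a
15% trial-level artifact rate, and the generator models them that way:
a large, slow (≤8 Hz, hence in-band) deflection on a random small
channel subset, scaled to ~20× the typical clean channel variance.
Broadband whole-head artifacts at a comparable rate would defeat the
rule — a real limitation of the procedure, not of the simulation.

## Decoding

Trial covariances are ridge-regularized (`1e-8 ×` mean diagonal) so
rank-deficient epochs stay positive definite; covariances are not
trace-normalized before alignment (a config switch exists).  The
Karcher mean under the affine-invariant metric is computed by tangent-
space gradient iteration from the arithmetic mean with an adaptive step
(grown 1.1× to a cap of 2 while the gradient norm decreases, halved
otherwise) — the unit-step fixed point can stall or slowly diverge on
small, dispersed trial sets.  Convergence is declared at tangent-norm
< 1e-9; exhausting the iteration budget returns the last iterate with a
warning.

Alignment is **per calibration run** for training (each run recentred by
its own mean, removing inter-run shift) and by the Karcher mean of
**all training trials' covariances** for testing, where no run context
exists yet.  CSP solves the generalized eigenproblem `P₁w = λP₂w` on
the class-average aligned covariances, rows sorted by descending λ,
scaled to `wᵀ(P₁+P₂)w = 1` (the Rayleigh quotient leaves scale free and
features must be comparable across refits), each row's sign fixed by
its largest-magnitude coefficient so exported filter topographies are
reproducible.  Six filters (first/last three rows) yield log-variance
features; LDA uses the unweighted average of the two class covariances
(equal to the pooled estimate for balanced classes) with the same small
ridge.  A decision value of exactly zero maps to class 1 ("right") — a
documented convention, since the sign of zero is otherwise undefined.

## Run evaluation and statistics

The class distance defaults to the **entrywise L1 norm** (sum of
absolute values) of the scatter matrices; induced-1-norm and trace
variants are switchable.  CD is exactly invariant to global feature
scaling under any of these; it is *not* rotation-invariant under the
entrywise norm, so cross-study comparisons should fix the convention.
The packaged-table statistics do not depend on this choice.

Off-line accuracy uses 10×10-fold stratified CV.  Riemannian alignment
is applied once per run beforehand — it uses no labels, so there is no
leakage — while CSP and LDA are refit inside every fold.  Within the
pipeline, the per-run class distance at run *r* uses a model fit on
runs 1..r only, mirroring what could have been shown after that run.

Paired comparisons use the two-tailed paired t-test (df = N−1), and
correlations the sample Pearson r with the t-transform p-value.  Table
reproduction rounds half-up to the printed precision (means 2 d.p.,
p-values 4 d.p.).

## Synthetic generator: scope and realism

The generator emulates exactly the statistical structure the pipeline
consumes: a 10-Hz oscillation with multiplicative lateralized envelope
modulation from 0.5 s post-cue (contralateral ×(1−e), ipsilateral
×(1+e)), unmodulated midline mu, white (optionally 1/f) background
noise, channel-subset artifacts, and biphasic blinks.  Defaults:
effect size 0.4, mu amplitude 10 µV, noise SD 3 µV, blink amplitude
300 µV, P(artifact) 0.05, P(blink) 0.1, 20 trials × 6 calibration runs,
10 × 4 testing runs.  Typical human ERD/ERS magnitudes vary widely and
are not calibrated against any dataset; the defaults are chosen so that
a "strong" subject (effect 0.5–0.6) is decodable and a null subject is
at chance.  One integer seed drives a splittable per-trial stream, so
any single trial is reproducible in isolation.

The generator does **not** model volume conduction or realistic source
geometry, inter-channel noise correlation, non-stationary drift within
a session, subject adaptation in response to feedback, or EMG/line
artifacts beyond the stylized types above.  Passing tests therefore
demonstrate the *correctness of the pipeline's mechanics and its
recovery of planted structure*, not expected performance on recorded
EEG.

## Problem sizes

The test suite and the acceptance script run full sessions (120
calibration + 40 testing trials), 500-trial Monte-Carlos for the
feedback and artifact-recovery rates, 10,000 random topographies for
the score bound, and 10,000 random unit vectors for CSP optimality —
sizes at which every Monte-Carlo margin in the assertions is several
standard errors wide.
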