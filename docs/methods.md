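# Methods

This note documents the models, defaults and numerical choices behind
`odorcode`, and what the synthetic sessions do and do not emulate.

## Task structure

Two paradigms are generated. **exp1** (six-odor classical conditioning):
each trial is 2 s of one of six odors (ketones hexanone/heptanone/octanone,
terpenes terpinene/pinene/limonene), followed after a 100–300 ms delay by
sucrose (S), a 70-psi airpuff (P) or nothing (X); each contingency group
holds one ketone and one terpene; on days ≥ 4 every odor's contingency is
reassigned. **exp2** (lick/no-lick): the spout is retracted 200 ms before
odor onset for the three N odors and returns 100 ms before the earliest
possible reward; sucrose follows a 1.1–1.3 s delay with probability 0, 0.5
or 1, each probability represented once in the L group and once in the N
group. Trials run in blocks — each block one permutation of the six odors —
with no odor more than twice in a row (enforced across block boundaries by
rejection sampling), 30 blocks per standard session, inter-trial intervals
uniform on 12–18 s. Odor onsets are snapped to the 5-Hz frame grid so that
"frame 0" of a trial-aligned tensor is exactly the onset frame.

The published description of exp2 pairs contingency and spout lists that
would give two 100%-sucrose N odors and no 100% L odor, contradicting the
design's own schematic (one L and one N odor per contingency level). The
generator follows the schematic: L = {hexanone, heptanone, octanone} at
p = {0, .5, 1}, N = {terpinene, pinene, limonene} at p = {0, .5, 1}.

## Encoding model and calcium generation

Each neuron carries latent weights (w_identity ∈ R⁶, w_valence, w_lick,
w_us, sign ∈ {±1}). Its response amplitude on trial *t* is

    a_t = sign · (w_identityᵀ onehot(odor_t) + w_valence · value(odor_t)
                  + w_lick · licks_t) + ε_t,   ε_t ~ N(0, noise_sd²)

where value(odor) is 1 for sucrose-contingent odors and 0 otherwise in exp1
(a signed variant, airpuff → −1, is a flag; the default is unsigned because
aversive-cue encoding is weak in this circuit) and the per-trial sucrose
probability in exp2; licks_t is the anticipatory lick count in the
paradigm's analysis bin (exp1: the 2-s odor period; exp2: last 0.5 s of
odor + first 0.5 s of delay, matching the delayed-reward design).

**Amplitude is the discriminable-contrast scale.** Valence neurons couple
one `amplitude` (default 15 fluorescence units on a baseline of 100, i.e. a
0.15 peak ΔF/F) to the contingency value. Pure identity neurons respond to
the six odors with a random permutation of six levels spaced `amplitude`
apart — graded full-rank tuning in which *every* odor pair carries at least
one amplitude of contrast. This is the archetype the quadrant analysis
presumes: a narrowly tuned (one-hot) neuron whose preferred odor happens to
be the comparison control odor is indistinguishable from a valence encoder
in the two-pair auROC projection, so "pure identity" is defined here as
all-pair discriminability. Vigor neurons couple `amplitude` per
`lick_per_amplitude` (default 5) anticipatory licks. The default
amplitude/noise ratio of 3 (noise_sd = 5) is the regime in which all
recovery properties are stated.

Amplitudes are rendered as an instantaneous rise at odor onset convolved
with a single-exponential decay kernel, exp(−t/τ), τ = 1.5 s (GCaMP7s-like;
no rise time — the simplest kernel that exercises 5-Hz windowing), added to
baseline + linear drift (per-neuron slope ~ N(0, 0.002 fl/s)) + a slow
sinusoid (amplitude ≤ 2 fl, period 600 s) + Gaussian observation noise
(sd 1 fl), clipped to stay positive (clips logged). Valence neurons also
carry a sucrose-locked transient (w_us), the substrate for the cross-day
analysis in which US-responsive neurons later become cue-responsive.

## Behavior generation

Licking is an inhomogeneous Poisson process: 0.05 Hz background, plus
0.1 Hz during the odor–US interval, plus an anticipatory term that ramps
linearly from odor onset to US time with gain 4 Hz × value(odor) × g_k,
where the learning state g_k = init + (1 − init)(1 − e^(−λk)) grows across
trials (λ = `learning_rate`; the task does not model learning mechanistically,
this logistic-saturation ramp is the simplest monotone stand-in). A 7-Hz
burst follows sucrose for 1 s; the rate is clamped to zero while the spout
is retracted. Locomotion (smoothed noise around a constant) dips by half and
eye area by 30 % during airpuff-predicting odors. Face features — tongue-tip
confidence, mouth-corner confidence, lip distance — are affine functions of
the binary per-frame lick state plus Gaussian noise (sd 0.15, a
signal-to-noise regime where the 3-feature logistic lick classifier reaches
≥ 95 % CV accuracy, as observed for the real tracking-based classifier).

**What the simulator does not emulate:** pixel-level imaging and source
extraction (traces are generated directly, so motion, neuropil and
segmentation errors are absent), spiking biophysics, rise-time kinetics,
correlated (shared-mode) trial noise, cross-day drift in neuronal identity,
and within-session satiation. Passing recovery tests therefore demonstrates
that the *analysis chain* is correct and calibrated under the stated
statistical structure — not that real data meet that structure.

## Preprocessing

Baseline: a two-component Gaussian mixture is fitted in a moving window of
2500 frames (500 s at 5 Hz); the mean of the lower-mean component is the
local baseline. Components = 2 and the lowest-mean selection rule are
package choices (the source procedure states neither); with sparse
transients the lower component tracks the quiescent distribution. For
tractability the GMM is refitted every 100 frames (centered windows,
truncated at edges) and interpolated linearly in between; `reg_covar = 1e-4`
and a fixed `random_state` make the fit deterministic. Constant windows
short-circuit to their value.

Windows are half-open `[t0, t1)` seconds, frames assigned by start time;
the odor period is `[0, 2)`, "last second of odor" `[1, 2)` (5 frames), the
pre-odor baseline `[−2, 0)`. ΔΔF/F rows with no positive entry are left NaN
in the scaled matrix and excluded from scaled-correlation analyses (scaling
by |min| would silently flip sign conventions).

## Statistics

*Responsiveness.* Each odor-period frame's 30 per-trial ΔF/F values are
tested against the pooled 300 pre-odor values (two-sided rank-sum,
asymptotic, midrank tie correction, no continuity correction — vectorized
over neurons × frames). The Holm family is the 10 odor-period frames of one
neuron × odor; responsive = ≥ 4 significant frames, any four (the source
does not say consecutive). Direction is the majority sign of significant
frames; exact ties are labelled "mixed" and excluded from direction-specific
counts. The US-response window for cross-day transfer is `[us, us + 2 s)`
against the same pre-odor pool.

*Single-neuron auROC.* The univariate logistic fit is unregularized with an
intercept; since its score is monotone in the feature, the training-data
auROC equals the folded tie-corrected Mann–Whitney statistic — the identity
is property-tested at 1e-12 on 500 instances, and degenerate fits (zero or
numerically collapsed slope, e.g. equal class means) fall back to the rank
statistic, which is the exact limit. The permutation null permutes labels
over precomputed midranks (closed form, identical to refitting), with
p = (1 + #{shuffled ≥ observed})/(n_shuffles + 1). An optional 5-fold CV
scoring mode exists behind a flag; the default is training-data ROC.

*Population decoding.* Features are per-neuron normalized within training
folds (no leakage); stratified 5-fold CV; permutation p-values from full CV
refits on shuffled labels (count configurable; 10,000 is the production
default, tests use less for runtime). SVM hyperparameters are fixed at
C = 1, gamma = "scale". Generalization orders each odor pair canonically
(sucrose-contingent first, then ketone before terpene) so class 1 means the
higher-contingency odor on both sides of a train/test transfer; training
uses per-frame features with the maximum taken over odor-period frames
(window-mean training is available by passing single-frame features).
PCA-restricted decoding computes components on training folds only; a
whole-data PCA mode exists behind a flag for comparison.

*Geometry.* Distance trajectories subtract each trial's 2-s pre-odor mean
before trial-averaging; distances are normalized by the global maximum over
pairs and frames. The participation ratio uses the unbiased covariance of
all trial-aligned frames concatenated across trials (a trial-averaged mode
is a flag); subsampling is without replacement, independent per resample.

*Clustering.* 18 features per neuron (first/last second of odor, first
second after, × 6 odors), Z-scored per neuron across the trial-averaged
trace (an across-features mode is a flag); Ward linkage on Euclidean
distance; clusters renumbered by ascending mean feature value (inhibited
first) for stable reporting.

*Decoupling.* The full model of per-trial response magnitude is
contingency + licking + interaction; each ΔR² drops one variable *and* the
interaction (keeping the interaction would leave the dropped main effect
partially in the model); ΔR² ≥ 0 by nesting. Lick-bout onsets require a
≥ 1-s lick-free gap and ≥ 3 licks within 1 s. Distributed-lag models
default to lags −2 s … 0 at frame resolution (features precede the target),
least squares with optional ridge, out-of-sample R² on the trailing 25 %,
and reject designs with condition number > 1e8. Δlick is range-normalized
within session before the accuracy-vs-behavior fits.

## Determinism and problem sizes

All randomness flows from one root seed fanned out to named substreams
(`derive_rng`), so toggling one pipeline stage never perturbs another's
draws; regenerating a session with the same seed is bit-identical, and HDF5
outputs are written without timestamps so output hashes are stable. Tests
run the recovery analyses on amplitude-level features (30 trials per odor,
10–30 neurons, 20–50 seeds) and the preprocessing round trips on rendered
sessions of 2–6 blocks; these sizes give the stated statistical power for
every property while keeping the default suite fast.

## Known limitations

- The quadrant categorization is a projection onto two odor pairs; mixed
  encoders and vigor encoders can legitimately occupy the valence quadrant
  in exp1 (resolved only by the exp2 decoupling analyses).
- The GMM baseline assumes transients occupy a minority of each 500-s
  window; dense activity biases the baseline upward.
- The behavioral model has no operant structure and no satiation; learning
  is a fixed parametric ramp.
- Cross-day analyses take neuron matching as given (the simulator provides
  identity); no image-based registration is attempted.
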