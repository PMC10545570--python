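# Methods

## The scientific question and the data it needs

Inhibition of return (IOR) is the two-stage validity effect in exogenous
cueing: responses to targets at a just-cued location are faster for
cue–target onset asynchronies (CTOAs) up to roughly 225 ms (facilitation),
then slower for a second or more (inhibition). Two mechanisms could produce
the inhibitory phase: a sustained inhibitory tag on the cued location, or a
theta-rhythmic (3–8 Hz) attentional spotlight that keeps revisiting it. The
two accounts make different predictions for the *shape* of the
invalid−valid reaction-time difference d(t) across densely sampled CTOAs:
a monotone decay versus an oscillation (or their sum). This package
implements the full decision chain — nonlinear model comparison on d(t) and
a familywise-corrected spectral test — together with a synthetic-data
generator so the chain can be validated end to end without any external
data.

## Synthetic data generator

**Design.** Defaults mirror the reference experiment: 25 CTOAs from 42 to
1050 ms in 42 ms steps, 12 trials per CTOA × validity cell, 60 target-absent
catch trials (9.1%), 6 blocks, 39 participants, a 2 s response deadline.
Every block holds an equal share of each cell and of the catch trials
(requiring divisibility by the block count, which is validated), and
within-block order is a seeded permutation. Per-participant random streams
derive from `SeedSequence((master_seed, participant_index))`, so any
sub-cohort is reproducible piecewise and equal seeds give byte-identical
CSVs.

**Generative signal.** The effect enters only through the difference curve
`d(t) = b0 + N0·exp(−t/τ) + a·sin(2πft + φ)` in z-units, split
symmetrically: valid trials get −d(t)/2 and invalid trials +d(t)/2 around a
common baseline. Only the difference enters the headline analyses, so this
is the simplest generative decomposition consistent with the observed
condition time courses. Defaults are the published hybrid-curve estimates
(b0 = −0.48, N0 = 0.82, τ = 0.18 s, a = 0.14, f = 1.05 Hz, φ = 0.72).

**Noise.** A non-catch RT is
`base + intercept_p + scale_p · (±d(t)/2 · effect_scale + ε)` with
ε ~ N(0, trial_sd) (a shifted-lognormal alternative with fixed shape
σ = 0.5, rescaled to zero mean and the same SD, is available for skewed-RT
realism), participant intercepts ~ N(0, 0.04 s), and lognormal participant
scale factors (σ = 0.10). `effect_scale` (s per z-unit) exists because the
within-participant z-scaling later divides the effect by the empirical
trial SD: with the defaults `trial_sd = effect_scale = 0.08 s`, the trial
noise is one z-unit and the recovered z-scored difference course is
≈ 0.97·d(t) (the small attenuation comes from the condition structure
itself contributing to each participant's SD). This choice preserves the
published curve's scale — the primary anchor — and yields grand-average
difference SEs of ≈ 0.06 z and post-hoc |t| ≈ 8 at the 504 ms CTOA, the
same order as the reference experiment. Catch trials are answered with
probability `false_alarm_rate` (default 0.05), non-catch trials missed with
probability 0.02, and RTs are clipped to (0, 2] s.

**What it does not emulate.** Aborted/repeated trials (anticipations,
broken fixations) are not simulated — the schedule is the realized trial
set; RT autocorrelation, fatigue and practice drifts, and
participant-specific curve shapes (everyone shares d(t) up to scale) are
absent. Passing recovery tests therefore show the *analysis chain* is
sound under its assumptions, not that real data satisfy them.

## Preprocessing

Participants are excluded when their catch-trial false-alarm rate strictly
exceeds 20% (a rate of exactly 20% is retained; a participant with no
catch trials is flagged as undefined and excluded). Default trial filters —
drop catch trials, drop misses, keep RTs in [0.15 s, deadline] — are our
own conventions and fully configurable, since exclusion conventions vary
between labs. z-scaling is computed per participant over *all* retained
trials (pooling CTOA and validity) after filtering and before cell means;
zero-variance or near-empty participants abort with a diagnostic. Cell
means require a complete participants × 25 × 2 grid; missing cells abort
rather than impute, because every downstream analysis assumes the full
grid. Within-subject error bars use the Cousineau–Morey procedure across
all M = 50 cells (subtract the participant mean, add the grand mean, take
SD/√n per cell, inflate by √(M/(M−1))); the difference course uses the
ordinary between-participant SE, which needs no correction for a
within-participant difference score.

## Model fitting

All five models are fitted to d(t) by unweighted ordinary least squares
(no weighting scheme is assumed), with t in seconds and f in Hz.
Conditional on the nonlinear parameters (τ and/or f) every model is linear,
so fitting uses variable projection: a deterministic grid over τ
(25 points, geometric, 0.02–2 s) and f (0.25 Hz steps across the bounds;
0.5 Hz for the participant-level batch fits) with an exact linear solve at
each node, followed by bounded trust-region least-squares polish from the
best nodes. This dominates any explicit phase grid because the phase is
profiled out exactly (a·sin(2πft+φ) = A·sin + B·cos), and it is fully
deterministic. The hybrid's grid is seeded with the exponential fit's τ̂ and
the rhythmic fit's f̂, so the RSS nesting inequality
rss(hybrid) ≤ min(rss(exponential), rss(rhythmic)) ≤ rss(intercept) holds
numerically. Amplitude is constrained a ≥ 0 with phase reported in [0, 2π)
to remove the sign/phase aliasing degeneracy; frequency estimates within
1e−6 Hz of the lower bound are flagged, since a sinusoid pinned at its
slowest allowed frequency is absorbing a trend rather than tracking a
rhythm. Bounds: |b0|, |b1|, |N0| ≤ 10 z (data are O(1)), τ ∈ [1e−3, 10] s,
a ∈ [0, 10], f within the preset (1–11 Hz "full", below the 11.9 Hz Nyquist
frequency of the 42 ms grid; 3–8 Hz "theta"). Optimizer, grids and
tolerances are this package's declared defaults, not reconstructions of any
other implementation.

## Model comparison

AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1) and BIC = n·ln(rss/n) + k·ln(n),
with the Gaussian constant n·ln(2π) + n omitted from both, so differences,
Akaike weights and Bayes factors are unaffected but absolute values are
convention-dependent. The effective parameter count is k = free model
parameters + 1 (residual variance); at n = 25 this convention reproduces
the BIC−AICc gaps of the published goodness-of-fit table for all five
models (1.89/2.51/2.88/2.94/1.94), which the tests audit. Akaike weights
are exp(−Δᵢ/2) renormalized over the full five-model set; Bayes factors use
the large-sample BIC approximation exp(ΔBIC/2), documented as an
approximation. Participant-level winners are the argmin per criterion;
ties within 1e−9 credit every tied model's class (intercept; IOR = linear
or exponential; rhythmic; hybrid).

## Spectral analysis

The grand-average course is detrended by projecting out {1, t, t²}
(least-squares quadratic; exact to ~1e−12 for any quadratic input, and a
4 Hz sinusoid on the default grid loses under 5% amplitude). Amplitudes
are 2|X_k|/N at bins k/(N·dt), k = 1..12 (0.952–11.43 Hz; DC excluded;
unrounded bin frequencies are reported). The permutation null shuffles the
25 CTOA labels independently within each participant — preserving each
participant's value distribution while destroying shared temporal
structure — then re-averages, re-detrends (valid because detrending is
linear and commutes with averaging, which is tested) and records the
maximum amplitude across bins; comparing every bin to this maximum
distribution controls the familywise error rate. p = (1 + #{max ≥ amp}) /
(n_perm + 1), so p can never be 0; the default budget is 10,000
permutations (1,000 in the calibration studies), with a warning below 999.
The 95th percentile of the max distribution is reported as the plotting
threshold. This permutation scheme is our own reconstruction of the
max-statistic lineage for dense-sampling designs. Its validity assumes
CTOA-label exchangeability: a deterministic trend (e.g. the exponential
IOR decay) is not fully removed by quadratic detrending and can leak into
low-frequency bins, so the familywise-error calibration uses a trend-free,
rhythm-free generator, and low-frequency significances on trended data
warrant caution.

## Replication ANOVA

The five grid CTOAs nearest the classic 50/100/200/300/500 ms probes are
selected by exact grid arithmetic (42, 84, 210, 294, 504 ms on the default
grid; ties break toward the shorter CTOA). The 2 × 5 fully within-subject
ANOVA runs on pingouin with Greenhouse–Geisser correction applied to every
effect with more than one numerator df and generalized eta squared in its
fully-within form (all subject-involving sums of squares in the
denominator); the tests verify F, ε and η²G against an independent
brute-force sums-of-squares and Box-epsilon implementation to 1e−8.
Post-hoc paired t tests (invalid − valid; positive t = facilitation) are
two-sided with df = n−1 and Bonferroni multiplier 5, the number of CTOAs
tested.

## Validation studies and the problem sizes used

`denseior.validation` (used by tests and `scripts/acceptance.py`) runs:
hybrid parameter recovery (noise-free: all six parameters to <1e−3; noisy:
median |τ̂ − τ| < 0.05 s over 100 cohorts); model-class recovery, scored as
the participant-level AICc winner tally reaching a strict plurality for
the target class over 100 cohorts per ground truth — a cohort-level
grand-average argmin is deliberately not used as the score, because with
realistic noise a frequency-scanned sinusoid needs only a ~35% RSS
reduction to beat AICc's penalty at n = 25 and therefore wins a
substantial share of pure-exponential cohorts; the participant-level tally
is also what the reference analysis reports — spectral familywise error
(200 trend-free null cohorts × 1,000 permutations) and power (50 cohorts
with a 0.5 z sinusoid on the 3.81 Hz bin). These sizes keep the full suite
and the acceptance script each inside a few hundred seconds on one core
while leaving Monte-Carlo margins well clear of the thresholds.

## Known limitations

- The generator's shared-curve assumption makes participant-level winner
  tallies more homogeneous than real cohorts would be.
- BIC Bayes factors inherit the unit-information-prior approximation.
- The spectral test's exchangeability caveat above: it tests "no structure
  across CTOAs", not "no rhythm on top of a trend".
- Absolute AICc/BIC values depend on the omitted Gaussian constant and are
  only comparable within this package's convention.
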