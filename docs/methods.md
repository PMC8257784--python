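# Methods

This note documents the models, estimators and numerical choices behind
`axonfid`, what the synthetic-data generator does and does not emulate,
and the decisions taken where the underlying measurement conventions were
genuinely open.

## Spike-train model and fidelity estimation

**Generative model.** Somatic spiking is an ordinary gamma renewal
process: interval shape k = 1/CV², scale chosen so the mean interval is
1/rate; the process starts at t = 0 with the first spike after one
interval. CV = 0 degenerates to a perfectly periodic train. The gamma
family is a modelling choice — the recordings this emulates report rate
and regularity but not an interval law — and the default CV of 0.5 is an
explicit placeholder, freely configurable.

Axonal propagation is per-spike Bernoulli thinning: each somatic spike is
deleted independently with probability p (0.00607 for control axons,
0.00112 for axons with a swelling, i.e. 6.07 and 1.12 failures per 1000
spikes). Surviving spikes are shifted by the axosomatic delay (default
0.2 ms; negative values are legitimate because spikes initiate in the
axon initial segment) plus Gaussian jitter (default SD 0.05 ms). Jitter
large enough to reorder spikes is allowed; the train is re-sorted and the
event flagged in the ground truth, as are spikes shifted outside the
recording window (expected ≈ rate × |delay| per train, i.e. ≪ 1 spike at
the default parameters).

**Matching.** Failures are identified by a two-pass procedure. The delay
is first estimated as the median over somatic spikes of the offset to the
nearest axonal spike — robust because failures are rare and mis-paired
offsets land an ISI (~22 ms) away from the ~0.2-ms mode. A greedy pass in
time order then assigns each somatic spike the closest unused axonal
spike within ±2 ms (configurable, echoed in every manifest) of its
expected arrival. At physiological ISIs (≫ window ≫ jitter) candidate
conflicts are essentially absent, and the greedy assignment coincides
with the exhaustive match-count-maximising, displacement-minimising
assignment on random instances (tested against a brute-force oracle).
The failure-calling window of the original analysis is unknown; ±2 ms is
wide enough to be insensitive to jitter and narrow enough (a tenth of an
ISI) not to capture neighbouring spikes.

**Conventions.** Failure rate = 1000 × unmatched/total somatic spikes.
The high/low fidelity boundary (exactly 1 per 1000) is assigned to *low*
— the published legend ("<1" high, ">1" low) leaves it open; low is the
conservative choice. The axosomatic delay statistic is the mean over
matched pairs (a median option would differ only under heavy-tailed
jitter, which the generator does not produce). CV2 is aggregated by the
median by default, robust to the bimodal ISI mixtures that partial
sodium-channel block induces; the mean is available. Step-session firing
frequency is spike count / 0.5 s (the step duration) — deterministic,
unlike instantaneous-frequency definitions. Reliability bins are
half-open [lo, hi) with origin 0 Hz and 20-Hz width; pooled success
equals the spike-weighted mean of bin successes by construction, and the
success "at maximal frequency" pools steps tied at the highest attained
frequency.

**Frequency-dependent failures.** In the step-current regime the failure
probability follows a logistic in the step's mean frequency:
p(f) = baseline + (ceiling − baseline)·σ(steepness·(f − midpoint)).
The defaults (control: midpoint 130 Hz, ceiling 0.33; swelling: midpoint
170 Hz, ceiling 0.075; steepness 0.05/Hz) are calibration knobs, not
measured values: with per-group f-I gains that place maximal driven
frequencies near the recorded ~128 Hz (control) and ~162 Hz (swelling),
they yield success-at-maximal-frequency values near 84% and 97%, the
scale of the recordings. The functional form is a convenience; only
monotonicity is treated as a model commitment.

## Network simulation

Each repetition draws a 40-cell cohort with round(40 × fraction) swelling
cells. Per cell, the firing rate (Hz) and failure rate (per 1000) are
drawn from the cell class's normal truncated at zero, with SD
reconstructed from the published group summaries as SEM·√n (control
failures: 6.07 ± 1.36, n = 11 → SD 4.51; swelling: 1.12 ± 0.41, n = 9;
rates 45.2 ± 3.15, n = 29 and 44.3 ± 3.71, n = 26). Both reconstruction
and truncation deserve emphasis: zero-truncating a normal whose SD is
comparable to its mean *raises* its expectation (control failure draws
average ≈ 6.87 per 1000, not 6.07), so all analytic cross-checks use the
truncated-normal moments (via `scipy.stats.truncnorm`), never the
untruncated means. A SEM of 0 is accepted and makes the draw
deterministic, which the degenerate-limit tests exploit.

Per repetition each cell emits Poisson(rate × duration) spikes (default
duration 1 s) and transmits each independently with probability
1 − p. The default 5000 repetitions give a 200,000-cell network.
"Information" is quantified as the transmitted-spike fraction
(equivalently spike loss); no Shannon measure is imposed. The closed-form
expectation used as the simulation oracle is spike-weighted:
E[frac] = Σ w_g·E[rate_g]·(1 − E[p_g]) / Σ w_g·E[rate_g], exact up to a
ratio-estimator correction of order 1/n_cells (≈ 5 × 10⁻⁶ at network
scale, well below Monte Carlo error).

Learning projection is linear in a chosen predictor (transmitted fraction
or swelling percentage); slope and intercept are calibration inputs
supplied by configuration, fitted on behavioural cohorts if desired — the
simulation makes no claim to determine them. The composition sweep runs
100 independent networks at each of {0, 25, 50, 75, 100}% (500 rows);
per-run generators are spawned from the master seed fraction-major,
run-minor, so the sweep is reproducible bit-for-bit and any single run
can be regenerated in isolation.

## Behaviour

Rotarod learning is mean(last two trials, final day) − mean(last two
trials, day 1), in seconds of latency; Erasmus-ladder learning is the
change in daily short-step count (final − first; a per-day slope option
exists). Both are invariant to adding a constant to all trials. The
Pearson p-value uses the exact t transform with n − 2 degrees of freedom
(two-tailed); |r| = 1 maps to p = 0. Learner cohorts are split at the
median with ties assigned to the high group — the original grouping rule
is not stated; the median rule reproduces a 10/11 partition of 21
distinct scores and is recorded in every output. Group comparisons use
Student's t (equal variances) or the Mann-Whitney U-test, exact when the
combined sample is ≤ 20 without ties, otherwise the tie-corrected normal
approximation. p-values are reported to 3 decimals in summary tables.

The cohort generator couples learning to swelling density linearly with
Gaussian noise; densities are normal clipped to [0, 100] (negligible
clipping at the default 35 ± 8%). Raw trial tables are constructed so the
scoring rule recovers the generated value exactly: the two scored trials
of each day equal the day mean, so the recomputed score equals the stored
"realized" ground truth to the last bit (the latent linear-model value
differs by float subtraction error, and by count rounding for the
ladder). `BehaviorGenSpec.for_population_correlation(r)` inverts
r = |slope|·σ_density / √(slope²σ_density² + σ_noise²) to target a
population correlation; defaults sit in the 0.5–0.8 regime the analyses
operate in. Very negative latent draws can produce unphysical negative
latencies; they are left unclipped to preserve exact round-trips.

VOR adaptation enters as a precomputed per-animal gain-change score; no
eye-trace processing is attempted.

## Morphometry

The g-ratio defaults to the standard inner/outer diameter convention
(unmyelinated limit 1.0). The alternative inner/(inner + outer) form,
which also appears in print but conflicts with the standard definition,
is available as `convention="sum_form"`; every output row carries the
convention tag because the two differ by roughly a factor of two.
Myelin thickness is the arithmetic mean of four cartesian-point widths.
Organelle density is organelle area / total axonal cross-section area.

Minimum Feret diameter: convex hull (`scipy.spatial.ConvexHull`), then
rotating calipers — the minimal width of a convex polygon is always
attained flush with a hull edge, so the minimum over edges of the
farthest-vertex distance is exact. Degenerate (collinear) traces return
width 0 with a warning. The test oracle is an independent dense angular
scan; because the width-angle function is kinked at its minimum, the scan
refines locally around the coarse argmin to reach 10⁻⁴ relative
agreement.

Time-lapse experiments are compared at the last timepoint with fields
(image acquisitions) as the statistical unit: per-field counts normalised
to 100 Purkinje cells, Kruskal-Wallis omnibus, then pairwise two-tailed
Mann-Whitney with Bonferroni adjustment min(1, p·m). This nonparametric
path replaces repeated-measures ANOVA (out of scope here); the generator's
count model is gamma-Poisson (Poisson at dispersion 0), unbiased for the
rate curve under the per-100-cell normalisation because cell counts vary
per field.

## What the generator does and does not emulate

It reproduces the statistical skeleton the estimators assume: renewal
spiking at the recorded rates, independent per-spike failures at the
recorded group probabilities, sub-millisecond delays with jitter,
monotone frequency-dependent failure, density-coupled learning with
realistic scatter, and overdispersed swelling counts. It does **not**
synthesise membrane-potential waveforms, biophysical conductances, bursty
or complex-spike firing, electrode artefacts, non-stationary drift, or
correlated failures (e.g. refractory-linked failure runs). Passing tests
therefore certify the estimators and the simulation under the stated
assumptions — not the assumptions themselves against real recordings.

## Problem sizes and numerics

Statistical tests run at sizes chosen so the quantity under test has
standard error well inside its tolerance band: ~10⁵-interval trains for
CV recovery (delta-method SE), ~10⁵-spike trains for binomial
failure-rate bands, 1500–5000 repetitions for network Monte Carlo
(between-repetition SE), 1000 replicates for null calibrations, 10⁵
permutations for the permutation-null comparison (3 MC SE plus a 0.1/n
first-order allowance for the conditional-vs-unconditional difference),
and 500 random polygons for the Feret oracle. Spike times are serialised
at 6 decimal places (µs); equality-sensitive identities (conservation,
weighted-mean reliability) are asserted to machine precision. Degenerate
inputs — empty trains, < 3 spikes, zero variance, identical scores,
collinear polygons — raise typed errors or return flagged NaN as
documented per function.

## Known limitations

- The failure-calling window, ISI distribution, original learner-split
  rule, and the original simulation's per-cell stochastic details are not
  recoverable from the published record; all are explicit, logged
  parameters here, but defaults are conventions, not reconstructions.
- The linear learning mapping is a deliberate simplification; any
  saturating relation would change projected-learning spreads at extreme
  compositions.
- The greedy matcher is only oracle-equivalent when the jitter scale is
  far below the ISI; dense bursting would require an assignment solver.
- Truncated-normal sampling of failure rates is one of several defensible
  choices (a log-normal or beta model would avoid the truncation bias
  discussed above); the closed-form oracles would need matching changes.
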