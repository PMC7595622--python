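# Methods

## Data model

Input is one epoch-level CSV per individual (`timestamp,count`), counts being
non-negative integers at a fixed epoch length (5 s in raw biobank extracts;
the package's reference configuration works on 5-minute epochs). Reading
places every series on a uniform grid: timestamp gaps become explicit missing
epochs, never silently dropped, because the two downstream algorithms need
different missing-data policies (the HMM marginalizes, the FFT interpolates).
Timestamps are treated as local clock time with no timezone arithmetic, since
every derived feature is clock-time based.

Cohort-level quality control excludes an individual when any of the
qualitative flags is set (data problem, poor wear time, poor calibration,
interrupted record, device requiring external calibration data) or when its
recording-error count exceeds `Q3 + 1.5×IQR` of the cohort's error counts.
Quartiles use linear interpolation between order statistics (numpy's default,
"type 7"); the estimator is a parameter of `qc_exclude` because QC pipelines
differ on this convention. The rule needs at least 4 individuals; smaller
tables are rejected explicitly rather than silently skipping the rule.

## Sleep/wake HMM

States: `s1` sleep, `s2` wake; observations `O_t = log(count_t + 1)`.
Emissions: sleep is zero-inflated truncated Gaussian (point mass `alpha` at
exactly zero, Gaussian `N(mu1, sigma1)` truncated to `[0, ∞)` elsewhere);
wake is Gaussian `N(mu2, sigma2)`. The closed-form band emission
`b1(0) = alpha + (1−alpha)·f_TN(0)` mixes the mass with the density value at
the origin; `emission_sleep` implements exactly that form, and
`alpha + ∫ b1(k) dk = 1` over `(0, ∞)` is verified by quadrature in the test
suite.

**Zero handling in the fitted likelihood.** The likelihood that Baum-Welch
maximizes and Viterbi decodes attributes an exact zero under sleep to the
point mass alone (`b1(0) = alpha`): a continuous truncated normal produces an
exact zero with probability zero, and a likelihood that adds the density
value on top of the mass has no finite maximizer — the truncated normal can
drive its density at the origin arbitrarily high (mu → −∞ with sigma growing)
and absorb the zeros, which empirically drags EM away from the generating
parameters even when started at them. With the point-mass convention EM is a
textbook zero-inflated mixture update: exactly monotone, and it recovers
alpha, mu1, sigma1 to the tolerances asserted in the tests. Away from zero
the two conventions are identical.

**E-step.** Log-space forward-backward (no scaling underflow for records of
10^5–10^6 epochs). Missing epochs inside a segment contribute an emission
factor of 1, i.e. are marginalized over; gaps longer than 60 minutes
(configurable) split the record into independent segments that share one
parameter set — no data are fabricated and each individual still gets a
single Θ.

**M-step.** Transition matrix and initial probabilities by the standard
ratios of expected transition/occupancy counts. Wake mean/SD are
gamma-weighted moments. Sleep: `alpha` is the gamma-weighted zero fraction;
(mu1, sigma1) maximize the weighted truncated-normal log-likelihood of the
positive observations, which depends on the data only through three weighted
sums. The maximizer starts from an inverse-Mills moment correction and the
current parameters and refines by Nelder-Mead; it never returns a point worse
than the current parameters, so each step is a generalized-EM update and the
observed-data log-likelihood cannot decrease (asserted at 1e-8 on every test
fit).

**Initialization** (`init="auto"`): a deterministic 1-D two-means split of
the observed values (centroids seeded at the 10th/90th percentiles); the
lower cluster seeds the sleep emission and its zero fraction seeds `alpha`,
the upper cluster seeds wake; transitions start at diag(0.95, 0.95) and
`pi = (0.5, 0.5)`. No randomness anywhere in fitting, so fits are
reproducible bit-for-bit.

**Identifiability.** EM could converge with the state roles reversed; fits
are relabeled post hoc so `mu_sleep < mu_wake` (sleep has lower activity by
construction). Convergence: relative log-likelihood change below 1e-6, at
most 500 iterations; non-convergence is reported in the diagnostics, not
raised.

## Sleep phenotypes

Days are noon-to-noon windows so a night is never split. Within a window,
maximal sleep runs separated by non-sleep gaps of at most 30 minutes
(configurable) are merged; the merged bout containing the most sleep, if it
holds at least 180 minutes of sleep, is the main sleep period. Sleep start
and end are its boundaries; duration counts only sleep epochs inside it, so
mid-night wake does not inflate durations. Windows with more than 20%
missing epochs, or no qualifying bout, are invalid. Per-individual
phenotypes average over valid days (at least 3 required, configurable);
short/long sleeper flags compare the mean duration against 5 h and 10 h. The
HMM emission parameters (state-wise activity mean/SD) are phenotypes in their
own right and are kept even when sleep timing is missing. Output formats:
CSV with NA, or PLINK `.pheno` (FID = IID = individual id, missing −9).

## PML circadian phenotyping

Counts are averaged into 5-minute bins (configurable), truncated to a whole
number of days so `period_days = record_days / frequency_index` is exact,
linearly interpolated across missing bins (individuals over 20% missing are
rejected), mean-subtracted and transformed with a one-sided FFT, magnitudes
scaled by 1/N; a pure cosine of amplitude A thus shows A/2 at its band. No
taper is applied — the selection statistic is the column norm of exactly
periodic bands, not a leakage-sensitive peak estimate.

The selector weight per band is the argmin over `[0, 1]` of
`−2θ‖x‖² + θ²‖x‖² + λ((1−α)/2·θ² + αθ)`, i.e.
`θ̂ = clip((2‖x‖² − αλ)/(2‖x‖² + (1−α)λ), 0, 1)`; the `+` in the denominator
follows from the derivative of the objective, and the implementation is
checked against grid-search minimization on a 1e-6 grid. The λ path is
geometric, 100 points from `2·max_j‖x_j‖²` down to 1e-4 of it, plus exactly
0; with the Lasso-only default (α = 1) a band activates exactly when
λ < 2‖x_j‖², so entry order equals descending spectral energy (asserted).
The reconstruction error `‖X − XΘ‖²_F = Σ_j (1−θ_jj)²‖x_j‖²` is reported per
λ for elbow inspection; the number of bands kept (default 3) is a user
choice, as no automatic stopping rule is imposed. Phenotypes default to the
unsquared magnitude at each selected band (squared power and per-individual
normalization are flags).

## Synthetic cohorts

`generate_cohort` emulates a 7-day, 50-individual accelerometer extract with
known ground truth. Hidden states follow a time-inhomogeneous two-state
chain: per 5-minute epoch, the hazard of switching toward the scheduled state
is 0.25 inside the night window and 0.003 against it, so individuals fall
asleep within ~20 minutes of a 23:00–07:00 schedule, show occasional brief
night wakings and day naps, and average 8.1 h sleep/day (within the ±30 min
band the tests assert). Bed and rise times wander night-to-night with SD
60 minutes — real sleep timing is not rigid, and a perfectly repeated
rectangle would carry artifactual high-order harmonics.

Observations come from the emission model on the log scale and are inverted
to counts via `count = round(exp(o) − 1)` clamped at 0. The day/night
rectangle produces the 1-day fundamental and harmonic structure as in real
data; explicit wake-mean modulation adds the within-day activity structure a
two-level profile lacks: log-scale amplitudes 0.35 at 1 day (afternoon peak),
0.3 at 1/2 day with phase π (bimodal morning/evening peaks — also in phase
with the rectangle's own 2nd harmonic rather than cancelling it), and 0.3 at
1/3 day with phase π (late-morning/evening peaks aligned with the sidebands
the multiplicative 24-h×12-h structure places on that band). An exactly 8-h
night has a null 3rd Fourier harmonic, so without this within-day structure
the 1/3-day band would sit at noise level — unlike real records, where
meal-anchored activity keeps it prominent. Under these defaults the cohort's
spectral energy ordering is 1-day > 1/2-day > 1/3-day > everything else with
comfortable margins (≥1.4× between ranked bands across seeds).

Count inversion coarsens the sleep emission near the origin: truncated-normal
draws below log(1.5) land on count 0, so on count data the fitted `alpha`
absorbs that extra zero probability (the effect is quantified and tested via
the analytic zero-fraction identity
`P(zero) = alpha + (1−alpha)·P_TN(o < log 1.5)`). Parameter-recovery checks
therefore use `simulate_observations`, which draws from the HMM directly on
the continuous log scale; count-level records are used for decoding-accuracy
and end-to-end checks, where discretization is part of the task. Passing
tests demonstrate correct inference under the model's own assumptions plus
count discretization and schedule noise; they do not certify behavior under
device artifacts, non-wear masquerading as sleep, shift-work schedules, or
emission distributions far from the assumed families.

## Problem sizes and numerics

The test suite and the acceptance script run cohorts of 50 individuals × 7
days at 5-minute epochs (2016 epochs/individual, spectral matrix 50×1008) and
20 replicate fits of 2016-epoch sequences; these sizes give stable estimates
(transition diagonals to ±0.02, emission means to ±0.1) while keeping a full
run in tens of seconds. Degenerate inputs are handled explicitly: all-missing
sequences, empty metadata tables and all-zero spectra raise or warn rather
than propagate NaN; σ estimates are floored at 1e-4; band ties on the λ path
break toward larger column norm, then lower frequency index.
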