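# Methods

## The model

`eegfp` predicts a deep-brain region's fMRI-BOLD time course from a single
EEG electrode.  The regression target is the ROI BOLD series resampled to
4 Hz and z-scored; the predictors are the preceding 12 s of EEG band
power.  Concretely, raw EEG (Pz in the original protocol) is notch-filtered
at the power-line frequency, transformed with the Stockwell transform
(S-transform: Fourier analysis with a Gaussian window of width sigma = 1/f
seconds, evaluated at integer-Hz voices over 1-40 Hz), averaged into 10
contiguous frequency bands, block-averaged to 4 Hz, and normalized against
rest-period statistics.  The model is linear:

    BOLD(t) = sum_b sum_d  C[b, d] * P[b, t - d] + c + noise,

with b over 10 bands and d over 48 delays (0 to 11.75 s in 0.25-s steps).
The (10 x 48) coefficient matrix C is the "finger-print": it names the
frequency bands and lags whose power co-varies with the ROI.  C is
estimated by ridge regression on column-centered data with an unpenalized
intercept.  Delays substitute for an explicit hemodynamic response model;
no HRF convolution is applied anywhere.

### Regularization choice

The ridge weight lambda is selected by repeated block cross-validation:
30 random splits, each holding out one contiguous window of 20% of the
rows (time-series rows are autocorrelated, so random row-level splits
would leak).  Candidate lambdas are 25 log-spaced values in [1e-2, 1e4];
the lambda minimizing mean validation NMSE (MSE / target variance) wins,
with ties broken toward the larger lambda.  Internally each split is
solved from downdated sufficient statistics (gram matrix minus the
validation window) and one eigendecomposition serving the whole lambda
grid, so a full session fit costs about a second.

### Band schemes

The 10 bands are not fixed canonical bands: the averaged log-amplitude
spectrum (mean over time of log(amplitude + 1e-12), averaged across the
relevant session set) is divided into 10 intervals of equal area, so bands
are narrow where the spectrum is rich and wide where it is flat.  Edges
snap to the 1 Hz voice grid by nearest cumulative-area match under a
strict-monotonicity constraint; each band's area is then within one bin's
area of the equal share.  The spectrum must be positive on the log scale
(amplitudes in microvolts satisfy this for physiological signals).  Two
scheme flavours exist: a comparison scheme pooled across *all* sessions
(used only to bring different models into one space) and the common-model
scheme pooled across the *selected* sessions.

## One-class session selection

Individual finger-prints differ strongly between subjects and sessions.
To build a subject-general model, the package selects a homogeneous
"positive" pool: each fitted matrix is expanded to the 1 Hz grid,
collapsed onto the uniform comparison scheme, and flattened; vectors are
compared by correlation distance 1 - R.  Agglomerative clustering merges,
at each step, the two clusters whose representative vectors (plain means
of member leaves) are closest.  Because representatives are leaf means,
merge heights are not guaranteed monotone; they are reported as computed.
Clustering stops at a configured cluster count or at the knee of the
merge-distance curve (the largest discrete second difference marks the
last cheap merge; a straight curve falls back to a 24/39 cluster ratio).
From the biggest cluster, the n sessions with the smallest maximum
internal distance are selected greedily (closest pair first, then the
member minimizing the resulting maximum); the greedy subset is validated
against exhaustive enumeration at small n in the test suite.

## Common model (cEFP)

The k selected sessions are validated leave-one-session-out: each fold
concatenates the other k-1 sessions as a whole unit, selects lambda by the
inner block CV with validation windows constrained inside single sessions
(one window per session per split, so no window spans a boundary), and
scores the fold model on the held-out session by Pearson r and NMSE.  The
final model refits on all k sessions using the modal fold lambda (ties to
the larger).  Sessions are featurized and normalized per session before
concatenation so they are scale-commensurate.

## Streaming engine

The real-time path mirrors the offline one.  A rolling buffer holds the
last 15 s of raw EEG (the 12-s window plus one 3-s packet); each arriving
3-s packet triggers the full preprocessing of the buffer, and the last 48
4-Hz columns are multiplied element-wise with the coefficient matrix to
emit one value.  The first value appears once 12 s of signal exist
(fourth packet).  The emitted value uses the buffer's newest columns,
accepting their Stockwell edge contamination in exchange for zero added
latency; the 15-s capacity keeps the window clear of the *leading* edge
at steady state.

Two offline comparators exist and should not be confused.  The stateless
`replay` evaluates exactly the same buffer windows from a stored record
and must match streamed output bit-for-bit (the suite asserts 1e-6); it
verifies the engine's buffering, indexing and warm-up logic.  Full-record
featurization (as used for fitting) is *not* numerically identical to the
windowed computation: at low frequencies the Stockwell Gaussian extends
beyond the 15-s buffer, so windowed amplitudes differ at the percent
level.  The suite checks that predictions from the two feature paths stay
highly correlated (r > 0.95), and the package consistently uses the
windowed path for anything streamed.

Feedback mapping: loudness = 50 dB + 10 dB * (value - rest mean) / sd,
clipped to [10, 90] dB.  The rest mean and sd come from a calibration
period of at least 60 s; after every feedback period the sd is reset to
the sample (n-1) sd of that period's values, so subsequent excursions are
rescaled by exactly the sd ratio.

## Evaluation statistics

Per subject, feedback-period values are compared with baseline values by
a one-sided Welch t-test; "success" is p(NF < BL) < 0.05.  The 3-s samples
are autocorrelated, so the effective sample size is smaller than the
nominal one and per-subject p-values are descriptive (no correction is
applied; none is standard for this design).  The group analysis is a
2 (test/sham) x 2 (BL/NF) mixed ANOVA on per-subject condition means —
with two within levels this reduces exactly to independent tests on
per-subject sums and differences, every F on df (1, n-2); simple
(within-group) condition effects against the pooled difference error are
reported as planned comparisons.  Group success counts are compared by a
two-sided Fisher exact test computed by full hypergeometric enumeration
(every table with fixed margins whose probability does not exceed the
observed one, with a 1e-7 relative tie tolerance).

## Synthetic data generator

No public paired EEG/BOLD data accompany this problem, so every claim the
test suite makes is grounded in a generator with known truth:

- Per band, a slow log-normal amplitude envelope is drawn directly on the
  4 Hz model grid (Gaussian log-process, correlation time 2 s, log-sd
  0.4).  75% of the log-variance is a shared "arousal" component — band
  powers co-fluctuate, as in real EEG.
- BOLD is the planted linear functional of the (z-scored) envelopes plus
  white Gaussian noise scaled to a requested variance ratio
  (snr = var(signal)/var(noise), default 10); the first 47 samples, which
  lack a full 12-s history, are dropped, and the series is z-scored.
- Planted coefficient matrices are smooth: per band a Gaussian delay bump
  (peak uniform in 4-8 s, width 1.5 s — hemodynamically plausible lags)
  with a standard-normal amplitude.
- Raw EEG, when needed, is synthesized as ten narrowband oscillatory
  carriers (random-phase sinusoids at 4, 8, ..., 40 Hz, one per band of
  the default scheme whose edges sit halfway between carriers)
  amplitude-modulated by the envelopes, plus a pink broadband background
  (12 uV RMS) that fills the spectrum between carriers.  Deterministic-
  phase carriers are used instead of filtered-noise carriers because a
  stochastic carrier's Rayleigh fading aliases into the 4 Hz band-power
  estimate and would swamp the envelope signal the oracle tests rely on;
  the exact 4 Hz carrier spacing additionally makes all interference
  beats integer multiples of 4 Hz, which the 250-ms block means cancel.
  Carrier RMS is 40 uV at 20 Hz with a mild sqrt(f/20) tilt.
- Studies plant a majority group sharing one coefficient matrix and a
  minority of outliers whose matrices receive a *smooth* correlated
  Gaussian perturbation (an independent draw from the same bump process,
  scale 3 by default, renormalized to equal Frobenius norm).  Smooth
  rather than white perturbations are essential: ridge estimation filters
  delay-incoherent structure, so white perturbations would be largely
  invisible to the clustering.  Scale 3 yields an estimated cross/within
  distance ratio >= 3, the regime the selection stage is specified for.
- Synthetic neurofeedback studies plant a mean amplitude change of -0.84
  units (subject sd 0.25) in 7 test subjects and none in 6 sham subjects,
  with baseline means 0.01 +- 0.07, per-sample sd 0.5, five 7-minute
  periods sampled every 3 s.

What the generator does **not** emulate: MR-gradient or cardio-ballistic
artifacts, eye blinks and muscle noise, non-stationary spectra,
hemodynamic nonlinearity, inter-regional coupling, or realistic fMRI noise
spectra.  Passing tests therefore demonstrate that the pipeline's
estimation, selection and streaming machinery is correct under the
model's own assumptions — not that the physiological claims hold on new
human data.

## Validation battery and problem sizes

`eegfp.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: solver-vs-oracle agreement (100 random
instances, 1e-8); parameter recovery on 10 seeded 300-s sessions at
snr 10 (median truth correlation >= 0.8, median held-out prediction
r >= 0.6 — the latter mirrors the 0.6 session-quality threshold used for
real sessions); one-class recovery on 20 studies of 10 positives + 5
outliers at 240 s (>= 9/10 recovered in >= 90% of runs); common-model
superiority over 20 replicates of 6 training + 4 fresh sessions at 180 s
(one-sided sign test); streaming-batch equivalence on a 300-s stream
(1e-6); equal-area banding on 50 random spectra (within one bin); and the
feedback anchors.  The heavier batteries use a coarser CV configuration
(10 splits, 8-point lambda grid) than the 30/25 default; session lengths
and replicate counts were fixed once as a realistic desk-scale study
design.

## Numerical choices and edge cases

- Stockwell voices require an integer number of cycles on the record
  (f * duration integral); analysis records and buffers are whole seconds.
- The frequency-domain Stockwell implementation is exact for the periodic
  signal model; the test oracle is a brute-force time-domain Gaussian sum
  with periodic images.
- Ridge with lambda = 0 on rank-deficient data returns the minimum-norm
  solution with a warning; inside the CV the eigendecomposition treats
  eigenvalues below 1e-10 of the largest as null directions.
- NMSE uses the population variance of the target; a zero-variance target
  is an error.
- A constant prediction has correlation 0 by convention (with a warning).
- Correlation distance requires positive variance on both sides; a
  zero-variance finger-print vector is an error, not distance 1.
- Clustering ties (equal distances) break toward the lexicographically
  smallest session-id pair; selection ties toward the smaller session id.
- Rest references with a band sd below 1e-8 of its mean (e.g. constant
  input leaving only filter ripple) are rejected as degenerate.
- Seeds: every stochastic routine takes an explicit seed; per-session
  streams derive from (study seed, session index, stream id), so studies
  are reproducible bitwise and sessions are independent.

## Known limitations

- The greedy minimax subset selection is not exact; it is validated to be
  within 10% of the enumerated optimum at n = 12 choose 10.
- The knee criterion is a reproducible stand-in for a visual judgement;
  its fallback ratio (24 clusters per 39 sessions) is a convention.
- Offline normalization z-scores per band against the session's own (or a
  rest reference's) statistics; whether the original pipeline divided by
  a scale online is not documented, and the shared affine contract here
  is what makes streaming and batch paths commensurate.
- The per-subject t-test ignores serial correlation of the 3-s samples;
  see above.
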