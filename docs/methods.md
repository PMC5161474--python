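# Methods

`mimeg` re-implements, as a tested library, a comparison of feature-extraction
pipelines for single-trial classification of left/right-hand motor imagery
(MI) from multichannel MEG: spectral features (multitaper PSD, STFT, Morlet),
spatial filters (CSP, FBCSP, SSD, SSD+CSP), classifier evaluation,
mu-rhythm-suppression quantification, and rank-based statistical comparison of
methods. Because no public recording exists for this paradigm, the package
ships a synthetic-data generator that plants the oscillatory structure the
analysis assumes, so every stage is validated as a recovery problem.

## The decoding problem

During hand motor imagery the 10-Hz (mu, 8–12 Hz) and 20-Hz (beta, 16–24 Hz)
sensorimotor rhythms are suppressed — event-related desynchronization (ERD) —
more deeply over the hemisphere contralateral to the imagined hand, and
rebound after imagery ends (ERS). Decoding left- vs right-hand imagery
exploits the lateralization of the suppression; decoding imagery vs rest
exploits the suppression itself. A trial spans a 5-s rest period, 2 s of
preparation, 3 s of imagery cued at t = 0, and feedback; the ERD starts
about 0.5 s after the cue (reaction time) and lasts until imagery offset.

## Pipelines

Ten named pipelines are evaluated per task plus the fixed `ONLINE` pipeline
used for real-time feedback (multitaper PSD over the 3-s imagery epoch in
1-Hz bins, chi-square top-50 features, LDA):

* sensor-space time–frequency features: `PSD` (23 one-Hz bins per channel
  over the imagery epoch), `STFT` and `Morlet` (band-average power in 8–30
  Hz pooled into 1-s windows, four windows at 0–4 s for left-vs-right);
* spatial filters with log-variance features over 0.5–3.0 s: `CSP` (3+3
  components on 8–30 Hz), `FBCSP` (per-band CSP on six 4-Hz bands,
  chi-square top-18 of 36 features), `SSD` (20 or 30 components around the
  individually determined peak-suppression frequency f\*, signal band
  f\*±2 Hz against adjacent 4-Hz flanks), `SSD+CSP` (CSP on the SSD
  component signals);
* time–frequency features on CSP components: `CSP+STFT`, `CSP+Morlet`,
  `CSP+PSD`.

Within 5-fold stratified cross-validation every data-dependent step — spatial
filters, the SSD peak frequency, chi-square selection, the classifier — is
fitted on the training partitions only. Band-pass filtering with a fixed band
is per-trial and data-independent and is therefore cached per session.

### Design choices that the source description leaves open

* **Feature budget.** Feature sets wider than 50 get chi-square top-50
  selection (the online pipeline's rule), fitted per training fold; narrower
  sets are used whole. Power features are log-transformed before
  classification (chi-square is scored on the linear, non-negative values);
  log-variance pipelines are already on a log scale.
* **Rest epochs.** The imagery-vs-rest task cuts a rest epoch from the
  pre-cue interval [−4.0, −1.0) s of every trial. Both epochs derived from a
  trial share its cross-validation fold. Because rest epochs are 3 s, this
  task uses three 1-s time–frequency windows instead of four.
* **Covariance estimation.** Class covariances are averages of per-trial
  covariances with analytic Ledoit–Wolf shrinkage toward the scaled
  identity. The shrinkage intensity is estimated **at the trial level**
  (each trial's covariance is one independent observation in the published
  estimator's dispersion-vs-structure balance): band-limited epochs are
  strongly autocorrelated, and the sample-level formula — which assumes
  i.i.d. time points — under-regularizes them badly enough that CSP on SSD
  components amplifies near-empty variance directions.
* **Trace normalization.** Per-trial trace normalization (standard CSP
  practice, equalizing trial power) is applied for left-vs-right, where the
  contrast is the spatial redistribution of power. For imagery-vs-rest it is
  disabled: total band power *is* the class contrast and normalizing trials
  cancels it — with normalization on, CSP training folds fit noise
  (train accuracy 1.0, test at chance).
* **Peak-suppression frequency.** `find_suppression_peak` ranks 1-Hz bins by
  the *absolute* power decrease between baseline (−4 to −2 s) and imagery
  (1–3 s), restricted to bins whose baseline power is at least 20 % of the
  strongest bin. The relative change of the source description is near-flat
  across a rhythm line's tails and leakage bins (any bin dominated by the
  rhythm suppresses by the same ratio), so its argmin is ranked by sampling
  noise and regularly lands 2 Hz off the line, starving the SSD signal band.
* **CSP numerics.** The generalized eigenproblem `C1 w = λ(C1+C2) w` is
  solved by whitening the composite covariance and diagonalising the
  transformed class covariance; eigenvector signs are fixed so the
  largest-magnitude pattern entry is positive. SSD flank bands are adjacent
  to the signal band with no spectral gap.
* **Filtering.** Zero-phase Hamming-window FIR (symmetric kernel, centred
  convolution), length from the transition width and capped at the epoch
  length; filtering is applied to whole epochs before cropping so edge
  transients fall outside analysis windows. STFT uses 0.5-s Hann segments
  with 50 % overlap; only segments lying fully inside a pooling window
  contribute, so power steps at window edges do not smear across windows.
  Morlet wavelets use 7 cycles; the multitaper bandwidth is 2 Hz.

## Rank statistics

`friedman_test` supports one or two observations per subject–method cell.
With two replicates the `2k` observations of a subject's block are ranked
jointly and

    chi2 = 12 * sum_j (R_j − E)² / (n m² k (mk + 1)),   E = n m (mk + 1) / 2,

which reduces to the classic statistic at m = 1. Ties receive mean ranks; by
default no tie-correction divisor is applied, and `tie_correction=True`
exposes the corrected variant (equal to `scipy.stats.friedmanchisquare` at
m = 1). The bundled worked-example tables reproduce their printed chi-square
statistics under the replicated scheme (two sessions per subject, the
single-session subject dropped) — including the two within-session tables,
whose printed statistics evidently came from that same scheme. Post-hoc
comparisons are two-sided z-tests on mean-rank differences with
`SE = sqrt(k (mk+1) / (6 n))`, Bonferroni-multiplied by the number of pairs.
One-sided paired t-tests over matched fold accuracies give the
"method a better than method b" matrix; a zero-variance, zero-mean
difference yields p = 0.5 by the t = 0 convention.

## Suppression statistics

`suppression_percent` implements
`(power_MI − power_rest) / power_rest × 100 %` on multitaper band power
integrated over the band's 1-Hz bins (baseline −4 to −2 s, imagery 1–3 s),
averaging per-(epoch, channel, bin) power over bins, then epochs, then
channels — the order matters because means of ratios differ from ratios of
means. Integrated (rather than per-frequency mean) band power leaves the
ratio unchanged and makes a unit in-band sinusoid read power 1/2. Pearson
correlations relate per-session suppression to accuracy, globally or
channel by channel.

## The synthetic generator

Each rhythm–hemisphere source is a phase-diffusing oscillator: constant
amplitude within a trial (times a slow ±15 % amplitude modulation and a
per-trial log-normal gain of σ = 0.1), with Brownian phase giving a
Lorentzian line of 1.2 Hz width; hemisphere peak frequencies are offset by
±0.2 Hz. This choice is load-bearing twice over: constant-phase sinusoids
make bilateral same-band sources mutually coherent (their covariance
cross-terms then dominate CSP/SSD estimation and the eigenvectors of the
near-degenerate source pair rotate arbitrarily), while broadband noise
sources would make single-trial power estimates fluctuate with only
`2BT ≈ 10` degrees of freedom. A phase-diffusing oscillator decorrelates the
hemispheres yet keeps windowed power envelope-determined.

ERD multiplies the source power by `1 + depth` between 0.5 and 3.0 s
(raised-cosine transitions of 0.25 s), followed by a rebound; depths are set
per (class, hemisphere, rhythm) via contralateral/ipsilateral maps, so the
planted suppression percentage is exactly `100 × depth`
(`planted_truth`). Sessions default to 80 trials (the experiment's 40
training plus 40 feedback trials, pooled for offline analysis), 48 channels
on a parietal grid with Gaussian hemisphere patterns, 250 Hz sampling
(configurable up to 1 kHz).

Background: per-channel white and pink noise, spatially structured pink
sources mixed through random smooth patterns with mildly heavy-tailed
per-trial power (artifact-like transients), and a task-irrelevant 14-Hz
distractor rhythm between the two scoring bands. The noise budget was set
analytically so that unsuppressed in-band power dilutes the suppression
statistic by under ~4 percentage points at the deepest planted depth; the
structured components sit spectrally away from the 8–12 and 16–24 Hz scoring
bands.

What the generator does **not** emulate: realistic MEG forward physics,
eye/cardiac artifacts, nonstationary drift within a session, source-depth
effects, or the rich many-source background of real recordings. Two
consequences matter when reading the synthetic results. First, the planted
contrast is low-rank, stationary and spatially smooth, so sensor-space
features with chi-square selection and LDA act as an implicit spatial filter
and perform near ceiling: the real-data finding that CSP filtering *before*
time–frequency decomposition improves accuracy does not reproduce here
(CSP+STFT trails STFT by ~10 points), and attempts to recreate it with
heavier structured noise conflict with the suppression-recovery budget
above. Second, SSD+CSP is not the top method on synthetic sessions the way
it is on the real data — with only two genuine narrowband sources, keeping
20 SSD components mostly adds noise dimensions; typical synthetic sessions
land at 75–85 % left-vs-right, bracketing the 73.7 % the method averaged on
the real recordings.

## Problem sizes

The validation suite uses 40- and 80-trial sessions at 250 Hz with 12–48
channels: suppression recovery uses 20 seeds × 4 depths at 40 trials; the
qualitative method ordering uses 20 seeded 40-trial sessions; chance-level
calibration uses 200 null sessions of 12 channels at 125 Hz; eigensolver
equivalence uses 1,000 random covariance pairs of up to 8 channels. The
acceptance script runs a 3-seed-per-depth recovery and one full
planted-separability session.

## Known limitations

* Imagery-vs-rest accuracies of the spatial-filter pipelines on synthetic
  sessions (~0.6–0.8) run below the real-data table values; the synthetic
  rest segments are statistically identical to the imagery segments except
  for source power, which is a harder contrast than real rest/task
  differences.
* The replicated Friedman variant assumes exactly two sessions per subject;
  unbalanced designs are not supported.
* `AccuracyTable` requires complete tables; missing cells must be handled
  upstream.
* The FIF reader adapter (`EpochSet.from_mne_epochs`) is a thin convenience
  and assumes event-id names are the class labels.
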