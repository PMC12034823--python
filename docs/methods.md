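# Methods

## Stimulus model

The Optimum-1 generator produces blocks of `15` lead-in standards followed
by a strict standard/deviant alternation at a constant SOA of `500 ms`
(configurable). Deviants are scheduled in consecutive sets of five, each a
uniform permutation of the five types {location, intensity, frequency,
gap, duration}; a permutation whose first type equals the previous set's
last type is rejected and redrawn, which leaves each admissible permutation
set uniform and guarantees zero same-type repeats within a block. The
two-version deviant types (location, intensity, frequency) draw their
version independently with P = 0.5. With the default `60` sets per block,
a block holds 300 deviants and 315 standards, so each deviant type
constitutes exactly 10 % of the non-lead-in tones. The eight concrete
deviants carry frozen identity codes 1–8 (location-left … duration),
which index all transition matrices.

Blocks are treated as independent recordings: the no-repeat constraint is
not continued across block boundaries, and a 5 s gap separates blocks.
Sessions default to 6 blocks (≥ 1800 deviant trials, the scale of a real
recording session). One master seed spawns per-block child seeds, so event
tables are bit-reproducible.

## Ideal observer

The observer state is an 8×8 transition-count matrix plus an 8-vector of
identity occurrence counts. After each deviant, TP(Y|X) =
counts[X→Y] / occ[X]; TP is undefined (NaN, never imputed) while occ[X] = 0
and for each block's first deviant. Two per-trial conventions are
implemented because the natural-language description of "up to the current
trial" is ambiguous: `exclusive` (default — the TP of trial *t* is the
observer's prediction, computed before counting the transition into *t*)
and `inclusive` (counted first). Every result records which mode produced
it. A block boundary resets the predecessor but not the counts; learning
accumulates over the session (a per-block reset is available as an option).

## Encoded information

Signals are discretized into `B = 128` equal-width bins spanning the
relevant extrema: interior edges e_k = lo + k·(hi − lo)/B with ±∞
sentinels, value v → bin k where e_{k−1} < v ≤ e_k. Symbols are serialized
one byte each (hence B ≤ 256) and compressed with zlib/DEFLATE at level 9;
compressed sizes include the header, whose constant overhead is absorbed
by the NCD's ε allowance (0.1) and by channel-mean normalization. The
concatenation order in C(xy) is fixed — reference first, trial second —
purely for determinism (NCD is near-symmetric).

Per channel, the reference is the mean over all retained standard trials
(lead-in standards included), and the binning range spans the global
extrema of the reference and all retained deviant trials of that channel,
so all comparisons within a channel share one codebook. Normalization is
division by the channel's mean EI over included trials (making the channel
mean of normalized EI exactly 1); a subtractive mode is available since
"normalized in terms of the channel mean" admits both readings.

## HFA pipeline

Preprocessing: FIR low-pass at 180 Hz (Hamming, ≈25 Hz transition),
4th-order Butterworth band-stops at the line frequency and its 2nd/3rd
harmonics (default 50/100/150 Hz, ±2 Hz), polyphase resampling to 1 kHz —
all zero-phase (forward–backward). Epochs are 2000 ms (−750…+1250 ms) and
demeaned; events too close to the recording edge are flagged rather than
fatal.

"Eight consecutive 10-Hz bands ranging 75–145 Hz" is arithmetically
ambiguous (the span is 70 Hz); the package uses eight bands *centered* at
75, 85, …, 145 Hz (each ±5 Hz), config-overridable. Per band: 4th-order
Butterworth band-pass, Hilbert analytic amplitude, per-trial baseline-mean
subtraction (−100…0 ms). Bands are averaged, each channel is divided by
the SD of baseline samples pooled over its retained trials, and the output
is cut to 0–400 ms (400 samples at 1 kHz).

Artifact rejection runs on the preprocessed broadband epochs (it is
described before HFA extraction, and HFA would hide low-frequency
artifacts): amplitude deviating from the channel mean by > 5 SD for
strictly more than 25 consecutive ms, or spectral power exceeding the
cross-trial mean by > 5 SD for strictly more than 6 consecutive Hz. The
amplitude baseline is the channel's mean/SD over all epoch samples;
spectra use Welch with 1-second segments, giving the 1 Hz resolution the
run-length rule is stated in (a full-length periodogram would halve the
bin width and break the "consecutive Hz" count).

## TP sensitivity

Trial selection: drop each block's first 30 *tone events* (the reading of
"first 30 trials"; counting 30 *deviant* trials instead is a config
switch), trials with TP > 0.7, undefined-TP trials, and artifact-flagged
trials; all eight identities are pooled into a single regressor. Channels
with fewer than 10 remaining trials are marked unusable.

The robust estimator is IRLS with Tukey bisquare weights (c = 4.685),
OLS start, MAD/0.6745 residual scale, at most 50 iterations, convergence
at 1e−8 relative coefficient change. It is implemented directly (rather
than through a generic robust-regression fit) so that the permutation null
— up to 1000 refits per channel — runs as vectorized array operations over
the stacked permuted regressors; a unit test verifies agreement with
statsmodels' RLM/TukeyBiweight to ~1e-3 on heavy-tailed data. Degenerate
cases: zero predictor variance raises; a perfect fit (zero residual scale)
terminates with the current coefficients, so constant responses yield
slope 0.

Surrogates permute the TP regressor only, preserving both marginals while
destroying the association; the two-sided p-value uses the add-one
correction p = (1 + #{|slope₀| ≥ |slope|})/(n_perm + 1) ∈ (0, 1], which
keeps Benjamini–Hochberg valid. FDR (via statsmodels) is applied jointly
across all usable channels at q = 0.05. Per-channel RNG streams derive
from (master seed, channel index), so single channels are reproducible in
isolation.

## Synthetic data

The raw-signal generator gives every tone a stereotyped evoked response —
a half-sine amplitude envelope over 0–400 ms modulating a 110 Hz carrier.
The carrier keeps the response inside the 75–145 Hz analysis bands: a pure
low-frequency burst would be removed by the band-pass and leave nothing
for the pipeline to measure. Deviants additionally receive white noise of
amplitude a0 + a1·(1 − TP) within the response window (undefined TP → 0,
maximal surprise). The perturbation is additive noise rather than
amplitude scaling because the compression distance responds to
incompressibility, not energy: added noise guarantees a monotone link
between (1 − TP) and EI. Background noise is Gaussian with SD 1.

The trial-level generator draws normalized EI directly from
ei = α + β·TP + N(0, σ²), with defaults β = −1, α = 1, σ = 0.5 — noise on
the order of half the TP effect range, which makes single-channel
detection comfortable at session scale without being trivial. Ground-truth
parameters are returned alongside every table.

What the generators do *not* emulate: 1/f spectra, epileptiform
transients, electrode geometry, inter-subject variability, or any real
anatomical mapping (the ROI assignment in the demo pipeline is
round-robin). Passing tests therefore establish the correctness and
calibration of the *analysis*, not claims about patient data.

## Test and simulation sizes

Stochastic checks are sized to finish quickly while keeping decisive
power: null calibration uses 80 channels × 200 permutations on a 2-block
session plus a 200-channel KS uniformity check at 199 permutations;
parameter recovery uses 50 replicate noise draws on one 6-block session
(median slope within ±0.1 of β = −1 at σ = 0.5; within 5 % across
β ∈ {−2, −1, −0.5, 0} at σ = 0.25, where 0.05 absolute is used for β = 0
since a relative band is empty at zero); the raw-signal recovery check
uses one block with three TP-coupled and three uncoupled channels. The
acceptance script runs the global-null calibration at full scale
(6 blocks, 200 channels, 500 permutations).

## Known limitations

* NCD values depend on the compressor; zlib level 9 is fixed and
  deterministic, but absolute EI values are not comparable across
  different compressors or bin counts.
* The permutation test assumes exchangeability of trials under the null;
  strong temporal autocorrelation in real EI series would make it
  anticonservative. The trial-level generator draws i.i.d. noise, so this
  is untested here.
* With ~1750 usable trials and the empirical TP spread of the paradigm
  (SD ≈ 0.08), single-channel slope estimates have an SE near 0.15 at
  σ = 0.5; per-channel values should be interpreted at the population
  level, as the group statistics do.
* The EDF reader for real recordings is out of scope; inputs are the
  package's own array containers or user-supplied epoched arrays.
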