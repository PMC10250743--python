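# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic data does and does
not establish.

## Signal model and montage

All analyses assume a 4-channel sub-hairline montage (F7, Fp1, Fp2, F8)
sampled at 256 Hz in microvolts. Two device conditions are compared
throughout: a textile-electrode headband ("garment") and a metal
dry-electrode baseline ("dry"), recorded serially on the same subjects,
so every statistic is a paired comparison across subjects.

## Preprocessing

*Amplitude outliers* (resting-state tasks only) are detected per channel
by high-passing at 60 Hz (4th-order Butterworth, forward–backward),
taking the magnitude of the Hilbert analytic signal as an instantaneous
amplitude, z-scoring it, and flagging samples more than 5 SD above the
mean. Flagged samples are replaced in the original signal by linear
interpolation between nearest unflagged neighbours; runs touching an
edge take the nearest unflagged value. Decisions the procedure leaves
open, resolved here: z-scoring is per channel (noise differs by
electrode site); flags are not dilated into windows; a channel whose
supra-60 Hz envelope is below 10⁻⁴ of its RMS is treated as numerically
silent (only filter residue) and never flagged. The step is deliberately
skipped for the artifact-induction task, whose purpose is to compare
contamination levels. A second pass on cleaned data flags < 0.1% of
samples (near-idempotence), verified in tests.

*Filtering* is always a 4th-order Butterworth applied forward and
backward (zero phase; effective 8th-order magnitude — one reading of
"non-causal", documented since the alternative is ambiguous),
implemented as cascaded second-order sections with scipy's default
odd-reflection padding for stability on multi-minute records. Broadband
analysis uses 0.1–100 Hz, movement analysis 0.3–30 Hz, display traces
0.5–30 Hz.

*Trial rejection* removes an epoch iff |x| > 250 μV on any channel at
any sample — absolute value, strict inequality (a peak of exactly
250 μV survives), survivor order preserved.

## Spectral analysis

Welch PSD with a 1 s Hamming window zero-padded to 1024 points
(0.25 Hz bins at 256 Hz) and 30 ms of overlap. The 30 ms figure is
honoured literally — 8 samples, i.e. near-disjoint windows, which is
unusual but well-defined; a conventional 30–50% overlap is one config
field away (`AnalysisConfig.psd_overlap_s`). Segment periodograms are
averaged in linear power; log10 is applied last (a constant offset,
irrelevant to paired differences); power is floored at 1e-20 μV²/Hz so
degenerate inputs stay finite; the grid is truncated to the analyzed
0–60 Hz.

Band power: log power is first averaged over the four electrodes per bin
("average electrode"), then over the bins of each band. A bin belongs to
a band iff lo ≤ center ≤ hi; at 0.25 Hz spacing adjacent bands (3 vs
4 Hz) share no bins.

## Time-frequency analysis

Complex Morlet wavelets over 5–30 Hz in 0.25 Hz steps (101
frequencies), constant n_cycles = 7 — the constant-Q convention for
sensorimotor-rhythm work; the cycle count is a package choice, exposed
as a parameter. Power is averaged over trials *before* baseline
normalization (per-trial normalization gives different maps); the
ERD/ERS map is the percent change against the per-frequency mean power
in [−5, −2] s. Epochs span [−7, 5] s around the movement cue so the
baseline sits inside the preceding rest period. Bins within one wavelet
half-length of an epoch edge are flagged in `TFR.edge_mask` but retained
everywhere — no statistic excludes them. The bin-wise device comparison
is an exact two-sided paired Wilcoxon per (f, t) bin with no
multiple-comparison correction; the reported masked map is
(dry − garment) with non-significant bins zeroed.

For untied continuous data the per-bin exact p depends only on (n, W),
so the bin-wise test is vectorized through a precomputed null table;
bins with zeros or ties fall back to the general tie-aware test. The two
routes agree to 1e-12 in tests.

## Wilcoxon signed-rank test

Differences d = x − y; zero differences discarded (classic convention,
not Pratt); midranks for tied |d|; W = sum of positive signed ranks.
For m ≤ 25 effective pairs the exact null distribution is built by
dynamic programming over the (doubled, integer) rank multiset —
equivalent to enumerating all 2^m sign assignments, in polynomial time,
and correct under ties. Two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
Above the cutoff: normal approximation with tie correction and
continuity correction. All-zero differences return p = 1 by convention.
Two-sided tests are the default everywhere; direction is reported
separately as the sign of the median paired difference.

## Impedance model

Skin-electrode interfaces are dispersive; a single-dispersion Cole
magnitude model is used as generator and summary:
|Z(f)| = |R_s + R_p / (1 + (i·2πf·τ)^α)| (principal branch). Defaults
α = 0.8, τ = 0.16 s place the dispersion inside the measured
0.1–30 Hz decade. Per technology, (R_s, R_p) are solved by bounded
least squares so the curve reproduces the technology's average |Z| at 1
and 10 Hz within 0.5%. The measurement grid is 10 log-spaced points
spanning 0.1–30 Hz inclusive. Repeated measurements are modeled as the
calibrated curve times i.i.d. log-normal noise with σ_log = 0.2
(a ±20% spread, realistic for repeat electrode placements), normalized
to unit mean so pooled averages are unbiased. Queries off the grid use
log-log linear interpolation (exact for power laws); the 5 kΩ wet-EEG
threshold check is a strict `<`. Only magnitudes are modeled — phase
is not part of the data model. Note the printed technology averages act
as calibration anchors for the generator; they are not recomputable
results, since no raw impedance sweeps ship with the package.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Background:** 1/f^γ pink noise (γ ≈ 1 per subject, range 0.8–1.2),
  synthesized by frequency-domain shaping of white noise, mixed from a
  shared source so inter-channel correlation is ρ ≈ 0.7 (shared frontal
  sources); each channel normalized to the subject's RMS scale
  (8–14 μV).
- **Alpha rhythm:** a coherent sinusoid at the subject's alpha frequency
  (9–11 Hz); eyes-closed amplitude 6–12 μV, eyes-open 20–50% of that.
- **Mains:** 50 Hz sinusoid; garment amplitude 2× dry (3 vs 1.5 μV) —
  the device contrast that makes the 45–55 Hz band an impedance
  surrogate.
- **Blinks:** 300 ms raised-cosine pulses at ~0.25 Hz with Fp:F
  amplitude ratio 3:1, eyes-open only.
- **Movement sessions:** alternating rest (7 ± 1 s uniform) and 5 s
  movement periods in 4 blocks of 20 trials; during movement the
  8–30 Hz content (brick-wall FFT split of the background, plus the
  alpha rhythm) is scaled by √(1−d) with 0.2 s cosine ramps, so band
  power drops by exactly the ERD depth d; an instructed blink follows
  each movement.
- **Artifact sessions:** nine scripted 10 s actions; large-motion
  actions are broadband (0.5–45 Hz) bursts, ocular actions are
  frontopolar-weighted pulses/deflections, jaw is EMG-like 15–60 Hz
  noise, all scaled by the device's artifact gain (garment 2.5× dry).
  The per-action amplitudes are free generator parameters, not
  estimates of real per-action artifact sizes.

Everything is reproducible from (profiles, seed). The calibrated device
contrast reproduces, at n = 10, the expected significance pattern:
resting-state delta–beta comparisons null, artifact-induction delta–beta
and all mains-band comparisons significant.

What passing tests on this data do **not** show: performance on real
recordings with non-stationary rhythms, heterogeneous artifact
morphologies, electrode drift, or reference asymmetries. The generator
validates the *pipeline's* correctness and calibration, not the
hardware comparison itself.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions chosen as the
package's own verification sizes: 40–180 s resting recordings, 50-trial
ERD recovery for one subject, 10-subject cohorts over 5 seeds for the
significance pattern, 500 replicates on a 10×20 grid for the bin-wise
type-I error, 10,000 draws for Wilcoxon size calibration. Wavelet power
is decimated 8× in time for map statistics (the maps are smooth at the
7-cycle bandwidth, so decimation does not change band means). The exact
Wilcoxon's discrete size at nominal α = 0.05, n = 10 is 0.048 — tests
on rejection rates use tolerances aware of this discreteness.

ERD recovery lands near −27% for an injected d = 0.30: Morlet bins at
8–12 Hz admit some unmodulated theta-side energy through their spectral
bandwidth (≈ f/7), diluting the measured drop. This is a property of
the constant-Q measurement, not a generator error, and sits inside the
±5-point recovery tolerance.

## Known limitations

- EDF support targets the common case (single rate, 16-bit EDF/EDF+C);
  BDF and mixed-rate layouts are rejected explicitly.
- The exact-test fast path assumes subject-wise exchangeability only;
  no cluster or permutation correction is offered (by design, matching
  the uncorrected bin-wise convention).
- The Cole model is a magnitude-only phenomenological fit; it should
  not be read as an equivalent-circuit identification of the interface.
- The comfort/ergonomics questionnaire side of a device validation is
  out of scope; its Likert tables can be fed directly to
  `wilcoxon_signed_rank`.
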