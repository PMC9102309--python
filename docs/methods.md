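# Methods

## Signal model

A recorded single-channel signal is modelled as `x(n) = s(n) + v(n)`: a
near-Gaussian, approximately stationary neural/hemodynamic source `s` plus a
motion artifact `v` that is temporally localized, non-Gaussian and has high
local variance.  In the wavelet packet domain the artifact's coefficients are
sparse and large, which motivates correcting the signal sub-band-wise rather
than sample-wise.

## Wavelet packet stage

`wp_decompose` applies the full dyadic packet recursion — both the
approximation and the detail branch are re-split at every level — with an
orthonormal QMF pair, giving `2^j` terminal nodes at level `j`.
Design choices:

* **Level `j = 4` by default** (16 sub-bands).  `j = 3` gives 8 bands, too
  coarse to separate artifact-dominated from signal-dominated content;
  `j = 5` gives 32 bands at double the cost with no observed benefit.
* **Boundary handling is periodization.**  This keeps the transform exactly
  orthonormal, so perfect reconstruction and Parseval hold to round-off
  (≤1e−14 observed, tested at 1e−8/1e−6), and the sub-band components sum
  exactly to the input.  Inputs whose length is not a multiple of `2^j` are
  padded symmetrically and trimmed after synthesis; the padding never enters
  metric computation.
* **Nodes are frequency-ordered** (Gray-code/sequency order), so column 0 is
  the approximation band `S_{2^j−1}` with the lowest centre frequency and the
  remaining columns are `D_1 … D_{2^j−1}` in ascending frequency.  Natural
  (Paley) order would interleave the bands.
* **Fejér-Korovkin filters.**  fk4/fk6/fk8 are not shipped by PyWavelets, so
  they are built at import: the squared magnitude response is the
  Fejér-Korovkin-kernel smoothing of the ideal half-band square wave
  (kernel orders 3, 6 and 8 for lengths 4, 6 and 8; Nielsen, *J. Approx.
  Theory* 108, 2001), factorized spectrally with the root at z = −1 deflated
  analytically and the minimum-phase factor selected.  The result matches the
  published tables to their printed precision (~1e−8, limited by the
  ill-conditioned double root on the unit circle) and satisfies the
  orthonormality invariants to ~1e−15.

A caveat documented by the tests: high wavelet-packet nodes of short filters
localize poorly in frequency.  A tone at the centre of band 5 (44 Hz at
fs = 256, j = 4) keeps only ~34 % (db1) to ~85 % (sym6) of its energy in its
nominal column, although the nominal column is always the energy argmax.
Low-band tones concentrate ≥ 90 % as expected.

## CCA stage

The 16 sub-band signals form the rows of `X`.  The surrogate set is the
neighbour sum `y_t = x_{t−1} + x_{t+1}` (implemented literally; the
covariances use the interior samples, `T − 2` columns).  Only the x-side
eigenproblem is solved, in whitened coordinates: with `Lx` the Cholesky
factor of the (ridge-regularized) `Cxx`, the symmetric matrix
`Lx⁻¹ Cxy Cyy⁻¹ Cyx Lx⁻ᵀ` is passed to a symmetric eigensolver, which keeps
all eigenvalues real; `ρ` are the square roots of the eigenvalues, clipped to
[0, 1].  Numerical choices:

* **Ridge `1e−10 · trace/M`** on both within-set covariances: sub-band
  channels can be near-collinear after narrow-band preprocessing.
* **Unit-variance sources, sign fixed** so each source correlates
  non-negatively with the summed channels.  Both are conventions only — the
  back-projection `W⁻¹·S` is invariant to them (tested).
* **`W⁻¹` via pseudo-inverse** to tolerate rank deficiency from regularized
  fits.

Component removal zeroes rows of `S`; re-mixing restores channel means, and
`collapse` sums the channels back into one signal.  Removing every component
is refused (the result would silently be the mean-only signal).

## Component selection

* **Reference-guided greedy** (`greedy_select`): hill-climbing over
  single-component removals, evaluated cumulatively against the current
  selection; the removal with the largest strict improvement (> 1e−12, a
  float-noise guard) in full-record Pearson correlation with the reference is
  committed each pass, ties broken toward the lowest index.  The same
  contract serves wavelet sub-bands and CCA sources.  On planted-artifact
  test families with M ≤ 6 the greedy optimum matches exhaustive search over
  all subsets (tested); greedy is not globally optimal in general.
  One-at-a-time evaluation against the original signal (rather than
  cumulative) was the other defensible reading; cumulative was chosen because
  it is the variant whose fixed point is a local optimum of the final
  objective.
* **Approximation-drop** (`approx_drop_select`): discard column 0 only,
  consulting no reference; the reference is then used only to score the
  result.  Defined for wavelet sub-bands; the pipeline rejects it for CCA
  sources.

## Preprocessing

EEG is decimated 2048 → 256 Hz (all clinical EEG bands, delta 1–4 Hz through
gamma 30–80 Hz, lie below the 128 Hz target Nyquist).  Integer decimation
uses a zero-phase FIR anti-alias filter (Kaiser β = 8, cutoff at 80 % of the
target Nyquist, 24·q + 1 taps applied forward-backward), giving > 60 dB
stopband attenuation; rational ratios fall back to polyphase resampling.
Power-line removal is a third-order Butterworth band-stop at 50 Hz and every
harmonic below Nyquist, 2 Hz wide (narrow enough to spare gamma content),
applied forward-backward.  When the notch centre is at or above Nyquist — the
25 Hz fNIRS case — the record is returned unchanged with a warning, since the
literal operation is undefined there.  Baseline drift is removed by
subtracting a least-squares polynomial (order 6 by default, configurable;
abscissa rescaled to [−1, 1] for conditioning).  All stages are linear and
zero-phase, and both channels of a pair are always processed identically, so
the metrics compare like with like.  Metrics are computed against the
preprocessed reference over the whole record.

## Metrics

`delta_snr` defaults to error-variance semantics,
`10·log10(var(ref−corrupted)/var(ref−cleaned))`; the variance of the
reference cancels in the difference of SNRs and is computed only for
reporting.  A literal mode using `var(corrupted)/var(cleaned)` is selectable,
because the defining sentence can be read either way; the error subscripts
point to the error-variance reading, which is the default.  Population
variances are used throughout (the convention cancels in ratios).  A
denominator at round-off level is floored to zero and reported as a ±300 dB
sentinel with a warning rather than ±∞.  `eta_ideal` (ρ_clean = 1) is the
default report — a worst-case convention that never claims more reduction
than the general form when ρ_after lies between ρ_before and ρ_clean;
`eta_general` is available when an epoch-derived ρ_clean is supplied, and is
reported as computed even when it exceeds 100 %.

## Synthetic benchmark generator

The generator emulates the two-channel validation protocol: two
simultaneously recorded, highly correlated channels, one disturbed by motion
for 10–25 s at regular 120 s intervals over 540 s records (EEG 2048 Hz,
fNIRS 25 Hz).

* **Clean EEG**: band-limited Gaussian noise in the five canonical bands with
  1/f-weighted band powers (amplitude ∝ 1/√f_centre); bands at or above
  Nyquist are skipped for low test rates.  **Clean fNIRS**: slow hemodynamic
  oscillation (< 0.1 Hz) + ~1.1 Hz cardiac component + low-level broadband
  noise.
* **Artifact**: per burst, an integrated-noise walk windowed by a Tukey
  (tapered-cosine) envelope.  The walk's 1/f² spectrum places ≈ 97 % of the
  artifact energy below 2 Hz (tested ≥ 90 %), i.e. inside the 0–8 Hz
  approximation band for EEG at 256 Hz and j = 4, so the approximation-drop
  rule has a recoverable planted target.  Real artifacts are physically
  induced and broader-band; this model captures the defining properties
  (temporal localization, smoothness, high local variance, non-Gaussianity)
  but not electrode-pop transients or amplifier saturation.
* **Amplitude**: `artifact_amplitude` is the whole-record artifact-RMS /
  clean-RMS ratio (default 3, i.e. bursts are locally ≈ 9× the clean RMS at
  the ≈ 11 % duty cycle).  Electrode-motion artifacts dwarf the underlying
  EEG, and the record-level convention keeps ρ_before in the range where
  correction is both needed and measurable; a per-burst convention would
  leave the average artifact power merely equal to the signal power.
* **Reference**: equals the clean signal exactly at the default
  `sensor_noise_level = 0`, making ρ_clean = 1 and matching the idealized η;
  a nonzero level exercises the general form.
* Separate child RNG streams drive the clean signal, the artifact shape and
  the sensor noise, so changing the amplitude rescales the artifact without
  altering any draws; ρ_before is monotone in the amplitude (tested).

## What the synthetic benchmark can and cannot show

On these synthetic pairs the single-stage method with either selection rule
reliably removes the planted artifact (η > 0 and ΔSNR > 0 on every record of
a 20-seed batch; ≈ 31 % and ≈ 11 dB at the defaults).  The two-stage method
also always improves the signal, but on average it trails the single-stage
method (≈ 22 % vs ≈ 31 %).  This is a geometric property of the synthetic
model, not an implementation defect: the sub-band components of a single
signal are *exactly* mutually orthogonal (projections onto orthogonal
subspaces), so an artifact confined to one sub-band presents a channel-space
geometry in which axis-aligned sub-band removal is optimal among linear
component removals, and any rotated (CCA) basis can at best match it.  This
was verified by exhaustive best-subset search over all 2^16 removals in both
bases, and the CCA machinery itself is validated independently (canonical
correlations match a whitening+SVD oracle to ~1e−11; removing the top source
of a planted rank-1 cross-channel artifact strips > 99 % of its band energy).
On real recordings — where artifact energy spreads across bands, records are
nonstationary and the greedy search over raw sub-bands can stall in poor
local optima — the two-stage method has room to do better; passing the
synthetic tests therefore validates correctness of every stage, not the
real-data ranking of the two methods.

## Problem sizes

The default test suite analyses whole 540 s records (≈ 1.1 M samples at
2048 Hz, 138 240 after decimation) end-to-end, 20 seeds per batch, matching
the benchmark's record length; unit tests use shorter records and lower rates
where the property under test allows it.

## Known limitations

* Selection needs a reference channel except for the approximation-drop rule;
  the autocorrelation-based automatic selector from the literature is out of
  scope.
* No native reader for binary PhysioNet/WFDB records; input is CSV.
* Whole-record processing only (no streaming/windowed mode).
* The fNIRS synthetic model is not a physiologically validated forward model;
  at 25 Hz the approximation band (0–0.78 Hz at j = 4) contains the dominant
  hemodynamic signal, so reference-guided selection often correctly declines
  to remove anything on synthetic fNIRS pairs.
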