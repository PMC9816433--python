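# Methods

## The problem being modelled

Inside an MR scanner, EEG picks up two artifacts. The gradient artifact
(GA) is induced by gradient switching: it is orders of magnitude larger
than EEG, but locked to the TR and highly reproducible, so sliding-window
average artifact subtraction (AAS) removes it almost completely. The
ballistocardiographic (BCG) artifact is driven by cardiac pulsation moving
the electrodes in the static field: its main deflection follows the ECG R
wave by roughly 210 ms, its power concentrates at cardiac harmonics within
1-15 Hz, and it varies from beat to beat, so every correction strategy
leaves residuals, removes signal, or both. This package quantifies that
trade-off on simulated recordings where the clean EEG is known exactly.

## Synthetic data model

A subject is the sample-wise sum `contaminated = clean + BCG + GA` on the
18 10-20 electrodes (Cz reference held as metadata), plus an ECG channel.

**Clean EEG.** Per channel, 1/f-shaped Gaussian noise (exponent 1, flat
below 1 Hz, 10 µV RMS) plus a single alpha source at 10 Hz projected
through a posterior topography (O1/O2 = 1.0 down to T5/T6 = 0.5, zero
frontally). The alpha envelope follows alternating 20-s eyes-closed /
eyes-open blocks (starting closed, 0.5-s raised-cosine transitions) with
amplitudes 15·√3 µV (EC) and 15 µV (EO), so the true EC/EO alpha power
ratio is (A_EC/A_EO)² = 3. The oscillation's phase performs a random walk
(2 rad/√s, a ~0.6-Hz linewidth): a mathematically pure sinusoid would be
exactly TR-periodic (20 cycles per 2-s TR) and would be subtracted by
gradient AAS — a coherence no physiological rhythm has. The empirical
ratio measured on clean data is ~2.85-2.9 rather than 3.0 because the 1/f
background contributes equally to both conditions.

**ECG.** A Gaussian-bump PQRST template (R peak 1 mV) placed at R times
drawn with RR = 0.9 ± 0.1 s (uniform jitter); the generator returns the
exact R-peak train as ground truth.

**BCG artifact.** Each heartbeat contributes five damped oscillatory
components (3.3, 6.6, 9.9, 13.6 Hz plus a small 35-Hz transient; relative
amplitudes 0.75/0.95/0.5/0.45/0.15; rises 0.1-0.2 s, decays 0.12-0.3 s,
cosine-faded at the 0.6-s cycle end). The waveform is anchored so its
global maximum falls ~210 ms after the R wave. Per cycle and per component
the amplitude is multiplied by `1 + 0.1·U(-1,1)`. Each component has its
own left-right antisymmetric topography (sign flip across the midline,
higher-frequency components weighted posteriorly), giving the artifact a
spatial rank of ~5 — so ICA plausibly splits it over several components,
as it does on real data. With these choices the pooled artifact spectrum
keeps ≥95% of its power in 1-15 Hz, theta and slow beta are the most
inflated bands after contamination, and occipital alpha-band contamination
is strong enough to pull the measured EC/EO ratio from ~2.9 down to
~1.1-1.5. The peak amplitude is 150 µV on the strongest channel.

**Gradient artifact.** One TR-long comb of slice-frequency harmonics
(30 slices / 2-s TR → 15 Hz fundamental), tiled bit-identically across
TRs, scaled to 50× the clean RMS, with a fixed per-channel gain in
[0.7, 1.3]. Perfectly periodic by default (no drift), so AAS cancellation
is exact — GA residual structure is deliberately not modelled.

**BOLD.** A 10×10×10 voxel grid over 120 volumes (TR 2 s). The per-epoch
clean O1 alpha power series is convolved with the gamma HRF and
mean-centered; 10% of voxels receive it with coefficient β = −0.01 (BOLD
a.u. per µV²) on top of AR(1) noise (φ = 0.3, innovation SD 1.0),
corresponding to a coupled-voxel correlation of roughly −0.6. The coupled
voxel set is a fixed function of the grid shape, shared by all subjects of
a cohort, so group permutation across subjects has a common effect locus.

**What the simulator does not emulate** (so what passing tests do not
show): eye blinks, head motion, helium-pump noise, GA residual drift,
beat-to-beat BCG *waveform* (as opposed to amplitude) changes, volume
conduction of a realistic head model, and spatially correlated EEG
background. Results on real recordings will be harder than on this
generator, particularly for methods whose failure mode is beat-shape
variability (AAS) or component mixing (ICA).

## Correction methods

Artifact epochs for cardiac methods span `R + delay − 0.25·RR̃` to
`R + delay + 0.75·RR̃` (RR̃ = median RR, delay = 210 ms); where epochs
overlap, ownership is truncated at the midpoint so each sample is
corrected by exactly one cycle.

* **AAS** subtracts the unweighted mean of the 21 nearest cycles
  (5 nearest volumes for GA), centered and edge-truncated. An optional
  per-cycle least-squares rescaling exists but is off by default; the
  unweighted template keeps the operator linear, which also makes PROJIC
  with all components selected algebraically identical to channel-space
  AAS.
* **OBS** builds, per channel, the matrix of aligned cycles, takes the
  mean waveform plus the top 4 principal components of the
  mean-subtracted matrix, least-squares fits that 5-column basis to every
  cycle and subtracts the fit. `n_pcs = 0` is the identity. The EEG
  distortion of OBS is the projection of the EEG onto this basis
  (including the part of the sample PCs that overfits epoch noise);
  measured on simulated data it is on the order of a few percent of EEG
  power.
* **ICA** uses FastICA (seeded, hence deterministic). The unmixing matrix
  is estimated on every 4th sample — after the 1-50 Hz band-pass a
  1000-Hz record is ~10× oversampled — and applied at full rate;
  `fit_decimate=1` restores a full fit. Components are scored on three
  criteria: (1) cardiac locking — RMS of the R-locked cycle average
  against a null of circularly shifted R trains (199 shifts, select at
  p < 0.01); (2) harmonic spectrum — periodogram mass within ±0.2·f₀ of
  the first three cardiac harmonics over the mass at the half-harmonic
  neighbors (select at ratio > 2); (3) topography — a polarity-inversion
  index over left-right and anterior-posterior electrode pairs
  (−Σaᵢaⱼ normalized; 1 = perfect inversion; select at > 0.5). A
  component is removed only if all three pass. Thresholds are
  configurable and logged in the correction report.
* **AAS-ICA / OBS-ICA** run the channel-space method first, then ICA
  removal; with zero components selected they equal the first stage.
* **PROJIC** applies AAS or OBS to the selected IC time series only and
  remixes through the mixing matrix; unselected sources are untouched
  sample-for-sample.
* **IFE** inverts the logic: it *keeps* only components with EC/EO
  source alpha-power ratio > 1.5, a Savitzky-Golay-smoothed spectral peak
  inside 8-12 Hz, and posterior share of |mixing weights| > 0.5, and
  reconstructs from those alone.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (1-50 Hz, forward-backward);
2-s epochs that never straddle an EC/EO block boundary; peak-to-peak epoch
rejection (the pipeline default is 500 µV — rejection runs before BCG
correction, so the threshold must sit above the ~150-µV artifact and
targets gross movement/blink transients, which this simulator does not
generate); a Pan-Tompkins-style QRS detector (5-15 Hz band-pass, squared
derivative, 150-ms integration, adaptive median threshold, refinement to
the local maximum of the absolute band-passed signal, 0.3-s refractory
period) that is polarity- and scale-invariant.

## Spectral metrics

Rectangular-window FFT power spectra of 2-s epochs (0.5-Hz bins), with
`sum(power) = mean(x²)` (Parseval). Bands are the contiguous half-open
partition [1,4), [4,8), [8,13), [13,18), [18,31), [31,50] Hz so every bin
between the printed integer band edges is assigned deterministically and
relative powers sum to 1; the relative-power denominator is the partition
total. Percent change is `(inside/outside)·100 − 100`. The alpha
descriptor smooths the mean spectrum with a Savitzky-Golay filter (frame
11, order 5), takes the highest interior local maximum in 7-13 Hz that
exceeds both range endpoints (otherwise peak and CoG are missing and a
quality flag is set), and computes the CoG as the power-weighted mean
frequency over the range. Absolute powers are log10-transformed before
ANOVA.

## Statistics

`rm_anova` delegates the omnibus one-way within-subject ANOVA to pingouin
and reports F at Greenhouse-Geisser-corrected degrees of freedom (ε is
clamped to [1/(k−1), 1]; k = 2 or degenerate designs fall back to ε = 1,
identical conditions to F = 0). Post-hoc contrasts are paired t-tests of
each method against the outside-scanner reference only, Bonferroni-scaled
and capped at 1. The hand-computed sums-of-squares and ε trace formula
serve as an independent oracle in the tests.

## EEG-informed fMRI

The predictor is the per-epoch alpha absolute power of O1 or O2 (chosen
automatically as the channel with the larger EC/EO ratio), with rejected
epochs replaced by the mean of the nearest kept neighbors (single
neighbor at the boundaries), convolved with a unit-sum gamma-density HRF
(mode 6 s, scale 1.2 s, 32-s support; convolution starts in steady state
via first-value padding so constant power gives a constant predictor),
sampled at the TR grid and mean-centered. The voxelwise GLM regresses
BOLD on [intercept, linear and quadratic drift, predictor]; an AR(1)
coefficient estimated from OLS residuals drives Cochrane-Orcutt
prewhitening (voxels batched on a 0.01 ρ grid), without which the null
uncorrected p < 0.05 rate under the generator's AR(1) noise is ~0.11
instead of ~0.05. The negative contrast (β < 0) is the default; the
significance mask controls multiplicity with Benjamini-Hochberg FDR
(Bonferroni selectable) — the standard voxelwise choice with cluster
enhancement out of scope. Group inference is a one-sample t with
sign-flipping max-statistic permutation, switching to exhaustive
enumeration when the permutation budget covers all 2^n sign patterns.

## Problem sizes and numerical choices

Default simulations are 240 s at 1000 Hz (120 volumes); the acceptance
script uses 10-minute recordings for the cancellation and QRS checks and
a 20-subject cohort for the end-to-end checks, which keeps the whole run
in the minutes range on one core. AAS/OBS edge cycles without a complete
template window are left uncorrected (and excluded from cancellation
measurements); EDF output quantizes to 16 bits over a symmetric
per-channel range (ECG stored in mV, EEG in µV); FastICA runs with
tol 1e-4, max 1000 iterations, unit-variance whitening. Known numerical
caveats: the percent-change round trip loses ~8 digits at extreme power
ratios, and AAS inherently leaks mean-of-window EEG into its template
(RMS ~ σ/√w, i.e. ~45% of EEG RMS for a 5-volume window — the price of a
short, adaptive window; the leaked component is uncorrelated with the
concurrent EEG and mostly inflates broadband power estimates slightly).
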