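# bcg-preserve

EEG recorded during simultaneous EEG-fMRI is contaminated by two large
artifacts: the gradient artifact (GA), locked to each fMRI volume (TR), and
the ballistocardiographic (BCG) artifact, a cardiac-pulse-driven electrode
motion artifact whose main deflection follows the ECG R wave by ~210 ms and
whose power concentrates at cardiac harmonics between 1 and 15 Hz.
Correcting the BCG artifact while *preserving* the underlying EEG — its
band powers, its individual alpha peak, its eyes-closed/eyes-open (EC-EO)
alpha reactivity, and its value as a BOLD predictor — is the hard part, and
different correction strategies trade artifact removal against signal loss
differently.

`bcg-preserve` is a benchmarking toolkit for exactly that question. It
provides:

* a **ground-truth simulator**: 18-channel 10-20 EEG at 1000 Hz with 1/f
  background and a posterior alpha rhythm modulated by 20-s EC/EO blocks, a
  jittered-RR ECG, a cardiac-locked multi-harmonic BCG artifact with
  left-right polarity-inverted topography, a TR-locked gradient artifact,
  and a BOLD voxel grid negatively coupled to epoch-wise alpha power
  through a gamma HRF (contaminated = clean + BCG + GA, exactly);
* the standard **correction family**: sliding-window average artifact
  subtraction (AAS) for GA (5 volumes) and BCG (21 cardiac cycles, 210-ms
  delay), optimal basis set (OBS, mean + 4 PCs per channel), ICA with
  automated artifact-component selection (cardiac locking, harmonic
  spectrum, topographic polarity inversion), the combinations AAS-ICA and
  OBS-ICA, PROJIC (AAS/OBS applied to selected IC time series), and ICA
  feature extraction (IFE, keeping only alpha components);
* **spectral metrics**: FFT band powers over delta/theta/alpha/slow
  beta/fast beta/gamma, percent change
  `(inside/outside)*100 - 100`, the occipital EC-EO alpha power ratio, and
  the individual alpha peak / center of gravity via Savitzky-Golay
  smoothing (frame 11, order 5, 7-13 Hz search);
* **inference**: one-way repeated-measures ANOVA with Greenhouse-Geisser
  correction and Bonferroni post-hocs against an outside-scanner reference;
* **EEG-informed fMRI**: per-epoch alpha power -> neighbor interpolation ->
  gamma-HRF convolution -> mean-centered predictor; voxelwise prewhitened
  GLM with a negative contrast; sign-flip max-statistic group permutation.

## Worked example

```python
from bcg_preserve import (SimulationConfig, assemble_subject, ga_aas,
                          bandpass, fit_ica, ife_alpha, epoch,
                          ec_eo_alpha_ratio)
from bcg_preserve.core_io import Recording

cfg = SimulationConfig(seed=7)              # 240 s, EC amp = sqrt(3) x EO amp
rec, truth = assemble_subject(cfg)          # contaminated 18-ch EEG + ECG

eeg = rec.pick(list(cfg.channels))
clean_ga, _ = ga_aas(eeg)                   # gradient artifact: 5-TR AAS
filt = bandpass(clean_ga, 1, 50)

ev = [e for e in rec.events if "ONSET" in e.label]
print(ec_eo_alpha_ratio(epoch(Recording(list(cfg.channels), cfg.fs,
                                        filt.data, ev), 2.0)))
# 1.263  <- BCG contamination flattens the EC/EO alpha contrast (truth: 3.0)

ica = fit_ica(filt, seed=7)
ife, report = ife_alpha(ica, rec.get_events("EC_ONSET"),
                        rec.get_events("EO_ONSET"), cfg.fs)
print(report.retained)
# [11]   <- one alpha component retained (EC-reactive, ~10-Hz peak, posterior)
print(ec_eo_alpha_ratio(epoch(Recording(list(cfg.channels), cfg.fs,
                                        ife.data, ev), 2.0)))
# 2.668  <- the retained-alpha reconstruction restores the reactivity
```

The numbers above are the output of this exact snippet: the uncorrected
ratio collapses toward 1 because BCG harmonics add alpha-band power equally
to both conditions, while the IFE reconstruction recovers a ratio within
~11% of the configured ground truth of 3.

A full cohort run (simulate -> correct with several methods -> spectra ->
ANOVA -> GLM) is one call or one command:

```bash
bcg-preserve run-all --seed 1 --subjects 3 --methods none,aas --out results/
```

which writes `spectral.csv`, `percent_change.csv`, `ratios.csv`,
`anova.csv`, `glm.csv` and a run manifest.

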