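# stressmux

Multimodal cold-pressor habituation analysis pipeline: synthetic
physiological-session generation with ground truth, beat-level
cardiovascular feature extraction, continuous HF heart-rate-variability
estimation, pupil and EEG band-power reduction, and a pointwise
permutation-null condition × trial statistical framework with
interaction-gated habituation contrasts.

## What it does

A study consists of paired **treatment** and **control** sessions per
subject, each with five 195-s trials (40 s baseline, 25 s prep, 90 s
immersion, 40 s recovery). The package covers the full loop:

- **`stressmux.synth`** — simulates complete sessions: ECG / dZ/dt / Z0
  impedance waveforms with known fiducials, continuous blood pressure,
  binocular pupil traces with blink dropouts, multichannel EEG with
  band-limited oscillators, per-trial pain ratings and three cortisol
  samples. Condition effects and multiplicative per-trial habituation
  (`delta · h^(trial-1)`) are configurable per measure, and every dataset
  ships with ground-truth tables for parameter-recovery tests. A
  panel-level shortcut (`simulate_measure_panel`) draws 1-Hz panels
  directly for calibration studies.
- **`stressmux.cardio`** — R-peak detection, Q/B/X fiducial location,
  15-s moving-ensemble averaging, Kubicek stroke volume, pressure
  measures (SBP/DBP/MAP/TPR), respiration estimation from Z0 and
  per-subject respiration residualization, 1-Hz resampling to the
  195-point trial grid.
- **`stressmux.hrv`** — trailing-32-s least-squares spectral HF power
  (0.15–0.40 Hz) on the R-point sequence, log-transformed; the first 32 s
  of each trial (80% of the baseline epoch) carry no estimate.
- **`stressmux.pupil`** — binocular averaging, blink-gap interpolation,
  1-s binning, missing-trial subject rejection, per-subject 0–1
  normalization, optional 5-s display smoothing.
- **`stressmux.eeg`** — bad-channel QC (flatline / amplitude /
  reconstruction-correlation rules), average referencing with
  spherical-spline interpolation, Hann-windowed 1 Hz × 1 s ERSP grids,
  and band (delta/theta/alpha/beta) × period (baseline/early/mid/late/
  recovery) reduction.
- **`stressmux.stats`** — baseline correction over the final 15 s of
  baseline, vectorised within-subject ANOVA, permutation nulls
  (condition-label swaps within participants, trial-label shuffles,
  sign-flip paired contrasts), the pointwise framework with
  interaction-gated T1vT5 / T1vT3 / T3vT5 contrasts, the three-way
  pre/post-baseline ANOVA, and scalar analyses (pain, pupil immersion
  average, electrode-wise EEG panels, cortisol mixed ANOVA with AM/PM
  start time).
- **`stressmux.report`** — trial time-course figures with stacked
  significance bars (every bar interval also written as CSV) and the
  resting-baseline summary table.

## CLI

```sh
stressmux simulate --subjects 8 --seed 1 --out scratch/sim
stressmux extract  --in scratch/sim --out scratch/panels
stressmux stats    --panel scratch/panels/panel_HR.csv \
                   --analysis corrected --nperm 1000 --seed 1 \
                   --out scratch/stats
stressmux report   --panel scratch/panels/panel_HR.csv \
                   --tracks scratch/stats/HR_corrected_tracks.csv \
                   --out scratch/figs
```

Panels are tidy CSV (`subject,condition,trial,measure,t,value,mask`);
sessions are stored as HDF5 (one group per trial, one dataset per channel
with a sampling-rate attribute) or per-channel CSV.

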