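# boldosc — spectral signatures of sleep in BOLD fMRI

During the descent from wakefulness into NREM sleep, the frequency content
of the fMRI BOLD signal reorganises: a scale-free 1/f spectrum acquires two
distinct oscillatory peaks — a low-frequency (LF) oscillation below 0.1 Hz
(typically 0.04–0.07 Hz), prominent in light/intermediate sleep, and a
higher-frequency (HF) oscillation above 0.1 Hz (typically 0.15–0.18 Hz),
prominent in deep sleep. Their power time courses track EEG spindle and
slow-wave activity respectively, making them candidate *local* markers of
sleep that can be read out region by region, with full brain coverage.

`boldosc` is a tested reimplementation of that analysis for simultaneous
EEG–fMRI sleep recordings, aimed at researchers who want to apply or probe
the method on their own data — and at anyone who wants to verify the
machinery, because the package ships a synthetic-data generator that
produces BOLD, EEG, hypnogram and physiological traces with known ground
truth for every stage of the pipeline.

## The method

For a region-by-volume BOLD matrix sampled at TR = 2.08 s:

1. **Sliding-window spectrogram** — FFT in 104-s (50-volume) Hamming
   windows, stepped one volume (2.08 s) at a time; power is
   amplitude-normalised so a unit sinusoid at a bin frequency reads 0.5 at
   its bin. Each window is labelled with the sleep stage covering the
   majority of its volumes (hypnogram input, 30-s AASM epochs); windows
   straddling stage changes are flagged as transitions.
2. **1/f fit and peak detection** — per region, a robust (Huber) line in
   log power vs log frequency, fitted outside the two peak search ranges;
   peaks are residual maxima in the LF (0.03–0.08 Hz) and HF
   (0.13–0.20 Hz) search ranges that exceed 2 robust SD and at least twice
   the aperiodic trend.
3. **Oscillation power traces and stage contrasts** — band power at each
   region's own peak (± 0.015 Hz LF / ± 0.03 Hz HF) per window;
   `percent_power_change` contrasts NREM-labelled against wake-labelled
   windows: `100 · (P_sleep − P_wake) / P_wake`.
4. **EEG events** — spindles (11–16 Hz bursts, envelope-threshold detector)
   and slow waves (0.5–4 Hz negative half-waves, trough + area criteria);
   event activity is integrated in 2.08-s bins and aggregated as
   Hamming-weighted averages in the same 104-s windows, so each point pairs
   with one BOLD spectrogram window.
5. **Multimodal correlation** — Pearson r between BOLD oscillation power
   and spindle/slow-wave activity (or sigma/delta band power), region by
   region, across and within stages; group inference on the Fisher-z
   distribution; the broadband BOLD amplitude serves as the
   frequency-blind control pairing.
6. **Physiological controls** — RETROICOR-style nuisance regressors
   (cardiac/respiratory phase to order 2, rate, volume, depth) regressed
   out of BOLD; spectra of the raw traces and derived rate/volume/depth
   series; alias frequencies of cardiac (~1 Hz) and respiratory (~0.25 Hz)
   rhythms at the volume sampling rate (a 1-Hz pulse aliases to 0.0385 Hz
   at TR 2.08 s — inside the LF band, which is why the controls matter).
7. **Lag maps** — at falling-asleep and waking transitions, time-lagged
   cross-correlation between every pair of region power traces; the
   per-region lead/lag is the row mean of the pairwise lag matrix
   (zero-centered; positive = leads).

## Worked example

Simulate one hour of synchronised recordings and detect the oscillation
peaks in intermediate (N2) sleep:

```bash
$ boldosc simulate --seed 7 demo
wrote synthetic recording to demo

$ boldosc peaks demo/bold.tsv demo/hypnogram.txt demo/peaks.json --stage N2
LF: 0.0673 Hz
HF: 0.1635 Hz
```

The two peaks fall in the 0.04–0.07 Hz and 0.15–0.18 Hz ranges where the
sleep oscillations live (the generator injected per-region frequencies in
exactly those ranges; `demo/truth.json` holds the injected values). The
fitted aperiodic slope in `demo/peaks.json` is −1.04, i.e. the 1/f
background the oscillations ride on.

The full pipeline — nuisance regression, spectrogram, peaks, power traces,
event detection, correlations, lag maps — runs from one command and writes
a checksummed manifest:

```bash
$ boldosc run --seed 7 runout
manifest: runout/manifest.json (17 outputs)
```

`runout/correlations.json` then shows the signature pattern (group mean r
across regions):

```
LF_power~spindle_activity    mean r = 0.46
LF_power~slow_wave_activity  mean r = 0.23
HF_power~spindle_activity    mean r = 0.41
HF_power~slow_wave_activity  mean r = 0.74
```

LF power couples preferentially to spindle activity and HF power to
slow-wave activity — the specificity the method is built to expose.
`boldosc report runout report.png` renders a summary figure.

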