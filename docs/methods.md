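# Methods

This note records the models, parameter choices and numerical conventions
behind `boldosc`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Windowing contract

Every windowed quantity — BOLD spectrogram, EEG band power, event-activity
aggregation, physiological band power — uses 104-s Hamming windows stepped
2.08 s (one fMRI volume) at a time, expressed in samples at each series'
native rate. A window starting at sample `i` with length `L` samples of
spacing `dt` is identified by its center `t0 + i·dt + L·dt/2`; with this
convention windows computed at 0.48 Hz (BOLD volumes), 250 Hz (EEG) and
50 Hz (physiology) over the same wall-clock span have *identical* centers,
and cross-modal correlation can require exact alignment instead of
truncating silently.

Windows are demeaned with the *taper-weighted* mean, which makes the
tapered DC component exactly zero; the DC bin is then dropped without
losing power and the one-sided spectral total equals the taper-normalised
time-domain power to rounding error (the Parseval identity asserted in the
tests at 1%). Power is amplitude-normalised by the taper's coherent gain,
`P_k = 2|X_k|² / (Σw)²`: a unit-amplitude sinusoid at a bin frequency
yields 0.5 at its bin in every window. The Hamming side lobes additionally
place ~0.19 in the two adjacent bins; no flat normalisation can remove
that, so "band" quantities in this package are means over the bins of a
band, with the tone's leakage included.

Each window takes the sleep stage covering the majority of its 50 volumes;
windows in which no stage reaches 80% are labelled transitions and are
excluded from stage averages and across-stage correlations (they remain
available to the lag analysis, which lives exactly at those transitions).

## Aperiodic fit and peak detection

Per region, `log10(power)` is fitted against `log10(f)` with iteratively
reweighted least squares (Huber norm, via statsmodels RLM) over
0.005–0.23 Hz excluding the two peak search ranges (LF 0.03–0.08 Hz, HF
0.13–0.20 Hz). At the 1/104 Hz resolution this leaves 11 bins — fitting
ranges much narrower than this would under-determine the line, which is
why the range spans the full analysis band. A peak is the maximum residual
within its search range, accepted when it exceeds both 2 robust SD of the
fit-range residuals and an absolute floor of 0.3 dex (power at least twice
the trend). The floor matters: the robust SD is estimated from 11 bins and
its tails alone false-alarm on roughly a quarter of peak-free spectra,
while genuine oscillation peaks sit at 1.4 dex and above, so the floor
costs no sensitivity (0/312 false peaks, 100% detection in calibration
runs). Bands are the peak ± 0.015 Hz (LF) / ± 0.03 Hz (HF), truncated to
the search range. Because peak frequencies differ between regions, regional
analyses (percent change, correlations, lag maps) integrate each region's
power in its *own* band.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with known truth. It is deterministic given `SimConfig.seed`; each
modality draws from an independent seed stream.

**Hypnogram** — W → N1 → N2 → N3 → N2 → W with dwell times (10, 5, 12.5,
15, 7.5, 10) min scaled to the recording and jittered ±10%, giving one
falling-asleep and one waking transition in a one-hour default session.

**BOLD** — per region: 1/f^β background (β = 1, frequency-domain shaping
of white noise, DC zeroed, unit SD) plus two stage-gated sinusoids with
per-region frequencies drawn in 0.04–0.07 Hz and 0.15–0.18 Hz, random
phases, and amplitude gains per stage of (LF, HF):
W (1.0, 1.0), N1 (1.9, 1.45), N2 (2.0, 1.78), N3 (1.7, 2.1).
The profile encodes the phenomenology the analysis targets — the LF
oscillation peaks in intermediate sleep and attenuates in deep sleep, the
HF oscillation ramps monotonically into deep sleep — and the
duration-weighted wake→sleep power step is 3.5× per band, so the recovered
band-power increase falls in the 200–300% range reported for sleeping
humans (measured ~225% after dilution by the in-band background). Gains
ramp at stage boundaries with a 20-s half-cosine (convolution of the step
series with a raised-cosine-derivative kernel), short against the 104-s
window; per-region gating delays (`onset_lag_s`, `offset_lag_s`) shift the
LF and HF gain functions in time for lag-recovery experiments.

**EEG** — pink background plus spindles (11–16 Hz Tukey-tapered bursts,
0.5–2 s, RMS amplitude 5× the background's sigma-band RMS) and biphasic
slow waves (negative half-sine then 0.6× positive half-sine, 1.0–1.6 s
total, trough 5× the background's delta-band RMS — against a ~20 µV
background delta that is a ~100 µV wave, typical of deep sleep). Event
onsets follow an inhomogeneous Poisson process: stage base rates
(spindles 2/min in N2; slow waves 7/min in N3) times a sinusoidal
infra-slow envelope (1 + 0.8 sin 2πf_env t), realised by thinning a
homogeneous process. The envelope frequencies default to 0.055 Hz
(spindles) and 0.165 Hz (slow waves) and are deliberately independent
config keys: the published event periodicities (2/min, 7/min) and the BOLD
oscillation bands are not numerically identical, and the generator does
not force them to agree. Overlapping events superpose (waves arrive in
trains); configurations whose expected occupancy exceeds 50% are rejected
outright.

**Physiology** — respiration: a sinusoid at 0.25 Hz whose instantaneous
rate and depth are band-limited (0.04–0.4 Hz) random walks (relative SD
0.08 and 0.15); cardiac: a von-Mises-shaped pulse train at 1 Hz with slow
rate variability (SD 0.05). Ground-truth rate/depth/volume series are
returned. The traces are generated independently of the BOLD streams, so
every BOLD–physiology correlation is null by construction — the basis of
the confound-control tests.

## Event detectors

Both detectors are amplitude-threshold/duration-window methods on
zero-phase (forward–backward, order-4 Butterworth) band-passed signals,
with all thresholds relative to per-channel statistics (hence invariant to
global rescaling) and every constant a keyword argument.

*Spindles*: sigma-band (11–16 Hz) moving-RMS envelope (0.2-s kernel);
events where the envelope exceeds 3× its channel median, with boundaries
at 1.5×, merged across gaps < 0.3 s, kept for durations 0.5–3 s.

*Slow waves*: delta-band (0.5–4 Hz) zero-crossing segmentation; negative
half-waves of 0.25–1.0 s are kept when the trough falls below −3.5× the
channel's median absolute deviation *and* the half-wave's negative area
exceeds 1.25 MAD·s. The area gate is essential at realistic SNR: Gaussian
delta-band noise produces ~48 candidate half-waves per minute whose trough
depths have a near-Rayleigh tail, so a trough criterion alone either
floods the output with brief noise troughs or misses genuine waves; the
area statistic approximates a matched filter for the half-wave shape and
separates far better. Both constants were calibrated once against the
generator's ground truth on 12 seeds (mean hit rate 0.82, false-positive
fraction 0.16, N3 density 6.3/min) and then frozen. Reported event
duration is the full biphasic wave (negative half plus following positive
half).

Multi-channel recordings are detected per channel and pooled; a
`--channel` option restricts detection to one channel.

## Correlation and group inference

Pearson (optionally Spearman) r between two windowed traces over the
selected windows (all non-transition windows "across stage", or one
stage's windows "within stage"); entries with fewer than 30 windows are
absent-with-reason. Adjacent windows overlap by 98%, so naive per-entry
p-values are anticonservative; each entry therefore carries a
Bartlett-corrected effective-sample-size p as a diagnostic, while group
inference treats each (region, run) coefficient as one observation:
Fisher-z transform, one-sample t-test of mean z against zero, paired
t-test for contrasts. For *null* controls (e.g. BOLD amplitude vs spindle
activity) even the entry-level pooling is optimistic, because the twelve
regions of one run share the same reference trace; the acceptance test for
the null therefore aggregates to one mean z per run before testing.

The broadband amplitude control is the SD of the demeaned, tapered window
(taper-RMS compensated, so white noise of SD σ reads σ). In the generator,
amplitude is made independent of event activity by running the control on
a flat-gain configuration: stage-independent oscillation gains leave only
noise-driven amplitude fluctuations, which is the stated null.

## Physiological regressors and aliasing

Cardiac peaks are local maxima with a 0.35-s refractory period; cardiac
phase is linear 0→2π between peaks. Respiratory phase uses the
amplitude-histogram transfer (empirical CDF of the trace amplitude, signed
by the derivative). Phases expand to sin/cos of orders 1–2
(RETROICOR-style); rates are reciprocal inter-peak intervals interpolated
linearly to volume midpoints; respiratory volume is a 6-s windowed SD,
depth the per-cycle peak-to-trough. "Volume" and "depth" are defined
differently across the physiological-noise literature; both are provided
and named explicitly in output headers. Regression removes
[intercept, linear drift, regressors] by least squares with pivoted-QR
dropping of collinear columns (dropped names reported); residuals are
orthogonal to the retained design (< 1e-8), which also makes the operation
idempotent. `alias_frequency` folds any rhythm into [0, f_N] by
reflection: r = f mod f_s, alias = r if r ≤ f_s/2 else f_s − r.

Band powers of physiological series are computed at each series' native
sampling rate with the common window contract. This matters: respiration
(0.25 Hz) and the 0.15–0.4 Hz rate/volume/depth band lie *above* the BOLD
Nyquist frequency (0.2404 Hz), so computing them at the volume rate would
alias the very rhythms being measured.

## Transition lag maps

The falling-asleep segment runs from the last sustained wake epoch before
the first sustained NREM run to the first sustained N2/N3 epoch, padded by
120 s (default); waking is the mirror image. Pairwise lags maximise the
normalised cross-correlation over integer window shifts within ± max_lag
(default 60 s), refined by parabolic interpolation; peaks at the search
boundary are flagged unreliable and excluded. The per-region lag is the
row mean of the pairwise matrix including the zero diagonal — for a
complete matrix this equals `l_i − mean(l)` exactly, whereas excluding the
diagonal would inflate every lag by R/(R−1) — zero-centered, with positive
values marking regions whose oscillation turns on (or off) earlier. A
`reference="global_mean"` mode lags each region against the mean trace
instead, as a sensitivity check. Onset traces are baseline-subtracted
(mean wake power removed) so the rising edge dominates.

Precision limit: a band-power trace smoothed by 98%-overlapping 104-s
windows has a noise correlation time of roughly the window length, so a
~10-min transition segment contains only a handful of independent noise
samples, and a single run's pairwise lag wanders by ~18 s at the default
background level (a derivative-based variant measured no better). Single
runs therefore rank 10-s gating differences unreliably; the stable
quantity — and what the lag analysis is designed to report — is the
*group-averaged* lag map. Over 20 seeded runs with gating delays of
0/10/20 s, the seed-averaged map orders the groups correctly
(Spearman ≈ 0.95 with the search bounded at 40 s, twice the largest
injected lag; ≈ 0.83 at the 60-s default). Recovered spacings are
truncation-biased toward zero by ~30–60%, so the map's *ordering* is
trustworthy at these noise levels while absolute lead times are
conservative.

## What the synthetic tests do and do not show

The generator produces stationary-within-stage sinusoidal oscillations,
linear superposition, Gaussian 1/f backgrounds, and physiology independent
of the neural streams. Real recordings add hemodynamic convolution, head
motion, scanner drift, non-sinusoidal and non-stationary oscillations,
EEG artifacts, true physiological coupling, and stage-scoring error — none
of which are modelled (REM phenomena are also out of scope, as the target
recordings contain no REM sleep). Passing tests therefore demonstrate that
the *machinery* — windowing, normalisation, fitting, detection, alignment,
correlation, lag projection — recovers known structure at realistic SNR;
they do not validate the neuroscientific interpretation of any particular
real dataset.

## Problem sizes

Defaults used throughout tests and the acceptance script: one-hour
sessions, 12 regions, one EEG channel at 250 Hz, physiology at 50 Hz;
multi-run checks use 5–20 seeded sessions (20 for the specificity and
lag-ordering checks, 10 for the percent-change recovery). These sizes make
the full suite run in about a minute while keeping every recovery
statistically resolvable; all of them scale through `SimConfig`.
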