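# Methods

`lfpei` implements a longitudinal LFP analysis stack for quantifying
excitation–inhibition balance in rodent recordings: the functional E/I
ratio (fE/I) gated by detrended fluctuation analysis (DFA), theta–gamma
phase–amplitude coupling via the Kullback–Leibler modulation index (MI),
rule-based epileptiform event detection, vigilance scoring, and the
repeated-measures statistics that link these metrics across a nested
mouse → channel → week design. A synthetic-LFP generator with exact
ground truth makes every stage testable without animal data.

## The fE/I ratio

A band-limited signal's amplitude envelope `A(t)` (magnitude of the
analytic signal after zero-phase FIR band-pass) is summarized per 5-s
window (80 % overlap, 1-s step) by two quantities:

* `w_amp` — the mean envelope amplitude in the window;
* `nF` — the RMS of the window's amplitude-normalized, linearly detrended
  signal profile, where the signal profile is the cumulative sum of the
  mean-subtracted envelope and the normalization divides the profile
  window by `w_amp`.

Then `fE/I = 1 − r`, with `r = Pearson(w_amp, nF)` pooled over all windows
of a recording's quiet-wake concatenation. In a balanced network high- and
low-amplitude stretches carry proportionate normalized fluctuations
(`r ≈ 0`, fE/I ≈ 1); excitation dominance suppresses normalized
fluctuations at high amplitude (`r < 0`, fE/I > 1) and inhibition
dominance the converse. The measure is only meaningful when the envelope
exhibits long-range temporal correlations, so fE/I is *missing (typed
`low_dfa`)* whenever the envelope's DFA exponent β < 0.6. All other
failure paths are typed too (`too_short` below 40 windows ≈ the 2-min
minimum; `degenerate` for zero-variance inputs; `excluded` for recordings
with < 2 min of quiet wake) — never a silent NaN.

fE/I is exactly invariant to amplitude rescaling (the normalization
cancels), and `fE/I = 1 − r` holds as an identity, both asserted in tests.

## DFA

DFA-1 of the envelope: cumulative profile, 20 log-spaced window sizes
spanning the 0.4–30 s fit range (capped at a quarter of the data), 50 %
window overlap, per-window linear detrend, mean residual RMS per size,
and β as the least-squares slope of log₁₀F against log₁₀size. Windows are
laid out *within* concatenation segments only (no window straddles a
seam), and the profile is centred on the pooled envelope mean.

Numerics: the per-window detrended RMS is computed from extended-precision
prefix sums of y, y² and k·y — O(n) per window size instead of O(n·win) —
validated against explicit per-window detrending to ≤ 1e-11 relative.
Windows whose residual sum of squares falls below the prefix-sum
cancellation floor (e.g. an exactly linear profile, where the residual is
analytically zero) are recomputed by explicit detrending, which cancels
exactly.

## Band grid

One delta band (1–4 Hz) plus 15 geometrically spaced bands over 4–150 Hz:
edges `e_k = 4·(150/4)^(k/15)`. Filtering always uses the raw geometric
edges; display labels round to the nearest 0.5 Hz (raw 35.19–44.81
displays as "35–45 Hz"). The raw edge 72.66 Hz rounds to 72.5 under this
one consistent rule.

## Filtering

Zero-phase FIR band-pass implemented as centred convolution with a
symmetric (hence linear-phase) `firwin` kernel — the centring compensates
the integer group delay exactly, preserving phase for PAC. The order
covers at least 3 cycles of the band's low edge *and* keeps the
transition width at or below the bandwidth; the second constraint is what
makes narrow constant-bandwidth PAC bands (2–10 Hz wide at gamma
frequencies) selective rather than mostly skirt. Cutoffs are widened by
0.12 of the transition width so the filter's equivalent noise bandwidth
matches the nominal band (firwin's half-amplitude cutoff convention would
otherwise shave ~20 % off in-band power). Band-limited processing of
state concatenations filters each interval independently *before*
concatenation and trims `ceil(2/lo)` seconds (two low-edge cycles) from
each side of every interval's envelope, removing Hilbert and filter edge
artifacts; intervals too short to filter are dropped with a note.

## Theta–gamma PAC

The Tort-style modulation index: phase is binned into 18 half-open 20°
bins starting at −180°; `P_j` is the mean fast-oscillation amplitude in
bin j normalized to sum 1; `KL = ln N + Σ P_j ln P_j` (natural log,
`0·ln 0 = 0`); `MI = KL / ln N ∈ [0, 1]`. MI is 0 for phase-independent
amplitude and exactly 1 when all amplitude mass occupies one bin. An
empty phase bin raises a typed insufficient-data error.

Comodulograms scan phase centers 2–14 Hz (2 Hz bandwidth, 1 Hz steps)
against amplitude centers 40–200 Hz (2 Hz bw, 1 Hz steps) for cortical
channels or 40–300 Hz (4 Hz bw, 2 Hz steps) for hippocampal channels;
printed frequencies are band centers and bands span center ± bw/2.
Amplitude bands reaching the Nyquist frequency are dropped with a warning
(truncated grid). Each band is filtered once per segment and pooled across
segments with one common edge trim (two cycles of the slowest phase band)
so all series stay sample-aligned. Monthly PAC concatenates a month's
active-wake intervals across its weekly recordings in chronological
order, truncates at 10 minutes, and flags (rather than drops) shortfalls.
Summaries average MI cells over θ (4–10 Hz) × low-γ (40–90 Hz), × high-γ
(90–160 Hz), and — hippocampal channels only — × total-γ (40–300 Hz).

## Epileptiform event detection

Detection is vigilance-agnostic and amplitude-scale invariant (all
thresholds are mean- or SD-relative).

* **Candidates** — nonlinear energy operator ψ[n] = x[n]² − x[n−1]x[n+1]
  on the 5–80 Hz band-passed trace, smoothed with an 8-ms Bartlett
  window, thresholded at 12 × mean(ψ); supra-threshold runs closer than
  30 ms merge into one candidate timed at the energy peak. The band stops
  at 80 Hz because ψ weights energy by frequency squared: sub-100-ms
  spike transients carry their energy below ~50 Hz, and broadband noise
  above 80 Hz would otherwise dominate ψ. The threshold constant 12 is
  where the injection benchmark holds both recall and precision ≥ 0.9 on
  stationary 1/f noise; both constants are configurable.
* **Amplitude/width** — signed amplitude in robust-SD units
  (1.4826 × MAD of the detection-band trace with candidate windows
  excised); width as the full width at half maximum around the peak.
* **SWDs** (prefrontal channels) — candidate peaks grouped into runs at
  inter-peak rate ≥ 6 Hz; accepted with ≥ 3 cycles, duration ≥ 1 s and
  peak-to-peak > 2 × background (median 1-s peak-to-peak over the
  surrounding 60 s, detected events excluded); episodes separated by
  < 1 s merge first.
* **Giant spikes** — a candidate time with a candidate on *every* channel
  within ±10 ms, |amplitude| > 10 SD on at least one hippocampal channel,
  and a positive mean over (t, t+200 ms] on all channels relative to the
  preceding second's median of the *raw* trace (a 300-ms positive
  deflection lies mostly below the detection band's 5-Hz high-pass). One
  representative event per giant (max-amplitude channel); the other
  channels' detections are typed `giant_member` so rates count physical
  events.
* **Isolated spikes** — remaining brief (< 100 ms) negative candidates on
  HC (or PTC) channels with no contralateral same-region candidate
  within ±100 ms; without a contralateral channel the pairing rule passes
  vacuously, with a logged caveat.

Rates are events per second over the full recording. ISI histograms use
24 logarithmic bins over 0.05–200 s by default, out-of-range intervals
clamped into the end bins so counts always sum to n − 1.

## Vigilance scoring

Per 5-s epoch: velocity > 1 cm/s → active wake; otherwise delta/theta
envelope-power ratio ≥ 1.5 → sleep, else quiet wake. The thresholds are
declared stand-ins for a full video/EEG scoring procedure; synthetic
cohorts carry ground-truth labels so no downstream analysis depends on
them. Epoch i covers [5i, 5(i+1)) seconds, half-open, 0-based.

## Statistics

* **Aggregation** — two-stage monthly means: weeks → electrode-month,
  then electrodes → mouse-month; typed-missing values drop out of the
  means; the electrode-month intermediate is retained for channel-level
  matching. Aggregation is idempotent.
* **rmcorr** — ANCOVA with per-subject intercepts and a common slope,
  computed by within-subject centering;
  `r_rm = sign(slope)·√(SS_effect/(SS_effect+SS_resid))`, dof = N − k − 1,
  p from the t distribution, CI via Fisher z with SE = 1/√(dof−1).
  Subjects with fewer than two pairs or zero x-variance are dropped (they
  carry no slope information). The implementation matches pingouin's
  `rm_corr` to 1e-9 and a brute-force design-matrix least-squares oracle
  to 1e-10 in tests, and is calibrated under the null (type-I error
  0.045–0.055 at α = 0.05 over 200 replicates).
* **Matching** — fE/I↔PAC joins electrode-level monthly values on
  (subject, channel, month); fE/I↔spikes averages fE/I across channels
  per (subject, week) and drops zero-rate weeks; PAC↔spikes joins
  mouse-level monthly means and drops zero-rate months. Analyses never
  pool across regions.
* **Genotype contrasts** — per month on mouse-level values: Levene's test
  (α = 0.05) selects Student's versus Welch's t-test; Benjamini–Hochberg
  across months at q = 0.05. Band sweeps report fixed per-comparison
  α = 0.01 as primary and 0.01–0.05 as marginal, with no further
  correction — documented as the reference analysis's own stance.
* **Multilevel export** — `bmlm_export` emits model-ready tidy tables
  (value, genotype, age_month, mouse, channel) for external Bayesian
  multilevel fitting; no sampler is implemented here.

## Synthetic LFP generator

The generator emulates the *statistical* structure the analyses assume —
not biophysics.

* **fGn** — exact fractional Gaussian noise by Davies–Harte circulant
  embedding; sample autocovariance matches the analytic form (checked at
  lags 0–5 within 3 SE).
* **LRTC envelope** — `exp(c·z)` with `z` an fGn(H) process generated at
  20 Hz and interpolated to the sampling rate. Exponentiation keeps the
  envelope positive without clipping (clipping destroys LRTC); the low
  generation rate puts the envelope's variance below the narrowband
  filter's half-bandwidth, so the planted Hurst exponent survives the
  analysis path (full-rate fGn is spectrally near-white and would not).
  A small (12 %) fast 1–8 Hz fluctuation adds short-scale texture.
  Recovery: β within ±0.07 of H through the full filter→envelope→DFA
  path; large additive white noise drives the recovered β to ~0.5.
* **Excitation bias** — the fE/I control knob: z is split into a
  very-slow level (10-s moving average, which sets windowed amplitude)
  and a mid-frequency remainder, and the remainder is scaled by
  `exp(−bias·level/sd)`. Positive bias makes high-amplitude stretches
  relatively quieter after amplitude normalization, i.e. fE/I > 1. At
  bias 0.3 the measured fE/I is ≈ 1.35 versus ≈ 0.95 unbiased; the knob
  destabilizes beyond ~0.5 (the exponential gain saturates), so planted
  effects stay at 0.3.
* **PAC** — `sin(2πf_φt) + a(t)·sin(2πf_At)` with
  `a = 1 − χ + χ(1+cos 2πf_φt)/2`; χ = 0 uncoupled, χ = 1 full-depth.
  The closed-form modulator gives an exact MI oracle.
* **Event templates** — parameterized waveforms (dominant negative
  Gaussian lobe with a smaller positive rebound for spikes; sharp
  negative spike + slow positive wave per SWD cycle; large spike plus
  300-ms positive deflection on all channels for giants), calibrated so
  the requested SD amplitude is exact *as measured in the detection
  band* (the band's high-pass removes a broad transient's DC content, so
  raw-peak calibration would understate the classified amplitude).
  Isolated spikes are negative-dominant because symmetric biphasic shapes
  randomize measured polarity in noise.
* **Cohorts** — genotype → mouse → (month × 4 weeks) → multichannel
  recording, with Gaussian mouse- and channel-level offsets on H and χ,
  genotype-by-month effects on (H, χ, spike rate, excitation bias), a
  block-structured vigilance sequence (mean bouts: quiet 65 s, active
  45 s, sleep 30 s), state-dependent delta content, velocity traces, and
  Poisson isolated spikes on one HC channel. Cohort spikes are placed
  outside quiet wake: the fE/I contract takes its input as
  artifact/spike-cleaned, and the generator emulates that cleaning at
  source (rates are still normalized to the full duration). All streams
  derive from one master seed via fixed-offset `SeedSequence` spawning.

What the generator does *not* emulate: real spectral shape beyond 1/f-ish
background, volume conduction, electrode drift, movement artifacts, true
sleep architecture, or any biophysical coupling between criticality,
coupling depth and spiking — the planted genotype effects are statistical
constructions. Passing tests therefore demonstrate that the *pipeline*
recovers what it claims to measure, not that the biology behaves this way.

## Problem sizes

Default study-condition scales were chosen once as realistic desk-scale
analogues of a longitudinal rodent study: DFA/fE/I recovery uses 200-s
signals at 1 kHz averaged over 10 seeds; event benchmarks use 600-s
five-channel recordings with 20 injected spikes, one SWD train and four
giants per replicate; end-to-end cohort replicates use 2 genotypes × 3
mice × 2 months × 4 weekly 400-s recordings at 500 Hz with two
hippocampal channels, coarse PAC grids (θ phase centers 4–10 Hz step 2;
amplitude centers 45–95 Hz step 10) and a 5-minute monthly PAC target.
The planted-effect check requires the genotype contrasts to flag exactly
the onset month and the band sweep to confine significant
fE/I↔spike-rate correlations to the 35–45 Hz band and its two
filter-overlap neighbours, in ≥ 80 % of seeded replicates; null cohorts
must stay near nominal false-flag rates.

## Known limitations

* The vigilance thresholds are stand-ins; real scoring pipelines use
  cited procedures with calibrated constants and hysteresis.
* The NEO threshold constant and detection band were tuned on the
  generator's noise families; real LFP may need the configurable
  constants adjusted.
* SWD candidate review is automatic only; the reference procedure adds
  manual visual inspection of candidates, which is out of scope.
* fE/I near criticality is systematically a few percent below 1 for
  symmetric lognormal envelopes (finite-window effect); comparisons are
  within-pipeline, so this offset cancels in contrasts.
* EDF files can be read (via mne) but not written; the delimited
  columnar format is the native interchange.
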