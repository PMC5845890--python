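# Methods

This note documents the models, estimators and numerical choices behind
`sensortrace`, and what the synthetic study conditions do and do not show
about real recordings.

## Sensor models

All sensor math lives in `sensortrace.sensors` as pure functions; the
assays and the generators share it, so every inversion tested against a
generated recording is a genuine round-trip rather than two copies of the
same formula agreeing with themselves.

**Hill intensity sensor (calcium).** Fraction bound
f(c) = cⁿ/(K_dⁿ + cⁿ). Presets: RCaMP1e K_d = 1.6 μM, n = 3.4
(pK_a 5.9 is carried for reference but never used — over the pH 7–8 range
relevant here the response is effectively pH-independent). With n = 3.4
the sensor is steeply sigmoidal: at ~0.1 μM resting free Ca²⁺ the bound
fraction is ~8 × 10⁻⁵, so resting fluctuations are invisible, while
stimulus-evoked rises toward and past K_d produce large ΔF/F₀; amplitudes
far above K_d saturate the response, which the generator reproduces.

**FRET ATP sensor.** Forward model
R = R_min + (R_max − R_min)·c^h/(K_d^h + c^h), presets ATeam1.03
K_d = 3.3 mM, R_max/R_min = 2.3, h = 2. The published characterization
gives h ≈ 2.1; the quadratic form is the standard simplification and h is
configurable. The inverse, in terms of the relative ratio r = R/R_min, is
[ATP] = K_d·((r − 1)/(R_max/R_min − r))^(1/h); for h = 2 this is the
square-root form. It was re-derived algebraically from the forward model
and is verified by a round-trip identity test (max error < 10⁻⁹ mM over
0–50 mM). r < 1 (baseline noise below the depletion floor) is clipped to
0 mM with a logged warning; r at or above the dynamic range is a
saturation error because the inversion diverges there.

**roGFP redox sensor and the Nernst chain.** Fraction reduced
R = (F − F_ox)/(F_red − F_ox) from chemically set calibration endpoints
(10 mM DTT, then 10 mM H₂O₂); values outside [0, 1] are clipped with a
warning, and fractions are clamped to [ε, 1 − ε], ε = 10⁻⁶, before any
logarithm (each clamp logged). The sensor equilibrates with the DTT couple
with K_eq = 0.070, giving
E′ = E°′(DTT) − (RT/nF)·ln(K_eq·R/(1 − R)),
with R = 8.315 J K⁻¹ mol⁻¹, T = 303.15 K (30 °C), n = 2,
F = 9.649 × 10⁴ C mol⁻¹, E°′(DTT) = −0.323 V by default (−0.330 V
selectable; the two presets give sensor midpoints of −0.288 V and
−0.295 V). The −0.291 V consensus value is the average of those two
*rounded* midpoints — the unrounded mean is −0.2918 V — so the package
reports the mean of the 3-decimal values, matching how the consensus
number was originally derived. Potentials are carried in volts internally
and rendered as mV in reports. Compartment pH enters as
E°′(pH) = E°′ − 60.1 mV·(pH − 7), applied to the DTT reference midpoint
(equivalently shifting the whole potential); defaults pH 7.0 (cytosol) and
7.98 (mitochondrial matrix).

Absolute roGFP-derived potentials drift between experimental series in
practice; the validated output of the redox pipeline is therefore the
*difference* between conditions or compartments (the pH identity is exact
by construction), not the absolute millivolt value.

## Trace primitives

**ΔF/F₀.** F₀ is the mean over a baseline window (default: first 10% of
the trace or everything before the first protocol event, whichever is
shorter). Normalization is invariant to detector gain by construction.

**Transient metrics.** The peak and the decay segment are located on a
lightly boxcar-smoothed copy (width 5 samples) so single noise samples
neither set the peak nor truncate the decay; the mono-exponential
a·exp(−t/τ) is then least-squares fitted to the *raw* samples from the
peak to the first smoothed return below 10% of peak. Without the smoothed
segmentation, the argmax lands on an upward noise excursion and the
segment ends on a downward one, biasing τ low by ~10–15% at SNR 10; with
it, the population-mean τ is recovered within a few percent. If the fit
explains < 50% of the variance (non-decaying or irregular tails) the
empirical 1/e time is reported instead and flagged — either metric
preserves group ordering, which is the scientifically meaningful content
of decay comparisons.

**Responder classification.** A neuron responds when its post-stimulus
ΔF/F₀ exceeds k·σ(baseline), k = 3, for at least 3 *consecutive* samples.
The persistence requirement is what makes the k = 3 threshold usable over
long search windows: a genuine transient outlasts many samples, while the
probability that iid noise exceeds 3σ three times in a row is ~10⁻⁸ per
position, keeping the per-trace false-positive rate far below the 1%
design bound (verified over 1000 noise traces). A single-sample peak rule
at the same k would false-positive on ~30% of noise traces.

**Rate estimation.** OLS slope with r² over an explicit window; when no
window is given, a sliding window (default 20 s, motivated by
FCCP-response timescales of tens of seconds) keeps the steepest segment
among those with r² ≥ 0.8, and reports an explicit "no reliable slope"
result if none qualifies.

## Assay pipelines

**FCCP ATP assay.** Challenges are the event pairs (FCCP_on → washout,
optionally kainate_on → washout). R_min is the mean raw ratio over the
depletion plateau — the last 20% of each uncoupled interval, taking the
deepest challenge — and the plateau must be settled (|OLS slope| ≤ 2 × 10⁻³
ratio/s, else a calibration error: the "minimum after depletion" premise
requires a settled minimum). The full trace is converted to mM and rates
are fitted on protocol-anchored windows rather than by steepest-window
search: maximizing |slope| over noisy candidate windows selects upward
noise excursions and biased rates by 10–20% in validation. The anchored
windows cover the quasi-linear stretch of each phase, excluding samples
below 0.5 mM — the inverse model's derivative d[ATP]/dr diverges as
r → 1, so ratio noise near the depletion floor maps to large mM noise —
and above 90% of baseline, where recovery saturates; slope estimation runs
on a 5-sample-smoothed copy of the ratio (the quantified trace returned to
the caller is unsmoothed). On noiseless recordings the calibration and
inversion are mutually exact (baseline ATP error ≤ 10⁻⁶ mM).

**Redox assay.** Calibration plateaus are the last 50% of the DTT and
H₂O₂ phases. Stability is judged relative to the calibration span
|F_red − F_ox|: drift (slope × duration) ≤ 10% of span and sample SD ≤ 25%
of span. A plain coefficient of variation was rejected because it scales
with 1/mean and fails any noisy *low* plateau even when perfectly settled.
Reduced-high polarity is asserted (reversed plateaus raise a polarity
error). The whole computation is invariant to affine rescaling of the raw
signal, since gain and offset cancel in the fraction.

**TMRM assay.** The readout is the pre-FCCP mito/cytosol mean-intensity
ratio per ROI pair — deliberately a *relative* potential measure, never
converted to mV. The FCCP-response check (mito declines AND cytosol rises,
one-sided Welch tests at α = 0.05 on pre vs post-settle windows) is the
dye-redistribution signature that validates a pair.

**Calcium population assay.** Per-neuron transient metrics plus the
responder fraction with a Wilson 95% binomial interval
(statsmodels); group summaries (peak, τ) are computed over responders.

## Network activity

**Event detection.** Onsets are upward crossings of
center + k·σ_noise (k = 3) sustained for ≥ 3 samples, with a 1-s
refractory interval and a hysteresis re-arm at half the threshold excess
(noise riding on a decaying tail cannot fire twice). Center is the median
of the recording; the noise scale is med|Δy|/(√2·Φ⁻¹(3/4)) from successive
differences. This estimator choice is load-bearing: spontaneous
recordings have no event-free baseline, and at ~17 bursts/min roughly a
third of all samples lie on transients, which inflates even the MAD by
>2× (silencing detection), while slow decays contribute almost nothing to
successive differences. On pure-noise traces the false-event rate is ≪ 1%.

**Synchrony definition.** The upstream analysis this replaces was done
with an external package whose parameters are not published, so the
definition here is the package's own, chosen so that fully synchronized
rasters are recovered exactly and independent-Poisson rasters yield
near-zero bursts: a candidate window is any 1-s interval starting at an
onset in which ≥ 20% of active neurons fire; overlapping candidates merge
into one burst. An "active" neuron has ≥ 1 detected event; participation
denominators use active neurons (the active fraction itself is also
reported). Absolute burst counts are validated against the generator and
against an independent brute-force implementation of the same definition,
not against published figures. Detection is exact on well-separated
bursts and merges pairs closer than the 1-s window, a ≤ 2-count effect at
the rates studied.

## Synthetic study conditions

Each generator emulates one protocol with recorded ground truth and a
seeded RNG (byte-identical regeneration; seed and scenario are written
into every emitted file header). Noise is additive Gaussian on the
emitted signal with SNR = peak amplitude / noise SD — shot-noise realism
without camera modeling. Defaults, chosen once to match the study
conditions or plausible physiology:

- **Calcium populations** (ΔF/F₀-domain and raw-fluorescence Hill-transduced
  variants): 100 neurons, stimulus at 10 s, amplitude 1.2 ΔF/F₀
  (Ca-domain: rest 0.1 μM, amplitude 1.5 μM), τ = 2 s, SNR 10, responder
  fraction 0.96 (healthy cultures; the impaired scenario uses 0.63). The
  ΔF/F₀-domain generator exists because the Hill transduction is
  nonlinear: fluorescence decay of a transduced Ca²⁺ exponential is not
  exponential, so decay-recovery truth must live in the fluorescence
  domain. Designed responder counts are exact (round(f·n)), making
  recovered fractions directly comparable.
- **ATP traces**: baseline 2 mM, consumption −0.04 mM/s, production
  +0.03 mM/s, R_min 0.5, SNR 20, 600 s at 1 Hz; protocol baseline → FCCP
  (60 s) → washout (240 s) → FCCP+kainate (360 s, rates × 1.5) → washout
  (480 s). Depletion reaches the 0 mM floor and plateaus, providing the
  R_min calibration.
- **Redox traces**: fraction reduced 0.9 (≈10% oxidized cytosolic
  baseline), plateaus 2.0/0.5, phase switches at 120 s and 300 s with 5-s
  exponential solution-exchange transitions, SNR 30, 2 Hz.
- **TMRM pairs**: 30 pairs, true ratio ~ N(4.0, 1.0²) truncated at 1.2,
  cytosol level 20 a.u.; after FCCP the mito signal falls to 40% and the
  cytosol rises to 160%.
- **Network rasters**: 225 neurons (the 200–250 range segmented per field
  of view), 180-s recordings at 10 Hz, burst participation 0.8,
  independent event rate 0.02 Hz/neuron, kernel τ = 1 s, SNR 10. Burst
  onsets follow a hard-core renewal process (2-s refractory gap plus
  exponential waiting with mean set so the realized rate equals the
  nominal bursts/min). A naively thinned Poisson process was rejected
  because dead-time thinning suppresses high nominal rates by ~35% at
  17/min; the renewal form keeps rates calibrated while still providing
  Poisson-like irregularity, and the actually generated onsets are
  recorded as truth regardless.
- **Titrations**: K_d 1.95 mM; residues 94/120/134/196 with Δδ_max
  0.30/0.22/0.18/0.12 ppm; 8 concentrations from 0 to 6 mM;
  multiplicative Gaussian noise, relative SD 5% (shift-proportional error,
  as for peak positions read off well-resolved spectra).

What passing these conditions does *not* show: real recordings add
photobleaching, baseline drift, motion, correlated (non-Gaussian) noise,
double-exponential indicator kinetics, and segmentation errors — none of
which are modeled. The recovery results validate the estimators under the
stated noise model, not robustness to those artifacts.

## Binding analysis choices

The titration fit uses the ligand-excess hyperbola rather than the exact
quadratic two-species solution because the measured K_d (~2 mM) exceeds
HSQC-typical labeled-protein concentrations by orders of magnitude; the
quadratic form is available via `protein_conc` and agrees with the
hyperbola to < 0.1% in that regime (tested). Least squares is unweighted.
Fits whose K_d exceeds 10× the highest titrated concentration, or that
fail to converge, are flagged unreliable and excluded from averaging. The
default fits ΔδN against ligand concentration (the quantity conventionally
plotted for titration curves); combined-csp fitting is available through
the same interface since `combined_csp` produces an equally valid series.
Per-fit K_d scatter at these conditions is ~13% (SD), so the four-residue
average — which is also what the original analysis reported — is the
stable quantity.

## Degenerate inputs and tie-breaks

- Flat recording at R_min: baseline ATP 0 mM, rates ≈ 0 — not an error.
- Rate windows that masking empties fall back to the unmasked window
  (flat/fully depleted segments report their near-zero slope).
- Zero baseline variance with zero peak → non-responder, not an error.
- Zero bursts → frequency 0 and participation reported as absent.
- Event detection refuses traces that do not look like ΔF/F₀ (values
  below −1, or strictly positive with median > 1).
- JSON results use sorted keys; reruns on identical inputs are
  byte-identical, and every result record embeds tool version, effective
  config, and input SHA-256 checksums.

## Problem sizes

Tests and the acceptance script use the generator defaults above
(100-neuron populations; 600-sample ATP traces; 960-sample redox traces;
225-neuron, 1800-frame rasters; 1000-trace null calibrations; 200-seed
bias checks with single-residue titrations), sizes at which every
validated tolerance is comfortably resolved while the full suite runs in
well under a minute of compute.

## Known limitations

- Decay metrics assume mono-exponential clearance; strongly
  double-exponential indicators will land in the 1/e fallback.
- The synchrony definition resolves bursts ≥ ~1 s apart; faster network
  oscillations would merge.
- TMRM analysis is non-quantitative by design (no mV calibration).
- The NMR module starts from assigned shift tables; no spectral
  processing, peak picking, or assignment.
- Absolute redox potentials inherit any calibration-plateau bias;
  between-condition differences are the robust readout.
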