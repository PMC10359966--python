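# Methods

This note documents the models, parameter choices and numerical decisions
behind `taumod`, in the order the pipeline applies them, followed by what
the synthetic generator does and does not emulate, and known limitations.

## Signal model and preprocessing

The pipeline assumes continuous, artifact-free multichannel field
recordings in microvolts at ≥ 500 Hz (1 kHz typical). Any NaN in the input
is a hard error: gaps must be handled before analysis, because every
downstream statistic assumes contiguous windows.

Preprocessing follows standard intracranial practice:

* **Common average reference** — the instantaneous across-channel mean is
  subtracted from every channel. With very few channels CAR is degenerate
  (with two it merely antisymmetrizes the pair), so it is skipped for
  single-channel data and can be disabled in `PipelineConfig`.
* **Line-noise notches** — FIR bandstops at 48–52 and 98–102 Hz (50 Hz
  regions; both bands configurable for 60 Hz mains).
* **FIR filtering** — all filters are Hamming-window linear-phase designs
  applied in a single pass with the group delay compensated, which is
  exactly zero-phase for a symmetric kernel. The transition bandwidth
  defaults to max(25 % of the lower cutoff, 0.1 Hz) for bandpass filters
  and 2 Hz for bandstops (the generic rule would smear a 4 Hz-wide notch
  across tens of Hz). The kernel length implied by a 0.1 Hz transition at
  1 kHz is ~33 000 taps; the design is capped at one third of the signal
  length so short recordings remain filterable, at the cost of a wider
  transition. Samples within half a kernel of either end are
  edge-contaminated; they are flagged in `BandPair.edge_mask` and every
  analysis window touching them is marked invalid rather than silently
  included.
* **Band pair extraction** — slow wave 0.2–4 Hz; broadband gamma 55–145 Hz
  (inside the line-noise-free region between the 50 Hz fundamental and its
  150 Hz harmonic), envelope by Hilbert transform at the native rate, then
  both series decimated to the 25 Hz feature rate. Order is fixed as
  envelope-then-decimate. Decimation applies an anti-alias low-pass at
  0.4 × the output rate (10 Hz) before taking every k-th sample; the
  in-to-out rate ratio must be an integer.

## Tau-modulation curves

A TMC is the vector of Pearson correlations between one 2.56 s slow-wave
segment (64 samples at 25 Hz), multiplied by a 64-point Hamming taper, and
the gamma envelope taken at 64 lags. Conventions that the literature leaves
open and that are therefore fixed explicitly here:

* **Lag grid** — τ_k = (k − 32)/25 s for k = 0…63, i.e. −1.28 … +1.24 s.
  The lag *count* (64 = 25 Hz × 2.56 s) is treated as binding; an inclusive
  ±1.28 s grid would need 65 points.
* **Sign convention** — positive lag means the gamma envelope is taken
  *later* in time than the slow-wave window (gamma lags the slow wave).
* **Taper** — the Hamming window multiplies the slow segment only; the
  gamma segment enters untapered. A consequence worth knowing: R is
  invariant to positive rescaling of the slow segment and to positive
  affine rescaling of the gamma segment, but *not* to an additive offset on
  the slow segment, because the taper is applied before the Pearson
  centering (a constant acquires the window's shape). Slow-band signals are
  zero-mean, so this never matters in the pipeline.
* **Validity** — windows are placed only where the full ±1.28 s lag context
  lies inside the recording (no zero-padding, which would bias the
  correlations); windows touching edge-flagged samples are kept in the
  series but set to NaN with `valid = False`. A constant slow or gamma
  segment yields NaN (degenerate), including a constant *raw* slow segment
  that the taper would give artificial shape.

The vectorized series computation is checked against a direct per-lag
Pearson loop to < 1e−10 in the test suite.

## Modulation strength

The strength of a 5 s observation window (25 consecutive TMCs) is

    SNR = σ² / ((1/n) Σᵢ σᵢ²),    n = 64,

with population variances throughout: σ² pools all 25 × 64 R values and
σᵢ² is the variance at lag i across the 25 curves. Population variance and
the pooled numerator are chosen because together they (a) reproduce the
two-curve worked example [[0,1],[1,0]] → SNR exactly 1 and (b) calibrate
the statistic to E[SNR] ≈ 1 + 1/25 for independent R samples (verified at
1.04 over 100 i.i.d. stacks). A window with more than 20 % NaN entries, or
with per-lag variances at the float-noise level (identical curves), returns
NaN.

**The raw null level under window overlap.** Consecutive TMCs 0.2 s apart
share up to 92 % of their data, so their R values are strongly correlated
(measured autocorrelation 0.96 at one step, decaying to ~0 by ~13 steps).
Within an observation stack this deflates the per-lag variances by a factor
(1 − ρ̄) and inflates the across-lag variance of the stack mean by ρ̄,
where ρ̄ ≈ 0.3 is the mean pairwise correlation among the 25 curves. The
net effect is a raw null level around 1.4–1.6 rather than 1.0 — an
intrinsic property of correlating heavily overlapping windows, independent
of signal content or waveform shape (sawtooth and sinusoidal nulls agree to
better than 1 %). Two consequences:

* inference about coupling should use the *baseline-normalized* strength
  (z-score against the awake eyes-covered period), which removes the offset
  exactly as it removes per-electrode gain differences; the raw ≈ 1
  calibration holds only for uncorrelated curves;
* the contrast that carries the method's robustness claim is *relative*:
  uncoupled data sit at the same level regardless of how non-sinusoidal the
  slow wave is, while genuine coupling raises the statistic by an order of
  magnitude (≈ 66 at depth 0.8 in the worked example).

Normalization subtracts the baseline mean and divides by the baseline
standard deviation; it requires ≥ 25 finite baseline values and refuses a
constant baseline.

## Modulation frequency

The 25 TMCs of each window are averaged and decomposed by greedy matching
pursuit over a discrete Gabor dictionary; the modulation frequency is the
center frequency of the first atom (in extraction order) at or above the
oscillatory threshold of 0.2 Hz (the slow-band floor; configurable). The
dictionary holds atoms

    g(τ) = exp(−(τ − t₀)² / 2s²) · cos(2πf(τ − t₀) − φ)

with center times t₀ at all 64 lag samples, frequencies 0 … 12.5 Hz in
steps of 1/(4 × 2.56) ≈ 0.098 Hz (a 4× refinement of the window's natural
resolution), five logarithmically spaced spreads s ∈ [0.08, 1.28] s, plus a
constant atom — 41 281 atoms in total. The phase φ is not discretized: for
each atom the optimal phase is solved analytically from the two quadrature
projections (a 2 × 2 Gram solve, vectorized across the dictionary; the
f = 0 atoms degenerate to a single quadrature). Extraction stops at 10
atoms, at residual energy below 5 % of the input, or — when only the
frequency is wanted — immediately after the first oscillatory atom, which
cannot change the result because extraction is greedy. Residual energy is
non-increasing by construction and is tested as such.

Windows with any invalid TMC yield NaN; so do windows whose decomposition
produces no oscillatory atom (e.g. a pure offset or linear ramp).

## Modulation polarity

The averaged TMC is detrended by a least-squares line in τ, and the
polarity is the sign of the mean detrended value over |τ| ≤ 0.12 s (three
lag samples each side of zero; configurable). Windows with fewer than 80 %
valid TMCs, or an exactly zero mean, return NaN — no tie-breaking. The
detrending step makes the sign robust to slow asymmetric drift across the
lag axis.

All three features are stamped at the center of their 5 s observation
window and advance every 0.2 s (5 Hz feature rate).

## Propagation map

Per channel, the z-normalized strength over an analysis interval (default
5–20 min after the injection marker) is fitted with a 20th-order
least-squares polynomial on time affinely mapped to [−1, 1] — a raw-seconds
Vandermonde fit of that order is numerically useless; the mapped-domain fit
agrees with a Chebyshev fit of the same order to 1e−6. The channel's peak
modulation time is the first *interior* local maximum of the fitted curve
(found on a 1 s evaluation grid, refined within the bracketing cell) whose
value exceeds a threshold, defaulting to the mean normalized strength of
the anesthetized period. Channels with no suprathreshold interior peak, too
few finite samples (< 200), or a degenerate fit are flagged invalid with a
reason code and kept in the table. Ordering channels by peak time gives the
propagation map; electrode coordinates are attached when available.

## Conventional baseline

`canolty_mi` implements the classic modulation index |mean(A·e^{iφ})| with
the preferred phase as the argument of that mean, plus a surrogate z-score
from circular time-shifts of the amplitude series (≥ 1 s by default), which
preserve the amplitude autocorrelation while destroying phase alignment.
Phase comes from the Hilbert transform of the narrowband slow wave — the
exact step the tau-modulation method avoids. Two caveats the examples
demonstrate: the raw index inflates dramatically for non-sinusoidal slow
waves even with independent gamma (the waveform artifact), and time-shift
surrogates do *not* flag that inflation as significant because the artifact
survives shifting; both raw and surrogate-normalized values are therefore
reported side by side rather than collapsed into one number.

## Synthetic generator

Each channel is

    x(t) = A_s(t)·m(t) + A_g(t)·max(0, 1 + d(t)·p·m(t − lag))·c(t)
           + 1/f background + line noise,

where m is the unit-normalized slow waveform evaluated on an integrated
(possibly non-stationary, piecewise-linear) frequency trajectory, c a
unit-RMS 55–145 Hz Gaussian-noise carrier, d the coupling depth, p the
polarity. Choices and defaults:

* waveforms: sinusoid; *asymmetric* — a phase-skewed sinusoid
  cos(θ + a·sin θ) with skew a = 0.5; *sawtooth* — a sharp-edged sawtooth
  (edge sharpness configurable) shifted so its maximum defines phase zero.
  No parametric form for irregular slow waves is established, so these
  three span the smooth-to-sharp range;
* the gamma carrier is band-limited noise, not a tone: broadband gamma is
  non-rhythmic, and a tonal carrier would put a spectral line where none
  belongs;
* the envelope is floored at 0 when d·|m| > 1 would drive it negative
  (amplitudes cannot be negative);
* amplitudes default to slow 100 µV, gamma 10 µV, 1/f background 20 µV RMS
  (exponent 1.0, flattened below 0.1 Hz so the variance is finite), line
  noise 5/2/1 µV at 50/100/150 Hz. The slow:gamma ratio of real recordings
  is not established quantitatively; these are order-of-magnitude choices
  exposed in `CouplingSpec`, not claims;
* sessions are stage timelines (awake eyes-open/covered, injection
  transient, suppression, anesthetized, recovery), each stage carrying its
  own coupling parameters. Continuous quantities (depth, amplitudes,
  frequency) crossfade over 5 s at stage boundaries; discrete ones
  (polarity, lag, waveform) switch sharply. Per-channel onset delays shift
  the whole timeline to emulate a travelling effect. Each channel receives
  a uniformly random initial slow-wave phase — phase-identical channels
  would cancel the slow wave under CAR, which no real array exhibits;
* randomness: one `SeedSequence` per session spawns one generator per
  channel; identical spec and seed reproduce identical bytes.

What the generator does **not** emulate: volume conduction and shared noise
across electrodes, pharmacokinetics, burst suppression's characteristic
temporal statistics, artifacts (movement, electrode pops), and genuine
moment-to-moment fluctuation of coupling depth. Passing recovery tests on
this data therefore demonstrates the estimator chain is correct and
well-calibrated, not that real recordings will be as clean; on real data
the invalid-window flags and the baseline normalization do more work.

## Problem sizes in the test and acceptance runs

Single-channel calibration and recovery runs use 5-minute recordings at
1 kHz (≈ 1 300 valid observation windows after edge trimming); polarity
recovery uses 60 s baseline + 240 s anesthetized sessions at depth 0.5 (the
hardest depth the recovery claim covers); the propagation check uses one
16-channel, 10-minute session with onsets staggered 0–300 s and recovers
the onset ordering with Spearman ρ ≈ 0.997; unit-level property checks use
60–90 s signals. These sizes were chosen so the estimator variance is small
relative to the tested effects while the whole suite stays quick to run.

## Known limitations

* The raw strength SNR's null level depends on the window/step overlap
  ratio (see above); comparing raw values across different window settings
  is not meaningful — normalize first.
* Modulation frequency and polarity are undefined where strength is at the
  null level; the NaN outputs there are by design, not missing data.
* The matching-pursuit dictionary resolves frequency to ~0.1 Hz and cannot
  separate two simultaneous modulation frequencies inside one window (the
  first oscillatory atom wins).
* EDF output is plain 16-bit EDF: quantization is (physical range)/2¹⁶ per
  channel, record duration 1 s (the signal is truncated to whole seconds),
  and markers travel in a text sidecar, not in the file itself.
* The 20th-order polynomial fit needs a few hundred finite strength values;
  very short analysis intervals or heavily masked channels are flagged
  invalid rather than fitted badly.
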