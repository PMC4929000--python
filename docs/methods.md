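# Methods

This note documents the models, algorithms and numerical choices behind
`swrgamma`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
establish.

## Signal model and conventions

A recording is a uniformly sampled trace `x[i]` at rate `fs` (Hz), voltage in
mV (LFP) or current in pA (voltage clamp). Time is in seconds, sample `i`
lives at `t0 + i/fs`, and all event intervals are half-open `[t_start,
t_end)` so abutting events never double-count samples. Areas are therefore
mV·s (SWR) and pA·s (PSC charge).

All detection thresholds are defined relative to baseline statistics of the
recording itself, never in absolute units, so the pipeline is invariant to an
overall amplitude rescaling (gain, electrode impedance); this is verified by
property tests.

## SWR detection

1. **Band splitting.** Zero-phase (forward–backward) Butterworth band-passes:
   sharp wave 2–50 Hz, ripple 100–300 Hz. The design order is 2 per pass
   (effective order 4 after the two passes); forward–backward application
   squares the magnitude response and cancels group delay, which matters
   because event boundaries and ripple phase are read off these traces.
   Traces are reflect-padded by at least half a second before filtering.
2. **Event-free baseline (two-pass).** The notion "mean + k·SD of event-free
   recording" needs an event-free mask before events are known. Pass 1 masks
   provisional events with a robust threshold on the rectified ripple trace,
   `median + 6·1.4826·MAD`, dilated by a ±100 ms guard; pass 2 computes mean
   and SD of the signed ripple trace over the remainder. The signed-trace SD
   makes the 6 SD voltage threshold interpretable as a Gaussian exceedance
   level (~2·10⁻⁹ per sample for pure noise). At least 1 s of event-free
   recording is required, otherwise the user is asked for a manual baseline.
3. **Voltage criterion.** Candidates are runs of the rectified ripple trace
   above `mean + 6·SD`; runs separated by ≤ 20 ms merge into one event
   (about 2–4 ripple cycles at 100–300 Hz); events with fewer than 3
   supra-threshold rectified *peaks* are discarded. Peaks, not runs: at
   moderate sampling rates the rectified trace need not dip below threshold
   between half-waves, so run counting would undercount ripples and
   paradoxically drop strong events at permissive thresholds.
4. **Spectral criterion.** For each candidate, the latest fully event-free
   70 ms window preceding it (skipping other candidates) yields the maximum
   absolute coefficient of a complex Morlet transform (cmor2-1
   parameterization: Gaussian envelope bandwidth 2, center frequency 1; 27
   scales log-spaced over 100–300 Hz). The acceptance threshold is
   `mean + 1·SD` of this null distribution; a candidate is accepted iff its
   own maximum coefficient exceeds it. Candidates with no available cutout
   are flagged rather than dropped. At least 3 cutouts are required.
   The CWT uses L1 (1/s) kernel normalization so that the coefficient
   magnitude of a pure tone peaks exactly at the matching center frequency —
   with L2 (1/√s) normalization the peak sits ~1.3% low, more than one scale
   step of the 134-scale display map. Coefficients are computed by
   FFT convolution batched over scales with reflect padding of one wavelet
   support; the implementation agrees with direct time-domain convolution to
   machine precision and with PyWavelets at high precision settings.
5. **Delimitation.** From the dominant-polarity sharp-wave peak, boundaries
   are the nearest flanking local minima within ±100 ms, where a "minimum"
   must be minimal over a 5 ms neighborhood to suppress single-sample noise
   dips. A side that reaches the search edge without a minimum is flagged
   (`rejection_reason="boundary"`) for curation.
6. **Quantification.** Area is the trapezoid integral of the *above-baseline*
   part of the polarity-corrected sharp-wave deflection between the
   boundaries. The clipped (positive-part) integral was chosen over the
   signed integral deliberately: the 2 Hz high-pass gives every sharp wave a
   negative undershoot, and because boundary placement wanders further into
   that undershoot for large events than for small ones (noise truncates
   small events earlier), the signed integral is sublinear in event amplitude
   — on synthetic sessions a 1.7× amplitude effect measured as ~1.63× signed
   but 1.71× clipped. Amplitude is the peak deflection; ripple count is the
   number of supra-threshold positive ripple-trace peaks inside the event;
   ripple frequency is the mean cycle rate `(count − 1)/span` between the
   first and last counted peak (reported for ≥ 2 peaks), which is the
   unbiased cycle-rate estimator and stays inside the 100–300 Hz band for
   short bursts.
7. **Curation.** The by-eye review step is represented as an edit list
   (accept / reject / set_bounds per event index), applied after automatic
   detection; detection with identical inputs and edits is deterministic.

## Gamma analysis

Oscillatory episodes are detected from the rectified, 1 Hz low-passed
band-limited envelope thresholded at `median + 3·1.4826·MAD` (scale-free),
keeping runs ≥ 10 s; explicit annotations bypass detection. An episode is
summarized by the peak bin of a Welch (1 s Hann segments, 50% overlap by
default) or averaged-FFT (4 consecutive segments by default) density
spectrum restricted to the band — gamma 25–90 Hz, theta 4–12 Hz, the
conventional rodent bands — plus `power × duration` as the exposure metric.
Peak ties break toward the lower frequency and are flagged. Band-integrated
power is available as a diagnostic; peak density is the default because the
exposure metric is defined on peak power.

## Plasticity statistics

The unit of replication is the session: per-session means of the windowed
metrics enter the paired tests. Windows default to 120 s ending 10 s before
gamma onset and 120 s starting 30 s after gamma offset. Values are
normalized to the mean of the pre-gamma sample; the reported percentage
change `100·(mean(post) − mean(pre))/mean(pre)` equals the mean of per-pair
normalized differences, whose SEM accompanies it.

The Wilcoxon signed-rank test drops zero differences (their count is
reported), ranks tied magnitudes by average ranks, and computes the null of
`W⁺` exactly for n ≤ 25 by convolving the rank generating function
`∏(1 + x^rᵢ)` over doubled ranks (so average ranks stay integral) — this is
identical to enumerating all 2ⁿ sign assignments, which the tests verify
brute-force up to n = 12. Above n = 25 a normal approximation with tie
correction and continuity correction is used. Two-sided p-values throughout;
all-zero differences yield a flagged degenerate result with p = 1.

Spearman correlation uses average ranks; the two-sided p is the exact
proportion over all n! permutations for n ≤ 9 and the t approximation
`t = ρ√((n−2)/(1−ρ²))` above. No multiple-testing correction is applied by
default.

PSC charge is the magnitude of the baseline-subtracted trapezoid integral
over the event window, with the baseline current defaulting to the median of
the 50 ms pre-event segment; PSC windows default to the concurrent SWR
boundaries. The EPSC-to-IPSC ratio is the ratio of window-mean charges.

## Synthetic sessions

The generator is phenomenological — it reproduces the statistical structure
the analysis assumes, not biophysics. A session is `quiet_pre | gamma |
quiet_post` (defaults 210/180/210 s; the gamma length mirrors a ~3 min
running episode). Quiet epochs carry Poisson SWRs at 1.33 Hz with a
refractory gap of 3 sharp-wave half-widths (keeping ground-truth areas
unambiguous; the gap thins the realized incidence by ~15% at default rates).
Each SWR is a Gaussian sharp-wave bump (FWHM 50 ms, log-normal amplitude
0.35 ± 0.10 mV) whose analytic area `A·σ√2π` is recorded as ground truth,
carrying a ripple burst with an integer number of sine cycles (~7, at a
per-event frequency ~180 ± 20 Hz) under a near-flat Tukey envelope, so the
true ripple count is known exactly. The gamma epoch is a theta carrier
(7.3 Hz) whose phase amplitude-modulates a gamma component (46.3 Hz), with
1 s on/off ramps. Background is 1/f Gaussian noise (SD 0.02 mV, exponent
configurable) plus an optional 50 Hz line. Post-gamma plasticity is injected
by scaling sharp-wave amplitudes (`post_area_scale`), incidence
(`post_rate_scale`) and ripple counts (`post_ripple_count_delta`) in the
post epoch. Current traces place one biexponential PSC (τ_rise 2 ms, τ_decay
15 ms, analytic charge `A(τ_d − τ_r)`) at each SWR onset, negative for EPSCs
at −70 mV, positive for IPSCs at 0 mV. A given config and seed reproduces
every sample bit-for-bit, and the PSC event stream is locked to the LFP
event stream of the same seed.

What the generator does *not* emulate: state-dependent SWR rate drift,
amplitude autocorrelation, overlapping or chained events, electrode drift
and movement artifacts, non-stationary gamma frequency, and realistic
event-shape variability beyond amplitude/frequency jitter. Passing the
benchmarks therefore demonstrates correctness of the measurement machinery
under the assumed signal structure, not field-readiness for every recording;
the curation path exists precisely because real sharp-wave traces produce
incorrect automatic boundaries in some cases.

## Benchmark problem sizes

The validation battery balances statistical power against desktop runtimes;
sampling rates are kept well above twice the ripple band throughout:

* detection fidelity: 20 sessions × 600 s at 5 kHz, recall/precision against
  truth with ≥ 50% interval overlap matching;
* effect recovery: 20 sessions × 600 s at 2 kHz per injected scale (1.25,
  1.70), 120 s standard windows;
* type-I calibration: 200 replicate experiments of 10 compact sessions each
  (95 s at 1 kHz, 40 s windows), Wilcoxon at α = 0.05 — with continuous
  session means the exact n = 10 test attains level ≈ 0.048;
* oracles (areas, signed-rank null, spectral peaks, PSC charges) run in
  seconds at analytic precision.

## Known limitations

* The spectral criterion measures "distinguishable from the event-free
  baseline": on sterile synthetic noise the baseline null is very tight, so
  nearly any supra-voltage-threshold transient passes it; its selectivity
  grows with baseline heterogeneity, as in real recordings.
* Candidate *counts* are not theoretically monotone in the voltage threshold
  (threshold crossings can split or merge); monotonicity holds for the
  supra-threshold sample set and, in practice, for event counts across
  sensible threshold ranges, which is what the property tests assert.
* In vitro SWR quantification reuses the same detection algorithm as the
  in vivo path; a single well-defined pipeline was preferred over emulating
  a second, unspecified commercial implementation.
* The 1/f noise floor is stationary; baseline estimation on strongly
  non-stationary recordings should use the manual-baseline escape hatch.
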