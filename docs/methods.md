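# Methods

## Problem and model

The quantity of interest is the average step length of a person walking or
jogging at a steady pace: the mean maximum separation between the two
ankles, where a transceiver pair is worn. The radio link between the ankles
is short-range and line of sight, so its average behaviour is captured by a
corrected free-space model,

    PL_OA(d) = 20 log10(4 π d / λ) + ΔPL,

with ΔPL a single scalar absorbing hardware non-linearity, insertion and
mismatch losses and mean multipath for the specific transceiver pair
(10 dB for the modelled hardware). Everything the model does not capture —
fading, antenna orientation during limb swing, quantization — appears as
dB-domain scatter around this curve. Inverting the model maps each valid
path-loss sample to an instantaneous distance estimate.

Key assumptions:

* the link is line of sight and body shadowing is negligible (the
  transceivers face each other on the inner ankles);
* the subject's pace is steady, so path-loss samples over the recording are
  draws from one stationary distribution;
* estimation is offline over the whole recording (no windowing or
  streaming).

## Estimation pipeline

1. **Cleaning.** PL = Pt + RSSI per packet (positive-attenuation logging
   convention; a signed-dBm convention is selectable). Samples with
   timestamp < 0.64 s (transceiver synchronization) are dropped by
   timestamp, then samples with PL ≥ the 120 dB sentinel (lost packets;
   `≥` so clipped values go too). All removals are counted, and
   retained + dropped = total is enforced by the data types.
2. **Histogram.** Probability mass per 1 dB bin, centred on integers —
   RSSI hardware reports integer dB, so each distinct value gets its own
   bin. Zero-mass bins are kept: they constrain the fitted tails.
3. **Two-term Gaussian fit.** Nonlinear least squares of
   f(x) = a1·exp(−((x−b1)/c1)²) + a2·exp(−((x−b2)/c2)²) against
   (bin centre, mass) pairs, amplitudes and widths bounded positive,
   initialized at the two most prominent local maxima of a 3-bin moving
   average (falling back to the 25th/75th mass percentiles), width guesses
   5 dB. Terms are relabelled after convergence so b1 < b2; the fit is
   therefore invariant to permuting the initial guesses. Tolerances are set
   near machine precision (1e−15) with at most 10,000 evaluations; on
   histograms that are exactly a two-term Gaussian the residual RMSE is at
   the 1e−17 level. Fitting probability *mass*, not density, matches the
   histogram's y-axis; a histogram normalized to unit total mass is fitted
   as-is (the a-coefficients then carry the normalization).
4. **Thresholds.** Upper: μ + k·σ with μ = b2, σ = c2/√2; k = 1 indoors,
   0.5 outdoors (indoor multipath widens the spread of losses around the
   full-separation events). The threshold is used as a continuous value,
   not rounded. Lower: the observed support value whose empirical survival
   S(x) = P(PL ≥ x) is nearest 0.68, ties toward the smaller value;
   nearest-value matching rather than interpolation because the support is
   integer-quantized. The 0.68 target is an empirical constant of the
   method, not fitted here.
5. **Filtering and averaging.** Values in [lower, upper] inclusive are
   retained (boundary values are not outliers). d̄ is the arithmetic mean
   of the per-sample distances — averaging in the distance domain, since
   the estimand is "the average estimated distance between two ankles".
   Because d(PL) is convex in dB, converting the mean dB value instead
   gives a smaller number; that variant is exposed as
   `mean_domain="db"` for sensitivity analysis only.

When ground truth d0 is available, grid mode sweeps all (lower, upper)
pairs — default candidates μ−3σ…μ and μ…μ+3σ in 1 dB steps — and picks the
pair minimizing the relative error, ties toward the narrower window and
then the lower upper bound (an arbitrary but deterministic convention).

Degenerate inputs behave predictably: an empty series, a histogram with
fewer than six nonzero bins (six free parameters), an unconverged fit, or a
window that retains nothing each raise a specific exception naming the
stage. A noise-free constant-separation trace is such a case — its
histogram is a single spike, so rule mode refuses rather than fit a
meaningless mixture; the channel inversion itself can still be checked on
such traces through explicit filtering.

## The simulator

`rssistep.simulate` emulates the statistical structure of real on-ankle
recordings, not biomechanics.

**Kinematics.** Inter-ankle separation is periodic with the step period T
(0.55 s walking, 0.38 s jogging). Within each period it dwells at the
minimum separation (0.10 m, ankles crossing) for 12 % of T, rises along a
half-cosine, dwells at the maximum — the true step length, 0.7140 m walking
/ 0.9395 m jogging — for 55 % of T, and falls back. The long top dwell
stands in for heel strike through double support and early stance, when
both feet are planted and ankle separation stays near maximal; velocity is
zero at both reversals as in smooth limb motion. A pure rectified-sine
sweep with no top dwell was rejected during design: it spends so much time
mid-swing that the survival-0.68 window is dominated by half-step
separations and no threshold rule of this family can recover the step
length from it, which contradicts the observed behaviour of real
recordings. Dwell fractions are configuration fields, not measured
quantities.

**Channel.** Per sample: clean on-ankle loss at the current separation,
plus zero-mean Gaussian noise (σ = 3 dB indoor, 2 dB outdoor), plus a
one-sided exponential *excess loss* with probability 0.35 / mean 2.5 dB
indoors and probability 0.65 / mean 2.4 dB outdoors, then rounding to
integer dB, then sentinel substitution with probability 0.01. The excess
term models multipath fading and antenna misalignment during movement; it
is what shifts the observed second hump 1–3 dB above the clean-model loss
at full separation, a feature the fitted hump centroids of real dynamic
recordings show consistently. The spike parameters were calibrated once so
that the simulated traces reproduce that behaviour — bimodal histograms
whose rule-derived windows recover the configured step length with
low-millimetre error, comparable to the accuracy reported for measured
data — and were then frozen; they are exposed in the configuration rather
than claimed as hardware measurements.

**What passing tests do and do not show.** The simulator shares the
estimator's channel model by construction, so end-to-end recovery tests
validate the pipeline's statistical machinery (fit, thresholds, averaging,
bookkeeping) under realistic noise, quantization and packet loss — they do
not validate the free-space-plus-10 dB model against real hardware, nor the
0.68 survival constant, both of which come from the measured study. Real
data features the simulator does not emulate: stride-to-stride variability,
pace drift, asymmetric gait, body shadowing, and burstiness of packet loss.

**Default problem sizes.** Presets run 320 s at 0.02 s sampling = 16,000
packets (≈15,840 valid after sentinel removal), matching the scale of one
recorded scenario (10 datasets × >1,500 packets). Recovery acceptance uses
20 independent seeds per preset.

## Numerical choices

* Wavelength from the 2.4 GHz carrier (λ ≈ 0.12491 m); the exact channel
  within the ISM band changes distances by < 1 %, and both the carrier and
  ΔPL are configurable.
* Integer-dB quantization is applied before sentinel substitution, matching
  logger behaviour.
* The sentinel comparison is `≥`, and trace validation requires the
  sentinel to exceed 80 dB so it can never collide with physical on-ankle
  losses (30–60 dB range).
* Survival curves and lower thresholds never interpolate; results always
  lie in the observed support.
* Grid-search tie-breaks: narrower window, then lower upper threshold.

## Known limitations

* Offline batch estimation only; no moving-average/online variant.
* One subject, one transceiver pair per trace; no multi-person handling.
* The indoor/outdoor environment label (choosing k) is a required user
  input, not inferred from data.
* Absolute accuracy on real hardware depends on the ΔPL calibration; an
  uncalibrated ΔPL biases all distances by a common factor of
  10^(δ/20).
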