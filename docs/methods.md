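# Methods

## Scope and model

`marchphys` analyses per-minute wearable data from a loaded field march and
compares cardiorespiratory-fitness tertiles. The analysis chain is:

1. **Fitness estimation.** Peak velocity of a progressive endurance run is
   the speed of the last *fully completed* 200 m stage (a partial stage does
   not count — the conservative convention for incremental field tests; a
   distance below one stage returns the start speed flagged as
   not-completed). VO2peak = 2.309·v_peak + 16.549 mL·kg⁻¹·min⁻¹. Tertiles
   are allocated by sorting on VO2peak and cutting into three contiguous
   groups whose sizes differ by at most one, extras going to the outer
   groups first (55 soldiers → 19/18/18); ties break by stable roster order.
   Tertiles are computed on the full starting roster; per-soldier
   physiology is analysed only for completers, mirroring field practice
   where truncated records are not comparable with complete ones.
2. **Segmentation.** All streams live on a 1-minute grid anchored at the
   march start (0-based, half-open segments). Marching strictly requires
   step frequency > 1 Hz, so exactly 1.0 Hz classifies as BREAK. Interior
   sensor gaps of ≤ 5 min are linearly interpolated; longer or edge gaps
   stay MISSING, and soldiers with > 10% missing minutes are excluded.
   Same-state runs shorter than a 3-minute debounce window are absorbed by
   their longer neighbour, so a momentary stop does not split a march.
3. **Energetics.** PAEE per minute from HR above rest (plus hip counts at
   breaks) with the state-specific linear models given in the README; the
   4.1868 divisor converts kJ·min⁻¹ to kcal·min⁻¹. Negative predictions
   (possible when HRaR < 20.4 bpm in a MARCH minute) are clamped to zero:
   expenditure cannot be negative. REE uses the Mifflin–St Jeor men's
   equation — the cohort modelled is all male; a women's-equation flag is
   reserved but unimplemented — prorated as daily REE × minutes/1440 over
   the non-missing protocol window. The proration is supported by cohort
   arithmetic: the mean soldier's prorated REE (583 kcal over 475 min) sits
   within 3% of the median TEE−PAEE difference (596 kcal). Percent of TEE
   replaced is rounded half-up to an integer. MISSING minutes contribute no
   PAEE and are excluded from proration.
4. **Recovery.** The slow (sympathetic-withdrawal) phase is scored over the
   third break by default: value at the last MARCH minute before onset
   minus value at the tenth break minute, counting the onset minute as
   break minute 1 (a configurable origin, since the indexing convention is
   ambiguous in the field; under clean segmentation the last MARCH minute
   and the minute preceding onset coincide). Breaks shorter than 10 minutes
   or missing boundary minutes mark the metric unavailable rather than
   raising.
5. **Statistics.** Shapiro–Wilk is applied per group (α = 0.05); the
   parametric track requires every group to pass. ANOVA post-hoc pairwise
   comparisons use t statistics on the pooled within-group MSE with
   df = N − k and Bonferroni ×3; the nonparametric track uses
   Kruskal–Wallis with Dunn's pooled-rank z tests (mid-ranks,
   tie-corrected variance) and the same Bonferroni adjustment. Post-hoc
   tests run regardless of the omnibus result and are flagged when the
   omnibus is non-significant. Ordinal questionnaire scores are forced
   nonparametric. The r×c exact test enumerates all tables with the
   observed margins (up to 2×10⁶ candidates) and sums conditional
   hypergeometric probabilities of tables no more probable than the
   observed one; larger problems fall back to a seeded Monte-Carlo sample
   of the same null (≥ 10⁵ draws). Rows or columns with zero margin carry
   no information and yield p = 1.

## Synthetic cohort: what it emulates, and what it does not

The generator's defaults reproduce the structure of a 34 km loaded march by
young male soldiers: 55 starters; age 20.3 ± 1.3 y, height 178.5 ± 7.0 cm,
weight 74.8 ± 9.8 kg, VO2peak 54.2 ± 7.9 mL·kg⁻¹·min⁻¹ (all truncated
Gaussians); a 475-minute timeline from 15:11 with four breaks of 19–24 min
(evenly spaced by default — the true break schedule is not specified
anywhere, only the count and duration range); marching step frequency
1.8 ± 0.1 Hz vs 0.5 ± 0.15 Hz at breaks; intake fractions of TEE
0.22/0.26/0.36 by tertile; pain-coupled dropout.

Key generative choices:

- **HR is generated by inverting the marching PAEE model** from a drawn true
  energy-cost profile (HR = rest + (4.1868·PAEE + 15.9337)/0.7810), plus
  Gaussian sensor noise (default SD 3 bpm). Because the analyzer's
  estimator is affine in HR, it is exactly identifiable: noise-free data
  are recovered bit for bit and noisy estimates are unbiased.
- **The marching energy cost scales with carried mass**: soldier rate =
  9.9 kcal·min⁻¹ × (body weight + 23.2 kg load)/(74.8 + 23.2), ±0.5 between
  soldiers and ±0.3 minute-to-minute. The 9.9 kcal·min⁻¹ reference makes
  the cohort-total PAEE over 475 min land near 4,200 kcal and the cohort
  mean HR near 129 bpm.
- **Resting HR falls with fitness** (−0.35 bpm per mL·kg⁻¹·min⁻¹ of
  VO2peak around the mean, SD 3 bpm): at the same absolute workload the
  least fit third therefore marches at higher HR, the expected
  endurance-training pattern.
- **Break HR decays exponentially** (τ = 2 min) from the pre-break level
  toward a standing-recovery equilibrium (HRaR 40 bpm — chosen to give
  slow-phase recoveries around 30 bpm), and the true break PAEE is defined
  through the break equation applied to the noise-free signals, preserving
  closure.
- **BCT follows first-order kinetics** toward a steady state affine in
  relative intensity (minute VO2 / VO2peak, at ≈ 200 mL O2 per kcal), with
  asymmetric time constants: heating τ = 40 min, cooling τ = 240 min. Core
  temperature rises from ~37.3 °C to a ~38.5 °C plateau — higher for less
  fit soldiers, whose relative intensity is higher — and barely falls
  during a 20-minute break, so BCT recovery is ~0.0 °C.
- **VO2peak is quantized through the run protocol**: the drawn value is
  inverted to a peak velocity, snapped to the 0.5 km·h⁻¹ stage grid, and
  mapped back, so roster velocity and VO2peak are mutually consistent at
  the field test's resolution. The truncation range (25–80 mL·kg⁻¹·min⁻¹)
  is deliberately wide: narrow clipping at an observed sample range would
  bias the mean of the generating distribution.
- **Dropout** is Bernoulli with probability hazard × pre-march pain
  (default 0.06 per pain point; pre-march pain averages slightly higher in
  the less fit tertiles), and a dropout's stream ends at a random march
  minute. Expected dropout is ~13% of starters, concentrated where pain is.

The generator does **not** emulate: GPS position or speed, weather, gait
biomechanics, HR/BCT autocorrelation beyond the first-order BCT kinetics,
device-specific artefacts (spikes, drift, pill transit), appetite dynamics
(intake is a fixed fraction of TEE plus noise), or the transient mid-march
BCT dip some field cohorts show. Passing the closure and recovery tests
therefore demonstrates that the *pipeline arithmetic* is correct and
unbiased under the stated noise model — not that the energy equations
themselves are valid for any particular population, which is a
device/equation validation question outside this package.

## Numerical choices

- Exactly 1.0 Hz → BREAK (marching strictly requires exceedance).
- Negative PAEE clamped at 0 (configurable off).
- Percent replaced rounded half-up (`floor(x + 0.5)`), not banker's.
- "Very heavy" requires strictly exceeding 7.5 kcal·min⁻¹.
- Tertile ties: stable roster order. Debounce ties: the longer neighbour
  absorbs; at equal durations the left neighbour wins.
- Enumeration tolerance for "as or more extreme" tables: probabilities
  within a 10⁻⁹ relative log-tolerance of the observed table count as tied.
- All randomness flows from one integer seed through independent named
  substreams (`SeedSequence([seed, k])`), so roster, streams, diaries and
  questionnaires are individually reproducible.

## Problem sizes in the validation suite

The packaged tests and the acceptance script use a 55-soldier cohort for
pipeline passes, 200 replicate soldiers for the TEE-bias Monte-Carlo
(observed bias ≪ 1% at 3 bpm HR noise), 2,000 replicates for the omnibus
type-I calibration, and 10⁵ draws for Monte-Carlo exact-test cross-checks —
sizes at which the binomial/Monte-Carlo error is well inside the asserted
bands.

## Known limitations

- The PAEE models are linear in HRaR and carry no individual calibration
  (no flex-HR point, no VO2-drift correction over 8 h of work).
- REE proration over the march window assumes the daily REE rate applies
  uniformly across the day.
- The Shapiro–Wilk gate at three groups of ~15 passes jointly only ~86% of
  the time under exact normality; borderline outcomes can switch tracks
  between similar datasets.
- The exact-test p is conditional on the observed margins; no odds-ratio
  style summary statistic is reported for r×c tables.
- Soldiers are generated independently: squad-level pacing correlation,
  terrain and weather effects are absent, so between-soldier variance in
  the synthetic cohort is likely optimistic.
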