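# Methods

`cycleamp` quantifies the infradian oscillation of nightly wearable
cardiovascular metrics — resting heart rate (RHR, BPM) and RMSSD heart-rate
variability (ms) — across the menstrual cycle, and distils it into a single
per-participant statistic, the *cardiovascular amplitude*. This note records
the model, the design choices made where the design was genuinely open, and
what the synthetic testbed does and does not demonstrate.

## Pipeline

1. **Cycle delineation.** A cycle runs from one self-reported bleeding onset
   to the day before the next; day 1 is the onset day. A single non-bleeding
   day flanked by bleeding days is treated as part of the same menses
   (self-reports are noisy) and `bleed_length` spans it; two or more
   consecutive gap days end the menses. The final, unclosed onset yields no
   cycle.
2. **Eligibility.** A cycle is analysed iff its length lies in [21, 35] days,
   bleeding lasts ≤ 7 days, and it belongs to a maximal run of ≥ 2
   back-to-back such cycles whose *pooled* wear fraction (days with an RHR
   reading / total days) is ≥ 0.95. The wear threshold is inclusive and
   pooled over the run; both readings of the criterion were defensible and
   the pooled one was chosen as the closer reading of "across a minimum of 2
   consecutive cycles". An exclusion ledger assigns each removed cycle its
   first failed rule, so rule counts + included = assessed.
3. **Normalization.** Within each participant-cycle and metric, days outside
   the Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR (quartiles by linear
   interpolation; no removal below 4 observed values, where quartiles are
   unstable) are dropped entirely, and the remaining days are expressed as
   offsets from the outlier-free cycle mean. Offsets therefore sum to zero
   per cycle by construction.
4. **Population model.** For each metric the per-day offsets y_i are fit by a
   penalized additive model: a cubic B-spline smooth of cycle day D
   (dimension 20, second-difference curvature penalty, sum-to-zero centering
   against the data; deliberately *not* periodic, because the day domain
   restarts at each onset and the late-luteal rise runs into the boundary)
   plus a ridge-penalized per-participant intercept — the minimal faithful
   random-effect structure. The adjusted variant adds penalized smooths of
   age and prior-day energy expenditure (kJ) and linear weekend and BMI
   terms, with listwise deletion of rows missing a covariate. Smoothing
   parameters are chosen by GCV (coordinate-wise grid search; an approximate
   REML criterion is available behind a flag). Pointwise 95% bands come from
   the Bayesian posterior covariance σ²(XᵀX + S)⁻¹.
5. **Extrema.** The partial dependence of cycle day is evaluated on a 0.01-day
   grid and the population nadir/peak are its argmin/argmax, rounded to the
   nearest integer day (ties toward the earlier day). The grid stops at the
   95th-percentile eligible cycle length: beyond it fewer than one cycle in
   twenty contributes and the spline is boundary-dominated, which otherwise
   produces spurious global extrema from a handful of long cycles.
6. **Amplitude.** For each cycle, the amplitude is the mean offset over the
   7-day window centered on the population peak day minus the mean over the
   window centered on the nadir day. Windows near the cycle edges shift to
   stay fully inside the cycle; an anchor within 3 days of the *population
   mean* cycle end uses each cycle's own final 7 days, reconciling a fixed
   population day (e.g. 26) with lengths 21–35. A window with fewer than 4
   usable days (default) leaves that cycle's amplitude undefined. The
   participant statistic (RHR_amp / RMSSD_amp) is the mean over defined
   cycles. For RHR the peak window is late-cycle; for RMSSD the curve is
   antiphase, so its own model-derived peak (early) and nadir (late) windows
   are used and the same peak-minus-nadir convention applies.
7. **Covariate models.** Participant amplitude is regressed on age (linear),
   the participant's baseline metric (mean raw value over eligible days,
   outliers removed) through a natural cubic spline with df = 4, and BMI
   (linear), Gaussian family. "Four knots" is read as four basis terms with
   interior knots at the baseline quartiles — the literal alternative (4
   interior knots ⇒ 5 terms) contradicts the four-row coefficient table this
   mirrors. The basis is the *cardinal* natural-spline basis (column k is 1
   at knot site k+1, 0 at the others; the lowest-site column is dropped
   against the intercept), so each coefficient reads directly as the
   contribution at its knot site and a hump-shaped dependence loads the
   middle coefficients. Linear functions are exactly representable.
8. **Cohort comparison.** Naturally-cycling vs contraceptive-pill amplitudes
   are compared with a two-tailed Welch t-test (safer than pooled variance
   for unequal group sizes/spreads; the report labels it). The age-matched
   sensitivity analysis uses 1:1 greedy nearest-neighbour matching on age
   without replacement or caliper, processing the smaller cohort in
   participant-id order for determinism, and reports standardized mean
   differences before and after.

## Synthetic cohort

Real cohort data of this kind are proprietary, so the package ships a
generator whose defaults are the published population moments: cycle length
27.4 ± 2.2 days (rounded Gaussian, resampled into [21, 35]), bleeding
4.7 ± 1.0 days (into [2, 7]), baseline RHR 59.7 ± 7.6 BPM, baseline RMSSD
60.4 ± 27.2 ms, daily expenditure 7530 ± 1004 kJ, age 34.9 ± 7.3 y, BMI
24.6 ± 4.3. Injected structure: a within-cycle template scaled by a true
amplitude of 2.7 BPM (RHR) / 4.7 ms (RMSSD, sign-inverted), attenuated by
90% for pill users and declining with age at −0.04 BPM/y and −0.09 ms/y;
weekend effects +0.9 BPM / −1.8 ms; a small linear kJ effect; Gaussian
day-to-day noise of 2.0 BPM / 8.0 ms; 2% missing wear days (bleeding-onset
days always logged, anchoring the cycle calendar); 1% outlier days spiked by
±(4–8)× the noise SD so the Tukey rule catches most of them. The noise SDs
were chosen to be physiologic for nightly wearable aggregates and are
consistent with the reported 7-day window-mean SDs (~1.1 BPM).

**Template.** The within-cycle shape is two wrapped-Gaussian (von Mises)
bumps: a trough of exactly −0.5 at the nadir day (5) with half-depth ±2 days
and a crest of exactly +0.5 at the peak day (26) with half-depth ±1.5 days,
emulating the published pattern of lowest RHR around days 3–7 (end of
menstruation) and highest RHR in the brief late-luteal window of days 25–27.
Anchoring the extrema exactly (range exactly 1) lets any injected amplitude
be recovered against a closed-form oracle. Smooth interpolating splines
through sparse anchor points were rejected because their true extrema drift
off the anchors; a plain cosine was rejected because its near-zero curvature
at the extrema makes the extrema days statistically unidentifiable at
desk-scale cohort sizes. The crest uses a fixed population day (clamped to
L−1 in short cycles) rather than tracking each cycle's end: end-tracking
makes the pooled day-indexed population curve climb monotonically into its
sparse right tail (only long cycles contribute there, each near its own
crest), destroying the extremum that the population model is supposed to
read.

**Windowed ("effective") amplitude.** Seven-day window means never reach the
template's pointwise extrema, so the statistic recovers
`true_amp × template_window_contrast(L)` (≈ 0.5 at the defaults), not the
peak-to-trough amplitude itself. `template_window_contrast` is the
brute-force oracle used by the recovery tests; recovered means sit a further
~0.1–0.2 BPM below it because the Tukey rule occasionally trims genuine
trough/crest days. Recovery tests therefore compare against the oracle, not
against the injected 2.7.

**What the testbed does not emulate.** Anovulatory or pregnant cycles,
luteal-phase-length physiology, autocorrelated (non-Gaussian) day-to-day
noise, device version effects, informative missingness (wear gaps are
independent of physiology), and mid-cycle drift between the trough and crest
(the template is flat there). Passing tests demonstrate that the pipeline
recovers known structure under realistic noise, missingness and cohort
heterogeneity — not that the published real-cohort coefficient values are
reproduced, which is impossible without the proprietary data.

## Numerical choices and degenerate inputs

- Day smooth: basis dimension 20 over the observed day range; doubling it
  moves the extrema by < 0.5 day (tested). GCV grid 10⁻³…10⁷, two
  coordinate sweeps.
- Each curvature penalty carries a tiny (10⁻⁷ scale-relative) null-space
  ridge: participant-constant covariates (age) are otherwise exactly
  confounded with the participant dummies and the normal equations become
  singular.
- Zero-noise inputs: the Tukey fences collapse onto the flat mid-cycle
  offsets and would excise the genuine extremes; `build_offsets` therefore
  accepts `remove_outliers=False`, used by the noiseless recovery tests.
- The Tukey step slightly attenuates any covariate that shifts whole days
  (weekend): elevated days sit nearer the upper fence and are censored more
  often. Model-recovery checks run on untrimmed offsets; the trimmed
  pipeline is checked for direction and significance.
- Flat partial dependence (range ≤ 10⁻⁹) raises "no cycle structure
  detected" rather than returning arbitrary extrema. Single-participant
  fits drop the random-intercept block with a warning. Constant or
  near-constant baseline vectors are rejected by the spline basis.
- Welch test with two constant equal samples returns t = 0, p = 1 rather
  than 0/0.

## Problem sizes

Tests and the acceptance script run the full pipeline on 200 simulated
participants (~800 cycles, ~20k observation-days), the null cohort on 120,
power/calibration loops on drawn amplitude samples (400 and 100 replicates),
and the GLM recovery on n = 5000 × 100 replicates — sizes at which every
recovery property above is comfortably identified while the whole suite runs
in well under a minute.

## Known limitations

- The random effect is an intercept only; participant-specific amplitudes
  (random smooths) are estimated only through the per-cycle windows.
- GCV can undersmooth in small cohorts (< ~50 participants), where extrema
  may wander ±1–2 days; the mgcv cross-check test operates at that scale and
  tolerates it.
- The amplitude statistic anchors every participant to the population
  extrema; individual phase differences appear as attenuation, not as
  shifted windows (per-individual phase estimation is out of scope).
- Term p-values for smooths use a Wald chi-square on the penalized block
  with edf degrees of freedom — adequate for screening, not a calibrated
  smooth-term test.
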