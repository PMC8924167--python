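# Methods

This note documents the models, estimators and design choices behind
`lobsterresp`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement problem

Intermittent-flow respirometry alternates sealed *measure* phases, during
which a chamber's dissolved-oxygen concentration declines as the animal
respires, with *flush* phases during which pumps re-oxygenate the chamber.
The default schedule is a 6-min seal followed by an 8-min flush, sampled
every 10 s, over a 48-h trial — the protocol used for the two spiny
lobster species (*Jasus edwardsii*, resident in Tasmania, and the
range-shifting *Sagmariasus verreauxi*) whose thermal-acclimation design
the synthetic generator emulates.

The per-cycle rate is the standard slope estimator

```
MO2 = (-b * V_eff - B) / M        [mg O2 h^-1 kg^-1]
```

where `b` is the OLS slope of concentration against time within one
sealed cycle (mg O2 L^-1 h^-1), `V_eff` the chamber volume minus the
animal's body volume (body volume defaults to mass / 1.12 g mL^-1, the
mean lobster body density), `B` the background (microbial) respiration
rate and `M` body mass. Background is interpolated linearly between the
pre- and post-trial blank rates; the study-scale magnitude is ~4.5–5% of
the standard metabolic rate.

## Trait definitions

Given the accepted (QC-passing) per-cycle series for one trial:

| trait | definition | default |
|---|---|---|
| SMR | mean of the lowest `ceil(0.1 n)` MO2 values | decile, whole trial |
| RMR (± SD) | mean/SD of MO2 from the recovery window to trial end | window starts 16 h |
| MMR | single highest MO2 of the trial | — |
| aerobic scope | MMR − SMR | — |
| factorial scope | MMR / SMR | — |
| recovery time | time of the 3rd cycle with MO2 < RMR + 1·SD | cumulative count |
| EPOC | trapezoidal ∫(MO2 − baseline)⁺ dt up to recovery time | baseline = RMR |
| recovery rate | EPOC / recovery time | — |

Open points in the protocol were resolved as follows, with both options
implemented where reasonable:

* **EPOC baseline.** A literal area under the curve (no baseline) is
  dimensionally valid but inconsistent with the magnitudes such trials
  report (hundreds of mg O2 kg^-1 over ~10 h implies a mean *excess* of
  a few tens of mg O2 h^-1 kg^-1, i.e. a baseline-subtracted integral).
  Default is baseline = RMR with negative excess clipped at zero; `smr`
  and `none` modes are selectable and the choice is echoed into every
  output row.
* **"Fell three times below" counting.** Cumulative from trial start by
  default (third occurrence anywhere); a consecutive-run variant is
  provided. The two agree on monotone recoveries, which is property-
  tested.
* **The SD in the recovery threshold** is the SD of the RMR window — the
  only SD defined in context.
* **Trial-level escape speed** is the mean over tail-flip events (the
  maximum is also reported).

QC flags (low fit r² < 0.9, cycles shorter than 3 samples, minimum
saturation below 77%, negative corrected rates, zero-variance cycles)
exclude a cycle from *all* trait estimation; nothing is clipped or
repaired. The SMR ≤ RMR ≤ MMR ordering is checked per trial and
violations surfaced, never reordered.

## Thermal analysis

Acute thermal sensitivity uses the standard coefficient
`Q10 = (R2/R1) ** (10/(T2−T1))`, computed from the two endpoint group
means (14.0 and 21.5 °C by default) rather than a log-linear fit across
all three temperatures. Note the algebraic identities: exchanging both
endpoints leaves Q10 unchanged; exchanging the rates only inverts it.
Group summaries report means with t-distribution 95% confidence
intervals (the CI method is a package choice; singleton groups are
flagged, not dropped). Species divergence is
`100 · (mean_comparison/mean_reference − 1)` per pooled cell;
acclimation contrasts are `100 · (1 − mean_warm/mean_cold)`. These
raw-mean contrasts intentionally differ from mixed-model estimated
marginal means: no LME/GLMM fitting is performed here.

## Escape kinematics

A tail flip is delimited by two video clicks (before/after positions in
pixels plus frame numbers, 24 frames s^-1 by default). Event speed is
the Euclidean pixel distance over the frame gap, times fps, divided by
the pixel-per-cm calibration; size-normalised speed divides by carapace
length. Zero-frame-gap events are counted but excluded from speed
statistics. Escape–EPOC association uses Pearson correlation gated by
Shapiro–Wilk normality per variable; a failed gate flags, but does not
suppress, the estimate.

## The synthetic generator

The generator's purpose is parameter recovery: every simulated trial
carries the truth it was built from.

* **True MO2 trajectory.** `RMR + (MMR − RMR)·exp(−t/τ)`. The
  exponential is a modelling choice for testability — its excess
  integral above RMR is exactly `(MMR − RMR)·τ`, giving an analytic EPOC
  target — not a physiological claim about lobsters. Defaults
  (SMR 40, RMR 50, MMR 110 mg O2 h^-1 kg^-1, τ = 3 h) sit inside the
  ranges such trials report, and imply recovery times near 9 h and EPOC
  near 180 mg O2 kg^-1.
* **Quiescence.** Rest bouts dip the baseline from RMR to SMR so the
  lowest-decile estimator targets `smr_true`; bouts follow an
  alternating-renewal process (mean bout 0.7 h, long-run rest share
  0.15) and are suppressed while the recovery excess still exceeds half
  the RMR–SMR gap, since an exhausted animal ventilates rather than
  rests. Sparse activity bursts (0.1 h^-1, rectangular, capped at MMR)
  add realistic upward noise.
* **Chamber forward model.** Sealed phases integrate
  `dC/dt = −(MO2·M + B)/V_eff` at the sampling resolution; flushes relax
  exponentially toward the saturation concentration with a rate constant
  chosen to reach 99% of saturation by the end of the 8-min flush (real
  flush kinetics are not published; only the resulting saturation floor
  is). Gaussian sensor noise (sd 0.01 mg L^-1) perturbs the recorded
  samples, never the chamber state, so concentrations respect physical
  bounds. Implausible parameter sets that would drive concentration
  non-positive raise an error naming the offending cycle.
* **Cohort structure.** The full design is 2 species × 3 acclimation ×
  3 acute temperatures × 6 animals = 108 trials. Trait truths scale
  acutely by trait Q10 (SMR 3.3, MMR 1.4), across acclimation by a
  multiplicative per-step factor (0.85, i.e. ≈28% lower maintenance
  after two warm steps — the "plastic floor"), and across species by
  configurable multipliers (the range-shifter gets +13% MMR, +15%
  escape speed, +28% tail flips). Between-animal lognormal variation
  (CV 0.10) plus tail-flip counts drawn proportional to each animal's
  true EPOC give the escape–EPOC correlation a known positive sign.
* **Seeding.** One global seed expands into per-animal and per-purpose
  substreams by SHA-256 hashing of stable string labels, so partial
  re-runs and re-ordered loops reproduce bit-identical data.

What the generator does **not** emulate: haemolymph chemistry, lactate
or arginine-phosphate dynamics, moulting, diurnal activity rhythms,
drifting sensor calibration, or any behavioural model of the chase
itself. Passing recovery tests therefore demonstrate estimator
correctness under a clean, known data-generating process — not
robustness to every artefact of field respirometry.

## Numerical choices and problem sizes

* OLS slopes via `scipy.stats.linregress` on time in hours; a
  zero-variance cycle returns slope 0 with undefined r² and is flagged
  as degenerate rather than given a fake fit quality.
* SMR tie-breaks use a stable sort, so equal values keep cycle order and
  the estimate is deterministic.
* EPOC integration uses `numpy.trapezoid` on cycle midpoints; with the
  default 14-min cycle the discretisation plus recovery-time truncation
  error on the analytic trajectory is ~2% and shrinks as the cycle
  period does (verified down to a 3.5-min period).
* Parameter-recovery checks use 54 trials of 48 h at the default
  chamber settings (~205 cycles each); the whole acceptance script runs
  in well under a minute on one core. Larger cohorts change only
  runtime, not the estimators.

## Known limitations

* The Svendsen-style slope calculation is the standard reading of the
  protocol; flush carry-over and mixing lags are not modelled, so very
  short flushes would bias slopes in ways the generator cannot reveal.
* Recovery time is undefined (trial flagged "not recovered") when fewer
  than three sub-threshold cycles exist; downstream EPOC and recovery
  rate are then absent rather than extrapolated.
* Group comparisons are raw-mean contrasts with t-intervals; repeated
  measures on the same animal across acute temperatures are not modelled
  (no mixed models by design), so cohort-level inference from this
  package is descriptive.
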