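# lobsterresp

Analysis pipeline for **intermittent-flow respirometry and escape
performance in spiny lobsters** — or any aquatic ectotherm measured with
sealed-chamber oxygen traces and chase-video click tracks.

The package was built around thermal-acclimation experiments on the
Tasmanian resident rock lobster *Jasus edwardsii* and the range-shifting
*Sagmariasus verreauxi*: animals acclimated to 14.0, 17.5 or 21.5 °C,
exhausted by chasing, then sealed in 10 L chambers with 6-min measure /
8-min flush cycles sampled every 10 s for 48 h. From such data it
derives the standard metabolic phenotyping traits and their thermal
structure:

* per-cycle oxygen consumption `MO2 = (−slope · V_eff − background) / mass`
  with QC (fit r², saturation floor, cycle length);
* **SMR** (mean of the lowest 10% of MO2 values), **RMR** (mean ± SD
  after a 16-h recovery window), **MMR** (single highest MO2),
  aerobic scope (MMR − SMR) and factorial scope (MMR/SMR);
* **recovery time** (third cycle below RMR + 1 SD), **EPOC**
  (trapezoidal area of MO2 above baseline up to recovery) and
  **recovery rate** (EPOC / recovery time);
* **Q10** thermal coefficients `(R2/R1)^(10/(T2−T1))` from endpoint
  group means, acclimation contrasts, species divergences, and group
  means with 95% t-intervals;
* **escape kinematics** from click tracks: tail-flip counts, event
  speeds `(d/Δframes)·fps/px_per_cm`, carapace-length-normalised speeds,
  and Shapiro-gated Pearson correlations with EPOC.

A synthetic-data generator produces whole cohorts (traces, chase tracks,
metadata) with known ground truth, so every estimator is testable by
parameter recovery. See `docs/methods.md` for models, assumptions and
limitations.

## Worked example

Simulate one post-exhaustion trial with known truth (SMR 40, RMR 50,
MMR 110 mg O₂ h⁻¹ kg⁻¹, recovery constant τ = 3 h, so analytic
EPOC = (110 − 50)·3 = 180 mg O₂ kg⁻¹) and push it through the pipeline:

```python
from lobsterresp import (
    AnimalRecord, ChamberSpec, SimulationTruth,
    simulate_mo2_trajectory, synthesize_trace, extract_mo2, summarize_metabolism,
)
from lobsterresp.trace_io import BackgroundRecord

truth = SimulationTruth(seed=42)          # SMR 40, RMR 50, MMR 110, tau 3 h
chamber = ChamberSpec()                   # 10 L, 6-min seal / 8-min flush, 48 h
traj = simulate_mo2_trajectory(truth, chamber.trial_duration_h,
                               chamber.sample_interval_s / 3600.0)
trace = synthesize_trace(traj, chamber, truth)

animal = AnimalRecord("demo-01", "J. edwardsii", "m", body_mass_kg=1.12,
                      carapace_length_cm=12.0, acclimation_temp_c=14.0,
                      experimental_temp_c=14.0, body_volume_l=1.0)
bg = truth.background_rate(animal.body_mass_kg)
series = extract_mo2(trace, chamber.chamber_volume_l, animal,
                     background=BackgroundRecord(bg, bg))
s = summarize_metabolism(series)
print(f"SMR  {s.smr:6.1f}  (truth {truth.smr_true:.1f}) mg O2/h/kg")
```

Output:

```
cycles accepted : 205
SMR    40.0  (truth 40.0) mg O2/h/kg
RMR    48.5  (truth 50.0)
MMR   109.7  (truth 110.0)
aerobic scope     69.7,  factorial 2.74
recovery time     8.92 h
EPOC  181.2  (analytic truth 180.0) mg O2/kg
recovery rate     20.3 mg O2/h/kg
```

The 48-h trace yields 205 sealed cycles; the lowest-decile estimator
lands on the true SMR, the highest cycle sits just under the true MMR
(the first cycle midpoint is 3 min into the decay), and the integrated
EPOC is within ~1% of the analytic value. RMR reads slightly below
truth because the animal's quiescent rest bouts — by design — pull the
post-16 h mean toward SMR.

## Command line

Every stage is also a subcommand operating on CSV/YAML files:

```bash
lobsterresp all --seed 1 --outdir results/demo        # full factorial cohort
lobsterresp simulate --outdir results/sim             # traces + tracks + truth
lobsterresp escape --track track.csv --fps 24 --px-per-cm 8 --out esc.csv
```

`all` simulates the 108-trial factorial cohort (2 species × 3
acclimation × 3 acute temperatures × 6 animals), extracts and summarises
every trial, and writes trait tables, group summaries, Q10, divergence
and contrast tables, correlations, figures and a run log (seed and every
mode choice included) under the output directory.

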