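# segflow

On-line monitoring of microbial population segregation by automated flow
cytometry: the statistics, the gating, the file formats, and a mechanistic
simulator of the whole measurement chain.

## The problem

When a bioreactor culture runs into substrate limitation, heat shock or
other process stress, the population splits into physiologically distinct
subpopulations — visible by flow cytometry as, for example, cells with
intermediate propidium-iodide (PI) uptake appearing next to the healthy,
PI-negative majority. Detecting that segregation *while the process runs*
requires (a) an automated sampling interface between reactor and
cytometer and (b) summary statistics simple enough to compute on the raw
event stream, without manual gating. segflow implements both sides in
software, for process engineers and researchers who want to prototype
on-line segregation monitoring or feedback control before (or without)
hardware.

## Statistics at the core

For gate fractions f_R1 (PI-negative) and f_R2 (PI-intermediate), the
**degree of segregation** is

    DoS = 1 − |f_R1 − f_R2|,   DoS ∈ [0, 1]

0 when one gate holds all cells, 1 when the cells are equally partitioned.
The gating-free companion is the **mean-to-median ratio** (MMR) of a
cytometric variable on the linear scale: ≈ 1 for a unimodal,
near-symmetric population, > 1 when a minority subpopulation at higher
intensity skews the distribution. The MMR needs no gates, which is what
makes it usable on-line.

The simulator couples Monod growth (μ = μ_max·S/(K_s+S); batch, chemostat
with dilution rate D, and glucose-pulse operation) to a destabilized-GFP
reporter, dG/dt = α·μ²/h(T) − δ(A,T)·G − μ·G, whose degradation
δ = δ₀ + h(T)·δ_max·A/(K_A+A) is fuelled by a lumped ATP pool A and
boosted by a σ32-like heat-shock factor h(T). A sampling-interface model
plans each 15-minute cycle: duty-cycled in-line dilution into the
instrument's linear range (< 3·10⁶ cells/mL), a ≥ 3-minute PI stain hold,
and a Poisson-arrival acquisition capped at 40,000 events. See
`docs/methods.md` for the full model description.

## Worked example

```python
from segflow import (ExperimentSpec, ReactorSpec, run_experiment,
                     scenario, residence_times)

# batch -> chemostat (D = 0.14 1/h) -> chemostat with glucose pulses
spec = ExperimentSpec(
    reactors=(ReactorSpec("r1", scenario("chemostat_pulses")),),
    duration_h=14.0, seed=1,
)
series = run_experiment(spec, keep_events=False).series["r1"]
frame = series.to_frame()
print(frame[["time_h", "fraction_R2", "degree_of_segregation", "mmr_FL3_all"]]
      .iloc[[8, 12, 24, 36, 52]].to_string(index=False))
print(residence_times(43.0, 0.14))
```

prints

```
 time_h  fraction_R2  degree_of_segregation  mmr_FL3_all
    2.0     0.026084               0.052168     1.294458
    3.0     0.037561               0.075123     1.402334
    6.0     0.361556               0.723112     3.547487
    9.0     0.385595               0.771190     3.564124
   13.0     0.318718               0.637462     3.420023
```

During the batch phase (t ≤ 3 h) almost all cells are PI-negative: the
degree of segregation is near 0 and the FL3 MMR near its unimodal
baseline. After the switch to chemostat operation, sustained substrate
limitation drives cells into the PI-intermediate state — the degree of
segregation climbs above 0.7 and the MMR above 3. Once glucose pulsing
starts (t > 9 h) the limitation is periodically relieved and both
indicators recede. `residence_times(43.0, 0.14)` returns
`ResidenceTimes(volumes=6.02, nearest=6)`: a 43-h stabilization at
D = 0.14 h⁻¹ exchanges six reactor volumes.

The same analysis runs from the shell:

```bash
segflow simulate chemostat_pulses -o out/ --seed 1          # simulate + analyze
segflow analyze sample1.fcs sample2.csv --gates gates.yaml -o out/
segflow calibrate-r3 heat_killed_control.fcs -o gates.yaml  # damaged-cell gate
```

`simulate` writes `series.csv` (one row per sample: gate fractions,
per-channel and per-gate mean/median/MMR, degree of segregation),
`schedule_<reactor>.csv` (the timed pump/stain/acquire actions of one
cycle) and an `events/` directory of per-sample list-mode files.

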