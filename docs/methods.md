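# Methods

This note documents the models, numerical choices and limitations behind
segflow: what is simulated, with which defaults, and what passing the test
suite does and does not establish about real instrument data.

## Segregation statistics

**Degree of segregation.** `degree_of_segregation(f_r1, f_r2)` returns
`1 − |f_R1 − f_R2|` on gate *fractions* in [0, 1]. On a 0–100 percent
scale the same expression leaves the unit interval, so percent-scale
inputs (fractions outside [0, 1], or a pair summing above 1) raise
immediately rather than returning a silently out-of-range value.

**Mean-to-median ratio.** `mmr` divides the arithmetic mean by the median
of the raw linear channel values. The median of an even-sized sample is
the mid-average of the two central order statistics — deterministic and
matching common instrument software. A zero median raises (the sample is
degenerate or off-scale) rather than returning ±inf. The statistic's
value as a segregation indicator lives on the linear scale, where a
minority high-intensity subpopulation pulls the mean away from the
median; a log-scale variant exists as `log_mmr` but is never used by
default. Per-gate MMRs computed from fewer than 100 events carry a
`low_count` flag: with only a handful of cells in a gate the mean and
median stop being meaningful (the sparse early PI-intermediate gate is
the motivating case). Summary statistics are computed on events passing
the forward-scatter acquisition threshold only; no further cleanup is
applied.

## Gating

Gates are rectangles with half-open, lower-inclusive bounds on linear
channel values; half-open intervals guarantee that abutting gates
partition the axis. Overlaps are resolved by explicit integer priority
(higher wins) so labelling is deterministic and testable. Config files
may give bounds in log10 display space; they are converted to linear on
load so all arithmetic happens in one canonical space. The FSC threshold
(default 80,000) is inclusive (`>=`).

The shipped R1/R2/R3 FL3 bounds (decade boundaries at 10^2.5 and
10^3.75) are calibrated to the synthetic generator's subpopulation bands,
**not** to any instrument: published dotplots of this kind of experiment
carry no numeric gate coordinates. For real data the damaged-cell gate is
meant to be calibrated from a heat-killed control (65 °C, 30 min —
maximal PI uptake) via `calibrate_damaged_gate`, which places the gate at
empirical FL3 quantiles of the control (default band (0.01, 1.0), upper
edge unbounded).

## Culture model

Growth follows Monod kinetics, μ = μ_max·S/(K_s + S), with biomass and
substrate balances; chemostat phases add −D·X and D·(S_feed − S), and
glucose pulses add their mass instantaneously at scheduled times.
Defaults — μ_max = 0.55 h⁻¹ (37 °C), K_s = 0.05 g/L, Y_xs = 0.5 g/g —
are conventional values for E. coli on glucose minimal medium, not
measurements. Growth temperature dependence is a piecewise-linear factor
on μ_max (0.65 at 30 °C, 1.0 at 37 °C, 1.05 at 42 °C): growth is
markedly slower at 30 °C and at most marginally faster above 37 °C.
Biomass converts to cell density at 2·10¹² cells per g dry weight, so a
spent 5 g/L batch sits near 5·10⁹ cells/mL.

The ATP pool is a lumped per-biomass scalar: source proportional to
specific substrate uptake q_s = μ/Y_xs, first-order drains for
maintenance (1.5 h⁻¹) and protease work (0.5 h⁻¹). The drains are sized
so starvation empties the pool on a sub-hour scale — the feature that
matters downstream, because protease activity collapses with it. No
metabolic network is modelled.

## Reporter model

Mean per-cell GFP follows

    dG/dt = α·μ²/h(T) − δ(A, T)·G − μ·G
    δ(A, T) = δ₀ + h(T)·δ_max·A/(K_A + A)

* synthesis is proportional to the square of the growth rate (the
  growth-rate-squared rule for this promoter), with α = 4000 a.u.·h a
  free scale constant setting overall fluorescence units;
* degradation saturates in ATP (the protease machinery is
  ATP-dependent): δ_max = 2.0 h⁻¹, δ₀ = 0.02 h⁻¹, K_A = 0.3 a.u. With a
  replete ATP pool the half-life ln2/δ is well under one hour, as a
  destabilized GFP variant requires;
* h(T) is a σ32-like heat-shock induction factor: 1 below 40 °C; on an
  upshift to 42 °C it spikes to 17.5× (midpoint of the reported 15–20×
  transient) and relaxes exponentially over ~5 minutes to a 2.5× plateau
  (midpoint of 2–3×). Cooling below the shock temperature resets the
  induction clock.

Synthesis is divided by the same h(T): while the heat-shock regulon holds
the transcription machinery, expression of the growth-rate reporter
drops. This choice is what lets ATP-fuelled degradation outrun synthesis
at 42 °C — without it, resumed growth after a post-shock glucose pulse
would *raise* GFP, the opposite of the behaviour the package is built to
emulate. It is a modelling decision, not a measured mechanism.

Only the degradation/ATP route of GFP dynamics is modelled. The
alternative explanation for GFP accumulation under prolonged limitation —
protein leakage feeding back on the nutrient-responsive promoter — is
deliberately not mechanistic here; the simulator cannot adjudicate
between the two hypotheses and does not try.

## Segregation dynamics

The PI-intermediate fraction f_R2 relaxes first-order (rate 0.8 h⁻¹)
toward f2_min + (f2_max − f2_min)·L, where L = 1 − S/(S + K_s) ∈ [0, 1]
is the substrate-limitation signal. Defaults f2_min = 0.02 (cultures
start below 5 % PI-intermediate) and f2_max = 0.5 (full limitation can
reach equal partition). The damaged fraction f_R3 changes only through an
explicit `kill_culture` event emulating a 65 °C control. This is a
phenomenological closure: the mechanism linking limitation to membrane
permeabilization is not modelled.

## Event sampling

Events are drawn per-subpopulation: membership multinomial in
(f_R1, f_R2, f_R3); FL3 log-normal with per-subpopulation log10
(location, scale) defaulting to (2.0, 0.15), (3.0, 0.18), (4.5, 0.15) —
bands a decade apart and narrow enough to stay well separated at the
shipped gate boundaries; FL1 log-normal centred on the current mean GFP
(log10 sd 0.12, widened to 0.25 while the heat-shock clock runs,
emulating the broadened GFP distributions seen after a shock); FSC/SSC
log-normal filler with ~0.05 % of events below the 80,000 FSC threshold.
All draws are a pure function of (state, n, seed).

What the generator does *not* emulate: instrument noise floors and
saturation, spectral spillover between channels, doublets/debris,
day-to-day drift, autofluorescence correlated with cell size, or
single-cell gene-expression stochasticity within a subpopulation.
Passing the pipeline tests therefore shows the statistics and plumbing
are correct under clean mixture assumptions — not that gates or MMR
thresholds transfer to a particular instrument without calibration.

## Sampling-interface model

Equal co-pumping of the two 32 mL/min peristaltic pumps dilutes only 2×,
which cannot bring a dense culture (10⁹–10¹⁰ cells/mL) into the
instrument's linear range (< 3·10⁶ cells/mL). The pump sequencing is
therefore modelled as **duty-cycle modulation** of the sampling pump:
intermittent sample injection into the continuous diluent stream, giving
diluted density ρ·(d·Q_s)/(d·Q_s + Q_d) for duty cycle
d ∈ [2·10⁻⁴, 1]. This is an interpretation of how such an interface can
reach large dilution factors, not a documented hardware fact; tubing
geometry is not modelled. The planner picks the largest feasible duty
cycle, reports the required pre-dilution when none is feasible, realizes
the PI contact time as an explicit ≥ 3-minute stain-hold stage (rather
than deriving it from unprinted tubing volumes), and always schedules a
line flush (cross-contamination itself is a non-goal). Acquisition is a
Poisson arrival stream at rate density × cytometer flow (33 μL/min),
recorded for up to 60 s or 40,000 events; the truncated flag is set iff
the cap was reached.

## Numerics and determinism

Integration is fixed-step explicit Euler with dt ≤ 0.01 h (the driver
uses 0.005 h). A step that drives a balance negative raises an
integration-failure error instead of clamping — simpler to reason about
and test than adaptive stepping; a tolerance of 10⁻⁶ absorbs the
discretization round-off of a balance legitimately hitting zero.
Closed-form checks (chemostat residual substrate S* = K_s·D/(μ_max − D),
reporter steady state G* = αμ²/(δ + μ), batch mass balance) hold within
1 % at these step sizes.

Experiment-level randomness derives from one global seed: per-reactor and
per-cycle seeds are SHA-256 hashes of (seed, reactor id, cycle index),
truncated below 2³¹. Hence runs are bit-reproducible, and a reactor's
results are independent of which other reactors share the experiment.

## Scenario defaults and problem sizes

The `chemostat_pulses` scenario compresses the reference cultivation:
batch to ~3 h (heavy 0.6 g/L inoculum so substrate exhausts by the
switch), chemostat at D = 0.14 h⁻¹ for 6 h, then 0.24 g glucose pulses
every 15 min (8 mL of 30 g/L scaled to the 1 L working volume) for the
remainder of a 14 h run. The published 43 h chemostat stabilization
(six residence times) is shortened: the segregation dynamics of interest
(rise under limitation, decline under pulsing) equilibrate within a few
hours at the configured relaxation rate, so the package's standard runs
use the compressed schedule; the steady-state closed-form checks use
their own longer dedicated integrations. `heatshock_pulse` starts three
hypothetical parallel vessels at 30 °C with a 1.2 g/L inoculum (glucose
exhausts well before the 4.5 h shock, so the unpulsed reference meets
the shock ATP-depleted), upshifts to 42 °C at 4.5 h and delivers a 2 g
glucose pulse into the 200 mL vessel. `unimodal_control` pins
segregation off and uses tight FL3 bands (log10 sd 0.06) — the MMR ≈ 1
reference condition. `three_temperatures` is the 37 °C member of the
30/37/42 °C batch comparison.

## Known limitations

* The FCS writer emits only the minimal FCS 3.1 keyword set (list mode,
  $DATATYPE=F, little-endian) plus private SEGFLOW$ metadata keywords;
  the reader handles $DATATYPE I/F and both byte orders but no ANALYSIS
  segments and no compensation ($SPILLOVER is ignored with a warning).
  Whether a given instrument's CSV export is linear or log-scale is not
  detectable from the file; the reader assumes linear raw values.
* Rectangular gates only; automated clustering-based gating is out of
  scope by design.
* The temperature dependence of GFP levels across constant-temperature
  batches (30/37/42 °C) emerges from the interplay of the μ² synthesis,
  the temperature factor on growth and h(T); only its heat-shock
  transient behaviour is validated by tests.
* Subpopulation FL3 bands are stationary; real PI-uptake intensities
  drift as membrane state changes within a subpopulation.
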