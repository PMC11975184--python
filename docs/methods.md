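# Methods

## The cultivation model

The simulator advances a fed-batch CHO culture one day at a time over days
0–12, matching the daily offline-sampling cadence of the process it
emulates; the machine-learning stages only ever see daily points, so
sub-daily dynamics would add cost without adding testable structure.

State per day: viable cell density VCD (10⁶ cells/mL), glucose (g/L),
glutamine (mM), lactate (g/L), cumulative titer (g/L), mean cell diameter
(µm). The daily update is

- growth: µ = µ_max · exp(−((pH − pH_opt)/w)²) · DO/(K_DO + DO) ·
  Glc/(K_Glc + Glc) · Gln/(K_Gln + Gln), with the pH term centered at
  pH_opt ≈ 7.15;
- death: k_d = k_base · (1 + g_age·(day/12)³) plus a starvation boost when
  glucose < 0.5 g/L, capped at 0.85/day so the population decays
  multiplicatively and never reaches exactly zero;
- VCD update VCD' = VCD·(1 + µ − k_d), floored at 0;
- specific productivity: q_p = (α_q·µ + β_q·exp(−((pH − pH_q)/w_q)²)) ·
  (1 + g_Gln·Gln/(K_Gln+Gln)) · Glc/(K_Glc+Glc), with the productivity pH
  optimum pH_q ≈ 7.45 *above* the growth optimum — this growth/production
  trade-off is the central response-surface feature: final titer
  (≈ q_p integrated against VCD) has an interior pH optimum between the
  two, and a mid-run pH shift from a growth-favoring to a
  productivity-favoring setpoint outperforms either static setpoint;
- titer increment q_p·VCD_avg/1000 (the 1000 converts pg/(cell·day) ×
  10⁶ cells/mL into g/L/day);
- feeding: daily macronutrient/micronutrient boluses (+0.5 g/L glucose,
  +0.53 mM glutamine) from the configured feed start day; from day 5 a
  glucose top-up to the configured target (5 g/L standard, 9 g/L enriched,
  0 = none). Samples are drawn before feeding, as in the real workflow;
- diameter grows with culture age weighted by how far growth is below
  µ_max (old, slow cultures have larger cells); viability declines
  logistically with cumulative starvation days plus a mild age term;
- lactate is a simple overflow byproduct (produced proportionally to
  glucose consumption, partially re-consumed when glucose runs low).
  Glutamate is not modelled; neither lactate nor viability feeds the
  machine-learning stage.

### Noise

Measurement noise is multiplicative lognormal (mean-one) with CV
`noise_cv` on VCD, metabolites and (attenuated) viability/diameter. Titer
noise is applied to each day's production increment rather than the
cumulative value, so measured titer remains non-decreasing within a run —
the invariant downstream code relies on. Two run-level lognormal factors
(CV/5 on growth, CV on productivity) model biological replicate
variability; at the study noise level (CV 0.05) standard-condition
replicates scatter with ≈7% CV in final titer, matching the few-percent
replicate spread of the real process.

### Calibration

Free kinetic parameters were fit once by least squares to the published
operating points of the process — standard conditions (VCD_max 23.71·10⁶
cells/mL, titer 3.02 g/L, max diameter 17.3 µm, Q_P ≈ 22 pg/(cell·day)),
the best optimized condition (pH 7.4, DO 40%, VCD₀ 0.5, 8 g/L glucose,
12 mM glutamine, 9 g/L glucose feed from day 1 → titer ≈ 4.65 g/L,
diameter ≈ 18.1 µm, Q_P ≈ 32), a no-feed batch (≈1.8 g/L), an enriched
glucose feed (≈3.2 g/L), and two high-pH/low-glutamine combinations — and
then frozen as the `SimulatorParams` defaults. The noise-free standard
run reproduces VCD_max within ±3·10⁶ cells/mL and titer within ±0.5 g/L
of those targets.

### Experimental designs

`build_design("FULL_58")` reconstructs a 58-run campaign: 3 standard
runs; a two-factor central-composite-circumscribed design over pH
[6.8, 7.5] and DO [20, 100] (axial points on the bounds, factorial points
at center ± range/(2√2), 9 distinct conditions + 2 center replicates);
pH-shift duplicates (7.1 → 7.3 on days 0/3/4/5); feeding/medium
variations (batch in triplicate, richer batch medium, glutamine 9/12 mM,
glucose 9/12 g/L, feed start days 1/2/4/5); six extreme/exploratory
pH–DO–glutamine combinations; a 2³ factorial over feed start day {1,5} ×
VCD₀ {0.1,0.5} × glutamine {6,12} + 2 center replicates; and glucose-feed
variants (no top-up ×3, 9 g/L ×3, 7 g/L ×2). The exact allocation within
the 55 varied runs is a reconstruction — only the totals (58 runs, 754
points) and the group types are fixed by the emulated campaign. The CCC
axial ranges default to pH [6.8, 7.5], DO [20, 100] and are exposed as
config since only the design's shape, not its printed bounds, is known.

## Data model

Runs persist as one JSON document per run (newline-delimited collections)
validated against `choopt/data/run_record_schema.json`; the validator
implements the schema-keyword subset the document uses and reports
violations with JSON paths. Flattening produces one row per (run, day)
with nine numeric inputs — the −1 sentinel encodes "no feed"/"no shift"
so the feature matrix stays numeric — and four KPI outputs computed as
*running* statistics up to the row's process time (running max VCD, titer
at that day, running max diameter, mean Q_P over days 1..t, defined 0 at
day 0). Running outputs are the default because process time is a model
input and carries information only if outputs depend on it; a
`whole_run` mode (full-run KPIs repeated on every row) is available as a
config switch.

## Preprocessing

- Cleaning drops any row with QC flags (contamination, analytics
  failure); surviving rows are untouched. The generator flags 19 of 754
  points by default, so the cleaned table has 735 rows.
- Iterative feature selection fits a 100-tree random forest of the
  remaining candidates on the target and accepts features with impurity
  importance strictly above 0.1. Impurity importances always sum to one,
  so the literal select-remove-refit loop would eventually promote pure
  noise once the real drivers are removed; the loop therefore works on a
  residual target (backfitting): each round subtracts the selected
  winners' out-of-bag contribution from the working target, and stops
  when the remaining pool no longer explains the residual (out-of-bag
  R² ≤ 0). On synthetic data with two known drivers and five noise
  features this recovers exactly the drivers in 20/20 seeds; on the
  simulated campaign it surfaces process time first, then the main
  process levers over three iterations.
- The train/test split is 80/20 at run level by default (no trajectory
  straddles the split); point-level splitting is available. Standardization
  uses training-partition means and population (ddof 0) standard
  deviations; constant columns get scale 1 with a warning.

## Surrogate models

Four families behind one interface (input/output scalers travel with the
fitted model; predictions return in physical units): ordinary least
squares, partial least squares (4 components), random forest (4 trees),
and a multilayer perceptron. The deployed network has five hidden layers
(100, 50, 25, 50, 100), 9 inputs and 4 outputs, adam optimization and
L2 weight α = 0.1. Activation and optimizer settings were tuned once on
the simulated campaign (grid over activation, initial learning rate,
stopping patience): tanh with initial learning rate 3·10⁻³ and patience
30 replaced the rectified-linear default because bounded activations
extrapolate conservatively — with relu, held-out runs at unique input
values occasionally produced runaway linear extrapolations and negative
CV R². Training stops at 2000 epochs or a 10⁻⁶ loss-improvement
tolerance; final regularized loss and training R² are recorded in the
model's provenance.

Cross-validation folds are seeded shuffled partitions at run level by
default, so repeating CV with different seeds samples different fold
assignments. Predictions outside the training min/max of any input are
returned but flagged as extrapolations.

## Screening and validation

Candidates are sampled uniformly: continuous inputs within the training
data's min/max (the surrogate is not trusted beyond its data ranges),
discrete inputs (glucose feed target, feed start day, pH-shift day,
process time) from their observed value sets. Uniform random sampling was
chosen over a grid for dimension-robustness; the candidate count defaults
to 10⁶. Survivors must have predicted titer strictly above the threshold
(default 4.6 g/L). Per-KPI rankings sort descending with ties broken by
candidate index. Process time is sampled like any input rather than fixed
at 12; the report computes the fraction of top-titer survivors at day 12
as a diagnostic (it is ≈1 in practice, as expected for an accumulating
product).

"Not too similar" proposal selection is formalized as greedy max–min
Euclidean distance in scaled input space, starting from the top-ranked
survivor, taking 5 proposals for titer and 4 for each other KPI from each
KPI's top-10 pool. Validation simulates each proposal (pH-shift target
7.4) plus three standard replicates with the ground-truth simulator and
tabulates predicted vs. validated vs. standard KPIs with absolute and
percent changes; the percent denominator for prediction accuracy is the
predicted value.

The pipeline trains the deployed surrogate on all nine canonical inputs;
the feature-selection stage runs as a diagnostic report. This mirrors the
emulated study, where the nine inputs are themselves the outcome of the
importance analysis.

## What the synthetic data does and does not show

The generator reproduces the response structure the analysis needs —
interior pH optimum, feed-timing and substrate effects, degraded
performance at extremes, replicate noise, QC failures — but it is smooth,
low-dimensional and driven by exactly the nine modelled inputs. Passing
tests therefore demonstrate that the loop's machinery (cleaning,
selection, training, screening, validation, reporting) is correct and
that the optimization recovers known optima of a known system; they do
not demonstrate predictive power on a real cultivation process, whose
drivers include unmodelled factors (osmolality, pCO₂, amino-acid
spectrum, clone state). Because the simulated optimum region is sharper
than the real process's, the in-silico titer gains (roughly +80% to
+150% depending on seed) exceed the tens-of-percent gains realistically
attainable; tests assert orderings and minimum relative gains, not those
magnitudes.

## Problem sizes and numerics

Default study sizes: 58 runs × 13 days = 754 points (19 flagged → 735),
80/20 run-level split, threefold CV, 10⁶ screened candidates (10⁵ in the
repeated-seed end-to-end property test), 17 + 3 validation runs. Seeds
derive from a single master seed via `numpy.random.SeedSequence`
spawning, keeping every derived seed below 2³¹; identical configurations
are bit-identical. Degenerate inputs are handled explicitly: zero-width
candidate bounds produce constant columns, constant scaler columns warn
and scale by 1, identical proposal pools warn and fall back to rank
order, constant R² denominators raise.

## Known limitations

- No glutamate, osmolality, pCO₂ or antifoam modelling; no intra-day
  dynamics; lactate/viability are cosmetic.
- The death-rate cap (0.85/day) keeps near-dead cultures at small positive
  VCD; measured VCD in crashed cultures is therefore optimistic by a small
  absolute amount.
- The validator covers only the schema subset the shipped schema uses; it
  is not a general JSON-schema engine.
- Model persistence is in-memory/provenance-based; there is no on-disk
  model directory format.
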