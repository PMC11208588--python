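# Methods

## Scope

`tuggait` implements a complete wearable-IMU TUG analysis chain — synthetic
trial generation with exact ground truth, gait-event detection and phase
segmentation, a fixed 64-feature gait/postural catalog, and the
nonparametric group-statistics battery used for biomarker screening in
HC / TD / PIGD cohorts.  This note documents the model behind the
simulator, the exact feature definitions adopted where several conventions
exist in the literature, the numerical choices, and the limitations of what
the synthetic study conditions can show.

## Trial simulator

### Kinematic model

Each body segment is modeled as a planar sagittal pendulum (shank, arm,
thigh) or as small-angle oscillations in the three anatomical planes (chest
and lumbar sensors); a full 3-D musculoskeletal model is deliberately out of
scope — the model is the minimal one that exercises every feature in the
catalog.

A deterministic event schedule is built first: initial sit, a sit-to-stand
transfer, a walking leg of `distance_m` (default 5 m), a 180° turn, the
return leg, a pre-sit turn, a stand-to-sit transfer.  Steps alternate sides
with per-side step times (the MAS share of the stride is
`step_phase_fraction_mas`) and optional multiplicative per-step timing
jitter.  Toe-off precedes each heel strike by the side's swing fraction of
the local stride.

Angle tracks are then rendered as sums of analytic Gaussian
angular-velocity lobes placed at the scheduled events, so the gyroscope is
the exact derivative of the angle track:

* **Shank:** a positive mid-swing lobe whose area is the commanded
  excursion (forward maximum − backward maximum) and whose width is set by
  the commanded peak angular velocity, plus two narrow negative lobes at
  heel strike ("foot flat", 60 % of the stance descent) and toe off
  ("push-off", 40 %).  This reproduces the classic shank-gyro morphology
  that event detection relies on.
* **Arm:** one anterior and one posterior lobe per cycle, anti-phase with
  the ipsilateral leg, anterior-positive sign convention (a backward
  maximum near 0° means the arm barely passes the vertical; a positive
  value means it never swings behind — the hallmark of the parkinsonian
  reduced backswing).
* **Trunk/lumbar:** ±RoM/2 oscillation per gait cycle and plane; turns ride
  on the transverse (yaw) channel as trapezoidal rate pulses integrating to
  180°; chair transfers ride on the sagittal (pitch) channel as three
  trapezoidal velocity segments (lean forward → rise through the backward
  overshoot → settle), with the middle segment's plateau equal to the
  commanded transfer peak velocity.  The walking yaw oscillation is
  suppressed within ±0.35 s of each turn so the turn pulse is the only
  axial rotation there — physically, the turn *is* the axial rotation.
* **Feet:** world-frame translation with raised-cosine swing velocity and a
  sine-squared 5 cm lift, stationary in stance.  Foot accelerometers carry
  gravity plus this motion term, so zero-velocity-update integration can
  recover placements; foot sensor frames are assumed world-aligned (no yaw),
  a documented simplification that keeps the 1-D footprint geometry exact.

Accelerometers on all other sites read the gravity projection through the
segment orientation (translational terms omitted for torso and limb
sensors).  Signals are clipped to ±8 g / ±2000 °/s and quantized at
0.00024 g / 0.06 °/s; additive i.i.d. Gaussian sensor noise is optional.
All randomness (jitter, noise) derives from one integer seed.

### Fixed-point correction of the shank track

Overlapping lobes shift both the realized extrema and the times of the
negative velocity peaks.  A damped fixed-point loop (18 sweeps, update gain
0.8) adjusts per-cycle lobe areas and event-lobe centers until the realized
extrema match the commanded values (residual ≲ 0.1°) and the realized
negative peaks sit exactly on the scheduled HS/TO times.  Near the
kinematic feasibility edge (wide swings commanded at low peak velocity) the
fixed point may not exist; the updates are clamped (targets within ±15° of
the command, peak-velocity factor within [0.5, 1.8], cumulative center
shifts within ±0.05 s) so the rendered signal stays physiologic, and the
truth channel records whatever is realized.  All feasibility constraints
(swing-lobe width vs. swing window, transfer segment widths, turn ramp
times ≥ ~0.1 s) are checked by `GaitPhenotype.validate`, which also rejects
degenerate walking speeds outside 0.1–3 m/s and over-long trials.

### Ground truth

The truth channel records phase intervals, per-side HS/TO times, foot
placements, per-cycle realized shank/arm extrema and peak velocities
(measured on the analytic pre-noise tracks with the same window rules the
extraction uses), per-cycle trunk/lumbar plane statistics, and the turn and
transfer parameters.  `synthesize_truth` provides the same ground truth
without rendering sensor streams (~100× faster), used for cohort-level
statistical studies; its per-cycle values are the commanded jittered
targets, which the rendered track matches to ~0.1° on every straight-walk
cycle.

## Segmentation

* Zero-phase Butterworth filters: 5 Hz for gait-event structure, 1.5 Hz for
  turn/transfer envelopes, 12 Hz for value reads (peak magnitudes) and
  sub-sample event timing.  Event times are found coarse-to-fine: peak
  structure on the 5 Hz trace, then a local parabolic refinement on the
  12 Hz trace.  A constant gyro bias is removed by median subtraction.
* Turns: |lumbar yaw rate| > 15 °/s with 5 °/s release hysteresis, minimum
  duration 0.5 s, validated by |integrated yaw| ≥ 90°; edges refined by
  extrapolating the 30–70 % band of the outermost velocity ramp to zero,
  which undoes most of the filter's corner rounding.  Integrated yaw is
  evaluated on the wide-band trace over the refined window ±0.25 s.
* Transfers: trunk pitch-velocity envelope > 3 °/s in the pre-walking and
  post-walking search regions, sub-lobes merged across < 0.8 s gaps, outer
  edges refined the same way (each edge anchored on the outermost sustained
  sub-lobe — robust to flat trapezoid plateaus where peak prominence is
  ill-defined).
* Phases: walking fills the gaps between the transfers and turns; overlaps
  resolve by precedence transfers > turns > walking; boundaries snap to the
  sample grid; intervals are half-open `[start, end)` in seconds from trial
  start.
* Orientation: first-order complementary filter (gain α = 0.01 per sample
  at 100 Hz) fusing gyro integration with the accelerometer tilt; yaw from
  plain gyro integration.  The filter state is initialized at the first
  accelerometer tilt estimate.

## Feature definitions

Where the literature offers several conventions, the adopted definition is
stated here and is switchable in code:

* **Cycle retention.**  Steady-state features use gait cycles fully inside
  a walking phase, dropping each bout's first and last cycle
  (acceleration/deceleration transients); bouts too short to spare both
  drop only the first.  Phase coordination drops only each bout's first
  cycle (the step pattern right after standing up or turning is not yet in
  steady anti-phase) but keeps terminal cycles to preserve sample count.
  Turning cycles contribute only to turning metrics.
* **Cadence** uses the step time ending on the reported side
  (contralateral→ipsilateral HS interval), which is what makes per-side
  cadence values differ when the step-phase split is asymmetric.
* **Stride length / velocity** use the path-length method: stride length =
  2 × walkway distance / steps counted in the phase; velocity = stride
  length / cycle time.  **Per-side step lengths** come from consecutive
  ZUPT foot placements, because timing alone cannot resolve a spatial
  left/right split; the feet-together start of the trial fixes the
  inter-foot offset.
* **Asymmetry indices** use the log-ratio convention
  `100·|ln(x_MAS/x_LAS)|` (zero iff equal, symmetric under side exchange);
  an `|L−R|/max` variant would be a one-line change in
  `asymmetry_index`.
* **Symbolic Symmetry Index** is implemented as the normalized per-cycle
  amplitude asymmetry `100·mean(|A_L−A_R|/(A_L+A_R))` over paired
  left/right cycles (A = swing angular amplitude of shank or arm).  There
  is no standard literature formula under this name; this interpretation is
  per-cycle, so cycle-to-cycle motor variability contributes even in
  perfectly side-symmetric gait.
* **Phase coordination**: with the left leg as reference, each stride gives
  φ = 360°·(t_HS,right − t_HS,left)/stride; Mean Phase Difference =
  100·mean|φ−180°|/180°; PCI adds the phase CV 100·SD(φ)/mean(φ) (sample
  SD).  At least 5 phase samples are required, else NaN.
* **Turning**: duration, peak |yaw rate|, steps = HS count (both sides)
  inside the window, step duration = duration/steps, average angular
  velocity = |integrated yaw|/duration; averaged over the mid-path and
  pre-sit turns.
* **Transfers**: window duration, peak |trunk pitch velocity|, and the
  pitch extrema inside the window (anterior lean negative).
* **Missing values** propagate as NaN with QC flags; subjects missing a
  feature drop pairwise per statistical test.  Swing + Stance = 100 is
  enforced algebraically at every aggregation level.

## Cohort generator

Group-level phenotype moments for HC (n = 39), TD (n = 24) and PIGD
(n = 20) are anchored to published group summaries for an early-PD TUG
cohort; median (Q1~Q3) entries are converted with mean ≈ median and
SD ≈ IQR/1.349, and all draws are normal, truncated at ±2.5 SD and
deterministically repaired into the simulator's feasibility region
(ordering of extrema, peak-velocity floors implied by excursions and cycle
time, band-limited turn ramps and transfer lobes).  Three calibration
layers reproduce the bilateral-coordination levels of such cohorts:

* left/right parameter pairs are drawn with a Gaussian copula
  (ρ = 0.76), set in closed form so the expected HC arm-velocity asymmetry
  `E|ln(v_L/v_R)| ≈ √(2(1−ρ))·CV·√(2/π)` lands at the ~20 % level;
* per-cycle amplitude jitter CVs (shank 0.205/0.155/0.17, arm
  0.60/0.50/0.68 for HC/TD/PIGD) set the Symbolic Symmetry Index level via
  `SSI ≈ 56·cv` (half-normal mean of the paired-cycle difference), with
  peak velocities varying at a quarter of the amplitude jitter;
* step-timing jitter CVs (0.047/0.040/0.051) set the PCI level through the
  induced phase SD.

Patients carry MDS-UPDRS item scores generated to be consistent with their
group (TD/PIGD ratio enforced by a bounded deterministic adjustment loop)
and with the intended more-affected side; a latent severity couples the
part-III motor total to arm backswing/velocity, transfer and turning
dynamics (loading 0.45), so severity correlations are non-trivial.
Demographics keep every generated subject eligible (age 45–79, MMSE ≥ 24).
Sensor noise defaults to zero in cohorts: device-grade noise (≤ 1 °/s) has
negligible feature-level impact and noise levels are set explicitly in the
robustness checks.  Two trials per subject are drawn with independent
jitter/noise streams from per-subject seed sequences spawned off the master
seed.

## Statistics

Kruskal–Wallis (tie-corrected, chi-square p) per feature across the three
groups; when significant at α = 0.05, pairwise Mann–Whitney tests with
Bonferroni correction over the three pairs (adjusted p = min(1, 3p));
Dunn's rank test is available behind `StatsConfig(posthoc="dunn")`.
Summaries display mean ± SD when all groups pass Shapiro–Wilk at α = 0.05,
else median (Q1~Q3).  Discrimination uses AUC = U/(n₁n₂) with half credit
for ties, oriented to ≥ 0.5 with the higher-scoring group recorded, and the
tie-corrected normal-approximation p-value.  Severity association uses
Spearman's rank correlation within each subtype, restricted to features
with a significant omnibus test and a significant relevant pairwise
comparison.  The biomarker shortlist groups features by role with default
thresholds AUC ≥ 0.7 and p < 0.05.

## Problem sizes used in the shipped checks

The test suite and the acceptance script use problem sizes chosen to make
each property measurable with comfortable margins: 20-subject mixed
cohorts for signal-level recovery, 3 seeds × 2 phenotypes for event-timing
accuracy, 1000/300/200 random draws for the AUC/Spearman/PCI oracle
identities, the full 34 650-relabeling enumeration for the Kruskal–Wallis
permutation oracle, 2000 null replicates at n = 20/20/20 for the type-I
rate, and 20 cohort seeds at n = 39/24/20 (truth channel) for directional
fidelity.

## Known limitations

* The path-length method ties stride length and velocity across sides, so
  the stride-length/velocity asymmetry indices sit near zero rather than at
  the few-percent level real estimators produce; those two indices carry no
  group signal in this generator.
* Directional fidelity holds in aggregate, but a handful of turning-metric
  orderings have printed between-group effects of roughly one standard
  error at these sample sizes, so their group-mean sign flips in ~10–15 %
  of cohort replicates no matter how the generator is built; per-ordering
  rates are reported by the acceptance script.
* The simulator's flat-foot, yaw-free foot-sensor frame makes ZUPT step
  lengths exact by construction; real foot sensors would require full
  orientation tracking, so the noiseless step-length recovery here is an
  upper bound on field performance.
* Tremor oscillations, freezing of gait, festination and soft-tissue
  artifacts are not modeled (the target population excludes marked
  festination/FoG); the optional 4–7 Hz band-stop for tremor masking is
  therefore off by default and untested against real tremor.
* Turning metrics average the mid-path and pre-sit turns; devices that
  report only the mid-path turn will differ for asymmetric turn behavior.
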