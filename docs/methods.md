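# Methods

## Scope

`rollmetrics` analyses instrumented-wheelchair field recordings: wheel-hub
gyroscopes (100 Hz), a 16-cell piezoresistive seat mat on an independent
clock (100 Hz), and smartphone GPS (1 Hz).  The analysis chain converts
these streams into frame kinematics and seat centre of pressure (COP),
aligns them on a common *distance* scale, and quantifies how strongly the
route drives speed and posture.  Because no public recordings exist, a
synthetic-run generator with known ground truth drives all tests and the
numbered analysis scripts.

## Clock synchronisation

The mat (slave) and IMU (master) clocks differ by offset and skew.  Five
deliberate wheel strikes at the start and end of a run ("trigger
pentads") appear in both streams; the largest spike of each pentad gives
one anchor pair, and the two pairs determine the affine map

    t_m = m·t_s + Δt_B + b,   m = (t_Bm − t_Em)/(t_Bs − t_Es),
    Δt_B = t_Bm − t_Bs,       b = t_Bs·(1 − m),

which maps both anchors exactly (the intercept printed in the source
material is typographically inconsistent; the implemented contract is the
unique affine map through both anchor pairs).  The remaining eight spikes
give a residual SD as a synchronisation-quality figure.  Spike detection
thresholds at 6 robust SDs (1.4826·MAD) above the channel median, merges
detections closer than 0.2 s, searches the first/last 60 s, and keeps the
5 largest detections per window — the strike count is part of the
protocol, and this rejects rare noise excursions past the threshold on
rectified channels.

## Wheel kinematics

A cambered differential-drive model: with wheel radius r = 0.305 m,
camber θ = 3.2° and hub track width w = 0.56 m,

    r_eff = r·cos θ,  w_g = w + 2r·sin θ,
    v = r_eff(ω_L + ω_R)/2,   ψ̇ = r_eff(ω_R − ω_L)/w_g,

with turn radius v/|ψ̇| reported as undefined below |ψ̇| = 10⁻³ rad/s.
The upstream wheel-odometry equations are not published in full; this
reconstruction (effective rolling radius from camber, ground-contact
track wider than the hubs) is a documented choice, and the ~0.13 %
reference-distance calibration absorbs the residual radius ambiguity
(cos 3.2° ≈ 0.9984).  Acceleration uses central differences after a
0.5 s moving average of v (raw 100 Hz differentiation is noise-
dominated); distance is the trapezoidal integral of v.  Distance
calibration scales v, a, distance (and hence turn radius) by
reference/computed.

## GPS

Micro-degree fixes are converted with a fixed small-area scale — 1.11 m
per 10 µ° latitude, times cos(latitude) for longitude, at the track's
mean latitude — matching the printed conversion rather than the WGS-84
ellipsoid (difference irrelevant over 800 m).  Path distance is the
chord-length sum; it is upward-biased under position noise (white σ = 2 m
per axis at 1 Hz roughly triples apparent distance), so GPS distance is
reported as a plausibility figure only; all per-section analysis uses the
wheel-odometry distance.

GPS-to-IMU clock alignment matches the standstill-to-motion ramps at both
ends of a run.  The raw 1 Hz GPS speed is rectified noise (~1 m/s at
σ = 1 m) and never returns to zero, so positions are smoothed with an
11 s moving average *before* differencing; the integer offset minimising
the mean squared speed difference over ±20 s ramp windows is returned.
Measured resolution on simulated runs: exact at σ = 0.5 m, occasionally
±1 s at σ = 1 m.

## Seat mat and COP

Cells are 50 × 65 mm in a 4 × 4 grid with 20 mm gaps; centroid columns at
x ∈ {−105, −35, 35, 105} mm, rows at y ∈ {−127.5, −42.5, 42.5, 127.5} mm
(+x right, +y forward, origin at mat centre).  Each cell is read through
a 70 Ω reference resistor (low side, 3.3 V supply), giving conductance
G = v/(R_ref(V_s − v)).  A 6th-order polynomial (conductance → pressure,
weighted 1/p to control relative error at the soft end) is fitted to
~20 loading-cycle peaks spanning 200 Pa–0.33 MPa; force is pressure times
the nominal 3.25 × 10⁻³ m² cell area.  Readings pinned at the 200 Pa
calibration floor are indistinguishable from no contact and are tared to
zero before the centroid, so unloaded cells do not drag the COP toward
the mat centre.  COP is the force-weighted centroid; all-zero frames
yield NaN-flagged gaps (transient unloading), bridged by linear
interpolation before distance alignment.  Agreement between two COP
series (e.g. mat vs force plate) is summarised per axis by OLS
slope/intercept, Pearson r² and Spearman rank r².

## Distance alignment and section statistics

Channels are resampled onto a uniform distance grid by linear
interpolation of (distance(t), value(t)); the grid uses **bin centres**
(0.5, 1.5, … m for 1 m steps), so no grid point falls exactly on a
section boundary and every point lies strictly inside one of the 13
sections — this is what lets the noise-free round trip reproduce section
means to machine precision.  COP channels get a 4 m moving average after
resampling (a presentation convention; disabled for exactness checks
because it smears section boundaries by construction).  Sections are
half-open [start, end), final boundary closed; distances beyond the
course end plus 0.5 m are flagged.

Per participant and parameter: one-way ANOVA over the 13 sections, all 78
Tukey-HSD pairs, and unsigned Cohen's d with the pooled SD.  These
within-trial statistics are descriptive — a single continuous trial
carries serial correlation — and the cohort filter below is the noise
control.  Tukey-Kramer p-values use an in-package studentized-range tail
probability (range CDF tabulated by quadrature, mixed over the χ scale
of the pooled SD; ~10⁻⁶ agreement with scipy's distribution at a small
fraction of its cost, which makes 50-seed cohort simulations practical).

The effect-size network connects a section pair when its Cohen's d,
averaged across participants, is ≥ 0.8 *and* the pair is
Tukey-significant (α = 0.05) in at least half the cohort; edge weight
maps [0.8, 2.0] linearly onto [0, 1] and saturates at d ≥ 2.  Whether
the original network additionally required per-participant significance
is not fully specified; the majority rule is this package's
documented reading (a `require_significance` switch exposes the pure
effect-size rule).

## Route compliance

Participants' distance-aligned profiles are pairwise correlated; the
squared Pearson R² measures route influence (the route is the only
shared variable).  Each participant is summarised by the median and IQR
of their 6 pairwise values — quartiles use linear interpolation between
order statistics, applied consistently in the IQR and in the low-side
outlier rule (flag if value < Q1 − 1.5·IQR).  Medians are ranked per
parameter (rank 1 = smallest, average ranks on ties), rank sums ordered,
and Kendall's W computed with judges = the 3 parameters and items = the
participants, with the tie-corrected denominator; χ² = m(n−1)W on n−1 df.
On the published rank table this standard formula gives W = 0.683
(χ² = 12.29, p ≈ 0.056), not the printed 0.7857 — the printed value is
not derivable from the stated procedure, so the package reports the
standard formula and asserts instead that two algebraically equivalent W
forms agree to 10⁻¹².  The Friedman test (tie-corrected) is cross-checked
against scipy's implementation.

## Synthetic-run generator

The generator inverts the processing chain so every stage can be tested
against planted truth.

**Speed and COP.** At distance d,

    v = scale·[λ·μ_v(sec d) + (1 − λ)·(v̄ + a(t)·σ_v(sec d))],  floor 0.1 m/s

where λ ∈ [0, 1] is the participant's route-compliance weight, μ_v/σ_v
the per-section mean/SD of the course table, v̄ the length-weighted
course mean and a(t) a unit AR(1) process (φ = 0.98 per 10 ms sample,
~0.6 m correlation at typical speeds).  COPx/COPy mix identically around
their section means, plus an off-centre seating offset on x.  Fully
compliant participants (λ = 1) track section means exactly in the
noise-free limit; individualistic ones (λ = 0) wander around the course
average and decorrelate across seeds.  Within-section SD observed in a
run is (1 − λ)σ, so λ governs both the mean structure and the noise
amplitude — by construction, pairwise R² is monotone in min(λᵢ, λⱼ) and
planted section contrasts survive cohort averaging.  A fast distance-
domain variant (`simulate_aligned_profiles`) draws the same model
directly on the analysis grid (AR correlation length 1 m) for
Monte-Carlo cohort statistics.

**Consequence.**  Simulated absolute R² levels (≈0.05–0.3 medians) sit
below the field-observed 0.31–0.50: real participants share fine-grained
terrain response that this mixing model deliberately omits, because a
cohort-shared within-section texture would make per-participant effect
sizes mutually dependent and planted-effect recovery unstable.  Passing
tests therefore demonstrate ordering and recovery properties, not
absolute R² magnitudes.

**Trajectory and wheels.**  The time loop advances distance with the
current speed (100 Hz); 90° turns at the marked boundaries are smooth
heading changes over a 3 m arc with a configurable speed dip (default
25 %).  Wheel rates come from the exact inverse of the kinematic model,
so the pipeline's forward pass reproduces v to machine precision.  Start
and end get 12 s standstill padding (trigger strikes happen there), a 3 s
start ramp and a 2 m deceleration.

**Mat.**  Cell forces are allocated by bilinear two-cell-per-axis
interpolation so the force-weighted centroid equals the planted COP
exactly (600 N default seated load; requested COP clipped 5 mm inside the
centroid hull — a centroid of non-negative forces cannot leave the hull,
so a 150 mm off-centre sitter is representable only up to ±100 mm).  The
sensor law is pressure = c₁G + c₂G² (linear-dominated conductance rise,
classic FSR behaviour; ~30 kΩ at 200 Pa, ~50 Ω at 0.33 MPa), exactly
invertible and inside the calibration fit's model class, so a clean
calibration recovers it to ~10⁻¹⁰.

**Clocks.**  The mat samples at the same physical instants as the master
but records timestamps through its distorted clock,
t_rec = (t_m − offset)/skew (default skew 1.0005, offset −3.2 s).  This
keeps trigger events exactly on both grids, so the two-point fit recovers
skew/offset to machine precision without sub-sample interpolation.
Timestamp jitter (when enabled) moves the four non-anchor spikes of each
pentad by N(0, σ) rounded to the sample grid; the anchor spikes are the
"clearest and highest" strikes and are modelled clean — this is what
makes the residual SD an unbiased estimate of the jitter.

**GPS.**  1 Hz snapshots of the integrated true path, Gaussian noise
(default σ = 2 m per axis), optional constant multipath offset over a
distance window, optional integer receiver-clock offset.  Local origin at
a fixed suburban reference (−37.82°, 145.03°).

**Randomness.**  All draws flow from one integer seed through named
`SeedSequence` spawn keys (participant streams keyed by `noise_seed`), so
cohorts are bit-reproducible and the CSV round trip is byte-identical.

**Default cohort.**  Seven participants with λ = (0.2, 0.5, 0.5, 0.5,
0.9, 0.8, 0.5): one strongly individualistic, two strongly route-driven,
four intermediate — the spectrum the compliance analysis is designed to
resolve.

## What the generator does not emulate

No slopes, surface vibration, slip, or traffic agents; no FSR hysteresis,
drift or viscoelastic phase shift (the sensor law is static and exact);
GPS noise is white, not the correlated multipath of urban canyons (a
constant offset window stands in for it); clock drift is strictly linear.
Field-recorded cohort values (per-participant medians like 1.44 m/s,
validation R² of 97.7 %/98.5 %) are inputs to the rank machinery where
printed, not simulation targets.

## Problem sizes and numerical choices

Analysis grid 1 m (789 points); simulations 100 Hz (~65 000 samples per
run); Monte-Carlo suites use 10–50 seeds per property and a two-section
160 m mini-course where only the sync chain is under test.  Turn-radius
floor 10⁻³ rad/s; COP gaps NaN-flagged, not raised; Tukey p-values
accurate to ~10⁻⁴–10⁻⁶ vs scipy; quartiles linear-interpolated
throughout.  The acceptance script (`scripts/acceptance.py`) re-runs all
of the above from scratch in under a minute on one CPU.
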