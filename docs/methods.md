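# Methods

## Models

### Single-cell growth and division

Cells grow exponentially, ds/dt = μs, with a single growth rate μ shared
by every cell (growth-rate noise is deliberately not modelled; it is one
of the known extensions listed under limitations).  Division is binary and
exactly symmetric: both daughters receive s_d/2, with no partitioning
noise.  Three division strategies are implemented:

* **timer** — the cycle duration τd is drawn at birth from a gamma
  distribution, independent of size.  Gamma laws are parameterised
  throughout by (mean, CV²): shape k = 1/CV², scale θ = mean·CV²; CV² = 0
  is treated as a point mass, not a degenerate gamma.  Cell sizes are not
  tracked for timers (under the exponential timer the stationary size
  distribution has no finite moments, and none of the timer statistics
  need sizes).
* **adder** — the added size Δd is drawn at birth from a gamma
  distribution; the cell divides at s_d = s_b + Δd after
  τd = ln(s_d/s_b)/μ.
* **rate-based adder** — mechanistic variant in which the division
  propensity per unit time is μ·s(t)/Δ̄d, i.e. constant hazard 1/Δ̄d per
  unit of *added* size.  Division times are drawn by inverse transform on
  the integrated hazard Λ(τ) = (s_b/Δ̄d)(e^{μτ} − 1), which makes Δd
  exponential with mean Δ̄d (CV²_Δd = 1).  Because this path never calls
  the gamma sampler it serves as an independent implementation check of
  the Δd-sampling adder at CV²_Δd = 1.

Division times are computed in closed form at birth and processed in
event order — there is no time discretisation anywhere in the simulator.
Ensembles draw one RNG substream per colony from the master seed
(`numpy` `SeedSequence.spawn`), so colony i is bitwise reproducible and
independent of the ensemble size.  Two samplers share this law: the
per-agent event heap (`simulate_colony`), which keeps full agent records
(birth/division times and sizes, lineage links), and a
generation-vectorised counts path (`simulate_counts`) that draws whole
generations per colony at once and keeps only division times; the test
suite cross-checks their moments.  The counts path makes 10⁴-colony
ensembles to 12 doublings a matter of seconds.

### Timer calibration

To compare timer ensembles across noise levels on a common footing the
mean cycle time is chosen so that the *population* doubles once per unit
time.  The asymptotic growth rate λ of a branching process with i.i.d.
gamma cycle times solves the Euler–Lotka relation 2·E[e^{−λτd}] = 1;
setting λ = ln 2 and inverting gives the closed form

    τ̄d = (2^{CV²} − 1) / (CV² · ln 2),

which reduces to τ̄d = 1 as CV² → 0 and to 1/ln 2 for the exponential
timer (CV² = 1), consistent with the Yule-process mean ⟨N(t)⟩ = e^{μt}
with μ = 1/τ̄d.  The calibration is verified by simulation at CV² = 0.2
(doubling ratio within 2%).

### Population statistics

Colonies are synchronised at progenitor birth (t = 0, N = 1) and N(t) is
right-continuous (a division at t counts at t).  Ensemble moments use the
unbiased (n−1) variance and the plug-in CV² = σ²_N/⟨N⟩²; uncertainty is
quantified by a percentile bootstrap (default B = 1000, seeded) that
resamples *colonies*, preserving within-colony time correlation.  Two
closed-form oracles anchor the exponential timer: N(t) geometric with
success probability e^{−μt}, and CV²_N(t) = 1 − e^{−μt}.

For size-coupled (adder-family) colonies the total biomass obeys
B(t) = Σᵢ sᵢ(t) = s_b e^{μt} exactly, across division events, because
symmetric halving conserves size and all cells share μ.  Consequently
CV²_B equals the progenitor size noise CV²_sb at every t, and the
decomposition CV²_N ≈ CV²_B + CV²_s/⟨N⟩ ties the late-time population
noise floor to the progenitor noise.  A diagnostic routine reports both
sides of the decomposition per grid point; the approximation is
asymptotic in ⟨N⟩ and is reported, not asserted, at small N.

Adder ensembles keep oscillating around their noise floor even at 12
doublings (colonies divide near-synchronously and dephase slowly), so the
"plateau" is estimated as the phase average of CV²_N over one full
doubling period ending at the evaluation time.  Oscillation detection for
the timer's damped ringing uses local maxima after a 3-point moving
average, which suppresses single-point Monte-Carlo jitter.

## Capsule geometry

Cells are approximated as sphero-cylinders (capsules): a cylinder of
diameter w capped by two hemispheres, tip-to-tip length L.  The canonical
capsule formulas are used throughout:

    A_p = w(L − w) + π(w/2)²        (projected/silhouette area)
    A   = πLw                        (surface area)
    V   = πLw²/4 − πw³/12            (volume)

These are the unique forms consistent with the spherical limit L = w
(A_p = πw²/4, A = πw², V = πw³/6) and with A = πLw.  Width inference
solves the quadratic (π/4 − 1)w² + Lw − A_p = 0; the quadratic
coefficient is negative, so the admissible root in (0, L] is unique and
exists iff A_p ≤ πL²/4.  Frames that violate this (possible under
measurement noise for near-spherical cells) are dropped and counted.

Noise propagation is first-order delta method with L and w independent:
CV²_F ≈ CV²_w (w ∂F/∂w / F)² + CV²_L (L ∂F/∂L / F)².  For A this is
exactly CV²_w + CV²_L; for the cylinder-only volume πLw²/4 exactly
4·CV²_w + CV²_L; the full capsule V uses its exact partials.  Accuracy
against Monte-Carlo with lognormal marginals is within 10% for CV² ≤ 0.05.
Power-law scaling of a dimension against length is fitted by OLS in
log-log space (estimator choice; R² reported on the log scale).

## Lineage-table analysis

Input is a frame-level table: `colony_id, cell_id, parent_id, time_min,
length_um, projected_area_um2`, parent −1 marking colony progenitors.
Width, surface area and volume are derived per frame; cycles are
reconstructed from the tracking topology (birth = first appearance,
division = first appearance of the daughters) and each cycle is fitted
per proxy by OLS of log size on time, extrapolating to the boundary
instants.  Cycles are excluded — with full accounting, no silent drops —
for nonpositive sizes, fewer than 3 frames, or zero time spread.
Censored cycles (no observed division) contribute birth-size statistics
only.

### Boundary convention

Birth and division events are only localised to within one frame interval
Δt.  The default `"midpoint"` convention places each boundary half an
interval before the first frame of the newborn(s); the estimated sizes
are then unbiased to first order in μΔt (≈9% per interval at the default
conditions), whereas the `"frame"` convention (boundary at the frame of
appearance, also available) carries a systematic e^{μδ}, δ ∈ [0, Δt)
factor of up to +5% on the means — larger than the bootstrap CIs at
realistic sample sizes.  Midpoint is therefore the default.

### Measurement-error correction

Extrapolated s_b and s_d carry estimation noise from two sources: the
propagated OLS error of the log-linear fit (computable per cycle from the
fit covariance), and boundary-localisation jitter, modelled as a uniform
offset over one frame interval, contributing multiplicative variance
(μΔt)²/12 per boundary.  Both inflate the across-cycle variances of s_b
and Δd (by ~10–15% of CV²_Δd at the default conditions) and bias the
Pearson correlation R(Δd, s_b) downward (the shared fit makes the s_b and
Δd errors anticorrelated).  The summary therefore subtracts the mean
estimated measurement variance from the observed variances and covariance
before forming CV² and R — a moment-based errors-in-variables correction;
corrected variances are floored at zero and raw plug-in values are
reported alongside (`*_raw` fields).  Colony progenitors are synchronised
to the movie start, so their *birth* carries no localisation jitter and
the jitter term applies to their division boundary only.  Validation
against ground truth
shows the per-cell error variance predicted by the correction matches the
realised one to a few percent, and corrected estimates are unbiased
within bootstrap CIs.

Newborn-size statistics are reported for two pools: all fitted newborns
(default headline) and the colony-progenitor subset.  The progenitor
subset is what drives the CV²_N plateau (CV²_B = progenitor CV²_sb), so
the proxy-comparison stage always simulates with the progenitor-subset
s_b statistics.  Bootstrap CIs resample cycles (or progenitors); the
bootstrap recomputes the correction per resample.

### Proxy comparison

For each proxy, an adder ensemble (gamma s_b from the progenitor stats,
gamma Δd, μ = ln 2/τ̄d) of 10× the observed colony count is simulated on
the observed frame grid, truncated to frame times at which ≥90% of
colonies are still being imaged (movies end at different times; the rule
avoids late-time censoring bias) and to t at or after the first observed
division.  The discrepancy per proxy is the mean squared difference of
CV²_N over the grid, weighted by the inverse bootstrap variance of the
observed CV²_N; proxies are ranked by discrepancy.  Only the
dimensionless statistics (CV²s, s̄_b/Δ̄d, μ) matter for N(t); absolute
size units cancel.

## Synthetic data generator

The generator emulates DeLTA-style segmentation/tracking output under the
measured study conditions, which are its defaults: surface area as the
governing proxy; doubling time 75.2 min (μ = ln 2/75.2 per min); gamma
added area, mean 4.75 µm², CV² 0.058; gamma progenitor area, mean
5.69 µm², CV² 0.025; 10-min frames; 154 colonies; 6 generations tracked
(the final generation appears but never divides — censored, as in a real
movie); multiplicative lognormal measurement noise of cv 3% applied
independently to length and projected area (the magnitude of the
shape-approximation error of the capsule fit).

Each cell draws one width per cycle from a gamma with mean 0.96 µm and
CV²_w = 0.010 (cv ≈ 10%).  The mean width makes A = πLw reproduce the
measured newborn length and area jointly; the width noise is the value
implied by the measured newborn length and area noise under the
independence assumption (CV²_A − CV²_L ≈ 0.025 − 0.0147).  Width draws
are subject to the geometric feasibility bound of the capsule — a cell of
area A admits no width above √(A/π) — enforced by per-cell rejection
(≤100 tries; exhaustion triggers a colony redraw, and more than ~1%
redraws aborts, as that signals parameters outside the capsule regime
rather than bad luck).  This truncation matters because descendants relax
to the stationary newborn mean s̄_b = Δ̄d, giving aspect ratios near 1.6
whose upper width tail would otherwise be infeasible.  Daughters inherit
half the governing-proxy size; widths are re-drawn independently
(mother–daughter and sister correlations are measured by the analysis but
deliberately not generated).  An optional within-cycle width-noise
profile (`width_noise_slope`) scales CV²_w linearly across the cycle
phase to emulate width-noise relaxation; it defaults off.

Two consequences of this construction are worth knowing when writing
tests against it.  First, with an *area*-governed adder and widths drawn
independently of area, the derived length L = A/(πw) carries *more* noise
than area — the classic CV²_L < CV²_A < CV²_V ordering presumes length
and width are the independent pair.  Ordering assertions on generated
data therefore use a length-governed configuration; on the default
area-governed data the three proxies still carry distinct noise levels,
which is all the proxy-identification stage needs.  Second, the scenario
of interest — progenitor mean above the stationary newborn mean
— makes the pooled all-newborn statistics a generation mixture; recovery
tests compare against ground-truth moments of the matched pool, or
against the generator parameters via the progenitor subset.

What passing tests on synthetic data do *not* show about real data: the
generator has no growth-rate noise, no partitioning noise, no
lineage correlations, no tracking errors, and its measurement noise is
i.i.d. lognormal; estimator performance on real segmentation output can
be worse in ways these tests cannot reveal.

## Numerical conventions

* Times in minutes, lengths in µm throughout the analysis layer; the
  simulator is unit-agnostic.
* Gamma (mean, CV²) parameterisation everywhere; CV² = 0 → point mass.
* Width inversion tolerance 1e−9 relative on the bracket; the forward
  projected-area evaluation reproduces A_p to 1e−9.
* Adder closure s_d − s_b = Δd and the biomass identity hold to machine
  precision (asserted at 1e−12 and 1e−9 respectively).
* Default ensemble grid: 64 uniform points; default bootstrap B = 1000
  (smaller in tests, stated per call); all bootstraps seeded.
* Cycle-phase noise bins: equal width in minutes, default 8; bins under
  20 cells merge into their left neighbour, with the merge count
  reported.

## Problem sizes

The test suite and the acceptance script use 10⁴-colony ensembles for
population-noise checks, 10⁴ cycles/newborns for distributional checks,
50 replicate synthetic datasets (154 colonies each) for parameter
recovery, and 20 replicates for proxy identification — sizes at which the
Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

* Growth-rate and partitioning noise, and mother/daughter or sister
  correlations, are measured (where applicable) but never simulated.
* The biomass decomposition diagnostic is asymptotic; at small ⟨N⟩ the
  reported sides differ by construction.
* The plateau of CV²_N is approached slowly; at 12 doublings a residual
  oscillation of a few percent of the plateau value remains, which is why
  plateau estimates are phase-averaged.
* The errors-in-variables correction assumes i.i.d. multiplicative
  measurement noise and uniform boundary offsets; correlated segmentation
  errors would violate it.
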