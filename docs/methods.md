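# Methods

## Constitutive model and kinematics

The aortic wall is modeled as an incompressible hyperelastic membrane. A
biaxial state is described by the circumferential and axial stretches
(λθ, λz); the radial stretch follows from incompressibility,
λr = 1/(λθ λz), so the deformation gradient is diag[λr, λθ, λz] in
cylindrical coordinates. The stored energy combines a neo-Hookean term for
the elastin-dominated amorphous matrix with four exponential fiber families
(axial, circumferential, and a symmetric ±α₀ diagonal pair that shares its
two parameters), giving eight independent parameters: c (kPa), c1/c2 per
distinct family, and α₀ (degrees). The ansatz Ŵ denotes the energy with
incompressibility substituted in, i.e. a function of C_θθ and C_zz only.

In-plane Cauchy stresses are obtained by eliminating the Lagrange
multiplier with the membrane condition σ_rr = 0. This thin-wall closure was
chosen over mean-wall equilibrium for a single consistent closed form that
is directly testable against finite-difference oracles; with wall
thickness-to-radius ratios near 40/600 the two differ by less than half the
luminal pressure in the normal stresses, which is absorbed into the fitting
objective. Stress and stiffness derivatives are analytic (not automatic
differentiation) and validated in the test suite against central
differences of the energy by two independent routes, at 1e−6 (stress) and
1e−4 (stiffness) relative tolerance.

Two numerical guards matter in practice. Fitted exponents can be printed as
small as ~1e−14, so below c2 = 1e−8 each family term uses its exact
quadratic (Taylor) limit (c1/4)(IV−1)², avoiding 0/0. Exponential
arguments are capped at 500 so that bracketing searches and optimizer
starts probing extreme stretches stay finite; the cap is far outside the
physically reached range and never binds at a solution.

## Experimental reduction

Raw records are per-sample CSVs of (pressure mmHg, outer diameter μm,
axial length mm, axial force g) tagged by protocol: pressure–diameter
sweeps at the in-vivo axial stretch and ±5% of it, and force–length sweeps
at 10/60/100/140 mmHg. Axial stretch is current length over the recorded
unloaded length. Loaded inner radius and thickness follow from conservation
of wall volume; the circumferential stretch is taken at mid-wall. Mean wall
stresses use thin-wall hoop equilibrium σθ = P·ri/h and the axial force
balance σz = (f + P·π·ri²)/(π·h·(2ri + h)), with 1 mmHg = 0.1333224 kPa and
1 gf = 9.80665 mN. Only the last recorded cycle of each protocol is
retained (pseudo-elastic behavior; hysteresis is not analyzed), and
pressure–diameter protocols keep the loading limb. Rows outside sanity
bands (P ∈ [0, 200] mmHg, f ∈ [−2, 10] g) or inconsistent with the wall
volume are rejected and logged with reasons.

The in-vivo axial stretch is the force-invariance point: for each axial
stretch sampled by the force–length protocols the slope of force vs
pressure is fitted by least squares, and the zero crossing of slope vs
stretch is located by linear interpolation. If all slopes share a sign the
tested range does not bracket the working point and the sample errors out
rather than extrapolating.

## Parameter estimation

The objective is least squares on both stress components, each normalized
by the per-component mean experimental stress, which balances hoop
(~hundreds of kPa) against axial stress and makes the objective invariant
to unit changes. Fitting stress–stretch pairs directly (rather than raw
P and f) keeps every objective evaluation a closed-form vectorized
expression — no root-finding inside the optimizer. The exponential terms
create local minima, so a bounded trust-region least-squares solver
(stress-like parameters in [0, 500] kPa, exponents in [0, 30], angle in
[0°, 90°]) is restarted from Latin-hypercube samples of the box; the
default is 24 starts, deterministic given the seed. Among starts tied at
the best objective the smallest parameter 2-norm wins, which pins
near-non-identifiable parameters (a family with c1 = 0 leaves its c2
unconstrained) at zero reproducibly. The reported RMSE is
sqrt(objective/(2n)); it is a relative error measure for ranking fit
quality, not a quantity with an external reference value.

## In-vivo metrics

The constitutive law closes into a structural response through
P = σθ·h/ri at the incompressible loaded geometry. The circumferential
stretch at a prescribed pressure is found by bracketed root search over
λθ ∈ [0.5, 3] followed by Brent polishing (residual < 1e−8 mmHg); the
lower bracket extends below 1 so the traction-free state at a fixed axial
stretch — a small circumferential contraction that minimizes the energy —
is representable. Diastole and systole are fixed at 80 and 120 mmHg.
Reported per vessel at the estimated in-vivo axial stretch: biaxial
stretches, wall stresses (kPa), circumferential/axial small-on-large
stiffness (MPa), stored energy (kPa), loaded thickness and luminal
diameters (μm), and cyclic distensibility. Diastolic/systolic diameters
for distensibility are the model-predicted luminal diameters, decoupling
the metric from acquisition noise. Distensibility is reported both raw
(mmHg⁻¹) and ×10³ for display, since the raw values are of order 1e−3.

## Allometric classification

Luminal systolic diameter scales with body mass as d = α·BM^β. A log
transform makes this linear; α and β come from OLS of ln d on ln BM fitted
to wild-type vessels only, then applied to all genotypes. The residual SD
s_log uses an n−2 denominator. Because individual vessels are being
screened, the "normal range" is a prediction interval for a new
observation, t-quantile times s_log·sqrt(1 + 1/n + leverage); the narrower
mean-response band is available behind a flag. The call is one-sided:
only the upper bound flags "dilated" (aneurysm context); lower-tail
outliers are flagged "small" separately. Normalized diameter is measured
over expected; above 1.5 the vessel is "aneurysmal", the clinical
convention. With these choices a healthy cohort is flagged at the upper
tail rate of the two-sided band (~2.5%), which the suite verifies by Monte
Carlo at n = 2000.

## Cohort statistics

Spearman's rank correlation uses mid-ranks for ties (normalized diameters
can tie after rounding). The p-value uses the t approximation
t = rs·sqrt((n−2)/(1−rs²)) on n−2 df, with exhaustive permutation
enumeration available (and the default) for n ≤ 8; the exact null at such
n is a coarse lattice, so the t approximation is only trusted for
decisions away from the atoms adjacent to the threshold. Strength labels:
mild |rs| ≤ 0.5, moderate 0.5 < |rs| ≤ 0.75, strong |rs| > 0.75,
boundaries inclusive as written. No multiple-testing correction is
applied; correlations are reported per metric and the output notes this.
ANOVA/Tukey/normality checks are convenience wrappers around standard
routines. Group summaries report mean ± SEM (SD/√n), with SEM missing —
not zero — for singleton groups.

## Synthetic data

The generator produces vessels whose ground truth is exactly the model
plus thin-wall equilibrium, under the bench protocols: pressure–diameter
sweeps at the in-vivo stretch and ±5% resampled on an even 10–140 mmHg
grid (each grid pressure solved exactly rather than interpolated), and
force–length sweeps truncated to the −0.5 to 5 g transducer window.
Reference parameter sets for eight genotype/age combinations are built in,
with printed values below 1e−3 kPa treated as exact zeros. The default
unloaded geometry (Ro = 540 μm, H = 90 μm, L = 4 mm) is a fixture chosen
to land loaded dimensions at murine scale (systolic thickness ~30–40 μm,
luminal diameter ~1.2–1.6 mm). Each simulated vessel's in-vivo stretch
truth is its own force-invariance point found by grid search plus root
polishing, so the stretch-estimation stage has a meaningful recovery
target; an explicit override exists.

Cohorts draw body masses uniformly on 15–35 g and assign systolic
diameters from the allometric law (α = 671.7862 μm·g^−β, β = 0.2816,
s_log = 0.04 — a realistic ~4% biological scatter) times a genotype
dilatation multiplier; the unloaded radii are then scaled so the
mechanical model reproduces the drawn diameter exactly (the equilibrium
stretches are invariant under uniform radial scaling), with 5% CV noise on
thickness and length. Measurement noise is multiplicative Gaussian on
diameter (CV 1%) and force (CV 2%) and additive 0.5 mmHg jitter on
pressure — typical camera/load-cell/transducer precision. All randomness
flows from a single seed.

What the generator does not emulate: hysteresis and preconditioning drift,
viscoelastic creep, smooth-muscle tone, residual stress/opening angle,
image-tracking artifacts, and any thick-wall stress gradient. Passing
tests therefore demonstrate correctness of the analysis pipeline under its
own modeling assumptions, not robustness to every feature of bench data.

## Problem sizes and determinism

Default per-vessel data: 27 pressures × 3 pressure–diameter protocols plus
≤28 stretches × 4 force–length protocols (~180 points after windowing).
Multi-start fits use 24 starts by default; the noisy-replicate and
grid-refinement checks in the suite use 8 starts and 5 replicates, and the
calibration checks use cohorts of 2000–4000 (body-mass/diameter pairs
only, no mechanics). Every stochastic stage is reproducible from an
integer seed; pipeline reruns with the same configuration are
byte-identical.

## Known limitations

- The membrane (σ_rr = 0) closure biases stresses by O(P/2) relative to a
  mean-wall treatment; for self-consistent synthetic data this cancels in
  recovery, and for bench data it is absorbed into the objective.
- Parameters of a family whose c1 fits to zero are not identifiable; the
  norm tie-break reports them as zero rather than arbitrary values.
- The normalized fitting RMSE is not comparable across objective
  definitions used elsewhere; it is internal to this package.
- Distensibility at murine scale is of order 1e−3 mmHg⁻¹; the ×10³ display
  column exists because the raw unit invites misreading.
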