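# Methods

This note records the model assumptions, parameter conventions, numerical
choices and known limitations behind `wolbsim`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model structure and assumptions

The population is a well-mixed, spatially homogeneous pool tracked through
egg, combined larva/pupa, and adult (male/female) stages, each split by
*Wolbachia* status — eight ODE compartments in total. Core biological
assumptions:

- **Exponential stage durations.** All transitions (hatching δ, emergence
  ψ) and deaths (stage-specific μ's) are constant per-capita rates; mean
  lifespans are the reciprocals of the death rates.
- **Instant impregnation.** Females are treated as impregnated immediately
  on emergence, with the father drawn from the current male pool in
  proportion to abundance; there are no separate pregnant/nonpregnant
  compartments. Released infected females are likewise counted as already
  impregnated.
- **Maternal transmission.** A fraction `v_w` of an infected female's eggs
  are infected regardless of the father; the remainder join the uninfected
  egg pool.
- **Cytoplasmic incompatibility.** A fraction `c_i` of eggs from
  uninfected-female × infected-male matings are nonviable, so the
  uninfected-egg birth rate per uninfected female is
  `phi_u * (M_u + (1 - c_i) * M_w)` with `M_·` the male proportions. At
  the wAlbB baseline `c_i = 1` (complete CI) and `v_w = 1` (perfect
  transmission).
- **Logistic larval regulation.** The hatch inflow into the larval pool is
  throttled by `K = 1 - (L_u + L_w)/K_l`. `K` is *not* clamped: initial
  conditions are required to satisfy `L_u + L_w <= K_l`, under which `K`
  remains in [0, 1] along any trajectory (the only term that could push
  larvae past capacity vanishes at `K = 0`). This keeps the right-hand
  side an exact transcription of the model equations and makes the guard
  testable.
- **Degenerate male pool.** When no males exist the infected-male
  proportion is defined as 0 (uninfected as 1). Any state reachable from
  valid initial data that has females but no males has vanishing birth
  flux anyway, so the convention does not alter dynamics; it only avoids
  0/0.

## Parameters

Defaults (per day unless noted) are the wAlbB-in-*Anopheles* baseline:
`delta = 1/3`, `psi = 1/18`, `mu_fu = 1/13`, `mu_fw = 1/15`,
`mu_mu = mu_mw = 1/7`, `mu_eu = 0.12`, `mu_ew = 0.33`, `mu_l = 0.01`,
`phi_u = 3.8`, `phi_w = 3.3` eggs·female⁻¹·day⁻¹, `v_w = c_i = 1`,
`b_f = 0.5`, `K_l = 2e5` individuals. The egg death rates encode hatch
fractions δ/(δ+μ_e) of 73% (uninfected) vs 50% (infected) — the dominant
fitness cost — and the laying rates encode a fixed ~50-egg lifetime output
divided by the respective female lifespans. `K_l` sets overall scale only:
every reported quantity (R0, fractions, release *factors*) is
scale-invariant, which the tests exploit.

## Analytic layer

Closed forms are transcriptions of the model's equilibrium algebra, not
re-derivations: next-generation numbers `G0u`, `G0w`; `R0 = G0w/G0u`; the
disease-free and complete-infection equilibria; and the coexistence
equilibrium parameterized by the larval ratio `r = L_w/L_u`, which solves

    (v_u/v_w)·k·r² + ((v_u/v_w)·k − 1)·r + (1 − R0)/R0 = 0,
    k = (δ+μ_ew)/(δ+μ_eu),

degenerating to `r = (1−R0)/R0` at `v_w = 1`. The coexistence forms assume
complete CI and equal male death rates (male rates then cancel entirely;
the code warns if they differ by more than 1%). Two numerical points:

- **Root selection.** When the quadratic has two positive roots, the
  *threshold branch* is the smaller one — the root that stays finite as
  `v_w → 1`; the larger diverges like `1/v_u`. The small root is computed
  by the rationalized formula `2c/(−b + √(b²−4ac))` to avoid cancellation
  (naïve evaluation loses ~4 digits at `v_w = 0.999`, enough to corrupt
  the `v_w` elasticity).
- **Threshold fraction.** The invasion threshold is *defined* as the
  female infected fraction at the unstable coexistence equilibrium,
  `c·r/(1+c·r)` with `c = mu_fu/mu_fw`. The ODE-basin probe below is an
  independent oracle, not the definition; the closed form is what makes
  the larval and male parameters exactly inert in the threshold's
  sensitivity row.

Stability is classified from the eigenvalues of the analytic Jacobian
(cross-checked against central differences at relative step 1e-6): stable
if every real part < −1e-9, unstable if any > +1e-9, otherwise "marginal"
— never silently stable, since eigenvalues cross zero exactly at
bifurcation points. The bifurcation scan varies `phi_u` over a log-spaced
grid chosen to cover R0 ∈ [0.3, 1.5] (60 points by default; the plotted
range of the scan is a package choice, as no canonical range exists).

### Basin-probe geometry

Bisecting initial states for establishment confirms that the separatrix
passes through the unstable coexistence equilibrium: probing along a short
segment through that equilibrium (in the wild→infected direction) recovers
the closed-form threshold fraction to ~1e-5. Probing along the *global*
chord from the wild-type to the fully-infected equilibrium instead locates
a crossing whose female fraction is ~0.006 higher at baseline — a genuine
curvature effect of the stable manifold, independent of horizon and
bisection resolution, not a numerical error. Both probes are implemented
(`basin_threshold_by_bisection(probe=...)`); the local probe is the
default because it measures the quantity the threshold is defined by.

## Sensitivity analysis

Elasticities `S = (p/q)·∂q/∂p` are evaluated at baseline by central
differences with relative step 1e-3 (analytic forms override for R0). The
step sits far below the two-significant-figure resolution at which the
indices are reported, and is large enough that the 1e-8-tolerance ODE
solves underlying the time QOI do not contaminate the quotient. Two
conventions:

- `v_w = 1` is the domain boundary, so `v_w` is perturbed downward only
  (first-order one-sided difference, same relative step).
- The composite `mu_adults` perturbs all four adult death rates by the
  same relative amount; its R0/threshold indices vanish identically
  because the female-rate elasticities are exactly antisymmetric and male
  rates are inert.

The time QOI is the establishment time (sustained time to 90% female
infection, see below) of a reference programme: 0.6/0.6
larviciding+fogging mitigation, release factor 2, five batches over 60
days. A perturbation under which the programme fails to establish yields a
flagged NaN in the table, never a silent drop. The time row is the one
place where scheme details matter at the second digit (the underlying QOI
involves interpolated crossing times); its values should be read at ±0.1
accuracy.

## Interventions

- **Release-factor convention.** Factor `F` = `F·Fu0` infected females
  *and* `F·Fu0` infected males per release (per-sex, not a summed total),
  with `Fu0` the unmitigated DFE female count. Under this reading a
  factor-1.13 single release puts the initial female infected fraction at
  53%, comfortably above the 34.7% natural-distribution threshold — the
  margin a transient needs because the released adults are not backed by
  infected eggs and larvae. The summed-then-split reading would leave a
  marginal 36% and does not reproduce the measured threshold factors.
- **Batch schedule.** `n` equal batches at times `start + i·window/n`
  (i = 0..n−1): five batches over 60 days leave a 12-day gap. Batches are
  applied as exact impulses (integrator stop–add–restart), not smoothed
  source terms.
- **Timing metric.** "Time to reach 90%" is the *sustained* crossing: the
  first time after which the chosen infected fraction stays above target
  through the horizon. A large adult release can jump the female fraction
  above 0.9 instantaneously (factor 9 starts at exactly 9/10) while wild
  eggs and larvae continue to emerge and dilute it; counting the first
  instantaneous crossing would make the time-limited threshold factor an
  artifact of the initial jump and erase the batch-count optimum. The
  female fraction is the default metric; the all-adult fraction is
  available via `metric="adult"` (the two differ by ~1 day at the
  reference scenarios).
- **Establishment.** Classified at a 3000-day horizon by final female
  fraction vs 0.5; bistability separates trajectories decisively, so the
  cutoff value is immaterial given the horizon. An unresolved case
  (fraction in [0.4, 0.6]) doubles the horizon once, then errors.
  Threshold factors are bisected to resolution 0.005 (0.05 for the
  time-limited variant) inside [0, 20]; the time-limited thresholds use a
  single batch at day 0.

## Seasonality

Rainfall drives breeding-site availability, so seasonality enters only
through `K_l(t) = K_l·s(t)` with `s` a mean-one, strictly positive,
365-day-periodic multiplier; temperature variation in the target region is
too small to move the rate parameters. `s` is a least-squares Fourier fit
(mean + two annual harmonics — the minimal bimodal-capable form) to 12
monthly totals at month midpoints, affinely rescaled about 1 so that
max/min equals a prescribed amplitude ratio. The default amplitude is the
raw max/min of the input series.

The synthetic monthly series `[30, 40, 80, 150, 260, 160, 120, 150, 190,
160, 90, 40]` mm emulates a bimodal Caribbean pattern — primary peak in
May, secondary in September, January minimum, raw amplitude ratio ~8.7 —
calibrated once so that the fitted curve is driest near day 21 and wettest
near day 134 and so that the dry/wet release dichotomy below holds at
release factor 1; it was not revisited afterwards. Seeded variants jitter
the base series by ~2% (lognormal), small enough to preserve the peak
ordering and the extreme-day calibration.

Seasonal release experiments first integrate the uninfected system for two
years to land on the periodic attractor (a plain seasonal steady state,
so day-of-year comparisons are not confounded by transients), reference
the release factor to the female count on day 1 of the year, then release
in batches from the chosen start day. What the fixture does *not* emulate:
year-to-year rainfall variability, within-month structure, humidity or
temperature pathways, or any real station record — conclusions are
qualitative (dry-season releases need fewer mosquitoes than wet-season
ones), not site predictions.

## Numerics

LSODA (stiff-capable) with rtol 1e-8, atol 1e-6 on the count scale,
config-overridable; dense output retained per integration segment so
threshold crossings are located by bracketed root finding to well within
±0.1 day. Trajectories failing a nonnegativity tolerance of −1e-6 × state
scale abort with an error; in practice compartments stay above −1e-9 ×
scale over 10⁴-day runs. With the constant multiplier `s ≡ 1` the seasonal
code path reproduces constant-capacity trajectories bit-for-bit (same
solver inputs), which the tests assert exactly.

Problem sizes used by the shipped analyses: establishment horizon 3000
days, basin bisection to 1e-3, bifurcation scans of 25–60 points,
batch-count grids up to factor 4–5 × 8 batch counts. These are full-size
for this model — the system is eight ODEs and every quantity is
desk-scale.

## Known limitations

- Deterministic mean-field only: no demographic stochasticity, so
  threshold statements are sharp where a real release faces extinction
  risk near the boundary.
- No spatial structure; a local release in a spatially extended population
  has a different (generally higher) threshold.
- Coexistence-equilibrium closed forms assume complete CI and equal male
  death rates; outside that regime they are approximations (the code
  warns).
- Parameterization is specific to the wAlbB strain; strains without
  complete CI or perfect transmission need their own `v_w`, `c_i` and
  fitness-cost values.
- No coupling to human malaria transmission: the package evaluates
  replacement of the vector population, not the downstream epidemiological
  effect.
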