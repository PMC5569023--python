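# Methods

## Scope and intent

`cartdegen` implements the iterative, overload-driven collagen-fibril
degeneration algorithm for knee cartilage at desk scale. The
subject-specific front end of the full workflow — MRI segmentation,
whole-knee and medial-compartment finite-element contact simulation — is
deliberately replaced by surrogate loading models and a synthetic cohort
generator, so the algorithm, its constitutive core and the
group-separation statistics can be exercised, tested and modified without
imaging data or an FE solver. No claim is made of reproducing any real
subject's stress fields or absolute degeneration magnitudes; the package
targets the algorithmic behaviour (thresholds, accumulation dynamics,
self-limitation, group ordering), which is what its tests verify.

## Constitutive model

Cartilage is fibril-reinforced poroviscoelastic (FRPVE): a nonfibrillar
matrix (proteoglycans and interstitial fluid) plus primary
(well-oriented) and secondary (randomly-oriented) collagen fibrils. The
package carries the full parameter set per region:

| parameter | tibial | femoral | units | role |
|---|---|---|---|---|
| `E_m` | 0.106 | 0.215 | MPa | nonfibrillar modulus |
| `E_0` | 0.18 | 0.92 | MPa | initial fibril network modulus |
| `E_eps` | 23.6 | 150 | MPa | strain-dependent fibril network modulus |
| `nu_m` | 0.15 | 0.15 | – | Poisson's ratio |
| `eta` | 1062 | 1062 | MPa·s | fibril damping coefficient |
| `k_0` | 18 | 6 | 1e-15 m⁴/(N·s) | permeability (carried, unused) |
| `n_f` | 0.8 − 0.15 z | 0.8 − 0.15 z | – | fluid fraction profile (carried, unused) |

Because no consolidation (Darcy-flow) problem is solved, `k_0` and `n_f`
are carried for completeness only, and the fluid pressure in the total
stress split is zero. The literature source for these constants prints
the two permeabilities as a single run-together figure; the 18 / 6 split
used here follows the tibial > femoral ordering typical of human knee
cartilage and has no effect on any computation. The nonfibrillar stress
is provided as plain linear isotropic elasticity from (`E_m`, `nu_m`);
the degeneration algorithm consumes only fibril tensile stress, so this
term exists to complete the total-stress decomposition, not to drive
degeneration.

The single-fibril law is the first-order viscoelastic rate relation

σ_f + [η / (2√((σ_f − E₀ε_f)·E_ε))]·σ̇_f
  = E₀ε_f + [η + ηE₀ / (2√((σ_f − E₀ε_f)·E_ε))]·ε̇_f  for ε_f > 0,

σ_f = 0 for ε_f ≤ 0.

Published statements of this law vary typographically (operator placement
and the square-root argument differ between printings); the form above is
the internally consistent reading, and its two model-defining limits are
enforced by tests: the tension-only branch, and the static limit
σ_f = E₀ε_f when both rates vanish.

### Time integration

The rate law is stiff near σ_f → E₀ε_f, where the square-root vanishes.
Integration is implicit backward Euler: at each increment the new σ_f
solves the discretized relation with σ̇_f and ε̇_f as backward
differences. The square-root argument is clamped from below at
`REG_FLOOR = 1e-9 MPa²`. The nonlinear scalar equation is solved by
damped Newton (numerical Jacobian, at most 50 iterations) with a
bracketed Brent fallback; if unloading pushes the unconstrained root
below zero the fibril is slack and σ_f = 0 is returned directly. On
smooth protocols away from the singular onset the observed convergence
order under dt-halving is 1, as expected for backward Euler; ramps
started exactly at the slack state show a reduced observed order (~0.85)
because of the square-root singularity at loading onset — a property of
the ODE, not of the solver.

## Degeneration algorithm

Per element and gait cycle, the per-increment factor is
D_t = ((S_t − T)/T)/100 for S_t > T (strictly; S_t = T does not
degenerate, following the printed branch conditions) and 0 otherwise,
clamped at 1. The level updates as
D_i = D_{i−1}·(1 − W^(1/1.5)) with W = Σ_t D_t·INC_t, the 1.5-th root
applying to the weighted sum only. Numerical choices:

- D is clamped to [0, 1]; W > 1 (possible only under extreme synthetic
  loading) drives D to exactly 0. W = 0 returns D unchanged bitwise, so
  subthreshold tissue is an exact fixed point.
- Iteration semantics: the trajectory index starts at the intact state
  (D₁ = 1); a run of `n_iterations` records `n_iterations` states and
  performs `n_iterations − 1` updates, the first of which uses stresses
  evaluated at D = 1. Under constant loading the loop therefore equals
  the closed form D_i = (1 − W^(2/3))^(i−1), which a test checks to
  1e-12 relative.
- INC_t is in seconds and the stance increments sum to 0.8 s, so W is a
  (dimensionless factor × seconds) quantity; iteration "time" is left in
  arbitrary units and never rescaled.
- Reported degeneration is 1 − D (0 = intact, 1 = fully degenerated), so
  outcome metrics increase with severity. An element counts toward
  degenerated volume when 1 − D > `degenerated_epsilon` (default 1e-9,
  i.e. any degeneration); the epsilon is exposed for sensitivity
  analysis because a severity cutoff is an equally defensible counting
  rule.

## Loading surrogates

The FE contact step is replaced by two regimes that bracket the
load-versus-displacement-control ambiguity:

- **static_field** (load control): prescribed per-element stress
  histories, independent of D. Degeneration accrues steadily; this is
  the conservative regime and the cohort default.
- **strain_driven** (displacement control): prescribed fibril strain
  histories pushed through the viscoelastic law; the modulated stress is
  exactly proportional to D, so softening tissue sheds load and
  degeneration is self-limiting (a fixture test verifies trajectory
  convergence with a Cauchy tail < 1e-6). The proportionality is also
  exploited computationally: the intact-tissue history is integrated
  once per element and scaled by D thereafter, which is exact.

The per-element tensile stress S_t is the maximum over the element's
fibrils of the degeneration-modulated fibril stress ρ·D·(C or 1)·σ_f.
This is a surrogate choice: an FE pipeline could equally threshold the
maximum principal total stress. The fibril weights ρ and C are not part
of this parameter set and default to 1.

The gait waveform is a double-peaked stance profile (loading response
and push-off) on a uniform grid: two Gaussian bumps (width 0.12 of
stance) at normalized times 0.25 and 0.75, each rescaled so its on-grid
maximum equals the requested peak, combined by pointwise maximum so peak
values are attained exactly. Default 50 increments per 0.8 s stance;
the FE increment count being emulated is unknown, and 50 resolves the
waveform while keeping a 100-iteration run cheap.

## Synthetic cohorts

`generate_cohort` emulates three severity groups of 7 subjects each (the
group size the statistics layer is designed around). Each subject is a
two-region grid mesh — 20×20 femoral elements of 1 mm³ and 20×20 tibial
elements of 0.125 mm³, matching ~1 mm and ~0.5 mm element sizes — under
a static contact-patch loading: a 2-D Gaussian bump over the grid
(normalized coordinates in [−1, 1], patch at centre) times the gait
waveform. Group severity enters through both the amplitude and the patch
width, because at near-equal body weight the potentially more severe group is
distinguished by larger degenerated areas rather than higher load:

| group | peak stress (MPa) | patch width | rationale |
|---|---|---|---|
| KL0 | 5.5 | 0.10 | below the 7 MPa threshold: radiographically intact |
| KL2 | 8.5 | 0.22 | suprathreshold excess 1.5 MPa |
| KL3 | 10.0 | 0.38 | roughly twice the KL2 excess, larger contact area |

The amplitude ratios were chosen once so the suprathreshold excesses
(and hence accumulated degeneration) reproduce the qualitative group
ratios reported for this class of simulation — intermediate-grade
maximum degeneration roughly half the severe-grade value, volumes
ordered more steeply — rather than scaling amplitudes with body-mass
index alone, which would make the two OA grades statistically
indistinguishable at this sample size. Subject variability is
multiplicative log-normal noise on the amplitude (σ = 0.1), drawn from a
single seeded generator so cohorts are bit-reproducible. A KL0 subject
crosses the threshold only for noise multipliers above 7/5.5 ≈ 1.27
(≈1% of draws), so KL0 peaks are "mostly below" threshold by
construction.

What the generator does *not* emulate: realistic contact mechanics
(menisci, kinematics, congruency), depth-dependent fibril architecture,
inter-element stress redistribution as neighbours soften, and any
subject-specific geometry. Consequently, passing cohort tests shows the
algorithm and statistics behave correctly under controlled group
structure — not that the pipeline would separate real clinical groups.
One visible artefact: under static loading the maximum degeneration is
identical across regions whenever they share the same stress field,
since the static regime never consults the material parameters; regions
then differ only through element volumes. Even-sized grids have no
element exactly at the patch centre, so on-grid peak stresses are
slightly below the nominal amplitude — on the default 20×20 grid the
attenuation is ≈0.6%.

## Statistics

All comparisons are nonparametric, designed for n = 7 per group:

- Mann–Whitney U (wins convention: U counts pairs where the first sample
  exceeds the second, ties half). `exact` mode uses the exact permutation
  null — feasible since C(14,7) = 3432 — and is delegated to
  `scipy.stats.mannwhitneyu(method="exact")`, cross-checked in the test
  suite against full enumeration of all labelings; `auto` switches to
  the tie-corrected normal approximation when ties exist or a sample
  exceeds 12. Two identical samples (zero variance under ties) are
  reported as p = 1 directly.
- ROC curves sweep all distinct scores plus sentinels, calling a subject
  positive when its score is at or above the threshold. AUC is the
  trapezoidal area, identical to the tie-adjusted pairwise-ordering
  fraction; its significance is the exact Mann–Whitney p through
  AUC = U/(n₁n₂), avoiding normal-approximation error at n = 7. The
  Youden cutoff maximizes sensitivity + specificity − 1; ties are broken
  toward the higher threshold (higher specificity, fewer false
  positives).
- The three-group confusion matrix uses two cutoffs: below the low
  cutoff → KL0, in [low, high) → KL2, at or above the high cutoff → KL3,
  swap-normalized. By convention the low cutoff is taken from the
  KL0-vs-KL2 ROC and the high one from the KL0-vs-KL3 ROC; both are
  explicit arguments, since other pairings are defensible. With this
  pairing the high cutoff sits near the smallest severe-group score, so
  intermediate-grade subjects above it are called severe — reproducing
  the characteristic pattern that the extreme groups classify well while
  the middle grade shows the most confusion.
- Group summaries report mean, median and a Student-t 95% confidence
  interval of the mean (undefined and flagged at n = 1).

## Problem sizes and determinism

Default experiment size: 21 subjects × 800 elements × 50 increments ×
100 iterations, a few seconds on one core because the per-iteration
update is vectorized over elements. The test suite uses 9×9 grids
(odd, so the patch peak is attained on-grid) with 12 increments and
30 iterations for cohort tests, and single- or two-element meshes for
algorithmic oracles. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical seeds give bit-identical
cohorts, trajectories and results tables.

## File formats

Meshes, loading specifications and results tables are plain structured
text (see module docstrings in `cartdegen.mesh` and `cartdegen.loading`);
floats are serialized via `repr` / 17 significant digits so every
round trip is bit-exact. A legacy-ASCII VTK unstructured-grid export of
per-element fields is provided for qualitative inspection of
degeneration maps; its geometry is a schematic raster of unit hexahedra,
since the mesh type stores no nodal coordinates.

## Known limitations

- Only collagen degenerates: proteoglycan loss, water-content change and
  permeability remodelling are out of scope.
- No poroelastic solve: fluid pressure is zero, and `k_0` / `n_f` are
  inert parameters.
- The degeneration threshold is a single constant (7 MPa); age- or
  subject-dependent failure limits are not modelled.
- Loading surrogates cannot redistribute load between elements, so
  spatial degeneration patterns are entirely determined by the imposed
  stress field.
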