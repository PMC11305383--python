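# Methods

## Biovolume estimation

Test volume is the body-size measure; each specimen carries one shape
class and the linear axes that class requires (full external diameters
and height, μm):

| shape | axes | volume |
|---|---|---|
| sphere | d₁ | (π/6)d₁³ |
| ellipsoid | d₁,d₂,d₃ | (π/6)d₁d₂d₃ |
| cylinder | d₁,h | π(d₁/2)²h |
| oval cylinder | d₁,d₂,h | π(d₁/2)(d₂/2)h |
| discoid / oval discoid | as cylinder / oval cylinder | same formulas |
| cone | d₁,h | (π/3)(d₁/2)²h |
| oval cone | d₁,d₂,h | (π/3)(d₁/2)(d₂/2)h |
| hemispheroid | d₁,(d₂),h | (2π/3)(d₁/2)(d₂/2)h |

Design choices that were genuinely open:

- **Discoids as low-aspect cylinders.** The shape names do not pin down
  formulas; the cylinder treatment is the simplest consistent
  convention, and `VOLUME_FORMULAS` is an overridable registry so an
  alternate convention can be swapped in without touching callers.
- **Hemispheroid** = half an ellipsoid whose polar semi-axis is the
  measured height; the second equatorial diameter defaults to the
  first (source data may record only one).
- The circular shapes evaluate through their oval generalizations with
  d₂ = d₁ so the degenerate identities (ellipsoid(d,d,d) ≡ sphere(d))
  hold bit-for-bit, which the property tests exploit.
- Missing axes are imputed as d₁ × (type-species aspect ratio); a
  specimen with no applicable ratio is dropped with a logged warning
  rather than aborting the run.

Genus size is the arithmetic mean of per-specimen log₁₀ volumes (the
geometric-mean volume), computed over sorted values so it is exactly
permutation-invariant; a singleton genus has sd = 0 by convention.
Species richness counts distinct named species, excluding unnamed or
indeterminate entries (`sp.`, `spp.`). Genera split into **large**
(mean log₁₀ V ≥ 7.4, closed at the threshold) and **small** classes;
7.4 log₁₀ μm³ is the suboxic diffusion limit derived below.

## Selectivity statistics

**Rank test.** Mann–Whitney U compares victim and survivor log sizes.
For tie-free pooled samples with n₁+n₂ ≤ 12 the two-sided p is obtained
by exhaustive enumeration of all label assignments
(p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1); otherwise a normal
approximation with the standard tie correction and a 0.5 continuity
correction toward the mean. The enumeration limit is a pure
compute-cost bound (C(12,6) = 924 assignments). The result carries the
group medians and the linear ratio 10^(median_v − median_s), the
"how-many-times-larger" number. Note the continuity-corrected normal
approximation deviates from the exact tail by up to ~0.09 at n₁=n₂=2
and ~0.015 at n₁=n₂=6 — an intrinsic property of the approximation, not
an implementation artifact.

**Logistic regression.** `fit_logistic_selectivity` fits
logit P(victim) = β₀ + Σβᵢxᵢ by IRLS (statsmodels GLM/Binomial,
max 50 iterations, tolerance 1e-8); Wald SEs come from the inverse
observed information and 95 % CIs are β ± 1.959964·SE. Covariates enter
untransformed by default (log₁₀ volume, raw richness, raw cell count)
so coefficients are per-unit interpretable; `standardize=True` z-scores
them. Complete separation is flagged when any |β| exceeds 15 on the
standardized scale; separated or non-converged fits are reported with
`converged=False` rather than suppressed. For the modern assessment the
geographic-range covariate is omitted by default because modern risk
status is itself defined partly by range, making the regressor
circular.

**Multiple comparisons.** Bonferroni, p_adj = min(1, m·p), with family
size m = 6 (five paleo events + modern) for the rank-test family.

**Bootstrap stability.** `resample_significance` redraws genera with
replacement and reports the fraction of 1000 iterations with p > α.
Two schemes, selectable by config:

- *stratified* (default): resample within the victim and survivor
  groups, preserving group sizes and class imbalance. Replicates
  inherit whatever difference the observed dataset carries, so this
  measures the stability of the observed verdict. Even for data drawn
  from a common distribution the expected nonsignificant fraction is
  ~0.8 at n = 20 per group, not 1 − α, because chance differences in
  the one observed sample propagate into every replicate.
- *pooled*: both pseudo-groups are drawn from the pooled sizes, which
  breaks any true association; under a null this is calibrated to
  ~1 − α and is the right scheme for null-calibration checks.

**Geographic range** is the number of occupied cells of a Lambert
cylindrical equal-area grid: uniform 5° longitude columns × 36 bands
uniform in sin(latitude), so all cells have equal area; both
resolutions are configurable. Duplicate occurrences collapse.

## Oxygen diffusion–consumption model

Steady-state diffusion with zero-order (concentration-independent)
consumption in a sphere:

(1/r²) d/dr(r² dC/dr) = Q/D, C(R) = C₀, dC/dr|₀ = 0,

with closed form C(r) = C₀ − Q(R² − r²)/(6D). Parameters and defaults:

- D = 1.7×10⁻⁹ m²/s — oxygen diffusivity in cytoplasm/seawater;
- Q = 1.45×10⁻³ mol/(m³·s) — volumetric oxygen consumption of benthic
  foraminifera at 25 °C (temperature dependence is not modeled; Q is a
  free parameter of the scenario);
- C₀ presets: oxygen-rich 0.2, hypoxic 0.06 and 0.045, suboxic
  0.005 mol/m³.

The profile minimum is at the center, so viability ⇔
C(0) = C₀ − QR²/(6D) ≥ 0, giving R_max = √(6DC₀/Q): 187.5 μm under the
suboxic preset, i.e. a maximum spherical test volume of
log₁₀((4/3)πR_max³) = 7.44 ≈ 7.4 log₁₀ μm³ — the size-class threshold
used throughout. Assumptions: sphere (the worst case for supplying the
center; flatter morphologies can grow larger), fixed surface
concentration (no external boundary layer), consumption constant
wherever C > 0, no photosymbiont oxygen source, no denitrification, no
cytoplasmic streaming.

**Numerical solver.** A conservative finite-volume discretization on a
uniform radial mesh: face fluxes r²ᵢ₊₁⁄₂(Cᵢ₊₁−Cᵢ)/h balance the
consumption integrated over each control volume by Simpson quadrature,
with a symmetry cell at r = 0 and a Dirichlet surface node; the
tridiagonal system is solved by banded LU (scipy). Because the source
integral is exact for uniform consumption, the scheme reproduces the
quadratic closed form to round-off at any mesh; for radially varying
consumption (the `q_profile` hook) it is second-order accurate, which
the convergence tests demonstrate against a manufactured quartic
solution (error ratio ≈ 4 per mesh doubling). Degenerate inputs: Q = 0
returns the flat profile C₀; meshes below 10 nodes are rejected.

## Synthetic data generator

`generate_genus_table` draws, per event: genus mean sizes
~ Normal(μ, σ) in log₁₀ μm³; species richness ~ zero-truncated
Poisson(λ), capped at the per-genus specimen count (a genus cannot have
more named species than specimens); range cells ~ 1 + Poisson(m−1);
extinction labels ~ Bernoulli(logit⁻¹(β₀ + Σβᵢ(xᵢ − x̄ᵢ))). Covariates
are centered before the betas apply so β₀ alone sets the base
extinction rate, which keeps recovery experiments easy to design.
Covariates are generated independently (a correlation hook is a known
omission). `generate_specimens` scatters per-specimen log volumes
~ Normal(genus mean, within-genus sd, default 0.2), emits spheres by
default (volume → diameter is invertible, so morphometry round-trips
exactly at zero noise) or cycles all nine shape branches with
volume-consistent axes, assigns species names to hit the target
richness exactly, and draws occurrences around area-uniform cluster
centers.

`paper_like_suite` fixes six event tables at the published genus counts
(43, 138, 142, 86, 218, 425) and stage mean sizes (6.89, 7.91, 7.53,
7.29, 7.73, 7.78 log₁₀ μm³). Each event's σ is set so the normal
reproduces the published large-genus share (21 %, 62 %, ~49 %, 42 %,
57 %, 63 %) where the normal family allows it; for P–T a mean above the
7.4 threshold with under half the genera large requires right skew that
no normal has, so σ = 1.3 is a compromise (~54 % large). Size
selectivity (positive β_size, ≈1.2 per size-SD) is switched on only for
G–L, P–T and K–Pg; the modern table instead carries negative richness
selectivity; the T–J intercept targets its reported ~43 % extinction
rate. These effect sizes are calibrated by pilot simulation, not
published values. What the generator does **not** emulate: skewed or
multimodal size distributions, phylogenetic autocorrelation,
covariate correlations, taphonomic/sampling bias, and stage-to-stage
occupancy dynamics — so green tests demonstrate statistical correctness
of the machinery, not fidelity to every feature of the fossil record.

## Reproducibility and problem sizes

A single top-level seed fans out to per-stage seeds through
`numpy.random.SeedSequence` (all derived seeds < 2³¹); identical
config + seed gives byte-identical JSON results. Default problem sizes:
1000 bootstrap iterations; 200 tables × 500 genera for the
parameter-recovery experiment; 200-node meshes for solver comparisons;
exhaustive rank-test sweeps up to n₁=n₂=6. These sizes put Monte-Carlo
noise well inside the assertion tolerances while keeping a full run in
tens of seconds.

## Known limitations

- Shape formulas are a stated convention, not a confirmed match to any
  particular measurement protocol; the registry exists to swap them.
- The rank test's exact path is limited to pooled n ≤ 12; beyond that
  the normal approximation's continuity correction is the only
  small-sample guard.
- The diffusion model is deliberately minimal: no Michaelis–Menten
  kinetics, no boundary layer, no geometry other than the sphere.
- Bootstrap stability fractions depend on the resampling scheme; the
  stratified default is not null-calibrated (see above), which matters
  when comparing against permutation-style expectations.
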