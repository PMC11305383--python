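# foramsize

Body-size-dependent extinction selectivity in benthic foraminifera, and
the oxygen-diffusion limit on their maximum test size.

Benthic foraminifera are single-celled sea-floor protists whose shells
("tests") fossilize across every major mass extinction. This package is
for paleobiologists and macroecologists who want to ask, at the genus
level: *did larger foraminifera go extinct preferentially — and why
would a big single cell be more vulnerable when the ocean loses oxygen?*

It implements three connected pieces:

1. **Morphometry.** Linear test measurements (diameters and height, μm)
   are converted to biovolumes through idealized solids — sphere,
   ellipsoid, (oval) cylinder, (oval) discoid, (oval) cone,
   hemispheroid — e.g. V<sub>sphere</sub> = (π/6)d³ and
   V<sub>ellipsoid</sub> = (π/6)d₁d₂d₃. Missing axes are imputed from
   type-species aspect ratios. Sizes are analyzed as log₁₀ V (μm³) and
   aggregated per genus × event, together with named-species richness
   and geographic range as occupied cells of a Lambert cylindrical
   equal-area grid.

2. **Selectivity statistics.** Per extinction event (Frasnian–Famennian,
   Guadalupian–Lopingian, Permian–Triassic, Triassic–Jurassic,
   Cretaceous–Paleogene, plus modern at-risk status), victim and
   survivor sizes are compared with a Mann–Whitney *U* test (exact
   enumeration for small tie-free samples, tie-corrected normal
   approximation otherwise), and extinction status is modeled by
   multiple binary logistic regression
   logit P(victim) = β₀ + β₁·size + β₂·richness + β₃·range,
   with Wald standard errors, 95 % CIs, Bonferroni correction across the
   event family, bootstrap stability of the rank-test verdict, and a
   pooled contrast of selectivity within the large (≥ 7.4 log₁₀ μm³)
   and small size classes.

3. **Oxygen diffusion model.** A spherical cell of radius R consuming
   oxygen at a constant volumetric rate Q (mol m⁻³ s⁻¹), supplied only
   by Fickian diffusion (J = −D dC/dr) from ambient concentration C₀,
   has the steady-state profile C(r) = C₀ − Q(R² − r²)/(6D). The cell is
   viable only while the center concentration stays non-negative, which
   bounds the radius at R_max = √(6·D·C₀/Q) and hence the maximum test
   volume per oxygen regime (oxygen-rich 0.2, hypoxic 0.06 / 0.045,
   suboxic 0.005 mol/m³). A conservative finite-volume solver of the
   same boundary-value problem cross-checks the closed form and handles
   radially varying consumption.

A seedable synthetic-data generator (`foramsize.synthdata`) emulates the
genus-level structure of the fossil record — per-stage size
distributions, zero-truncated richness counts, clustered occurrences,
logistic extinction labels — so the whole pipeline is testable and
parameter-recovery experiments are reproducible without any external
data.

## Worked example

```python
from foramsize import (
    DiffusionScenario, compute_volume, log10_volume,
    mann_whitney_u, max_log10_volume, max_radius,
)

# a 360 um diameter sphere sits just below the large/small boundary
lv = log10_volume(compute_volume("sphere", {"d1": 360.0}))
print(f"log10 volume: {lv:.2f}")            # log10 volume: 7.39

# Permian-Triassic anchor: victim/survivor medians 7.69 / 7.15
res = mann_whitney_u([7.30, 7.69, 8.10], [6.80, 7.15, 7.50])
print(f"median ratio: {res.median_ratio_linear:.2f}x")   # median ratio: 3.47x

# maximum sustainable spherical test under suboxic oxygen
sub = DiffusionScenario.from_preset("suboxic")
print(f"R_max = {max_radius(sub):.1f} um")               # R_max = 187.5 um
print(f"max size = {max_log10_volume(sub):.2f} log10 um^3")  # max size = 7.44 log10 um^3
```

The median ratio says extinct Permian–Triassic genera were typically
3.47× larger (in linear volume) than survivors; the diffusion model says
a spherical test larger than ~7.4 log₁₀ μm³ (radius ≈ 187 μm) cannot
keep its center oxygenated in suboxic water — the mechanistic link
between deoxygenation and size-selective extinction.

End-to-end run on synthetic data (writes `results.json`,
`genus_table.csv`, `coefficients.csv`):

```bash
foramsize run --events P-T,K-Pg --resample 1000 --seed 42 --out out/
foramsize diffusion --preset all --max-size
```

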