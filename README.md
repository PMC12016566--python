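# altadapt

Tools for dissecting the genetics of high-altitude adaptation in sheep-like
cohorts, built around the analysis chain used to map the β-globin structural
haplotypes: a linear mixed-model association scan between genetic variants
and habitat altitude, a cross-population extended-haplotype-homozygosity
(XP-EHH) selection scan, read-depth diplotyping of a large (~40 kb)
structural deletion, hemoglobin oxygen-equilibrium analytics (Hill plots,
Bohr effect, Van't Hoff oxygenation enthalpy), and per-gene
expression-versus-altitude trend tests. A seeded synthetic-data module
generates every input the pipeline needs, so all stages are testable without
any sequence download.

It is aimed at population geneticists and comparative physiologists who want
a compact, fully reproducible implementation of these methods to study,
extend, or validate against.

## The models

**Association.** Per marker the univariate mixed model

y = Wα + xβ + u + ε,  u ~ MVN(0, λτ⁻¹K),  ε ~ MVN(0, τ⁻¹Iₙ)

with y the altitude phenotype, W an intercept plus principal-component
covariates, x the dosage, K a centered genomic relationship matrix, and λ
the variance-component ratio. λ is estimated once under the null by REML
(spectral decomposition of K plus 1-D profile optimisation) and reused for
every marker; per-marker β̂ and SE are generalised least squares in the
whitened space, with a two-sided Wald t-test (n − c − 1 df) and Bonferroni
thresholding α / n_tests.

**Selection.** EHH(d) = Σ_g C(n_g, 2)/C(n, 2) over haplotype groups
identical from a core site out to distance d; iHH is its trapezoidal
integral over bp (both flanks, truncated at EHH < 0.05); the raw XP-EHH
score is ln(iHH_focal / iHH_reference), standardised over scored sites and
summarised in 50-kb windows sliding by 10 kb with two-sided empirical
top-1% thresholds.

**Structural diplotyping.** Mean depth over the candidate deletion interval
divided by the chromosome-wide mean estimates the haplotype-A copy
fraction; calls use the fixed thresholds ratio ≥ 0.75 → AA,
0.25 ≤ ratio < 0.75 → AB, ratio < 0.25 → BB, and haplotype frequency
follows by allele counting f_A = (2n_AA + n_AB)/2n.

**Oxygen binding.** Hill plots log₁₀[Y/(1−Y)] vs log₁₀PO₂ yield n₅₀ (slope)
and P₅₀ (x-intercept); Φ = Δlog₁₀P₅₀/ΔpH; ΔH = 2.303 R Δlog₁₀P₅₀/Δ(1/T)
with R = 8.314 J/mol/K, and ΔH′ = ΔH + 12.6 kJ/mol after removing the heat
of O₂ dissolution.

## Worked example

```python
import numpy as np
from altadapt.simulate import SimConfig, simulate_deletion_cohort
from altadapt.lmm import compute_grm, association_scan, conditional_scan

cfg = SimConfig(seed=1, n_samples=300, n_variants=120, residual_sd=50.0)
cohort = simulate_deletion_cohort(cfg, beta_sv=800.0)
K = compute_grm(cohort.genotypes.dosages[:, ~cohort.region_mask])

scan = association_scan(cohort.genotypes, cohort.phenotype.altitude, None, K,
                        maf_min=0.0)
region = scan.table.loc[cohort.region_mask]
print(f"min p in deletion-linked region: {region['p'].min():.3g} "
      f"(threshold {scan.bonferroni_p:.3g})")

cond = conditional_scan(cohort.genotypes, cohort.phenotype.altitude, None,
                        cohort.a_dosage, K, maf_min=0.0)
ok = cond.table["testable"] & cohort.region_mask
print(f"min p after conditioning on haplotype A: "
      f"{cond.table.loc[ok, 'p'].min():.3g}")
```

prints

```
min p in deletion-linked region: 3.21e-130 (threshold 0.000417)
min p after conditioning on haplotype A: 0.00541
```

The deletion-linked locus is overwhelmingly significant in the
unconditional scan, and the signal vanishes (all region p-values above the
Bonferroni threshold) once the haplotype-A dosage is included as a
covariate — the hallmark of the structural haplotype itself carrying the
association.

A complete run of every stage, with a JSON manifest of output digests:

```sh
altadapt all --seed 1 --out-dir demo_out
```

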