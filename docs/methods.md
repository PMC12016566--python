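# Methods

## Scope and design

`altadapt` implements the computational chain for mapping altitude-adaptive
variation in a structured ruminant cohort: mixed-model association of
variants with habitat altitude, a cross-population haplotype-homozygosity
selection scan, read-depth diplotyping of a large structural deletion at
the β-globin locus, hemoglobin oxygen-equilibrium analytics, and per-gene
expression–altitude trend tests. Upstream steps (read alignment, variant
calling, statistical phasing, transcript quantification) are out of scope;
the package starts from genotypes, depth profiles, equilibrium curves and
count tables, and ships seeded generators for all of them.

## Synthetic cohorts

The genotype generator uses a Balding–Nichols model: ancestral allele
frequencies are uniform on the configured MAF range (default 0.05–0.5,
matching the association panel's MAF > 0.05 filter), and each of
`n_subpops` subpopulations draws its frequency from a Beta distribution
around the ancestral value with drift parameter `fst` (default 0.05). This
creates genuine kinship/PC structure while keeping sites unlinked.
Haplotypes are generated phased; dosages are their sum by construction, an
identity asserted in tests. What this deliberately does *not* emulate:
coalescent genealogies, recombination-driven LD decay, or sequencing error —
so passing tests demonstrate correctness of the statistical machinery under
the stated model, not robustness to every artefact of real short-read data.

The phenotype follows the additive mixed model exactly: fixed causal
effects plus a polygenic draw with covariance λτ⁻¹K (λ = h²/(1−h²), τ⁻¹ =
`residual_sd`², default 1.0) plus independent noise. Altitude doubles as
association phenotype and expression covariate.

Depth profiles are windowed (default 1-kb windows, aligned so no window
straddles a deletion boundary) with per-copy Poisson counts at rate
`mean_depth`/2 per base (default 20× diploid, typical of the short-read
cohorts this emulates); haplotype B contributes nothing inside the deletion
interval (default Chr15:47,954,795–48,033,976, the candidate region). A
noiseless switch emits expectations exactly, giving inside/outside copy
ratios of exactly 1.0 / 0.5 / 0.0 for AA / AB / BB — the basis of the exact
frequency-recovery checks.

The deletion-cohort generator (`simulate_deletion_cohort`) places the
structural allele at subpopulation frequencies 0.9 / 0.15 (high- vs
low-altitude demes), lets the first block of variants tag it with per-site
flip probability 0.05 (strong local LD), and makes the phenotype
800 m of altitude per haplotype-A copy over a 50-m residual SD — a strong,
cleanly localised signal suitable for the conditional-analysis property.

Oxygen curves are exact Hill curves, optionally with additive Gaussian
noise clipped into (0, 1). Expression counts are Poisson with
ln-mean linear in altitude (slope per km) for designated trend genes.

All generators draw from named substreams spawned deterministically from
one root seed, so identical configurations give byte-identical outputs.

## Mixed-model scan

The GRM is the centered, variance-standardised form
K = ZZᵀ/m with Z_ij = (x_ij − 2p_j)/√(2p_j(1−p_j)), after per-variant mean
imputation of missing dosages; monomorphic variants are excluded, and
eigenvalues below 1e−8 of the maximum are clipped to zero. PC covariates
come from the GRM of a greedily LD-pruned panel (window 50 variants, step
5, r² > 0.2), signs fixed by the largest-magnitude loading.

The null model is fitted by REML: K is eigendecomposed once, the restricted
likelihood profiled over the covariate coefficients and τ, and the
resulting 1-D criterion optimised on log λ ∈ [−10, 10] by a 101-point grid
plus bounded Brent refinement (verified against a 10,001-point grid in
tests). REML rather than ML because variance components are the target;
Wald rather than LRT because a single fitted alternative per marker is
cheapest and standard for this model class. When K = I the ratio is
unidentified; the fit is flagged (`boundary=True`) and the total variance
τ̂⁻¹(λ̂+1) still matches the OLS residual variance.

Per-marker tests reuse the null λ̂ (the EMMAX-style approximation, recorded
in scan metadata; exact per-marker re-optimisation is available via
`per_variant_lambda=True`). In the whitened space the scan reduces to
residualised simple regression, so the whole panel is tested with dense
linear algebra; the Wald t uses n − c − 1 df. MAF filtering is ≥ 0.05
inclusive by default (configurable flag). Variants constant after
imputation, or collinear with the conditioning covariate in a conditional
scan, are reported untestable and excluded from the Bonferroni denominator.
When the tested locus itself contributes to relatedness, the kinship should
be built leaving that region out (as the example and tests do), otherwise
the random effect absorbs part of the signal.

## Selection scan

EHH uses exact pair counting via incremental prefix grouping, equivalent to
enumerating all C(n, 2) haplotype pairs (the test oracle does exactly
that). iHH integrates EHH over physical bp by the trapezoid rule, stopping
at the last point with EHH ≥ 0.05 (the conventional cutoff; configurable),
both flanks summed; genetic-map distances are not supported. XP-EHH is the
log-ratio of iHH between focal and reference panels, z-standardised over
scored sites; sites with zero iHH in either panel are excluded. Window
summaries use the window **mean** (the per-window statistic is not uniquely
determined by convention; mean is recorded as this package's choice) over
50-kb windows anchored at coordinate 1 sliding by 10 kb. Without a
chromosome length every non-empty window on the grid is reported; with one,
only full windows fitting on the chromosome. Empirical thresholds split the
two-sided top fraction evenly (0.5% + 0.5% for the top 1%); the degenerate
quantile 1.0 returns the observed range.

## Depth diplotyping and clines

The normalized ratio divides the candidate-region mean depth by the
chromosome-wide mean; by default the chromosome mean includes the candidate
region (its share is negligible at chromosome scale; a flag excludes it).
Thresholds 0.75 / 0.25 partition [0, ∞) exhaustively; ratios above 1 are
clamped into AA with a flag (duplications out of scope). Haplotype
frequency is plain allele counting, Hardy–Weinberg expectations are
(p², 2pq, q²), and the cline summary regresses per-population frequency on
altitude by OLS, reporting slope and r²; a zero-variance frequency vector
is returned as slope 0, r² 0 with a flag rather than an error.

## Oxygen equilibrium analytics

Hill fits use points with saturation in (0.05, 0.95) — the approximately
linear region of the Hill plot; the window is configurable. n₅₀ is the
fitted slope and P₅₀ = 10^(−intercept/slope). The Bohr factor and Van't
Hoff enthalpy normalise argument order internally (higher pH/temperature as
the second point), making both invariant to call order. Temperatures
convert to kelvin by +273.15. The solution-heat correction is implemented
as ΔH′ = ΔH − (−12.6 kJ/mol) = ΔH + 12.6 kJ/mol, isolated in one constant
(`O2_SOLUTION_HEAT`); the identity ΔH′ − ΔH = +12.6 kJ/mol is asserted.
Degenerate group comparisons follow fixed conventions: identical replicate
sets give p = 1; zero within-group variance with distinct means is flagged
as exact separation and reported with p = 0.

## Expression trends

TPM is the standard length-normalised within-sample unit (columns sum to
10⁶ whenever any count is positive). The trend test regresses
log2(abundance + 1) on altitude — the log transform because expression
noise is multiplicative and the +1 guard because zeros are common; the
transform is a parameter. Zero-variance genes are skipped, not errored.
BH-FDR comes from the step-up procedure; DE flags require |log2FC| ≥ 1
("minimum fold change of 1" read on the log2 scale — FC = 1 on the natural
scale would flag nothing) and q strictly below 0.05.

## Problem sizes and checks

The shipped tests and the acceptance script run at desk scale: cohorts of
80–500 samples, panels of 40–5,000 variants, 1,000-gene expression tables,
20–100 simulation replicates per property — sizes chosen so each
Monte-Carlo check has enough resolution for its stated tolerance while the
whole suite stays interactive. Genome-scale quantities from real data
(panel-wide p-values, published XP-EHH cutoffs, real-population cline r²)
are arithmetic or property checks only, not reproduced from sequence.

## Known limitations

Unlinked variants mean the XP-EHH sweep-recovery test constructs LD
explicitly rather than inheriting it from the genotype generator; the LMM
assumes homoskedastic Gaussian residuals; the depth model ignores GC and
mappability bias; expression counts are Poisson (no overdispersion), so the
trend test's type-I behaviour on real RNA-seq will be anti-conservative
relative to these simulations; unphased input to the selection scan is
rejected rather than phased.
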