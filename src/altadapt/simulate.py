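"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analyses
assume: structured diploid genotypes with an altitude-associated locus and
a polygenic background under the mixed model, sequencing-depth profiles in
which one structural haplotype lacks a large (~40 kb) segment, Hill-equation
oxygen-equilibrium curves, and expression counts whose log-mean trends with
altitude.  Every draw flows from a single seed through deterministic
substreams, so identical configurations yield byte-identical outputs.

Population structure follows a Balding–Nichols model: each subpopulation's
allele frequency is a Beta draw around a shared ancestral frequency with
drift parameter ``fst``.  Haplotypes are generated phased; dosages are the
sum of the two haplotype alleles by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "PhenotypeTable",
    "DepthProfileSet",
    "OxygenEquilibriumCurve",
    "ExpressionTable",
    "simulate_genotypes",
    "simulate_altitude_phenotype",
    "simulate_depth_profiles",
    "simulate_oxygen_curve",
    "simulate_expression",
    "simulate_deletion_cohort",
]


class ConfigError(ValueError):
    """A SimConfig field violates its invariant; message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration for all synthetic generators.

    Parameters
    ----------
    seed
        Root seed; all module substreams derive from it deterministically.
    n_samples, n_variants, n_subpops
        Cohort and marker-panel dimensions.
    maf_range
        Ancestral allele frequencies are drawn uniformly in this interval,
        which must lie within (0, 0.5].
    fst
        Balding–Nichols drift of subpopulation frequencies from the
        ancestral frequency (0 = panmictic).
    heritability
        Fraction of phenotypic variance contributed by the polygenic random
        effect, in [0, 1].
    causal_positions, causal_effects
        Variant indices with direct fixed effects on the phenotype, and the
        per-causal effect size in phenotype units (metres of altitude).
    deletion_interval
        1-based inclusive genomic interval (bp) removed on haplotype B.
    mean_depth
        Expected reads per base for a diploid (two-copy) genome.
    hb_P50, hb_n50
        Hill-curve parameters used by the oxygen-curve generator (torr,
        dimensionless).
    residual_sd
        Standard deviation of the independent phenotype noise, i.e. sqrt of
        the residual variance tau^-1 (phenotype units).
    pheno_intercept
        Baseline phenotype value (metres a.s.l.).
    chrom, chrom_length
        Chromosome label and span over which variant positions are placed.
    """

    seed: int = 0
    n_samples: int = 100
    n_variants: int = 1000
    n_subpops: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.05
    heritability: float = 0.5
    causal_positions: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    deletion_interval: tuple[int, int] = (47_954_795, 48_033_976)
    mean_depth: float = 20.0
    hb_P50: float = 20.0
    hb_n50: float = 2.5
    residual_sd: float = 1.0
    pheno_intercept: float = 2500.0
    chrom: str = "15"
    chrom_length: int = 1_000_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.heritability <= 1.0):
            raise ConfigError("heritability must be in [0, 1]")
        if self.deletion_interval[1] < self.deletion_interval[0]:
            raise ConfigError("deletion_interval must have positive length")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.n_variants < 1:
            raise ConfigError("n_variants must be >= 1")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be >= 1")
        if len(self.causal_positions) != len(self.causal_effects):
            raise ConfigError("causal_positions and causal_effects must align")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigError("fst must be in [0, 1)")

    def substream(self, name: str) -> np.random.Generator:
        """Deterministic named RNG substream derived from the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[name],))
        )


_STREAMS = {
    "genotypes": 0,
    "phenotype": 1,
    "depth": 2,
    "oxygen": 3,
    "expression": 4,
    "deletion": 5,
}


@dataclass
class GenotypeMatrix:
    """Diploid dosages plus phased haplotypes for biallelic variants.

    ``dosages`` is n_samples x n_variants with entries in {0, 1, 2} (or -1
    for missing); ``haplotypes`` is (2 * n_samples) x n_variants binary,
    rows 2i and 2i+1 belonging to sample i.  ``variants`` carries chrom,
    pos (1-based), ref, alt and type (SNP|INDEL); positions are strictly
    increasing within a chromosome.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None
    subpop: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PhenotypeTable:
    """Per-sample phenotype (altitude, m a.s.l.) and optional covariates."""

    sample_ids: list[str]
    altitude: np.ndarray
    covariates: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "altitude_m": self.altitude})
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df


@dataclass
class DepthProfileSet:
    """Windowed sequencing depth over a region for a set of samples.

    Windows are 0-based half-open intervals on one chromosome; ``depth``
    is n_samples x n_windows mean reads per base.
    """

    sample_ids: list[str]
    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    depth: np.ndarray
    diplotypes: list[str] | None = None

    def window_mask(self, interval: tuple[int, int]) -> np.ndarray:
        """Windows fully inside a 1-based inclusive interval."""
        lo, hi = interval
        return (self.starts >= lo - 1) & (self.ends <= hi)

    def region_mean(self, interval: tuple[int, int]) -> np.ndarray:
        """Per-sample mean depth over windows inside the interval (base-weighted)."""
        m = self.window_mask(interval)
        if not m.any():
            raise ValueError("interval covers no depth windows")
        w = (self.ends - self.starts)[m].astype(float)
        return (self.depth[:, m] * w).sum(axis=1) / w.sum()

    def overall_mean(self, exclude: tuple[int, int] | None = None) -> np.ndarray:
        """Per-sample mean depth over all windows, optionally excluding an interval."""
        m = np.ones(self.starts.shape, dtype=bool)
        if exclude is not None:
            m &= ~self.window_mask(exclude)
        w = (self.ends - self.starts)[m].astype(float)
        return (self.depth[:, m] * w).sum(axis=1) / w.sum()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.sample_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": self.chrom,
                        "start": self.starts,
                        "end": self.ends,
                        "sample": sid,
                        "depth": self.depth[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class OxygenEquilibriumCurve:
    """(PO2, fractional saturation) points under one experimental condition."""

    po2_torr: np.ndarray
    saturation: np.ndarray
    ph: float = 7.4
    temp_c: float = 37.0
    condition: str = "stripped"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "po2_torr": self.po2_torr,
                "saturation": self.saturation,
                "ph": self.ph,
                "temp_c": self.temp_c,
                "condition": self.condition,
            }
        )


@dataclass
class ExpressionTable:
    """Gene x sample abundances with effective lengths and sample metadata."""

    counts: pd.DataFrame  # genes x samples
    effective_lengths: pd.Series  # per gene, bp
    samples: pd.DataFrame  # sample_id, altitude_m


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw structured phased genotypes under a Balding–Nichols model.

    Ancestral frequencies are uniform on ``config.maf_range``; each
    subpopulation drifts them with parameter ``fst``; haplotype alleles are
    Bernoulli draws from the subpopulation frequency.  Samples are assigned
    to subpopulations in contiguous, near-equal blocks.
    """
    rng = config.substream("genotypes")
    n, m, k = config.n_samples, config.n_variants, config.n_subpops
    lo, hi = config.maf_range

    p_anc = rng.uniform(lo, hi, size=m)
    if config.fst > 0 and k > 1:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p_sub = rng.beta(a[None, :], b[None, :], size=(k, m))
        p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
    else:
        p_sub = np.broadcast_to(p_anc, (k, m)).copy()

    subpop = np.array_split(np.arange(n), k)
    labels = np.empty(n, dtype=int)
    for j, idx in enumerate(subpop):
        labels[idx] = j

    p_hap = p_sub[labels]  # n x m, frequency per sample
    haps = (rng.random((2, n, m)) < p_hap[None]).astype(np.int8)
    dosages = haps.sum(axis=0).astype(np.int8)
    haplotypes = haps.transpose(1, 0, 2).reshape(2 * n, m)

    positions = np.sort(
        rng.choice(np.arange(1, config.chrom_length + 1), size=m, replace=False)
    )
    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "type": "SNP",
        }
    )
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants, dosages, haplotypes, labels)


def simulate_altitude_phenotype(
    genotypes: GenotypeMatrix,
    kinship: np.ndarray | None,
    config: SimConfig,
) -> PhenotypeTable:
    """Draw a phenotype under the additive mixed model.

    y = intercept + sum_c x_c * beta_c + u + eps with
    u ~ MVN(0, lambda * tau^-1 * K) and eps ~ MVN(0, tau^-1 * I), where
    tau^-1 = residual_sd**2 and lambda = h2 / (1 - h2) so the polygenic
    share of (u + eps) variance equals the configured heritability.
    """
    rng = config.substream("phenotype")
    n = genotypes.n_samples
    y = np.full(n, config.pheno_intercept, dtype=float)

    for idx, beta in zip(config.causal_positions, config.causal_effects):
        y += beta * genotypes.dosages[:, idx].astype(float)

    tau_inv = config.residual_sd**2
    h2 = config.heritability
    if h2 > 0:
        if kinship is None:
            raise ValueError("kinship required when heritability > 0")
        K = np.asarray(kinship, dtype=float)
        if K.shape != (n, n):
            raise ValueError(
                f"kinship shape {K.shape} does not match n_samples {n}"
            )
        if h2 >= 1.0:
            lam = np.inf
        else:
            lam = h2 / (1.0 - h2)
        w, V = np.linalg.eigh((K + K.T) / 2)
        w = np.clip(w, 0.0, None)
        z = rng.standard_normal(n)
        scale = tau_inv * (lam if np.isfinite(lam) else 1.0)
        u = V @ (np.sqrt(scale * w) * z)
        y += u
        if np.isfinite(lam):
            y += rng.normal(0.0, config.residual_sd, size=n)
    else:
        y += rng.normal(0.0, config.residual_sd, size=n)

    return PhenotypeTable(list(genotypes.sample_ids), y)


_DIPLO_COPIES = {"AA": (1, 1), "AB": (1, 0), "BB": (0, 0)}


def simulate_depth_profiles(
    diplotypes: list[str],
    config: SimConfig,
    *,
    noiseless: bool = False,
    window: int = 1000,
    flank: int = 40_000,
) -> DepthProfileSet:
    """Windowed depth over the deletion interval plus flanking sequence.

    Each structural haplotype contributes reads at rate mean_depth / 2 per
    base everywhere except inside the deletion interval, where haplotype B
    contributes nothing.  Stochastic mode draws Poisson counts per window
    per haplotype copy; ``noiseless`` emits expectations exactly, so the
    inside/outside copy ratio is exactly 1.0 (AA), 0.5 (AB) or 0.0 (BB).
    """
    if len(diplotypes) == 0:
        raise ValueError("diplotype list is empty")
    bad = sorted({d for d in diplotypes if d not in _DIPLO_COPIES})
    if bad:
        raise ValueError(f"unknown diplotypes: {bad}; expected AA, AB or BB")

    rng = config.substream("depth")
    lo, hi = config.deletion_interval  # 1-based inclusive
    region_start = max(0, lo - 1 - flank)
    region_end = hi + flank
    # window edges aligned to the deletion boundaries so no window straddles them
    edges = np.unique(
        np.concatenate(
            [
                np.arange(region_start, lo - 1, window),
                np.arange(lo - 1, hi, window),
                np.arange(hi, region_end, window),
                [lo - 1, hi, region_end],
            ]
        )
    )
    starts, ends = edges[:-1], edges[1:]
    widths = (ends - starts).astype(float)

    # fraction of each window overlapping the deleted segment [lo-1, hi)
    ov = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo - 1), 0, None)
    frac_del = ov / widths

    per_copy = config.mean_depth / 2.0
    n = len(diplotypes)
    depth = np.empty((n, starts.size), dtype=float)
    for i, d in enumerate(diplotypes):
        copies_present = sum(_DIPLO_COPIES[d])
        # expected reads/base: full copies outside, reduced inside deletion
        exp_rate = per_copy * (2.0 * (1 - frac_del) + copies_present * frac_del)
        if noiseless:
            depth[i] = exp_rate
        else:
            depth[i] = rng.poisson(exp_rate * widths) / widths

    sample_ids = [f"D{i:04d}" for i in range(n)]
    return DepthProfileSet(
        sample_ids, config.chrom, starts, ends, depth, list(diplotypes)
    )


def simulate_oxygen_curve(
    P50: float,
    n50: float,
    po2_grid,
    noise_sd: float = 0.0,
    *,
    rng: np.random.Generator | None = None,
    ph: float = 7.4,
    temp_c: float = 37.0,
    condition: str = "stripped",
) -> OxygenEquilibriumCurve:
    """Hill-equation saturations Y = PO2^n / (PO2^n + P50^n) with optional noise.

    Noise is additive Gaussian, and saturations are clipped to the open
    interval (0, 1) so downstream Hill-plot linearisation is always defined.
    """
    po2 = np.asarray(po2_grid, dtype=float)
    if P50 <= 0:
        raise ValueError("P50 must be > 0")
    if n50 <= 0:
        raise ValueError("n50 must be > 0")
    if np.any(po2 <= 0):
        raise ValueError("all PO2 values must be > 0")
    t = po2**n50
    y = t / (t + P50**n50)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    eps = 1e-9
    y = np.clip(y, eps, 1 - eps)
    return OxygenEquilibriumCurve(po2, y, ph=ph, temp_c=temp_c, condition=condition)


def simulate_expression(
    n_genes: int,
    samples: PhenotypeTable,
    trend_genes: dict[str, float] | None,
    config: SimConfig,
    *,
    base_mean: float = 200.0,
) -> ExpressionTable:
    """Poisson counts whose log-mean is linear in altitude for trend genes.

    ``trend_genes`` maps gene name (``G{i:05d}``) to the slope of the
    natural-log mean per km of altitude; unlisted genes are flat.  Effective
    lengths are drawn uniformly in [500, 3000) bp.
    """
    rng = config.substream("expression")
    trend_genes = trend_genes or {}
    for g, s in trend_genes.items():
        if not np.isfinite(s):
            raise ValueError(f"non-finite slope for gene {g}")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    alt_km = np.asarray(samples.altitude, dtype=float) / 1000.0

    slopes = np.array([trend_genes.get(g, 0.0) for g in genes])
    log_mu = np.log(base_mean) + slopes[:, None] * alt_km[None, :]
    counts = rng.poisson(np.exp(log_mu)).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples.sample_ids)
    lengths = pd.Series(
        rng.uniform(500, 3000, size=n_genes), index=genes, name="effective_length"
    )
    meta = pd.DataFrame(
        {"sample_id": samples.sample_ids, "altitude_m": samples.altitude}
    )
    return ExpressionTable(counts_df, lengths, meta)


@dataclass
class DeletionCohort:
    """A cohort whose causal signal is the structural haplotype itself."""

    genotypes: GenotypeMatrix
    phenotype: PhenotypeTable
    a_dosage: np.ndarray  # copies of haplotype A per sample, {0,1,2}
    region_mask: np.ndarray  # variants linked to the deletion


def simulate_deletion_cohort(
    config: SimConfig,
    *,
    n_region: int = 40,
    p_a_by_subpop: tuple[float, ...] = (0.9, 0.15),
    tag_flip: float = 0.05,
    beta_sv: float = 800.0,
) -> DeletionCohort:
    """Cohort where a deletion haplotype drives the altitude phenotype.

    The first ``n_region`` variants sit in the deletion-linked region: their
    haplotype alleles copy the structural allele (A = 1) with per-site flip
    probability ``tag_flip``, creating strong local LD with the deletion.
    The phenotype is beta_sv * (A copies) plus independent noise, so an
    unconditional scan lights up the region while a scan conditional on the
    A dosage removes the signal.
    """
    base = simulate_genotypes(config)
    rng = config.substream("deletion")
    n = config.n_samples
    k = len(p_a_by_subpop)
    labels = np.array_split(np.arange(n), k)
    p_a = np.empty(n)
    for j, idx in enumerate(labels):
        p_a[idx] = p_a_by_subpop[j]

    sv_haps = (rng.random((n, 2)) < p_a[:, None]).astype(np.int8)  # A = 1
    a_dosage = sv_haps.sum(axis=1)

    m = base.n_variants
    n_region = min(n_region, m)
    region_mask = np.zeros(m, dtype=bool)
    region_mask[:n_region] = True

    haps = base.haplotypes.reshape(n, 2, m)
    flips = rng.random((n, 2, n_region)) < tag_flip
    haps[:, :, :n_region] = sv_haps[:, :, None] ^ flips
    dosages = haps.sum(axis=1).astype(np.int8)
    genotypes = GenotypeMatrix(
        base.sample_ids, base.variants, dosages, haps.reshape(2 * n, m), base.subpop
    )

    noise = rng.normal(0.0, config.residual_sd, size=n)
    y = config.pheno_intercept + beta_sv * a_dosage + noise
    phen = PhenotypeTable(list(genotypes.sample_ids), y)
    return DeletionCohort(genotypes, phen, a_dosage.astype(float), region_mask)
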