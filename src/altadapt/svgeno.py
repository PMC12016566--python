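"""Read-depth diplotyping of the beta-globin structural haplotypes.

Haplotype B lacks an ~40-kb segment of the beta-globin locus, so the mean
sequencing depth over the candidate interval, divided by the chromosome-wide
mean depth, estimates the fraction of structural-haplotype-A copies an
individual carries: ~1.0 for AA homozygotes, ~0.5 for AB heterozygotes and
~0.0 for BB homozygotes.  Calls use the fixed thresholds 0.75 and 0.25.

The module also provides haplotype/genotype frequency arithmetic (allele
counting, Hardy-Weinberg expectations) and a frequency-versus-altitude
cline summary with an ordinary least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DepthProfileSet

__all__ = [
    "TARGET_REGION",
    "normalized_ratio",
    "call_diplotype",
    "diplotype_table",
    "haplotype_frequency",
    "hwe_expected",
    "cline_summary",
]

# candidate deletion interval on chromosome 15, 1-based inclusive
TARGET_REGION = ("15", 47_954_795, 48_033_976)

AA_MIN = 0.75  # ratio >= 0.75 -> homozygous haplotype A
BB_MAX = 0.25  # ratio < 0.25 -> homozygous haplotype B

A_DOSAGE = {"AA": 2, "AB": 1, "BB": 0}


def normalized_ratio(region_depth: float, chrom_depth: float) -> float:
    """Region mean depth divided by the chromosome-wide mean depth."""
    if chrom_depth <= 0:
        raise ValueError("chromosome mean depth must be > 0; sample unusable")
    return float(region_depth) / float(chrom_depth)


def call_diplotype(ratio: float) -> tuple[str, bool]:
    """Classify a normalized depth ratio into a structural diplotype.

    Returns (call, clamped): AA for ratio >= 0.75, AB for 0.25 <= ratio <
    0.75, BB for ratio < 0.25.  Ratios above 1 are clamped into the AA
    class with ``clamped=True`` (duplications are out of scope).
    """
    if ratio < 0:
        raise ValueError("depth ratio must be non-negative")
    if ratio > 1.0:
        return "AA", True
    if ratio >= AA_MIN:
        return "AA", False
    if ratio >= BB_MAX:
        return "AB", False
    return "BB", False


def diplotype_table(
    profiles: DepthProfileSet,
    region: tuple[int, int],
    *,
    exclude_region_from_mean: bool = False,
) -> pd.DataFrame:
    """Per-sample ratio and diplotype call from a depth profile set.

    The chromosome-wide mean by default includes the candidate region (its
    contribution is negligible at chromosome scale); set
    ``exclude_region_from_mean`` to drop it.
    """
    region_mean = profiles.region_mean(region)
    overall = profiles.overall_mean(exclude=region if exclude_region_from_mean else None)
    rows = []
    for sid, rd, cd in zip(profiles.sample_ids, region_mean, overall):
        ratio = normalized_ratio(rd, cd)
        call, clamped = call_diplotype(ratio)
        rows.append((sid, ratio, call, clamped))
    return pd.DataFrame(rows, columns=["sample", "ratio", "call", "clamped"])


def haplotype_frequency(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Frequency of haplotype A by allele counting: (2 nAA + nAB) / 2n."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("diplotype counts must be non-negative")
    total = n_aa + n_ab + n_bb
    if total < 1:
        raise ValueError("at least one individual required")
    return (2 * n_aa + n_ab) / (2 * total)


def hwe_expected(p: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype proportions (p^2, 2p(1-p), (1-p)^2)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("allele frequency must be in [0, 1]")
    q = 1.0 - p
    return (p * p, 2 * p * q, q * q)


def cline_summary(populations: pd.DataFrame) -> dict:
    """Haplotype-A frequency per population and its OLS trend on altitude.

    ``populations`` needs columns population, altitude_m, n_aa, n_ab, n_bb.
    Returns the per-population frequency table plus slope (frequency per
    metre), intercept and r^2 of frequency regressed on altitude.  A
    zero-variance frequency vector yields slope 0, r^2 = 0 and a flag.
    """
    req = {"population", "altitude_m", "n_aa", "n_ab", "n_bb"}
    missing = req - set(populations.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    df = populations.copy()
    df["n"] = df[["n_aa", "n_ab", "n_bb"]].sum(axis=1)
    df["freq_a"] = [
        haplotype_frequency(a, h, b)
        for a, h, b in zip(df["n_aa"], df["n_ab"], df["n_bb"])
    ]
    alt = df["altitude_m"].to_numpy(dtype=float)
    freq = df["freq_a"].to_numpy(dtype=float)
    out = {"table": df, "slope": np.nan, "intercept": np.nan, "r2": np.nan,
           "fit_defined": False, "zero_variance": False}
    if np.unique(alt).size < 2:
        return out
    if np.allclose(freq, freq[0]):
        out.update(slope=0.0, intercept=float(freq[0]), r2=0.0,
                   fit_defined=True, zero_variance=True)
        return out
    fit = stats.linregress(alt, freq)
    out.update(slope=float(fit.slope), intercept=float(fit.intercept),
               r2=float(fit.rvalue**2), fit_defined=True)
    return out
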