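"""Cross-population extended haplotype homozygosity (XP-EHH) selection scan.

EHH at distance d from a core site is the probability that two randomly
drawn haplotypes are identical over every site from the core out to d:

    EHH(d) = sum_g C(n_g, 2) / C(n, 2)

over the groups g of haplotypes with identical alleles from the core to d.
iHH integrates EHH over physical distance (trapezoid rule, truncated where
EHH falls below a cutoff, both flanks summed), and the raw XP-EHH score at
a site is ln(iHH_focal / iHH_reference), standardised to zero mean and unit
variance over all scored sites.  Window summaries use the sliding-window
convention of the altitude scan: 50-kb windows advancing in 10-kb steps,
anchored at coordinate 1, with two-sided empirical-quantile thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "ehh",
    "ihh",
    "xpehh_scan",
    "windowize",
    "empirical_threshold",
]

DEFAULT_EHH_CUTOFF = 0.05
WINDOW_BP = 50_000
STEP_BP = 10_000


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (rows) over ordered sites (columns)."""

    haplotypes: np.ndarray  # n_hap x n_sites, alleles 0/1
    positions: np.ndarray  # bp, strictly increasing
    chrom: str = "15"
    label: str = "focal"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (haplotype x site)")
        if self.positions.shape[0] != self.haplotypes.shape[1]:
            raise ValueError("positions do not match number of sites")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("alleles must be coded 0/1 (phased)")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


def _ehh_series(H: np.ndarray) -> np.ndarray:
    """EHH over columns of H scanned left to right from the (virtual) core.

    H's first column is the site adjacent to the core; entry k of the
    result is EHH after extending through columns 0..k.
    """
    n = H.shape[0]
    pairs_total = n * (n - 1) / 2
    out = np.empty(H.shape[1])
    # group haplotypes by their growing prefix; encode group ids incrementally
    group = np.zeros(n, dtype=np.int64)
    for k in range(H.shape[1]):
        key = group * 2 + H[:, k]
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        out[k] = (counts * (counts - 1) / 2).sum() / pairs_total
    return out


def ehh(
    panel: HaplotypePanel,
    core_site: int,
    direction: str,
    allele: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH from a core site outward, one flank at a time.

    Parameters
    ----------
    core_site
        Column index of the core site.
    direction
        ``"upstream"`` (towards lower positions) or ``"downstream"``.
    allele
        Restrict to haplotypes carrying this allele at the core; ``None``
        uses the whole panel (the XP-EHH convention).

    Returns
    -------
    (positions, ehh_values) for the flank, starting at the core itself
    where EHH is 1 by definition.  Raises if fewer than two haplotypes
    carry the requested core allele (statistic undefined).
    """
    H = panel.haplotypes
    if allele is not None:
        carriers = H[:, core_site] == allele
        if carriers.sum() < 2:
            raise ValueError(
                f"core allele {allele} carried by <2 haplotypes; EHH undefined"
            )
        H = H[carriers]
    if direction == "downstream":
        cols = np.arange(core_site + 1, panel.n_sites)
    elif direction == "upstream":
        cols = np.arange(core_site - 1, -1, -1)
    else:
        raise ValueError("direction must be 'upstream' or 'downstream'")
    pos = np.concatenate([[panel.positions[core_site]], panel.positions[cols]])
    if cols.size == 0:
        return pos, np.array([1.0])
    series = _ehh_series(H[:, cols])
    return pos, np.concatenate([[1.0], series])


def ihh(
    ehh_values: np.ndarray,
    positions: np.ndarray,
    truncation: float = DEFAULT_EHH_CUTOFF,
) -> float:
    """Trapezoidal integral of one EHH flank over physical distance (bp).

    Integration stops at the last point whose EHH is still >= the
    truncation cutoff; a flank with fewer than two usable points has zero
    width and contributes 0.
    """
    e = np.asarray(ehh_values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if e.shape != pos.shape:
        raise ValueError("ehh_values and positions must align")
    below = np.nonzero(e < truncation)[0]
    stop = below[0] if below.size else e.size
    if stop < 2:
        return 0.0
    d = np.abs(pos[:stop] - pos[0])
    return float(np.trapezoid(e[:stop], d))


def _site_ihh(panel: HaplotypePanel, core: int, truncation: float) -> float:
    total = 0.0
    for direction in ("upstream", "downstream"):
        pos, e = ehh(panel, core, direction)
        total += ihh(e, pos, truncation)
    return total


def xpehh_scan(
    focal: HaplotypePanel,
    reference: HaplotypePanel,
    truncation: float = DEFAULT_EHH_CUTOFF,
) -> pd.DataFrame:
    """Per-site raw and normalised XP-EHH between two panels.

    Sites where either population has zero integrated EHH are excluded
    from scoring.  Normalised scores have mean 0 and SD 1 over the scored
    sites by construction.
    """
    if focal.n_sites != reference.n_sites or np.any(
        focal.positions != reference.positions
    ):
        raise ValueError("panels must share an identical site list")
    n_sites = focal.n_sites
    ihh_f = np.array([_site_ihh(focal, j, truncation) for j in range(n_sites)])
    ihh_r = np.array([_site_ihh(reference, j, truncation) for j in range(n_sites)])
    scored = (ihh_f > 0) & (ihh_r > 0)
    if not scored.any():
        raise ValueError("no site has positive iHH in both populations")
    raw = np.full(n_sites, np.nan)
    raw[scored] = np.log(ihh_f[scored] / ihh_r[scored])
    mu = np.nanmean(raw)
    sd = np.nanstd(raw)
    norm = (raw - mu) / sd if sd > 0 else np.where(scored, 0.0, np.nan)
    return pd.DataFrame(
        {
            "chrom": focal.chrom,
            "pos": focal.positions,
            "ihh_focal": ihh_f,
            "ihh_reference": ihh_r,
            "xpehh_raw": raw,
            "xpehh_norm": norm,
            "scored": scored,
        }
    )


def windowize(
    per_site: pd.DataFrame,
    stat_col: str = "xpehh_norm",
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Sliding-window means of a per-site statistic.

    Windows are 1-based inclusive [start, start + window - 1], anchored at
    coordinate 1 and advancing by ``step``; windows containing no scored
    site are omitted.  When ``chrom_length`` is given, windows are further
    required to fit inside [1, chrom_length] (only full windows on the
    chromosome); otherwise every non-empty window on the anchored grid is
    reported.
    """
    df = per_site.dropna(subset=[stat_col]).sort_values("pos")
    if df.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "stat", "n_variants"]
        )
    pos = df["pos"].to_numpy()
    vals = df[stat_col].to_numpy()
    chrom = df["chrom"].iloc[0]
    max_pos = pos.max()
    starts = np.arange(1, max_pos + 1, step)
    if chrom_length is not None:
        starts = starts[starts + window - 1 <= chrom_length]
    rows = []
    for s in starts:
        e = s + window - 1
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="right")
        if hi > lo:
            rows.append((chrom, int(s), int(e), vals[lo:hi].mean(), hi - lo))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat", "n_variants"])


def empirical_threshold(
    window_stats: np.ndarray, quantile: float = 0.01
) -> tuple[float, float]:
    """Two-sided empirical cutoffs capturing the top ``quantile`` of windows.

    The extreme mass is split evenly: lower cutoff at quantile/2, upper at
    1 - quantile/2.  With fewer than 1/quantile windows the quantiles are
    still computed but poorly resolved (a warning is emitted).  The
    degenerate ``quantile = 1.0`` collapses to the observed (min, max).
    """
    x = np.asarray(window_stats, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no window statistics supplied")
    if not (0 < quantile <= 1):
        raise ValueError("quantile must be in (0, 1]")
    if x.size < 1 / quantile:
        import warnings

        warnings.warn(
            f"only {x.size} windows for a {quantile:.1%} threshold; "
            "cutoffs are poorly resolved",
            stacklevel=2,
        )
    if quantile == 1.0:
        return float(x.min()), float(x.max())
    lower = float(np.quantile(x, quantile / 2))
    upper = float(np.quantile(x, 1 - quantile / 2))
    return lower, upper
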